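# avsynch

A virtual-patient bench for accelerometer-based atrial sensing in leadless
pacemakers. The package synthesizes per-cycle intracardiac accelerometer
signals (Ricker-wavelet components A1–A4, with A3+A4 merging into a single
summated event at high sinus rates), drives them through a model of the
device's sensing/pacing state machine, and scores atrioventricular
synchrony (AVS) over Monte Carlo cohorts.

Two generations of automatic A3 Threshold adaptation are modelled — a
per-cycle adaptive rule whose threshold drifts upward during sustained
high-rate episodes, and a daily histogram-percentile rule that learns the
isolated A3 amplitude — together with the three-phase atrial sensing setup
that programs the vector combination, thresholds and A3 window end for
either device variant.

## Layout

| module | contents |
| --- | --- |
| `avsynch.waveform` | Ricker wavelet, A3 lobe-train rendering, beat synthesis |
| `avsynch.virtual_patient` | patient scripts, Monte Carlo beat schedules, synthetic cohorts |
| `avsynch.device_core` | timing cycles, threshold detection, VDD/VDI pacing, two engines |
| `avsynch.threshold_algos` | per-cycle adaptive and daily-histogram A3 Thresholds |
| `avsynch.sensing_setup` | three-phase setup for the `AV` and `AV2` variants |
| `avsynch.metrics_stats` | AVS reports, McNemar paired test, survey arithmetic |
| `avsynch.cli_io` | JSON/CSV serialization, CLI, run manifests |

## CLI

```sh
avsynch make-cohort --n 30 --seed 2024 --out cohort/
avsynch setup --script cohort/VP001.json --variant AV2 --seed 1 --out setup.json
avsynch simulate --script cohort/VP001.json --algo autoplus --duration-min 30 \
    --seed 7 --out events.csv
avsynch compare --cohort cohort/ --seed 0 --out report.json
avsynch survey --out survey.json
```

Every command writes a `*.manifest.json` (config snapshot, input digests,
seed, version) so outputs reproduce bit-for-bit.

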