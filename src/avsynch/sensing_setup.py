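"""Three-phase atrial sensing setup.

The setup test runs in VDI mode (ventricular pacing at the lower rate, no
atrial tracking), so the A4 timing sweeps through the paced cycle and the
device can observe the A3/A4 signals at every phase offset.

* **Phase 1** interleaves the four accelerometer vector combinations,
  collects A3-window maxima and clean (post-window) A4 amplitudes, selects
  the vector combination, finalizes the A3 Threshold and initializes the A4
  Threshold and A3 Window End.
* **Phase 2** fine-tunes the A3 Window End: per cycle, the last time the
  A3 signal exceeds the phase's A4 Threshold (the fixed legacy value 1.2
  m/s^2 for the ``AV`` variant, the phase-1 initialized value for ``AV2``)
  is found; the maximum over cycles, snapped up to the 25 ms grid, becomes
  the Max A3 Window End (Min = Max - 100 ms).
* **Phase 3** finalizes the A4 Threshold from the post-window A4 amplitudes
  observed with the fine-tuned window; identical for both variants.

Quantities the paper leaves unstated (the "large A4" cut, the half-median
threshold rules, the min/max window spread, the isolation discriminator)
are module constants chosen so the published parameter orderings emerge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .device_core import DeviceConfig, snap_to_grid
from .threshold_algos import A3Histogram
from .virtual_patient import VECTOR_COMBOS, PatientScript, modulate_interval
from .waveform import BeatTiming, a3_train, beat_components, effective_a3_end, half_support_ms

#: Legacy fixed A4 Threshold used by the AV variant during phase 2 (m/s^2).
LEGACY_PHASE2_A4_THRESHOLD = 1.2
#: Provisional detection level used during phase-1 data collection.
PROVISIONAL_A4_THRESHOLD = 1.2
#: A two-vector combination is "large" when its clean A4 median reaches this.
A4_SELECT_MIN = 1.5
#: Phase-1 measurement window end (generous; fine-tuned later), ms.
MEASURE_WINDOW_END_MS = 900.0
#: Post-window measurements start this far beyond the window end, ms.
POST_WINDOW_SLACK_MS = 40.0
#: Min A3 Window End sits this far below the Max, ms.
WINDOW_SPREAD_MS = 100.0
#: Device ceiling for the A3 Threshold, m/s^2.
A3_THRESHOLD_CEILING = 6.0

_TWO_VECTOR_ORDER = ("1+2", "1+3", "2+3")


class SetupFailure(RuntimeError):
    """Raised when a setup phase cannot produce a result."""


@dataclass
class PhaseCycleObs:
    """Per-cycle observation collected during a VDI setup phase."""

    combo: str
    a3_amplitude: float
    a3_end_ms: float
    window_max: float
    post_max: Optional[float]  # max beyond the measurement window, if any
    isolated: bool  # A4 observed beyond the window => A3 window was clean
    timing: BeatTiming


@dataclass
class SetupResult:
    """Parameters chosen by the three-phase setup."""

    variant: str
    chosen_vector_combo: str
    a3_threshold: float
    a3_window_end_min_ms: float
    a3_window_end_max_ms: float
    a4_threshold: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chosen_vector_combo not in VECTOR_COMBOS:
            raise ValueError(f"unknown combo {self.chosen_vector_combo!r}")
        if self.a3_window_end_min_ms > self.a3_window_end_max_ms:
            raise ValueError("min window end exceeds max")
        for v in (self.a3_window_end_min_ms, self.a3_window_end_max_ms):
            if abs(v - snap_to_grid(v)) > 1e-6:
                raise ValueError(f"window end {v} not on the 25 ms grid")
        if self.a4_threshold > self.a3_threshold:
            raise ValueError("a4_threshold must not exceed a3_threshold")

    def apply_to(self, config: DeviceConfig) -> DeviceConfig:
        from dataclasses import replace

        return replace(
            config,
            a3_threshold=self.a3_threshold,
            a4_threshold=self.a4_threshold,
            a3_window_end_min_ms=self.a3_window_end_min_ms,
            a3_window_end_max_ms=self.a3_window_end_max_ms,
        )


# ---------------------------------------------------------------------------
# VDI observation pass
# ---------------------------------------------------------------------------


def _signal_max(components, lo: float, hi: float, step: float = 1.0) -> float:
    if hi <= lo:
        return 0.0
    t = np.arange(lo, hi, step)
    out = np.zeros_like(t)
    for c in components:
        out += c.evaluate(t)
    return float(np.max(np.abs(out))) if t.size else 0.0


def observe_vdi_cycles(
    script: PatientScript,
    combo_for_cycle: Callable[[int], str],
    n_cycles: int,
    rng: np.random.Generator,
    config: DeviceConfig,
    measure_window_end_ms: float = MEASURE_WINDOW_END_MS,
) -> list[PhaseCycleObs]:
    """Collect per-cycle setup observations over ``n_cycles`` VDI cycles.

    The ventricle is paced at the lower rate; the atrial clock runs from the
    script's hour-0 sinus interval with the usual modulation, so the A4
    sweeps through the paced cycle.  Per cycle the A3-window maximum (up to
    ``measure_window_end_ms``) and the post-window signal maximum are
    measured; a cycle whose post-window signal crosses the provisional
    detection level is marked *isolated* (its A4 fell beyond the window, so
    the window maximum is an uncontaminated A3 measurement).
    """
    lr = config.lower_rate_interval_ms
    timing = script.timing
    hour0 = script.hourly_sinus_interval_ms[0]
    hs = half_support_ms()

    # Pre-generate the atrial event stream for the whole phase.
    p_times = []
    clock = 0.0
    horizon = n_cycles * lr + 2000.0
    while clock < horizon:
        clock += modulate_interval(hour0, script.interval_variability_fraction, rng)
        p_times.append(clock)
    p_times = np.array(p_times)

    obs: list[PhaseCycleObs] = []
    for k in range(n_cycles):
        combo = combo_for_cycle(k)
        dists = script.combos[combo]
        t0 = k * lr
        a3_amp = dists.a3.sample(rng)
        a3_end = effective_a3_end(timing, lr, rng)
        in_cycle = p_times[(p_times + timing.a4_delay_ms + hs >= t0) &
                           (p_times + timing.a4_delay_ms < t0 + lr)]
        pairs = [(p - t0, dists.a4.sample(rng)) for p in in_cycle]
        comps, _ = beat_components(
            a3_amp, None, None, timing, a3_end_ms=a3_end, extra_p_onsets=pairs
        )
        window_max = _signal_max(comps, config.pvab_ms, measure_window_end_ms)
        post_lo = measure_window_end_ms + POST_WINDOW_SLACK_MS
        post_max = _signal_max(comps, post_lo, lr)
        isolated = post_max >= PROVISIONAL_A4_THRESHOLD
        obs.append(
            PhaseCycleObs(
                combo=combo,
                a3_amplitude=a3_amp,
                a3_end_ms=a3_end,
                window_max=window_max,
                post_max=post_max if post_max > 0 else None,
                isolated=isolated,
                timing=timing,
            )
        )
    return obs


# ---------------------------------------------------------------------------
# Phase rules
# ---------------------------------------------------------------------------


def phase1_select_vector(
    observations: Sequence[PhaseCycleObs], variant: str, margin: float = 1.0
) -> tuple[str, float, float, float]:
    """Vector selection, final A3 Threshold, initial window end / A4 Threshold.

    The two-vector combination with the largest clean-A4 median is chosen
    provided that median reaches :data:`A4_SELECT_MIN`; otherwise the
    three-vector combination is used.  The ``AV`` variant sets the A3
    Threshold from the maximum observed A3-window amplitude (contaminated by
    merged A3+A4 windows); ``AV2`` uses the 95th percentile of isolated-A3
    window maxima, the same logic as its daily adaptation.
    """
    if variant not in ("AV", "AV2"):
        raise ValueError(f"variant must be AV or AV2, got {variant!r}")
    if not observations:
        raise SetupFailure("phase 1 received no observations")

    by_combo: dict[str, list[PhaseCycleObs]] = {c: [] for c in VECTOR_COMBOS}
    for o in observations:
        by_combo[o.combo].append(o)

    def clean_a4_median(combo: str) -> Optional[float]:
        vals = [o.post_max for o in by_combo[combo] if o.isolated and o.post_max]
        return float(np.median(vals)) if vals else None

    best_combo = None
    best_median = -np.inf
    for combo in _TWO_VECTOR_ORDER:
        med = clean_a4_median(combo)
        if med is not None and med >= A4_SELECT_MIN and med > best_median:
            best_combo, best_median = combo, med
    if best_combo is None:
        best_combo = "1+2+3"
        best_median = clean_a4_median("1+2+3") or 0.0

    chosen = by_combo[best_combo]
    if not chosen:
        raise SetupFailure(f"no phase-1 cycles observed for combo {best_combo}")

    a4_initial = max(best_median / 2.0, 1.0) if best_median > 0 else 1.0

    if variant == "AV":
        a3_th = max(o.window_max for o in chosen) + margin
    else:
        hist = A3Histogram()
        isolated = [o.window_max for o in chosen if o.isolated]
        if not isolated:
            # fall back to the legacy rule rather than fail outright
            a3_th = max(o.window_max for o in chosen) + margin
        else:
            for v in isolated:
                hist.add(v)
            a3_th = hist.percentile_nearest_rank(95.0) + margin
    a3_th = min(max(a3_th, a4_initial + 0.2), A3_THRESHOLD_CEILING)

    window_initial = snap_to_grid(max(o.a3_end_ms for o in chosen), up=True)
    return best_combo, float(a3_th), float(window_initial), float(a4_initial)


def _last_a3_exceedance(obs: PhaseCycleObs, threshold: float) -> Optional[float]:
    """Last time the cycle's A3 train (alone) is at or above ``threshold``.

    Detected A4 support is excluded by construction: only the A3 component
    is scanned.  Returns ``None`` when the train never reaches the level.
    """
    lobes = a3_train(obs.a3_amplitude, obs.timing, obs.a3_end_ms)
    if not lobes:
        return None
    lo = min(c.support_start_ms for c in lobes)
    hi = max(c.support_end_ms for c in lobes)
    t = np.arange(lo, hi, 1.0)
    s = np.zeros_like(t)
    for c in lobes:
        s += c.evaluate(t)
    idx = np.flatnonzero(np.abs(s) >= threshold)
    return float(t[idx[-1]]) if idx.size else None


def phase2_window_end(
    vdi_cycle_summaries: Sequence[PhaseCycleObs],
    phase_a4_threshold: float,
    variant: str,
    config: Optional[DeviceConfig] = None,
) -> tuple[float, float, bool]:
    """Fine-tune the A3 Window End from a 2-min VDI pass.

    Returns ``(min_ms, max_ms, flagged)``.  A larger phase threshold reaches
    less deeply into the decaying A3 train, so it shortens the window; the
    AV2 variant passes its phase-1 initialized A4 Threshold here where the
    AV variant used the fixed legacy 1.2 m/s^2.
    """
    cfg = config or DeviceConfig()
    floor = cfg.pvab_ms + 50.0
    ceiling = 1100.0
    last_times = []
    for obs in vdi_cycle_summaries:
        t = _last_a3_exceedance(obs, phase_a4_threshold)
        if t is not None:
            last_times.append(t)
    if not last_times:
        return floor, floor + WINDOW_SPREAD_MS, True
    max_end = snap_to_grid(max(last_times), up=True)
    max_end = float(np.clip(max_end, floor + WINDOW_SPREAD_MS, ceiling))
    min_end = float(np.clip(max_end - WINDOW_SPREAD_MS, floor, ceiling))
    return min_end, max_end, False


def phase3_a4_threshold(
    cycle_summaries: Sequence[PhaseCycleObs],
    window_end_ms: float,
    a3_threshold: float,
    fallback: float,
) -> tuple[float, bool]:
    """Final A4 Threshold: half the median post-window A4 peak, clamped.

    Identical for both variants.  Returns ``(threshold, flagged)`` where
    ``flagged`` marks the no-A4-observed fallback path.
    """
    peaks = [
        o.post_max
        for o in cycle_summaries
        if o.post_max is not None and o.post_max >= PROVISIONAL_A4_THRESHOLD
    ]
    if not peaks:
        return min(max(fallback, 0.8), a3_threshold - 0.2), True
    med = float(np.median(peaks))
    return float(np.clip(med / 2.0, 0.8, a3_threshold - 0.2)), False


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_setup(
    variant: str,
    patient: PatientScript,
    durations_min: tuple[float, float, float] = (20.0, 2.0, 2.0),
    rng: Optional[np.random.Generator] = None,
    config: Optional[DeviceConfig] = None,
) -> SetupResult:
    """Chain setup phases 1-3 over simulated VDI operation.

    Deterministic for a fixed ``(variant, patient, durations, seed)``; the
    same seed run for both variants observes identical Monte Carlo beats, so
    paired variant comparisons isolate the algorithm differences.
    """
    if rng is None:
        rng = np.random.default_rng(patient.seed)
    cfg = config or DeviceConfig()
    lr = cfg.lower_rate_interval_ms

    n1 = max(int(durations_min[0] * 60_000.0 / lr), len(VECTOR_COMBOS))
    obs1 = observe_vdi_cycles(
        patient, lambda k: VECTOR_COMBOS[k % len(VECTOR_COMBOS)], n1, rng, cfg
    )
    combo, a3_th, window_initial, a4_initial = phase1_select_vector(
        obs1, variant, margin=cfg.a3_amplitude_margin
    )

    n2 = max(int(durations_min[1] * 60_000.0 / lr), 10)
    obs2 = observe_vdi_cycles(
        patient, lambda k: combo, n2, rng, cfg,
        measure_window_end_ms=window_initial,
    )
    phase_a4 = LEGACY_PHASE2_A4_THRESHOLD if variant == "AV" else a4_initial
    win_min, win_max, win_flagged = phase2_window_end(obs2, phase_a4, variant, cfg)

    n3 = max(int(durations_min[2] * 60_000.0 / lr), 10)
    obs3 = observe_vdi_cycles(
        patient, lambda k: combo, n3, rng, cfg, measure_window_end_ms=win_max
    )
    a4_th, a4_flagged = phase3_a4_threshold(obs3, win_max, a3_th, a4_initial)

    return SetupResult(
        variant=variant,
        chosen_vector_combo=combo,
        a3_threshold=round(a3_th, 3),
        a3_window_end_min_ms=win_min,
        a3_window_end_max_ms=win_max,
        a4_threshold=round(a4_th, 3),
        diagnostics={
            "phase1_cycles": len(obs1),
            "phase2_cycles": len(obs2),
            "phase3_cycles": len(obs3),
            "initial_a4_threshold": a4_initial,
            "initial_window_end_ms": window_initial,
            "phase2_a4_threshold": phase_a4,
            "phase2_flagged": win_flagged,
            "phase3_flagged": a4_flagged,
        },
    )
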