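"""Per-cycle accelerometer trace synthesis from Ricker-wavelet components.

A cardiac cycle's intracardiac accelerometer signal is modelled as a sum of
Ricker ("Mexican hat") wavelets.  Four component families are rendered:

* ``A1`` and ``A2`` -- ventricular events early in the cycle (inside the
  post-ventricular blanking period, so their exact shape never influences
  atrial detection),
* ``A3`` -- passive ventricular relaxation, rendered as a short train of
  decaying Ricker lobes that terminates at a configurable "signal end" time,
* ``A4`` -- the atrial mechanical contraction, a single Ricker wavelet tied
  to the P-wave onset.

When the A4 wavelet's support begins before the A3 signal end, the two
components are summed sample-wise into a single merged event (flagged
``a7=True`` in the ground truth).

The cycle origin ``t = 0`` is the ventricular event (pace or sense).
All times are milliseconds, all amplitudes m/s^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default peak frequency of every wavelet component, Hz.
DEFAULT_PEAK_FREQUENCY_HZ = 20.0

#: Wavelet support is truncated at |t| <= HALF_SUPPORT_CYCLES / f
#: (the Ricker amplitude is below 1e-5 beyond that point).
HALF_SUPPORT_CYCLES = 2.5

#: Allowed values for the Gaussian jitter applied to the A3 signal end, ms.
A3_END_VARIATION_CHOICES = (0.0, 17.0, 33.0)


def ricker(t_ms, f_hz: float = DEFAULT_PEAK_FREQUENCY_HZ):
    """Dimensionless Ricker wavelet ``[1 - 2*pi^2*f^2*t^2] * exp(-pi^2*f^2*t^2)``.

    Parameters
    ----------
    t_ms:
        Time relative to the wavelet peak, in milliseconds.  Scalar or
        array-like.
    f_hz:
        Peak frequency in Hz; must be positive.

    Returns
    -------
    Amplitude in ``[-2*exp(-3/2), 1]`` (about ``[-0.446, 1]``); an ndarray
    when ``t_ms`` is array-like, otherwise a float.
    """
    if f_hz <= 0:
        raise ValueError(f"peak frequency must be positive, got {f_hz}")
    t_s = np.asarray(t_ms, dtype=float) / 1000.0
    x = (np.pi * f_hz * t_s) ** 2
    out = (1.0 - 2.0 * x) * np.exp(-x)
    if np.isscalar(t_ms):
        return float(out)
    return out


def half_support_ms(f_hz: float = DEFAULT_PEAK_FREQUENCY_HZ) -> float:
    """Half-width of the truncated wavelet support, ms."""
    return 1000.0 * HALF_SUPPORT_CYCLES / f_hz


@dataclass(frozen=True)
class WaveletComponent:
    """One rendered Ricker wavelet.

    ``label`` identifies the component family (A1--A4); an A3 train is a
    sequence of components all labelled ``"A3"``.
    """

    label: str
    peak_amplitude: float
    peak_time_ms: float
    peak_frequency_hz: float = DEFAULT_PEAK_FREQUENCY_HZ

    def __post_init__(self):
        if self.label not in ("A1", "A2", "A3", "A4"):
            raise ValueError(f"unknown component label {self.label!r}")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.peak_frequency_hz <= 0:
            raise ValueError("peak_frequency_hz must be > 0")
        if self.peak_time_ms < 0:
            raise ValueError("peak_time_ms must be >= 0")

    @property
    def support_start_ms(self) -> float:
        return self.peak_time_ms - half_support_ms(self.peak_frequency_hz)

    @property
    def support_end_ms(self) -> float:
        return self.peak_time_ms + half_support_ms(self.peak_frequency_hz)

    def evaluate(self, t_ms) -> np.ndarray:
        """Wavelet value at absolute cycle times ``t_ms`` (support-truncated)."""
        t = np.asarray(t_ms, dtype=float)
        rel = t - self.peak_time_ms
        out = self.peak_amplitude * ricker(rel, self.peak_frequency_hz)
        out = np.where(np.abs(rel) <= half_support_ms(self.peak_frequency_hz), out, 0.0)
        return out


@dataclass(frozen=True)
class BeatTiming:
    """Timing parameters of one synthesized cardiac cycle.

    ``a2_delay_ms`` is measured from the ventricular event to the *start* of
    the A2 wavelet; ``a4_delay_ms`` from P-wave onset to the start of the A4
    wavelet.  The A3 train spans ``[a3_start_ms, a3_signal_end_ms]``: lobes
    are spaced ``a3_lobe_spacing_ms`` apart, the last lobe peaking
    ``a3_peak_offset_ms`` before the signal end, with amplitudes decaying
    geometrically to ``a3_end_fraction`` of the first lobe.
    """

    a2_delay_ms: float = 300.0
    a4_delay_ms: float = 90.0
    a3_signal_end_ms: float = 800.0
    a3_end_variation_sd_ms: float = 0.0
    auto_adjust_a3_end_with_rate: bool = False
    a3_start_ms: float = 500.0
    a3_lobe_spacing_ms: float = 50.0
    a3_peak_offset_ms: float = 40.0
    a3_end_fraction: float = 0.4

    def __post_init__(self):
        for name in ("a2_delay_ms", "a4_delay_ms", "a3_signal_end_ms", "a3_start_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.a3_end_variation_sd_ms not in A3_END_VARIATION_CHOICES:
            raise ValueError(
                f"a3_end_variation_sd_ms must be one of {A3_END_VARIATION_CHOICES}, "
                f"got {self.a3_end_variation_sd_ms}"
            )
        if self.a3_lobe_spacing_ms <= 0:
            raise ValueError("a3_lobe_spacing_ms must be > 0")
        if not 0 < self.a3_end_fraction <= 1:
            raise ValueError("a3_end_fraction must be in (0, 1]")


def effective_a3_end(
    timing: BeatTiming,
    current_rr_ms: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """A3 signal end for one cycle after rate adjustment and jitter.

    With ``auto_adjust_a3_end_with_rate`` enabled the nominal end is scaled
    by ``current_rr_ms / 1000`` for RR intervals below 1000 ms (atrial rate
    above 60 bpm), floored at ``a2_delay_ms + 100``.  Gaussian jitter with
    the configured sd is then added when an ``rng`` is supplied.
    """
    end = timing.a3_signal_end_ms
    if timing.auto_adjust_a3_end_with_rate and current_rr_ms is not None:
        if current_rr_ms < 1000.0:
            end = max(end * current_rr_ms / 1000.0, timing.a2_delay_ms + 100.0)
    if rng is not None and timing.a3_end_variation_sd_ms > 0:
        end = end + rng.normal(0.0, timing.a3_end_variation_sd_ms)
    return max(end, timing.a2_delay_ms + 100.0)


def a3_train(
    amplitude: float,
    timing: BeatTiming,
    a3_end_ms: Optional[float] = None,
    f_hz: float = DEFAULT_PEAK_FREQUENCY_HZ,
) -> list[WaveletComponent]:
    """Decaying Ricker-lobe train representing the A3 signal.

    Lobe peaks run from ``a3_start_ms`` in steps of ``a3_lobe_spacing_ms`` up
    to ``a3_end_ms - a3_peak_offset_ms``; amplitudes decay geometrically from
    ``amplitude`` at the first lobe to ``a3_end_fraction * amplitude`` at the
    last.  A degenerate (very short) A3 yields a single lobe.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return []
    end = timing.a3_signal_end_ms if a3_end_ms is None else a3_end_ms
    last_peak = end - timing.a3_peak_offset_ms
    if last_peak <= timing.a3_start_ms:
        return [WaveletComponent("A3", amplitude, max(last_peak, 1.0), f_hz)]
    # Lobes are anchored at the signal end and walk backwards on a uniform
    # grid; a non-uniform terminal step would let adjacent lobes sum into a
    # spurious bump above the decay envelope.
    n_lobes = int((last_peak - timing.a3_start_ms) // timing.a3_lobe_spacing_ms) + 1
    peaks = last_peak - timing.a3_lobe_spacing_ms * np.arange(n_lobes - 1, -1, -1)
    span = peaks[-1] - peaks[0]
    if span <= 0:
        amps = np.array([amplitude])
    else:
        amps = amplitude * timing.a3_end_fraction ** ((peaks - peaks[0]) / span)
    return [WaveletComponent("A3", float(a), float(p), f_hz) for p, a in zip(peaks, amps)]


# Fixed A1/A2 rendering: both fall inside the post-ventricular blanking
# period, so their sizes never influence detection.
A1_PEAK_MS = 50.0
A1_AMPLITUDE = 3.0
A2_AMPLITUDE = 2.0


def beat_components(
    a3_amplitude: float,
    a4_amplitude: Optional[float],
    p_onset_ms: Optional[float],
    timing: BeatTiming,
    a3_end_ms: Optional[float] = None,
    f_hz: float = DEFAULT_PEAK_FREQUENCY_HZ,
    include_a1_a2: bool = True,
    extra_p_onsets: Sequence[tuple[float, float]] = (),
) -> tuple[list[WaveletComponent], dict]:
    """Standard component list for one cycle plus ground-truth metadata.

    ``p_onset_ms`` is the P-wave onset relative to the cycle's ventricular
    event; the A4 wavelet starts ``a4_delay_ms`` later.  ``extra_p_onsets``
    allows additional ``(p_onset_ms, a4_amplitude)`` pairs when more than one
    atrial event falls inside a long cycle.

    Returns ``(components, meta)`` where ``meta`` records the effective A3
    end, the A4 support start (or None) and whether A3/A4 merged (``a7``).
    """
    hs = half_support_ms(f_hz)
    comps: list[WaveletComponent] = []
    if include_a1_a2:
        comps.append(WaveletComponent("A1", A1_AMPLITUDE, A1_PEAK_MS, f_hz))
        comps.append(WaveletComponent("A2", A2_AMPLITUDE, timing.a2_delay_ms + hs, f_hz))
    end = timing.a3_signal_end_ms if a3_end_ms is None else a3_end_ms
    comps.extend(a3_train(a3_amplitude, timing, end, f_hz))
    a4_support_start = None
    a7 = False
    pairs = []
    if p_onset_ms is not None and a4_amplitude:
        pairs.append((p_onset_ms, a4_amplitude))
    pairs.extend(extra_p_onsets)
    for onset, amp in pairs:
        start = onset + timing.a4_delay_ms
        comps.append(WaveletComponent("A4", amp, start + hs, f_hz))
        if a4_support_start is None or start < a4_support_start:
            a4_support_start = start
        if a3_amplitude > 0 and start < end:
            a7 = True
    meta = {
        "a3_end_ms": end,
        "a4_support_start_ms": a4_support_start,
        "a7": a7,
        "a3_amplitude": a3_amplitude,
        "a4_amplitude": a4_amplitude,
    }
    return comps, meta


@dataclass
class BeatTrace:
    """Synthesized rectified accelerometer samples for one cycle.

    ``samples`` is the rectified (absolute-value) trace, ``raw_samples`` the
    signed sum prior to rectification (kept so linearity can be checked
    before rectification).  ``ground_truth`` records the components actually
    rendered and whether A3/A4 summation occurred.
    """

    samples: np.ndarray
    sample_period_ms: float
    ground_truth: dict = field(default_factory=dict)
    raw_samples: Optional[np.ndarray] = None

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_period_ms

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.sample_period_ms

    def to_csv(self, path) -> None:
        """Two-column export: time_ms, accel_m_s2."""
        arr = np.column_stack([self.times_ms, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_ms,accel_m_s2", comments="")


def synthesize_beat(
    components: Sequence[WaveletComponent],
    timing: BeatTiming,
    p_onset_ms: Optional[float] = None,
    sampling_rate_hz: float = 1000.0,
    rng: Optional[np.random.Generator] = None,
    duration_ms: Optional[float] = None,
    noise_sd: float = 0.0,
) -> BeatTrace:
    """Render one cycle as a rectified sum of scaled Ricker wavelets.

    When ``rng`` is given and ``timing.a3_end_variation_sd_ms > 0``, Gaussian
    jitter is drawn once and applied to the A3 signal end; every A3-labelled
    component is shifted by the same amount so that the rendered train tracks
    the jittered end.  With sd 0 (or ``rng=None``) the synthesis is fully
    deterministic.

    Raises a ``ValueError`` when the sampling rate is below four times the
    highest component peak frequency (aliasing guard).
    """
    components = list(components)
    max_f = max((c.peak_frequency_hz for c in components), default=DEFAULT_PEAK_FREQUENCY_HZ)
    if sampling_rate_hz < 4.0 * max_f:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz is below 4x the peak frequency "
            f"{max_f} Hz; the rendered wavelets would alias"
        )
    if timing.a3_end_variation_sd_ms > 0 and rng is None and any(
        c.label == "A3" for c in components
    ):
        raise ValueError("a3_end_variation_sd_ms > 0 requires an rng")

    a3_end = timing.a3_signal_end_ms
    if rng is not None and timing.a3_end_variation_sd_ms > 0:
        delta = rng.normal(0.0, timing.a3_end_variation_sd_ms)
        a3_end += delta
        components = [
            replace(c, peak_time_ms=max(c.peak_time_ms + delta, 0.0))
            if c.label == "A3"
            else c
            for c in components
        ]

    # A1/A2 overlapping the A3 train is permitted (they simply sum) but is
    # unusual enough to be worth a debug note.
    a3_start = min(
        (c.support_start_ms for c in components if c.label == "A3"), default=np.inf
    )
    for c in components:
        if c.label in ("A1", "A2") and c.support_end_ms > a3_start:
            logger.debug("%s support overlaps the A3 train in this cycle", c.label)

    if duration_ms is None:
        duration_ms = max((c.support_end_ms for c in components), default=0.0) + 50.0
    period = 1000.0 / sampling_rate_hz
    n = int(np.ceil(duration_ms / period))
    t = np.arange(n) * period
    raw = np.zeros(n)
    for c in components:
        raw += c.evaluate(t)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        raw = raw + rng.normal(0.0, noise_sd, size=n)

    a4_start = None
    a7 = False
    for c in components:
        if c.label == "A4":
            start = c.support_start_ms
            if a4_start is None or start < a4_start:
                a4_start = start
            if start < a3_end and any(k.label == "A3" for k in components):
                a7 = True
    gt = {
        "components": [
            {
                "label": c.label,
                "peak_amplitude": c.peak_amplitude,
                "peak_time_ms": c.peak_time_ms,
                "peak_frequency_hz": c.peak_frequency_hz,
            }
            for c in components
        ],
        "a3_end_ms": a3_end,
        "a4_support_start_ms": a4_start,
        "a7": a7,
        "p_onset_ms": p_onset_ms,
    }
    return BeatTrace(
        samples=np.abs(raw), sample_period_ms=period, ground_truth=gt, raw_samples=raw
    )
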