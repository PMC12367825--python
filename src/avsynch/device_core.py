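"""Pacemaker sensing/pacing state machine.

Timing cycles, threshold crossing, atrial-mechanical (AM) detection,
ventricular pace scheduling, VDD/VDI modes and upper-tracking-rate limiting.
Two detection engines are provided:

* a **dense** engine (:func:`run_cycle`) that scans a synthesized 1 kHz
  rectified trace sample by sample -- the validation reference, and
* an **event-level** engine that evaluates the analytic wavelet sum only
  inside the sensing windows and refines crossings by bisection -- used for
  long sessions.

Detection is first-crossing of the rectified signal: within
``[pvab, a3_window_end)`` the first sample at or above the A3 Threshold
raises AM; from the window end until the cycle closes, the first sample at
or above the (lower) A4 Threshold raises AM.  No atrial sensing occurs
during PVAB, and at most one AM is honored per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import waveform
from .virtual_patient import BeatSchedule
from .waveform import BeatTiming, WaveletComponent, beat_components, effective_a3_end

#: Programmable window-end values live on a 25 ms grid.
WINDOW_GRID_MS = 25.0


def snap_to_grid(value_ms: float, up: bool = False) -> float:
    """Snap to the 25 ms parameter grid (nearest by default, ceil if ``up``)."""
    if up:
        return WINDOW_GRID_MS * math.ceil(value_ms / WINDOW_GRID_MS - 1e-9)
    return WINDOW_GRID_MS * round(value_ms / WINDOW_GRID_MS)


@dataclass(frozen=True)
class DeviceConfig:
    """Programmable device parameters (shipped values are the nominals)."""

    mode: str = "VDD"
    pvab_ms: float = 550.0
    upper_tracking_rate_bpm: float = 105.0
    lower_rate_bpm: float = 50.0
    a3_threshold: float = 4.0
    a4_threshold: float = 1.8
    a3_window_end_min_ms: float = 700.0
    a3_window_end_max_ms: float = 800.0
    am_to_vp_delay_ms: float = 20.0
    a3_amplitude_margin: float = 1.0

    def __post_init__(self):
        if self.mode not in ("VDD", "VDI"):
            raise ValueError(f"mode must be VDD or VDI, got {self.mode!r}")
        if not self.pvab_ms < self.a3_window_end_min_ms <= self.a3_window_end_max_ms:
            raise ValueError(
                "require pvab < a3_window_end_min <= a3_window_end_max, got "
                f"({self.pvab_ms}, {self.a3_window_end_min_ms}, {self.a3_window_end_max_ms})"
            )
        for name in ("a3_threshold", "a4_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.a4_threshold > self.a3_threshold:
            raise ValueError("a4_threshold must not exceed a3_threshold")
        for name in ("a3_window_end_min_ms", "a3_window_end_max_ms"):
            v = getattr(self, name)
            if abs(v - snap_to_grid(v)) > 1e-6:
                raise ValueError(f"{name}={v} is not on the {WINDOW_GRID_MS} ms grid")
        if self.upper_tracking_rate_bpm <= self.lower_rate_bpm:
            raise ValueError("upper tracking rate must exceed the lower rate")

    @property
    def lower_rate_interval_ms(self) -> float:
        return 60_000.0 / self.lower_rate_bpm

    @property
    def utr_interval_ms(self) -> float:
        return 60_000.0 / self.upper_tracking_rate_bpm


def a3_window_end_for_rate(config: DeviceConfig, current_rr_ms: float) -> float:
    """Rate-responsive A3 window end.

    Max window end at RR >= 1000 ms, min at RR <= 667 ms, linear in between,
    snapped to the 25 ms grid.
    """
    if current_rr_ms <= 0:
        raise ValueError("current_rr_ms must be > 0")
    lo, hi = config.a3_window_end_min_ms, config.a3_window_end_max_ms
    if current_rr_ms >= 1000.0:
        return hi
    if current_rr_ms <= 667.0:
        return lo
    frac = (current_rr_ms - 667.0) / (1000.0 - 667.0)
    return float(np.clip(snap_to_grid(lo + frac * (hi - lo)), lo, hi))


@dataclass(frozen=True)
class MarkerEvent:
    """Time-stamped device marker (absolute ms)."""

    time_ms: float
    kind: str  # VP, VS, AM, VE, P
    cycle_index: int
    annotation: str = ""

    def __post_init__(self):
        if self.kind not in ("VP", "VS", "AM", "VE", "P"):
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass
class CycleSummary:
    """Per-cycle record used by the threshold algorithms and the metrics."""

    cycle_index: int
    v_time_ms: float
    rr_ms: float
    window_end_ms: float
    a3_window_max: float
    am_time_ms: Optional[float]  # relative to the cycle's V event
    am_in_window: bool
    a3_threshold: float
    a4_threshold: float
    a7: bool
    beat_class: str
    pp_interval_ms: Optional[float]
    a3_end_effective_ms: float


class EventLog:
    """Ordered marker stream plus aligned per-cycle summaries."""

    def __init__(self):
        self.events: list[MarkerEvent] = []
        self.cycles: list[CycleSummary] = []

    def add(self, event: MarkerEvent) -> None:
        self.events.append(event)

    def markers(self, kind: str) -> np.ndarray:
        return np.array([e.time_ms for e in self.events if e.kind == kind])

    def ventricular_times(self) -> np.ndarray:
        return np.array(
            sorted(e.time_ms for e in self.events if e.kind in ("VP", "VS"))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"time_ms": e.time_ms, "kind": e.kind, "cycle": e.cycle_index,
                 "annotation": e.annotation}
                for e in sorted(self.events, key=lambda e: (e.time_ms, e.kind))
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DeviceState:
    """Run-time state carried between cycles."""

    v_prev_ms: float = 0.0
    rr_prev_ms: float = 1000.0
    cycle_index: int = 0


def _first_crossing_dense(samples: np.ndarray, threshold: float) -> Optional[int]:
    idx = np.flatnonzero(samples >= threshold)
    return int(idx[0]) if idx.size else None


def run_cycle(
    config: DeviceConfig,
    state: DeviceState,
    trace: waveform.BeatTrace,
    p_onset_ms: Optional[float] = None,
) -> tuple[list[MarkerEvent], DeviceState, CycleSummary]:
    """Dense-engine processing of one cycle from a synthesized trace.

    The trace's time axis is relative to the cycle's ventricular event.  The
    returned markers are absolute.  Raises on traces shorter than the lower
    rate interval (the device could not complete the escape cycle).
    """
    lr = config.lower_rate_interval_ms
    if trace.duration_ms < lr:
        raise ValueError(
            f"trace spans {trace.duration_ms:.0f} ms but the lower-rate interval "
            f"is {lr:.0f} ms"
        )
    period = trace.sample_period_ms
    window_end = a3_window_end_for_rate(config, state.rr_prev_ms)
    i_pvab = int(math.ceil(config.pvab_ms / period))
    i_win = int(math.ceil(window_end / period))
    i_lr = int(math.ceil(lr / period))

    a3_seg = trace.samples[i_pvab:i_win]
    a3_window_max = float(a3_seg.max()) if a3_seg.size else 0.0
    am_rel = None
    am_in_window = False
    hit = _first_crossing_dense(a3_seg, config.a3_threshold)
    if hit is not None:
        am_rel = (i_pvab + hit) * period
        am_in_window = True
    else:
        hit = _first_crossing_dense(trace.samples[i_win:i_lr], config.a4_threshold)
        if hit is not None:
            am_rel = (i_win + hit) * period

    markers, new_state, summary = _close_cycle(
        config, state, window_end, a3_window_max, am_rel, am_in_window,
        vs_rel=None, beat_class="sinus", pp_interval=None,
        a3_end_eff=trace.ground_truth.get("a3_end_ms", float("nan")),
        a7=bool(trace.ground_truth.get("a7", False)),
    )
    return markers, new_state, summary


def _close_cycle(
    config: DeviceConfig,
    state: DeviceState,
    window_end: float,
    a3_window_max: float,
    am_rel: Optional[float],
    am_in_window: bool,
    vs_rel: Optional[float],
    beat_class: str,
    pp_interval: Optional[float],
    a3_end_eff: float,
    a7: bool,
) -> tuple[list[MarkerEvent], DeviceState, CycleSummary]:
    """Shared cycle bookkeeping: VP scheduling, markers, state advance."""
    lr = config.lower_rate_interval_ms
    if config.mode == "VDD" and am_rel is not None:
        vp_rel = am_rel + config.am_to_vp_delay_ms
        vp_rel = max(vp_rel, config.utr_interval_ms)  # tracking limited at UTR
        vp_rel = min(vp_rel, lr)
    else:
        vp_rel = lr
    kind = "VP"
    v_next_rel = vp_rel
    if vs_rel is not None and vs_rel < vp_rel:
        v_next_rel = vs_rel
        kind = "VS"

    t0 = state.v_prev_ms
    cyc = state.cycle_index
    markers = []
    if am_rel is not None and am_rel < v_next_rel:
        markers.append(MarkerEvent(t0 + am_rel, "AM", cyc, f"{a3_window_max:.2f}"))
    else:
        am_rel = am_rel if am_rel is not None and am_rel < v_next_rel else None
    if window_end < v_next_rel:
        markers.append(MarkerEvent(t0 + window_end, "VE", cyc))
    markers.append(MarkerEvent(t0 + v_next_rel, kind, cyc))
    markers.sort(key=lambda m: m.time_ms)

    summary = CycleSummary(
        cycle_index=cyc,
        v_time_ms=t0,
        rr_ms=v_next_rel,
        window_end_ms=window_end,
        a3_window_max=a3_window_max,
        am_time_ms=am_rel,
        am_in_window=am_in_window if am_rel is not None else False,
        a3_threshold=config.a3_threshold,
        a4_threshold=config.a4_threshold,
        a7=a7,
        beat_class=beat_class,
        pp_interval_ms=pp_interval,
        a3_end_effective_ms=a3_end_eff,
    )
    new_state = DeviceState(
        v_prev_ms=t0 + v_next_rel, rr_prev_ms=v_next_rel, cycle_index=cyc + 1
    )
    return markers, new_state, summary


# ---------------------------------------------------------------------------
# Event-level engine
# ---------------------------------------------------------------------------

_PROBE_STEP_MS = 1.0
_REFINE_TOL_MS = 0.01


def _signal(components: Sequence[WaveletComponent], t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for c in components:
        out += c.evaluate(t)
    return np.abs(out)


def _refine_crossing(
    components: Sequence[WaveletComponent], threshold: float, lo: float, hi: float
) -> float:
    """Bisection on |analytic sum| - threshold between a sub- and supra point."""
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if float(_signal(components, np.array([mid]))[0]) >= threshold:
            hi = mid
        else:
            lo = mid
        if hi - lo < _REFINE_TOL_MS:
            break
    return hi


def sense_cycle_analytic(
    components: Sequence[WaveletComponent],
    config: DeviceConfig,
    window_end_ms: float,
    horizon_ms: float,
) -> tuple[float, Optional[float], bool]:
    """Event-level detection for one cycle.

    Evaluates the analytic wavelet sum on a coarse probe grid restricted to
    the sensing windows and refines the first supra-threshold crossing by
    bisection.  Returns ``(a3_window_max, am_time_rel or None,
    am_in_window)``.
    """
    t_win = np.arange(config.pvab_ms, window_end_ms, _PROBE_STEP_MS)
    s_win = _signal(components, t_win) if t_win.size else np.array([])
    a3_window_max = float(s_win.max()) if s_win.size else 0.0
    hit = np.flatnonzero(s_win >= config.a3_threshold) if s_win.size else np.array([])
    if hit.size:
        i = int(hit[0])
        if i == 0:
            return a3_window_max, float(t_win[0]), True
        am = _refine_crossing(components, config.a3_threshold, t_win[i - 1], t_win[i])
        return a3_window_max, am, True
    t_post = np.arange(window_end_ms, horizon_ms, _PROBE_STEP_MS)
    s_post = _signal(components, t_post) if t_post.size else np.array([])
    hit = np.flatnonzero(s_post >= config.a4_threshold) if s_post.size else np.array([])
    if hit.size:
        i = int(hit[0])
        if i == 0:
            return a3_window_max, float(t_post[0]), False
        am = _refine_crossing(components, config.a4_threshold, t_post[i - 1], t_post[i])
        return a3_window_max, am, False
    return a3_window_max, None, False


def run_session(
    config: DeviceConfig,
    schedule: BeatSchedule,
    timing: BeatTiming,
    threshold_algo=None,
    engine: str = "event",
    sampling_rate_hz: float = 1000.0,
    rng: Optional[np.random.Generator] = None,
) -> EventLog:
    """Process a beat schedule through the device state machine.

    ``threshold_algo``, when given, must expose
    ``update(summary, config, now_ms) -> float`` returning the A3 Threshold
    to use from the next cycle on (see :mod:`avsynch.threshold_algos`).
    P-wave onsets from the schedule are logged as ``P`` markers so synchrony
    can be scored afterwards.  Deterministic for fixed
    ``(config, schedule, algo state, rng seed)``.
    """
    if len(schedule.beats) == 0:
        raise ValueError("schedule is empty")
    if engine not in ("event", "dense"):
        raise ValueError(f"unknown engine {engine!r}")
    if timing.a3_end_variation_sd_ms > 0 and rng is None:
        raise ValueError("schedule timing uses A3 end jitter; an rng is required")

    log = EventLog()
    state = DeviceState(v_prev_ms=0.0, rr_prev_ms=1000.0, cycle_index=0)
    a3_th = config.a3_threshold

    # Atrial events (absolute) and ectopic ventricular events.
    p_events = [
        (b.p_onset_ms, b.a4_amplitude, b.beat_class)
        for b in schedule.beats
        if b.p_onset_ms is not None
    ]
    vs_events = [b.vs_time_ms for b in schedule.beats if b.vs_time_ms is not None]
    a3_amps = [b.a3_amplitude for b in schedule.beats]
    for t_p, _, _ in p_events:
        log.add(MarkerEvent(t_p, "P", -1))

    hs = waveform.half_support_ms()
    p_idx = 0
    vs_idx = 0
    beat_idx = 0
    lr = config.lower_rate_interval_ms
    while state.v_prev_ms < schedule.duration_ms:
        t0 = state.v_prev_ms
        cfg = replace(config, a3_threshold=max(a3_th, config.a4_threshold))
        window_end = a3_window_end_for_rate(cfg, state.rr_prev_ms)

        # A4 components: every P whose wavelet support intersects this cycle.
        while p_idx < len(p_events) and p_events[p_idx][0] + timing.a4_delay_ms + 2 * hs < t0:
            p_idx += 1
        pairs = []
        beat_class = "sinus"
        pp_interval = None
        j = p_idx
        while j < len(p_events) and p_events[j][0] + timing.a4_delay_ms < t0 + lr:
            t_p, a4_amp, cls = p_events[j]
            # A4s peaking before the cycle origin end inside PVAB; skip them.
            if t_p - t0 + timing.a4_delay_ms + hs >= 0:
                pairs.append((t_p - t0, a4_amp))
            if beat_class == "sinus" and cls == "PAC":
                beat_class = "PAC"
            if j > 0:
                pp_interval = t_p - p_events[j - 1][0]
            j += 1

        a3_amp = a3_amps[min(beat_idx, len(a3_amps) - 1)]
        a3_end = effective_a3_end(timing, state.rr_prev_ms, rng)
        comps, meta = beat_components(
            a3_amp, None, None, timing, a3_end_ms=a3_end, extra_p_onsets=pairs
        )

        # Ectopic ventricular event pending in this cycle?
        while vs_idx < len(vs_events) and vs_events[vs_idx] <= t0:
            vs_idx += 1
        vs_rel = None
        if vs_idx < len(vs_events) and vs_events[vs_idx] < t0 + lr:
            vs_rel = vs_events[vs_idx] - t0
            beat_class = "PVC"

        if engine == "event":
            a3_max, am_rel, am_in_win = sense_cycle_analytic(
                comps, cfg, window_end, lr + _PROBE_STEP_MS
            )
        else:
            trace = waveform.synthesize_beat(
                comps, timing, sampling_rate_hz=sampling_rate_hz,
                duration_ms=lr + 2.0,
            )
            period = trace.sample_period_ms
            i_pvab = int(math.ceil(cfg.pvab_ms / period))
            i_win = int(math.ceil(window_end / period))
            i_lr = int(math.ceil(lr / period))
            seg = trace.samples[i_pvab:i_win]
            a3_max = float(seg.max()) if seg.size else 0.0
            am_rel = None
            am_in_win = False
            hit = _first_crossing_dense(seg, cfg.a3_threshold)
            if hit is not None:
                am_rel = (i_pvab + hit) * period
                am_in_win = True
            else:
                hit = _first_crossing_dense(
                    trace.samples[i_win:i_lr], cfg.a4_threshold
                )
                if hit is not None:
                    am_rel = (i_win + hit) * period

        markers, state, summary = _close_cycle(
            cfg, state, window_end, a3_max, am_rel, am_in_win,
            vs_rel=vs_rel, beat_class=beat_class, pp_interval=pp_interval,
            a3_end_eff=a3_end, a7=meta["a7"],
        )
        for m in markers:
            log.add(m)
        log.cycles.append(summary)
        beat_idx += 1

        if threshold_algo is not None:
            a3_th = float(threshold_algo.update(summary, config, state.v_prev_ms))

    return log
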