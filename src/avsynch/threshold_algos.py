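"""Automatic A3 Threshold adaptation.

Two generations are modelled:

* **Auto** (first generation) -- a per-cycle adaptive rule that tracks the
  recent A3-window maxima.  The update law here (8-cycle max plus a 0.5
  m/s^2 margin, clamped) is a behavioral emulation: it reproduces the
  documented failure mode -- sustained merged A3+A4 windows during high
  sinus rates drag the threshold up until the merged signal itself is
  undersensed -- with every constant exposed for configuration.
* **Auto+** (second generation) -- accumulates the A3-window maximum of
  *isolated* A3 cycles into an amplitude histogram and, once per "day",
  sets the threshold to the histogram's nearest-rank 95th percentile plus a
  programmable amplitude margin (nominal 1.0 m/s^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .device_core import CycleSummary, DeviceConfig

logger = logging.getLogger(__name__)

#: Auto rule constants (emulation; see module docstring).
AUTO_UPDATE_PERIOD_CYCLES = 8
AUTO_MARGIN = 0.5
AUTO_THRESHOLD_CEILING = 6.0

#: Auto+ isolation guard: a cycle qualifies as isolated when its AM fell at
#: least this far beyond the window end (the A4 landed outside the window) …
ISOLATION_AM_SLACK_MS = 40.0
#: … or the instantaneous atrial rate was below this (no A3/A4 merge expected).
ISOLATION_RATE_BPM = 80.0

MS_PER_DAY = 86_400_000.0


@dataclass
class A3Histogram:
    """Fixed-grid amplitude histogram (0–10 m/s^2, 0.1 m/s^2 bins).

    The bin width resolves the worked adaptation example exactly: all mass
    at 2.1 m/s^2 with a 1.0 m/s^2 margin yields a 3.1 m/s^2 threshold.
    """

    lo: float = 0.0
    hi: float = 10.0
    bin_width: float = 0.1
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = int(round((self.hi - self.lo) / self.bin_width))
        if self.counts is None:
            self.counts = np.zeros(n, dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.size != n:
                raise ValueError("counts length inconsistent with bin grid")

    @property
    def bin_edges(self) -> np.ndarray:
        return self.lo + self.bin_width * np.arange(self.counts.size + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def add(self, amplitude: float) -> None:
        if amplitude < self.lo:
            amplitude = self.lo
        idx = int(math.floor((amplitude - self.lo) / self.bin_width + 1e-9))
        if idx >= self.counts.size:
            logger.info(
                "amplitude %.2f above histogram range; clipped to top bin", amplitude
            )
            idx = self.counts.size - 1
        self.counts[idx] += 1

    def percentile_nearest_rank(self, q: float) -> float:
        """Nearest-rank percentile; returns the bin's lower edge."""
        if self.total == 0:
            raise ValueError("empty histogram has no percentile")
        rank = max(1, math.ceil(q / 100.0 * self.total))
        cum = np.cumsum(self.counts)
        idx = int(np.searchsorted(cum, rank))
        return float(self.lo + idx * self.bin_width)

    def reset(self) -> None:
        self.counts[:] = 0


@dataclass(frozen=True)
class AutoState:
    """State of the first-generation per-cycle adaptive rule."""

    buffer: tuple[float, ...] = ()
    threshold: float = 4.0


def auto_av_update(state: AutoState, cycle_a3_max: float, config: DeviceConfig) -> AutoState:
    """One cycle of the modeled first-generation Auto rule.

    The cycle's A3-window maximum is appended to an 8-cycle buffer; when the
    buffer fills, the threshold becomes ``max(buffer) + 0.5`` clamped to
    ``[a4_threshold + 0.5, 6.0]`` and the buffer restarts.  Sustained merged
    (A7-contaminated) windows therefore drive the threshold up -- the
    documented failure mode.
    """
    if cycle_a3_max < 0:
        raise ValueError("cycle_a3_max must be >= 0")
    buffer = state.buffer + (float(cycle_a3_max),)
    if len(buffer) < AUTO_UPDATE_PERIOD_CYCLES:
        return replace(state, buffer=buffer)
    new_th = max(buffer) + AUTO_MARGIN
    new_th = min(max(new_th, config.a4_threshold + AUTO_MARGIN), AUTO_THRESHOLD_CEILING)
    return AutoState(buffer=(), threshold=new_th)


def cycle_is_isolated(summary: CycleSummary, config: DeviceConfig) -> bool:
    """Isolation guard for the Auto+ histogram.

    A cycle's A3-window maximum is taken to be an isolated A3 measurement
    when the beat was not ectopic and either the AM fell clearly beyond the
    window end (the A4 was sensed outside the A3 window) or the
    instantaneous atrial rate was below 80 bpm.
    """
    if summary.beat_class != "sinus":
        return False
    if (
        summary.am_time_ms is not None
        and summary.am_time_ms > summary.window_end_ms + ISOLATION_AM_SLACK_MS
    ):
        return True
    if summary.pp_interval_ms is not None:
        rate_bpm = 60_000.0 / summary.pp_interval_ms
        if rate_bpm < ISOLATION_RATE_BPM:
            return True
    return False


def av2_accumulate(
    hist: A3Histogram, cycle_summary: CycleSummary, config: DeviceConfig
) -> A3Histogram:
    """Bin the cycle's A3-window maximum when the cycle qualifies as isolated."""
    if cycle_is_isolated(cycle_summary, config):
        hist.add(cycle_summary.a3_window_max)
    return hist


def av2_daily_update(hist: A3Histogram, margin: float) -> Optional[float]:
    """Daily threshold from the accumulated histogram.

    Returns ``nearest-rank 95th percentile + margin`` and resets the
    histogram for the next day; ``None`` (retain previous threshold) when
    the histogram is empty.
    """
    if hist.total == 0:
        logger.info("empty A3 histogram at daily update; threshold retained")
        return None
    th = hist.percentile_nearest_rank(95.0) + margin
    hist.reset()
    return th


# ---------------------------------------------------------------------------
# Session-facing wrappers (the ``threshold_algo`` protocol of run_session)
# ---------------------------------------------------------------------------


class AutoA3Threshold:
    """Per-cycle adaptive threshold (first generation, modeled)."""

    name = "auto"

    def __init__(self, initial_threshold: Optional[float] = None):
        self._initial = initial_threshold
        self.state: Optional[AutoState] = None
        self.trajectory: list[tuple[float, float]] = []

    def update(self, summary: CycleSummary, config: DeviceConfig, now_ms: float) -> float:
        if self.state is None:
            self.state = AutoState(
                threshold=self._initial if self._initial is not None else config.a3_threshold
            )
        self.state = auto_av_update(self.state, summary.a3_window_max, config)
        self.trajectory.append((now_ms, self.state.threshold))
        return self.state.threshold


class AutoPlusA3Threshold:
    """Daily histogram-percentile threshold (second generation).

    ``day_length_ms`` is configurable (nominally 24 h) so desk-scale tests
    and short simulations still exercise the daily update.
    """

    name = "autoplus"

    def __init__(
        self,
        day_length_ms: float = MS_PER_DAY,
        margin: float = 1.0,
        initial_threshold: Optional[float] = None,
    ):
        if day_length_ms <= 0:
            raise ValueError("day_length_ms must be > 0")
        self.day_length_ms = day_length_ms
        self.margin = margin
        self.hist = A3Histogram()
        self._initial = initial_threshold
        self.threshold: Optional[float] = initial_threshold
        self._next_update_ms = day_length_ms
        self.trajectory: list[tuple[float, float]] = []

    def update(self, summary: CycleSummary, config: DeviceConfig, now_ms: float) -> float:
        if self.threshold is None:
            self.threshold = config.a3_threshold
        av2_accumulate(self.hist, summary, config)
        while now_ms >= self._next_update_ms:
            new_th = av2_daily_update(self.hist, self.margin)
            if new_th is not None:
                self.threshold = new_th
            self._next_update_ms += self.day_length_ms
        self.trajectory.append((now_ms, self.threshold))
        return self.threshold


def trajectory_frame(algos: dict[str, object]):
    """Threshold trajectories as a tidy table (time_ms, algo, threshold)."""
    import pandas as pd

    rows = []
    for name, algo in algos.items():
        for t, th in getattr(algo, "trajectory", []):
            rows.append({"time_ms": t, "algo": name, "threshold": th})
    return pd.DataFrame(rows)
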