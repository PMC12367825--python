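"""Synchrony metrics, paired cohort statistics and survey arithmetic.

A cardiac cycle is *synchronous* when a ventricular marker follows the
P-wave onset within 300 ms.  AVS (atrioventricular synchrony) is the
fraction of scored cycles that are synchronous; cycles without a P-wave
(PVCs) are excluded from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .device_core import EventLog

#: Sinus-rate bin edges for reporting, bpm.  The 80-100 bpm aggregate is the
#: headline comparison band.
RATE_BIN_EDGES_BPM = (0.0, 60.0, 70.0, 80.0, 90.0, 100.0, math.inf)
RATE_BIN_LABELS = ("<60", "60-70", "70-80", "80-90", "90-100", ">=100")

SYNC_WINDOW_MS = 300.0


class UndefinedAVSError(ValueError):
    """Raised when a log contains no P markers to score."""


@dataclass
class AVSReport:
    """AVS summary for one session."""

    overall_avs: float
    n_scored: int
    per_bin: dict[str, tuple[Optional[float], int]]
    band_80_100: tuple[Optional[float], int]

    def as_dict(self) -> dict:
        return {
            "overall_avs": self.overall_avs,
            "n_scored": self.n_scored,
            "per_bin": {k: {"avs": v[0], "n": v[1]} for k, v in self.per_bin.items()},
            "band_80_100": {"avs": self.band_80_100[0], "n": self.band_80_100[1]},
        }


def compute_avs(
    log: EventLog | tuple[Sequence[float], Sequence[float]],
    window_ms: float = SYNC_WINDOW_MS,
) -> AVSReport:
    """Score synchrony by matching each P onset to the first later V event.

    ``log`` is either an :class:`EventLog` or a ``(p_times, v_times)`` pair.
    A P with no subsequent V event within the log span is left unscored.
    The rate bin of each scored cycle comes from the preceding P-P interval
    (the first P has no rate bin but still counts toward the overall AVS).
    """
    if isinstance(log, EventLog):
        p_times = np.sort(log.markers("P"))
        v_times = log.ventricular_times()
    else:
        p_times = np.sort(np.asarray(log[0], dtype=float))
        v_times = np.sort(np.asarray(log[1], dtype=float))
    if p_times.size == 0:
        raise UndefinedAVSError("log contains no P markers; AVS undefined")

    idx = np.searchsorted(v_times, p_times, side="left")
    scored = idx < v_times.size
    deltas = np.full(p_times.size, np.nan)
    deltas[scored] = v_times[idx[scored]] - p_times[scored]
    sync = deltas <= window_ms

    pp = np.diff(p_times)
    rate_bpm = np.full(p_times.size, np.nan)
    rate_bpm[1:] = 60_000.0 / pp

    n_scored = int(np.count_nonzero(scored))
    overall = float(np.count_nonzero(sync[scored]) / n_scored) if n_scored else float("nan")

    per_bin: dict[str, tuple[Optional[float], int]] = {}
    for lo, hi, label in zip(RATE_BIN_EDGES_BPM[:-1], RATE_BIN_EDGES_BPM[1:], RATE_BIN_LABELS):
        mask = scored & (rate_bpm >= lo) & (rate_bpm < hi)
        n = int(np.count_nonzero(mask))
        per_bin[label] = (float(np.count_nonzero(sync[mask]) / n) if n else None, n)

    band_mask = scored & (rate_bpm >= 80.0) & (rate_bpm < 100.0)
    n_band = int(np.count_nonzero(band_mask))
    band = (float(np.count_nonzero(sync[band_mask]) / n_band) if n_band else None, n_band)

    return AVSReport(overall_avs=overall, n_scored=n_scored, per_bin=per_bin,
                     band_80_100=band)


def mcnemar_paired(b: int, c: int) -> tuple[float, float]:
    """Paired-proportion test on the discordant counts.

    ``b`` and ``c`` are the two discordant cell counts.  For ``b + c < 25``
    the exact two-sided binomial test is used (statistic ``|b - c|``); for
    larger counts, the chi-square statistic with continuity correction
    ``(|b - c| - 1)^2 / (b + c)``.  ``b == c == 0`` returns ``p = 1`` by
    convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if n < 25:
        k = min(b, c)
        p = 2.0 * float(sps.binom.cdf(k, n, 0.5))
        if b == c:  # the middle term would be double-counted
            p -= float(sps.binom.pmf(k, n, 0.5))
        return float(abs(b - c)), min(p, 1.0)
    stat = (abs(b - c) - 1.0) ** 2 / n
    return float(stat), float(sps.chi2.sf(stat, df=1))


def proportion_above(values: Sequence[float], cutoff: float = 0.70) -> float:
    """Fraction of per-patient values strictly above ``cutoff``."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty cohort")
    return float(np.count_nonzero(vals > cutoff) / vals.size)


def paired_discordance(
    values_a: Sequence[float], values_b: Sequence[float], cutoff: float = 0.70
) -> tuple[int, int]:
    """Discordant counts for above-cutoff status between paired runs."""
    a = np.asarray(values_a) > cutoff
    b = np.asarray(values_b) > cutoff
    return int(np.count_nonzero(a & ~b)), int(np.count_nonzero(~a & b))


def bootstrap_mean_ci(
    values: Sequence[float],
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Patient-level percentile bootstrap CI for the cohort mean."""
    rng = rng or np.random.default_rng(0)
    vals = np.asarray(values, dtype=float)
    means = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
    return (
        float(np.quantile(means, alpha / 2)),
        float(np.quantile(means, 1 - alpha / 2)),
    )


# ---------------------------------------------------------------------------
# Survey arithmetic
# ---------------------------------------------------------------------------

SURVEY_BINS = ("<5", "5-10", "11-20", ">20")
#: Midpoint (min) assigned to each response bin; 25 for the open-ended bin.
SURVEY_MIDPOINTS_MIN = {"<5": 2.5, "5-10": 7.5, "11-20": 15.5, ">20": 25.0}


@dataclass(frozen=True)
class SurveyTable:
    """Response percentages for one device over the four time bins."""

    device: str
    percentages: tuple[float, float, float, float]
    n_responses: Optional[int] = None

    def __post_init__(self):
        if len(self.percentages) != len(SURVEY_BINS):
            raise ValueError(f"need {len(SURVEY_BINS)} percentages")
        total = sum(self.percentages)
        if total > 100.0 + 1e-9:
            raise ValueError(f"percentages sum to {total} > 100")

    def median_bin(self) -> str:
        """First bin at which the cumulative percentage reaches 50%."""
        cum = 0.0
        for label, pct in zip(SURVEY_BINS, self.percentages):
            cum += pct
            if cum >= 50.0:
                return label
        raise ValueError("cumulative percentages never reach 50%")

    def median_midpoint_min(self) -> float:
        return SURVEY_MIDPOINTS_MIN[self.median_bin()]


@dataclass(frozen=True)
class SurveySummary:
    median_bin: dict[str, str]
    median_midpoint_min: dict[str, float]
    saving_per_patient_min: float
    hours_saved_per_100_implants: float


def survey_summary(baseline: SurveyTable, comparison: SurveyTable) -> SurveySummary:
    """Median check-time bins, per-patient saving and clinic-hours arithmetic.

    The saving is ``baseline median midpoint - comparison median midpoint``
    (minutes); the projected clinic time saved per 100 implants is that
    difference times 100, converted to hours and rounded to one decimal.
    """
    m_base = baseline.median_midpoint_min()
    m_comp = comparison.median_midpoint_min()
    saving = m_base - m_comp
    hours = round(saving * 100.0 / 60.0, 1)
    return SurveySummary(
        median_bin={baseline.device: baseline.median_bin(),
                    comparison.device: comparison.median_bin()},
        median_midpoint_min={baseline.device: m_base, comparison.device: m_comp},
        saving_per_patient_min=saving,
        hours_saved_per_100_implants=hours,
    )
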