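"""Raw binocular recordings -> baseline-corrected pupil-change timecourses.

The stage order is fixed: eye-to-eye regression imputation, binocular
averaging, 60->10 Hz downsampling, missingness-based exclusion, rolling
median filtering, linear blink interpolation, baseline subtraction.
Missing data are NaN throughout; observed values are never overwritten by
any cleaning step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import PreprocessConfig
from .simulate import RawRecording

__all__ = [
    "CleanTimecourse",
    "ExclusionReport",
    "regress_eyes",
    "mean_pupil",
    "downsample",
    "exclude_by_missingness",
    "median_filter",
    "interpolate_gaps",
    "baseline_correct",
    "preprocess",
]


@dataclass
class CleanTimecourse:
    """One participant x one block of baseline-corrected pupil change (mm)."""

    participant_id: str
    group_label: str
    block_id: int
    time_s: np.ndarray      # uniform 10 Hz grid, t=0 at trial onset
    dpd_mm: np.ndarray      # NaN = missing
    baseline_mm: float


@dataclass
class ExclusionReport:
    """Bookkeeping of everything dropped during preprocessing."""

    excluded_trials: list = field(default_factory=list)       # dicts
    excluded_participants: list = field(default_factory=list)  # dicts
    warnings: list = field(default_factory=list)

    def add_trial(self, participant_id: str, block_id: int, reason: str,
                  missing_fraction: float) -> None:
        self.excluded_trials.append({
            "participant_id": participant_id,
            "block_id": block_id,
            "reason": reason,
            "missing_fraction": float(missing_fraction),
        })

    def add_participant(self, participant_id: str, reason: str,
                        missing_fraction: float) -> None:
        self.excluded_participants.append({
            "participant_id": participant_id,
            "reason": reason,
            "missing_fraction": float(missing_fraction),
        })

    def to_dict(self) -> dict:
        return {
            "excluded_trials": self.excluded_trials,
            "excluded_participants": self.excluded_participants,
            "warnings": self.warnings,
        }


def regress_eyes(left: np.ndarray, right: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cross-impute one-eye-missing samples via OLS between the eyes.

    Fits left~right and right~left on jointly valid samples and fills
    samples where exactly one eye is missing from the corresponding fit.
    Samples where both eyes are missing stay missing; observed values are
    never altered.  With fewer than two jointly valid samples the inputs
    are returned unchanged (with a warning).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must have equal length")
    both = ~np.isnan(left) & ~np.isnan(right)
    if both.sum() < 2:
        warnings.warn("fewer than 2 jointly valid samples; skipping eye regression")
        return left.copy(), right.copy()

    lf, rf = left.copy(), right.copy()
    only_left = ~np.isnan(left) & np.isnan(right)
    only_right = np.isnan(left) & ~np.isnan(right)

    def fit(x, y):
        # OLS y ~ x on jointly-valid samples; constant x degenerates to mean
        if np.ptp(x[both]) == 0:
            return 0.0, float(np.mean(y[both]))
        slope, intercept = np.polyfit(x[both], y[both], 1)
        return float(slope), float(intercept)

    if only_right.any():
        slope, intercept = fit(right, left)
        lf[only_right] = slope * right[only_right] + intercept
    if only_left.any():
        slope, intercept = fit(left, right)
        rf[only_left] = slope * left[only_left] + intercept
    return lf, rf


def mean_pupil(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Per-sample mean of the available eyes; NaN only where both missing."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must have equal length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack([left, right]), axis=0)


def downsample(series: np.ndarray, factor: int = 6) -> np.ndarray:
    """Average non-overlapping bins of ``factor`` samples.

    The bin value is the mean of its non-missing members and is missing only
    when all members are missing.  Bin timestamps are anchored at the bin
    start.  A trailing partial bin is dropped.
    """
    series = np.asarray(series, dtype=float)
    n_bins = len(series) // factor
    if n_bins == 0:
        return np.array([])
    chunk = series[: n_bins * factor].reshape(n_bins, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(chunk, axis=1)


def missing_fraction(series: np.ndarray) -> float:
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        return 1.0
    return float(np.isnan(series).mean())


def exclude_by_missingness(
    trials: Sequence[dict],
    cfg: PreprocessConfig,
    report: ExclusionReport | None = None,
) -> tuple[list[dict], ExclusionReport]:
    """Drop trials, then participants, whose missing fraction exceeds the cap.

    ``trials`` entries are dicts with keys participant_id, group_label,
    block_id, series (the 10 Hz mean-pupil series, before interpolation).
    Exclusion uses strict inequality: a trial at exactly the threshold is
    kept.  The participant-level fraction pools all of that participant's
    samples, including those in already-excluded trials.
    """
    report = report if report is not None else ExclusionReport()

    surviving: list[dict] = []
    for tr in trials:
        frac = missing_fraction(tr["series"])
        if frac > cfg.trial_missing_max:
            report.add_trial(tr["participant_id"], tr["block_id"],
                             "missing_fraction", frac)
        else:
            surviving.append(tr)

    by_participant: dict[str, list[dict]] = {}
    for tr in trials:
        by_participant.setdefault(tr["participant_id"], []).append(tr)

    dropped: set[str] = set()
    for pid, plist in by_participant.items():
        total = sum(len(tr["series"]) for tr in plist)
        miss = sum(int(np.isnan(tr["series"]).sum()) for tr in plist)
        pooled = miss / total if total else 1.0
        if pooled > cfg.participant_missing_max:
            report.add_participant(pid, "missing_fraction", pooled)
            dropped.add(pid)

    kept = [tr for tr in surviving if tr["participant_id"] not in dropped]
    return kept, report


def median_filter(series: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered rolling median, ignoring missing samples within each window.

    Missing positions stay missing in the output.  At the edges the window
    shrinks symmetrically to the available span, so a constant series (of
    any length) is a fixed point.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    series = np.asarray(series, dtype=float)
    n = len(series)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if np.isnan(series[i]):
            continue
        win = series[i - h: i + h + 1]
        win = win[~np.isnan(win)]
        out[i] = np.median(win)
    return out


def interpolate_gaps(series: np.ndarray) -> np.ndarray:
    """Linearly bridge internal runs of missing samples.

    Leading and trailing missing runs are preserved (no extrapolation);
    observed values are returned untouched.  An all-missing series is
    returned unchanged with a warning.
    """
    series = np.asarray(series, dtype=float).copy()
    valid = ~np.isnan(series)
    if not valid.any():
        warnings.warn("all-missing series; nothing to interpolate")
        return series
    idx = np.arange(len(series))
    first, last = idx[valid][0], idx[valid][-1]
    inner = (idx > first) & (idx < last) & ~valid
    if inner.any():
        series[inner] = np.interp(idx[inner], idx[valid], series[valid])
    return series


class NoBaselineError(ValueError):
    """Raised when the baseline window contains no valid sample."""


def baseline_correct(
    series: np.ndarray,
    time_s: np.ndarray,
    cfg: PreprocessConfig,
) -> tuple[np.ndarray, float]:
    """Subtract the mean over the baseline window [start, end) from the trace.

    Returns the pupil-change series and the baseline value used.  Raises
    :class:`NoBaselineError` when no valid sample falls in the window.
    """
    series = np.asarray(series, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    in_win = (time_s >= cfg.baseline_start_s) & (time_s < cfg.baseline_end_s)
    vals = series[in_win]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise NoBaselineError("no valid sample in baseline window")
    baseline = float(np.mean(vals))
    return series - baseline, baseline


def preprocess(
    recordings: Iterable[RawRecording],
    cfg: PreprocessConfig | None = None,
) -> tuple[list[CleanTimecourse], ExclusionReport]:
    """Run the full cleaning chain over a collection of raw recordings.

    Applies, per participant x trial:
    regress_eyes -> mean_pupil -> downsample -> exclude_by_missingness ->
    median_filter -> interpolate_gaps -> baseline_correct.  Per-trial
    failures (e.g. an empty baseline window) land in the report rather than
    aborting the run.
    """
    cfg = cfg or PreprocessConfig()
    report = ExclusionReport()
    factor = cfg.decimation

    staged: list[dict] = []
    for rec in recordings:
        if rec.rate_hz != cfg.in_rate_hz:
            raise ValueError(
                f"recording {rec.participant_id} sampled at {rec.rate_hz} Hz, "
                f"config expects {cfg.in_rate_hz}"
            )
        for tid, trial in rec.trials():
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                lf, rf = regress_eyes(trial.pupil_left_mm, trial.pupil_right_mm)
            for w in wlist:
                report.warnings.append(
                    f"{rec.participant_id}/block{tid}: {w.message}")
            merged = mean_pupil(lf, rf)
            coarse = downsample(merged, factor)
            staged.append({
                "participant_id": rec.participant_id,
                "group_label": rec.group_label,
                "block_id": tid,
                "series": coarse,
            })

    kept, report = exclude_by_missingness(staged, cfg, report)

    clean: list[CleanTimecourse] = []
    for tr in kept:
        series = median_filter(tr["series"], cfg.median_window)
        series = interpolate_gaps(series)
        time_s = np.arange(len(series)) * cfg.dt_out
        try:
            dpd, baseline = baseline_correct(series, time_s, cfg)
        except NoBaselineError:
            report.add_trial(tr["participant_id"], tr["block_id"],
                             "no baseline", missing_fraction(tr["series"]))
            continue
        clean.append(CleanTimecourse(
            participant_id=tr["participant_id"],
            group_label=tr["group_label"],
            block_id=tr["block_id"],
            time_s=time_s,
            dpd_mm=dpd,
            baseline_mm=baseline,
        ))
    return clean, report
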