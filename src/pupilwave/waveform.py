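"""Between-group waveform comparison with run-length-calibrated pointwise tests.

Two groups' pupil-change waveforms are compared with a Welch t-test at every
timepoint.  Because the waveforms are strongly autocorrelated, a run of
nominally significant timepoints is only declared a significance window when
it is at least as long as a threshold calibrated by Monte Carlo: null
studies of Gaussian AR(1) participant waveforms (lag-1 coefficient estimated
from the data) are simulated, and the threshold is the shortest run length
whose null exceedance probability is at or below the family-wise level.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy import stats as sps

from .config import StatsConfig
from .preprocess import CleanTimecourse

__all__ = [
    "GroupWaveforms",
    "PointwiseTest",
    "RunThreshold",
    "SignificanceWindow",
    "WindowsReport",
    "stack_waveforms",
    "pointwise_welch",
    "cohens_d",
    "estimate_phi",
    "null_max_run",
    "exact_max_run_tail",
    "run_threshold",
    "find_windows",
    "compare_groups",
]


@dataclass
class GroupWaveforms:
    """Participant-block x timepoint matrix of pupil change for one group."""

    group_label: str
    data: np.ndarray       # (n_rows, T), NaN = missing
    time_s: np.ndarray     # (T,), shared axis

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data.shape[1] != len(self.time_s):
            raise ValueError("data columns must match time axis length")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


def stack_waveforms(
    clean: Sequence[CleanTimecourse],
    group_label: Optional[str] = None,
    dt: float = 0.1,
) -> GroupWaveforms:
    """Stack timecourses into a matrix, NaN-padding rows that end early."""
    if group_label is not None:
        clean = [c for c in clean if c.group_label == group_label]
    if not clean:
        raise ValueError(f"no timecourses for group {group_label!r}")
    T = max(len(c.dpd_mm) for c in clean)
    data = np.full((len(clean), T), np.nan)
    for i, c in enumerate(clean):
        data[i, : len(c.dpd_mm)] = c.dpd_mm
    label = group_label if group_label is not None else clean[0].group_label
    return GroupWaveforms(label, data, np.arange(T) * dt)


@dataclass
class PointwiseTest:
    """Welch test at a single timepoint; ``testable`` is False when either
    group has too few observations there."""

    time_s: float
    t: float
    df: float
    p: float
    n_A: int
    n_B: int
    mean_A: float
    mean_B: float
    testable: bool


@dataclass
class RunThreshold:
    """Minimal significant-run length controlling the family-wise error."""

    k_samples: int
    k_seconds: float
    phi_hat: float
    null_tail: float    # empirical P(max null run >= k_samples)
    n_sim: int


@dataclass
class SignificanceWindow:
    """A maximal run of consecutively significant timepoints."""

    start_s: float
    end_s: float
    peak_time_s: float
    t: float
    df: float
    p: float
    cohens_d: float
    length_samples: int


@dataclass
class WindowsReport:
    """Full, serializable result of one group-pair comparison."""

    group_a: str
    group_b: str
    config: dict
    phi_hat: float
    threshold: RunThreshold
    pointwise: list
    windows: list
    time_s: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "config": self.config,
            "phi_hat": self.phi_hat,
            "threshold": asdict(self.threshold),
            "windows": [asdict(w) for w in self.windows],
            "n_timepoints": len(self.pointwise),
        }


# ---------------------------------------------------------------------------
# Welch machinery (vectorized core shared by data tests and the null sim)

def _welch_arrays(a: np.ndarray, b: np.ndarray, min_n: int = 2):
    """Vectorized Welch t over columns of two (rows x T) matrices with NaN.

    Returns (t, df, n_A, n_B, testable); t > 0 when mean(A) > mean(B).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        nA = np.sum(~np.isnan(a), axis=0)
        nB = np.sum(~np.isnan(b), axis=0)
        mA = np.nanmean(a, axis=0)
        mB = np.nanmean(b, axis=0)
        vA = np.nanvar(a, axis=0, ddof=1)
        vB = np.nanvar(b, axis=0, ddof=1)
    testable = (nA >= min_n) & (nB >= min_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        sA = vA / nA
        sB = vB / nB
        se2 = sA + sB
        t = (mA - mB) / np.sqrt(se2)
        df = se2 ** 2 / (sA ** 2 / (nA - 1) + sB ** 2 / (nB - 1))
    # degenerate zero-variance columns: identical data -> t = 0
    zero = testable & (se2 == 0)
    if np.any(zero):
        diff = mA - mB
        t = np.where(zero & (diff == 0), 0.0, t)
        t = np.where(zero & (diff > 0), np.inf, t)
        t = np.where(zero & (diff < 0), -np.inf, t)
        df = np.where(zero, nA + nB - 2.0, df)
    t = np.where(testable, t, np.nan)
    df = np.where(testable, df, np.nan)
    return t, df, nA, nB, testable


def _one_tailed_p(t: np.ndarray, df: np.ndarray, tail: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if tail == "A_less":
            return sps.t.cdf(t, df)
        if tail == "A_greater":
            return sps.t.sf(t, df)
        return 2.0 * sps.t.sf(np.abs(t), df)


def pointwise_welch(
    group_a: GroupWaveforms,
    group_b: GroupWaveforms,
    cfg: StatsConfig | None = None,
) -> list[PointwiseTest]:
    """Welch t-test (Satterthwaite df) at every timepoint of the shared grid.

    Each timepoint uses the rows observed there (pairwise deletion), so late
    timepoints where trials have ended simply have fewer contributors.
    """
    cfg = cfg or StatsConfig()
    if group_a.data.shape[1] != group_b.data.shape[1]:
        raise ValueError("groups must share the time axis")
    t, df, nA, nB, testable = _welch_arrays(
        group_a.data, group_b.data, cfg.min_n_per_point)
    p = _one_tailed_p(t, df, cfg.tail)
    if not testable.any():
        raise ValueError("no testable timepoint (all have n < min_n_per_point)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mA = np.nanmean(group_a.data, axis=0)
        mB = np.nanmean(group_b.data, axis=0)
    return [
        PointwiseTest(
            time_s=float(group_a.time_s[i]),
            t=float(t[i]), df=float(df[i]),
            p=float(p[i]) if testable[i] else float("nan"),
            n_A=int(nA[i]), n_B=int(nB[i]),
            mean_A=float(mA[i]), mean_B=float(mB[i]),
            testable=bool(testable[i]),
        )
        for i in range(len(t))
    ]


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean_A - mean_B) / pooled SD, pooling variances with (n-1) weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled SD; Cohen's d undefined")
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# Autocorrelation estimation

def _lag1_corr(x: np.ndarray) -> float:
    """Pairwise-complete lag-1 Pearson autocorrelation of one series."""
    x0, x1 = x[:-1], x[1:]
    ok = ~np.isnan(x0) & ~np.isnan(x1)
    if ok.sum() < 3:
        return float("nan")
    a, b = x0[ok], x1[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def estimate_phi(group_a: GroupWaveforms, group_b: GroupWaveforms) -> float:
    """Average lag-1 autocorrelation of participant residual waveforms.

    Each row's residual is the row minus its group's pointwise mean
    waveform; the estimate is the mean of the per-row lag-1 correlations,
    clipped to [0, 0.999].
    """
    if group_a.data.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    vals = []
    for grp in (group_a, group_b):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gmean = np.nanmean(grp.data, axis=0)
        resid = grp.data - gmean
        for row in resid:
            vals.append(_lag1_corr(row))
    vals = np.asarray(vals)
    if np.all(np.isnan(vals)):
        raise ValueError("all residual series degenerate; cannot estimate phi")
    return float(np.clip(np.nanmean(vals), 0.0, 0.999))


# ---------------------------------------------------------------------------
# Monte Carlo run-length null

def _simulate_ar1_matrix(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """Stationary unit-variance Gaussian AR(1) along the last axis."""
    e = rng.standard_normal(shape)
    if phi == 0.0:
        return e
    e[..., 1:] *= np.sqrt(1.0 - phi * phi)
    return signal.lfilter([1.0], [1.0, -phi], e, axis=-1)


def _significant_mask(t: np.ndarray, df: np.ndarray, n_a: int, n_b: int,
                      alpha: float, tail: str) -> np.ndarray:
    """p < alpha without evaluating the t CDF everywhere.

    The Welch df lies in [min(nA,nB)-1, nA+nB-2]; the critical value is
    monotone in df, so only statistics inside the narrow band between the
    two extreme critical values need an exact p.
    """
    if tail == "two_sided":
        stat = np.abs(t)
        a_eff = alpha / 2.0
    elif tail == "A_less":
        stat = -t
        a_eff = alpha
    else:
        stat = t
        a_eff = alpha
    df_lo = min(n_a, n_b) - 1.0
    df_hi = n_a + n_b - 2.0
    c_hi = sps.t.isf(a_eff, df_lo)   # largest critical value
    c_lo = sps.t.isf(a_eff, df_hi)   # smallest
    sig = stat > c_hi
    band = (stat > c_lo) & ~sig
    if np.any(band):
        sig[band] = stat[band] > sps.t.isf(a_eff, df[band])
    return sig


def _max_run_per_row(sig: np.ndarray) -> np.ndarray:
    """Longest run of True along the last axis of a 2-D boolean array."""
    R, T = sig.shape
    run = np.zeros(R, dtype=np.int64)
    best = np.zeros(R, dtype=np.int64)
    for t in range(T):
        run = np.where(sig[:, t], run + 1, 0)
        np.maximum(best, run, out=best)
    return best


def null_max_run(
    T: int,
    n_a: int,
    n_b: int,
    phi: float,
    cfg: StatsConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the longest pointwise-significant run.

    Each replicate simulates ``n_a + n_b`` independent participant waveforms
    as stationary unit-variance Gaussian AR(1) series with coefficient
    ``phi``, runs the pointwise Welch test at the configured tail, and
    records the longest run of consecutive timepoints with p < alpha_point.
    Returns the ``cfg.n_sim`` maxima (run length 0 allowed).
    """
    cfg = cfg or StatsConfig()
    if T < 1 or n_a < 2 or n_b < 2:
        raise ValueError("need T >= 1 and n >= 2 per group")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    maxima = np.empty(cfg.n_sim, dtype=np.int64)
    # small chunks keep the (chunk, n, T) cube cache-friendly
    chunk = max(1, min(cfg.n_sim, int(1.5e6 / ((n_a + n_b) * T + 1)) or 1))
    done = 0
    while done < cfg.n_sim:
        m = min(chunk, cfg.n_sim - done)
        x = _simulate_ar1_matrix(rng, (m, n_a + n_b, T), phi)
        a, b = x[:, :n_a, :], x[:, n_a:, :]
        mA = a.sum(axis=1) / n_a
        mB = b.sum(axis=1) / n_b
        vA = (np.einsum("ijk,ijk->ik", a, a) - n_a * mA * mA) / (n_a - 1)
        vB = (np.einsum("ijk,ijk->ik", b, b) - n_b * mB * mB) / (n_b - 1)
        sA, sB = vA / n_a, vB / n_b
        se2 = sA + sB
        t = (mA - mB) / np.sqrt(se2)
        df = se2 ** 2 / (sA ** 2 / (n_a - 1) + sB ** 2 / (n_b - 1))
        sig = _significant_mask(t, df, n_a, n_b, cfg.alpha_point, cfg.tail)
        maxima[done: done + m] = _max_run_per_row(sig)
        done += m
    return maxima


def exact_max_run_tail(T: int, k: int, alpha: float) -> float:
    """P(longest success run >= k) in T independent Bernoulli(alpha) trials.

    Exact dynamic program over (position, current run length); serves as the
    independent-case oracle for :func:`null_max_run` at phi = 0.
    """
    if k <= 0:
        return 1.0
    if k > T:
        return 0.0
    # state[j] = P(current run length == j, not yet absorbed)
    state = np.zeros(k)
    state[0] = 1.0
    absorbed = 0.0
    for _ in range(T):
        absorbed += state[k - 1] * alpha
        new = np.zeros(k)
        new[0] = state.sum() * (1.0 - alpha)
        new[1:] = state[:-1] * alpha
        state = new
    return float(absorbed)


def run_threshold(
    null_dist: np.ndarray,
    cfg: StatsConfig | None = None,
    phi_hat: float = float("nan"),
) -> RunThreshold:
    """Smallest run length whose null exceedance probability is <= alpha_fw."""
    cfg = cfg or StatsConfig()
    null_dist = np.asarray(null_dist)
    if null_dist.size == 0:
        raise ValueError("empty null distribution")
    n = len(null_dist)
    if cfg.alpha_fw < 1.0 / n:
        raise ValueError(
            f"alpha_fw={cfg.alpha_fw} is below the Monte Carlo resolution "
            f"1/{n}; increase n_sim"
        )
    for k in range(1, int(null_dist.max()) + 2):
        tail = float(np.mean(null_dist >= k))
        if tail <= cfg.alpha_fw:
            return RunThreshold(
                k_samples=k, k_seconds=k * 0.1,
                phi_hat=float(phi_hat), null_tail=tail, n_sim=n,
            )
    raise AssertionError("unreachable: tail at max+1 is 0")


# ---------------------------------------------------------------------------
# Window extraction

def _runs_of_true(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


def find_windows(
    tests: Sequence[PointwiseTest],
    threshold: RunThreshold,
    group_a: GroupWaveforms,
    group_b: GroupWaveforms,
    cfg: StatsConfig | None = None,
) -> list[SignificanceWindow]:
    """Turn long-enough significant runs into windows with summary stats.

    Untestable timepoints break runs.  Per window, t/df/p and Cohen's d are
    reported at the timepoint of maximum |t| (or, with
    ``cfg.window_summary == "mean"``, averaged over the window, with d still
    taken at the peak-|t| timepoint's data).
    """
    cfg = cfg or StatsConfig()
    sig = np.array([tp.testable and tp.p < cfg.alpha_point for tp in tests])
    windows: list[SignificanceWindow] = []
    for s, e in _runs_of_true(sig):
        length = e - s
        if length < threshold.k_samples:
            continue
        tvals = np.array([tests[i].t for i in range(s, e)])
        peak = s + int(np.argmax(np.abs(tvals)))
        a_vals = group_a.data[:, peak]
        b_vals = group_b.data[:, peak]
        try:
            d = cohens_d(a_vals, b_vals)
        except ValueError:
            d = float("nan")
        if cfg.window_summary == "mean":
            t_rep = float(np.mean(tvals))
            df_rep = float(np.mean([tests[i].df for i in range(s, e)]))
            p_rep = float(np.mean([tests[i].p for i in range(s, e)]))
        else:
            t_rep = float(tests[peak].t)
            df_rep = float(tests[peak].df)
            p_rep = float(tests[peak].p)
        windows.append(SignificanceWindow(
            start_s=float(tests[s].time_s),
            end_s=float(tests[e - 1].time_s),
            peak_time_s=float(tests[peak].time_s),
            t=t_rep, df=df_rep, p=p_rep,
            cohens_d=d, length_samples=length,
        ))
    return windows


def compare_groups(
    group_a: GroupWaveforms | Sequence[CleanTimecourse],
    group_b: GroupWaveforms | Sequence[CleanTimecourse],
    cfg: StatsConfig | None = None,
    rng: np.random.Generator | None = None,
) -> WindowsReport:
    """Full comparison: phi estimate, null calibration, tests, windows.

    Accepts either prepared waveform matrices or lists of clean
    timecourses.  Reproducible from ``cfg.seed`` when no generator is
    passed.
    """
    cfg = cfg or StatsConfig()
    if not isinstance(group_a, GroupWaveforms):
        group_a = stack_waveforms(group_a)
    if not isinstance(group_b, GroupWaveforms):
        group_b = stack_waveforms(group_b)
    group_a, group_b = _common_grid(group_a, group_b)

    phi_hat = estimate_phi(group_a, group_b)
    T = group_a.data.shape[1]
    # null sample sizes: modal per-timepoint counts
    n_a = max(2, int(np.median(np.sum(~np.isnan(group_a.data), axis=0))))
    n_b = max(2, int(np.median(np.sum(~np.isnan(group_b.data), axis=0))))
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    null = null_max_run(T, n_a, n_b, phi_hat, cfg, rng)
    thr = run_threshold(null, cfg, phi_hat)
    tests = pointwise_welch(group_a, group_b, cfg)
    windows = find_windows(tests, thr, group_a, group_b, cfg)
    return WindowsReport(
        group_a=group_a.group_label,
        group_b=group_b.group_label,
        config=asdict(cfg),
        phi_hat=phi_hat,
        threshold=thr,
        pointwise=tests,
        windows=windows,
        time_s=group_a.time_s,
    )


def _common_grid(a: GroupWaveforms, b: GroupWaveforms) -> tuple[GroupWaveforms, GroupWaveforms]:
    Ta, Tb = a.data.shape[1], b.data.shape[1]
    if Ta == Tb:
        return a, b
    T = max(Ta, Tb)
    time = a.time_s if Ta == T else b.time_s

    def pad(g: GroupWaveforms) -> GroupWaveforms:
        if g.data.shape[1] == T:
            return GroupWaveforms(g.group_label, g.data, time)
        out = np.full((g.n_rows, T), np.nan)
        out[:, : g.data.shape[1]] = g.data
        return GroupWaveforms(g.group_label, out, time)

    return pad(a), pad(b)
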