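"""Self-validation experiments for the run-length calibration machinery.

These routines exercise the full pipeline against independent oracles and
known operating characteristics: exact independent-case run-length tails,
family-wise error under a pure null, threshold monotonicity in the
autocorrelation, and recovery of an injected group effect.  They are used
by the acceptance test suite and the standalone acceptance report script.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .config import EffectSpec, SimConfig, StatsConfig
from .preprocess import preprocess
from .simulate import simulate_study
from .waveform import (GroupWaveforms, compare_groups, exact_max_run_tail,
                       null_max_run, run_threshold, stack_waveforms)

__all__ = [
    "oracle_equivalence",
    "fwer_null_studies",
    "threshold_monotonicity",
    "effect_recovery",
]


def oracle_equivalence(
    T: int = 100,
    n_per_group: int = 15,
    alpha_point: float = 0.1,
    n_sim: int = 10_000,
    k_max: int = 20,
    seed: int = 0,
) -> dict:
    """Compare Monte Carlo run-length tails at phi=0 with the exact DP oracle.

    Returns per-k Monte Carlo and exact tails plus the deviation in binomial
    standard errors (using the exact tail's SE at the Monte Carlo size).
    """
    cfg = StatsConfig(alpha_point=alpha_point, tail="two_sided",
                      n_sim=n_sim, seed=seed)
    dist = null_max_run(T, n_per_group, n_per_group, 0.0, cfg)
    ks = np.arange(1, k_max + 1)
    mc = np.array([np.mean(dist >= k) for k in ks])
    exact = np.array([exact_max_run_tail(T, int(k), alpha_point) for k in ks])
    se = np.sqrt(exact * (1.0 - exact) / n_sim)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(mc - exact) / se,
                     np.where(mc == exact, 0.0, np.inf))
    return {
        "k": ks, "mc_tail": mc, "exact_tail": exact, "se": se, "z": z,
        "max_z": float(np.max(z)),
    }


def _ar1_rows(rng: np.random.Generator, n: int, T: int, phi: float,
              sd: float = 1.0) -> np.ndarray:
    e = rng.standard_normal((n, T))
    if phi:
        e[:, 1:] *= np.sqrt(1.0 - phi * phi)
        e = signal.lfilter([1.0], [1.0, -phi], e, axis=-1)
    return sd * e


def fwer_null_studies(
    n_reps: int = 500,
    n_per_group: int = 12,
    T: int = 600,
    phi: float = 0.9,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive fraction over repeated null comparisons.

    Each replicate draws two groups from the same AR(1) null generator and
    runs the full comparison (autocorrelation estimate, Monte Carlo
    threshold, pointwise tests, window extraction); a false positive is any
    detected window.
    """
    root = np.random.SeedSequence(seed)
    time_s = np.arange(T) * 0.1
    false_positives = 0
    for rep_seq in root.spawn(n_reps):
        rng = np.random.default_rng(rep_seq)
        a = GroupWaveforms("A", _ar1_rows(rng, n_per_group, T, phi), time_s)
        b = GroupWaveforms("B", _ar1_rows(rng, n_per_group, T, phi), time_s)
        cfg = StatsConfig(tail="A_less", n_sim=n_sim, seed=0)
        report = compare_groups(a, b, cfg, rng)
        false_positives += bool(report.windows)
    return {"n_reps": n_reps, "n_false_positive": false_positives,
            "fwer": false_positives / n_reps}


def threshold_monotonicity(
    phis: tuple = (0.0, 0.5, 0.9),
    T: int = 600,
    n_per_group: int = 12,
    n_sim: int = 4000,
    seed: int = 0,
) -> dict:
    """Run-length thresholds across autocorrelation levels (should increase)."""
    ks = []
    for i, phi in enumerate(phis):
        cfg = StatsConfig(alpha_point=0.1, tail="A_less", n_sim=n_sim, seed=seed + i)
        dist = null_max_run(T, n_per_group, n_per_group, phi, cfg)
        ks.append(run_threshold(dist, cfg, phi).k_samples)
    return {"phi": list(phis), "k_samples": ks,
            "monotone": all(a <= b for a, b in zip(ks, ks[1:]))}


def _recovery_sim_config(seed: int) -> SimConfig:
    # tonic_sd chosen so the realized between-participant effect size for a
    # -0.3 mm offset is ~1.5 after preprocessing
    return SimConfig(trial_length_s=60.0, phi=0.7, tonic_sd=0.22,
                     noise_sd=0.03, blink_rate_hz=0.1, seed=seed)


def effect_recovery(
    n_reps: int = 200,
    magnitude_mm: float = -0.3,
    onset_s: float = 20.0,
    duration_s: float = 19.0,
    n_per_group: int = 12,
    n_sim: int = 600,
    seed: int = 0,
) -> dict:
    """Detection rate of an injected offset through the full pipeline.

    Simulates raw recordings with a group offset ramping in at ``onset_s``
    and out after ``onset_s + duration_s``, preprocesses them, and counts
    replicates with a detected window overlapping the interval where the
    offset is fully active (ramps excluded, so chance windows brushing the
    boundary at the nominal family-wise rate do not count as detections).
    """
    ramp_s = 1.0
    root = np.random.SeedSequence(seed)
    hits = 0
    active_start = onset_s + ramp_s
    active_end = onset_s + duration_s
    for rep_seq in root.spawn(n_reps):
        child = rep_seq.generate_state(1)[0]
        sim = _recovery_sim_config(int(child))
        eff = EffectSpec("A", onset_s=onset_s, magnitude_mm=magnitude_mm,
                         ramp_s=ramp_s, duration_s=duration_s)
        recs = simulate_study(sim, [("A", n_per_group, eff),
                                    ("B", n_per_group, None)])
        clean, _ = preprocess(recs)
        wave_a = stack_waveforms(clean, "A")
        wave_b = stack_waveforms(clean, "B")
        cfg = StatsConfig(tail="A_less", n_sim=n_sim, seed=0)
        report = compare_groups(wave_a, wave_b, cfg,
                                np.random.default_rng(rep_seq))
        if any(w.start_s < active_end and w.end_s > active_start
               for w in report.windows):
            hits += 1
    return {"n_reps": n_reps, "n_detected": hits,
            "detection_rate": hits / n_reps}
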