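"""Synthetic binocular eye-tracker recordings.

Generates raw 60 Hz dual-eye pupil traces with the statistical structure the
downstream analysis assumes: a slow autocorrelated tonic drift, an onset
light-reflex constriction, correlated per-eye measurement noise, binocular
blink gaps, and optional group-level additive effects.

The tonic component is an AR(1) process generated on the coarse (10 Hz) grid
and sample-and-held up to the recording rate, so that after downsampling the
cleaned series has lag-1 autocorrelation ``phi`` by construction — the
quantity the run-length null calibration depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import EffectSpec, SimConfig

__all__ = ["RawRecording", "simulate_trial", "simulate_study"]


@dataclass
class RawRecording:
    """Raw samples for one participant, possibly spanning several trials.

    Missing pupil values are NaN; the validity flags are True exactly where
    the corresponding pupil value is present and positive.
    """

    participant_id: str
    group_label: str
    trial_id: np.ndarray        # int, one entry per sample
    timestamp_ms: np.ndarray    # float ms, strictly increasing within a trial
    pupil_left_mm: np.ndarray   # float, NaN = missing
    pupil_right_mm: np.ndarray
    valid_left: np.ndarray      # bool
    valid_right: np.ndarray
    rate_hz: int = 60

    def __post_init__(self) -> None:
        n = len(self.trial_id)
        for name in ("timestamp_ms", "pupil_left_mm", "pupil_right_mm",
                     "valid_left", "valid_right"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has mismatched length")

    @property
    def n_samples(self) -> int:
        return len(self.trial_id)

    def trials(self) -> Iterable[tuple[int, "RawRecording"]]:
        """Yield (trial_id, single-trial view) pairs in order of appearance."""
        for tid in np.unique(self.trial_id):
            m = self.trial_id == tid
            yield int(tid), RawRecording(
                self.participant_id, self.group_label,
                self.trial_id[m], self.timestamp_ms[m],
                self.pupil_left_mm[m], self.pupil_right_mm[m],
                self.valid_left[m], self.valid_right[m], self.rate_hz,
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.group_label == other.group_label
            and np.array_equal(self.trial_id, other.trial_id)
            and np.array_equal(self.timestamp_ms, other.timestamp_ms)
            and np.array_equal(self.pupil_left_mm, other.pupil_left_mm, equal_nan=True)
            and np.array_equal(self.pupil_right_mm, other.pupil_right_mm, equal_nan=True)
            and np.array_equal(self.valid_left, other.valid_left)
            and np.array_equal(self.valid_right, other.valid_right)
        )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary Gaussian AR(1) with marginal SD ``sd`` and lag-1 coef phi."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    e = rng.standard_normal(n)
    x[0] = sd * e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov_sd * e[t]
    return x


def _effect_profile(effect: EffectSpec, t_s: np.ndarray) -> np.ndarray:
    """Additive offset (mm) at each time, with linear ramp in (and out)."""
    off = np.zeros_like(t_s)
    if effect.ramp_s > 0:
        up = np.clip((t_s - effect.onset_s) / effect.ramp_s, 0.0, 1.0)
    else:
        up = (t_s >= effect.onset_s).astype(float)
    off = up
    if effect.duration_s is not None:
        t_end = effect.onset_s + effect.duration_s
        if effect.ramp_s > 0:
            down = np.clip((t_s - t_end) / effect.ramp_s, 0.0, 1.0)
        else:
            down = (t_s >= t_end).astype(float)
        off = np.minimum(up, 1.0 - down)
    return effect.magnitude_mm * off


def simulate_trial(
    cfg: SimConfig,
    effect: Optional[EffectSpec] = None,
    seed: Optional[int] = None,
    *,
    participant_id: str = "p0",
    group_label: str = "sim",
    trial_id: int = 0,
) -> RawRecording:
    """Simulate one trial of binocular 60 Hz pupil data.

    The signal per eye is

        baseline + tonic AR(1) (held from the coarse grid)
        - light_reflex_amp_mm * exp(-t / light_reflex_tau_s)
        + effect offset (if any) + white measurement noise,

    with left/right noise correlated at ``eye_corr``.  Blinks arrive as a
    Poisson process and blank both eyes for an exponentially distributed
    duration.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    hold = cfg.rate_hz // cfg.tonic_rate_hz
    n_coarse = int(round(cfg.trial_length_s * cfg.tonic_rate_hz))
    n = n_coarse * hold
    t_s = np.arange(n) / cfg.rate_hz

    tonic = np.repeat(_ar1(rng, n_coarse, cfg.phi, cfg.tonic_sd), hold)

    signal = cfg.baseline_mm + tonic
    if cfg.light_reflex_amp_mm > 0:
        signal = signal - cfg.light_reflex_amp_mm * np.exp(-t_s / cfg.light_reflex_tau_s)
    if effect is not None:
        if effect.onset_s < 1.0:
            raise ValueError(
                "effect onset_s must be >= 1.0 s so the baseline window "
                "stays uncontaminated"
            )
        signal = signal + _effect_profile(effect, t_s)

    if cfg.noise_sd > 0:
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        r = cfg.eye_corr
        left_noise = cfg.noise_sd * z1
        right_noise = cfg.noise_sd * (r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2)
    else:
        left_noise = right_noise = np.zeros(n)

    left = signal + left_noise
    right = signal + right_noise

    valid = np.ones(n, dtype=bool)
    if cfg.blink_rate_hz > 0:
        n_blinks = rng.poisson(cfg.blink_rate_hz * cfg.trial_length_s)
        starts = rng.uniform(0.0, cfg.trial_length_s, size=n_blinks)
        durs = rng.exponential(cfg.blink_dur_ms / 1000.0, size=n_blinks)
        for s, d in zip(starts, durs):
            i0 = int(np.floor(s * cfg.rate_hz))
            i1 = int(np.ceil((s + d) * cfg.rate_hz))
            valid[i0: max(i1, i0 + 1)] = False

    left = np.where(valid, left, np.nan)
    right = np.where(valid, right, np.nan)

    return RawRecording(
        participant_id=participant_id,
        group_label=group_label,
        trial_id=np.full(n, trial_id, dtype=int),
        timestamp_ms=t_s * 1000.0,
        pupil_left_mm=left,
        pupil_right_mm=right,
        valid_left=valid.copy(),
        valid_right=valid.copy(),
        rate_hz=cfg.rate_hz,
    )


def simulate_study(
    cfg: SimConfig,
    groups: Sequence[tuple[str, int, Optional[EffectSpec]]],
    seed: Optional[int] = None,
    *,
    n_trials: int = 1,
) -> list[RawRecording]:
    """Simulate a full study: one recording per participant per group.

    Per-participant seeds are spawned deterministically from the top-level
    seed, so the output is reproducible and insensitive to generation order.
    """
    labels = [g[0] for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels in {labels}")

    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    recordings: list[RawRecording] = []
    for (label, n_participants, effect), gseq in zip(groups, root.spawn(len(groups))):
        for pidx, pseq in enumerate(gseq.spawn(max(n_participants, 0))):
            pid = f"{label}_{pidx:03d}"
            parts = []
            for tid, tseq in enumerate(pseq.spawn(n_trials)):
                parts.append(simulate_trial(
                    cfg, effect,
                    seed=tseq,
                    participant_id=pid, group_label=label, trial_id=tid,
                ))
            recordings.append(_concat_trials(parts))
    return recordings


def _concat_trials(parts: list[RawRecording]) -> RawRecording:
    first = parts[0]
    return RawRecording(
        first.participant_id, first.group_label,
        np.concatenate([p.trial_id for p in parts]),
        np.concatenate([p.timestamp_ms for p in parts]),
        np.concatenate([p.pupil_left_mm for p in parts]),
        np.concatenate([p.pupil_right_mm for p in parts]),
        np.concatenate([p.valid_left for p in parts]),
        np.concatenate([p.valid_right for p in parts]),
        first.rate_hz,
    )
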