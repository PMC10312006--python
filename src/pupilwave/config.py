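"""Configuration objects for every pipeline stage.

All tunables live in small frozen dataclasses that validate themselves on
construction.  :class:`PipelineConfig` nests one of each and can be loaded
from / dumped to a plain YAML mapping, so a run is fully described by a
single text file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "SimConfig",
    "EffectSpec",
    "PreprocessConfig",
    "StatsConfig",
    "ComparisonSpec",
    "PipelineConfig",
    "load_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic binocular recording generator."""

    n_per_group: int = 12
    trial_length_s: float = 60.0
    rate_hz: int = 60
    tonic_rate_hz: int = 10
    phi: float = 0.5
    tonic_sd: float = 0.3
    noise_sd: float = 0.05
    eye_corr: float = 0.8
    blink_rate_hz: float = 0.2
    blink_dur_ms: float = 150.0
    light_reflex_amp_mm: float = 0.5
    light_reflex_tau_s: float = 0.3
    baseline_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi < 1.0):
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")
        for name in ("tonic_sd", "noise_sd", "blink_rate_hz", "blink_dur_ms",
                     "light_reflex_amp_mm", "light_reflex_tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-1.0 <= self.eye_corr <= 1.0):
            raise ValueError("eye_corr must lie in [-1, 1]")
        if self.rate_hz <= 0 or self.tonic_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.rate_hz % self.tonic_rate_hz != 0:
            raise ValueError(
                f"rate_hz ({self.rate_hz}) must be divisible by "
                f"tonic_rate_hz ({self.tonic_rate_hz})"
            )
        if self.trial_length_s <= 0:
            raise ValueError("trial_length_s must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Additive group-level pupil-diameter offset injected into a simulation.

    The offset ramps in linearly over ``ramp_s`` seconds starting at
    ``onset_s`` and, if ``duration_s`` is given, ramps back out over
    ``ramp_s`` after ``onset_s + duration_s``; otherwise it persists to the
    end of the trial.  Negative ``magnitude_mm`` means lower arousal.
    """

    group_label: str
    onset_s: float
    magnitude_mm: float
    ramp_s: float = 1.0
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be >= 0")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive when given")


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning, downsampling and exclusion rules for raw recordings."""

    in_rate_hz: int = 60
    out_rate_hz: int = 10
    trial_missing_max: float = 0.75
    participant_missing_max: float = 0.75
    median_window: int = 11
    baseline_start_s: float = 0.5
    baseline_end_s: float = 1.0

    def __post_init__(self) -> None:
        if self.in_rate_hz % self.out_rate_hz != 0:
            raise ValueError("in_rate_hz must be divisible by out_rate_hz")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if not (0.0 <= self.baseline_start_s < self.baseline_end_s):
            raise ValueError("need 0 <= baseline_start_s < baseline_end_s")
        for name in ("trial_missing_max", "participant_missing_max"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def decimation(self) -> int:
        return self.in_rate_hz // self.out_rate_hz

    @property
    def dt_out(self) -> float:
        return 1.0 / self.out_rate_hz


TAILS = ("A_less", "A_greater", "two_sided")


@dataclass(frozen=True)
class StatsConfig:
    """Pointwise test and run-length calibration parameters."""

    alpha_point: float = 0.1
    alpha_fw: float = 0.05
    tail: str = "A_less"
    n_sim: int = 10_000
    min_n_per_point: int = 2
    window_summary: str = "peak"  # or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_point < 1.0):
            raise ValueError("alpha_point must lie in (0, 1)")
        if not (0.0 < self.alpha_fw < 1.0):
            raise ValueError("alpha_fw must lie in (0, 1)")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}, got {self.tail!r}")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.min_n_per_point < 2:
            raise ValueError("min_n_per_point must be >= 2")
        if self.window_summary not in ("peak", "mean"):
            raise ValueError("window_summary must be 'peak' or 'mean'")


@dataclass(frozen=True)
class ComparisonSpec:
    """One ordered group-pair comparison: A vs B with a tail direction."""

    group_a: str
    group_b: str
    tail: str = "A_less"

    def __post_init__(self) -> None:
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")


_KNOWN_TOP_KEYS = {
    "sim", "preprocess", "stats", "groups", "effects", "comparisons",
    "seed", "log_level", "out_dir", "in_path", "dialect",
}


@dataclass
class PipelineConfig:
    """Top-level run description tying all stage configs together."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    #: (group_label, n_participants) pairs for simulation
    groups: list = field(default_factory=lambda: [["parent", 12], ["child", 12]])
    #: EffectSpec entries applied during simulation
    effects: list = field(default_factory=list)
    comparisons: list = field(default_factory=lambda: [ComparisonSpec("parent", "child")])
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "pupilwave_run"
    in_path: Optional[str] = None
    dialect: str = "native"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, section):
            if section is None:
                return klass()
            bad = set(section) - {f.name for f in dataclasses.fields(klass)}
            if bad:
                raise ValueError(
                    f"unknown keys in {klass.__name__}: {sorted(bad)}"
                )
            return klass(**section)

        effects = [
            e if isinstance(e, EffectSpec) else EffectSpec(**e)
            for e in raw.get("effects", [])
        ]
        comparisons = [
            c if isinstance(c, ComparisonSpec) else ComparisonSpec(**c)
            for c in raw.get("comparisons", [ComparisonSpec("parent", "child")])
        ]
        return cls(
            sim=build(SimConfig, raw.get("sim")),
            preprocess=build(PreprocessConfig, raw.get("preprocess")),
            stats=build(StatsConfig, raw.get("stats")),
            groups=[list(g) for g in raw.get("groups", [["parent", 12], ["child", 12]])],
            effects=effects,
            comparisons=comparisons,
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            out_dir=raw.get("out_dir", "pupilwave_run"),
            in_path=raw.get("in_path"),
            dialect=raw.get("dialect", "native"),
        )


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return PipelineConfig.from_dict(raw)
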