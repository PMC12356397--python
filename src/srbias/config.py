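"""Run configuration: strict, serializable, with every default recorded.

A :class:`RunConfig` captures everything a simulation or analysis run
depends on: the root seed, ladder, field geometry, the observer-cohort
parameter distribution, staircase settings, block-structure overrides and
analysis options.  Unknown keys are rejected so a run can always be
reproduced from its emitted snapshot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["LadderConfig", "FieldConfig", "ObserverCohortConfig",
           "QuestConfig", "BlockConfig", "AnalysisConfig", "RunConfig",
           "load_config", "dump_config"]


def _from_dict(cls, d: dict):
    if not isinstance(d, dict):
        raise ValueError(f"{cls.__name__} section must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class LadderConfig:
    sigma_min: float = 0.25
    sigma_max: float = 64.0
    n_nonzero: int = 6


@dataclass(frozen=True)
class FieldConfig:
    rows: int = 100
    cols: int = 100
    glyph_height: int = 85
    background: float = 127.0


@dataclass(frozen=True)
class ObserverCohortConfig:
    """Cohort distribution of synthetic-participant parameters.

    Per-participant theta and w are drawn from truncated normals; the
    remaining parameters are shared.  ``p_prefer_consonant`` is the
    probability a participant's innate bias favours consonants (the rest
    favour vowels and have their base rates flipped after block 2).
    """

    theta_mean: float = 50.0
    theta_sd: float = 4.0
    w_mean: float = 0.03
    w_sd: float = 0.012
    w_min: float = 0.005
    lapse: float = 0.02
    internal_noise_sd: float = 10.0
    decision_noise_sd: float = 0.07
    n_frames_integrated: int = 12
    category_prior: float = 0.8
    p_prefer_consonant: float = 0.75


@dataclass(frozen=True)
class QuestConfig:
    beta: float = 3.5
    delta: float = 0.05
    gamma: float = 1.0 / 6.0
    target_p: float = 0.70
    prior_mean: float = 1.5
    prior_sd: float = 0.5
    grid_span: float = 2.5
    grid_points: int = 201
    max_increment: float = 128.0
    min_increment: float = 0.5


@dataclass(frozen=True)
class BlockConfig:
    n_per_level: int = 30
    quest_trials: int = 50
    bias_block_trials: int = 48
    max_quest_reruns: int = 2


@dataclass(frozen=True)
class AnalysisConfig:
    bf_prior_scale: float = 0.707
    correlation_prior_width: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    cohort_size: int = 22
    ladder: LadderConfig = field(default_factory=LadderConfig)
    field_geometry: FieldConfig = field(default_factory=FieldConfig)
    observer: ObserverCohortConfig = field(default_factory=ObserverCohortConfig)
    quest: QuestConfig = field(default_factory=QuestConfig)
    blocks: BlockConfig = field(default_factory=BlockConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")

    _SECTIONS = {"ladder": LadderConfig, "field_geometry": FieldConfig,
                 "observer": ObserverCohortConfig, "quest": QuestConfig,
                 "blocks": BlockConfig, "analysis": AnalysisConfig}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub in cls._SECTIONS.items():
            if name in d:
                d[name] = _from_dict(sub, d[name])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
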