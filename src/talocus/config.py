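"""Run configuration: every tunable threshold of the pipeline, with defaults.

A fully-resolved copy of the configuration is embedded in every output
report so that results are reproducible from the report alone.  Unknown keys
in a config file are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "load_config"]


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            if hasattr(f.type, "__dataclass_fields__") or f.name in _NESTED:
                value = _from_dict(_NESTED[f.name], value)
            kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class PromoterConfig:
    min_m10: int = 4
    min_score: float = 8.0
    lambda_spacer: float = 0.5
    tss_offset: int = 7


@dataclass
class TerminatorConfig:
    min_stem: int = 5
    loop_min: int = 3
    loop_max: int = 9
    min_u: int = 4
    max_mismatch_stem: int = 1


@dataclass
class OrfConfig:
    min_aa: int = 20
    max_aa: int = 40
    start_policy: str = "ATG_GTG"


@dataclass
class RbsConfig:
    window_min: int = 4
    window_max: int = 14
    min_sd: int = 3


@dataclass
class DrConfig:
    min_len: int = 15
    max_mismatch_frac: float = 0.1


@dataclass
class FinderConfig:
    max_transcript: int = 400
    min_transcript: int = 30
    convergence_gap: int = 120
    gravy_min: float = 0.8
    antitoxin_min_len: int = 50
    antitoxin_max_len: int = 200
    # composite-score weights; a ranking heuristic, not a biological model
    w_promoter: float = 1.0
    w_terminator: float = 0.5
    w_dr: float = 0.3
    w_gravy: float = 2.0
    w_sd: float = 0.5


@dataclass
class AfmConfig:
    window_bp: int = 40
    nm_per_bp: float = 0.34
    contour_tolerance: float = 0.25
    bin_bp: int = 25


_NESTED = {
    "promoter": PromoterConfig,
    "terminator": TerminatorConfig,
    "orf": OrfConfig,
    "rbs": RbsConfig,
    "dr": DrConfig,
    "finder": FinderConfig,
    "afm": AfmConfig,
}


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    terminator: TerminatorConfig = field(default_factory=TerminatorConfig)
    orf: OrfConfig = field(default_factory=OrfConfig)
    rbs: RbsConfig = field(default_factory=RbsConfig)
    dr: DrConfig = field(default_factory=DrConfig)
    finder: FinderConfig = field(default_factory=FinderConfig)
    afm: AfmConfig = field(default_factory=AfmConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _from_dict(cls, data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; None yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)
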