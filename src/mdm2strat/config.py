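"""Run configuration: every pipeline tunable with a documented default,
round-tripping losslessly to YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig"]

_ALL_STAGES = ("fixtures", "dose", "curate", "stratify", "cutoff")


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Stage toggles select which pipeline stages execute.  When the input
    paths are None the synthetic fixture bundle is generated; user TSVs can
    replace any of them.  Per-stage random seeds are derived from ``seed``
    by hashing the stage name, so stages are independently reproducible.
    """

    seed: int = 7
    stages: tuple[str, ...] = _ALL_STAGES
    # fixture / input selection
    registry_path: str | None = None
    mutations_path: str | None = None
    genotypes_path: str | None = None
    reference_genotypes_path: str | None = None
    tumor_path: str | None = None
    # dose response
    max_dose: float = 50.0
    # curation
    cv_threshold: float = 0.3
    min_count: float = 200.0
    match_threshold: float = 80.0
    expr_quantile: float = 0.1
    # stratification
    n_probesets: int = 200
    n_perm: int = 199
    ridge_lambda: float = 1.0
    tie: str = "mid"
    balanced_tissues_only: bool = False
    # amplification cutoff
    grid_lo: float = 0.0
    grid_hi: float = 4.0
    grid_step: float = 0.05

    def __post_init__(self):
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in _ALL_STAGES]
        if bad:
            raise ValidationError(f"unknown stages {bad}; valid: {_ALL_STAGES}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
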