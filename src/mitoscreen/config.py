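"""Run configuration: every tunable threshold of the screen in one place.

The defaults mirror the published analysis protocol: a promoter window of
-500..+100 around the TSS, a TF family is called enriched when its members
hit at least 85% of the target promoters at Fisher p < 0.05, individual
family members are retained at 50% promoter coverage, the differential
signature is filtered at raw p < 0.05, organelle set scores at adjusted
p < 0.05, and upstream regulators at p < 0.01.  PWM scanning uses
MatInspector-style matrix/core similarity cutoffs of 0.85 / 0.75.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    promoter_upstream: int = 500
    promoter_downstream: int = 100
    family_coverage_min: float = 0.85
    member_coverage_min: float = 0.50
    deg_alpha: float = 0.05
    set_alpha_adjusted: float = 0.05
    regulator_alpha: float = 0.01
    matrix_sim_threshold: float = 0.85
    core_sim_threshold: float = 0.75
    input_is_log2: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "family_coverage_min",
            "member_coverage_min",
            "deg_alpha",
            "set_alpha_adjusted",
            "regulator_alpha",
            "matrix_sim_threshold",
            "core_sim_threshold",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter window extents must be >= 0")
        self.rng_seed = int(self.rng_seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
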