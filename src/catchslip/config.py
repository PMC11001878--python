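"""Run configuration: a validated JSON schema shared by the CLI commands.

Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .elasticity import ThermalContext, WLCParameters
from .kinetics import EXPERIMENT_SPEEDS, GEOMETRY_TABLE, PullProtocol


class WLCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Lc_nm: float = 124.0
    p_nm: float = 0.4


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    force_floor_pN: float = 5.0
    min_force_drop_pN: float = 15.0
    min_delta_Lc_nm: float = 10.0
    min_total_Lc_nm: float = 124.0
    histogram_bin_nm: float = 1.0


class RunConfig(BaseModel):
    """Top-level configuration (all units SI-suffixed in the field names)."""

    model_config = ConfigDict(extra="forbid")

    version: int = 1
    temperature_K: float = 298.0
    geometry: str = "native"
    speeds_nm_s: list[float] = Field(default_factory=lambda: list(EXPERIMENT_SPEEDS))
    spring_constant_pN_nm: float = 100.0
    wlc: WLCConfig = Field(default_factory=WLCConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    n_replicates: int = 1000
    seed: int = 1

    @field_validator("geometry")
    @classmethod
    def _known_geometry(cls, v):
        if v not in GEOMETRY_TABLE:
            raise ValueError(f"unknown geometry {v!r}; expected one of {sorted(GEOMETRY_TABLE)}")
        return v

    @field_validator("speeds_nm_s")
    @classmethod
    def _positive_speeds(cls, v):
        if not v or any(s <= 0 for s in v):
            raise ValueError("speeds must be positive and nonempty")
        return v

    def thermal_context(self) -> ThermalContext:
        return ThermalContext(temperature=self.temperature_K)

    def protocols(self) -> list[PullProtocol]:
        wlc = WLCParameters(Lc=self.wlc.Lc_nm, p=self.wlc.p_nm)
        return [
            PullProtocol(V=v, k=self.spring_constant_pN_nm, wlc=wlc)
            for v in self.speeds_nm_s
        ]

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))
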