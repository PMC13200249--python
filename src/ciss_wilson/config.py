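"""Declarative experiment configuration (YAML) with schema validation.

Unknown keys are rejected, physical invariants (positive frequencies, bond
indices in range) are enforced at load time, and every run can dump the
fully-resolved configuration back out for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model_builder import Bond, ChainSpec, ModeSpec, PeierlsCoupling

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BondConfig(_Strict):
    i: int
    j: int
    t: float = 0.0
    lam: float = 0.0
    v: tuple[float, float, float] = (0.0, 0.0, 1.0)


class PeierlsConfig(_Strict):
    bond: tuple[int, int]
    g: float = 0.0
    chi: float = 0.0


class ModeConfig(_Strict):
    omega0: float
    holstein: list[float] = Field(default_factory=list)
    peierls: list[PeierlsConfig] = Field(default_factory=list)


class ModelConfig(_Strict):
    n_sites: int
    topology: Literal["open", "ring"] = "open"
    onsite: Optional[list[float]] = None
    bonds: list[BondConfig]
    modes: list[ModeConfig] = Field(default_factory=list)
    truncation: int = 10

    @model_validator(mode="after")
    def _physical(self):
        if self.onsite is not None and len(self.onsite) != self.n_sites:
            raise ValueError("onsite must list one energy per site")
        for b in self.bonds:
            if not (1 <= b.i <= self.n_sites and 1 <= b.j <= self.n_sites):
                raise ValueError(f"bond ({b.i}, {b.j}) outside 1..{self.n_sites}")
        for m in self.modes:
            if m.omega0 <= 0:
                raise ValueError(f"mode frequency {m.omega0} must be positive")
        if self.truncation < 1:
            raise ValueError("boson truncation must be >= 1")
        return self

    def to_chain(self) -> ChainSpec:
        onsite = tuple(self.onsite) if self.onsite is not None else (0.0,) * self.n_sites
        bonds = tuple(Bond(b.i, b.j, b.t, b.lam, tuple(b.v)) for b in self.bonds)
        return ChainSpec(self.n_sites, onsite, bonds, self.topology)

    def to_modes(self) -> tuple[ModeSpec, ...]:
        return tuple(
            ModeSpec(
                m.omega0,
                tuple(m.holstein),
                tuple(PeierlsCoupling(tuple(p.bond), p.g, p.chi) for p in m.peierls),
            )
            for m in self.modes
        )


class AnalysisConfig(_Strict):
    tolerance: float = 1e-10


class DynamicsConfig(_Strict):
    t_max: float = 1000.0
    n_steps: int = 2000
    site: int = 1
    spin: str | tuple[float, float, float] = "mixed"


class MapConfig(_Strict):
    omega0: float = 0.05
    g_min: float = 0.0
    g_max: float = 0.04
    chi_min: float = 0.0
    chi_max: float = 0.02
    n_g: int = 5
    n_chi: int = 5
    sites: Optional[list[int]] = None
    t_max: float = 1000.0
    n_steps: int = 2000


class OpenSystemConfig(_Strict):
    gamma: float = 5e-5
    gamma_d: float = 0.0
    eps_donor: float = 0.3
    eps_acceptor: float = -0.3
    t_max: float = 20000.0
    n_steps: int = 400


class ExperimentConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    model: ModelConfig
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    map: MapConfig = Field(default_factory=MapConfig)
    open_system: OpenSystemConfig = Field(default_factory=OpenSystemConfig)

    def resolved(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_and_validate(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment config, applying defaults and rejecting
    unknown keys or physically invalid values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return ExperimentConfig.model_validate(raw)
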