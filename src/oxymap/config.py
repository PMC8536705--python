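"""Pipeline configuration: schema, YAML loading, hashing.

The configuration is one YAML document with five blocks (``parameters``,
``quadrature``, ``ocean``, ``regions``, ``diagnostics``), validated
strictly — unknown keys are rejected with their location so that typos
never silently fall back to defaults.  :func:`default_config` is the
study configuration: priors with 50 % relative sd on w and kappa and
25 % on a, a 5-point-per-dimension tensor quadrature (125 runs),
third-order Hermite basis, and the 6 % low-variance mask threshold.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .diagnostics import RegionMask
from .params import ParameterSet
from .toyocean import DEFAULT_REGIMES, ColumnGrid, OceanConstants, RegimeSpec, WorldConfig

__all__ = ["PipelineConfig", "load_config", "default_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParameterCfg(_Strict):
    mean: float = Field(gt=0)
    rel_sd: float = Field(gt=0, lt=1)
    floor: float | None = Field(default=None, ge=0)


class ParametersBlock(_Strict):
    w: ParameterCfg
    kappa: ParameterCfg
    a: ParameterCfg


class QuadratureBlock(_Strict):
    points_per_dim: int = Field(default=5, ge=1)
    max_order: int = Field(default=3, ge=0)


class GridCfg(_Strict):
    depth: float = Field(default=1000.0, gt=0)
    dz: float = Field(default=10.0, gt=0)


class ConstantsCfg(_Strict):
    s0: float = 350.0
    s1: float = 6.0
    f_max: float = 40.0
    k_a: float = 0.3
    r: float = 0.1


class RegimeCfg(_Strict):
    name: str
    fraction: float = Field(gt=0, le=1)
    temperature: dict[int, float]
    stratification: dict[int, float]
    production_factor: float = Field(ge=0)
    kappa_ml: float = Field(ge=0)
    z_ml: float = Field(gt=0)
    kappa_deep: float = Field(ge=0)


class OceanBlock(_Strict):
    grid: GridCfg = GridCfg()
    constants: ConstantsCfg = ConstantsCfg()
    n_columns: int = Field(default=100, ge=1)
    seed: int = 0
    regimes: list[RegimeCfg] | None = None


class RegionCfg(_Strict):
    name: str
    regime: str | None = None
    columns: list[int] | None = None
    box: list[float] | None = None


class DiagnosticsBlock(_Strict):
    eps: float = Field(default=1e-6, gt=0)
    mask_threshold: float = Field(default=0.06, gt=0)
    weighted: bool = True
    spread_quantile: float = Field(default=0.5, ge=0, le=1)
    top_k: int = Field(default=5, ge=1)


class PipelineConfig(_Strict):
    parameters: ParametersBlock
    quadrature: QuadratureBlock = QuadratureBlock()
    ocean: OceanBlock = OceanBlock()
    regions: list[RegionCfg] | None = None
    diagnostics: DiagnosticsBlock = DiagnosticsBlock()

    # -- converters to domain objects -----------------------------------

    def parameter_set(self) -> ParameterSet:
        cfg = {}
        for name in ("w", "kappa", "a"):
            entry = getattr(self.parameters, name)
            d = {"mean": entry.mean, "rel_sd": entry.rel_sd}
            if entry.floor is not None:
                d["floor"] = entry.floor
            cfg[name] = d
        return ParameterSet.from_config(cfg)

    def grid(self) -> ColumnGrid:
        return ColumnGrid(self.ocean.grid.depth, self.ocean.grid.dz)

    def constants(self) -> OceanConstants:
        c = self.ocean.constants
        return OceanConstants(c.s0, c.s1, c.f_max, c.k_a, c.r)

    def world_config(self) -> WorldConfig:
        if self.ocean.regimes is None:
            regimes = DEFAULT_REGIMES
        else:
            regimes = tuple(
                RegimeSpec(
                    name=r.name,
                    fraction=r.fraction,
                    temperature=dict(r.temperature),
                    stratification=dict(r.stratification),
                    production_factor=r.production_factor,
                    kappa_ml=r.kappa_ml,
                    z_ml=r.z_ml,
                    kappa_deep=r.kappa_deep,
                )
                for r in self.ocean.regimes
            )
        return WorldConfig(n_columns=self.ocean.n_columns, regimes=regimes)

    def region_masks(self) -> list[RegionMask]:
        if self.regions is None:
            # Default: one region per default regime, by label.
            names = [r.name for r in (self.ocean.regimes or [])] or [
                r.name for r in DEFAULT_REGIMES
            ]
            return [RegionMask(name=n, regime=n) for n in names]
        out = []
        for r in self.regions:
            out.append(
                RegionMask(
                    name=r.name,
                    regime=r.regime,
                    columns=tuple(r.columns) if r.columns is not None else None,
                    box=tuple(r.box) if r.box is not None else None,
                )
            )
        return out


def load_config(path) -> PipelineConfig:
    """Load and strictly validate a YAML configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as err:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        )
        raise ValueError(f"config {path} invalid: {locs}") from err


def default_config() -> PipelineConfig:
    """The shipped default configuration."""
    path = Path(__file__).parent / "data" / "default.yaml"
    return load_config(path)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
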