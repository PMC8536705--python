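"""Synthetic multi-column ocean oxygen simulator.

A deliberately small stand-in for a full Earth-system model: each
horizontal location ("column") is an independent 1-D water column in
which dissolved oxygen obeys a steady diffusion--consumption balance,

    d/dz [ (kappa + s * kappa_dyn(z)) dO2/dz ] = J(z),

with the surface held at the temperature-dependent saturation
concentration and a zero-flux bottom.  Oxygen is consumed at depth by
remineralization of sinking detritus: the export flux out of the
surface layer, F0, is set by the maximum phytoplankton growth rate
``a`` (saturating Michaelis--Menten response) and a per-column
production factor L, and decays with depth as F(z) = F0 exp(-r z / w),
so the volumetric sink is J(z) = (r / w) F(z).  The three uncertain
parameters enter exactly as in a coarse biogeochemical ocean model:
``w`` sets how deep consumption reaches, ``kappa`` sets the background
ventilation below the dynamically mixed layer, and ``a`` scales the
oxygen demand.

Warming scenarios are encoded per time slice (1850 / 2000 / 2100) by a
higher surface temperature (lower solubility) and a stratification
factor s in (0, 1] that throttles the dynamic mixing profile.  The
generated world contains three regime families whose responses differ
qualitatively: deep-water-formation columns (cold, vigorously mixed,
low production — large projected change, little parameter sensitivity),
tropical oxygen-minimum-zone columns (warm, weakly mixed below a
shallow mixed layer, productive — small change, strong parameter
sensitivity) and intermediate columns.

Each column is a linear tridiagonal solve, so a full 125-run x
100-column x 3-slice ensemble takes seconds; it is not an emulator of
any particular Earth-system model, and its role is to produce ensembles
with the *statistical* structure the sensitivity analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

from .params import ParameterSet
from .pce import QuadratureDesign

__all__ = [
    "TIME_SLICES",
    "OceanConstants",
    "ColumnGrid",
    "ColumnForcing",
    "RegimeSpec",
    "WorldConfig",
    "OxygenProfile",
    "o2_saturation",
    "export_flux",
    "remineralization_sink",
    "solve_column",
    "generate_world",
    "run_ensemble",
    "DEFAULT_REGIMES",
]

#: The three climate states: preindustrial, contemporary, projected.
TIME_SLICES = (1850, 2000, 2100)


@dataclass(frozen=True)
class OceanConstants:
    """Global constants of the toy ocean, with units.

    s0, s1:
        Linearized O2 solubility O2_sat = s0 - s1*T
        (mmol m^-3 and mmol m^-3 degC^-1).
    f_max:
        Maximum export flux scale (mmol O2-equivalent m^-2 day^-1).
    k_a:
        Half-saturation of export with respect to growth rate (day^-1).
    r:
        Remineralization rate of sinking detritus (day^-1).
    """

    s0: float = 350.0
    s1: float = 6.0
    f_max: float = 40.0
    k_a: float = 0.3
    r: float = 0.1


@dataclass(frozen=True)
class ColumnGrid:
    """Uniform vertical grid: depth H (m) split into cells of height dz."""

    depth: float = 1000.0
    dz: float = 10.0

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.depth <= 0:
            raise ValueError("depth and dz must be positive")
        n = self.depth / self.dz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("depth must be an integer multiple of dz")

    @property
    def n_cells(self) -> int:
        return int(round(self.depth / self.dz))

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dz

    @property
    def interfaces(self) -> np.ndarray:
        return np.arange(self.n_cells + 1) * self.dz


@dataclass(frozen=True)
class ColumnForcing:
    """Physical environment of one column, per time slice."""

    column_id: int
    regime: str
    surface_temperature: dict[int, float]  # degC per slice
    production_factor: float  # dimensionless L >= 0
    kappa_ml: float  # mixed-layer dynamic diffusivity peak, m^2/s
    z_ml: float  # mixed-layer e-folding depth, m
    kappa_deep: float  # deep dynamic diffusivity, m^2/s
    stratification: dict[int, float]  # multiplier on kappa_dyn per slice

    def __post_init__(self) -> None:
        if self.production_factor < 0:
            raise ValueError("production factor must be >= 0")
        if min(self.kappa_ml, self.kappa_deep) < 0 or self.z_ml <= 0:
            raise ValueError("mixing profile parameters must be non-negative")
        for s in self.stratification.values():
            if not 0 < s <= 1:
                raise ValueError("stratification factor must lie in (0, 1]")

    def kappa_dyn(self, z) -> np.ndarray:
        """Dynamic diffusivity profile (m^2/s): strong near-surface
        mixed-layer mixing decaying over z_ml plus a deep floor."""
        z = np.asarray(z, dtype=float)
        return self.kappa_ml * np.exp(-((z / self.z_ml) ** 2)) + self.kappa_deep


@dataclass(frozen=True)
class OxygenProfile:
    """Steady-state solution for one column, one run, one slice."""

    o2: np.ndarray  # mmol m^-3 per cell, clipped at 0
    min_o2: float  # column minimum of the clipped profile
    suboxic: bool  # True if the raw linear solution went negative
    surface_influx: float  # diffusive O2 supply at z=0 (mmol m^-2/day)
    consumption: float  # column-integrated sink (mmol m^-2/day)


def o2_saturation(temperature, s0: float = 350.0, s1: float = 6.0):
    """Linearized O2 solubility (mmol m^-3), strictly decreasing in T."""
    T = np.asarray(temperature, dtype=float)
    if np.any(T < -2.0) or np.any(T > 35.0):
        raise ValueError("temperature outside the admissible range [-2, 35] degC")
    out = s0 - s1 * T
    return float(out) if out.ndim == 0 else out


def export_flux(a: float, production_factor: float, f_max: float = 40.0, k_a: float = 0.3) -> float:
    """Export of organic matter out of the surface layer.

    Michaelis--Menten in the growth rate: F0 = f_max * L * a / (a + k_a),
    in mmol O2-equivalent m^-2 day^-1.  Zero growth exports nothing;
    the response saturates for a >> k_a.
    """
    if a < 0 or production_factor < 0:
        raise ValueError("a and production factor must be >= 0")
    return f_max * production_factor * a / (a + k_a)


def remineralization_sink(f0: float, w: float, r: float, grid: ColumnGrid) -> np.ndarray:
    """Cell-averaged volumetric O2 consumption J (mmol m^-3 day^-1).

    The sinking flux decays as F(z) = F0 exp(-r z / w); each cell
    receives the exact flux divergence (F(top) - F(bottom)) / dz, so
    the discrete column integral equals F0 (1 - exp(-r H / w)) to
    machine precision regardless of resolution.
    """
    if w <= 0 or r <= 0:
        raise ValueError("w and r must be positive")
    F = f0 * np.exp(-r * grid.interfaces / w)
    return (F[:-1] - F[1:]) / grid.dz


SECONDS_PER_DAY = 86400.0


def solve_column(
    forcing: ColumnForcing,
    grid: ColumnGrid,
    w: float,
    kappa: float,
    a: float,
    time_slice: int,
    constants: OceanConstants = OceanConstants(),
) -> OxygenProfile:
    """Steady-state oxygen profile for one column and parameter triple.

    Discretized by centered second-order finite volumes on the uniform
    grid with a Dirichlet surface condition at saturation and a
    zero-flux bottom; the resulting tridiagonal system is solved
    directly.  Negative concentrations (possible because the sink does
    not shut off at zero oxygen) are clipped to zero after solving and
    flagged, so downstream checks can exclude clipped columns from
    smooth-response assertions.
    """
    if min(w, kappa, a) <= 0:
        raise ValueError("parameters w, kappa, a must be positive")
    if time_slice not in forcing.surface_temperature:
        raise KeyError(f"no forcing for time slice {time_slice}")

    n, dz = grid.n_cells, grid.dz
    s = forcing.stratification[time_slice]
    # Effective diffusivity at cell interfaces, converted to m^2/day to
    # match the day-based biogeochemical rates.
    kappa_if = (kappa + s * forcing.kappa_dyn(grid.interfaces)) * SECONDS_PER_DAY

    sat = o2_saturation(forcing.surface_temperature[time_slice], constants.s0, constants.s1)
    f0 = export_flux(a, forcing.production_factor, constants.f_max, constants.k_a)
    J = remineralization_sink(f0, w, constants.r, grid) if f0 > 0 else np.zeros(n)

    inv_dz2 = 1.0 / dz**2
    lower = kappa_if[1:-1] * inv_dz2  # coupling across interior interfaces
    diag = np.zeros(n)
    diag[:-1] -= kappa_if[1:-1] * inv_dz2
    diag[1:] -= kappa_if[1:-1] * inv_dz2
    diag[0] -= 2.0 * kappa_if[0] * inv_dz2  # half-cell Dirichlet stencil
    rhs = J.copy()
    rhs[0] -= 2.0 * kappa_if[0] * sat * inv_dz2
    # bottom: zero flux — no extra term

    ab = np.zeros((3, n))
    ab[0, 1:] = lower  # superdiagonal
    ab[1, :] = diag
    ab[2, :-1] = lower  # subdiagonal (symmetric)
    o2_raw = solve_banded((1, 1), ab, rhs)
    if not np.all(np.isfinite(o2_raw)):
        raise FloatingPointError("non-finite oxygen solution")

    suboxic = bool(np.any(o2_raw < 0))
    o2 = np.maximum(o2_raw, 0.0)
    influx = 2.0 * kappa_if[0] * (sat - o2_raw[0]) / dz
    consumption = float(np.sum(J) * dz)
    return OxygenProfile(o2, float(o2.min()), suboxic, float(influx), consumption)


@dataclass(frozen=True)
class RegimeSpec:
    """One regime family of the synthetic world."""

    name: str
    fraction: float
    temperature: dict[int, float]
    stratification: dict[int, float]
    production_factor: float
    kappa_ml: float
    z_ml: float
    kappa_deep: float


#: Default regime families.  Values are order-of-magnitude-typical for
#: the respective ocean environments; the qualitative contracts are
#: what matters: deep-water-formation columns warm and stratify hard
#: but consume little oxygen, tropical columns are productive and rely
#: on weak background mixing, intermediates sit between.
DEFAULT_REGIMES = (
    RegimeSpec(
        name="deep_water_formation",
        fraction=0.2,
        temperature={1850: 2.0, 2000: 2.5, 2100: 6.5},
        stratification={1850: 1.0, 2000: 0.95, 2100: 0.45},
        production_factor=0.02,
        kappa_ml=1.0e-2,
        z_ml=150.0,
        kappa_deep=3.0e-3,
    ),
    RegimeSpec(
        name="tropical_omz",
        fraction=0.4,
        temperature={1850: 26.0, 2000: 26.5, 2100: 28.0},
        stratification={1850: 1.0, 2000: 0.97, 2100: 0.85},
        production_factor=0.12,
        kappa_ml=1.0e-3,
        z_ml=40.0,
        kappa_deep=1.5e-5,
    ),
    RegimeSpec(
        name="intermediate",
        fraction=0.4,
        temperature={1850: 12.0, 2000: 12.8, 2100: 15.0},
        stratification={1850: 1.0, 2000: 0.95, 2100: 0.75},
        production_factor=0.06,
        kappa_ml=3.0e-3,
        z_ml=60.0,
        kappa_deep=2.0e-4,
    ),
)


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world."""

    n_columns: int = 100
    regimes: tuple[RegimeSpec, ...] = DEFAULT_REGIMES
    jitter_production: float = 0.2  # relative, uniform
    jitter_temperature: float = 0.5  # degC, uniform offset (all slices)
    jitter_z_ml: float = 0.2  # relative
    jitter_kappa_deep: float = 0.3  # relative

    def __post_init__(self) -> None:
        if self.n_columns < len(self.regimes):
            raise ValueError("need at least one column per regime")
        total = sum(r.fraction for r in self.regimes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"regime fractions must sum to 1, got {total}")


def _regime_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n columns to regimes."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # most short-changed first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def generate_world(config: WorldConfig = WorldConfig(), seed: int = 0) -> list[ColumnForcing]:
    """Deterministically generate the column forcings of a world.

    Columns are grouped by regime (regime order and within-regime order
    are deterministic given the seed); each column jitters its regime's
    production factor, temperatures, mixed-layer depth and deep mixing
    so that no two columns are identical.
    """
    rng = np.random.default_rng(seed)
    counts = _regime_counts(config.n_columns, [r.fraction for r in config.regimes])
    world: list[ColumnForcing] = []
    cid = 0
    for regime, count in zip(config.regimes, counts):
        for _ in range(count):
            u = rng.uniform(-1.0, 1.0, size=4)
            t_off = config.jitter_temperature * u[1]
            world.append(
                ColumnForcing(
                    column_id=cid,
                    regime=regime.name,
                    surface_temperature={t: T + t_off for t, T in regime.temperature.items()},
                    production_factor=regime.production_factor * (1.0 + config.jitter_production * u[0]),
                    kappa_ml=regime.kappa_ml,
                    z_ml=regime.z_ml * (1.0 + config.jitter_z_ml * u[2]),
                    kappa_deep=regime.kappa_deep * (1.0 + config.jitter_kappa_deep * u[3]),
                    stratification=dict(regime.stratification),
                )
            )
            cid += 1
    return world


def run_ensemble(
    design: QuadratureDesign,
    world: list[ColumnForcing],
    grid: ColumnGrid = ColumnGrid(),
    constants: OceanConstants = OceanConstants(),
    time_slices: tuple[int, ...] = TIME_SLICES,
    progress: bool = False,
):
    """Solve every column for every design row and time slice.

    Returns an :class:`oxymap.archive.EnsembleArchive` whose run order
    equals the design row order.  The archive stores the water-column
    oxygen minimum (mmol m^-3) plus a suboxia flag per run/column/slice
    and the full design metadata.
    """
    from .archive import EnsembleArchive  # local import to avoid a cycle

    import logging

    log = logging.getLogger(__name__)
    R, N, S = design.n_runs, len(world), len(time_slices)
    min_o2 = np.empty((R, N, S))
    suboxic = np.zeros((R, N, S), dtype=bool)
    for q in range(R):
        w, kappa, a = design.nodes_phys[q]
        for j, forcing in enumerate(world):
            for k, t in enumerate(time_slices):
                prof = solve_column(forcing, grid, w, kappa, a, t, constants)
                min_o2[q, j, k] = prof.min_o2
                suboxic[q, j, k] = prof.suboxic
        if progress and (q + 1) % 25 == 0:
            log.info("run %d/%d complete", q + 1, R)
    regimes = [f.regime for f in world]
    return EnsembleArchive.build(min_o2, suboxic, design, regimes, list(time_slices))
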