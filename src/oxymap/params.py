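"""Uncertain-parameter space for the perturbed-parameter ensemble.

Three biogeochemical parameters are treated as uncertain: the detritus
sinking speed ``w`` (m day^-1), the vertical background diffusivity
``kappa`` (m^2 s^-1) and the maximum phytoplankton growth rate ``a``
(day^-1).  Each carries an independent Gaussian prior specified by its
mean and a relative standard deviation, truncated from below at a floor
so that physically meaningless (negative or near-zero) rates never reach
the simulator.

The standardized coordinate ``xi = (x - mean) / (rel_sd * mean)`` is the
unit-normal variable in which the Hermite chaos basis lives; all
quadrature designs and polynomial expansions downstream are expressed
in ``xi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["UncertainParameter", "ParameterSet", "PARAM_NAMES"]

#: Canonical parameter order used by every multi-index downstream.
PARAM_NAMES = ("w", "kappa", "a")


@dataclass(frozen=True)
class UncertainParameter:
    """A single uncertain input with a truncated-Gaussian prior.

    Parameters
    ----------
    name:
        One of ``"w"``, ``"kappa"``, ``"a"``.
    mean:
        Prior mean in physical units (w: m/day, kappa: m^2/s, a: 1/day).
    rel_sd:
        Standard deviation as a fraction of the mean (0 < rel_sd < 1).
    floor:
        Minimum admissible physical value; draws and quadrature nodes
        below it are clipped up to it.
    """

    name: str
    mean: float
    rel_sd: float
    floor: float

    def __post_init__(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter name {self.name!r}, expected one of {PARAM_NAMES}")
        if not self.mean > 0:
            raise ValueError(f"{self.name}: mean must be > 0, got {self.mean}")
        if not 0 < self.rel_sd < 1:
            raise ValueError(f"{self.name}: rel_sd must lie in (0, 1), got {self.rel_sd}")
        if not 0 <= self.floor < self.mean:
            raise ValueError(f"{self.name}: floor must satisfy 0 <= floor < mean, got {self.floor}")

    @property
    def sd(self) -> float:
        """Absolute standard deviation, in physical units."""
        return self.rel_sd * self.mean

    def standardize(self, x):
        """Map a physical value to the standardized coordinate xi.

        Pure location-scale inverse; truncation is *not* undone (it is
        not invertible), so ``standardize(destandardize(xi)) == xi``
        only on the untruncated branch.
        """
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def destandardize(self, xi):
        """Map standardized xi to a physical value, applying the floor.

        The result is ``max(mean * (1 + rel_sd * xi), floor)`` and is
        therefore non-decreasing in xi and never below the floor.
        """
        return np.maximum(self.mean * (1.0 + self.rel_sd * np.asarray(xi, dtype=float)), self.floor)

    def truncated_mass(self) -> float:
        """Prior probability mass clipped onto the floor (normal CDF)."""
        from scipy.stats import norm

        return float(norm.cdf((self.floor - self.mean) / self.sd))


@dataclass(frozen=True)
class ParameterSet:
    """The ordered triple (w, kappa, a) of uncertain parameters."""

    params: tuple[UncertainParameter, UncertainParameter, UncertainParameter]

    def __post_init__(self) -> None:
        names = tuple(p.name for p in self.params)
        if names != PARAM_NAMES:
            raise ValueError(f"parameters must be ordered {PARAM_NAMES}, got {names}")

    def __iter__(self) -> Iterator[UncertainParameter]:
        return iter(self.params)

    def __len__(self) -> int:
        return 3

    def __getitem__(self, key) -> UncertainParameter:
        if isinstance(key, str):
            return self.params[PARAM_NAMES.index(key)]
        return self.params[key]

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES

    @property
    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.params])

    def standardize(self, x) -> np.ndarray:
        """Vectorized standardize over the last axis (length 3)."""
        x = np.asarray(x, dtype=float)
        means = self.means
        sds = np.array([p.sd for p in self.params])
        return (x - means) / sds

    def destandardize(self, xi) -> np.ndarray:
        """Vectorized floor-truncated inverse map over the last axis."""
        xi = np.asarray(xi, dtype=float)
        means = self.means
        sds = np.array([p.sd for p in self.params])
        floors = np.array([p.floor for p in self.params])
        return np.maximum(means + sds * xi, floors)

    @classmethod
    def from_config(cls, cfg: dict) -> "ParameterSet":
        """Build from a ``parameters:`` config block.

        Expected layout::

            parameters:
              w:     {mean: 15.0,  rel_sd: 0.5,  floor: 0.75}
              kappa: {mean: 3.0e-5, rel_sd: 0.5, floor: 1.5e-6}
              a:     {mean: 0.6,   rel_sd: 0.25, floor: 0.03}

        ``floor`` may be omitted, in which case 5 % of the mean is used.
        """
        params = []
        for name in PARAM_NAMES:
            if name not in cfg:
                raise KeyError(f"parameters block missing entry for {name!r}")
            entry = cfg[name]
            mean = float(entry["mean"])
            floor = float(entry.get("floor", 0.05 * mean))
            params.append(UncertainParameter(name, mean, float(entry["rel_sd"]), floor))
        return cls(tuple(params))

    @classmethod
    def default(cls) -> "ParameterSet":
        """Priors with 50 % relative sd on w and kappa and 25 % on a.

        Means are typical coarse-BGCM values (w = 15 m/day, kappa =
        3e-5 m^2/s, a = 0.6 1/day); floors sit at 5 % of the mean, which
        truncates < 3 % of prior mass per parameter.
        """
        return cls(
            (
                UncertainParameter("w", 15.0, 0.5, 0.75),
                UncertainParameter("kappa", 3.0e-5, 0.5, 1.5e-6),
                UncertainParameter("a", 0.6, 0.25, 0.03),
            )
        )
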