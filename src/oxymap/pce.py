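"""Polynomial chaos expansion and Sobol variance decomposition.

The ensemble is designed as a full tensor Gauss-Hermite quadrature in
the standardized (unit-normal) coordinates of the three uncertain
parameters.  Running the simulator only at the quadrature nodes
("collocation") allows a non-intrusive spectral projection onto the
orthonormal probabilists' Hermite basis:

    Y(xi) ~= sum_alpha c_alpha * psi_alpha(xi),
    psi_alpha(xi) = prod_i He_{alpha_i}(xi_i) / sqrt(alpha_i!),

with coefficients obtained by discrete projection

    c_alpha = sum_q w_q * Y(xi_q) * psi_alpha(xi_q).

Because the basis is orthonormal under the standard-normal product
measure, the output variance decomposes over squared coefficients and
Sobol indices fall out by grouping multi-indices by the set of
parameters they involve: the main effect of parameter i collects every
alpha whose only nonzero entry is position i, pairwise interactions
collect the alphas supported on exactly that pair, and so on.  With a
total-order-3 basis in three parameters this yields three main effects,
three pairwise interactions and one triple interaction that together
account for 100 % of the expansion variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .params import PARAM_NAMES, ParameterSet

__all__ = [
    "hermite",
    "basis_eval",
    "multi_indices",
    "QuadratureDesign",
    "build_design",
    "PCEField",
    "fit_pce",
    "SobolField",
    "sobol_decompose",
    "ensemble_moments",
    "SOBOL_GROUPS",
]


def hermite(n: int, x):
    """Probabilists' Hermite polynomial He_n(x).

    Evaluated by the three-term recurrence He_0 = 1, He_1 = x,
    He_{n+1}(x) = x He_n(x) - n He_{n-1}(x).  Orthogonal under the
    standard-normal weight with E[He_m He_n] = n! delta_mn.
    """
    if n < 0:
        raise ValueError("order must be non-negative")
    x = np.asarray(x, dtype=float)
    h_prev = np.ones_like(x)
    if n == 0:
        return h_prev if h_prev.ndim else float(h_prev)
    h = x.copy()
    for k in range(1, n):
        h, h_prev = x * h - k * h_prev, h
    return h if h.ndim else float(h)


def multi_indices(max_order: int = 3, ndim: int = 3) -> list[tuple[int, ...]]:
    """All multi-indices with total order <= max_order, constant first.

    Ordered by total order, then lexicographically; for max_order 3 and
    three dimensions this is the 20-member basis.
    """
    out = []
    for total in range(max_order + 1):
        for alpha in itertools.product(range(total + 1), repeat=ndim):
            if sum(alpha) == total:
                out.append(alpha)
    return out


def basis_eval(alpha: tuple[int, ...], xi) -> np.ndarray:
    """Orthonormal tensor Hermite basis function psi_alpha(xi).

    ``xi`` has the parameter dimension last (shape (..., ndim)); returns
    shape (...).  Normalization by sqrt(alpha_i!) makes the family
    orthonormal under the independent standard-normal measure.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape[-1] != len(alpha):
        raise ValueError(f"xi last axis {xi.shape[-1]} != multi-index length {len(alpha)}")
    out = np.ones(xi.shape[:-1])
    for i, n in enumerate(alpha):
        if n:
            out = out * hermite(n, xi[..., i]) / math.sqrt(math.factorial(n))
    return out


@dataclass(frozen=True)
class QuadratureDesign:
    """Tensor Gauss-Hermite collocation design.

    Attributes
    ----------
    nodes_std:
        (R, 3) standardized coordinates of the runs.
    nodes_phys:
        (R, 3) physical parameter values (floor truncation applied).
    weights:
        (R,) positive quadrature weights, normalized to sum to 1.
    points_per_dim:
        Size of the underlying 1-D rule; R = points_per_dim**3.
    """

    nodes_std: np.ndarray
    nodes_phys: np.ndarray
    weights: np.ndarray
    points_per_dim: int

    def __post_init__(self) -> None:
        R = self.points_per_dim ** self.nodes_std.shape[1]
        if self.nodes_std.shape[0] != R or self.weights.shape != (R,):
            raise ValueError("design shape inconsistent with points_per_dim")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")

    @property
    def n_runs(self) -> int:
        return self.nodes_std.shape[0]


def build_design(params: ParameterSet, points_per_dim: int = 5) -> QuadratureDesign:
    """Full tensor Gauss-Hermite design in standardized coordinates.

    The 1-D rule is Gauss-Hermite for the *standard normal* weight:
    physicists' nodes scaled by sqrt(2), weights divided by sqrt(pi).
    An n-point rule integrates polynomials to degree 2n-1 exactly, so
    the default 5-point rule (125 runs in 3-D) is exact for all products
    of basis functions up to total order 3 on each axis.

    Physical node values pass through the truncation floor; weights are
    left untouched (the design mimics running a simulator whose inputs
    were clipped, not a renormalized prior).
    """
    if points_per_dim < 1:
        raise ValueError("points_per_dim must be >= 1")
    # hermgauss is the physicists' rule (weight exp(-x^2)).
    x_phys, w_phys = np.polynomial.hermite.hermgauss(points_per_dim)
    nodes_1d = x_phys * math.sqrt(2.0)
    weights_1d = w_phys / math.sqrt(math.pi)
    weights_1d /= weights_1d.sum()  # remove rounding residue

    grids = np.meshgrid(*([nodes_1d] * 3), indexing="ij")
    nodes_std = np.stack([g.ravel() for g in grids], axis=-1)
    wg = np.meshgrid(*([weights_1d] * 3), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wg], axis=-1), axis=-1)
    weights /= weights.sum()

    nodes_phys = params.destandardize(nodes_std)
    return QuadratureDesign(nodes_std, nodes_phys, weights, points_per_dim)


@dataclass(frozen=True)
class PCEField:
    """Per-gridpoint Hermite-chaos coefficients for one output field.

    ``coeffs`` has shape (n_terms, n_gridpoints); ``basis[0]`` is always
    the zero multi-index, whose coefficient equals the weighted ensemble
    mean.
    """

    basis: tuple[tuple[int, ...], ...]
    coeffs: np.ndarray
    output_name: str = "output"

    def __post_init__(self) -> None:
        if self.basis[0] != (0,) * len(self.basis[0]):
            raise ValueError("basis must list the constant term first")
        if self.coeffs.shape[0] != len(self.basis):
            raise ValueError("coefficient rows must match basis size")

    @property
    def mean(self) -> np.ndarray:
        return self.coeffs[0]

    @property
    def variance(self) -> np.ndarray:
        """Expansion variance D = sum_{alpha != 0} c_alpha^2."""
        return np.sum(self.coeffs[1:] ** 2, axis=0)

    def evaluate(self, xi) -> np.ndarray:
        """Emulator prediction at standardized points xi (..., 3)."""
        psi = np.stack([basis_eval(a, xi) for a in self.basis], axis=-1)
        return psi @ self.coeffs


def fit_pce(design: QuadratureDesign, outputs, max_order: int = 3, output_name: str = "output") -> PCEField:
    """Spectral projection of per-run outputs onto the Hermite basis.

    Parameters
    ----------
    design:
        The quadrature design the runs were executed at.
    outputs:
        Array of shape (R,) or (R, n_gridpoints); one value per design
        row per gridpoint, no missing values.
    max_order:
        Total polynomial order retained (default 3; with three
        parameters this keeps 20 terms).
    """
    Y = np.asarray(outputs, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != design.n_runs:
        raise ValueError(f"outputs has {Y.shape[0]} rows but design has {design.n_runs} runs")
    if not np.all(np.isfinite(Y)):
        raise ValueError("outputs contain non-finite values; mask gridpoints beforehand")

    basis = tuple(multi_indices(max_order, 3))
    psi = np.stack([basis_eval(a, design.nodes_std) for a in basis], axis=0)  # (T, R)
    coeffs = (psi * design.weights) @ Y  # (T, G)
    return PCEField(basis, coeffs, output_name)


# Parameter subsets in canonical report order: mains, pairs, triple.
SOBOL_GROUPS: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2),
)


def sobol_group_name(group: tuple[int, ...]) -> str:
    return "S_" + "_".join(PARAM_NAMES[i] for i in group)


@dataclass(frozen=True)
class SobolField:
    """Per-gridpoint variance fractions from a PCE.

    ``fractions`` maps group names (``S_w`` ... ``S_w_kappa_a``) to
    arrays in percent.  Gridpoints with zero total variance carry NaN
    fractions rather than zeros: 0 % would falsely assert insensitivity.
    """

    total_variance: np.ndarray
    fractions: dict[str, np.ndarray]
    output_name: str = "output"

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of gridpoints where fractions are defined."""
        return self.total_variance > 0

    def main_effects(self) -> dict[str, np.ndarray]:
        return {f"S_{n}": self.fractions[f"S_{n}"] for n in PARAM_NAMES}


def sobol_decompose(pce: PCEField) -> SobolField:
    """Variance-based Sobol decomposition from PCE coefficients.

    The fraction for a parameter subset U sums c_alpha^2 over every
    multi-index whose nonzero positions are exactly U, divided by the
    total expansion variance, in percent.  Main effects, the three
    pairwise interactions and the triple interaction jointly account
    for all of the variance (they partition the non-constant basis).
    """
    D = pce.variance
    # A numerically zero variance (projection residue of a constant
    # output) must not masquerade as a defined decomposition.
    sd_floor = 1e-12 * (1.0 + np.abs(pce.mean))
    defined = D > sd_floor**2
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_D = np.where(defined, 1.0 / np.where(defined, D, 1.0), np.nan)
    D = np.where(defined, D, 0.0)

    fractions: dict[str, np.ndarray] = {}
    for group in SOBOL_GROUPS:
        gset = frozenset(group)
        part = np.zeros_like(D)
        for row, alpha in enumerate(pce.basis):
            if frozenset(i for i, n in enumerate(alpha) if n) == gset:
                part += pce.coeffs[row] ** 2
        fractions[sobol_group_name(group)] = 100.0 * part * inv_D
    return SobolField(D, fractions, pce.output_name)


def ensemble_moments(design: QuadratureDesign, outputs) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature-weighted per-gridpoint mean and standard deviation.

    mean = sum_q w_q Y_q;  sd = sqrt(sum_q w_q (Y_q - mean)^2).  The
    weights are collocation weights, so these are estimates of the
    prior-predictive moments, not sample statistics of equiprobable
    members.
    """
    Y = np.asarray(outputs, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != design.n_runs:
        raise ValueError(f"outputs has {Y.shape[0]} rows but design has {design.n_runs} runs")
    w = design.weights
    mean = w @ Y
    var = w @ (Y - mean) ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    if squeeze:
        return float(mean[0]), float(sd[0])
    return mean, sd
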