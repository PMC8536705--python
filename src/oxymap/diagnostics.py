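"""Map-level diagnostics of the perturbed-parameter ensemble.

Everything here reduces the run x column ensemble fields to per-column
maps and tables: the ensemble-mean projected change, the
noise-to-signal ratio of that change (ensemble sd normalized by the
magnitude of the mean change, in %), the contemporary ensemble spread
and coefficient of variation, the low-variance mask applied before
interpreting sensitivity maps, spatial averages of Sobol indices over
named regions, and the benchmarking scores that combine a dominant
main effect with a large contemporary spread.

Statistics are quadrature-weighted by default — the ensemble members
sit at collocation nodes and are not equiprobable samples — but every
entry point accepts ``weights=None`` for plain unweighted statistics,
for comparison with archives produced by equal-weight designs.

Missing values are always explicit NaN sentinels, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .archive import EnsembleArchive
from .params import PARAM_NAMES
from .pce import SobolField

__all__ = [
    "DiagnosticMaps",
    "RegionMask",
    "change_field",
    "weighted_moments",
    "noise_to_signal",
    "contemporary_spread_maps",
    "mask_low_variance",
    "regional_average",
    "benchmark_scores",
    "benchmark_report",
    "contemporary_vs_projected_rank_correlation",
    "compute_diagnostics",
]


def weighted_moments(values: np.ndarray, weights: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and sd over the run axis (axis 0).

    ``weights=None`` gives unweighted statistics (population sd).
    """
    Y = np.asarray(values, dtype=float)
    if weights is None:
        w = np.full(Y.shape[0], 1.0 / Y.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (Y.shape[0],):
            raise ValueError("weights must have one entry per run")
        w = w / w.sum()
    mean = np.tensordot(w, Y, axes=(0, 0))
    var = np.tensordot(w, (Y - mean) ** 2, axes=(0, 0))
    return mean, np.sqrt(np.maximum(var, 0.0))


def change_field(archive: EnsembleArchive, from_slice: int = 1850, to_slice: int = 2100) -> np.ndarray:
    """Per-run, per-column change (to_slice minus from_slice)."""
    return (archive.slice(to_slice) - archive.slice(from_slice)).values


def noise_to_signal(
    change: np.ndarray, weights: np.ndarray | None, eps: float = 1e-6
) -> np.ndarray:
    """Ensemble sd of the change over |ensemble mean change|, in %.

    Columns whose mean change magnitude does not exceed ``eps``
    (mmol m-3) get NaN — the ratio is undefined there, not infinite.
    """
    mean, sd = weighted_moments(change, weights)
    out = np.full_like(mean, np.nan)
    ok = np.abs(mean) > eps
    out[ok] = 100.0 * sd[ok] / np.abs(mean[ok])
    return out


def contemporary_spread_maps(
    archive: EnsembleArchive,
    weights: np.ndarray | None = None,
    year: int = 2000,
    eps: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble spread (mmol m-3) and CV (%) of the contemporary field.

    The CV is definitionally the noise-to-signal ratio applied to the
    raw (not differenced) field of the given year.
    """
    field = archive.slice(year).values
    mean, sd = weighted_moments(field, weights)
    cv = np.full_like(mean, np.nan)
    ok = np.abs(mean) > eps
    cv[ok] = 100.0 * sd[ok] / np.abs(mean[ok])
    return sd, cv


def mask_low_variance(
    sobol: SobolField, mean_field: np.ndarray, threshold_frac: float = 0.06
) -> np.ndarray:
    """True where the ensemble sd falls below a fraction of the mean.

    Sensitivity fractions are meaningless where the ensemble barely
    varies; the default masks columns whose standard deviation
    (sqrt of the PCE total variance) is below 6 % of the local mean
    magnitude, and always masks zero-variance columns.
    """
    sd = np.sqrt(np.maximum(sobol.total_variance, 0.0))
    return sd < threshold_frac * np.abs(np.asarray(mean_field, dtype=float))


@dataclass(frozen=True)
class RegionMask:
    """A named set of columns, selected one of three ways.

    Exactly one of ``columns`` (explicit ids), ``regime`` (label match
    against the archive's regime codes) or ``box`` (lat/lon bounds
    ``(lat_min, lat_max, lon_min, lon_max)``, requiring per-column
    ``lat``/``lon`` variables in the archive) must be given.
    """

    name: str
    columns: tuple[int, ...] | None = None
    regime: str | None = None
    box: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        n = sum(x is not None for x in (self.columns, self.regime, self.box))
        if n != 1:
            raise ValueError(f"region {self.name!r}: give exactly one of columns/regime/box")

    def resolve(self, archive: EnsembleArchive) -> np.ndarray:
        if self.columns is not None:
            idx = np.asarray(self.columns, dtype=int)
        elif self.regime is not None:
            idx = np.flatnonzero(archive.regimes == self.regime)
        else:
            if "lat" not in archive.ds or "lon" not in archive.ds:
                raise ValueError(f"region {self.name!r}: archive has no lat/lon variables")
            lat = np.asarray(archive.ds["lat"].values, dtype=float)
            lon = np.asarray(archive.ds["lon"].values, dtype=float)
            la0, la1, lo0, lo1 = self.box
            idx = np.flatnonzero((lat >= la0) & (lat <= la1) & (lon >= lo0) & (lon <= lo1))
        if idx.size == 0:
            raise ValueError(f"region {self.name!r} selects no columns")
        return idx


SOBOL_COLUMNS = ("S_w", "S_kappa", "S_a", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a")


def regional_average(
    sobol: SobolField,
    regions: list[RegionMask],
    archive: EnsembleArchive,
    mask: np.ndarray | None = None,
    mode: str = "mean_percent",
) -> pd.DataFrame:
    """Spatial averages of the Sobol fractions over named regions.

    ``mode="mean_percent"`` (default) takes the unweighted arithmetic
    mean of the per-column percentage indices over the unmasked columns
    of each region — every location counts equally.
    ``mode="pooled_variance"`` instead pools the absolute variance
    contributions first (sum of each group's variance share over the
    region divided by the summed total variance), which weights
    high-variance columns more.  Regions whose columns are all masked
    produce an all-NaN row.  Regions must not overlap.
    """
    if mode not in ("mean_percent", "pooled_variance"):
        raise ValueError(f"unknown mode {mode!r}")
    import logging

    log = logging.getLogger(__name__)
    seen: set[int] = set()
    rows = []
    for region in regions:
        idx = region.resolve(archive)
        overlap = seen.intersection(idx.tolist())
        if overlap:
            raise ValueError(f"region {region.name!r} overlaps another region (columns {sorted(overlap)[:5]}...)")
        seen.update(idx.tolist())
        keep = idx if mask is None else idx[~np.asarray(mask)[idx]]
        row: dict[str, float] = {"region": region.name, "n_columns": len(keep)}
        if len(keep) == 0:
            log.warning("region %s has no unmasked columns; reporting NaN", region.name)
            for c in SOBOL_COLUMNS:
                row[c] = np.nan
            row["variance_total"] = np.nan
        else:
            D = sobol.total_variance[keep]
            for c in SOBOL_COLUMNS:
                if mode == "mean_percent":
                    row[c] = float(np.nanmean(sobol.fractions[c][keep]))
                else:
                    part = np.nansum(sobol.fractions[c][keep] / 100.0 * D)
                    row[c] = float(100.0 * part / D.sum()) if D.sum() > 0 else np.nan
            row["variance_total"] = float(np.mean(D))
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def benchmark_scores(
    sobol: SobolField,
    spread: np.ndarray,
    mask: np.ndarray,
    spread_quantile: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-parameter benchmarking scores, NaN where ineligible.

    A column is eligible for benchmarking a parameter when it is not
    masked for low variance and its contemporary ensemble spread
    exceeds the given quantile of the spread over unmasked columns;
    the score is then simply that parameter's contemporary main effect
    in percent — observations at high-spread columns dominated by one
    parameter constrain that parameter best.
    """
    mask = np.asarray(mask, dtype=bool)
    spread = np.asarray(spread, dtype=float)
    unmasked = ~mask
    if not unmasked.any():
        return {name: np.full(mask.shape, np.nan) for name in PARAM_NAMES}
    threshold = np.quantile(spread[unmasked], spread_quantile)
    eligible = unmasked & (spread > threshold)
    scores = {}
    for name in PARAM_NAMES:
        s = np.where(eligible, sobol.fractions[f"S_{name}"], np.nan)
        scores[name] = s
    return scores


def benchmark_report(
    scores: dict[str, np.ndarray],
    archive: EnsembleArchive,
    top_k: int = 5,
) -> pd.DataFrame:
    """Top-k benchmarking columns per parameter, with regime labels."""
    regimes = archive.regimes
    rows = []
    for name, s in scores.items():
        order = np.argsort(-np.where(np.isnan(s), -np.inf, s))
        kept = [i for i in order[: top_k] if np.isfinite(s[i])]
        for rank, i in enumerate(kept, start=1):
            rows.append(
                {
                    "parameter": name,
                    "rank": rank,
                    "column": int(i),
                    "regime": regimes[i],
                    "score_pct": float(s[i]),
                }
            )
    return pd.DataFrame(rows)


def contemporary_vs_projected_rank_correlation(
    contemporary_cv: np.ndarray, projected_ns: np.ndarray
) -> float:
    """Spearman rank correlation across columns (NaNs dropped pairwise).

    Contemporary parameter sensitivity need not be collocated with
    projection uncertainty; this statistic quantifies how far the two
    maps agree in ranking, without asserting any particular value.
    """
    ok = np.isfinite(contemporary_cv) & np.isfinite(projected_ns)
    if ok.sum() < 3:
        return float("nan")
    rho, _ = stats.spearmanr(contemporary_cv[ok], projected_ns[ok])
    return float(rho)


@dataclass(frozen=True)
class DiagnosticMaps:
    """Bundle of the per-column diagnostic maps."""

    mean_change: np.ndarray  # mmol m-3, projected minus preindustrial
    noise_to_signal: np.ndarray  # %
    contemporary_spread: np.ndarray  # mmol m-3
    contemporary_cv: np.ndarray  # %
    low_variance_mask: np.ndarray  # bool
    rank_correlation: float


def compute_diagnostics(
    archive: EnsembleArchive,
    sobol_contemporary: SobolField,
    weighted: bool = True,
    eps: float = 1e-6,
    mask_threshold: float = 0.06,
    from_slice: int = 1850,
    to_slice: int = 2100,
) -> DiagnosticMaps:
    """Compute the full set of maps in one pass."""
    weights = archive.weights if weighted else None
    change = change_field(archive, from_slice, to_slice)
    mean_change, _ = weighted_moments(change, weights)
    ns = noise_to_signal(change, weights, eps)
    spread, cv = contemporary_spread_maps(archive, weights, eps=eps)
    mean_2000, _ = weighted_moments(archive.slice(2000).values, weights)
    mask = mask_low_variance(sobol_contemporary, mean_2000, mask_threshold)
    rho = contemporary_vs_projected_rank_correlation(cv, ns)
    return DiagnosticMaps(mean_change, ns, spread, cv, mask, rho)
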