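"""Gridded ensemble archives: the run x column x time-slice O2 minima.

The archive is an xarray Dataset with a small fixed schema, written as
classic NetCDF so that any NetCDF tool can read it:

    dims        run (R), column (N), time (3), param (3)
    variables   min_O2   (run, column, time)  [mmol m-3]
                suboxic  (run, column, time)  0/1 flag
                node_phys, node_std (run, param)
                weight   (run)
                regime_code (column)          index into regime_labels
    attrs       param_names, regime_labels, points_per_dim,
                seed, config_hash

Externally produced archives (e.g. output deposited alongside a model
study) flow through the same class: :func:`read_archive` accepts a
variable-name mapping and a unit-conversion table so that a file whose
minimum-oxygen variable has a different name or is stored in mol m-3
can be adapted without rewriting it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .pce import PCEField, QuadratureDesign, SobolField

__all__ = [
    "EnsembleArchive",
    "read_archive",
    "UNIT_CONVERSIONS",
    "NETCDF_ENGINE",
    "pce_to_dataset",
    "dataset_to_pce",
    "sobol_to_dataset",
    "dataset_to_sobol",
]

#: Engine used for all NetCDF I/O (classic NetCDF3 format).
NETCDF_ENGINE = "scipy"

#: Accepted spellings of the canonical unit, and conversion factors to
#: mmol m-3 for units that need rescaling.
CANONICAL_UNITS = {"mmol m-3", "mmol m^-3", "mmol/m3", "mmol/m^3", "mmol O2 m-3"}
UNIT_CONVERSIONS = {
    "mol m-3": 1.0e3,
    "mol/m3": 1.0e3,
    "umol l-1": 1.0,  # 1 umol/L == 1 mmol/m3
    "umol/l": 1.0,
    "mumol l-1": 1.0,
}


@dataclass(frozen=True)
class EnsembleArchive:
    """Validated wrapper around the archive Dataset."""

    ds: xr.Dataset

    REQUIRED_DIMS = ("run", "column", "time")
    REQUIRED_VARS = ("min_O2", "node_phys", "node_std", "weight")

    def __post_init__(self) -> None:
        for dim in self.REQUIRED_DIMS:
            if dim not in self.ds.dims:
                raise ValueError(f"archive schema error: missing dimension {dim!r}")
        for var in self.REQUIRED_VARS:
            if var not in self.ds:
                raise ValueError(f"archive schema error: missing variable {var!r}")
        if tuple(self.ds["min_O2"].dims) != self.REQUIRED_DIMS:
            raise ValueError("archive schema error: min_O2 must have dims (run, column, time)")
        w = np.asarray(self.ds["weight"].values, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("archive schema error: quadrature weights must sum to 1")
        units = str(self.ds["min_O2"].attrs.get("units", "")).strip()
        if units and units not in CANONICAL_UNITS:
            raise ValueError(
                f"archive schema error: min_O2 units {units!r}; expected mmol m-3 "
                "(pass unit_conversions to read_archive to rescale)"
            )

    # -- construction ---------------------------------------------------

    @classmethod
    def build(
        cls,
        min_o2: np.ndarray,
        suboxic: np.ndarray,
        design: QuadratureDesign,
        regimes: list[str],
        time_slices: list[int],
        seed: int | None = None,
        config_hash: str = "",
    ) -> "EnsembleArchive":
        R, N, S = min_o2.shape
        labels = sorted(set(regimes))
        code = {name: i for i, name in enumerate(labels)}
        ds = xr.Dataset(
            data_vars={
                "min_O2": (
                    ("run", "column", "time"),
                    np.asarray(min_o2, dtype=float),
                    {"units": "mmol m-3", "long_name": "water-column oxygen minimum"},
                ),
                "suboxic": (
                    ("run", "column", "time"),
                    np.asarray(suboxic, dtype=np.int8),
                    {"long_name": "1 where the unclipped solution went negative"},
                ),
                "node_phys": (("run", "param"), design.nodes_phys),
                "node_std": (("run", "param"), design.nodes_std),
                "weight": (("run",), design.weights),
                "regime_code": (("column",), np.array([code[r] for r in regimes], dtype=np.int32)),
            },
            coords={
                "run": ("run", np.arange(R, dtype=np.int32)),
                "column": ("column", np.arange(N, dtype=np.int32)),
                "time": ("time", np.asarray(time_slices, dtype=np.int32), {"units": "year"}),
                "param": ("param", np.arange(3, dtype=np.int32)),
            },
            attrs={
                "title": "perturbed-parameter ensemble of water-column oxygen minima",
                "param_names": "w kappa a",
                "regime_labels": ",".join(labels),
                "points_per_dim": np.int32(design.points_per_dim),
                "config_hash": config_hash,
            },
        )
        if seed is not None:
            ds.attrs["seed"] = np.int32(seed)
        return cls(ds)

    # -- accessors ------------------------------------------------------

    @property
    def min_o2(self) -> xr.DataArray:
        return self.ds["min_O2"]

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.ds["weight"].values, dtype=float)

    @property
    def times(self) -> list[int]:
        return [int(t) for t in self.ds["time"].values]

    @property
    def n_runs(self) -> int:
        return self.ds.sizes["run"]

    @property
    def n_columns(self) -> int:
        return self.ds.sizes["column"]

    @property
    def regimes(self) -> np.ndarray:
        """Per-column regime labels (empty strings if not recorded)."""
        if "regime_code" not in self.ds:
            return np.array([""] * self.n_columns)
        labels = str(self.ds.attrs.get("regime_labels", "")).split(",")
        codes = np.asarray(self.ds["regime_code"].values, dtype=int)
        return np.array([labels[c] if 0 <= c < len(labels) else "" for c in codes])

    @property
    def design(self) -> QuadratureDesign:
        ppd = int(self.ds.attrs.get("points_per_dim", round(self.n_runs ** (1 / 3))))
        return QuadratureDesign(
            np.asarray(self.ds["node_std"].values, dtype=float),
            np.asarray(self.ds["node_phys"].values, dtype=float),
            self.weights,
            ppd,
        )

    def slice(self, year: int) -> xr.DataArray:
        """The (run, column) field of one time slice."""
        if year not in self.times:
            raise KeyError(f"time slice {year} not in archive (has {self.times})")
        return self.min_o2.sel(time=year)

    # -- I/O ------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path, engine=NETCDF_ENGINE)

    @classmethod
    def open(cls, path, var_map: dict | None = None, unit_conversions: dict | None = None) -> "EnsembleArchive":
        return read_archive(path, var_map=var_map, unit_conversions=unit_conversions)


def read_archive(path, var_map: dict | None = None, unit_conversions: dict | None = None) -> EnsembleArchive:
    """Open and validate an ensemble archive.

    Parameters
    ----------
    path:
        NetCDF file following the archive schema, possibly with
        different names.
    var_map:
        Optional mapping from the file's dimension/variable names to
        the schema names, e.g. ``{"member": "run", "o2min": "min_O2"}``.
    unit_conversions:
        Optional mapping ``unit string -> factor to mmol m-3`` merged
        over the built-in table; applied when min_O2 carries a
        non-canonical unit.
    """
    with xr.open_dataset(path, engine=NETCDF_ENGINE) as ds:
        ds = ds.load()
    if var_map:
        rename = {src: dst for src, dst in var_map.items() if src in ds or src in ds.dims}
        missing = set(var_map) - set(rename)
        if missing:
            raise ValueError(f"var_map names not present in file: {sorted(missing)}")
        ds = ds.rename(rename)

    if "min_O2" in ds:
        units = str(ds["min_O2"].attrs.get("units", "")).strip()
        table = {**UNIT_CONVERSIONS, **(unit_conversions or {})}
        if units and units not in CANONICAL_UNITS:
            if units in table:
                ds["min_O2"] = ds["min_O2"] * table[units]
                ds["min_O2"].attrs["units"] = "mmol m-3"
            else:
                raise ValueError(
                    f"min_O2 has units {units!r} with no declared conversion to mmol m-3"
                )
    return EnsembleArchive(ds)


# -- PCE / Sobol field serialization ------------------------------------
#
# One Dataset can hold several output fields (the three time slices and
# the projected-change field); they share the basis, indexed by the
# ``term`` dimension whose multi-index lives in the alpha_* variables.


def pce_to_dataset(fields: dict[str, PCEField]) -> xr.Dataset:
    names = list(fields)
    first = fields[names[0]]
    basis = first.basis
    for name in names[1:]:
        if fields[name].basis != basis:
            raise ValueError("all PCE fields in one dataset must share a basis")
    alpha = np.array(basis, dtype=np.int32)
    data = {f"coeff_{name}": (("term", "column"), fields[name].coeffs) for name in names}
    ds = xr.Dataset(
        data_vars={
            **data,
            "alpha_w": (("term",), alpha[:, 0]),
            "alpha_kappa": (("term",), alpha[:, 1]),
            "alpha_a": (("term",), alpha[:, 2]),
        },
        coords={"term": ("term", np.arange(len(basis), dtype=np.int32))},
        attrs={"field_names": ",".join(names), "basis": "probabilists Hermite, orthonormal"},
    )
    return ds


def dataset_to_pce(ds: xr.Dataset) -> dict[str, PCEField]:
    names = [n for n in str(ds.attrs.get("field_names", "")).split(",") if n]
    if not names:
        names = [v[len("coeff_"):] for v in ds.data_vars if str(v).startswith("coeff_")]
    basis = tuple(
        (int(w), int(k), int(a))
        for w, k, a in zip(ds["alpha_w"].values, ds["alpha_kappa"].values, ds["alpha_a"].values)
    )
    out = {}
    for name in names:
        coeffs = np.asarray(ds[f"coeff_{name}"].values, dtype=float)
        out[name] = PCEField(basis, coeffs, output_name=name)
    return out


_SOBOL_VARS = ("S_w", "S_kappa", "S_a", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a")


def sobol_to_dataset(fields: dict[str, SobolField]) -> xr.Dataset:
    names = list(fields)
    data = {}
    for var in _SOBOL_VARS:
        data[var] = (
            ("field", "column"),
            np.stack([fields[n].fractions[var] for n in names]),
            {"units": "%"},
        )
    data["variance_total"] = (
        ("field", "column"),
        np.stack([fields[n].total_variance for n in names]),
        {"units": "(mmol m-3)^2"},
    )
    return xr.Dataset(
        data_vars=data,
        coords={"field": ("field", np.arange(len(names), dtype=np.int32))},
        attrs={"field_names": ",".join(names)},
    )


def dataset_to_sobol(ds: xr.Dataset) -> dict[str, SobolField]:
    names = [n for n in str(ds.attrs["field_names"]).split(",") if n]
    out = {}
    for i, name in enumerate(names):
        fractions = {var: np.asarray(ds[var].values[i], dtype=float) for var in _SOBOL_VARS}
        out[name] = SobolField(
            np.asarray(ds["variance_total"].values[i], dtype=float), fractions, output_name=name
        )
    return out
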