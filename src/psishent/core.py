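"""Core domain types and file IO for compositional grid time series.

The raw input of every analysis here is *compositional* spatio-temporal
data: on a rectangular lattice of grid cells, at each time step, each
category of a categorical variable (a land-cover class, a species group,
a disease state ...) occupies a fraction of the cell.  The fractions are
non-negative and sum to at most 1 per (cell, time) — a remainder below 1
is treated as unclassified ground.  *Observational* data are the point
form of the same information: (x, y, t, category, weight) records.

Two file dialects are supported for grids: a long CSV with one row per
(cell, time, category) and a gridded NetCDF-style array with dimensions
(time, y, x, category).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger("psishent")

#: absolute slack allowed on per-(cell,time) fraction sums
FRACTION_SUM_TOL = 1e-9

LONG_CSV_COLUMNS = ["cell_id", "row", "col", "lon", "lat", "time", "category", "fraction"]
REQUIRED_LONG_COLUMNS = ["cell_id", "row", "col", "time", "category", "fraction"]


class FormatError(ValueError):
    """A file does not match the declared dialect."""


class DuplicateKeyError(ValueError):
    """The same (cell, time, category) key appears more than once."""


class ValidationError(ValueError):
    """Data violate a structural invariant."""


@dataclass
class Violation:
    """One invariant violation, with enough context to locate it."""

    kind: str
    location: tuple
    message: str


# ---------------------------------------------------------------------------
# CompositionGrid
# ---------------------------------------------------------------------------

@dataclass
class CompositionGrid:
    """Per-(cell, time, category) occupation fractions on a lattice.

    Parameters
    ----------
    cell_index
        (n_cells, 2) integer array of 0-based (row, col) lattice positions.
    cell_ids
        Opaque identifiers, one per cell.
    times
        Strictly increasing time labels (numeric or orderable).
    categories
        Unique category labels, order fixed.
    fractions
        Array of shape (n_cells, n_times, n_categories), values in [0, 1].
    coords
        Optional (n_cells, 2) array of (lon, lat); passthrough metadata.
    """

    cell_index: np.ndarray
    cell_ids: list
    times: list
    categories: list
    fractions: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_index = np.asarray(self.cell_index, dtype=int)
        self.fractions = np.asarray(self.fractions, dtype=float)
        expected = (len(self.cell_ids), len(self.times), len(self.categories))
        if self.fractions.shape != expected:
            raise ValidationError(
                f"fractions shape {self.fractions.shape} != (cells, times, categories) {expected}"
            )
        report = validate(self)
        if report:
            raise ValidationError(
                "invalid grid: " + "; ".join(v.message for v in report[:5])
                + (f" (+{len(report) - 5} more)" if len(report) > 5 else "")
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the enclosing lattice."""
        return (int(self.cell_index[:, 0].max()) + 1, int(self.cell_index[:, 1].max()) + 1)

    def category_plane(self, category, time) -> np.ndarray:
        """Dense (n_rows, n_cols) fraction plane for one category at one time.

        Cells absent from the grid are NaN.
        """
        ci = self.categories.index(category) if category in self.categories else -1
        if ci < 0:
            raise KeyError(f"unknown category {category!r}")
        try:
            ti = self.times.index(time)
        except ValueError:
            raise KeyError(f"unknown time {time!r}") from None
        plane = np.full(self.shape, np.nan)
        plane[self.cell_index[:, 0], self.cell_index[:, 1]] = self.fractions[:, ti, ci]
        return plane

    def renormalised(self) -> "CompositionGrid":
        """Rescale fractions so each (cell, time) sums to 1 (zero sums kept)."""
        sums = self.fractions.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = np.where(sums > 0, self.fractions / sums, self.fractions)
        return dataclasses.replace(self, fractions=fr)


@dataclass
class ObservationSet:
    """Point records (x, y, t, category, weight) over a declared label set."""

    records: pd.DataFrame
    categories: list

    def __post_init__(self) -> None:
        needed = {"x", "y", "t", "category", "weight"}
        missing = needed - set(self.records.columns)
        if missing:
            raise FormatError(f"observation records missing columns: {sorted(missing)}")
        report = validate(self)
        if report:
            raise ValidationError("; ".join(v.message for v in report[:5]))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ProximitySpec:
    """Collocation rule for co-occurrences of order k across space/time/category.

    ``d_eps_S/T/C`` are the per-dimension collocation radii of the
    distance-rule (a k-subset co-occurs when every pair is within every
    radius); ``d_border`` admits observations just outside a spatial
    stratum; ``dissimilarity_C`` is a symmetric zero-diagonal category
    dissimilarity (None means the 0/1 indicator).
    """

    order_k: int = 3
    d_eps_S: float = 1.0
    d_eps_T: float = 0.0
    d_eps_C: float = 0.0
    d_border: float = 0.0
    metric_S: str = "euclidean"
    metric_T: str = "euclidean"
    dissimilarity_C: np.ndarray | None = None
    symmetric: bool = False
    categorisation_rule: Literal["strict", "fuzzy", "majority"] = "strict"
    d_refine: float | None = None  # tighter radius used by the fuzzy rule

    def __post_init__(self) -> None:
        if self.order_k < 2:
            raise ValidationError("order_k must be >= 2")
        if not (0 <= self.d_border < self.d_eps_S or self.d_eps_S == 0 == self.d_border):
            raise ValidationError("d_border must satisfy 0 <= d_border < d_eps_S")
        if self.dissimilarity_C is not None:
            d = np.asarray(self.dissimilarity_C, dtype=float)
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValidationError("dissimilarity_C must be square")
            if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
                raise ValidationError("dissimilarity_C must be symmetric with zero diagonal")
            self.dissimilarity_C = d


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(obj) -> list[Violation]:
    """Report every invariant violation in a grid or observation set.

    Returns an empty list iff all invariants hold; never raises.
    """
    out: list[Violation] = []
    if isinstance(obj, CompositionGrid):
        fr = obj.fractions
        if np.any(fr < 0) or np.any(fr > 1):
            bad = np.argwhere((fr < 0) | (fr > 1))
            for c, t, k in bad[:20]:
                out.append(Violation(
                    "fraction-range", (obj.cell_ids[c], obj.times[t], obj.categories[k]),
                    f"fraction {fr[c, t, k]:.6g} outside [0,1] at "
                    f"(cell {obj.cell_ids[c]}, time {obj.times[t]}, {obj.categories[k]})",
                ))
        sums = fr.sum(axis=2)
        bad = np.argwhere(sums > 1 + FRACTION_SUM_TOL)
        for c, t in bad[:20]:
            out.append(Violation(
                "fraction-sum", (obj.cell_ids[c], obj.times[t]),
                f"fraction sum {sums[c, t]:.6g} > 1 at (cell {obj.cell_ids[c]}, time {obj.times[t]})",
            ))
        ts = np.asarray(obj.times)
        if len(ts) > 1 and not np.all(ts[1:] > ts[:-1]):
            out.append(Violation("times-order", (), "times are not strictly increasing"))
        if len(set(obj.categories)) != len(obj.categories):
            out.append(Violation("category-dup", (), "category labels are not unique"))
        if len(set(obj.cell_ids)) != len(obj.cell_ids):
            out.append(Violation("cell-dup", (), "cell ids are not unique"))
    elif isinstance(obj, ObservationSet):
        rec = obj.records
        if (rec["weight"] < 0).any():
            idx = rec.index[rec["weight"] < 0][:20]
            out.append(Violation("weight", tuple(idx), "negative observation weights"))
        xy = rec[["x", "y", "t"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            out.append(Violation("coords", (), "non-finite coordinates"))
        unknown = set(rec["category"]) - set(obj.categories)
        if unknown:
            out.append(Violation("category", tuple(sorted(map(str, unknown))),
                                 f"categories outside the declared set: {sorted(map(str, unknown))}"))
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot validate {type(obj).__name__}")
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _grid_from_long(df: pd.DataFrame) -> CompositionGrid:
    missing = [c for c in REQUIRED_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"long-csv missing column(s): {missing}")
    dup = df.duplicated(subset=["cell_id", "time", "category"])
    if dup.any():
        keys = df.loc[dup, ["cell_id", "time", "category"]].head(5).to_records(index=False)
        raise DuplicateKeyError(f"duplicate (cell,time,category) keys, e.g. {list(keys)}")
    bad = (df["fraction"] < 0) | (df["fraction"] > 1)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} rows with fraction outside [0,1], "
            f"first at index {int(df.index[bad][0])}"
        )
    cells = (df[["cell_id", "row", "col"]].drop_duplicates("cell_id")
             .sort_values(["row", "col"]).reset_index(drop=True))
    times = sorted(df["time"].unique())
    categories = sorted(df["category"].unique())
    ci = {c: i for i, c in enumerate(cells["cell_id"])}
    ti = {t: i for i, t in enumerate(times)}
    ki = {k: i for i, k in enumerate(categories)}
    fr = np.zeros((len(cells), len(times), len(categories)))
    fr[df["cell_id"].map(ci), df["time"].map(ti), df["category"].map(ki)] = df["fraction"]
    coords = None
    if {"lon", "lat"} <= set(df.columns) and df["lon"].notna().any():
        cc = df[["cell_id", "lon", "lat"]].drop_duplicates("cell_id").set_index("cell_id")
        coords = cc.loc[cells["cell_id"], ["lon", "lat"]].to_numpy(dtype=float)
    return CompositionGrid(
        cell_index=cells[["row", "col"]].to_numpy(),
        cell_ids=list(cells["cell_id"]),
        times=times,
        categories=categories,
        fractions=fr,
        coords=coords,
    )


def _grid_from_dataset(ds: xr.Dataset) -> CompositionGrid:
    for dim in ("time", "y", "x", "category"):
        if dim not in ds.dims:
            raise FormatError(f"gridded-array missing dimension '{dim}'")
    if "fraction" not in ds:
        raise FormatError("gridded-array missing 'fraction' variable")
    da = ds["fraction"].transpose("time", "y", "x", "category")
    arr = np.asarray(da.values, dtype=float)
    nt, ny, nx, nc = arr.shape
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cell_index = np.column_stack([rows.ravel(), cols.ravel()])
    fr = arr.reshape(nt, ny * nx, nc).transpose(1, 0, 2)
    keep = ~np.all(np.isnan(fr), axis=(1, 2))
    fr = np.nan_to_num(fr[keep], nan=0.0)
    cell_index = cell_index[keep]
    times = [t.item() if hasattr(t, "item") else t for t in ds["time"].values]
    categories = [c.item() if hasattr(c, "item") else c for c in ds["category"].values]
    cell_ids = [f"r{r}c{c}" for r, c in cell_index]
    return CompositionGrid(cell_index=cell_index, cell_ids=cell_ids, times=times,
                           categories=categories, fractions=fr)


def read_composition(path: str | Path,
                     dialect: Literal["long-csv", "gridded-array"] = "long-csv",
                     ) -> CompositionGrid:
    """Read a compositional grid from file.

    ``long-csv`` expects columns (cell_id, row, col, time, category,
    fraction) with optional lon/lat; ``gridded-array`` a NetCDF file with
    a ``fraction`` variable over dims (time, y, x, category).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long-csv":
        return _grid_from_long(pd.read_csv(path, float_precision="round_trip"))
    if dialect == "gridded-array":
        with xr.open_dataset(path, engine="scipy") as ds:
            return _grid_from_dataset(ds.load())
    raise ValueError(f"unknown dialect {dialect!r}")


def write_composition(grid: CompositionGrid, path: str | Path,
                      dialect: Literal["long-csv", "gridded-array"] = "long-csv") -> None:
    """Write a grid in either dialect (inverse of :func:`read_composition`)."""
    path = Path(path)
    if dialect == "long-csv":
        n_c, n_t, n_k = grid.fractions.shape
        ci = np.repeat(np.arange(n_c), n_t * n_k)
        ti = np.tile(np.repeat(np.arange(n_t), n_k), n_c)
        ki = np.tile(np.arange(n_k), n_c * n_t)
        df = pd.DataFrame({
            "cell_id": np.asarray(grid.cell_ids, dtype=object)[ci],
            "row": grid.cell_index[ci, 0],
            "col": grid.cell_index[ci, 1],
            "lon": grid.coords[ci, 0] if grid.coords is not None else np.nan,
            "lat": grid.coords[ci, 1] if grid.coords is not None else np.nan,
            "time": np.asarray(grid.times, dtype=object)[ti],
            "category": np.asarray(grid.categories, dtype=object)[ki],
            "fraction": grid.fractions.ravel(),
        })
        df.to_csv(path, index=False, columns=LONG_CSV_COLUMNS)
    elif dialect == "gridded-array":
        ny, nx = grid.shape
        arr = np.full((len(grid.times), ny, nx, len(grid.categories)), np.nan)
        arr[:, grid.cell_index[:, 0], grid.cell_index[:, 1], :] = (
            grid.fractions.transpose(1, 0, 2))
        ds = xr.Dataset(
            {"fraction": (("time", "y", "x", "category"), arr)},
            coords={"time": grid.times, "y": np.arange(ny), "x": np.arange(nx),
                    "category": [str(c) for c in grid.categories]},
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Grid -> observations
# ---------------------------------------------------------------------------

def to_observations(grid: CompositionGrid,
                    rule: Literal["dominant", "weighted-multiple"] = "weighted-multiple",
                    threshold: float = 0.0) -> ObservationSet:
    """Turn a compositional grid into point observations.

    ``dominant`` keeps one record per (cell, time): the arg-max category
    with its fraction as weight (ties broken deterministically by lowest
    category index and logged).  ``weighted-multiple`` keeps one record
    per (cell, time, category) whose fraction is >= ``threshold``
    (strictly positive when threshold is 0), weight = fraction.

    Coordinates are the lattice (col, row) pair — x east, y south — and
    t the time index.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0,1]")
    fr = grid.fractions
    n_c, n_t, n_k = fr.shape
    rows = []
    if rule == "dominant":
        arg = fr.argmax(axis=2)
        best = fr.max(axis=2)
        n_ties = int(((fr == best[:, :, None]).sum(axis=2) > 1)[best > 0].sum())
        skipped = int((best <= 0).sum())
        for c in range(n_c):
            for t in range(n_t):
                if best[c, t] <= 0:
                    continue
                rows.append((grid.cell_index[c, 1], grid.cell_index[c, 0], t,
                             grid.categories[arg[c, t]], best[c, t], grid.cell_ids[c]))
        if n_ties:
            logger.info("to_observations: %d dominant-category ties broken by lowest index", n_ties)
        if skipped:
            logger.info("to_observations: %d (cell,time) pairs skipped (zero total)", skipped)
    elif rule == "weighted-multiple":
        mask = fr >= threshold if threshold > 0 else fr > 0
        for c, t, k in np.argwhere(mask):
            rows.append((grid.cell_index[c, 1], grid.cell_index[c, 0], t,
                         grid.categories[k], fr[c, t, k], grid.cell_ids[c]))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    rec = pd.DataFrame(rows, columns=["x", "y", "t", "category", "weight", "unit_id"])
    return ObservationSet(records=rec, categories=list(grid.categories))
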