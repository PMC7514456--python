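"""Spatial and temporal patches and their categorical descriptors.

A *spatial patch* (SP) is a maximal connected set of grid cells whose
occupation fraction for one category exceeds a threshold at one time; a
*temporal patch* (TP) is a maximal run of consecutive time steps above
the threshold at one cell.  Patch sizes are grouped into ordered classes
(the categorical variables Si and Ti), spatial geometry is clustered
into shape classes (Sh), and per-cell fraction series are labelled with
ordinal permutation motifs (Th), the building blocks of permutation
entropy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import CompositionGrid, ValidationError

#: size-class bounds used for spatial patches in the boreal land-cover
#: case study: 1, 2, >2, >7, >25, >50, >100
SPATIAL_SIZE_CLASSES = [1, 2, 3, 8, 26, 51, 101]
#: the matching temporal classing: 1, 2, >2, >4, >7, >20, >30, >60
TEMPORAL_SIZE_CLASSES = [1, 2, 3, 5, 8, 21, 31, 61]


@dataclass
class Patch:
    patch_id: str
    kind: Literal["spatial", "temporal"]
    category: object
    #: time label (spatial patches) or cell id (temporal patches)
    anchor: object
    #: (row, col) pairs (spatial) or time indices (temporal)
    members: tuple
    membership: tuple  # per-member degree in (0, 1]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PatchSet:
    patches: list[Patch]
    kind: Literal["spatial", "temporal"]
    connectivity: int | None = None
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.patches)

    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.patches], dtype=int)

    def extend(self, other: "PatchSet") -> "PatchSet":
        if other.kind != self.kind:
            raise ValueError("cannot mix spatial and temporal patch sets")
        return PatchSet(self.patches + other.patches, self.kind,
                        self.connectivity, self.threshold)


@dataclass
class SizeClassing:
    """Ordered size classes given by their lower bounds.

    ``bounds[i]`` is the smallest size in class i; every positive
    integer falls in exactly one class (closed-open intervals, the last
    class unbounded).  Labels follow the usual convention: a singleton
    class prints its size, a wider one prints "> bound-1".
    """

    bounds: Sequence[int]
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        b = list(self.bounds)
        if b != sorted(b) or len(set(b)) != len(b) or b[0] != 1:
            raise ValidationError("size-class bounds must be strictly increasing and start at 1")
        if self.labels is None:
            labels = []
            for i, lo in enumerate(b):
                hi = b[i + 1] - 1 if i + 1 < len(b) else None
                labels.append(str(lo) if hi == lo else f">{lo - 1}" if lo > 1 else "1")
            self.labels = labels
        if len(self.labels) != len(b):
            raise ValidationError("one label per bound required")

    def classify(self, size: int) -> str:
        if size < 1:
            raise ValueError("patch size must be >= 1")
        idx = int(np.searchsorted(self.bounds, size, side="right")) - 1
        return self.labels[idx]


@dataclass
class ShapeClassing:
    feature_names: list[str]
    features: np.ndarray  # (n_patches, n_features)
    labels: np.ndarray | None = None
    n_classes: int | None = None


@dataclass
class MotifLabeling:
    """Ordinal (permutation) motif labels of a numeric series."""

    length: int
    lag: int
    refined: bool
    delta: float
    labels: list[str]            # one label per window
    counts: dict[str, int]       # histogram over observed labels
    n_ties: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# Patch construction
# ---------------------------------------------------------------------------

_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def spatial_patches(grid: CompositionGrid, category, threshold: float = 0.15,
                    connectivity: Literal[4, 8] = 4, time=None) -> PatchSet:
    """Connected components of cells with fraction(category) > threshold.

    One patch per component at the given time (strict inequality).
    Membership degree of each cell is its fraction, so patches of
    different categories may overlap; they are computed independently
    per category.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    plane = grid.category_plane(category, time)  # raises KeyError on bad keys
    mask = np.nan_to_num(plane, nan=0.0) > threshold
    lab, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    patches = []
    for i in range(1, n + 1):
        rc = np.argwhere(lab == i)
        members = tuple(map(tuple, rc))
        degrees = tuple(float(plane[r, c]) for r, c in members)
        patches.append(Patch(
            patch_id=f"SP-{category}-{time}-{i}", kind="spatial", category=category,
            anchor=time, members=members, membership=degrees))
    return PatchSet(patches, "spatial", connectivity=connectivity, threshold=threshold)


def temporal_patches(grid: CompositionGrid, category, threshold: float = 0.15,
                     cell=None) -> PatchSet:
    """Maximal runs of consecutive above-threshold time steps at one cell."""
    try:
        ki = grid.categories.index(category)
    except ValueError:
        raise KeyError(f"unknown category {category!r}") from None
    try:
        ci = grid.cell_ids.index(cell)
    except ValueError:
        raise KeyError(f"unknown cell {cell!r}") from None
    series = grid.fractions[ci, :, ki]
    mask = series > threshold
    patches = []
    # run-length scan over the boolean series
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for j, (start, stop) in enumerate(zip(edges[::2], edges[1::2]), 1):
        members = tuple(range(start, stop))
        patches.append(Patch(
            patch_id=f"TP-{category}-{cell}-{j}", kind="temporal", category=category,
            anchor=cell, members=members,
            membership=tuple(float(series[t]) for t in members)))
    return PatchSet(patches, "temporal", threshold=threshold)


def assign_size_class(patch_set: PatchSet, classing: SizeClassing
                      ) -> tuple[list[str], dict[str, int]]:
    """Label every patch with its size class; also return class counts."""
    labels = [classing.classify(p.size) for p in patch_set.patches]
    counts = {lab: 0 for lab in classing.labels}
    for lab in labels:
        counts[lab] += 1
    return labels, counts


# ---------------------------------------------------------------------------
# Shape features and classes
# ---------------------------------------------------------------------------

def shape_features(patch_set: PatchSet) -> ShapeClassing:
    """Geometric features of spatial patches.

    area: member count; perimeter: number of exposed unit cell edges;
    compactness: 4*pi*area / perimeter**2 (1 for a disc, clipped to
    (0, 1]); elongation: ratio of the principal axes of the member cell
    layout, each cell taken as a unit square so a single cell has
    elongation 1.
    """
    if patch_set.kind != "spatial":
        raise ValueError("shape features are defined for spatial patches only")
    rows = []
    for p in patch_set.patches:
        rc = np.asarray(p.members)
        area = len(rc)
        cells = set(map(tuple, rc))
        adjacencies = sum((r + dr, c + dc) in cells
                          for r, c in cells for dr, dc in ((0, 1), (1, 0)))
        perimeter = 4 * area - 2 * adjacencies
        compactness = min(1.0, 4 * math.pi * area / perimeter ** 2)
        cov = np.cov(rc.T, bias=True) if area > 1 else np.zeros((2, 2))
        cov = np.atleast_2d(cov) + np.eye(2) / 12.0  # unit-square cell extent
        ev = np.sort(np.linalg.eigvalsh(cov))
        elongation = float(np.sqrt(ev[1] / ev[0]))
        rows.append((area, perimeter, compactness, elongation))
    features = np.array(rows, dtype=float).reshape(-1, 4)
    return ShapeClassing(["area", "perimeter", "compactness", "elongation"], features)


def classify_shapes(shapes: ShapeClassing, n_classes: int, seed: int = 0) -> ShapeClassing:
    """Partition patches into shape classes by k-means on standardised features.

    Deterministic for a fixed seed.  Empty classes (possible when many
    patches share identical features) are reported via the returned
    ``n_classes`` versus the number of distinct labels.
    """
    X = shapes.features
    if len(X) < n_classes:
        raise ValueError(f"{len(X)} patches < {n_classes} requested classes")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    return ShapeClassing(shapes.feature_names, X, labels=labels, n_classes=n_classes)


# ---------------------------------------------------------------------------
# Ordinal motifs
# ---------------------------------------------------------------------------

def _fuzzy_order(values: Sequence[float], delta: float) -> tuple[tuple[int, ...], bool]:
    """Stable ordering of window positions by value.

    Pairs closer than ``delta`` (or exactly tied) keep their time order
    (earlier index first).  Returns the 1-based position sequence and a
    flag marking whether any tie occurred.
    """
    order = list(range(len(values)))
    # stable insertion sort: move left only on a meaningful (> delta) drop
    for i in range(1, len(order)):
        j = i
        while j > 0 and values[order[j]] < values[order[j - 1]] - delta:
            order[j], order[j - 1] = order[j - 1], order[j]
            j -= 1
    tied = any(abs(values[order[j]] - values[order[j - 1]]) <= delta
               for j in range(1, len(order)))
    return tuple(i + 1 for i in order), tied


def motif_classes(series: Sequence[float], l: int = 3, tau: int = 1,
                  refined: bool = False, delta: float = 0.0,
                  tb_first_gap_large: bool = True) -> MotifLabeling:
    """Label each lagged window of a series with its ordinal permutation motif.

    A window (x_t, x_{t+tau}, ..., x_{t+(l-1)tau}) is labelled by the
    1-based positions of its values in increasing order, e.g. (1,3,2)
    for a rise then a partial fall.  ``delta`` is the minimum meaningful
    difference: smaller gaps count as ties and are resolved by time
    order.  With ``refined`` (l=3 only) each class splits into a "t"
    variant (first gap of the sorted values >= second, i.e. the larger
    change first when increasing) and "b" otherwise; set
    ``tb_first_gap_large=False`` to flip the convention.
    """
    x = np.asarray(series, dtype=float)
    n_windows = len(x) - (l - 1) * tau
    if n_windows < 1:
        raise ValueError(f"series of length {len(x)} too short for l={l}, tau={tau}")
    if refined and l != 3:
        raise ValueError("the t/b refinement is defined for l=3")
    labels: list[str] = []
    n_ties = 0
    for t in range(n_windows):
        w = x[t: t + (l - 1) * tau + 1: tau]
        order, tied = _fuzzy_order(list(w), delta)
        n_ties += tied
        lab = "".join(str(i) for i in order)
        if refined:
            v = sorted(w)
            first_gap, second_gap = v[1] - v[0], v[2] - v[1]
            big_first = first_gap >= second_gap
            lab += ("t" if big_first == tb_first_gap_large else "b")
        labels.append(lab)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return MotifLabeling(length=l, lag=tau, refined=refined, delta=delta,
                         labels=labels, counts=counts, n_ties=n_ties)


# ---------------------------------------------------------------------------
# Convenience: grid-wide labelled patch tables
# ---------------------------------------------------------------------------

def all_spatial_patches(grid: CompositionGrid, threshold: float = 0.15,
                        connectivity: Literal[4, 8] = 4,
                        categories: Iterable | None = None,
                        times: Iterable | None = None) -> PatchSet:
    """Spatial patches for every (category, time) combination."""
    out = PatchSet([], "spatial", connectivity=connectivity, threshold=threshold)
    for c in (categories if categories is not None else grid.categories):
        for t in (times if times is not None else grid.times):
            out = out.extend(spatial_patches(grid, c, threshold, connectivity, t))
    return out


def all_temporal_patches(grid: CompositionGrid, threshold: float = 0.15,
                         categories: Iterable | None = None) -> PatchSet:
    """Temporal patches for every (category, cell) combination."""
    out = PatchSet([], "temporal", threshold=threshold)
    for c in (categories if categories is not None else grid.categories):
        for cell in grid.cell_ids:
            out = out.extend(temporal_patches(grid, c, threshold, cell))
    return out
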