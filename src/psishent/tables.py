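"""Multiway distribution-like tables over labelled spatio-temporal data.

The joint information crossing patch descriptors (Si, Ti, Sh, Th ...)
with the category variable C is carried by a named-mode non-negative
tensor.  Cell values may be plain occurrence counts (per grid cell or
per patch), counts of k-co-occurrences under a collocation distance
rule, or distance-ratio weights — any non-negative statistic positively
correlated with the local observation count yields a distribution-like
table for the entropy machinery.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import ObservationSet, ProximitySpec, ValidationError

logger = logging.getLogger("psishent")


@dataclass
class MultiwayTable:
    """Named-mode non-negative tensor with derived probabilities and margins."""

    mode_names: list[str]
    mode_labels: list[list]
    values: np.ndarray
    statistic: str = "occurrence"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.mode_names):
            raise ValidationError("one mode name per tensor dimension required")
        for ax, labels in enumerate(self.mode_labels):
            if len(labels) != self.values.shape[ax]:
                raise ValidationError(
                    f"mode {self.mode_names[ax]!r}: {len(labels)} labels for "
                    f"axis of length {self.values.shape[ax]}")
        if np.any(self.values < 0):
            raise ValidationError("table values must be non-negative")

    @property
    def n_modes(self) -> int:
        return self.values.ndim

    @property
    def total(self) -> float:
        """Total mass N."""
        return float(self.values.sum())

    @property
    def p(self) -> np.ndarray:
        """Joint probability tensor values / N."""
        n = self.total
        if n == 0:
            raise ValidationError("empty table has no probability tensor")
        return self.values / n

    def margin(self, mode: str | int) -> np.ndarray:
        """One-mode marginal distribution."""
        ax = mode if isinstance(mode, int) else self.mode_names.index(mode)
        axes = tuple(i for i in range(self.n_modes) if i != ax)
        return self.p.sum(axis=axes)

    def margins(self) -> list[np.ndarray]:
        return [self.margin(i) for i in range(self.n_modes)]

    def marginalise(self, modes: Sequence[str]) -> "MultiwayTable":
        """Sum out every mode not in ``modes`` (result mode order follows ``modes``)."""
        keep = [self.mode_names.index(m) for m in modes]
        drop = tuple(i for i in range(self.n_modes) if i not in keep)
        vals = self.values.sum(axis=drop)
        vals = np.transpose(vals, np.argsort(np.argsort(keep)))
        return MultiwayTable([self.mode_names[i] for i in keep],
                             [self.mode_labels[i] for i in keep], vals, self.statistic)

    def drop_empty(self) -> tuple["MultiwayTable", dict[str, list]]:
        """Remove labels with zero margin; report what was dropped per mode."""
        t, dropped = self, {}
        for ax, name in enumerate(self.mode_names):
            m = t.values.sum(axis=tuple(i for i in range(t.n_modes) if i != ax))
            if np.any(m == 0):
                keep = np.flatnonzero(m > 0)
                dropped[name] = [t.mode_labels[ax][i] for i in np.flatnonzero(m == 0)]
                labels = [list(l) for l in t.mode_labels]
                labels[ax] = [labels[ax][i] for i in keep]
                t = MultiwayTable(list(t.mode_names), labels,
                                  np.take(t.values, keep, axis=ax), t.statistic)
        return t, dropped

    # -- IO -----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Long CSV (one row per cell) plus a JSON sidecar with metadata."""
        path = Path(path)
        idx = list(itertools.product(*[range(len(l)) for l in self.mode_labels]))
        rows = {name: [self.mode_labels[ax][i[ax]] for i in idx]
                for ax, name in enumerate(self.mode_names)}
        rows["value"] = [float(self.values[i]) for i in idx]
        pd.DataFrame(rows).to_csv(path, index=False)
        sidecar = {"mode_names": self.mode_names,
                   "mode_labels": [[str(l) for l in labs] for labs in self.mode_labels],
                   "N": self.total, "statistic": self.statistic}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MultiwayTable":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        df = pd.read_csv(path)
        labels = meta["mode_labels"]
        shape = tuple(len(l) for l in labels)
        vals = np.zeros(shape)
        lut = [{l: i for i, l in enumerate(labs)} for labs in labels]
        for _, row in df.iterrows():
            key = tuple(lut[ax][str(row[name])] for ax, name in enumerate(meta["mode_names"]))
            vals[key] = row["value"]
        return cls(meta["mode_names"], labels, vals, meta["statistic"])


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

def occurrence_table(labelings: Mapping[str, Mapping],
                     weights: Mapping | None = None,
                     mode_labels: Mapping[str, Sequence] | None = None,
                     count_unit: Literal["cell", "patch"] = "cell") -> MultiwayTable:
    """Cross-tabulate per-unit labels into a multiway count table.

    ``labelings`` maps each mode name to a {unit: label} mapping; all
    modes must cover the same units.  A unit contributes its weight
    (default 1) to the cell addressed by its labels.  ``count_unit``
    only names what the units are — grid cells (a cell lying in m
    patches appears as m units) or patches counted once each; the
    caller builds the unit set accordingly.
    """
    names = list(labelings)
    unit_sets = [set(labelings[n]) for n in names]
    base = unit_sets[0]
    for n, s in zip(names[1:], unit_sets[1:]):
        if s != base:
            diff = sorted(map(str, base ^ s))[:10]
            raise ValidationError(f"mode {n!r} covers different units, e.g. {diff}")
    units = sorted(base, key=str)
    if mode_labels is None:
        mode_labels = {}
    labels = [list(mode_labels.get(n)) if mode_labels.get(n) is not None
              else sorted({labelings[n][u] for u in units}, key=str)
              for n in names]
    lut = [{l: i for i, l in enumerate(labs)} for labs in labels]
    vals = np.zeros(tuple(len(l) for l in labels))
    for u in units:
        key = tuple(lut[ax][labelings[n][u]] for ax, n in enumerate(names))
        vals[key] += 1.0 if weights is None else float(weights[u])
    kind = "patch-occurrence" if count_unit == "patch" else "occurrence"
    return MultiwayTable(names, labels, vals, kind)


# ---------------------------------------------------------------------------
# k-co-occurrence tables
# ---------------------------------------------------------------------------

def _majority(labels: Sequence, ordered: Sequence) -> tuple[object, bool]:
    """Majority label; ties broken by lowest index in ``ordered``."""
    counts: dict = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    winners.sort(key=lambda l: ordered.index(l) if l in ordered else len(ordered))
    return winners[0], len(winners) > 1


def cooccurrence_table(obs: ObservationSet, spec: ProximitySpec,
                       grouping: Mapping | None = None,
                       s_labels: Sequence | None = None,
                       t_labels: Sequence | None = None) -> MultiwayTable:
    """Count unordered k-subsets of observations that are collocated.

    Asymmetric mode (``spec.symmetric`` False): ``grouping`` maps each
    observation index to its spatio-temporal stratum (s, t); a k-subset
    of common category c with all pairwise spatial distances <= d_eps_S
    counts once at (s, t, c).  At least one member must lie in the
    stratum; with ``spec.d_border`` > 0 the others may come from a
    different stratum at the same time if within d_border of an inside
    member (cross-border subsets are intentionally not deduplicated).

    Symmetric mode: every k-subset satisfying the per-dimension distance
    rule (pairwise dS <= d_eps_S, dT <= d_eps_T, dC <= d_eps_C) counts;
    its (s, t, c) cell follows ``spec.categorisation_rule`` — strict
    (all labels common, else skipped), majority (per-dimension vote,
    lowest-label tie-break), or fuzzy (dimensions whose pairwise
    distances are all <= ``spec.d_refine`` contribute every member
    label; one count per valid label combination).
    """
    rec = obs.records.reset_index(drop=True)
    n, k = len(rec), spec.order_k
    cats = list(obs.categories)
    if grouping is None:  # one spatial stratum per time step
        grouping = {i: (0, rec.at[i, "t"]) for i in range(n)}
    st = [grouping[i] for i in range(n)]
    s_all = s_labels if s_labels is not None else sorted({s for s, _ in st}, key=str)
    t_all = t_labels if t_labels is not None else sorted({t for _, t in st}, key=str)
    labels = [list(s_all), list(t_all), cats]
    vals = np.zeros((len(s_all), len(t_all), len(cats)))
    table = MultiwayTable(["S", "T", "C"], labels, vals, "cooccurrence")
    if n < k:
        logger.warning("cooccurrence_table: k=%d exceeds %d observations; empty table", k, n)
        return table
    xy = rec[["x", "y"]].to_numpy(dtype=float)
    tt = rec["t"].to_numpy(dtype=float)
    cat_idx = rec["category"].map({c: i for i, c in enumerate(cats)}).to_numpy()
    dS = squareform(pdist(xy)) if n > 1 else np.zeros((1, 1))
    dT = np.abs(tt[:, None] - tt[None, :])
    if spec.dissimilarity_C is not None:
        dC = spec.dissimilarity_C[np.ix_(cat_idx, cat_idx)]
    else:
        dC = (cat_idx[:, None] != cat_idx[None, :]).astype(float)
    si = {s: i for i, s in enumerate(s_all)}
    ti = {t: i for i, t in enumerate(t_all)}
    n_ties = 0

    if not spec.symmetric:
        # per-stratum enumeration with optional border overlap
        strata = sorted({g for g in st}, key=str)
        for (s, t) in strata:
            inside = [i for i in range(n) if st[i] == (s, t)]
            pool = list(inside)
            if spec.d_border > 0:
                for j in range(n):
                    if st[j] != (s, t) and st[j][1] == t and any(
                            dS[j, i] <= spec.d_border for i in inside):
                        pool.append(j)
            for combo in itertools.combinations(sorted(set(pool)), k):
                if not any(st[i] == (s, t) for i in combo):
                    continue
                c0 = cat_idx[combo[0]]
                if any(cat_idx[i] != c0 for i in combo[1:]):
                    continue
                if max(dS[a, b] for a, b in itertools.combinations(combo, 2)) <= spec.d_eps_S:
                    vals[si[s], ti[t], c0] += 1
    else:
        for combo in itertools.combinations(range(n), k):
            pairs = list(itertools.combinations(combo, 2))
            if (max(dS[a, b] for a, b in pairs) > spec.d_eps_S
                    or max(dT[a, b] for a, b in pairs) > spec.d_eps_T
                    or max(dC[a, b] for a, b in pairs) > spec.d_eps_C):
                continue
            dims = [[st[i][0] for i in combo], [st[i][1] for i in combo],
                    [cats[cat_idx[i]] for i in combo]]
            rule = spec.categorisation_rule
            if rule == "strict":
                if all(len(set(d)) == 1 for d in dims):
                    vals[si[dims[0][0]], ti[dims[1][0]], cats.index(dims[2][0])] += 1
            elif rule == "majority":
                key = []
                for d, ordered in zip(dims, (list(s_all), list(t_all), cats)):
                    lab, tie = _majority(d, ordered)
                    n_ties += tie
                    key.append(lab)
                vals[si[key[0]], ti[key[1]], cats.index(key[2])] += 1
            elif rule == "fuzzy":
                dr = spec.d_refine if spec.d_refine is not None else 0.0
                dmats = (dS, dT, dC)
                valid = []
                ok = True
                for d, dm in zip(dims, dmats):
                    if max(dm[a, b] for a, b in pairs) <= dr:
                        valid.append(sorted(set(d), key=str))
                    elif len(set(d)) == 1:
                        valid.append([d[0]])
                    else:
                        ok = False
                        break
                if ok:
                    for s_, t_, c_ in itertools.product(*valid):
                        vals[si[s_], ti[t_], cats.index(c_)] += 1
            else:  # pragma: no cover
                raise ValueError(f"unknown categorisation rule {rule!r}")
    if n_ties:
        logger.info("cooccurrence_table: %d majority ties broken by lowest label index", n_ties)
    return MultiwayTable(["S", "T", "C"], labels, vals, "cooccurrence")


# ---------------------------------------------------------------------------
# Distance-ratio tables
# ---------------------------------------------------------------------------

def distance_ratio_table(obs: ObservationSet, spec: ProximitySpec,
                         grouping: Mapping | None = None,
                         mode: Literal["local-asymmetric", "symmetric"] = "local-asymmetric",
                         invert: bool = False,
                         s_labels: Sequence | None = None,
                         t_labels: Sequence | None = None,
                         ) -> tuple[MultiwayTable, dict]:
    """Distance-ratio weights per (s, t, c) cell, normalised to a distribution.

    local-asymmetric: within each stratum Est, the mean spatial distance
    over within-category pairs W divided by the mean over between pairs
    B (small = strong clustering of c).  symmetric: W are pairs both
    within ``d_eps_S`` of some member of the cell's observation set, B
    pairs where one lies within that radius and the other at least that
    far from every member.  ``invert`` stores 1/ratio instead, so large
    values mean clustering.  Cells with an empty W or B are undefined
    and excluded from normalisation; the report lists them.
    """
    rec = obs.records.reset_index(drop=True)
    n = len(rec)
    cats = list(obs.categories)
    if grouping is None:
        grouping = {i: (0, rec.at[i, "t"]) for i in range(n)}
    st = [grouping[i] for i in range(n)]
    s_all = list(s_labels) if s_labels is not None else sorted({s for s, _ in st}, key=str)
    t_all = list(t_labels) if t_labels is not None else sorted({t for _, t in st}, key=str)
    xy = rec[["x", "y"]].to_numpy(dtype=float)
    dS = squareform(pdist(xy)) if n > 1 else np.zeros((1, 1))
    cat_idx = rec["category"].map({c: i for i, c in enumerate(cats)}).to_numpy()
    vals = np.full((len(s_all), len(t_all), len(cats)), np.nan)
    for a, s in enumerate(s_all):
        for b, t in enumerate(t_all):
            members = [i for i in range(n) if st[i] == (s, t)]
            for c in range(len(cats)):
                within: list[float] = []
                between: list[float] = []
                if mode == "local-asymmetric":
                    ins = [i for i in members if cat_idx[i] == c]
                    outs = [i for i in members if cat_idx[i] != c]
                    within = [dS[i, j] for i, j in itertools.combinations(ins, 2)]
                    between = [dS[i, j] for i in ins for j in outs]
                elif mode == "symmetric":
                    cell_members = [i for i in members if cat_idx[i] == c]
                    if cell_members:
                        d_to = dS[:, cell_members]
                        near = d_to.min(axis=1) <= spec.d_eps_S
                        far = (d_to >= spec.d_eps_S).all(axis=1)
                        within = [dS[i, j] for i, j in itertools.combinations(
                            np.flatnonzero(near), 2)]
                        between = [dS[i, j] for i in np.flatnonzero(near)
                                   for j in np.flatnonzero(far)]
                else:
                    raise ValueError(f"unknown mode {mode!r}")
                if within and between and np.mean(between) > 0:
                    r = float(np.mean(within) / np.mean(between))
                    vals[a, b, c] = (1.0 / r if invert and r > 0 else
                                     np.nan if invert else r)
    undefined = [(s_all[i], t_all[j], cats[k]) for i, j, k in np.argwhere(np.isnan(vals))]
    filled = np.nan_to_num(vals, nan=0.0)
    report = {"undefined_cells": undefined, "mode": mode, "inverted": invert,
              "raw": vals.copy()}
    table = MultiwayTable(["S", "T", "C"], [s_all, t_all, cats], filled, "distance-ratio")
    return table, report


# ---------------------------------------------------------------------------
# Si x Ti x C tables straight from a compositional grid
# ---------------------------------------------------------------------------

def patch_size_table(grid, si_classing, ti_classing, threshold: float = 0.15,
                     connectivity: int = 4,
                     count_unit: Literal["cell", "patch"] = "cell",
                     categories: Sequence | None = None,
                     times: Sequence | None = None,
                     ) -> tuple[MultiwayTable, pd.DataFrame]:
    """Cross spatial size class, temporal size class and category.

    For every category, spatial patches are extracted at each time and
    temporal patches at each cell (same threshold).  With
    ``count_unit="cell"`` each member cell of a spatial patch counts
    once at (Si class of its patch, Ti class of the temporal run
    covering that time at that cell, category) — a cell lying in
    patches of m categories contributes m counts.  With
    ``count_unit="patch"`` each spatial patch counts once, its Ti class
    being the most common one among its member cells (ties to the
    smaller class).

    Returns the table and a long DataFrame (cell_id, time, category,
    si, ti) of the per-unit labels behind it, which feeds the map
    statistics.
    """
    from .patches import all_spatial_patches, temporal_patches

    cats = list(categories) if categories is not None else list(grid.categories)
    tms = list(times) if times is not None else list(grid.times)
    cell_of = {tuple(rc): cid for rc, cid in zip(map(tuple, grid.cell_index), grid.cell_ids)}
    # per (category, cell): time index -> temporal size class
    ti_lut: dict = {}
    for c in cats:
        for cid in grid.cell_ids:
            runs = temporal_patches(grid, c, threshold, cid)
            lut = {}
            for p in runs.patches:
                lab = ti_classing.classify(p.size)
                for tix in p.members:
                    lut[tix] = lab
            ti_lut[(c, cid)] = lut
    sp = all_spatial_patches(grid, threshold, connectivity, categories=cats, times=tms)
    rows = []
    for p in sp.patches:
        si = si_classing.classify(p.size)
        tix = grid.times.index(p.anchor)
        labs = []
        for (r, c_) in p.members:
            cid = cell_of[(r, c_)]
            ti = ti_lut[(p.category, cid)].get(tix)
            if ti is None:  # cannot happen when thresholds match; defensive
                continue
            labs.append((cid, ti))
        if count_unit == "cell":
            for cid, ti in labs:
                rows.append((cid, p.anchor, p.category, si, ti))
        else:
            if not labs:
                continue
            order = {l: i for i, l in enumerate(ti_classing.labels)}
            counts: dict = {}
            for _, ti in labs:
                counts[ti] = counts.get(ti, 0) + 1
            best = max(counts.values())
            ti = min((l for l, n in counts.items() if n == best), key=order.get)
            rows.append((p.patch_id, p.anchor, p.category, si, ti))
    detail = pd.DataFrame(rows, columns=["cell_id", "time", "category", "si", "ti"])
    units = dict(enumerate(rows))
    labelings = {
        "Si": {u: rows[u][3] for u in units},
        "Ti": {u: rows[u][4] for u in units},
        "C": {u: rows[u][2] for u in units},
    }
    mode_labels = {"Si": list(si_classing.labels), "Ti": list(ti_classing.labels),
                   "C": cats}
    table = occurrence_table(labelings, mode_labels=mode_labels, count_unit=count_unit)
    return table, detail
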