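"""Seeded synthetic compositional grids and structured fixture tables.

The grid generator emulates the kind of data produced by a land-surface
model forecasting vegetation composition: per grid cell and time step a
vector of category fractions summing to 1, with spatially autocorrelated
dominant-category patches and smooth multi-decadal prevalence trends.
The construction is a softmax of smoothed Gaussian random fields plus
linear logit-scale trends — it guarantees valid compositions and makes
patchiness (via the spatial correlation length) and change (via the
trend slopes) directly tunable.  It emulates none of the physics of a
real simulation: no climate forcing, no spatial covariates, no abrupt
regime shifts.

Also provided: rank-one structured multiway tables with known
decompositions (oracles for the correspondence analysis) and the
printed reference values of the boreal plant-functional-type land-cover
case study used throughout the documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import CompositionGrid, ValidationError
from .tables import MultiwayTable


@dataclass
class SimulationSpec:
    """Parameters of the compositional grid generator.

    The defaults describe a desk-scale analogue of a 2-degree boreal
    land-cover forecast: a few hundred cells, 11 vegetation categories,
    87 annual steps, correlation length of a few cells and slow
    prevalence trends.
    """

    n_rows: int = 16
    n_cols: int = 16
    n_times: int = 87
    n_categories: int = 11
    correlation_length: float = 3.0   # cells; patch size scale
    trend_slopes: np.ndarray | None = None  # logit units per step, per category
    noise_scale: float = 0.15         # temporal field roughness (logit units)
    patch_intensity: float = 2.0      # field amplitude; larger = sharper patches
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_times, self.n_categories) < 1:
            raise ValidationError("all dimensions must be >= 1")
        if self.correlation_length <= 0:
            raise ValidationError("correlation length must be > 0")
        if self.trend_slopes is not None:
            self.trend_slopes = np.asarray(self.trend_slopes, dtype=float)
            if self.trend_slopes.shape != (self.n_categories,):
                raise ValidationError("one trend slope per category required")


def default_trend_slopes(n_categories: int, scale: float = 0.01,
                         seed: int = 0) -> np.ndarray:
    """Zero-sum slopes of order ``scale`` logit units per step."""
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, scale, n_categories)
    return s - s.mean()


def simulate_composition(spec: SimulationSpec) -> CompositionGrid:
    """Generate a compositional grid time series (softmax of smooth fields).

    Per category k the logit field is
    ``patch_intensity * G_k(x, y) + slope_k * t + noise_scale * E_k(x, y, t)``
    with G_k a unit-variance smoothed Gaussian field (correlation length
    in cells) and E_k an independent smoothed space-time field; the
    softmax across categories yields fractions summing to 1 everywhere.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx, nt, nk = spec.n_rows, spec.n_cols, spec.n_times, spec.n_categories
    slopes = (spec.trend_slopes if spec.trend_slopes is not None
              else np.zeros(nk))
    logits = np.empty((nk, nt, ny, nx))
    t_idx = np.arange(nt)
    for k in range(nk):
        base = _smooth_field(rng.standard_normal((ny, nx)), spec.correlation_length)
        logits[k] = spec.patch_intensity * base[None, :, :] + slopes[k] * t_idx[:, None, None]
        if spec.noise_scale > 0:
            noise = gaussian_filter(
                rng.standard_normal((nt, ny, nx)),
                sigma=(max(spec.correlation_length, 1.0), spec.correlation_length,
                       spec.correlation_length), mode="nearest")
            sd = noise.std()
            if sd > 0:
                logits[k] += spec.noise_scale * noise / sd
    logits -= logits.max(axis=0, keepdims=True)
    frac = np.exp(logits)
    frac /= frac.sum(axis=0, keepdims=True)
    # (cell, time, category) layout
    fr = frac.transpose(2, 3, 1, 0).reshape(ny * nx, nt, nk)
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cell_index = np.column_stack([rows.ravel(), cols.ravel()])
    return CompositionGrid(
        cell_index=cell_index,
        cell_ids=[f"r{r}c{c}" for r, c in cell_index],
        times=list(range(nt)),
        categories=[f"cat{k + 1}" for k in range(nk)],
        fractions=fr,
    )


def _smooth_field(white: np.ndarray, sigma: float) -> np.ndarray:
    f = gaussian_filter(white, sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# Rank-one structured oracle tables
# ---------------------------------------------------------------------------

def make_rank_structured_table(dims: tuple[int, ...] = (5, 6, 7),
                               sigma_star: float = 0.2, seed: int = 0,
                               ) -> tuple[MultiwayTable, dict]:
    """Product-of-margins table plus one known weighted rank-one perturbation.

    p = W . (1 + sigma* v1 (x) v2 (x) v3) where W is the product of
    random positive margins and each v has zero weighted mean and unit
    weighted norm — so the margins of p equal the construction margins
    and a correct correspondence analysis must recover sigma_1 = sigma*
    with these vectors.  Raises when sigma* is large enough to create
    negative cells.
    """
    rng = np.random.default_rng(seed)
    margins = [rng.dirichlet(np.full(n, 5.0)) for n in dims]
    vecs = []
    for m in margins:
        v = rng.standard_normal(len(m))
        v = v - np.dot(m, v)                 # zero weighted mean: <v,1>_m = 0
        v = v / np.sqrt(np.dot(m, v ** 2))   # unit weighted norm
        vecs.append(v)
    w = np.array(1.0)
    r1 = np.array(1.0)
    for m, v in zip(margins, vecs):
        w = np.multiply.outer(w, m)
        r1 = np.multiply.outer(r1, v)
    p = w * (1.0 + sigma_star * r1)
    if np.any(p < 0):
        raise ValidationError(
            f"sigma*={sigma_star} makes {int((p < 0).sum())} cells negative; "
            "use a smaller perturbation")
    table = MultiwayTable([f"M{i}" for i in range(len(dims))],
                          [[f"l{j}" for j in range(n)] for n in dims],
                          p, "occurrence")
    return table, {"sigma": sigma_star, "margins": margins, "vectors": vecs}


# ---------------------------------------------------------------------------
# Reference fixtures from the boreal land-cover case study
# ---------------------------------------------------------------------------

PFT_LABELS = ["pft1", "pft4", "pft5", "pft6", "pft7", "pft8",
              "pft9", "pft10", "pft12", "pft13", "pft14"]


def worked_example_fixtures() -> dict:
    """Published reference values of the land-cover worked example.

    These are inputs for demonstrations and cross-checks (the original
    simulation data are not redistributable): the normalised-entropy
    decomposition table per year, the log-cardinality weights for 7 and
    11 labels, the per-component CTR entropies, the multiway-table
    margins with signed CTR percentages of the four leading rank-one
    tensors, and the size classings used.
    """
    table1 = {
        "Si": {2020: 0.7030593, 2050: 0.7933917, 2100: 0.7640653},
        "C|Si": {2020: 0.6548033, 2050: 0.5613683, 2100: 0.6314215},
        "C": {2020: 0.8520292, 2050: 0.8745148, 2100: 0.9297879},
        "Si|C": {2020: 0.4600228, 2050: 0.4075092, 2100: 0.3963961},
        "Si,C": {2020: 0.6764207, 2050: 0.6653087, 2100: 0.6908424},
    }
    weights_7_11 = (0.4479736, 0.5520264)
    # per-component CTR-tensor normalised entropies (Si, Ti, C, combined)
    table4 = {
        "tensor_40.9": {"Si": 0.786, "Ti": 0.596, "C": 0.894, "CTR-tensor": 0.765},
        "tensor_16.70": {"Si": 0.661, "Ti": 0.596, "C": 0.830, "CTR-tensor": 0.703},
        "tensor_9.54": {"Si": 0.786, "Ti": 0.908, "C": 0.452, "CTR-tensor": 0.701},
        "tensor_3.55": {"Si": 0.929, "Ti": 0.830, "C": 0.356, "CTR-tensor": 0.683},
    }
    # the running-text value for the independence tensor's Ti entropy is
    # 0.595 (0.596 in the printed table); both are kept
    text_independence_hu = {"Si": 0.786, "Ti": 0.595, "C": 0.894, "combined": 0.764}
    shares_percent = [40.9, 16.70, 9.54, 3.55]
    si_classes = ["1", "2", ">2", ">7", ">25", ">50", ">100"]
    ti_classes = ["1", "2", ">2", ">4", ">7", ">20", ">30", ">60"]
    margins_percent = {
        "Si": dict(zip(si_classes, [2, 2, 5, 14, 12, 23, 42])),
        "Ti": dict(zip(ti_classes, [1, 1, 1, 2, 8, 7, 21, 59])),
        "C": dict(zip(PFT_LABELS, [10, 6, 2, 4, 4, 4, 23, 13, 5, 22, 7])),
    }
    signed_ctrs_percent = {
        "tensor_16.70": {
            "Si": dict(zip(si_classes, [3, 3, 7, 35, 2, 2, -48])),
            "Ti": dict(zip(ti_classes, [1, 1, 1, 2, 8, 7, 21, 59])),
            "C": dict(zip(PFT_LABELS, [5, 0, 10, 0, 2, 6, -21, 7, 21, -22, 6])),
        },
        "tensor_9.54": {
            "Si": dict(zip(si_classes, [2, 2, 5, 14, 12, 23, 42])),
            "Ti": dict(zip(ti_classes, [18, 15, 11, 9, 18, 6, 1, -24])),
            "C": dict(zip(PFT_LABELS, [60, 0, -1, 1, 3, 2, -29, 0, 0, -4, 0])),
        },
        "tensor_3.55": {
            "Si": dict(zip(si_classes, [-16, -9, -26, -15, -5, 7, 22])),
            "Ti": dict(zip(ti_classes, [27, 29, 14, 13, 9, 0, -2, -8])),
            "C": dict(zip(PFT_LABELS, [-81, 1, 5, 3, 1, 1, 0, 3, 3, 0, 2])),
        },
    }
    return {
        "table1": table1,
        "weights_7_11": weights_7_11,
        "table4": table4,
        "text_independence_hu": text_independence_hu,
        "shares_percent": shares_percent,
        "si_classes": si_classes,
        "ti_classes": ti_classes,
        "margins_percent": margins_percent,
        "signed_ctrs_percent": signed_ctrs_percent,
        "n_time_steps": 87,
        "pft_labels": PFT_LABELS,
    }
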