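"""Weighted multiway correspondence analysis of distribution tables.

The ratio-to-independence tensor z = p / (pS (x) pT (x) pC) is expanded
as a weighted sum of rank-one tensors,

    z = 1 + sum_r sigma_r (vS_r (x) vT_r (x) vC_r),

where every mode vector has unit margin-weighted norm
(sum_s pS_s vS_rs^2 = 1) and the sigma_r are generalised singular
values: component 0 is the exact independence part (sigma_0 = 1,
all-ones vectors) and for a complete two-mode decomposition
sum_r sigma_r^2 = 1 + chi^2/N, the classical correspondence-analysis
identity.  Components are extracted greedily by higher-order power
iteration under the margin-weighted metric, each mode vector kept
orthogonal (weighted) to its predecessors, which reduces to the SVD of
standardised residuals for two-mode tables.

Because the mode vectors carry signs, every rank-one term is summarised
two ways: the non-negative CTR-tensor (outer product of the relative
contributions p v^2, a genuine product distribution whose entropy can
be decomposed additively) and the analytic positive split of the signed
term into at most 4 + 4 mutually orthogonal non-negative rank-one
tensors built from the positive/negative factor parts.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError
from .entropy import combine_normalized, entropy, log_cardinality_weights, normalized_entropy
from .tables import MultiwayTable


# ---------------------------------------------------------------------------
# Ratio tensor and chi-square
# ---------------------------------------------------------------------------

def independence_ratio_tensor(table: MultiwayTable
                              ) -> tuple[np.ndarray, list[np.ndarray], dict]:
    """Elementwise p / (outer product of margins), with empty labels dropped.

    Returns (ratio tensor, margins, report of dropped labels).
    """
    t, dropped = table.drop_empty()
    margins = t.margins()
    w = _outer(margins)
    return t.p / w, margins, {"dropped": dropped, "table": t}


def chi_square(table: MultiwayTable) -> float:
    """chi^2 / N: weighted squared distance of p to the product of margins."""
    t, _ = table.drop_empty()
    w = _outer(t.margins())
    return float(((t.p - w) ** 2 / w).sum())


def _outer(vectors: Sequence[np.ndarray]) -> np.ndarray:
    out = np.array(1.0)
    for v in vectors:
        out = np.multiply.outer(out, np.asarray(v, dtype=float))
    return out


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

@dataclass
class RankOneComponent:
    """One rank-one term sigma (v1 (x) v2 (x) ...) of the expansion."""

    index: int
    sigma: float
    vectors: list[np.ndarray]        # per-mode, unit weighted norm
    margins: list[np.ndarray]
    mode_names: list[str]
    mode_labels: list[list]
    converged: bool = True
    n_iter: int = 0

    @property
    def factors(self) -> list[np.ndarray]:
        """Signed per-mode factors p v of the rank-one probability term."""
        return [m * v for m, v in zip(self.margins, self.vectors)]

    @property
    def ctr_vectors(self) -> list[np.ndarray]:
        """Relative contributions p v^2 per mode; each sums to 1."""
        return [m * v ** 2 for m, v in zip(self.margins, self.vectors)]

    def tensor(self) -> np.ndarray:
        """sigma * (p1 v1) (x) (p2 v2) (x) ... on the probability scale."""
        return self.sigma * _outer(self.factors)


@dataclass
class MwcaResult:
    components: list[RankOneComponent]
    chi2_over_n: float
    mode_names: list[str]
    mode_labels: list[list]
    dropped: dict
    residual_norm: float

    @property
    def total_sq(self) -> float:
        """1 + chi^2/N, the complete sum of squared singular values."""
        return 1.0 + self.chi2_over_n

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    def shares(self, percent: bool = True) -> np.ndarray:
        """Variability shares sigma_r^2 / (1 + chi^2/N) per component."""
        s = self.sigmas ** 2 / self.total_sq
        return 100.0 * s if percent else s

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode_names": self.mode_names,
            "mode_labels": [[str(l) for l in labs] for labs in self.mode_labels],
            "chi2_over_n": self.chi2_over_n,
            "shares_percent": list(map(float, self.shares())),
            "residual_norm": self.residual_norm,
            "dropped": {k: list(map(str, v)) for k, v in self.dropped.items()},
            "components": [
                {"index": c.index, "sigma": c.sigma, "converged": c.converged,
                 "n_iter": c.n_iter,
                 "vectors": [list(map(float, v)) for v in c.vectors]}
                for c in self.components],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def decompose_fca(table: MultiwayTable, n_components: int = 3,
                  tol: float = 1e-12, max_iter: int = 500,
                  seed: int = 0, n_restarts: int = 8) -> MwcaResult:
    """Greedy weighted rank-one decomposition of the ratio-to-independence tensor.

    Component 0 is always the exact independence term (sigma_0 = 1,
    all-ones vectors).  Each subsequent component maximises the weighted
    projection of the residual onto a rank-one tensor by higher-order
    power iteration, initialised from the SVD of the mode-0 unfolding
    with seeded perturbation restarts; every mode vector is kept
    orthogonal, in the margin metric, to the same mode's vectors of all
    previous components.  For two-mode tables this reproduces classical
    correspondence analysis.

    Sign convention: the largest-magnitude entry of the last mode's
    vector (the category mode C in the standard layout) is positive.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    z, margins, rep = independence_ratio_tensor(table)
    t = rep["table"]
    sq = [np.sqrt(m) for m in margins]
    # transformed space: ztil = sqrt(W) o z turns the weighted problem into
    # a plain best rank-one problem with unit 2-norm vectors
    ztil = z * _outer(sq)
    shape = ztil.shape
    k = ztil.ndim
    rng = np.random.default_rng(seed)

    comp0 = RankOneComponent(0, 1.0, [np.ones(n) for n in shape], margins,
                             list(t.mode_names), [list(l) for l in t.mode_labels])
    residual = ztil - _outer(sq)
    basis = [[s.copy()] for s in sq]   # transformed previous vectors per mode
    components = [comp0]

    max_rank = min(shape)  # per-mode orthogonality bounds the component count
    for r in range(1, n_components + 1):
        if r >= max_rank:
            break
        best = None
        for attempt in range(n_restarts):
            if attempt == 0:  # HOSVD-style init, then fully random restarts
                vecs = _init_vectors(residual, rng, perturb=False)
            else:
                vecs = [_safe_unit(rng.standard_normal(n), rng) for n in shape]
            vecs = [_project(v, basis[ax]) for ax, v in enumerate(vecs)]
            vecs = [_safe_unit(v, rng) for v in vecs]
            sigma_prev, sigma, n_it, ok = 0.0, 0.0, 0, False
            for n_it in range(1, max_iter + 1):
                for ax in range(k):
                    g = _contract_all_but(residual, vecs, ax)
                    g = _project(g, basis[ax])
                    nrm = np.linalg.norm(g)
                    if nrm < 1e-300:
                        g = _safe_unit(_project(rng.standard_normal(shape[ax]),
                                                basis[ax]), rng)
                        vecs[ax] = g
                    else:
                        vecs[ax] = g / nrm
                sigma = float(np.dot(residual.ravel(), _outer(vecs).ravel()))
                if abs(sigma - sigma_prev) <= tol * max(1.0, abs(sigma)):
                    ok = True
                    break
                sigma_prev = sigma
            if best is None or abs(sigma) > abs(best[0]):
                best = (sigma, [v.copy() for v in vecs], n_it, ok)
        sigma, vecs, n_it, ok = best
        if sigma < 0:  # absorb the sign into one mode vector
            vecs[0] = -vecs[0]
            sigma = -sigma
        # fix sign indeterminacy: largest |entry| of the last mode positive
        last = vecs[k - 1]
        if last[np.argmax(np.abs(last))] < 0:
            vecs[k - 1] = -last
            vecs[k - 2] = -vecs[k - 2]
        residual = residual - sigma * _outer(vecs)
        for ax in range(k):
            basis[ax].append(vecs[ax].copy())
        orig = [v / s for v, s in zip(vecs, sq)]    # back to weighted space
        components.append(RankOneComponent(
            r, sigma, orig, margins, list(t.mode_names),
            [list(l) for l in t.mode_labels], converged=ok, n_iter=n_it))

    return MwcaResult(components=components, chi2_over_n=chi_square(table),
                      mode_names=list(t.mode_names),
                      mode_labels=[list(l) for l in t.mode_labels],
                      dropped=rep["dropped"],
                      residual_norm=float(np.linalg.norm(residual)))


def _init_vectors(residual: np.ndarray, rng, perturb: bool) -> list[np.ndarray]:
    """Leading SVD of the mode-0 unfolding, folded back per mode."""
    vecs = []
    for ax in range(residual.ndim):
        m = np.moveaxis(residual, ax, 0).reshape(residual.shape[ax], -1)
        try:
            u, _, _ = np.linalg.svd(m, full_matrices=False)
            v = u[:, 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            v = rng.standard_normal(residual.shape[ax])
        if perturb:
            v = v + 0.1 * rng.standard_normal(v.shape)
        vecs.append(v / max(np.linalg.norm(v), 1e-300))
    return vecs


def _contract_all_but(tensor: np.ndarray, vecs: Sequence[np.ndarray], keep: int
                      ) -> np.ndarray:
    out = tensor
    for ax in range(tensor.ndim - 1, -1, -1):
        if ax == keep:
            continue
        out = np.tensordot(out, vecs[ax], axes=([ax], [0]))
    return out


def _project(v: np.ndarray, basis: Sequence[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - np.dot(v, b) * b
    return v


def _safe_unit(v: np.ndarray, rng) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-300:
        v = rng.standard_normal(v.shape)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# CTR tensors and their entropies
# ---------------------------------------------------------------------------

def ctr(component: RankOneComponent) -> tuple[np.ndarray, dict]:
    """CTR-tensor and signed per-label CTR percentages of one component.

    The CTR-tensor is the outer product of the per-mode p v^2 vectors —
    a non-negative product distribution.  The signed percentages are
    100 p v^2 carrying the sign of v, the usual correspondence-analysis
    contribution layout; each mode sums to +/-100 in absolute value.
    """
    cvs = component.ctr_vectors
    tensor = _outer(cvs)
    signed = {
        name: pd.Series(100.0 * cv * np.where(v < 0, -1.0, 1.0),
                        index=[str(l) for l in labels])
        for name, cv, v, labels in zip(component.mode_names, cvs,
                                       component.vectors, component.mode_labels)
    }
    return tensor, signed


def ctr_entropy(component: RankOneComponent) -> dict:
    """Normalised entropy of each mode's CTR vector and their combination.

    The combined value is the log-cardinality-weighted mean, which
    equals the joint Hu of the (product) CTR-tensor.
    """
    cvs = component.ctr_vectors
    cards = [len(v) for v in cvs]
    per_mode = {name: normalized_entropy(v)
                for name, v in zip(component.mode_names, cvs)}
    combined = combine_normalized(list(per_mode.values()), cards)
    return {"per_mode": per_mode, "combined": combined, "cardinalities": cards}


# ---------------------------------------------------------------------------
# Positive rank-one splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitTerm:
    """One non-negative rank-one term f1 (x) f2 (x) f3 of a positive split."""

    signs: tuple[int, ...]            # +1/-1 per mode: which factor part
    factors: list[np.ndarray]         # non-negative parts, original scale
    mu: float                         # product of factor sums
    latents: list[np.ndarray]         # factors normalised to distributions

    def tensor(self) -> np.ndarray:
        return _outer(self.factors)


@dataclass
class SignedSplit:
    """Analytic split of a signed rank-one tensor into non-negative terms.

    positive - negative reconstructs sigma (p1 v1) (x) (p2 v2) (x) (p3 v3)
    exactly; all terms are pairwise orthogonal (disjoint supports), and
    each part holds at most 2^(k-1) terms (4 for three modes).
    """

    sigma: float
    positive: list[SplitTerm]
    negative: list[SplitTerm]
    mode_names: list[str]

    def reconstruct(self) -> np.ndarray:
        terms = self.positive + self.negative
        if not terms:
            raise ValidationError("empty split")
        out = np.zeros(terms[0].tensor().shape)
        for t in self.positive:
            out = out + self.sigma * t.tensor()
        for t in self.negative:
            out = out - self.sigma * t.tensor()
        return out


def positive_split(component: RankOneComponent) -> SignedSplit:
    """Split sigma (p v)1 (x) (p v)2 (x) ... into positive and negative parts.

    Each factor u = p v is written u+ - u-; expanding the tensor product
    sorts the 2^k sign combinations by the parity of the number of
    negative parts: even-parity terms form the positive part, odd the
    negative part.  Terms with an all-zero factor are omitted.
    """
    factors = component.factors
    k = len(factors)
    pos: list[SplitTerm] = []
    neg: list[SplitTerm] = []
    for signs in itertools.product((1, -1), repeat=k):
        parts = [np.maximum(s * f, 0.0) for s, f in zip(signs, factors)]
        if any(p.sum() == 0 for p in parts):
            continue
        sums = [p.sum() for p in parts]
        term = SplitTerm(signs=signs, factors=parts,
                         mu=float(np.prod(sums)),
                         latents=[p / s for p, s in zip(parts, sums)])
        (pos if signs.count(-1) % 2 == 0 else neg).append(term)
    return SignedSplit(sigma=component.sigma, positive=pos, negative=neg,
                       mode_names=list(component.mode_names))


# ---------------------------------------------------------------------------
# Entropy ratios of latent distributions
# ---------------------------------------------------------------------------

def entropy_ratios(distributions: Sequence[np.ndarray],
                   mode_names: Sequence[str] | None = None) -> dict:
    """Entropic contribution of each mode to a product distribution.

    For latent per-mode distributions p'_1 ... p'_k (of a split term or
    a CTR-tensor), the joint entropy of their product is the sum of the
    per-mode entropies; the ratio H(p'_m)/H(joint) measures how much of
    the extracted structuring each mode carries, and its complement
    (sum of the other modes) the rest.  NaN when the joint entropy is 0.
    """
    hs = [entropy(np.asarray(d, dtype=float)) for d in distributions]
    joint = sum(hs)
    names = list(mode_names) if mode_names is not None else [
        f"mode{i}" for i in range(len(hs))]
    if joint == 0:
        ratios = {n: float("nan") for n in names}
        compl = dict(ratios)
    else:
        ratios = {n: h / joint for n, h in zip(names, hs)}
        compl = {n: (joint - h) / joint for n, h in zip(names, hs)}
    return {"H": dict(zip(names, hs)), "H_joint": joint,
            "ratio": ratios, "complement_ratio": compl}


def hr_ctr(component: RankOneComponent) -> dict:
    """Entropy ratios computed on the CTR vectors of a component."""
    return entropy_ratios(component.ctr_vectors, component.mode_names)


# ---------------------------------------------------------------------------
# Map scores
# ---------------------------------------------------------------------------

def signed_scores(result: MwcaResult, component_index: int,
                  cell_labels: Mapping) -> dict:
    """Per-cell signed geometric-mean CTR score for one component.

    ``cell_labels`` maps each cell id to one label per mode (in the
    result's mode order, the last mode being the category C).  The
    score is the cube root (k-th root) of the product of the CTR
    weights at those labels, signed by the category-mode vector entry —
    a spatial intensity of the component's pattern.  Missing labels
    give NaN.
    """
    comp = result.components[component_index]
    cvs = comp.ctr_vectors
    luts = [{str(l): i for i, l in enumerate(labels)} for labels in comp.mode_labels]
    k = len(cvs)
    out = {}
    for cell, labs in cell_labels.items():
        idx = [lut.get(str(l)) for lut, l in zip(luts, labs)]
        if any(i is None for i in idx):
            out[cell] = float("nan")
            continue
        weights = [cv[i] for cv, i in zip(cvs, idx)]
        prod = float(np.prod(weights))
        sign = math.copysign(1.0, comp.vectors[-1][idx[-1]]) if comp.vectors[-1][idx[-1]] != 0 else 0.0
        out[cell] = sign * prod ** (1.0 / k) if prod > 0 else 0.0
    return out
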