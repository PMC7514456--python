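"""Shannon entropy decomposition of multiway distribution tables.

Everything is the plug-in estimator in natural log with the 0*log(0)=0
convention.  The normalised entropy Hu divides by the log of the number
of labels, so it spans [0, 1] (1 = uniform) and is base-invariant.  The
chain decomposition of a joint Hu uses log-cardinality weights: with
modes X and Y,

    Hu(X,Y) = w_X Hu(X) + w_Y Hu(Y|X),
    w_X = log|X| / (log|X| + log|Y|),

which is the entropy decomposition theorem H(X,Y) = H(X) + H(Y|X)
rewritten on the normalised scale.  The conditional-entropy ratio
p_s H(C|S=s) / H(C|S) apportions a conditional entropy among the
conditioning labels and is identical for raw and normalised entropies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .core import ValidationError
from .tables import MultiwayTable

#: absolute tolerance on probability normalisation checks
PROB_TOL = 1e-6
#: absolute tolerance at which decomposition identities are asserted
IDENTITY_TOL = 1e-9


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative probability mass")
    if abs(p.sum() - 1.0) > PROB_TOL:
        raise ValidationError(f"probabilities sum to {p.sum():.8f}, not 1")
    return p


def entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p log p in nats (0 log 0 = 0)."""
    p = _check_p(p)
    return float(-xlogy(p, p).sum())


def normalized_entropy(p: np.ndarray, n_labels: int | None = None) -> float:
    """Entropy divided by log of the label count; in [0, 1].

    A single-label distribution is degenerate-uniform and returns 1 by
    convention.  ``n_labels`` defaults to the number of entries of p
    (zero-probability labels still count).
    """
    p = np.asarray(p, dtype=float)
    n = p.size if n_labels is None else n_labels
    if n < 1:
        raise ValidationError("need at least one label")
    if n == 1:
        import warnings
        warnings.warn("normalised entropy of a 1-label mode is 1 by convention")
        return 1.0
    return entropy(p) / math.log(n)


def log_cardinality_weights(cardinalities: Sequence[int]) -> np.ndarray:
    """Weights log|X_i| / sum_j log|X_j| of the normalised decomposition."""
    logs = np.log(np.asarray(cardinalities, dtype=float))
    return logs / logs.sum()


def combine_normalized(hu_values: Sequence[float], cardinalities: Sequence[int]) -> float:
    """Log-cardinality-weighted mean of normalised entropies.

    For a chain this rebuilds the joint Hu from Hu(X) and Hu(Y|X)...;
    for a product distribution it equals the joint Hu of the product.
    """
    w = log_cardinality_weights(cardinalities)
    return float(np.dot(w, np.asarray(hu_values, dtype=float)))


def conditional_entropy(table: MultiwayTable, target: Sequence[str] | str,
                        given: Sequence[str] | str, normalized: bool = False,
                        ) -> tuple[float, dict]:
    """H(target | given) = sum_g p_g H(target | given=g), with parts.

    Returns the conditional entropy and a dict mapping each conditioning
    label combination g to its part p_g * H(target|given=g).  Empty
    strata contribute zero.  The normalised variant divides both by the
    log of the number of target label combinations.
    """
    target = [target] if isinstance(target, str) else list(target)
    given = [given] if isinstance(given, str) else list(given)
    if set(target) & set(given):
        raise ValidationError("target and given modes must be disjoint")
    joint = table.marginalise(given + target)
    p = joint.p
    n_given = tuple(len(joint.mode_labels[i]) for i in range(len(given)))
    g_axes = tuple(range(len(given)))
    t_axes = tuple(range(len(given), p.ndim))
    p_g = p.sum(axis=t_axes)
    parts: dict = {}
    total = 0.0
    for key in np.ndindex(*n_given):
        mass = float(p_g[key])
        if mass <= 0:
            continue
        cond = p[key] / mass
        part = mass * float(-xlogy(cond, cond).sum())
        label = tuple(joint.mode_labels[ax][key[ax]] for ax in g_axes)
        parts[label if len(label) > 1 else label[0]] = part
        total += part
    if normalized:
        n_target = int(np.prod([len(table.mode_labels[table.mode_names.index(m)])
                                for m in target]))
        scale = math.log(n_target) if n_target > 1 else 1.0
        total /= scale
        parts = {k: v / scale for k, v in parts.items()}
    return total, parts


def mutual_information(table: MultiwayTable) -> float:
    """MI = KL(p || product of margins), generalised to any number of modes.

    Equals sum of per-mode entropies minus the joint entropy; >= 0.
    """
    if table.n_modes < 2:
        raise ValidationError("mutual information needs >= 2 modes")
    p = table.p
    prod = np.ones_like(p)
    for ax, m in enumerate(table.margins()):
        shape = [1] * p.ndim
        shape[ax] = -1
        prod = prod * m.reshape(shape)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / prod[mask])).sum())


@dataclass
class EntropyReport:
    """Full decomposition of one table along one conditioning chain."""

    chain: list[str]
    cardinalities: list[int]
    weights: np.ndarray                    # log-cardinality weights per mode
    mode_H: dict                           # per-mode marginal H
    mode_Hu: dict
    joint_H: float
    joint_Hu: float
    conditional_H: dict                    # {"X|Y,Z": value} along the chain
    conditional_Hu: dict
    conditional_parts: dict                # per-condition p_g H(target|g)
    mutual_information: float
    max_identity_residual: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("H(joint)", self.joint_H), ("Hu(joint)", self.joint_Hu),
                ("MI", self.mutual_information)]
        rows += [(f"H({m})", v) for m, v in self.mode_H.items()]
        rows += [(f"Hu({m})", v) for m, v in self.mode_Hu.items()]
        rows += [(f"H({k})", v) for k, v in self.conditional_H.items()]
        rows += [(f"Hu({k})", v) for k, v in self.conditional_Hu.items()]
        rows += [(f"weight({m})", w) for m, w in zip(self.chain, self.weights)]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "chain": self.chain, "cardinalities": self.cardinalities,
            "weights": list(map(float, self.weights)),
            "mode_H": {str(k): v for k, v in self.mode_H.items()},
            "mode_Hu": {str(k): v for k, v in self.mode_Hu.items()},
            "joint_H": self.joint_H, "joint_Hu": self.joint_Hu,
            "conditional_H": {str(k): v for k, v in self.conditional_H.items()},
            "conditional_Hu": {str(k): v for k, v in self.conditional_Hu.items()},
            "mutual_information": self.mutual_information,
            "max_identity_residual": self.max_identity_residual,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def decompose(table: MultiwayTable, chain: Sequence[str] | None = None) -> EntropyReport:
    """Entropy decomposition of a table along a conditioning chain.

    ``chain`` is a permutation of the mode names; the report carries
    H(X1), H(X2|X1), H(X3|X1,X2) ... on both raw and normalised scales,
    the log-cardinality weights, the multiway mutual information and
    the largest residual of the identities it asserts (chain rule and
    the normalised weighted-sum identity).
    """
    chain = list(chain) if chain is not None else list(table.mode_names)
    if sorted(chain) != sorted(table.mode_names):
        raise ValidationError("chain must be a permutation of the table modes")
    cards = [len(table.mode_labels[table.mode_names.index(m)]) for m in chain]
    weights = log_cardinality_weights(cards)
    p = table.p
    joint_H = float(-xlogy(p, p).sum())
    joint_Hu = joint_H / math.log(np.prod(cards))
    mode_H = {m: entropy(table.margin(m)) for m in chain}
    mode_Hu = {m: normalized_entropy(table.margin(m)) for m in chain}
    cond_H, cond_Hu, parts = {}, {}, {}
    chain_sum = mode_H[chain[0]]
    hu_terms = [mode_Hu[chain[0]]]
    for i in range(1, len(chain)):
        tgt, giv = chain[i], chain[:i]
        h, pp = conditional_entropy(table, tgt, giv)
        key = f"{tgt}|{','.join(giv)}"
        cond_H[key] = h
        cond_Hu[key] = h / math.log(cards[i]) if cards[i] > 1 else h
        parts[key] = pp
        chain_sum += h
        hu_terms.append(cond_Hu[key])
    mi = mutual_information(table) if table.n_modes >= 2 else 0.0
    res = abs(chain_sum - joint_H)
    res = max(res, abs(float(np.dot(weights, hu_terms)) - joint_Hu))
    res = max(res, abs(sum(mode_H.values()) - mi - joint_H))
    if res > IDENTITY_TOL:
        raise AssertionError(f"entropy decomposition identity residual {res:.3e}")
    return EntropyReport(chain=chain, cardinalities=cards, weights=weights,
                         mode_H=mode_H, mode_Hu=mode_Hu, joint_H=joint_H,
                         joint_Hu=joint_Hu, conditional_H=cond_H,
                         conditional_Hu=cond_Hu, conditional_parts=parts,
                         mutual_information=mi, max_identity_residual=res)


def conditional_entropy_ratio(table: MultiwayTable, target: str | Sequence[str],
                              given: str | Sequence[str],
                              subset: Sequence) -> float:
    """Share of H(target|given) carried by a subset of conditioning labels.

    (sum over the subset of p_s H(target|given=s)) / H(target|given);
    1.0 over all labels, additive over disjoint subsets.  Raw and
    uniform-normalised versions coincide.  Returns NaN when the
    conditional entropy is zero.
    """
    if not len(subset):
        raise ValidationError("subset must be non-empty")
    h, parts = conditional_entropy(table, target, given)
    if h == 0:
        return float("nan")
    return sum(parts.get(s, 0.0) for s in subset) / h


def map_statistic(cell_labels: Mapping, table: MultiwayTable,
                  target: str | Sequence[str], given: str | Sequence[str],
                  as_percent: bool = True) -> dict:
    """Per-cell conditional-entropy ratio restricted to locally occurring labels.

    ``cell_labels`` maps each cell id to the set of conditioning labels
    occurring there (e.g. the size classes of the patches covering the
    cell).  Each cell gets the share of the global conditional entropy
    carried by those labels, as a percentage by default; cells with an
    empty label set get NaN (no patches — read as local uniformity).
    """
    h, parts = conditional_entropy(table, target, given)
    out = {}
    for cell, labs in cell_labels.items():
        if not labs or h == 0:
            out[cell] = float("nan")
        else:
            v = sum(parts.get(l, 0.0) for l in set(labs)) / h
            out[cell] = 100.0 * v if as_percent else v
    return out
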