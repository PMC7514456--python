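"""Multiway correspondence analysis: CA equivalence, identities, CTRs, splits."""

import itertools
import math

import numpy as np
import pytest

import psishent as ps
from psishent.tables import MultiwayTable

from conftest import random_table


def ca_oracle(table):
    """Classical correspondence analysis by SVD of standardised residuals."""
    p = table.p
    pi, pj = table.margin(0), table.margin(1)
    S = (p - np.outer(pi, pj)) / np.sqrt(np.outer(pi, pj))
    u, s, vt = np.linalg.svd(S)
    return s, u, vt


def product_table(*margins):
    vals = np.array(1.0)
    for m in margins:
        vals = np.multiply.outer(vals, np.asarray(m, dtype=float))
    names = [f"M{i}" for i in range(len(margins))]
    labels = [[f"{n}{j}" for j in range(len(m))] for n, m in zip(names, margins)]
    return MultiwayTable(names, labels, vals)


class TestRatioTensor:
    def test_product_table_all_ones(self):
        t = product_table([0.4, 0.6], [0.2, 0.3, 0.5])
        z, _, _ = ps.independence_ratio_tensor(t)
        assert np.allclose(z, 1.0)

    def test_diagonal_hand_computation(self):
        t = MultiwayTable(["S", "C"], [["a", "b"], ["x", "y"]],
                          np.array([[0.5, 0.0], [0.0, 0.5]]))
        z, _, _ = ps.independence_ratio_tensor(t)
        assert np.allclose(z, [[2.0, 0.0], [0.0, 2.0]])

    def test_reconstruction_identity(self, rng):
        t = random_table(rng, (4, 3, 2))
        z, margins, _ = ps.independence_ratio_tensor(t)
        w = np.einsum("i,j,k->ijk", *margins)
        assert np.allclose(z * w, t.p, atol=1e-14)

    def test_empty_labels_dropped_and_reported(self, rng):
        vals = rng.random((3, 4))
        vals[1, :] = 0.0
        t = MultiwayTable(["S", "C"], [list("abc"), list("wxyz")], vals)
        z, margins, rep = ps.independence_ratio_tensor(t)
        assert z.shape == (2, 4)
        assert rep["dropped"] == {"S": ["b"]}


class TestChiSquare:
    def test_product_table_zero(self):
        t = product_table([0.4, 0.6], [0.2, 0.8])
        assert ps.chi_square(t) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_two_by_two(self):
        t = MultiwayTable(["S", "C"], [["a", "b"], ["x", "y"]],
                          np.array([[0.5, 0.0], [0.0, 0.5]]))
        # direct formula: 4 cells, each (0.5-0.25)^2/0.25 or (0-0.25)^2/0.25
        assert ps.chi_square(t) == pytest.approx(1.0)


class TestDecomposeFca:
    def test_component_zero_is_independence(self, rng):
        t = random_table(rng, (3, 4, 2))
        res = ps.decompose_fca(t, 1, seed=0)
        c0 = res.components[0]
        assert c0.sigma == 1.0
        for v in c0.vectors:
            assert np.allclose(v, 1.0)

    def test_product_table_no_further_structure(self):
        t = product_table([0.4, 0.6], [0.2, 0.3, 0.5], [0.7, 0.3])
        res = ps.decompose_fca(t, 1, seed=0)
        assert abs(res.components[1].sigma) < 1e-10

    def test_two_by_two_phi_coefficient(self):
        t = MultiwayTable(["S", "C"], [["a", "b"], ["x", "y"]],
                          np.array([[0.3, 0.2], [0.2, 0.3]]))
        res = ps.decompose_fca(t, 1, seed=0)
        assert res.components[1].sigma == pytest.approx(0.2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_mode_matches_ca_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, (5, 7))
        s, u, vt = ca_oracle(t)
        res = ps.decompose_fca(t, 4, seed=0)
        assert np.allclose(res.sigmas[1:], s[:4], atol=1e-8)
        # vectors match up to sign, after unweighting
        pi = t.margin(0)
        for r in range(1, 5):
            v_ca = u[:, r - 1] / np.sqrt(pi)
            v_us = res.components[r].vectors[0]
            assert min(np.abs(v_ca - v_us).max(), np.abs(v_ca + v_us).max()) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_completeness_identity_two_mode(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_table(rng, (5, 7))
        res = ps.decompose_fca(t, 4, seed=0)
        assert (res.sigmas ** 2).sum() == pytest.approx(1 + ps.chi_square(t), abs=1e-8)

    def test_unit_weighted_norm_per_mode(self, rng):
        t = random_table(rng, (4, 3, 5))
        res = ps.decompose_fca(t, 2, seed=0)
        for comp in res.components[1:]:
            for m, v in zip(comp.margins, comp.vectors):
                assert np.dot(m, v ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_recovery(self):
        table, info = ps.make_rank_structured_table((5, 6, 7), 0.05, seed=3)
        res = ps.decompose_fca(table, 1, seed=0)
        assert res.components[1].sigma == pytest.approx(0.05, abs=1e-6)
        for m in range(3):
            got, want = res.components[1].vectors[m], info["vectors"][m]
            assert min(np.abs(got - want).max(), np.abs(got + want).max()) < 1e-6

    def test_nestedness_of_greedy_extraction(self, rng):
        t = random_table(rng, (4, 5, 3))
        r1 = ps.decompose_fca(t, 1, seed=0)
        r3 = ps.decompose_fca(t, 3, seed=0)
        assert r1.components[1].sigma == pytest.approx(r3.components[1].sigma, abs=1e-9)

    def test_determinism_under_seed(self, rng):
        t = random_table(rng, (4, 5, 3))
        a = ps.decompose_fca(t, 2, seed=42)
        b = ps.decompose_fca(t, 2, seed=42)
        for ca_, cb in zip(a.components, b.components):
            assert ca_.sigma == cb.sigma
            for va, vb in zip(ca_.vectors, cb.vectors):
                assert np.array_equal(va, vb)


class TestCtr:
    def test_component_zero_ctr_is_margin_product(self, rng):
        t = random_table(rng, (3, 4))
        res = ps.decompose_fca(t, 1, seed=0)
        tensor, signed = ps.ctr(res.components[0])
        assert np.allclose(tensor, np.outer(t.margin(0), t.margin(1)))

    def test_per_mode_ctr_sums_to_hundred(self, rng):
        t = random_table(rng, (3, 4, 5))
        res = ps.decompose_fca(t, 2, seed=0)
        for comp in res.components:
            _, signed = ps.ctr(comp)
            for series in signed.values():
                assert series.abs().sum() == pytest.approx(100.0, abs=1e-9)

    def test_synthetic_rank_one_dominant_cell(self):
        # a sharp rank-one perturbation concentrates the CTR where built
        table, info = ps.make_rank_structured_table((4, 4, 4), 0.05, seed=5)
        res = ps.decompose_fca(table, 1, seed=0)
        comp = res.components[1]
        for m in range(3):
            want = info["margins"][m] * info["vectors"][m] ** 2
            assert np.allclose(comp.ctr_vectors[m], want, atol=1e-8)


class TestCtrEntropy:
    def test_worked_combination(self):
        hu = ps.combine_normalized([0.786, 0.595, 0.894], [7, 8, 11])
        assert hu == pytest.approx(0.764, abs=1e-3)

    def test_uniform_ctr_combined_is_one(self):
        comp = ps.RankOneComponent(
            index=1, sigma=0.1,
            vectors=[np.ones(3), np.ones(4)],
            margins=[np.full(3, 1 / 3), np.full(4, 0.25)],
            mode_names=["A", "B"], mode_labels=[list("abc"), list("wxyz")])
        out = ps.ctr_entropy(comp)
        assert out["combined"] == pytest.approx(1.0)

    def test_weighted_mean_equals_joint_of_product(self, rng):
        t = random_table(rng, (4, 3, 5))
        res = ps.decompose_fca(t, 1, seed=0)
        comp = res.components[1]
        out = ps.ctr_entropy(comp)
        tensor, _ = ps.ctr(comp)
        cards = [len(v) for v in comp.ctr_vectors]
        joint_hu = ps.entropy(tensor.ravel()) / math.log(np.prod(cards))
        assert out["combined"] == pytest.approx(joint_hu, abs=1e-12)


class TestPositiveSplit:
    def test_nonnegative_factors_trivial_split(self, rng):
        t = random_table(rng, (3, 4))
        res = ps.decompose_fca(t, 1, seed=0)
        split = ps.positive_split(res.components[0])
        assert split.negative == []
        assert np.allclose(split.reconstruct(), res.components[0].tensor())

    def test_mixed_sign_first_factor_two_terms_each(self):
        comp = ps.RankOneComponent(
            index=1, sigma=1.0,
            vectors=[np.array([1.0, -1.0]), np.array([1.0, 1.0]), np.array([1.0, 1.0])],
            margins=[np.full(2, 0.5)] * 3,
            mode_names=["S", "T", "C"], mode_labels=[list("ab")] * 3)
        split = ps.positive_split(comp)
        # y, z >= 0: positive part x+ (x) y (x) z, negative part x- (x) y (x) z
        assert len(split.positive) == 1 and len(split.negative) == 1
        assert split.positive[0].signs == (1, 1, 1)
        assert np.allclose(split.reconstruct(), comp.tensor(), atol=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_signed_exact_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, (3, 4, 5))
        res = ps.decompose_fca(t, 2, seed=0)
        for comp in res.components[1:]:
            split = ps.positive_split(comp)
            assert len(split.positive) <= 4 and len(split.negative) <= 4
            assert np.abs(split.reconstruct() - comp.tensor()).max() < 1e-12
            # all term pairs orthogonal (disjoint supports)
            terms = [s.tensor() for s in split.positive + split.negative]
            for a, b in itertools.combinations(terms, 2):
                assert abs(np.vdot(a, b)) < 1e-12
            # every term non-negative
            for term in terms:
                assert term.min() >= 0


class TestEntropyRatios:
    def test_uniform_factors_closed_form(self):
        dists = [np.full(7, 1 / 7), np.full(8, 1 / 8), np.full(11, 1 / 11)]
        out = ps.entropy_ratios(dists, ["S", "T", "C"])
        total = math.log(7) + math.log(8) + math.log(11)
        assert out["ratio"]["S"] == pytest.approx(math.log(7) / total)

    def test_degenerate_mode_ratio_zero(self):
        dists = [np.array([1.0, 0.0]), np.full(3, 1 / 3)]
        out = ps.entropy_ratios(dists, ["S", "T"])
        assert out["ratio"]["S"] == 0.0

    def test_ratio_and_complement_sum_to_one(self, rng):
        t = random_table(rng, (3, 4, 5))
        res = ps.decompose_fca(t, 1, seed=0)
        split = ps.positive_split(res.components[1])
        term = split.positive[0]
        out = ps.entropy_ratios(term.latents, res.mode_names)
        for m in res.mode_names:
            assert out["ratio"][m] + out["complement_ratio"][m] == pytest.approx(1.0)

    def test_zero_joint_entropy_flagged(self):
        dists = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        out = ps.entropy_ratios(dists, ["S", "T"])
        assert math.isnan(out["ratio"]["S"])


class TestSignedScores:
    def test_zero_weight_cell_scores_zero(self, rng):
        t = random_table(rng, (3, 4, 5))
        res = ps.decompose_fca(t, 1, seed=0)
        comp = res.components[1]
        comp.vectors[0][0] = 0.0  # kill one label's weight
        scores = ps.signed_scores(res, 1, {"cell": (
            comp.mode_labels[0][0], comp.mode_labels[1][0], comp.mode_labels[2][0])})
        assert scores["cell"] == 0.0

    def test_positive_weights_cube_root(self, rng):
        t = random_table(rng, (3, 4, 5))
        res = ps.decompose_fca(t, 1, seed=0)
        comp = res.components[1]
        labs = (comp.mode_labels[0][1], comp.mode_labels[1][1], comp.mode_labels[2][1])
        scores = ps.signed_scores(res, 1, {"cell": labs})
        w = [cv[1] for cv in comp.ctr_vectors]
        expected = math.copysign((w[0] * w[1] * w[2]) ** (1 / 3),
                                 comp.vectors[2][1])
        assert scores["cell"] == pytest.approx(expected)

    def test_missing_label_is_nan(self, rng):
        t = random_table(rng, (3, 4, 5))
        res = ps.decompose_fca(t, 1, seed=0)
        scores = ps.signed_scores(res, 1, {"cell": ("nope", "nope", "nope")})
        assert math.isnan(scores["cell"])

    def test_toy_grid_hand_enumeration(self, rng):
        t = random_table(rng, (2, 2, 2))
        res = ps.decompose_fca(t, 1, seed=0)
        comp = res.components[1]
        cells = {}
        expected = {}
        for i, j, k in itertools.product(range(2), repeat=3):
            cid = f"c{i}{j}{k}"
            cells[cid] = (comp.mode_labels[0][i], comp.mode_labels[1][j],
                          comp.mode_labels[2][k])
            w = (comp.ctr_vectors[0][i] * comp.ctr_vectors[1][j]
                 * comp.ctr_vectors[2][k])
            sgn = 1.0 if comp.vectors[2][k] > 0 else -1.0 if comp.vectors[2][k] < 0 else 0.0
            expected[cid] = sgn * w ** (1 / 3) if w > 0 else 0.0
        scores = ps.signed_scores(res, 1, cells)
        for cid in cells:
            assert scores[cid] == pytest.approx(expected[cid], abs=1e-12)
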