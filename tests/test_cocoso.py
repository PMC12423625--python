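"""CoCoSo ranking: worked values, dominance, and oracle equivalence."""

import numpy as np
import pytest

from hesrank.cocoso import (
    DegenerateMinimumError,
    appraisal_scores,
    comparability_sequences,
    composite_scores,
    minmax_normalize,
    rank_alternatives,
    run_cocoso,
)
from hesrank.entropy import compute_entropy_weights, divergence_weights

from .conftest import cocoso_oracle, make_matrix


def weights_of(values, ids=None):
    values = np.asarray(values, dtype=float)
    # wrap an arbitrary weight vector: entropy/divergence are irrelevant here
    return divergence_weights(1.0 - values, ids)


class TestMinMaxNormalize:
    def test_benefit_column(self):
        norm = minmax_normalize(make_matrix([[10.0], [30.0], [20.0]]))
        assert norm.values[:, 0].tolist() == [0.0, 1.0, 0.5]

    def test_cost_column_reversed(self):
        norm = minmax_normalize(
            make_matrix([[10.0], [30.0], [20.0]], directions=["cost"])
        )
        assert norm.values[:, 0].tolist() == [1.0, 0.0, 0.5]

    def test_constant_column_all_best(self):
        norm = minmax_normalize(make_matrix([[50.0, 1.0], [50.0, 2.0]]))
        assert norm.values[:, 0].tolist() == [1.0, 1.0]


class TestComparabilitySequences:
    def test_unit_and_zero_powers(self):
        norm = minmax_normalize(make_matrix([[1.0, 0.0], [0.0, 1.0]]))
        S, P = comparability_sequences(norm, np.array([0.6, 0.4]))
        assert S.tolist() == [0.6, 0.4]
        assert P.tolist() == [pytest.approx(1.0), pytest.approx(1.0)]

    def test_all_ones_row(self):
        norm = minmax_normalize(make_matrix([[9.0, 9.0, 9.0], [1.0, 1.0, 1.0]]))
        S, P = comparability_sequences(norm, np.array([0.2, 0.3, 0.5]))
        assert S[0] == pytest.approx(1.0)
        assert P[0] == pytest.approx(3.0)  # n terms of 1


class TestAppraisalScores:
    def test_worked_example(self):
        k_a, k_b, k_c = appraisal_scores(
            np.array([0.6, 0.4]), np.array([1.0, 1.0]), lam=0.5
        )
        assert np.round(k_a, 4).tolist() == [0.5333, 0.4667]
        assert k_b.tolist() == [2.5, 2.0]
        assert k_c.tolist() == pytest.approx([1.0, 0.875])

    def test_identical_alternatives_symmetry(self):
        S = np.array([0.5, 0.5, 0.5])
        P = np.array([2.0, 2.0, 2.0])
        k_a, k_b, k_c = appraisal_scores(S, P)
        assert np.allclose(k_a, 1 / 3)
        assert np.allclose(k_b, 2.0)
        assert np.allclose(k_c, 1.0)

    def test_lambda_one_reduces_to_additive_share(self):
        S = np.array([0.6, 0.3])
        P = np.array([1.9, 1.2])
        _, _, k_c = appraisal_scores(S, P, lam=1.0)
        assert np.allclose(k_c, S / S.max())

    def test_lambda_half_symmetric_in_s_p_exchange(self):
        S = np.array([0.6, 0.3, 0.9])
        P = np.array([1.9, 1.2, 2.4])
        _, _, k_c = appraisal_scores(S, P, lam=0.5)
        _, _, k_c_swapped = appraisal_scores(P, S, lam=0.5)
        assert np.allclose(k_c, k_c_swapped)

    def test_zero_minimum_raises_unless_guarded(self):
        S = np.array([0.0, 0.5])
        P = np.array([1.0, 2.0])
        with pytest.raises(DegenerateMinimumError):
            appraisal_scores(S, P)
        k_a, k_b, k_c = appraisal_scores(S, P, epsilon_guard=True)
        assert np.isfinite(k_b).all()


class TestCompositeAndRank:
    def test_worked_composites(self):
        C = composite_scores(
            np.array([0.5333, 0.4667]),
            np.array([2.5, 2.0]),
            np.array([1.0, 0.875]),
        )
        assert np.round(C, 3).tolist() == [2.445, 2.049]
        rank, tied = rank_alternatives(C, ["A", "B"])
        assert rank.tolist() == [1, 2] and not tied

    def test_unit_scores_closed_form(self):
        C = composite_scores(np.ones(2), np.ones(2), np.ones(2))
        assert np.allclose(C, 2.0)

    def test_tie_breaks_alphabetically_and_flags(self):
        rank, tied = rank_alternatives(np.array([1.0, 1.0]), ["Zed", "Ann"])
        assert rank.tolist() == [2, 1] and tied

    def test_literal_variant_differs(self):
        k = (np.array([0.5, 0.5]), np.array([2.5, 2.0]), np.array([1.0, 0.9]))
        assert not np.allclose(
            composite_scores(*k), composite_scores(*k, variant="arith_only")
        )


class TestRunCocoso:
    def test_symmetric_matrix_exact_tie(self):
        matrix = make_matrix([[1.0, 0.0], [0.0, 1.0]])
        wv = weights_of([0.5, 0.5], matrix.indicator_ids)
        res = run_cocoso(matrix, wv)
        assert res.C[0] == res.C[1]
        assert res.tied

    def test_dominating_country_scores_higher(self):
        rng = np.random.default_rng(11)
        for trial in range(25):
            scores = rng.uniform(10, 90, size=(5, 3))
            # make row 0 dominate row 1 on every benefit criterion
            scores[0] = scores[1] + rng.uniform(1.0, 10.0, size=3)
            matrix = make_matrix(scores)
            res = run_cocoso(matrix, compute_entropy_weights(matrix))
            assert res.C[0] > res.C[1]

    def test_all_intermediates_match_transcription_oracle(self):
        rng = np.random.default_rng(23)
        checked = 0
        for trial in range(60):
            scores = rng.uniform(1.0, 100.0, size=(4, 3))
            directions = rng.choice(["benefit", "cost"], size=3).tolist()
            matrix = make_matrix(scores, directions=directions)
            w = rng.dirichlet(np.ones(3))
            wv = divergence_weights(1.0 - w, matrix.indicator_ids)
            try:
                res = run_cocoso(matrix, wv)
            except DegenerateMinimumError:
                continue  # one alternative worst on every criterion
            S, P, k_a, k_b, k_c, C = cocoso_oracle(scores, w, directions)
            for got, exp in [(res.S, S), (res.P, P), (res.k_a, k_a),
                             (res.k_b, k_b), (res.k_c, k_c), (res.C, C)]:
                assert np.allclose(got, exp, atol=1e-12)
            checked += 1
        assert checked >= 30

    def test_invariants_on_random_instances(self):
        rng = np.random.default_rng(5)
        while True:
            scores = rng.uniform(5, 95, size=(8, 4))
            matrix = make_matrix(scores)
            try:
                res = run_cocoso(matrix, compute_entropy_weights(matrix))
                break
            except DegenerateMinimumError:
                continue
        assert res.k_a.sum() == pytest.approx(1.0, abs=1e-9)
        # k_c is bounded by 1; it attains 1 exactly when one alternative
        # maximises S and P simultaneously
        assert res.k_c.max() <= 1.0 + 1e-12
        if np.argmax(res.S) == np.argmax(res.P):
            assert res.k_c.max() == pytest.approx(1.0)
        assert (res.k_b >= 2.0 - 1e-12).all()
        assert (res.C > 0).all()
        assert sorted(res.rank.tolist()) == list(range(1, 9))
        # C non-increasing along the ranking
        C_sorted = res.C[np.argsort(res.rank)]
        assert (np.diff(C_sorted) <= 1e-12).all()
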