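import itertools
from math import log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mhagscan.association import (
    PermutationResult,
    call_significant,
    direction,
    lrt_statistic,
    manhattan_table,
    permutation_threshold,
    scan,
)
from mhagscan.mismatch import build_match_matrix

from conftest import make_matrix, make_pairs


def loglik_ratio_oracle(o):
    """2 x (saturated - independence) multinomial log-likelihood, from scratch."""
    o = np.asarray(o, dtype=float)
    n = o.sum()
    p_row = o.sum(axis=1) / n
    p_col = o.sum(axis=0) / n
    ll_sat = sum(o[i, j] * log(o[i, j] / n) for i in (0, 1) for j in (0, 1) if o[i, j] > 0)
    ll_ind = sum(
        o[i, j] * log(p_row[i] * p_col[j])
        for i in (0, 1)
        for j in (0, 1)
        if o[i, j] > 0 and p_row[i] * p_col[j] > 0
    )
    return 2.0 * (ll_sat - ll_ind)


def enumerate_tables(n_max):
    for n in range(1, n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield np.array([[a, b], [c, n - a - b - c]])


class TestLrtStatistic:
    def test_balanced_table_is_zero(self):
        assert lrt_statistic([[5, 5], [5, 5]]) == 0.0

    def test_perfect_separation_closed_form(self):
        assert lrt_statistic([[10, 0], [0, 10]]) == pytest.approx(40 * log(2))

    def test_near_perfect_table(self):
        assert lrt_statistic([[9, 1], [0, 10]]) == pytest.approx(21.0239, abs=1e-3)

    def test_zero_marginal_tables_are_zero(self):
        assert lrt_statistic([[0, 0], [3, 7]]) == 0.0
        assert lrt_statistic([[3, 0], [7, 0]]) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            lrt_statistic([[1, -1], [0, 2]])

    def test_matches_loglik_oracle_exhaustively(self):
        for o in enumerate_tables(8):
            assert lrt_statistic(o) == pytest.approx(loglik_ratio_oracle(o), abs=1e-10)

    def test_matches_scipy_g_test_on_positive_tables(self):
        for o in enumerate_tables(6):
            if (o > 0).all():
                g, _, _, _ = stats.chi2_contingency(o, correction=False, lambda_="log-likelihood")
                assert lrt_statistic(o) == pytest.approx(g, abs=1e-10)

    def test_label_swap_invariance_and_direction_flip(self):
        for o in ([[9, 1], [0, 10]], [[4, 6], [7, 3]], [[2, 2], [5, 1]]):
            o = np.asarray(o)
            swapped = o[::-1, ::-1]  # relabel rows and columns together
            assert lrt_statistic(o) == pytest.approx(lrt_statistic(swapped))
            col_flip = o[:, ::-1]  # matched <-> mismatched
            assert lrt_statistic(o) == pytest.approx(lrt_statistic(col_flip))
            if direction(o) != "none":
                assert direction(col_flip) != direction(o)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=0, max_value=40), min_size=4, max_size=4))
def test_statistic_properties_on_arbitrary_tables(cells):
    """Non-negativity, transpose-style invariance and oracle agreement hold
    for arbitrary count tables."""
    o = np.array(cells, dtype=float).reshape(2, 2)
    if o.sum() == 0:
        return
    g = lrt_statistic(o)
    assert g >= 0.0
    assert g == pytest.approx(loglik_ratio_oracle(o), abs=1e-9)
    assert g == pytest.approx(lrt_statistic(o[::-1, ::-1]), abs=1e-9)


class TestDirection:
    def test_rejection_acceptance_and_symmetry(self):
        assert direction([[9, 1], [0, 10]]) == "rejection"
        assert direction([[0, 10], [9, 1]]) == "acceptance"
        assert direction([[5, 5], [5, 5]]) == "none"


def _cohort_with_status(status, outcomes):
    """Build genotypes whose model2 match statuses equal the given grid.

    Donor fixed AA; recipient AA for matched, BB for mismatched, missing for
    unknown. Pair i uses donor s{2i}, recipient s{2i+1}.
    """
    status = np.asarray(status)
    n_pairs, n_loci = status.shape
    calls = np.zeros((2 * n_pairs, n_loci), dtype=int)
    for i in range(n_pairs):
        for j in range(n_loci):
            calls[2 * i + 1, j] = {0: 0, 1: 2, -1: -1}[status[i, j]]
    gm = make_matrix(calls)
    cohort = make_pairs(
        gm, [(f"s{2 * i}", f"s{2 * i + 1}", outcomes[i]) for i in range(n_pairs)]
    )
    return gm, cohort


class TestScan:
    def test_status_equals_outcome_gives_max_statistic(self):
        outcomes = ["rejected"] * 10 + ["accepted"] * 10
        status = np.array([[1] * 1] * 10 + [[0]] * 10)
        gm, cohort = _cohort_with_status(status, outcomes)
        match = build_match_matrix(gm, cohort, "model2")
        res = scan(match, cohort)
        assert res["lrt"].iloc[0] == pytest.approx(40 * log(2))
        assert res["direction"].iloc[0] == "rejection"
        assert res["pointwise_p"].iloc[0] == pytest.approx(stats.chi2.sf(40 * log(2), 1))

    def test_all_matched_locus_untestable(self):
        status = np.array([[0, 1], [0, 0], [0, 1], [0, 0]])
        gm, cohort = _cohort_with_status(status, ["rejected", "accepted"] * 2)
        match = build_match_matrix(gm, cohort, "model2")
        res = scan(match, cohort)
        assert not res["testable"].iloc[0]
        assert res["lrt"].iloc[0] == 0.0

    def test_scan_agrees_with_single_table_statistic(self, rng):
        status = rng.choice([0, 1, -1], size=(12, 30), p=[0.45, 0.45, 0.1])
        outcomes = ["rejected" if x else "accepted" for x in rng.integers(0, 2, 12)]
        if "rejected" not in outcomes:
            outcomes[0] = "rejected"
        if "accepted" not in outcomes:
            outcomes[1] = "accepted"
        gm, cohort = _cohort_with_status(status, outcomes)
        match = build_match_matrix(gm, cohort, "model2")
        res = scan(match, cohort)
        rej = cohort.rejected
        for j in range(30):
            col = status[:, j]
            o = [
                [((col == 0) & ~rej).sum(), ((col == 1) & ~rej).sum()],
                [((col == 0) & rej).sum(), ((col == 1) & rej).sum()],
            ]
            if res["testable"].iloc[j]:
                assert res["lrt"].iloc[j] == pytest.approx(lrt_statistic(o), abs=1e-10)
                assert res["direction"].iloc[j] == direction(o)

    def test_invariant_to_locus_order(self, rng):
        status = rng.choice([0, 1], size=(10, 20))
        outcomes = ["rejected"] * 5 + ["accepted"] * 5
        perm = rng.permutation(20)
        gm1, cohort1 = _cohort_with_status(status, outcomes)
        gm2, cohort2 = _cohort_with_status(status[:, perm], outcomes)
        r1 = scan(build_match_matrix(gm1, cohort1, "model2"))
        r2 = scan(build_match_matrix(gm2, cohort2, "model2"))
        np.testing.assert_allclose(r1["lrt"].to_numpy()[perm], r2["lrt"].to_numpy())

    def test_single_class_outcomes_error(self):
        gm, cohort = _cohort_with_status([[1], [0]], ["rejected", "rejected"])
        match = build_match_matrix(gm, cohort, "model2")
        with pytest.raises(ValueError):
            scan(match, cohort)


def exhaustive_max_distribution(status, rejected_count):
    """All C(n, r) outcome assignments, max statistic each; independent loop oracle."""
    status = np.asarray(status)
    n = status.shape[0]
    maxima = []
    for combo in itertools.combinations(range(n), rejected_count):
        rej = np.zeros(n, dtype=bool)
        rej[list(combo)] = True
        best = 0.0
        for j in range(status.shape[1]):
            col = status[:, j]
            known = col != -1
            o = [
                [((col == 0) & ~rej & known).sum(), ((col == 1) & ~rej).sum()],
                [((col == 0) & rej & known).sum(), ((col == 1) & rej).sum()],
            ]
            if np.asarray(o).sum() and min(np.sum(o, 0).min(), np.sum(o, 1).min()) > 0:
                best = max(best, lrt_statistic(o))
        maxima.append(best)
    return np.array(maxima)


class TestPermutationThreshold:
    def test_auto_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(5)
        status = rng.choice([0, 1], size=(6, 4))
        outcomes = ["rejected"] * 3 + ["accepted"] * 3
        gm, cohort = _cohort_with_status(status, outcomes)
        match = build_match_matrix(gm, cohort, "model2")
        perm = permutation_threshold(match, cohort, n_perm=100_000, alpha=0.05, seed=1)
        assert perm.exact
        ref = np.sort(exhaustive_max_distribution(status, 3))
        np.testing.assert_allclose(np.sort(perm.max_lrt_draws), ref, atol=1e-10)
        k = int(np.ceil(0.95 * ref.size))
        assert perm.threshold == pytest.approx(ref[k - 1])

    def test_sampled_mode_is_seed_reproducible(self):
        rng = np.random.default_rng(7)
        status = rng.choice([0, 1], size=(12, 25))
        outcomes = ["rejected"] * 6 + ["accepted"] * 6
        gm, cohort = _cohort_with_status(status, outcomes)
        match = build_match_matrix(gm, cohort, "model2")
        p1 = permutation_threshold(match, cohort, n_perm=500, alpha=0.05, seed=42)
        p2 = permutation_threshold(match, cohort, n_perm=500, alpha=0.05, seed=42)
        assert not p1.exact
        np.testing.assert_array_equal(p1.max_lrt_draws, p2.max_lrt_draws)
        assert p1.threshold == p2.threshold

    def test_quantile_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        status = rng.choice([0, 1], size=(10, 15))
        gm, cohort = _cohort_with_status(status, ["rejected"] * 5 + ["accepted"] * 5)
        match = build_match_matrix(gm, cohort, "model2")
        perm = permutation_threshold(match, cohort, n_perm=400, seed=9)
        assert perm.quantile(0.05) >= perm.quantile(0.10)

    def test_identical_outcomes_everywhere_give_zero_threshold(self):
        # every locus untestable -> trivial null distribution
        gm, cohort = _cohort_with_status([[0], [0], [0], [0]], ["rejected", "accepted"] * 2)
        match = build_match_matrix(gm, cohort, "model2")
        perm = permutation_threshold(match, cohort, n_perm=50, seed=0)
        assert perm.threshold == 0.0


class TestCallSignificant:
    def _perm(self, threshold, model="model2"):
        return PermutationResult(model, 100, 0.05, threshold, np.array([threshold]), 0)

    def test_strict_inequality_at_threshold(self):
        gm, cohort = _cohort_with_status(
            np.array([[1]] * 10 + [[0]] * 10), ["rejected"] * 10 + ["accepted"] * 10
        )
        res = scan(build_match_matrix(gm, cohort, "model2"))
        out = call_significant(res, self._perm(16.9))
        assert out["genomewide_significant"].iloc[0]  # 27.73 > 16.9
        out2 = call_significant(res, self._perm(res["lrt"].iloc[0]))
        assert not out2["genomewide_significant"].iloc[0]

    def test_model_mismatch_rejected(self):
        gm, cohort = _cohort_with_status([[1], [0]], ["rejected", "accepted"])
        res = scan(build_match_matrix(gm, cohort, "model2"))
        with pytest.raises(ValueError):
            call_significant(res, self._perm(1.0, model="model1"))

    def test_empty_results_pass_through(self):
        import pandas as pd

        empty = pd.DataFrame({"model": [], "lrt": [], "testable": []})
        out = call_significant(empty, self._perm(1.0))
        assert len(out) == 0


class TestManhattanExport:
    def test_ordering_and_unknowns_last(self):
        import pandas as pd

        res = pd.DataFrame(
            {
                "locus_id": ["a", "b", "c", "d", "e"],
                "chromosome": ["2", "1", "0", "1", "Y"],
                "position_bp": [5, 100, 0, 0, 3],
                "lrt": [1.0, 2.0, 3.0, 4.0, 5.0],
                "direction": ["none"] * 5,
            }
        )
        out = manhattan_table(res)
        assert list(out["locus_id"]) == ["b", "d", "a", "c"]  # chr1 pos, chr1 unknown, chr2, chr0


def test_null_calibration_band_and_chi2_proximity(rng):
    # 2000 independent null loci at 20 pairs (10 rejected / 10 accepted):
    # the pointwise 5% exceedance sits in the small-sample discreteness band,
    # and the statistic's CDF tracks chi-squared(1)
    n_loci = 2000
    maf = 0.5 * rng.beta(3, 3.25, n_loci)
    freqs = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]).T  # loci x 3
    donor = (rng.random((20, n_loci))[..., None] < freqs.cumsum(1)[None]).argmax(2)
    recip = (rng.random((20, n_loci))[..., None] < freqs.cumsum(1)[None]).argmax(2)
    status = (donor != recip).astype(int)  # model-2 coding, independent of outcome
    gm, cohort = _cohort_with_status(status, ["rejected"] * 10 + ["accepted"] * 10)
    res = scan(build_match_matrix(gm, cohort, "model2"))
    frac = (res["lrt"] > 3.841).mean()
    assert 0.01 <= frac <= 0.07
    # Kolmogorov distance to chi2(1): reported loose, not asserted tight
    grid = np.linspace(0, 12, 200)
    ecdf = (res["lrt"].to_numpy()[:, None] <= grid).mean(axis=0)
    kd = np.abs(ecdf - stats.chi2.cdf(grid, 1)).max()
    assert kd < 0.25
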