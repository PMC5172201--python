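import itertools
import math

import numpy as np
import pandas as pd
import pytest

from comorbinet.comorbidity_stats import (
    CooccurrenceCounts,
    UndefinedStatisticError,
    category_correlations,
    category_summaries,
    cooccurrence,
    pearson,
    permutation_pvalue,
    phi_correlation,
    relative_risk,
)
from comorbinet.network_io import PatientRecords


def records_from(diags: dict[str, set[str]]) -> PatientRecords:
    return PatientRecords({p: frozenset(d) for p, d in diags.items()})


def brute_force_counts(records: PatientRecords, di: str, dj: str) -> CooccurrenceCounts:
    """Independent oracle: explicit per-patient set intersection."""
    c = i_i = i_j = 0
    for diag in records.diagnoses.values():
        has_i, has_j = di in diag, dj in diag
        c += has_i and has_j
        i_i += has_i
        i_j += has_j
    return CooccurrenceCounts(di, dj, c, i_i, i_j, records.n_patients)


class TestCooccurrence:
    def test_hand_counts(self):
        rec = records_from({"p1": {"d1", "d2"}, "p2": {"d1"}})
        row = cooccurrence(rec).iloc[0]
        assert (row["c_ij"], row["i_i"], row["i_j"], row["n"]) == (1, 2, 1, 2)

    def test_all_patients_share_both(self):
        rec = records_from({f"p{i}": {"d1", "d2"} for i in range(5)})
        row = cooccurrence(rec).iloc[0]
        assert row["c_ij"] == row["i_i"] == row["i_j"] == row["n"] == 5

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(8)
        diseases = [f"d{k}" for k in range(6)]
        rec = records_from(
            {
                f"p{i:03d}": {d for d in diseases if rng.random() < 0.3}
                for i in range(100)
            }
        )
        table = cooccurrence(rec, diseases=diseases).set_index(
            ["disease_i", "disease_j"]
        )
        for di, dj in itertools.combinations(diseases, 2):
            oracle = brute_force_counts(rec, di, dj)
            row = table.loc[(di, dj)]
            assert row["c_ij"] == oracle.c_ij
            assert row["i_i"] == oracle.i_i
            assert row["i_j"] == oracle.i_j

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            cooccurrence(records_from({}))


class TestRelativeRisk:
    def test_independence_gives_one(self):
        # C = I_i * I_j / N exactly
        assert relative_risk(CooccurrenceCounts("a", "b", 2, 4, 5, 10)) == 1.0

    def test_direct_arithmetic(self):
        c = CooccurrenceCounts("a", "b", 10, 100, 200, 10_000)
        assert relative_risk(c) == pytest.approx(5.0)

    def test_zero_cooccurrence_gives_zero(self):
        assert relative_risk(CooccurrenceCounts("a", "b", 0, 3, 3, 10)) == 0.0

    def test_absent_disease_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            relative_risk(CooccurrenceCounts("a", "b", 0, 0, 3, 10))


class TestPhi:
    def test_independence_gives_zero(self):
        assert phi_correlation(CooccurrenceCounts("a", "b", 2, 4, 5, 10)) == 0.0

    def test_perfect_cooccurrence_gives_one(self):
        assert phi_correlation(CooccurrenceCounts("a", "b", 3, 3, 3, 10)) == 1.0

    def test_closed_form_and_indicator_vector_oracle(self):
        c = CooccurrenceCounts("a", "b", 10, 100, 200, 10_000)
        expected = (10 * 10_000 - 100 * 200) / math.sqrt(
            100 * 200 * 9_900 * 9_800
        )
        assert phi_correlation(c) == pytest.approx(expected, abs=1e-15)
        # oracle: Pearson correlation of the explicit binary indicators
        x = np.zeros(10_000)
        y = np.zeros(10_000)
        x[:100] = 1  # first 10 patients have both
        y[:10] = 1
        y[100:290] = 1
        assert phi_correlation(c) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_degenerate_marginals_undefined(self):
        # disease present in every patient: indicator has zero variance
        with pytest.raises(UndefinedStatisticError):
            phi_correlation(CooccurrenceCounts("a", "b", 3, 5, 3, 5))


class TestPearson:
    def test_examples(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1, 2, 3], [5, 5, 5])
        with pytest.raises(UndefinedStatisticError):
            pearson([1, 2], [3, 4])


class TestPermutationPvalue:
    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = permutation_pvalue(x, y, n_perm=5000, seed=123)
        b = permutation_pvalue(x, y, n_perm=5000, seed=123)
        assert a.p_value == b.p_value and a.pcc == b.pcc

    def test_identical_vectors_small_p(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        report = permutation_pvalue(x, x, n_perm=10_000, seed=0)
        assert report.p_value < 0.01

    def test_perfectly_anticorrelated_p_near_one(self):
        x = np.arange(25.0)
        report = permutation_pvalue(x, -x, n_perm=4000, seed=0)
        assert report.p_value > 0.95

    def test_min_resolvable_p_reported(self):
        x = np.arange(10.0)
        report = permutation_pvalue(x, x**2, n_perm=1000, seed=0)
        assert report.min_p == 1e-3


def _toy_tables():
    pairs = pd.DataFrame(
        dict(
            disease_a=["d1", "d1", "d1", "d2", "d2", "d3"],
            disease_b=["d2", "d3", "d4", "d3", "d4", "d4"],
            xd=[0.5, 0.4, 0.3, -0.1, 0.2, -0.2],
            ng=[2, 0, 0, 1, 0, 0],
            scorable=[True] * 6,
        )
    )
    pairs["xd_ab"] = pairs["xd"]
    pairs["xd_ba"] = pairs["xd"]
    from comorbinet.xd_scoring import classify_pair

    pairs["category"] = [
        classify_pair(x, n) for x, n in zip(pairs["xd"], pairs["ng"])
    ]
    cooc = pd.DataFrame(
        dict(
            disease_i=pairs["disease_a"],
            disease_j=pairs["disease_b"],
            c_ij=[5, 4, 3, 2, 2, 1],
            i_i=[10] * 6,
            i_j=[10] * 6,
            n=[100] * 6,
        )
    )
    cooc["rr"] = cooc["c_ij"] * cooc["n"] / (cooc["i_i"] * cooc["i_j"])
    cooc["phi"] = 0.1 * cooc["c_ij"]
    return pairs, cooc


class TestCategoryTables:
    def test_constant_ng_cell_is_na(self):
        pairs, cooc = _toy_tables()
        corr = category_correlations(pairs, cooc, n_perm=100, seed=0)
        cell = corr[
            (corr["filter"] == "+XDnot+NG")
            & (corr["x_var"] == "NG")
            & (corr["y_var"] == "RR")
        ].iloc[0]
        assert np.isnan(cell["pcc"])
        assert cell["note"] == "constant variable"

    def test_small_group_is_na_with_reason(self):
        pairs, cooc = _toy_tables()
        corr = category_correlations(pairs, cooc, n_perm=100, seed=0)
        cell = corr[
            (corr["filter"] == "+XDand+NG") & (corr["x_var"] == "XD")
        ].iloc[0]
        assert np.isnan(cell["pcc"])
        assert cell["note"] == "fewer than 3 pairs"

    def test_all_group_correlation_computed(self):
        pairs, cooc = _toy_tables()
        corr = category_correlations(pairs, cooc, n_perm=500, seed=1)
        cell = corr[
            (corr["filter"] == "ALL")
            & (corr["x_var"] == "XD")
            & (corr["y_var"] == "RR")
        ].iloc[0]
        expected = pearson(pairs["xd"], cooc["rr"])
        assert cell["pcc"] == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= cell["p_value"] <= 1.0

    def test_summary_means_and_single_pair_se(self):
        pairs, cooc = _toy_tables()
        summ = category_summaries(pairs, cooc).set_index("filter")
        merged = pairs.merge(
            cooc, left_on=["disease_a", "disease_b"],
            right_on=["disease_i", "disease_j"],
        )
        both = merged[merged["category"] == "+XDand+NG"]
        assert summ.loc["+XDand+NG", "mean_rr"] == pytest.approx(both["rr"].mean())
        assert summ.loc["+XDand+NG", "n_pairs"] == 1
        assert np.isnan(summ.loc["+XDand+NG", "se_rr"])  # single pair: no SE

    def test_hand_built_group_means(self):
        # RR groups {1, 3} and {2} have equal means
        assert np.mean([1.0, 3.0]) == np.mean([2.0]) == 2.0


def test_null_fixture_rr_balanced_around_one():
    """With independent diagnoses, pairs land above and below RR=1 evenly."""
    rng = np.random.default_rng(21)
    diseases = [f"d{k}" for k in range(14)]
    rec = records_from(
        {
            f"p{i:05d}": {d for d in diseases if rng.random() < 0.1}
            for i in range(4000)
        }
    )
    rr = cooccurrence(rec)["rr"].dropna()
    above = int((rr > 1).sum())
    below = int((rr < 1).sum())
    n = above + below
    # binomial error around an even split
    assert abs(above - n / 2) < 3 * math.sqrt(n * 0.25)
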