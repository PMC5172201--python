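import numpy as np
import pytest

from comorbinet import GeneNetwork, bin_scores, rwr, xd_directed, xd_score
from comorbinet.network_io import DiseaseGeneMap
from comorbinet.propagation import PropagationResult
from comorbinet.xd_scoring import (
    CATEGORY_BOTH,
    CATEGORY_NEITHER,
    CATEGORY_NG_ONLY,
    CATEGORY_UNSCORABLE,
    UnscorablePairError,
    classify_pair,
    count_shared_genes,
    score_all_pairs,
)

from conftest import random_network


def make_result(scores):
    genes = tuple(f"g{i:03d}" for i in range(len(scores)))
    return PropagationResult(
        genes=genes,
        scores=np.asarray(scores, dtype=float),
        seed_genes=frozenset(),
        restart_p=0.9,
        iterations=1,
        converged=True,
    )


def uniform_result(n=100):
    """n distinct scores spreading exactly 10 genes into each of 10 bins."""
    return make_result(np.linspace(1.0, 0.0, n))


class TestBinScores:
    def test_equal_bin_widths(self):
        prof = bin_scores(uniform_result(), {"g000"}, n_bins=10)
        widths = -np.diff(prof.bin_edges)
        np.testing.assert_allclose(widths, 0.1, atol=1e-12)

    def test_bins_partition_all_genes_and_fractions_sum_to_one(self):
        prof = bin_scores(uniform_result(), {"g000", "g050"}, n_bins=10)
        assert prof.p_all.sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.p_target.sum() == pytest.approx(1.0, abs=1e-12)
        assert sum(len(b) for b in prof.genes_per_bin) == 100

    def test_target_equal_to_background_gives_identical_fractions(self):
        res = uniform_result()
        prof = bin_scores(res, set(res.genes), n_bins=10)
        np.testing.assert_array_equal(prof.p_all, prof.p_target)

    def test_top_scoring_target_concentrates_in_first_bin(self):
        # brute-force oracle: explicit score list, explicit bin rule
        res = uniform_result()
        target = {f"g{i:03d}" for i in range(10)}  # the 10 highest scores
        prof = bin_scores(res, target, n_bins=10)
        assert prof.p_target[0] == 1.0
        assert prof.p_target[1:].sum() == 0.0

    def test_extreme_scores_land_in_first_and_last_bin(self):
        res = uniform_result()
        prof = bin_scores(res, {"g000"}, n_bins=10)
        assert prof.bin_of[0] == 1  # maximum score
        assert prof.bin_of[-1] == 10  # minimum score

    def test_degenerate_all_equal_scores_flagged(self):
        prof = bin_scores(make_result([0.5] * 8), {"g001"}, n_bins=10)
        assert prof.degenerate and prof.n_bins == 1
        with pytest.warns(UserWarning, match="degenerate"):
            assert xd_directed(prof) == 0.0

    def test_empty_target_intersection_errors(self):
        with pytest.raises(UnscorablePairError):
            bin_scores(uniform_result(), {"absent"}, n_bins=10)


class TestXDDirected:
    def test_matched_background_gives_exact_zero(self):
        res = uniform_result()
        assert xd_directed(bin_scores(res, set(res.genes))) == 0.0

    def test_all_target_in_bin_one_matches_harmonic_form(self):
        # target occupies bin 1 entirely, background uniform:
        # XD = (1 - 0.1)/1 - sum_{i=2..10} 0.1/i = 0.9 - 0.1 (H_10 - 1)
        res = uniform_result()
        target = {f"g{i:03d}" for i in range(10)}
        expected = 0.9 - 0.1 * (sum(1 / i for i in range(1, 11)) - 1)
        assert xd_directed(bin_scores(res, target)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_all_target_in_bin_ten_is_negative(self):
        # XD = -0.1 H_9 + (1 - 0.1)/10; below-average network association
        res = uniform_result()
        target = {f"g{i:03d}" for i in range(90, 100)}
        expected = -0.1 * sum(1 / i for i in range(1, 10)) + 0.09
        value = xd_directed(bin_scores(res, target))
        assert value == pytest.approx(expected, abs=1e-6)
        assert value < 0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(60)
        target = {f"g{i:03d}" for i in rng.choice(60, 12, replace=False)}
        base = xd_directed(bin_scores(make_result(scores), target))
        scaled = xd_directed(bin_scores(make_result(3.5 * scores + 2.0), target))
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_adding_bin1_gene_never_decreases_and_bin10_never_increases(self):
        res = uniform_result()
        target = {f"g{i:03d}" for i in (5, 30, 77)}
        base = xd_directed(bin_scores(res, target))
        up = xd_directed(bin_scores(res, target | {"g000"}))
        down = xd_directed(bin_scores(res, target | {"g099"}))
        assert up >= base
        assert down <= base

    def test_alternative_weighting_pluggable(self):
        res = uniform_result()
        target = {f"g{i:03d}" for i in range(10)}
        prof = bin_scores(res, target)
        geo = xd_directed(prof, weights="geometric")
        expected = (1 - 0.1) * 1.0 - 0.1 * sum(0.5**i for i in range(1, 10))
        assert geo == pytest.approx(expected, abs=1e-12)


class TestPairScoring:
    def test_identical_gene_sets_give_symmetric_directed_scores(self, two_cliques):
        net, a, _ = two_cliques
        ps = xd_score(net, a, a)
        assert ps.xd_ab == ps.xd_ba == ps.xd

    def test_symmetry_of_final_score(self, two_cliques):
        net, a, b = two_cliques
        assert xd_score(net, a, b).xd == xd_score(net, b, a).xd

    def test_disjoint_target_clique_scores_negative(self, two_cliques):
        # with restart 0.9 a non-seed gene's score is bounded near
        # (1-p) * M, so even an adjacent disjoint clique sits in the bottom
        # equal-width bin: below-average association, negative XD
        net, a, b = two_cliques
        assert xd_score(net, a, b).xd < 0

    def test_same_module_overlapping_sets_score_positive(self):
        # two gene sets drawn from one dense module (4 genes shared) against
        # a sparse background: closer-than-average association, XD > 0
        edges = {}
        clique = [f"c{i:02d}" for i in range(20)]
        for i in range(20):
            for j in range(i + 1, 20):
                edges[(clique[i], clique[j])] = 1.0
        ring = [f"r{i:02d}" for i in range(80)]
        for i in range(80):
            edges[(ring[i], ring[(i + 1) % 80])] = 1.0
        edges[("c00", "r00")] = 1.0
        net = GeneNetwork.from_edges(edges)
        ps = xd_score(net, set(clique[:12]), set(clique[8:]))
        assert ps.xd > 0
        assert ps.category == CATEGORY_BOTH

    def test_disjoint_components_score_negative(self):
        a = {f"a{i}": i for i in range(8)}
        b = {f"b{i}": i for i in range(8)}
        edges = {}
        for grp in (list(a), list(b)):
            for i in range(len(grp)):
                for j in range(i + 1, len(grp)):
                    edges[(grp[i], grp[j])] = 1.0
        net = GeneNetwork.from_edges(edges)
        ps = xd_score(net, set(a), set(b))
        assert ps.xd_ab < 0 and ps.xd_ba < 0

    def test_unscorable_pair_is_flagged_not_zero(self, path_graph):
        ps = xd_score(path_graph, {"A", "B"}, {"zz1", "zz2"})
        assert not ps.scorable
        assert ps.xd is None
        assert ps.category == CATEGORY_UNSCORABLE

    def test_mean_xd_over_random_targets_near_zero(self):
        # with targets drawn uniformly, concentration above and below average
        # cancels: the empirical mean is within 3 SE of 0
        rng = np.random.default_rng(12)
        net = random_network(rng, 80, 0.08)
        prop = rwr(net, set(rng.choice(net.genes, 6, replace=False)), tol=1e-12)
        values = []
        for _ in range(200):
            target = set(rng.choice(net.genes, 10, replace=False))
            values.append(xd_directed(bin_scores(prop, target)))
        values = np.asarray(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean()) < 3 * se


class TestClassification:
    @pytest.mark.parametrize(
        "xd,ng,expected",
        [
            (0.5, 2, CATEGORY_BOTH),
            (-0.1, 0, CATEGORY_NEITHER),
            (0.0, 1, CATEGORY_NG_ONLY),  # zero XD is not positive
            (0.2, 0, "+XDnot+NG"),
            (None, 3, CATEGORY_UNSCORABLE),
        ],
    )
    def test_labels(self, xd, ng, expected):
        assert classify_pair(xd, ng) == expected

    def test_count_shared_genes(self):
        assert count_shared_genes({"g1"} | {f"x{i}" for i in range(6)},
                                  {"g1"} | {f"x{i}" for i in range(6)}) == 7
        assert count_shared_genes({"a"}, {"b"}) == 0
        assert count_shared_genes({"g1", "g2", "g3"}, {"g3", "g4"}) == 1


class TestScoreAllPairs:
    def test_pair_count_and_ordering(self, two_cliques):
        net, a, b = two_cliques
        dg = DiseaseGeneMap(
            {"d1": frozenset(a), "d2": frozenset(b), "d3": frozenset(list(a)[:3])}
        )
        df = score_all_pairs(net, dg)
        assert len(df) == 3
        assert list(df["disease_a"]) == ["d1", "d1", "d2"]

    def test_duplicated_disease_matches_self_symmetric_score(self, two_cliques):
        net, a, _ = two_cliques
        dg = DiseaseGeneMap({"d1": frozenset(a), "d1copy": frozenset(a)})
        row = score_all_pairs(net, dg).iloc[0]
        self_score = xd_score(net, a, a)
        assert row["xd"] == pytest.approx(self_score.xd, abs=1e-12)
        assert row["ng"] == len(a)

    def test_matches_pairwise_xd_score(self, two_cliques):
        net, a, b = two_cliques
        dg = DiseaseGeneMap({"d1": frozenset(a), "d2": frozenset(b)})
        row = score_all_pairs(net, dg).iloc[0]
        direct = xd_score(net, a, b)
        assert row["xd_ab"] == pytest.approx(direct.xd_ab, abs=1e-12)
        assert row["xd_ba"] == pytest.approx(direct.xd_ba, abs=1e-12)

    def test_unscorable_disease_flagged_in_table(self, path_graph):
        dg = DiseaseGeneMap(
            {"d1": frozenset({"A", "B"}), "d2": frozenset({"zz"})}
        )
        df = score_all_pairs(path_graph, dg)
        assert not df.iloc[0]["scorable"]
        assert np.isnan(df.iloc[0]["xd"])
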