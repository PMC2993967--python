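"""Transforms, Bray-Curtis, UPGMA, SIMPROF, SIMPER, ANOSIM and NMDS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from omicdiv.compare import (
    aggregate_by_category,
    anosim,
    bray_curtis,
    kruskal_stress1,
    nmds,
    rare_taxon_filter,
    simper,
    simprof,
    simprof_test,
    transform_counts,
    upgma,
)


class TestTransformsAndFilters:
    def test_sqrt_and_presence_absence(self):
        m = pd.DataFrame({"s": [4, 0, 7]})
        assert transform_counts(m, "sqrt")["s"].tolist() == [2.0, 0.0, pytest.approx(np.sqrt(7))]
        assert transform_counts(m, "presence_absence")["s"].tolist() == [1.0, 0.0, 1.0]

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            transform_counts(pd.DataFrame({"s": [1]}), "log")

    def test_rare_filter_boundary(self):
        m = pd.DataFrame({"s1": [50, 60], "s2": [49, 40]}, index=["f99", "f100"])
        out = rare_taxon_filter(m, min_total=100)
        assert list(out.index) == ["f100"]

    def test_rare_filter_identity_and_empty(self):
        m = pd.DataFrame({"s1": [100, 200]})
        assert rare_taxon_filter(m, 100).equals(m)
        assert rare_taxon_filter(m, 1000).empty

    def test_aggregate_preserves_column_sums(self):
        m = pd.DataFrame({"s1": [3, 1, 2], "s2": [4, 0, 5]}, index=["fa", "fb", "fc"])
        out = aggregate_by_category(m, {"fa": "cat1", "fb": "cat1"})
        assert out.loc["cat1"].tolist() == [4, 4]
        assert out.loc["unannotated"].tolist() == [2, 5]
        assert (out.sum(axis=0) == m.sum(axis=0)).all()

    def test_aggregate_warns_on_unknown_features(self):
        m = pd.DataFrame({"s1": [1]}, index=["fa"])
        with pytest.warns(UserWarning, match="unknown"):
            aggregate_by_category(m, {"ghost": "cat"})


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        m = pd.DataFrame({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0], "c": [0, 0, 3, 1]})
        sim = bray_curtis(m)
        sim.validate()
        assert sim.data.loc["a", "b"] == pytest.approx(100.0)
        assert sim.data.loc["a", "c"] == pytest.approx(0.0)

    def test_worked_example_50(self):
        m = pd.DataFrame({"a": [1, 1, 0], "b": [0, 1, 1]})
        assert bray_curtis(m).data.loc["a", "b"] == pytest.approx(50.0)

    def test_all_zero_sample_named_in_error(self):
        m = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(m)

    def test_feature_order_invariance(self, small_counts):
        s1 = bray_curtis(small_counts).data
        s2 = bray_curtis(small_counts.iloc[::-1]).data
        pd.testing.assert_frame_equal(s1, s2)


class TestUpgma:
    def test_two_samples_single_merge(self):
        m = pd.DataFrame({"a": [3.0, 1.0], "b": [1.0, 3.0]})
        sim = bray_curtis(m)
        tree = upgma(sim)
        assert tree.height == pytest.approx(100.0 - sim.data.loc["a", "b"])
        assert sorted(tree.leaves) == ["a", "b"]

    def test_hand_agglomeration(self):
        d = pd.DataFrame(
            100.0 - np.array([[0, 10, 40], [10, 0, 40], [40, 40, 0]]),
            index=list("ABC"),
            columns=list("ABC"),
        )
        from omicdiv.compare import SimilarityMatrix

        tree = upgma(SimilarityMatrix(data=d))
        assert tree.height == pytest.approx(40.0)
        inner = [n for n in tree.nodes() if n.children and n is not tree]
        assert len(inner) == 1
        assert sorted(inner[0].leaves) == ["A", "B"]
        assert inner[0].height == pytest.approx(10.0)

    def test_heights_non_decreasing_rootward(self, small_counts, rng):
        tree = upgma(bray_curtis(transform_counts(small_counts, "sqrt")))

        def check(node):
            for child in node.children or ():
                assert child.height <= node.height + 1e-9
                check(child)

        check(tree)

    def test_newick_roundtrip_parses(self, small_counts):
        newick = upgma(bray_curtis(small_counts)).to_newick()
        assert newick.endswith(";")
        for s in small_counts.columns:
            assert s in newick


class TestSimprof:
    def test_two_sample_nodes_untestable(self, small_counts):
        tree = simprof(transform_counts(small_counts, "sqrt"), seed=1)
        for node in tree.nodes():
            if node.children and len(node.leaves) == 2:
                assert not node.tested

    def test_structured_root_significant(self, small_counts):
        tree = simprof(transform_counts(small_counts, "sqrt"), seed=1)
        assert tree.tested and tree.significant

    def test_constant_matrix_not_significant(self):
        m = pd.DataFrame(np.full((6, 5), 3.0), columns=[f"s{i}" for i in range(5)])
        tree = simprof(m, seed=0)
        assert not any(n.significant for n in tree.nodes())

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            simprof_test(np.ones((4, 2)))

    def test_simprof_test_deterministic_given_rng(self, small_counts):
        X = transform_counts(small_counts, "sqrt").values
        r1 = simprof_test(X, rng=np.random.default_rng(9))
        r2 = simprof_test(X, rng=np.random.default_rng(9))
        assert r1 == r2


class TestSimper:
    GROUPS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_hand_computed_two_feature_example(self):
        # every between-group pair has column sum 14, so each pair's per-feature
        # contribution is 100*|y_j - y_k|/14; averaging the four pairs by hand:
        # f1: (4+6+2+4)/4 * 100/14 = 28.5714..., f2 identical by construction.
        m = pd.DataFrame(
            {"a1": [6, 1], "a2": [4, 3], "b1": [2, 5], "b2": [0, 7]},
            index=["f1", "f2"],
        )
        res = simper(m, self.GROUPS)[("A", "B")]
        expected = 100.0 / 14.0 * 4.0
        contribs = res.table.set_index("feature")["contribution"]
        assert contribs["f1"] == pytest.approx(expected)
        assert contribs["f2"] == pytest.approx(expected)
        assert res.overall_dissimilarity == pytest.approx(2 * expected)
        assert res.table["contrib_pct"].tolist() == pytest.approx([50.0, 50.0])

    def test_single_differing_feature_contributes_everything(self):
        m = pd.DataFrame(
            {"a1": [5, 2], "a2": [5, 2], "b1": [1, 2], "b2": [1, 2]},
            index=["hot", "flat"],
        )
        table = simper(m, self.GROUPS)[("A", "B")].table.set_index("feature")
        assert table.loc["hot", "contrib_pct"] == pytest.approx(100.0)
        assert table.loc["flat", "contrib_pct"] == pytest.approx(0.0)

    def test_contributions_sum_to_100_and_match_bc(self, small_counts, rng):
        m = pd.DataFrame(
            rng.integers(0, 30, size=(12, 6)).astype(float),
            columns=list("abcdef"),
        )
        m.iloc[0] += 1  # guard against an all-zero sample
        groups = {s: ("G1" if s in "abc" else "G2") for s in m.columns}
        res = simper(m, groups)[("G1", "G2")]
        assert res.table["contrib_pct"].sum() == pytest.approx(100.0, abs=0.01)
        assert np.all(np.diff(res.table["cum_pct"]) >= -1e-9)
        # overall equals mean pairwise BC dissimilarity between the groups
        sim = bray_curtis(m)
        pairs = [(i, j) for i in "abc" for j in "def"]
        mean_d = np.mean([100.0 - sim.data.loc[i, j] for i, j in pairs])
        assert res.overall_dissimilarity == pytest.approx(mean_d)

    def test_single_group_errors(self):
        m = pd.DataFrame({"a1": [1], "a2": [2]})
        with pytest.raises(ValueError):
            simper(m, {"a1": "A", "a2": "A"})


class TestAnosim:
    def test_perfect_separation_r_is_one(self, small_counts):
        sim = bray_curtis(small_counts)
        res = anosim(sim, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, n_perms=None)
        assert res.r == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self, rng):
        m = pd.DataFrame(
            rng.integers(1, 40, size=(10, 6)).astype(float), columns=list("abcdef")
        )
        sim = bray_curtis(m)
        rs = []
        for i in range(500):
            lab = np.random.default_rng(i).permutation(["g1"] * 3 + ["g2"] * 3)
            rs.append(anosim(sim, dict(zip("abcdef", lab)), n_perms=49, seed=i).r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se

    def test_sampled_p_matches_exhaustive(self, rng):
        m = pd.DataFrame(rng.integers(0, 20, size=(8, 6)) + 1.0, columns=list("abcdef"))
        sim = bray_curtis(m)
        groups = {"a": "x", "b": "x", "c": "x", "d": "y", "e": "y", "f": "y"}
        exact = anosim(sim, groups, n_perms=None)
        sampled = anosim(sim, groups, n_perms=20000, seed=0)
        assert exact.r == pytest.approx(sampled.r)
        # Monte-Carlo error: 4 s.e. of a binomial proportion at 20000 draws
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
        assert abs(sampled.p_value - exact.p_value) < 4 * se + 1e-4

    def test_matches_skbio_oracle(self, small_counts):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        m = small_counts.astype(float)
        sim = bray_curtis(m)
        dm = skbio.DistanceMatrix(
            (100.0 - sim.data.values) / 100.0, ids=list(m.columns)
        )
        ours = anosim(sim, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, n_perms=999)
        theirs = sk_anosim(dm, grouping=["A", "A", "B", "B"], permutations=999)
        assert ours.r == pytest.approx(float(theirs["test statistic"]))

    def test_single_group_errors(self, small_counts):
        with pytest.raises(ValueError):
            anosim(bray_curtis(small_counts), {c: "same" for c in small_counts})


class TestNmds:
    @staticmethod
    def _euclidean_sim(points):
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(points))
        d = 100.0 * d / d.max()
        ids = [f"p{i}" for i in range(len(points))]
        from omicdiv.compare import SimilarityMatrix

        return SimilarityMatrix(
            data=pd.DataFrame(100.0 - d, index=ids, columns=ids)
        )

    def test_perfect_2d_embedding(self, rng):
        sim = self._euclidean_sim(rng.normal(size=(7, 2)))
        res = nmds(sim, k=2, restarts=4, seed=0)
        assert res.stress < 1e-4

    def test_collinear_configuration(self):
        pts = np.array([[0.0, 0], [1, 0], [2.5, 0], [4, 0], [7, 0]])
        res = nmds(self._euclidean_sim(pts), k=2, restarts=4, seed=0)
        assert res.stress < 1e-4

    def test_stress_non_increasing_in_k(self, rng):
        m = pd.DataFrame(
            rng.integers(1, 50, size=(20, 6)).astype(float), columns=list("abcdef")
        )
        sim = bray_curtis(m)
        s2 = nmds(sim, k=2, restarts=8, seed=1).stress
        s3 = nmds(sim, k=3, restarts=8, seed=1).stress
        assert s3 <= s2 + 1e-9

    def test_coords_centered_and_k_bound(self, small_counts):
        sim = bray_curtis(small_counts.astype(float))
        res = nmds(sim, k=2, restarts=3, seed=0)
        assert np.allclose(res.coords.mean(axis=0), 0.0, atol=1e-9)
        with pytest.raises(ValueError):
            nmds(sim, k=4)

    def test_stress1_zero_on_exact_configuration(self, rng):
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist

        assert kruskal_stress1(pdist(pts), pts) < 1e-12
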