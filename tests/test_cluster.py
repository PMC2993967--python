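"""Alignment identity, greedy family clustering, SLP preclustering and OTUs."""

import numpy as np
import pytest

from omicdiv.cluster import (
    ClusterParams,
    align_identity,
    average_linkage_otus,
    build_family_matrix,
    greedy_cluster,
    pairwise_nt_distance,
    slp_precluster,
    two_step_cluster,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA), size=n))


def substitute(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = AA[(AA.index(out[p]) + 7) % len(AA)]
    return "".join(out)


BASE100 = protein(100, seed=42)


class TestAlignIdentity:
    def test_identical(self):
        assert align_identity(BASE100, BASE100) == (1.0, 1.0)

    def test_exact_prefix_85_of_100(self):
        ident, cov = align_identity(BASE100, BASE100[:85])
        assert ident == pytest.approx(1.0)
        assert cov == pytest.approx(0.85)

    def test_five_substitutions(self):
        other = substitute(BASE100, [3, 20, 47, 68, 91])
        ident, cov = align_identity(BASE100, other)
        assert ident == pytest.approx(0.95)
        assert cov == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = BASE100, substitute(BASE100, [10, 30])[:80]
        assert align_identity(a, b) == align_identity(b, a)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            align_identity("", BASE100)


def oracle_partition(items, identity, min_coverage):
    """Independent first-fit oracle over precomputed all-pairs alignments."""
    seqs = {sid: seq for sid, seq, *_ in items}
    pair = {}
    ids = list(seqs)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            pair[(a, b)] = pair[(b, a)] = align_identity(seqs[a], seqs[b])
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), seqs[sid], sid))
    clusters = []  # [rep id, member ids]
    for sid in order:
        for c in clusters:
            ident, cov = pair[(c[0], sid)]
            if ident >= identity and cov >= min_coverage:
                c[1].append(sid)
                break
        else:
            clusters.append([sid, [sid]])
    return sorted(frozenset(c[1]) for c in clusters)


def random_instance(seed, n_max=25):
    """Sequences mutated from a few ancestors, so real cluster structure exists."""
    rng = np.random.default_rng(seed)
    ancestors = [protein(int(rng.integers(45, 90)), seed=1000 * seed + k) for k in range(4)]
    items = []
    for i in range(int(rng.integers(5, n_max + 1))):
        anc = ancestors[int(rng.integers(len(ancestors)))]
        n_mut = int(rng.integers(0, max(2, len(anc) // 8)))
        pos = rng.choice(len(anc), size=n_mut, replace=False)
        seq = substitute(anc, pos)
        if rng.random() < 0.3:  # truncate to exercise the coverage rule
            seq = seq[: int(rng.integers(int(0.7 * len(seq)), len(seq) + 1))]
        items.append((f"s{i:03d}", seq, None))
    return items


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        items = [(f"x{i}", BASE100, None) for i in range(5)]
        cs = greedy_cluster(items, identity=0.95)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0]) == [f"x{i}" for i in range(5)]

    def test_coverage_rule_splits_79aa_prefix(self):
        items = [("long", BASE100, None), ("short", BASE100[:79], None)]
        cs = greedy_cluster(items, identity=0.95, min_coverage=0.80)
        assert len(cs.clusters) == 2
        # at 0.80 coverage an 80 aa prefix joins
        cs80 = greedy_cluster(
            [("long", BASE100, None), ("short", BASE100[:80], None)], 0.95, 0.80
        )
        assert len(cs80.clusters) == 1

    def test_representative_is_longest_member(self):
        items = [("long", BASE100, None), ("short", BASE100[:90], None)]
        cs = greedy_cluster(items, identity=0.95)
        assert cs.representatives[0] == "long"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 0.95)

    def test_order_independence(self):
        items = random_instance(seed=7)
        cs1 = greedy_cluster(items, 0.9)
        cs2 = greedy_cluster(list(reversed(items)), 0.9)
        assert sorted(map(frozenset, cs1.clusters.values())) == sorted(
            map(frozenset, cs2.clusters.values())
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_instances(self, seed):
        items = random_instance(seed)
        cs = greedy_cluster(items, 0.9, 0.80)
        assert sorted(map(frozenset, cs.clusters.values())) == oracle_partition(
            items, 0.9, 0.80
        )


class TestTwoStep:
    def test_all_identical(self):
        items = [(f"x{i}", BASE100, "a") for i in range(4)]
        level95, level60 = two_step_cluster(items)
        assert len(level95.clusters) == 1 and len(level60.clusters) == 1

    def test_two_groups_merge_at_60(self):
        g1 = BASE100
        g2 = substitute(BASE100, range(0, 90, 3))  # 30 substitutions: ~70% identity
        items = [
            ("a1", g1, "s"),
            ("a2", substitute(g1, [5, 50]), "s"),
            ("b1", g2, "s"),
            ("b2", substitute(g2, [6, 51]), "s"),
        ]
        level95, level60 = two_step_cluster(items)
        assert len(level95.clusters) == 2
        assert len(level60.clusters) == 1
        assert sorted(level60.clusters[0]) == ["a1", "a2", "b1", "b2"]

    def test_membership_conserved(self):
        items = random_instance(seed=3)
        level95, level60 = two_step_cluster(items)
        assert level95.n_members() == len(items)
        assert level60.n_members() == len(items)
        assert sorted(level60.membership()) == sorted(i[0] for i in items)


class TestFamilyMatrix:
    def _clusterset(self, clusters, provenance):
        from omicdiv.cluster import ClusterSet

        return ClusterSet(
            clusters=clusters,
            representatives={cid: members[0] for cid, members in clusters.items()},
            level=0.60,
            provenance=provenance,
        )

    def test_total_two_dropped_total_three_kept(self):
        cs = self._clusterset(
            {0: ["m1", "m2", "m3"], 1: ["m4", "m5"], 2: ["m6"]},
            {"m1": "A", "m2": "A", "m3": "B", "m4": "A", "m5": "B", "m6": "A"},
        )
        fam = build_family_matrix(cs)
        assert list(fam.index) == ["family_00000"]
        assert fam.loc["family_00000", "A"] == 2
        assert fam.loc["family_00000", "B"] == 1

    def test_column_sums_bounded_by_input(self):
        items = random_instance(seed=9)
        items = [(sid, seq, "sampleA" if i % 2 else "sampleB") for i, (sid, seq, _) in enumerate(items)]
        _, level60 = two_step_cluster(items)
        fam = build_family_matrix(level60)
        per_sample = {"sampleA": 0, "sampleB": 0}
        for _, _, s in items:
            per_sample[s] += 1
        for s in fam.columns:
            assert fam[s].sum() <= per_sample[s]


class TestNtDistance:
    NT = "".join(np.random.default_rng(1).choice(list("ACGT"), size=100))

    def test_identical_zero(self):
        d = pairwise_nt_distance([self.NT, self.NT])
        assert d[0, 1] == 0.0

    def test_one_substitution_in_100(self):
        other = list(self.NT)
        other[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[40]]
        d = pairwise_nt_distance([self.NT, "".join(other)])
        assert d[0, 1] == pytest.approx(0.01)

    def test_symmetric_zero_diagonal(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(4)]
        d = pairwise_nt_distance(seqs)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_nt_distance([self.NT, ""])


class TestSlpAndOtus:
    def test_close_pair_merged(self):
        d = np.array([[0.0, 0.01], [0.01, 0.0]])
        pre = slp_precluster(d, [10, 2])
        assert len(pre) == 1
        assert pre[0].abundance == 12 and pre[0].representative == 0

    def test_single_linkage_is_transitive(self):
        d = np.array(
            [[0.0, 0.02, 0.04], [0.02, 0.0, 0.02], [0.04, 0.02, 0.0]]
        )
        pre = slp_precluster(d, [5, 5, 5])
        assert len(pre) == 1 and pre[0].members == [0, 1, 2]

    def test_all_far_stay_singletons(self):
        d = np.full((3, 3), 0.05)
        np.fill_diagonal(d, 0.0)
        pre = slp_precluster(d, [1, 2, 3])
        assert [pc.members for pc in pre] == [[0], [1], [2]]

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            slp_precluster(np.zeros((3, 3)), [1, 2])

    def test_all_zero_distances_single_otu(self):
        labels = average_linkage_otus(np.zeros((4, 4)), [1, 1, 1, 1])
        for lbl in labels.values():
            assert len(np.unique(lbl)) == 1

    def test_two_groups_cut_pattern(self):
        # two tight pairs (within 0.01), between-group distance 0.08
        d = np.array(
            [
                [0.0, 0.01, 0.08, 0.08],
                [0.01, 0.0, 0.08, 0.08],
                [0.08, 0.08, 0.0, 0.01],
                [0.08, 0.08, 0.01, 0.0],
            ]
        )
        labels = average_linkage_otus(d, [1, 1, 1, 1], thresholds=(0.03, 0.06, 0.10))
        assert len(np.unique(labels[0.03])) == 2
        assert len(np.unique(labels[0.06])) == 2
        assert len(np.unique(labels[0.10])) == 1

    def test_otu_counts_monotone_in_threshold(self, rng):
        x = rng.random((8, 2))
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(x)) / 10
        labels = average_linkage_otus(d, rng.integers(1, 20, size=8), (0.03, 0.06, 0.10))
        counts = [len(np.unique(labels[t])) for t in (0.03, 0.06, 0.10)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_threshold_outside_unit_interval_errors(self):
        with pytest.raises(ValueError):
            average_linkage_otus(np.zeros((2, 2)), [1, 1], thresholds=(1.5,))

    def test_precluster_below_otu_threshold_enforced(self):
        from omicdiv.cluster import OtuParams

        with pytest.raises(ValueError):
            OtuParams(precluster_distance=0.05, otu_thresholds=(0.03,)).validate()
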