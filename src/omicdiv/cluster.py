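"""Greedy protein-family clustering, SLP preclustering and average-linkage OTUs.

Protein families are built CD-HIT-style: sequences sorted by decreasing length seed
clusters greedily, joining the first cluster whose representative they match at the
identity threshold over sufficient coverage of the representative; a second pass at a
lower identity groups representatives into families. Identity is measured against the
shorter sequence (CD-HIT's convention) from a semi-global alignment with free end gaps;
coverage is the aligned span on the longer sequence divided by its length.

OTUs are built from pairwise global-alignment distances: a single-linkage precluster
step at 2% absorbs likely sequencing variants into their abundant parents, then
abundance-weighted average-linkage agglomeration is cut at the requested thresholds
(3/6/10% by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from Bio import Align

from .orfs import Porf


# ---------------------------------------------------------------------------
# Alignment primitives
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -1.0
    a.end_gap_score = 0.0  # semi-global: terminal overhangs are free
    return a


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -1.0
    a.end_gap_score = 0.0
    return a


_PROT = _protein_aligner()
_NT = _nt_aligner()


def align_identity(a: str, b: str) -> Tuple[float, float]:
    """Semi-global identity and coverage between two amino-acid sequences.

    identity = identical aligned positions / length of the shorter sequence;
    coverage_of_longer = aligned span on the longer sequence / its length.
    Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    longer, shorter = (a, b) if len(a) >= len(b) else (b, a)
    aln = _PROT.align(longer, shorter)[0]
    counts = aln.counts()
    identity = counts.identities / len(shorter)
    blocks = aln.aligned[0]  # aligned blocks on the longer (target) sequence
    if len(blocks) == 0:
        return 0.0, 0.0
    span = int(blocks[-1][1] - blocks[0][0])
    return identity, span / len(longer)


def pairwise_nt_distance(seqs: Sequence[str]) -> np.ndarray:
    """Global-alignment distances: (mismatches + internal gap columns) / alignment
    length, with terminal gap columns excluded from numerator and denominator."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if any(not s for s in seqs):
        raise ValueError("empty sequence")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _nt_pair_distance(seqs[i], seqs[j])
    return d


def _nt_pair_distance(a: str, b: str) -> float:
    if a == b:
        return 0.0
    aln = _NT.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # strip terminal gap columns (leading/trailing runs where either row is gapped)
    lo, hi = 0, len(row_a)
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 1.0
    diffs = sum(
        1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x != y or x == "-"
    )
    return diffs / (hi - lo)


# ---------------------------------------------------------------------------
# Greedy protein-family clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterParams:
    identity_step1: float = 0.95
    identity_step2: float = 0.60
    min_coverage: float = 0.80
    min_cluster_size_kept: int = 2  # families with total members <= this are dropped

    def validate(self) -> None:
        if not 0 < self.identity_step2 <= self.identity_step1 <= 1:
            raise ValueError("require 0 < identity_step2 <= identity_step1 <= 1")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0,1]")


@dataclass
class ClusterSet:
    """A partition of sequences into clusters with longest-member representatives."""

    clusters: Dict[int, List[str]]  # cluster id -> member ids
    representatives: Dict[int, str]  # cluster id -> representative member id
    level: float
    provenance: Dict[str, Optional[str]] = field(default_factory=dict)  # member -> sample

    def n_members(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def membership(self) -> Dict[str, int]:
        return {m: cid for cid, members in self.clusters.items() for m in members}


def _as_seq_items(porfs: Sequence) -> List[Tuple[str, str, Optional[str]]]:
    """Normalize input to (id, sequence, sample) triples."""
    items = []
    for p in porfs:
        if isinstance(p, Porf):
            items.append((p.id, p.aa, p.sample))
        elif isinstance(p, tuple):
            items.append((p[0], p[1], p[2] if len(p) > 2 else None))
        else:
            raise TypeError("expected Porf or (id, seq[, sample]) tuples")
    return items


def greedy_cluster(
    porfs: Sequence, identity: float, min_coverage: float = 0.80, level: Optional[float] = None
) -> ClusterSet:
    """First-fit greedy clustering against cluster representatives.

    Sequences are processed by (length desc, sequence, id); each joins the first
    existing cluster whose representative it matches at >= identity with coverage of
    the representative >= min_coverage, else it seeds a new cluster. The partition is
    independent of input order because the processing order is re-derived internally.
    """
    items = _as_seq_items(porfs)
    if not items:
        raise ValueError("empty input")
    order = sorted(items, key=lambda it: (-len(it[1]), it[1], it[0]))
    clusters: Dict[int, List[str]] = {}
    reps: Dict[int, str] = {}
    rep_seqs: List[Tuple[int, str]] = []  # (cluster id, rep sequence) in creation order
    provenance: Dict[str, Optional[str]] = {}
    for sid, seq, sample in order:
        provenance[sid] = sample
        placed = False
        for cid, rep_seq in rep_seqs:
            ident, cov = align_identity(rep_seq, seq)
            if ident >= identity and cov >= min_coverage:
                clusters[cid].append(sid)
                placed = True
                break
        if not placed:
            cid = len(rep_seqs)
            clusters[cid] = [sid]
            reps[cid] = sid
            rep_seqs.append((cid, seq))
    return ClusterSet(
        clusters=clusters,
        representatives=reps,
        level=identity if level is None else level,
        provenance=provenance,
    )


def two_step_cluster(
    porfs: Sequence, params: Optional[ClusterParams] = None
) -> Tuple[ClusterSet, ClusterSet]:
    """95% clustering of all pORFs, then 60% clustering of the 95% representatives;
    each family's membership is the union of its constituent 95% clusters."""
    params = params or ClusterParams()
    params.validate()
    items = _as_seq_items(porfs)
    level95 = greedy_cluster(items, params.identity_step1, params.min_coverage)
    seq_by_id = {sid: seq for sid, seq, _ in items}
    sample_by_id = {sid: sample for sid, _, sample in items}
    rep_items = [
        (rep_id, seq_by_id[rep_id], sample_by_id[rep_id])
        for rep_id in level95.representatives.values()
    ]
    rep_level = greedy_cluster(rep_items, params.identity_step2, params.min_coverage)
    # expand each 60% family to the union of its 95% clusters
    cluster_of_rep = {rep: cid for cid, rep in level95.representatives.items()}
    families: Dict[int, List[str]] = {}
    for fid, rep_members in rep_level.clusters.items():
        members: List[str] = []
        for rep_id in rep_members:
            members.extend(level95.clusters[cluster_of_rep[rep_id]])
        families[fid] = members
    level60 = ClusterSet(
        clusters=families,
        representatives=dict(rep_level.representatives),
        level=params.identity_step2,
        provenance={sid: sample_by_id[sid] for sid, _, _ in items},
    )
    return level95, level60


def build_family_matrix(level60: ClusterSet, min_members_exclusive: int = 2):
    """Family x sample count matrix; families with total members <= the threshold are
    removed. Rows ordered by descending total, then family id."""
    import pandas as pd

    samples = sorted({s for s in level60.provenance.values() if s is not None})
    rows = {}
    for cid, members in level60.clusters.items():
        if len(members) <= min_members_exclusive:
            continue
        counts = {s: 0 for s in samples}
        for m in members:
            s = level60.provenance.get(m)
            if s is not None:
                counts[s] += 1
        rows[f"family_{cid:05d}"] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples).fillna(0).astype(int)
    if len(df):
        totals = df.sum(axis=1)
        df = df.loc[sorted(df.index, key=lambda r: (-totals[r], r))]
    df.index.name = "feature_id"
    return df


# ---------------------------------------------------------------------------
# OTU construction: SLP preclustering + weighted average linkage
# ---------------------------------------------------------------------------

@dataclass
class OtuParams:
    precluster_distance: float = 0.02
    otu_thresholds: Tuple[float, ...] = (0.03, 0.06, 0.10)

    def validate(self) -> None:
        if self.precluster_distance >= min(self.otu_thresholds):
            raise ValueError("precluster distance must be below all OTU thresholds")


@dataclass
class Precluster:
    members: List[int]
    abundance: int
    representative: int  # index of most abundant member


def slp_precluster(
    dist: np.ndarray, abundances: Sequence[int], threshold: float = 0.02
) -> List[Precluster]:
    """Single-linkage preclustering: sequences (abundance-descending) merge with any
    already-placed sequence within the distance threshold; linkage is transitive."""
    dist = np.asarray(dist)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if len(abundances) != n:
        raise ValueError("abundance vector length must match the distance matrix")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(range(n), key=lambda i: (-abundances[i], i))
    placed: List[int] = []
    for i in order:
        for j in placed:
            if dist[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        placed.append(i)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        members_sorted = sorted(members, key=lambda i: (-abundances[i], i))
        out.append(
            Precluster(
                members=sorted(members),
                abundance=int(sum(abundances[i] for i in members)),
                representative=members_sorted[0],
            )
        )
    out.sort(key=lambda pc: pc.members[0])
    return out


def weighted_average_linkage(
    dist: np.ndarray, weights: Sequence[float]
) -> List[Tuple[float, List[int], List[int]]]:
    """Abundance-weighted average-linkage agglomeration.

    Returns the merge list [(height, left members, right members), ...] in merge
    order. The linkage update is d(i∪j, k) = (w_i d_ik + w_j d_jk)/(w_i + w_j), i.e.
    UPGMA on the abundance-expanded data. Ties merge the pair with the smallest
    member-index sets.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    active: Dict[int, List[int]] = {i: [i] for i in range(n)}
    w = {i: float(weights[i]) for i in range(n)}
    merges: List[Tuple[float, List[int], List[int]]] = []
    dmat = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > 1:
        best = min(
            dmat.items(),
            key=lambda kv: (kv[1], sorted(active[kv[0][0]] + active[kv[0][1]])),
        )
        (i, j), h = best
        merges.append((h, active[i], active[j]))
        wi, wj = w[i], w[j]
        new = min(i, j)
        other = max(i, j)
        for k in list(active):
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dk = (wi * dmat[a] + wj * dmat[b]) / (wi + wj)
            dmat[(min(new, k), max(new, k))] = dk
        merged_members = active[i] + active[j]
        del active[other]
        del w[other]
        active[new] = merged_members
        w[new] = wi + wj
        dmat = {k: v for k, v in dmat.items() if other not in k}
    return merges


def average_linkage_otus(
    dist: np.ndarray,
    weights: Sequence[float],
    thresholds: Sequence[float] = (0.03, 0.06, 0.10),
) -> Dict[float, np.ndarray]:
    """Cut the abundance-weighted average-linkage tree at each threshold.

    A merge at height h is applied for threshold t when h <= t; returns, per
    threshold, an integer OTU label per input sequence.
    """
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError(f"threshold {t} outside (0,1)")
    n = np.asarray(dist).shape[0]
    merges = weighted_average_linkage(dist, weights)
    out: Dict[float, np.ndarray] = {}
    for t in thresholds:
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h, left, right in merges:
            if h <= t:
                parent[find(left[0])] = find(right[0])
        roots = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
        out[t] = labels
    return out
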