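"""Nonparametric multivariate community comparison.

The toolkit used throughout the analysis: square-root or presence/absence transforms,
a rare-feature filter, Bray-Curtis similarity on the 0-100 scale, group-average
(UPGMA) dendrograms with SIMPROF structure tests, SIMPER decomposition of between-group
dissimilarity, the ANOSIM rank permutation test, and non-metric multidimensional
scaling (Kruskal stress-1, isotonic regression, random restarts).

Similarities are kept on the 0-100 percent scale; dissimilarity = 100 - similarity
everywhere.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# Transforms and filters
# ---------------------------------------------------------------------------

def transform_counts(matrix: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Element-wise square-root or presence/absence transform."""
    if (matrix.values < 0).any():
        raise ValueError("counts must be non-negative")
    if mode == "sqrt":
        return np.sqrt(matrix.astype(float))
    if mode == "presence_absence":
        return (matrix > 0).astype(float)
    if mode == "none":
        return matrix.astype(float)
    raise ValueError(f"unknown transform mode {mode!r}")


def rare_taxon_filter(matrix: pd.DataFrame, min_total: int = 100) -> pd.DataFrame:
    """Drop features whose total abundance across samples is below ``min_total``."""
    return matrix.loc[matrix.sum(axis=1) >= min_total]


def aggregate_by_category(
    matrix: pd.DataFrame, annotation: Dict[str, str], unannotated_label: str = "unannotated"
) -> pd.DataFrame:
    """Sum feature rows into category rows; unmapped features accumulate in an
    'unannotated' row. Column sums are preserved exactly."""
    unknown = set(annotation) - set(matrix.index)
    if unknown:
        warnings.warn(f"annotation references {len(unknown)} unknown features; ignored")
    cats = pd.Series(
        [annotation.get(f, unannotated_label) for f in matrix.index], index=matrix.index
    )
    out = matrix.groupby(cats).sum()
    out.index.name = "feature_id"
    return out


# ---------------------------------------------------------------------------
# Bray-Curtis similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric samples x samples Bray-Curtis similarity matrix, percent scale."""

    data: pd.DataFrame
    transform: str = "none"

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    def dissimilarity(self) -> pd.DataFrame:
        return 100.0 - self.data

    def condensed_dissimilarity(self) -> np.ndarray:
        return squareform(self.dissimilarity().values, checks=False)

    def validate(self) -> None:
        v = self.data.values
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if (v < -1e-9).any() or (v > 100 + 1e-9).any():
            raise ValueError("similarities must lie in [0, 100]")


def bray_curtis(matrix: pd.DataFrame, transform: str = "none") -> SimilarityMatrix:
    """Pairwise Bray-Curtis similarity S_jk = 100 x 2 sum min / sum (y_j + y_k)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = matrix.values.astype(float)
    if (X < 0).any():
        raise ValueError("entries must be non-negative")
    zero = matrix.columns[X.sum(axis=0) == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, zero))}")
    sim = 100.0 * (1.0 - squareform(pdist(X.T, metric="braycurtis")))
    np.fill_diagonal(sim, 100.0)
    df = pd.DataFrame(sim, index=matrix.columns, columns=matrix.columns)
    return SimilarityMatrix(data=df, transform=transform)


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------

@dataclass
class DendrogramNode:
    """Binary merge tree on dissimilarity (100 - similarity) heights."""

    height: float
    children: Tuple["DendrogramNode", "DendrogramNode"] | None = None
    leaf: Optional[str] = None
    # SIMPROF annotations
    pi: Optional[float] = None
    p_value: Optional[float] = None
    tested: bool = False
    significant: bool = False

    @property
    def leaves(self) -> List[str]:
        if self.leaf is not None:
            return [self.leaf]
        return self.children[0].leaves + self.children[1].leaves

    def nodes(self) -> Iterable["DendrogramNode"]:
        yield self
        if self.children:
            yield from self.children[0].nodes()
            yield from self.children[1].nodes()

    def clades(self) -> List[frozenset]:
        return [frozenset(n.leaves) for n in self.nodes() if n.children]

    def to_newick(self) -> str:
        def fmt(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.leaf is not None:
                return f"{node.leaf}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        inner = ",".join(fmt(c, self.height) for c in self.children) if self.children else self.leaf
        return f"({inner});" if self.children else f"{self.leaf};"


def upgma(sim: SimilarityMatrix) -> DendrogramNode:
    """Unweighted group-average agglomeration on dissimilarity, with deterministic
    tie-breaking (merge the pair with the lexicographically smallest leaf-name set)."""
    ids = sim.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    d = sim.dissimilarity().values.astype(float)
    nodes: Dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, leaf=name) for i, name in enumerate(ids)
    }
    sizes = {i: 1 for i in nodes}
    dmat = {(i, j): d[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))}
    while len(nodes) > 1:
        (i, j), h = min(
            dmat.items(),
            key=lambda kv: (kv[1], sorted(nodes[kv[0][0]].leaves + nodes[kv[0][1]].leaves)),
        )
        merged = DendrogramNode(height=h, children=(nodes[i], nodes[j]))
        ni, nj = sizes[i], sizes[j]
        new, other = min(i, j), max(i, j)
        for k in nodes:
            if k in (i, j):
                continue
            a = (min(i, k), max(i, k))
            b = (min(j, k), max(j, k))
            dmat[(min(new, k), max(new, k))] = (ni * dmat[a] + nj * dmat[b]) / (ni + nj)
        del nodes[other]
        del sizes[other]
        nodes[new] = merged
        sizes[new] = ni + nj
        dmat = {k: v for k, v in dmat.items() if other not in k}
    return next(iter(nodes.values()))


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------

def _bc_profiles(stack: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Sorted Bray-Curtis similarity profiles for a stack of matrices.

    stack: (P, F, S) non-negative arrays; pairs: (npair, 2) column indices.
    Returns (P, npair) sorted similarities (percent scale).
    """
    a = stack[:, :, pairs[:, 0]]
    b = stack[:, :, pairs[:, 1]]
    num = np.abs(a - b).sum(axis=1)
    den = (a + b).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 100.0 * (1.0 - num / den)
    sim = np.nan_to_num(sim, nan=100.0)  # two empty samples: identically empty
    sim.sort(axis=1)
    return sim


def _permuted_stack(
    X: np.ndarray, n_perms: int, rng: np.random.Generator, block: int = 250
) -> Iterable[np.ndarray]:
    """Yield blocks of matrices with each feature's values permuted independently
    across samples."""
    f, s = X.shape
    remaining = n_perms
    while remaining > 0:
        p = min(block, remaining)
        keys = rng.random((p, f, s))
        idx = np.argsort(keys, axis=2)
        yield np.take_along_axis(np.broadcast_to(X, (p, f, s)), idx, axis=2)
        remaining -= p


def simprof_test(
    X: np.ndarray,
    n_mean_perms: int = 1000,
    n_test_perms: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """One SIMPROF test: compare the observed ordered similarity profile to the mean
    profile under within-feature permutation. Returns (pi, p_value)."""
    rng = rng if rng is not None else np.random.default_rng()
    X = np.asarray(X, dtype=float)
    f, s = X.shape
    if s < 3:
        raise ValueError("SIMPROF needs at least three samples")
    pairs = np.array(list(itertools.combinations(range(s), 2)))
    obs = _bc_profiles(X[None, :, :], pairs)[0]
    mean_prof = np.zeros(len(pairs))
    for blockX in _permuted_stack(X, n_mean_perms, rng):
        mean_prof += _bc_profiles(blockX, pairs).sum(axis=0)
    mean_prof /= n_mean_perms
    pi_obs = float(np.abs(obs - mean_prof).sum())
    n_ge = 0
    for blockX in _permuted_stack(X, n_test_perms, rng):
        pi_null = np.abs(_bc_profiles(blockX, pairs) - mean_prof).sum(axis=1)
        n_ge += int((pi_null >= pi_obs - 1e-12).sum())
    p = (1 + n_ge) / (n_test_perms + 1)
    return pi_obs, p


def simprof(
    matrix: pd.DataFrame,
    n_mean_perms: int = 1000,
    n_test_perms: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    tree: Optional[DendrogramNode] = None,
) -> DendrogramNode:
    """UPGMA dendrogram with top-down SIMPROF structure tests.

    ``matrix`` is the (already transformed) feature x sample table. At each node with
    at least three samples the similarity profile of its samples is tested; the descent
    stops below non-significant nodes, whose subtrees are reported homogeneous.
    Two-sample nodes are untestable by construction.
    """
    if tree is None:
        tree = upgma(bray_curtis(matrix))
    rng = np.random.default_rng(seed)
    cols = {c: i for i, c in enumerate(matrix.columns)}
    Xall = matrix.values.astype(float)

    def visit(node: DendrogramNode) -> None:
        leaves = node.leaves
        if node.children is None or len(leaves) < 3:
            node.tested = False
            return
        X = Xall[:, [cols[s] for s in leaves]]
        node.pi, node.p_value = simprof_test(X, n_mean_perms, n_test_perms, rng)
        node.tested = True
        node.significant = node.p_value <= alpha
        if node.significant:
            visit(node.children[0])
            visit(node.children[1])

    visit(tree)
    return tree


def simprof_annotation_table(tree: DendrogramNode) -> pd.DataFrame:
    rows = []
    for node in tree.nodes():
        if node.children:
            rows.append(
                {
                    "leaves": ";".join(sorted(node.leaves)),
                    "height": node.height,
                    "pi": node.pi,
                    "p_value": node.p_value,
                    "tested": node.tested,
                    "significant": node.significant,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResult:
    group_pair: Tuple[str, str]
    overall_dissimilarity: float  # percent
    table: pd.DataFrame  # feature, av_abund per group, contribution, contrib_pct, cum_pct


def simper(
    matrix: pd.DataFrame, groups: Dict[str, str]
) -> Dict[Tuple[str, str], SimperResult]:
    """Per-feature decomposition of average between-group Bray-Curtis dissimilarity.

    For each between-group sample pair (j,k), feature i contributes
    100 |y_ij - y_ik| / sum_i (y_ij + y_ik); contributions are averaged over pairs and
    expressed as percentages of the overall average dissimilarity.
    """
    labels = pd.Series({s: groups[s] for s in matrix.columns})
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    out: Dict[Tuple[str, str], SimperResult] = {}
    X = matrix.values.astype(float)
    cols = {c: i for i, c in enumerate(matrix.columns)}
    for g1, g2 in itertools.combinations(names, 2):
        s1 = [cols[s] for s in labels.index[labels == g1]]
        s2 = [cols[s] for s in labels.index[labels == g2]]
        if not s1 or not s2:
            raise ValueError("each group needs at least one sample")
        contribs = np.zeros(matrix.shape[0])
        n_pairs = 0
        for j in s1:
            for k in s2:
                den = (X[:, j] + X[:, k]).sum()
                if den == 0:
                    raise ValueError("pair of all-zero samples")
                contribs += 100.0 * np.abs(X[:, j] - X[:, k]) / den
                n_pairs += 1
        contribs /= n_pairs
        overall = float(contribs.sum())
        table = pd.DataFrame(
            {
                "feature": matrix.index,
                f"av_abund_{g1}": X[:, s1].mean(axis=1),
                f"av_abund_{g2}": X[:, s2].mean(axis=1),
                "contribution": contribs,
            }
        )
        table = table.sort_values(
            ["contribution", "feature"], ascending=[False, True]
        ).reset_index(drop=True)
        table["contrib_pct"] = 100.0 * table["contribution"] / overall if overall else 0.0
        table["cum_pct"] = table["contrib_pct"].cumsum()
        out[(g1, g2)] = SimperResult(
            group_pair=(g1, g2), overall_dissimilarity=overall, table=table
        )
    return out


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    sim: Union[SimilarityMatrix, pd.DataFrame],
    groups: Dict[str, str],
    n_perms: Optional[int] = 999,
    seed: int = 0,
) -> AnosimResult:
    """Rank-based ANOSIM. R = (mean between-group rank - mean within-group rank)/(M/2).

    ``n_perms=None`` enumerates all label permutations exhaustively (small n only);
    otherwise the p-value is estimated from ``n_perms`` random label permutations with
    the observed labelling included in numerator and denominator. Mid-ranks for ties.
    """
    data = sim.data if isinstance(sim, SimilarityMatrix) else sim
    ids = list(data.columns)
    labels = np.array([groups[s] for s in ids])
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two groups")
    diss = squareform(100.0 - data.values, checks=False)
    ranks = rankdata(diss)
    n = len(ids)
    iu = np.triu_indices(n, k=1)

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(ranks, within_mask(labels))
    if n_perms is None:
        perms = list(itertools.permutations(range(n)))
        rs = np.array([_anosim_r(ranks, within_mask(labels[list(p)])) for p in perms])
        p = float((rs >= r_obs - 1e-12).mean())
        return AnosimResult(r=r_obs, p_value=p, n_permutations=len(perms))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        if _anosim_r(ranks, within_mask(labels[perm])) >= r_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_perms + 1)
    return AnosimResult(r=r_obs, p_value=p, n_permutations=n_perms)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coords: pd.DataFrame  # samples x k, centered
    stress: float  # Kruskal stress-1
    best_restart: int
    seed: int


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Principal-coordinates (classical MDS) configuration for initialization."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def kruskal_stress1(d: np.ndarray, config: np.ndarray) -> float:
    """Stress-1 with monotone regression of configuration distances on the
    dissimilarity order (primary tie treatment)."""
    from sklearn.isotonic import IsotonicRegression

    dist = pdist(config)
    order = np.argsort(d, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(dist)
    dhat[order] = iso.fit_transform(np.arange(len(d)), dist[order])
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def nmds(
    sim: Union[SimilarityMatrix, pd.DataFrame],
    k: int = 2,
    restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    nested_init: bool = True,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``restarts`` runs.

    The first restart starts from the principal-coordinates configuration of the
    dissimilarities; with ``nested_init`` (default) one extra restart starts from the
    best (k-1)-dimensional solution padded with a zero column, which guarantees that
    the reported stress is non-increasing in k; the rest start from random
    configurations. Returns the centered configuration with minimum stress-1.
    """
    from sklearn.manifold import MDS

    data = sim.data if isinstance(sim, SimilarityMatrix) else sim
    ids = list(data.columns)
    n = len(ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    dmat = (100.0 - data.values).astype(float)
    np.fill_diagonal(dmat, 0.0)
    dcond = squareform(dmat, checks=False)
    rng = np.random.default_rng(seed)

    inits = [_classical_mds(dmat, k)]
    if nested_init and k > 1:
        sub = nmds(data, k - 1, restarts, max_iter, tol, seed, nested_init=True)
        inits.append(np.hstack([sub.coords.values, np.zeros((n, 1))]))
    while len(inits) < restarts + (nested_init and k > 1):
        inits.append(rng.normal(size=(n, k)))

    best_cfg, best_stress, best_idx = None, np.inf, -1
    for r, init in enumerate(inits):
        mds = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
            normalized_stress=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = mds.fit_transform(dmat, init=init)
        stress = kruskal_stress1(dcond, cfg)
        # the SMACOF iterations can drift on a perfect configuration; keep the
        # initialization if it already fits better
        stress_init = kruskal_stress1(dcond, init)
        if stress_init < stress:
            cfg, stress = init, stress_init
        if stress < best_stress:
            best_cfg, best_stress, best_idx = cfg, stress, r
    best_cfg = best_cfg - best_cfg.mean(axis=0)
    coords = pd.DataFrame(
        best_cfg, index=ids, columns=[f"nmds{i+1}" for i in range(k)]
    )
    return NmdsResult(coords=coords, stress=best_stress, best_restart=best_idx, seed=seed)
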