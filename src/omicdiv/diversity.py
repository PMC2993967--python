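"""Rarefaction and diversity/coverage indices.

Implements equal-effort resampling (uniform subsampling without replacement to a
common depth) and the nonparametric summary statistics used to compare samples:
observed richness S, Good's coverage C = (1 - n1/N) x 100 where n1 is the number of
singleton features, Margalef richness d = (S - 1)/ln N, and bias-corrected Simpson
evenness 1 - lambda' with lambda' = sum n_i(n_i - 1) / (N(N - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def rarefy(counts: Sequence[int] | pd.Series, depth: int, seed: int = 0) -> np.ndarray | pd.Series:
    """Subsample one sample's feature counts to ``depth`` observations without
    replacement (multivariate hypergeometric). Errors if depth exceeds the total;
    never upsamples."""
    is_series = isinstance(counts, pd.Series)
    arr = np.asarray(counts.values if is_series else counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds the sample total {total}")
    rng = np.random.default_rng(seed)
    out = rng.multivariate_hypergeometric(arr, depth)
    if is_series:
        return pd.Series(out, index=counts.index)
    return out


def rarefy_matrix(matrix: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Rarefy every sample (column) to the same depth; per-column seeds are derived
    deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    cols = {}
    for col in matrix.columns:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cols[col] = rarefy(matrix[col], depth, seed=sub_seed)
    return pd.DataFrame(cols, index=matrix.index)


def goods_coverage(counts: Sequence[int]) -> float:
    """Good's coverage on the percent scale: (1 - n1/N) x 100, with n1 the number of
    features observed exactly once."""
    arr = np.asarray(counts)
    n_total = int(arr.sum())
    if n_total <= 0:
        raise ValueError("total count must be positive")
    n1 = int((arr == 1).sum())
    return (1.0 - n1 / n_total) * 100.0


def margalef_d(s: int, n: int) -> float:
    """Margalef's depth-adjusted richness d = (S - 1)/ln N."""
    if n < 2:
        raise ValueError("N must be at least 2")
    if s < 1:
        raise ValueError("S must be at least 1")
    return (s - 1) / log(n)


def simpson_evenness(
    counts: Sequence[int], bias_corrected: bool = True
) -> Tuple[float, float]:
    """Simpson dominance lambda' and evenness 1 - lambda'.

    The bias-corrected (finite-sample) form sum n_i(n_i-1)/(N(N-1)) is the default;
    ``bias_corrected=False`` gives the plug-in sum p_i^2.
    """
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    n = arr.sum()
    if n < 2:
        raise ValueError("need at least two observations")
    if bias_corrected:
        lam = float((arr * (arr - 1)).sum() / (n * (n - 1)))
    else:
        p = arr / n
        lam = float((p**2).sum())
    return lam, 1.0 - lam


def richness_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between two richness vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class DiversitySummary:
    sample: str
    n: int
    s: int
    n1: int
    coverage: float
    margalef: float
    simpson_lambda: float
    evenness: float


def summarize_matrix(
    matrix: pd.DataFrame, depth: Optional[int] = None, seed: int = 0
) -> pd.DataFrame:
    """Per-sample diversity summary, optionally rarefying all samples first."""
    if depth is not None:
        matrix = rarefy_matrix(matrix, depth, seed=seed)
    rows = []
    for col in matrix.columns:
        v = matrix[col].values
        v = v[v > 0]
        n = int(v.sum())
        lam, even = simpson_evenness(v)
        rows.append(
            DiversitySummary(
                sample=col,
                n=n,
                s=int((v > 0).sum()),
                n1=int((v == 1).sum()),
                coverage=goods_coverage(v),
                margalef=margalef_d(int((v > 0).sum()), n),
                simpson_lambda=lam,
                evenness=even,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("sample")
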