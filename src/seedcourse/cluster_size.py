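"""Permutation Mahalanobis test on subcluster-size distributions.

Does a temporal co-expression set break into subclusters whose size
distribution deviates from what independent transcripts would give?
Each permutation independently shuffles every transcript's line profile
across lines (destroying transcript-transcript co-association while
preserving each transcript's value multiset), re-clusters into k
groups, sorts the sizes descending and drops the smallest, yielding a
(k-1)-vector.  The observed vector's squared Mahalanobis distance from
the permutation mean, under the permutation covariance, is referred to
a chi-squared distribution with k-1 degrees of freedom (7 when k = 8).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2

from .gcoe import _profiles


def _size_vector(data: np.ndarray, k: int, method: str) -> np.ndarray:
    Z = linkage(data, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    sizes = np.sort(np.bincount(labels, minlength=k + 1)[1:])[::-1]
    return sizes[:-1].astype(float)          # drop the smallest


def mahalanobis_d2(x: np.ndarray, mean: np.ndarray,
                   cov: np.ndarray) -> float:
    """Squared Mahalanobis distance (pseudo-inverse on singular cov)."""
    diff = np.asarray(x, float) - np.asarray(mean, float)
    try:
        sol = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError:
        warnings.warn("singular permutation covariance; using pseudo-inverse")
        sol = np.linalg.pinv(cov) @ diff
    return float(diff @ sol)


@dataclass
class MahalanobisResult:
    d2: float
    df: int
    p: float
    observed_sizes: np.ndarray
    null_mean: np.ndarray
    null_cov: np.ndarray


def mahalanobis_test(lsm: pd.DataFrame, members, k: int = 8,
                     n_perm: int = 1000, seed: int = 0,
                     method: str = "ward") -> MahalanobisResult:
    """Cluster-size deviation test for one set of transcripts."""
    members = list(members)
    if not 2 <= k <= len(members):
        raise ValueError(f"need 2 <= k <= {len(members)}")
    if n_perm < k:
        raise ValueError("n_perm must be at least k for an estimable covariance")
    rng = np.random.default_rng(seed)
    data = _profiles(lsm, members, standardize=True)
    m, L = data.shape
    observed = _size_vector(data, k, method)

    null = np.empty((n_perm, k - 1))
    for b in range(n_perm):
        idx = rng.random((m, L)).argsort(axis=1)
        null[b] = _size_vector(np.take_along_axis(data, idx, axis=1),
                               k, method)
    mean = null.mean(axis=0)
    cov = np.cov(null, rowvar=False)
    d2 = mahalanobis_d2(observed, mean, cov)
    df = k - 1
    return MahalanobisResult(d2, df, float(chi2.sf(d2, df)), observed,
                             mean, cov)


def bonferroni_screen(p_values, alpha: float = 0.05) -> np.ndarray:
    """Flag tests with ``p < alpha / m`` (family-wise control)."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / p.size
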