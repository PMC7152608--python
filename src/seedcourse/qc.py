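"""Sample/transcript filtering, normalization and sample-level PCA.

The QC path from a raw tag-count matrix to an analysis-ready matrix:
drop shallow samples (< 0.5M mapped reads by default), drop rarely
expressed transcripts, normalize by median-of-ratios size factors,
variance-stabilize with a shifted log2, run PCA on the top-variance
transcripts, and split off an outlier sample cluster when one exists.

The variance stabilizer is ``log2(count / sf + 1)``: downstream stages
use the matrix only through variance ranking, linear models and PCA, for
which the shifted log of depth-normalized counts is an accepted
stabilizer.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import CountMatrix, NormalizedMatrix


def filter_samples(cm: CountMatrix, min_mapped: int = 500_000) -> CountMatrix:
    """Retain samples whose total count is at least ``min_mapped``."""
    if min_mapped < 0:
        raise ValueError("min_mapped must be non-negative")
    keep = cm.counts.sum(axis=0) >= min_mapped
    if not keep.any():
        raise ValueError(
            f"no sample has >= {min_mapped} mapped reads; nothing retained")
    return cm.subset_samples(cm.sample_ids[keep])


def filter_transcripts(cm: CountMatrix, min_count: int = 2,
                       min_samples: int = 10,
                       literal_removal: bool = False) -> CountMatrix:
    """Drop rarely expressed transcripts.

    Default reading (standard expression filtering): retain transcripts
    with at least ``min_count`` counts in at least ``min_samples``
    samples.  ``literal_removal=True`` instead removes transcripts with
    fewer than ``min_count`` counts in at least ``min_samples`` samples.
    """
    if min_count < 0 or min_samples < 1:
        raise ValueError("min_count must be >= 0 and min_samples >= 1")
    if min_samples > cm.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {cm.n_samples}")
    if literal_removal:
        keep = (cm.counts < min_count).sum(axis=1) < min_samples
    else:
        keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    return cm.subset_transcripts(cm.transcript_ids[keep])


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the median over reference transcripts (those with
    positive counts in every sample) of count / geometric mean.
    """
    counts = cm.counts.to_numpy(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no transcript has positive counts in all samples; consider a "
            "pseudo-reference fallback or stricter transcript filtering")
    ref = counts[positive]
    geo = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
    sf = np.median(ref / geo, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def variance_stabilize(cm: CountMatrix,
                       sf: pd.Series | None = None) -> NormalizedMatrix:
    """Shifted-log stabilization: ``log2(count / sf + 1)``."""
    if sf is None:
        sf = size_factors(cm)
    sf = sf.loc[cm.sample_ids]
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    values = np.log2(cm.counts.to_numpy(float) / sf.to_numpy()[None, :] + 1.0)
    return NormalizedMatrix(
        pd.DataFrame(values, index=cm.transcript_ids, columns=cm.sample_ids),
        sf, cm.metadata)


def sample_pca(nm: NormalizedMatrix, top_n: int = 500,
               n_components: int = 10):
    """PCA of samples on the ``top_n`` highest-variance transcripts.

    Transcripts are centered (not scaled).  Returns ``(scores,
    variance_explained)`` where scores is samples x components and the
    variance-explained fractions refer to the total variance of the
    centered submatrix.
    """
    if nm.values.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    if top_n > nm.values.shape[0]:
        raise ValueError(
            f"top_n={top_n} exceeds transcript count {nm.values.shape[0]}")
    vals = nm.values.to_numpy()
    order = np.argsort(vals.var(axis=1, ddof=1))[::-1][:top_n]
    sub = vals[np.sort(order)]
    centered = (sub - sub.mean(axis=1, keepdims=True)).T  # samples x top_n
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    scores = pd.DataFrame(u[:, :k] * s[:k], index=nm.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(k)])
    varexp = (s ** 2 / (s ** 2).sum())[:k]
    return scores, varexp


def split_outlier_cluster(scores: pd.DataFrame,
                          min_minor_fraction: float = 0.05,
                          min_silhouette: float = 0.65,
                          random_state: int = 0):
    """2-means on PCs 1-2; returns ``(major_ids, minor_ids)``.

    The larger group is "major".  The split is only accepted when it
    looks like two genuinely distinct clusters: the minor group must
    hold at least ``min_minor_fraction`` of samples and the 2-means
    partition must reach a mean silhouette of ``min_silhouette``
    (2-means cheerfully halves a continuous gradient or a single blob;
    the silhouette criterion rejects those).  Otherwise all samples are
    returned as major (minor empty).  Equal group sizes are broken
    deterministically: the group containing the lexicographically first
    sample ID is major.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to look for a split")
    pts = scores.iloc[:, :2].to_numpy()
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
    labels = km.fit_predict(pts)
    sil = silhouette_score(pts, labels)
    ids = scores.index
    g0, g1 = ids[labels == 0], ids[labels == 1]
    if len(g0) > len(g1):
        major, minor = g0, g1
    elif len(g1) > len(g0):
        major, minor = g1, g0
    else:
        first = min(ids)
        major, minor = (g0, g1) if first in g0 else (g1, g0)
    if len(minor) < min_minor_fraction * len(ids) or sil < min_silhouette:
        return ids, ids[:0]
    return major, minor


def time_correlation(nm: NormalizedMatrix, method: str = "spearman"
                     ) -> pd.DataFrame:
    """Correlation of per-time mean expression between time points.

    Expression is averaged over samples within each time point per
    transcript, then correlated pairwise between time points (the
    adjacent-time-points correlation structure of a developmental
    course).
    """
    daa = nm.metadata["daa"]
    times = sorted(daa.unique())
    means = pd.DataFrame(
        {t: nm.values.loc[:, daa[daa == t].index].mean(axis=1) for t in times})
    return means.corr(method=method)
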