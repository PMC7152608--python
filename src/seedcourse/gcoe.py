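"""Genetic co-expression (GCoE) subclustering of temporal pattern sets.

From the normalized expression matrix, this module (1) removes one
latent batch factor estimated from the residuals of the known design,
(2) collapses samples to a lines x transcripts least-squares-mean
(lsmean) matrix under ``~ Line + Location + Location/Replication +
Time``, (3) splits each temporal co-expression set into subclusters of
transcripts with correlated per-line profiles (Ward clustering of
standardized profiles), and (4) summarizes each subcluster by its
per-line first-principal-component score, the module "eigengene".

The number of subclusters is chosen per set to make subcluster
heritabilities high and homogeneous: ``score(k) = median(h2) -
lambda * IQR(h2)``, maximized over the search range with ties broken
toward smaller k.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._design import check_full_rank, design_matrix
from .containers import NormalizedMatrix
from .genetics import estimate_h2

LSMEAN_TERMS = ("line", "location", "loc_rep", "daa")


@dataclass
class LatentAdjustment:
    adjusted: NormalizedMatrix
    factor_scores: pd.Series
    loadings: pd.Series


def adjust_latent(nm: NormalizedMatrix) -> LatentAdjustment:
    """Remove the leading latent factor of unwanted variation.

    Each transcript is residualized on the known design (Line,
    Location, Replication within Location, Time); the first principal
    component of the residual matrix across samples is the latent
    factor, and its fitted per-transcript contribution is removed from
    the normalized values.  Because the factor lives in the orthogonal
    complement of the design space, design effects are untouched.
    """
    md = nm.metadata
    X, names = design_matrix(md, list(LSMEAN_TERMS))
    check_full_rank(X, names)
    Y = nm.values.to_numpy()
    H = X @ np.linalg.pinv(X)          # hat matrix on the sample dimension
    R = Y - Y @ H.T
    _, s, vt = np.linalg.svd(R, full_matrices=False)
    f = vt[0]                           # unit-norm factor scores per sample
    gamma = R @ f
    adjusted = Y - np.outer(gamma, f)
    out = NormalizedMatrix(
        pd.DataFrame(adjusted, index=nm.values.index, columns=nm.values.columns),
        nm.size_factors, md)
    return LatentAdjustment(
        out,
        pd.Series(f, index=nm.values.columns, name="latent_factor"),
        pd.Series(gamma, index=nm.values.index, name="loading"))


def lsmeans(nm: NormalizedMatrix) -> pd.DataFrame:
    """Lines x transcripts least-squares means.

    Per transcript the fixed-effects model ``~ Line + Location +
    Location/Replication + Time`` is fitted by OLS; a line's lsmean is
    its prediction averaged with equal weight over all observed levels
    of the other factors.  Lines absent from the data get NaN rows with
    a warning.
    """
    md = nm.metadata
    X, names = design_matrix(md, list(LSMEAN_TERMS))
    Y = nm.values.to_numpy().T          # samples x transcripts
    B = np.linalg.lstsq(X, Y, rcond=None)[0]

    lines = sorted(md["line"].unique())
    locs = sorted(md["location"].unique())
    times = sorted(md["daa"].unique())
    grid_rows = []
    for loc in locs:
        reps = sorted(md.loc[md["location"] == loc, "replicate"].unique())
        for rep in reps:
            for t in times:
                grid_rows.append((loc, rep, t))

    out = np.empty((len(lines), Y.shape[1]))
    for i, line in enumerate(lines):
        gmd = pd.DataFrame(grid_rows, columns=["location", "replicate", "daa"])
        gmd.insert(0, "line", line)
        G = _grid_design(gmd, md, names)
        out[i] = (G @ B).mean(axis=0)
    result = pd.DataFrame(out, index=pd.Index(lines, name="line"),
                          columns=nm.values.index)
    return result


def _grid_design(gmd: pd.DataFrame, md: pd.DataFrame, names) -> np.ndarray:
    """Design rows for a prediction grid using the training coding."""
    n = len(gmd)
    cols = []
    for name in names:
        if name == "Intercept":
            cols.append(np.ones(n))
        elif name.startswith("loc_rep["):
            loc, rep = name[len("loc_rep["):-1].split(":")
            cols.append(((gmd["location"].astype(str) == loc)
                         & (gmd["replicate"].astype(str) == rep))
                        .to_numpy(float))
        else:
            factor, level = name[:-1].split("[")
            cols.append((gmd[factor].astype(str) == level).to_numpy(float))
    return np.column_stack(cols)


def _profiles(lsm: pd.DataFrame, members, standardize: bool = True
              ) -> np.ndarray:
    """Member transcripts as rows of (standardized) per-line profiles."""
    sub = lsm.loc[:, list(members)].to_numpy().T   # members x lines
    if standardize:
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        sub = (sub - mu) / sd
    return sub


def subcluster(lsm: pd.DataFrame, members, k: int, method: str = "ward",
               standardize: bool = True) -> pd.Series:
    """Agglomerative clustering of a set's transcripts into ``k`` groups.

    Observations are per-line lsmean profiles (standardized per
    transcript by default), Euclidean distance, Ward linkage.
    """
    members = list(members)
    if not 2 <= k <= len(members):
        raise ValueError(f"need 2 <= k <= {len(members)} members, got k={k}")
    data = _profiles(lsm, members, standardize)
    Z = linkage(data, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(members, name="transcript_id"),
                     name="gcoe_id")


def pc1_scores(lsm: pd.DataFrame, members):
    """Per-line PC1 score of a subcluster and its variance explained.

    PCA over lines (observations) by member transcripts (variables,
    centered).  The sign is fixed so the score correlates positively
    with the mean member profile.
    """
    members = list(members)
    if len(members) < 1:
        raise ValueError("need at least one member transcript")
    M = lsm.loc[:, members].to_numpy(float)
    Mc = M - M.mean(axis=0, keepdims=True)
    if np.allclose(Mc, 0):
        raise ValueError("all member transcripts have zero variance across lines")
    u, s, _ = np.linalg.svd(Mc, full_matrices=False)
    scores = u[:, 0] * s[0]
    mean_profile = Mc.mean(axis=1)
    if float(scores @ mean_profile) < 0:
        scores = -scores
    varexp = float(s[0] ** 2 / np.sum(s ** 2))
    return pd.Series(scores, index=lsm.index, name="pc1"), varexp


def choose_k(lsm: pd.DataFrame, members, grm: pd.DataFrame,
             k_range=range(4, 21), lam: float = 1.0,
             method: str = "ward", tie_tol: float = 0.01):
    """Pick the subcluster count maximizing ``median(h2) - lam * IQR(h2)``.

    The score favours partitions whose subclusters are all highly
    heritable with little spread.  Candidate k values beyond the member
    count are skipped; scores within ``tie_tol`` of the best count as
    ties and go to the smallest k (so featureless data default to the
    low end of the range).  Returns ``(k, per-k summary table)``.
    """
    members = list(members)
    ks = [k for k in k_range if 2 <= k <= len(members)]
    if not ks:
        raise ValueError("k_range contains no feasible cluster count")
    rows = []
    for k in ks:
        labels = subcluster(lsm, members, k, method=method)
        h2s = []
        for g in sorted(labels.unique()):
            mem = labels.index[labels == g]
            try:
                scores, _ = pc1_scores(lsm, mem)
            except ValueError:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h2s.append(estimate_h2(scores, grm).h2)
        h2s = np.asarray(h2s)
        med = float(np.median(h2s))
        iqr = float(np.percentile(h2s, 75) - np.percentile(h2s, 25))
        rows.append((k, med, iqr, med - lam * iqr))
    summary = pd.DataFrame(rows, columns=["k", "median_h2", "iqr_h2", "score"])
    best = summary["score"].max()
    best_k = int(summary.loc[summary["score"] >= best - tie_tol, "k"].min())
    return best_k, summary
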