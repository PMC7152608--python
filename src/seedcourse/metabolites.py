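"""Metabolite-to-module association by simple linear regression.

Mature-seed metabolites (measured once per line x location x replicate)
are filtered to those with design-based heritability above a threshold
(strictly greater than 0.4 by default), collapsed to per-line means,
and regressed one at a time on the per-line PC1 score of each genetic
co-expression set.  Because statistical power at panel size is too low
for per-test multiplicity correction, inference is by comparison with a
permutation null: PC1 scores are permuted across lines and all
regressions recomputed, and the observed p-value collection is compared
with the permuted one (quantiles per module plus a one-sided rank-sum
test of observed < permuted).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import metabolite_h2


def metabolite_h2_table(df: pd.DataFrame) -> pd.Series:
    """Design-based heritability for every metabolite in a long table."""
    out = {}
    for m, sub in df.groupby("metabolite", observed=True, sort=True):
        out[m] = metabolite_h2(sub).h2
    return pd.Series(out, name="h2").rename_axis("metabolite")


def filter_heritable(df: pd.DataFrame, h2: pd.Series,
                     threshold: float = 0.4) -> pd.DataFrame:
    """Keep metabolites with ``h2 > threshold`` (strict inequality)."""
    keep = h2.index[h2 > threshold]
    if len(keep) == 0:
        warnings.warn("no metabolite passes the heritability filter")
    return df[df["metabolite"].isin(keep)]


def line_means(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse plot-level values to a lines x metabolites table."""
    wide = df.pivot_table(index="line", columns="metabolite", values="value",
                          aggfunc="mean", observed=True)
    return wide


def regress_on_pc1(met_lines: pd.DataFrame, pc1: pd.DataFrame) -> pd.DataFrame:
    """OLS slope test of every metabolite on every module's PC1 score.

    ``met_lines`` is lines x metabolites, ``pc1`` lines x modules
    (matching line index).  Two-sided p from the t distribution on
    ``n_lines - 2`` degrees of freedom; zero-variance predictors yield
    missing p.
    """
    common = met_lines.index.intersection(pc1.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared lines")
    Y = met_lines.loc[common].to_numpy(float)
    n = len(common)
    dof = n - 2
    rows = []
    for mod in pc1.columns:
        x = pc1.loc[common, mod].to_numpy(float)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx <= 0:
            for met in met_lines.columns:
                rows.append((met, mod, np.nan, np.nan, np.nan))
            continue
        Yc = Y - Y.mean(axis=0, keepdims=True)
        slope = (xc @ Yc) / sxx
        resid = Yc - np.outer(xc, slope)
        s2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(s2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        for j, met in enumerate(met_lines.columns):
            rows.append((met, mod, float(slope[j]), float(t[j]), float(p[j])))
    return pd.DataFrame(rows, columns=["metabolite", "gcoe", "slope", "t", "p"])


@dataclass
class PermutationComparison:
    observed: pd.DataFrame           # regress_on_pc1 output
    permuted_p: np.ndarray           # all permuted p-values, flattened
    per_module: pd.DataFrame         # quantile comparison per module
    ranksum_stat: float
    ranksum_p: float                 # one-sided: observed p < permuted p


def permutation_compare(met_lines: pd.DataFrame, pc1: pd.DataFrame,
                        n_perm: int = 100, seed: int = 0
                        ) -> PermutationComparison:
    """Observed vs permutation-null regression p-values.

    Per permutation, each module's PC1 scores are independently
    permuted across lines and all regressions recomputed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = regress_on_pc1(met_lines, pc1)
    common = met_lines.index.intersection(pc1.index)
    perm_frames = []
    for _ in range(n_perm):
        shuffled = pd.DataFrame(
            {mod: pc1.loc[common, mod].to_numpy()[rng.permutation(len(common))]
             for mod in pc1.columns}, index=common)
        perm_frames.append(regress_on_pc1(met_lines.loc[common], shuffled))
    permuted = pd.concat(perm_frames, ignore_index=True)

    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    rows = []
    for mod in pc1.columns:
        po = observed.loc[observed["gcoe"] == mod, "p"].dropna().to_numpy()
        pp = permuted.loc[permuted["gcoe"] == mod, "p"].dropna().to_numpy()
        rows.append([mod] + [float(np.quantile(po, q)) if po.size else np.nan
                             for q in qs]
                    + [float(np.quantile(pp, q)) if pp.size else np.nan
                       for q in qs])
    per_module = pd.DataFrame(
        rows, columns=["gcoe"] + [f"obs_q{int(q * 100)}" for q in qs]
        + [f"perm_q{int(q * 100)}" for q in qs])

    po_all = observed["p"].dropna().to_numpy()
    pp_all = permuted["p"].dropna().to_numpy()
    res = stats.mannwhitneyu(po_all, pp_all, alternative="less")
    return PermutationComparison(observed, pp_all, per_module,
                                 float(res.statistic), float(res.pvalue))
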