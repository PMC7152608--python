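"""Per-transcript negative-binomial GLMs over the time course.

Counts for transcript *t* in sample *s* are modelled as
``NB(mean = sf_s * mu_{t,s}, dispersion alpha_t)`` with
``log mu = X beta`` and the log size factor as offset.  Two tests are
run per transcript:

* an interaction screen comparing ``~ genotype + time + genotype:time``
  against ``~ genotype + time`` by likelihood-ratio test (transcripts
  with a genotype-by-time interaction are removed before pattern
  coding);
* Wald contrasts between adjacent time-level coefficients in
  ``~ genotype + time`` (differential expression between time points,
  controlling for genotype), Benjamini-Hochberg adjusted within each
  interval.

Dispersion is a per-transcript method-of-moments estimate shrunk toward
a gamma-GLM mean-dispersion trend (geometric mean with weight 0.5) — a
deliberately lean version of the empirical-Bayes machinery of dedicated
count-model packages, keeping the mean-dispersion structure that
matters for test calibration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._design import check_full_rank, design_matrix
from .containers import CountMatrix

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


# ---------------------------------------------------------------------------
# NB GLM engine
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    """One fitted negative-binomial GLM."""

    coefficients: np.ndarray
    cov: np.ndarray
    dispersion: float
    loglik: float
    converged: bool
    names: list | None = None


def nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion: float) -> float:
    """NB log-likelihood with mean/dispersion parameterization."""
    if dispersion < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / dispersion
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu))
                        + y * np.log(mu / (r + mu))))


def fit_nb_glm(y, X, offset=None, dispersion: float = 1e-8,
               max_iter: int = 100, tol: float = 1e-8) -> NBFit:
    """IRLS maximization of the NB log-likelihood with log link."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, float)
    if not np.isfinite(offset).all():
        raise ValueError("offsets must be finite")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")

    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    converged = False
    alpha = max(dispersion, 1e-12)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq((X.T * w) @ X, xtw @ z, rcond=None)[0]
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return NBFit(beta, cov, alpha, nb_loglik(y, mu, alpha), converged)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(cm: CountMatrix, sf: pd.Series,
                         design_factors=("line", "daa")) -> pd.Series:
    """Per-transcript dispersions: method of moments shrunk to a trend.

    The raw estimate comes from within-cell residual variance of
    depth-normalized counts (cells = unique combinations of
    ``design_factors``): ``alpha = (s2 - xim * mu) / mu^2`` with ``xim``
    the mean reciprocal size factor.  A gamma-GLM trend
    ``alpha ~ a0 + a1 / mu`` is fitted across transcripts and the final
    value is the geometric mean of the raw and trend estimates, floored
    at 1e-8.
    """
    md = cm.metadata
    X, names = design_matrix(md, [f for f in design_factors])
    check_full_rank(X, names)
    cells = md.groupby(list(design_factors), sort=True, observed=True).indices
    n = cm.n_samples
    n_cells = sum(1 for idx in cells.values() if len(idx) >= 1)
    resid_df = n - n_cells
    if resid_df < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    q = cm.counts.to_numpy(float) / sf.loc[cm.sample_ids].to_numpy()[None, :]
    mu_bar = q.mean(axis=1)
    ss = np.zeros(cm.n_transcripts)
    for idx in cells.values():
        idx = np.asarray(idx)
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / resid_df
    xim = float(np.mean(1.0 / sf.to_numpy()))

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - xim * mu_bar) / mu_bar ** 2
    raw = np.where(np.isfinite(raw), raw, DISPERSION_FLOOR)
    raw = np.clip(raw, DISPERSION_FLOOR, DISPERSION_CEIL)

    trend = _dispersion_trend(mu_bar, raw)
    final = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))
    final = np.clip(final, DISPERSION_FLOOR, DISPERSION_CEIL)
    return pd.Series(final, index=cm.transcript_ids, name="dispersion")


def _dispersion_trend(mu_bar: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Gamma-GLM fit of raw dispersions on 1/mean (identity link)."""
    use = (raw > DISPERSION_FLOOR * 10) & (mu_bar > 0)
    fallback = float(np.median(raw[use])) if use.any() else float(np.median(raw))
    fallback = max(fallback, DISPERSION_FLOOR)
    pred = np.full(mu_bar.shape, fallback)
    if use.sum() >= 10:
        try:
            import warnings

            import statsmodels.api as sm

            xmat = np.column_stack([np.ones(use.sum()), 1.0 / mu_bar[use]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(raw[use], xmat,
                               family=sm.families.Gamma(
                                   sm.families.links.Identity()))
                res = model.fit(start_params=[fallback, 1.0], maxiter=100)
            a0, a1 = res.params
            if a0 > 0 and np.isfinite(a0) and np.isfinite(a1):
                with np.errstate(divide="ignore"):
                    cand = a0 + a1 / mu_bar
                pred = np.where((cand > 0) & np.isfinite(cand), cand, fallback)
        except Exception:
            pass
    return np.clip(pred, DISPERSION_FLOOR, DISPERSION_CEIL)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _offsets(sf: pd.Series, cm: CountMatrix) -> np.ndarray:
    return np.log(sf.loc[cm.sample_ids].to_numpy(float))


def interaction_lrt(cm: CountMatrix, sf: pd.Series, alpha: float = 0.1,
                    dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Genotype-by-time interaction screen (likelihood-ratio test).

    Returns a table with the LRT statistic, chi-squared p-value on
    ``(G - 1)(T - 1)`` degrees of freedom, BH-adjusted p-value and a
    removal flag at FDR ``alpha``.
    """
    md = cm.metadata
    n_geno = md["line"].nunique()
    n_time = md["daa"].nunique()
    df = (n_geno - 1) * (n_time - 1)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, sf)
    off = _offsets(sf, cm)
    Xr, names_r = design_matrix(md, ["line", "daa"])
    if df > 0:
        Xf, names_f = design_matrix(md, ["line", "daa", "line:daa"])
        check_full_rank(Xf, names_f)
        counts_per_cell = md.groupby(["line", "daa"], observed=True).size()
        if (counts_per_cell < 1).any():
            raise ValueError("full model needs every genotype x time cell observed")
    else:
        Xf = Xr

    rows = []
    counts = cm.counts.to_numpy(float)
    for i, tid in enumerate(cm.transcript_ids):
        disp = float(dispersions.iloc[i])
        if df == 0:
            rows.append((tid, 0.0, df, 1.0))
            continue
        fr = fit_nb_glm(counts[i], Xr, off, disp)
        ff = fit_nb_glm(counts[i], Xf, off, disp)
        if not (fr.converged and ff.converged):
            rows.append((tid, np.nan, df, np.nan))
            continue
        stat = max(0.0, 2.0 * (ff.loglik - fr.loglik))
        p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
        rows.append((tid, stat, df, p))
    out = pd.DataFrame(rows, columns=["transcript_id", "stat", "df", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["flagged"] = out["padj"] < alpha
    return out.set_index("transcript_id")


def adjacent_contrasts(cm: CountMatrix, sf: pd.Series, alpha: float = 0.05,
                       dispersions: pd.Series | None = None) -> dict:
    """Wald contrasts between adjacent time points, per transcript.

    Fits ``~ genotype + time`` once per transcript and tests the
    difference of consecutive time-level coefficients; the sign of
    log2fc is later minus earlier.  Returns ``{interval_label:
    DataFrame(log2fc, se, stat, p, padj)}`` with BH adjustment within
    each interval.
    """
    md = cm.metadata
    times = sorted(md["daa"].unique())
    if len(times) < 2:
        raise ValueError("need at least two time levels")
    intervals = [f"{a}-{b}" for a, b in zip(times, times[1:])]
    if dispersions is None:
        dispersions = estimate_dispersions(cm, sf)
    off = _offsets(sf, cm)
    X, names = design_matrix(md, ["line", "daa"])
    check_full_rank(X, names)
    # index of each time level's coefficient; reference level -> None
    time_cols = {t: (names.index(f"daa[{t}]") if f"daa[{t}]" in names else None)
                 for t in times}

    ln2 = np.log(2.0)
    counts = cm.counts.to_numpy(float)
    per_interval: dict = {lab: [] for lab in intervals}
    for i, tid in enumerate(cm.transcript_ids):
        fit = fit_nb_glm(counts[i], X, off, float(dispersions.iloc[i]))
        for (t0, t1), lab in zip(zip(times, times[1:]), intervals):
            if not fit.converged:
                per_interval[lab].append((tid, np.nan, np.nan, np.nan, np.nan))
                continue
            c = np.zeros(X.shape[1])
            if time_cols[t1] is not None:
                c[time_cols[t1]] += 1.0
            if time_cols[t0] is not None:
                c[time_cols[t0]] -= 1.0
            diff = float(c @ fit.coefficients)
            var = float(c @ fit.cov @ c)
            se = np.sqrt(max(var, 0.0))
            if se == 0:
                per_interval[lab].append((tid, np.nan, np.nan, np.nan, np.nan))
                continue
            stat = diff / se
            p = 2.0 * float(stats.norm.sf(abs(stat)))
            per_interval[lab].append((tid, diff / ln2, se / ln2, stat, p))

    out = {}
    for lab in intervals:
        tab = pd.DataFrame(per_interval[lab],
                           columns=["transcript_id", "log2fc", "se", "stat", "p"]
                           ).set_index("transcript_id")
        tab["padj"] = bh_adjust(tab["p"].to_numpy())
        out[lab] = tab
    return out
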