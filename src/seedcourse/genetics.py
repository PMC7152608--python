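"""Genomic relationships and variance-component estimation.

The central model is a one-random-effect mixed model for a per-line
trait y (a module's PC1 score):

    y = mu + u + e,   u ~ N(0, K sigma_u^2),   e ~ N(0, I sigma_e^2)

with K the genomic relationship matrix (GRM).  Heritability is
``h2 = sigma_u^2 / (sigma_u^2 + sigma_e^2)``.  The model is fitted by
REML, profiling the variance ratio ``lambda = sigma_u^2 / sigma_e^2``
after a one-off eigendecomposition of K, and the null
``sigma_u^2 = 0`` is assessed by likelihood-ratio test against the
boundary-corrected 0.5 chi2(0) + 0.5 chi2(1) mixture (plain chi2(1) is
available behind a flag).

Metabolite heritability uses the all-random randomized-complete-block
model ``~ Line + Location + Location/Replication + Location:Line``
fitted by EM-REML, with
``h2 = sL2 / (sL2 + sLxLoc2 / n_loc + se2 / (n_loc * n_rep))``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG10_RATIO_BOUNDS = (-6.0, 6.0)


def grm_vanraden(genotypes) -> pd.DataFrame:
    """GRM from 0/1/2 dosages: centered cross-product over Sum 2p(1-p)."""
    if isinstance(genotypes, pd.DataFrame):
        lines = genotypes.index
        M = genotypes.to_numpy(float)
    else:
        M = np.asarray(genotypes, float)
        lines = pd.Index([f"L{i + 1}" for i in range(M.shape[0])])
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (M.var(axis=0) > 0)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers for a GRM")
    Mc = M[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    G = (Mc @ Mc.T) / denom
    G = (G + G.T) / 2.0
    return pd.DataFrame(G, index=lines, columns=lines)


@dataclass
class H2Estimate:
    """REML fit of the one-random-effect model for a per-line trait."""

    sigma_u2: float
    sigma_e2: float
    h2: float
    lrt_stat: float
    p: float
    loglik_full: float = np.nan
    loglik_reduced: float = np.nan


def _reml_profile(lam: float, d: np.ndarray, xt: np.ndarray,
                  yt: np.ndarray) -> tuple:
    """Profiled restricted log-likelihood at variance ratio ``lam``.

    Works in the eigenbasis of K: V = sigma_e^2 (lam D + I).
    """
    n = yt.size
    v = lam * d + 1.0
    xvx = float(np.sum(xt * xt / v))
    xvy = float(np.sum(xt * yt / v))
    yvy = float(np.sum(yt * yt / v))
    ypy = max(yvy - xvy ** 2 / xvx, 1e-300)
    sigma_e2 = ypy / (n - 1)
    ll = -0.5 * ((n - 1) * (np.log(2 * np.pi * sigma_e2) + 1.0)
                 + float(np.sum(np.log(v))) + np.log(xvx))
    return ll, sigma_e2


def _align(y, K):
    if isinstance(K, pd.DataFrame):
        Km = K.to_numpy(float)
        if isinstance(y, pd.Series):
            y = y.loc[K.index]
    else:
        Km = np.asarray(K, float)
    return np.asarray(y, float), Km


def estimate_h2(y, K, boundary_mixture: bool = True,
                grid_points: int = 121) -> H2Estimate:
    """REML heritability of a per-line trait under a GRM.

    The variance ratio is profiled on a log-spaced grid over
    ``[1e-6, 1e6]`` and refined by bounded scalar optimization; the LRT
    compares against the no-genetic-variance model (``lambda = 0``).
    """
    y, Km = _align(y, K)
    n = y.size
    if Km.shape != (n, n):
        raise ValueError("y length must match GRM dimension")
    if n < 3:
        raise ValueError("need at least 3 lines")
    if np.max(np.abs(Km - Km.T)) > 1e-8 * max(1.0, np.max(np.abs(Km))):
        raise ValueError("GRM must be symmetric")
    if np.std(y) < 1e-12 * (np.abs(y).mean() + 1.0):
        warnings.warn("trait is constant across lines; h2 set to 0")
        return H2Estimate(0.0, 0.0, 0.0, 0.0, 1.0)

    d, U = np.linalg.eigh((Km + Km.T) / 2.0)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError("GRM is not positive semi-definite")
    if d.min() < 1e-10:
        warnings.warn("GRM is singular; adding ridge 1e-6 to its spectrum")
        d = d + 1e-6
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    ll0, _ = _reml_profile(0.0, d, xt, yt)
    lo, hi = LOG10_RATIO_BOUNDS
    grid = np.logspace(lo, hi, grid_points)
    lls = np.array([_reml_profile(g, d, xt, yt)[0] for g in grid])
    i = int(np.argmax(lls))
    a = np.log10(grid[max(i - 1, 0)])
    b = np.log10(grid[min(i + 1, grid_points - 1)])
    res = optimize.minimize_scalar(
        lambda t: -_reml_profile(10.0 ** t, d, xt, yt)[0],
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-10})
    lam = float(10.0 ** res.x)
    ll_full, sigma_e2 = _reml_profile(lam, d, xt, yt)
    # improvements below float-noise level collapse to the boundary
    # (K = I makes the surface exactly flat; ties go to no genetics)
    if ll0 >= ll_full - 1e-8:
        lam, ll_full = 0.0, ll0
        _, sigma_e2 = _reml_profile(0.0, d, xt, yt)
    sigma_u2 = lam * sigma_e2
    h2 = lam / (1.0 + lam)
    lrt = max(0.0, 2.0 * (ll_full - ll0))
    if lrt <= 0:
        p = 1.0
    elif boundary_mixture:
        p = 0.5 * float(stats.chi2.sf(lrt, 1))
    else:
        p = float(stats.chi2.sf(lrt, 1))
    return H2Estimate(sigma_u2, sigma_e2, h2, lrt, p, ll_full, ll0)


def h2_permutation_null(lsm: pd.DataFrame, sets: dict, K: pd.DataFrame,
                        n_perm: int = 50, seed: int = 0) -> pd.DataFrame:
    """Permutation null for module heritability.

    Each permutation shuffles line identity of the lsmean matrix
    relative to the GRM (breaking genetics while keeping the expression
    covariance among transcripts), then re-runs subclustering, PC1
    extraction and REML per set.  ``sets`` maps tcoe_id -> (member
    transcript list, k).  Returns long rows (perm, tcoe_id, gcoe_id,
    h2).
    """
    from .gcoe import pc1_scores, subcluster

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_perm):
        perm = rng.permutation(len(lsm))
        shuffled = pd.DataFrame(lsm.to_numpy()[perm], index=lsm.index,
                                columns=lsm.columns)
        for tcoe_id, (members, k) in sets.items():
            labels = subcluster(shuffled, members, k)
            for g in sorted(labels.unique()):
                mem = labels.index[labels == g]
                scores, _ = pc1_scores(shuffled, mem)
                est = estimate_h2(scores, K)
                rows.append((b, tcoe_id, int(g), est.h2))
    return pd.DataFrame(rows, columns=["perm", "tcoe_id", "gcoe_id", "h2"])


# ---------------------------------------------------------------------------
# metabolite heritability
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteH2:
    h2: float
    components: dict
    converged: bool


def _incidence(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def ems_components(df: pd.DataFrame) -> dict:
    """Method-of-moments (expected-mean-squares) variance components.

    Exact for the balanced two-location randomized-complete-block
    layout; used as EM starting values and as a cross-check for
    balanced fixtures.
    """
    y = df["value"].to_numpy(float)
    a = df["line"].nunique()
    b = df["location"].nunique()
    r = df["replicate"].nunique()
    grand = y.mean()
    m_line = df.groupby("line", observed=True)["value"].mean()
    m_loc = df.groupby("location", observed=True)["value"].mean()
    m_lr = df.groupby(["location", "replicate"], observed=True)["value"].mean()
    m_ll = df.groupby(["line", "location"], observed=True)["value"].mean()

    ss_line = b * r * ((m_line - grand) ** 2).sum()
    ss_loc = a * r * ((m_loc - grand) ** 2).sum()
    ss_lr = a * ((m_lr - m_loc.reindex(
        m_lr.index.get_level_values(0)).to_numpy()) ** 2).sum()
    ll_expect = (m_line.reindex(m_ll.index.get_level_values(0)).to_numpy()
                 + m_loc.reindex(m_ll.index.get_level_values(1)).to_numpy()
                 - grand)
    ss_ll = r * ((m_ll.to_numpy() - ll_expect) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_e = ss_tot - ss_line - ss_loc - ss_lr - ss_ll

    ms_line = ss_line / (a - 1)
    ms_loc = ss_loc / (b - 1) if b > 1 else 0.0
    ms_lr = ss_lr / (b * (r - 1)) if r > 1 else 0.0
    ms_ll = ss_ll / ((a - 1) * (b - 1)) if b > 1 else 0.0
    df_e = (a - 1) * b * (r - 1)
    ms_e = ss_e / df_e if df_e > 0 else 0.0

    s_e = ms_e
    s_ll = (ms_ll - ms_e) / r
    s_line = (ms_line - ms_ll) / (b * r)
    s_lr = (ms_lr - ms_e) / a
    s_loc = (ms_loc - ms_ll - ms_lr + ms_e) / (a * r)
    return {"line": max(s_line, 0.0), "location": max(s_loc, 0.0),
            "loc_rep": max(s_lr, 0.0), "loc_line": max(s_ll, 0.0),
            "residual": max(s_e, 0.0)}


def metabolite_h2(df: pd.DataFrame, max_iter: int = 500,
                  tol: float = 1e-6) -> MetaboliteH2:
    """Design-based heritability of one metabolite by EM-REML.

    ``df`` holds one row per plot with columns ``line, location,
    replicate, value``.  All terms of ``~ Line + Location +
    Location/Replication + Location:Line`` are random;
    ``h2 = sL2 / (sL2 + sLxLoc2 / n_loc + se2 / (n_loc * n_rep))``.
    """
    for col in ("line", "location", "replicate", "value"):
        if col not in df.columns:
            raise ValueError(f"metabolite table lacks column {col!r}")
    a = df["line"].nunique()
    b = df["location"].nunique()
    r = df["replicate"].nunique()
    if a < 2 or b < 2 or r < 1:
        raise ValueError("need >= 2 lines, >= 2 locations and >= 1 replicate")
    if df.groupby(["line", "location"], observed=True).size().max() < 1:
        raise ValueError("design completely confounded")

    y = df["value"].to_numpy(float)
    n = y.size
    line_c = pd.Categorical(df["line"]).codes
    loc_c = pd.Categorical(df["location"]).codes
    lr_c = pd.Categorical(df["location"].astype(str) + ":"
                          + df["replicate"].astype(str)).codes
    ll_c = pd.Categorical(df["location"].astype(str) + ":"
                          + df["line"].astype(str)).codes
    Zs = {"line": _incidence(line_c, line_c.max() + 1),
          "location": _incidence(loc_c, loc_c.max() + 1),
          "loc_rep": _incidence(lr_c, lr_c.max() + 1),
          "loc_line": _incidence(ll_c, ll_c.max() + 1)}
    X = np.ones((n, 1))

    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        return MetaboliteH2(0.0, {k: 0.0 for k in list(Zs) + ["residual"]},
                            True)
    start = ems_components(df)
    floor = 1e-8 * vary
    sig = {k: max(start.get(k, 0.0), 0.05 * vary) for k in Zs}
    sig_e = max(start.get("residual", vary), 0.05 * vary)

    converged = False
    for _ in range(max_iter):
        V = sig_e * np.eye(n)
        for k, Z in Zs.items():
            V += sig[k] * (Z @ Z.T)
        Vinv = np.linalg.inv(V)
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        Py = P @ y
        new = {}
        for k, Z in Zs.items():
            q = Z.shape[1]
            ZtPy = Z.T @ Py
            tr = float(np.trace(Z.T @ P @ Z))
            new[k] = sig[k] + sig[k] ** 2 / q * (float(ZtPy @ ZtPy) - tr)
            new[k] = max(new[k], floor)
        new_e = sig_e + sig_e ** 2 / n * (float(Py @ Py) - float(np.trace(P)))
        new_e = max(new_e, floor)
        delta = max(abs(new[k] - sig[k]) for k in sig)
        delta = max(delta, abs(new_e - sig_e))
        sig, sig_e = new, new_e
        if delta < tol * vary:
            converged = True
            break

    comps = {k: (0.0 if sig[k] <= 2 * floor else float(sig[k])) for k in sig}
    comps["residual"] = 0.0 if sig_e <= 2 * floor else float(sig_e)
    denom = (comps["line"] + comps["loc_line"] / b
             + comps["residual"] / (b * r))
    h2 = comps["line"] / denom if denom > 0 else 0.0
    return MetaboliteH2(float(np.clip(h2, 0.0, 1.0)), comps, converged)
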