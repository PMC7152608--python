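"""Discrete temporal pattern coding and its permutation null.

Each differentially expressed transcript (DET) is coded as a string of
one character per adjacent time interval: ``u`` (significantly up),
``d`` (significantly down) or ``0`` (no significant change).  With five
intervals there are ``3^5 = 243`` possible codes; transcripts coded all
zero are not DETs and are excluded.  A temporal co-expression (TCoE) set
is simply all DETs sharing one code.

The permutation null shuffles each interval's character column
independently across transcripts: per-interval marginal counts of
u/d/0 are preserved exactly while any dependence between intervals is
destroyed.  Observed statistics (number of distinct patterns, top-k
mass, monotone fraction, down-then-up fraction among direction
reversers) are compared against the null extrema and quantiles.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHABET = ("u", "d", "0")
NULL_CHAR = "0"


def encode_patterns(de_tables: dict, alpha: float = 0.05) -> pd.Series:
    """Code transcripts from per-interval DE tables.

    ``de_tables`` maps interval label -> DataFrame indexed by transcript
    with columns ``log2fc`` and ``padj``.  Character i is ``u`` if
    ``padj < alpha`` and ``log2fc > 0``, ``d`` if ``padj < alpha`` and
    ``log2fc < 0``, else ``0``.  Transcripts missing from any interval
    (e.g. non-converged fits) and transcripts coded all-zero are
    excluded.
    """
    labels = list(de_tables)
    common = None
    for lab in labels:
        tab = de_tables[lab]
        idx = tab.index[tab["padj"].notna() & tab["log2fc"].notna()]
        common = idx if common is None else common.intersection(idx)
    chars = np.full((len(common), len(labels)), NULL_CHAR, dtype="<U1")
    for j, lab in enumerate(labels):
        tab = de_tables[lab].loc[common]
        sig = tab["padj"].to_numpy() < alpha
        up = sig & (tab["log2fc"].to_numpy() > 0)
        down = sig & (tab["log2fc"].to_numpy() < 0)
        chars[up, j] = "u"
        chars[down, j] = "d"
    codes = pd.Series(["".join(row) for row in chars], index=common,
                      name="pattern")
    return codes[codes != NULL_CHAR * len(labels)]


def enumerate_patterns(codes):
    """Frequency table of observed codes plus the theoretical count.

    Returns ``(table, theoretical)`` where the table has columns
    ``code, n_transcripts, rank`` sorted by descending count with
    lexicographic tie-break, and ``theoretical = 3^k`` for k intervals.
    """
    codes = pd.Series(codes)
    k = len(codes.iloc[0]) if len(codes) else 0
    counts = codes.value_counts()
    table = counts.rename_axis("code").reset_index(name="n_transcripts")
    table = table.sort_values(["n_transcripts", "code"],
                              ascending=[False, True], kind="mergesort",
                              ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table, 3 ** k


def top_mass(table: pd.DataFrame, k: int = 20) -> float:
    """Share of DETs held by the ``k`` most populous patterns."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = table["n_transcripts"].sum()
    if total == 0:
        return 0.0
    top = table.nsmallest(min(k, len(table)), "rank")["n_transcripts"].sum()
    return float(top / total)


def _nonzero(code: str) -> str:
    return code.replace(NULL_CHAR, "")


def direction_stats(codes):
    """(monotone fraction, down-then-up fraction among reversers).

    A code is monotone when its non-zero characters are all identical
    (the transcript only ever moves in one direction).  Among codes
    containing both ``u`` and ``d``, "down then up" means the first
    non-zero character is ``d``.
    """
    codes = list(codes)
    if not codes:
        return np.nan, np.nan
    nz = [_nonzero(c) for c in codes]
    monotone = sum(1 for s in nz if s and len(set(s)) == 1)
    reversers = [s for s in nz if "u" in s and "d" in s]
    down_up = sum(1 for s in reversers if s[0] == "d")
    mono_frac = monotone / len(codes)
    du_frac = down_up / len(reversers) if reversers else np.nan
    return mono_frac, du_frac


def mirror_code(code: str) -> str:
    """Swap ``u`` and ``d`` per character (self-inverse)."""
    return code.translate(str.maketrans("ud", "du"))


def symmetry_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of each up-leading code against its mirrored code.

    Every observed pair is reported once, keyed by the member whose
    first non-zero character is ``u``; columns ``code, mirror, n_up,
    n_down``.
    """
    counts = dict(zip(table["code"], table["n_transcripts"]))
    rows = []
    for code in counts:
        nz = _nonzero(code)
        if not nz or nz[0] != "u":
            continue
        m = mirror_code(code)
        rows.append((code, m, counts[code], counts.get(m, 0)))
    return pd.DataFrame(rows, columns=["code", "mirror", "n_up", "n_down"])


def all_codes(k: int = 5, include_null: bool = False) -> list:
    """All 3^k codes (optionally including the all-zero non-DET code)."""
    out = ["".join(c) for c in itertools.product(ALPHABET, repeat=k)]
    if not include_null:
        out = [c for c in out if c != NULL_CHAR * k]
    return out


@dataclass
class PatternNullResult:
    """Null distributions from interval-wise column shuffling."""

    observed: dict
    null: pd.DataFrame  # one row per permutation, one column per statistic

    def summary(self) -> pd.DataFrame:
        """min/max/mean and empirical tail probabilities per statistic.

        ``p_le``/``p_ge`` are the add-one-smoothed fractions of
        permutations with a statistic <=/>= the observed value.
        """
        rows = []
        n = len(self.null)
        for stat, obs in self.observed.items():
            col = self.null[stat].to_numpy()
            ok = ~np.isnan(col)
            m = ok.sum()
            p_le = (np.sum(col[ok] <= obs) + 1) / (m + 1) if m else np.nan
            p_ge = (np.sum(col[ok] >= obs) + 1) / (m + 1) if m else np.nan
            rows.append((stat, obs, np.nanmin(col) if m else np.nan,
                         np.nanmax(col) if m else np.nan,
                         np.nanmean(col) if m else np.nan, p_le, p_ge))
        return pd.DataFrame(rows, columns=["statistic", "observed", "null_min",
                                           "null_max", "null_mean",
                                           "p_le", "p_ge"])


def _stats_of(codes: list, top_k: int) -> dict:
    table, _ = enumerate_patterns(codes)
    mono, du = direction_stats(codes)
    return {
        "n_distinct_patterns": float(len(table)),
        "top_k_mass": top_mass(table, top_k) if len(table) else np.nan,
        "monotone_fraction": mono,
        "down_then_up_fraction": du,
    }


def permutation_null(codes, n_perm: int = 1000, top_k: int = 20,
                     seed: int = 0) -> PatternNullResult:
    """Interval-independence null for the pattern statistics.

    Each permutation independently shuffles every interval's character
    column across transcripts; codes that become all-zero drop out of
    that permutation's DET universe (matching the observed universe's
    definition).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = list(codes)
    chars = np.array([list(c) for c in codes])
    n, k = chars.shape
    rng = np.random.default_rng(seed)
    observed = _stats_of(codes, top_k)
    rows = []
    null_code = NULL_CHAR * k
    for _ in range(n_perm):
        perm = chars.copy()
        for j in range(k):
            perm[:, j] = perm[rng.permutation(n), j]
        pcodes = ["".join(row) for row in perm]
        pcodes = [c for c in pcodes if c != null_code]
        rows.append(_stats_of(pcodes, top_k))
    return PatternNullResult(observed, pd.DataFrame(rows))
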