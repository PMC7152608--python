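"""Treatment-coded design matrices built from the sample metadata table.

Factors are coded with the first (sorted) level as reference.  The
replication-within-location term (``loc_rep``) is coded nested: for each
location, dummies for every replicate beyond that location's first.
Interaction terms use products of the two factors' non-reference dummies.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _levels(md: pd.DataFrame, col: str) -> list:
    if col not in md.columns:
        raise KeyError(f"metadata lacks column {col!r}")
    return sorted(pd.unique(md[col]))


def design_matrix(md: pd.DataFrame, terms: Sequence[str]):
    """Return ``(X, names)`` for an intercept + the requested terms.

    Supported terms: any metadata column (categorical, drop-first),
    ``"loc_rep"`` for replication nested in location, and ``"a:b"`` for a
    two-factor interaction.
    """
    n = len(md)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in terms:
        if term == "loc_rep":
            for loc in _levels(md, "location"):
                in_loc = (md["location"] == loc).to_numpy()
                reps = sorted(pd.unique(md.loc[md["location"] == loc, "replicate"]))
                for rep in reps[1:]:
                    cols.append((in_loc & (md["replicate"] == rep).to_numpy())
                                .astype(float))
                    names.append(f"loc_rep[{loc}:{rep}]")
        elif ":" in term:
            a, b = term.split(":")
            for la in _levels(md, a)[1:]:
                da = (md[a] == la).to_numpy().astype(float)
                for lb in _levels(md, b)[1:]:
                    db = (md[b] == lb).to_numpy().astype(float)
                    cols.append(da * db)
                    names.append(f"{a}[{la}]:{b}[{lb}]")
        else:
            for lv in _levels(md, term)[1:]:
                cols.append((md[term] == lv).to_numpy().astype(float))
                names.append(f"{term}[{lv}]")
    X = np.column_stack(cols)
    return X, names


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise ``ValueError`` listing aliased columns if X is rank deficient."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # identify aliased columns greedily via QR on growing column sets
    aliased = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            aliased.append(names[j])
    raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")
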