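"""Data containers and plain-text I/O.

Everything the pipeline writes to disk is TSV so runs can be diffed and
versioned: the count matrix (transcripts in rows, header = sample IDs), a
sample metadata table, the genomic relationship matrix (line IDs as both
header and first column) and metabolite tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Required columns of the sample metadata table.
METADATA_COLUMNS = ["line", "location", "replicate", "daa"]


@dataclass
class CountMatrix:
    """Transcripts x samples tag-count matrix with aligned sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, transcript IDs in the index and
        sample IDs in the columns.
    metadata
        One row per sample (indexed by sample ID, or carrying a
        ``sample_id`` column) with at least the columns
        ``line, location, replicate, daa``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        md = self.metadata
        if "sample_id" in md.columns:
            md = md.set_index("sample_id")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate transcript IDs in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = self.counts.columns.difference(md.index)
        if len(missing):
            raise ValueError(
                f"samples absent from metadata: {sorted(missing)[:5]}"
            )
        absent = [c for c in METADATA_COLUMNS if c not in md.columns]
        if absent:
            raise ValueError(f"metadata lacks required columns: {absent}")
        # keep metadata aligned to (and restricted to) the count columns
        self.metadata = md.loc[self.counts.columns]

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def transcript_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)],
                           self.metadata.loc[list(sample_ids)])

    def subset_transcripts(self, transcript_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(transcript_ids)],
                           self.metadata)


@dataclass
class NormalizedMatrix:
    """Depth-normalized, variance-stabilized expression on a log2-like scale."""

    values: pd.DataFrame
    size_factors: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        self.size_factors = self.size_factors.loc[self.values.columns]
        md = self.metadata
        if "sample_id" in md.columns:
            md = md.set_index("sample_id")
        self.metadata = md.loc[self.values.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "NormalizedMatrix":
        ids = list(sample_ids)
        return NormalizedMatrix(self.values.loc[:, ids],
                                self.size_factors.loc[ids],
                                self.metadata.loc[ids])


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
    cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_counts(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts, metadata)


def write_matrix(values: pd.DataFrame, path, index_label: str = "id") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_grm(grm: pd.DataFrame, path) -> None:
    grm.to_csv(path, sep="\t", index_label="line")


def read_grm(path) -> pd.DataFrame:
    grm = pd.read_csv(path, sep="\t", index_col=0)
    grm.index = grm.index.astype(str)
    grm.columns = grm.columns.astype(str)
    if list(grm.index) != list(grm.columns):
        raise ValueError("GRM row and column labels disagree")
    return grm


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
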