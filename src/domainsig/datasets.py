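"""Gene-level count matrices with sample class labels.

The central container is :class:`CountDataset`: an integer gene x sample
count matrix (pandas DataFrame, genes on rows) together with a class label
per sample. Text round-trip goes through plain TSV so that datasets written
by the simulator can be re-read bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class CountDataset:
    """Integer gene x sample count matrix plus per-sample class labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; values must
        be non-negative integers.
    classes
        Series indexed by sample id giving each sample's class label; index
        must match the count matrix columns exactly (same order).
    """

    counts: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise InputError("duplicate gene ids in count matrix")
        if not self.counts.columns.equals(self.classes.index):
            raise InputError("sample ids of counts and classes differ")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise InputError("counts must be integers")
        if (vals < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def class_levels(self) -> list:
        """Distinct class labels in first-appearance order."""
        return list(dict.fromkeys(self.classes))

    def subset_genes(self, gene_ids) -> "CountDataset":
        return CountDataset(self.counts.loc[list(gene_ids)], self.classes)

    def subset_samples(self, sample_ids) -> "CountDataset":
        ids = list(sample_ids)
        return CountDataset(self.counts[ids], self.classes.loc[ids])

    # ------------------------------------------------------------------ I/O

    def write_counts_tsv(self, path) -> None:
        """Write the count matrix as TSV: gene_id index, sample-id header."""
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", lineterminator="\n")

    def write_classes_tsv(self, path) -> None:
        """Write sample classes as a two-column TSV (sample_id, class)."""
        df = pd.DataFrame(
            {"sample_id": self.classes.index, "class": self.classes.to_numpy()}
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a gene x sample count TSV written by :meth:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.astype(np.int64)


def read_classes_tsv(path) -> pd.Series:
    """Read a (sample_id, class) TSV into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "class"}.issubset(df.columns):
        raise InputError(f"{path}: expected columns sample_id, class")
    return pd.Series(df["class"].to_numpy(), index=pd.Index(df["sample_id"], name=None))


def read_count_dataset(counts_path, classes_path) -> CountDataset:
    """Assemble a :class:`CountDataset` from its two TSV files."""
    counts = read_counts_tsv(counts_path)
    classes = read_classes_tsv(classes_path)
    try:
        classes = classes.loc[counts.columns]
    except KeyError as exc:
        raise InputError("classes TSV is missing samples present in counts") from exc
    return CountDataset(counts, classes)


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    """Read a MatrixMarket count matrix with row/column name sidecar files."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray().astype(np.int64)
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise InputError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(samples)} samples"
        )
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
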