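"""Core expression containers and their on-disk formats.

Count and expression matrices are gene x patient pandas DataFrames wrapped
with the per-gene annotation the pipeline needs (chromosome labels for the
sex-linkage filter).  Counts round-trip through TSV and MatrixMarket;
expression matrices through TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "unknown"])


@dataclass
class CountMatrix:
    """Raw gene x patient read counts plus gene annotation.

    Parameters
    ----------
    values
        Non-negative integer counts, genes as rows (index = gene ids),
        patients as columns (columns = patient ids).
    chromosome
        Per-gene chromosome label: "1".."22", "X", "Y" or "unknown"
        (the latter marks features not mapped to a known gene).
    """

    values: pd.DataFrame
    chromosome: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate patient ids in count matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.chromosome = self.chromosome.reindex(self.values.index)
        labels = set(self.chromosome.dropna().unique())
        bad = labels - VALID_CHROMOSOMES
        if bad:
            raise ValueError(f"unknown chromosome labels: {sorted(bad)}")
        self.chromosome = self.chromosome.fillna("unknown")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[gene_ids], self.chromosome.loc[gene_ids])

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, counts_path, annotation_path) -> None:
        self.values.to_csv(counts_path, sep="\t", index_label="gene_id")
        ann = pd.DataFrame({"gene_id": self.gene_ids, "chromosome": self.chromosome.values})
        ann.to_csv(annotation_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, annotation_path) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotation_path, sep="\t", dtype={"chromosome": str})
        chrom = pd.Series(ann["chromosome"].values, index=ann["gene_id"].values)
        return cls(values, chrom)

    def to_mtx(self, directory) -> None:
        """Write MatrixMarket triple: matrix.mtx, genes.tsv, patients.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.csr_matrix(self.values.to_numpy()))
        ann = pd.DataFrame({"gene_id": self.gene_ids, "chromosome": self.chromosome.values})
        ann.to_csv(directory / "genes.tsv", sep="\t", index=False)
        pd.Series(self.patient_ids, name="patient_id").to_csv(
            directory / "patients.tsv", sep="\t", index=False
        )

    @classmethod
    def from_mtx(cls, directory) -> "CountMatrix":
        directory = Path(directory)
        mat = scipy.io.mmread(directory / "matrix.mtx")
        ann = pd.read_csv(directory / "genes.tsv", sep="\t", dtype={"chromosome": str})
        patients = pd.read_csv(directory / "patients.tsv", sep="\t")["patient_id"]
        values = pd.DataFrame(
            np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.int64),
            index=ann["gene_id"].values,
            columns=patients.values,
        )
        return cls(values, pd.Series(ann["chromosome"].values, index=ann["gene_id"].values))


@dataclass
class ExpressionMatrix:
    """Variance-stabilized gene x patient expression on a log2-like scale."""

    values: pd.DataFrame
    vst_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        meta = {"vst_params": list(self.vst_params) if self.vst_params else None}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = Path(str(path) + ".meta.json")
        params = None
        if meta_path.exists():
            raw = json.loads(meta_path.read_text()).get("vst_params")
            params = tuple(raw) if raw else None
        return cls(values, params)
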