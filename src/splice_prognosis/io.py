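"""Readers, writers and expression preprocessing.

All on-disk formats are plain text: tab-separated expression matrices
(features x samples), clinical tables (``sample_id``, ``time_days``,
``event``), two-column transcript-to-gene maps, standard GMT gene-set
files and FASTA.

Expression matrices are held as a thin validated wrapper around a pandas
DataFrame so that the unit (TPM vs raw counts) travels with the values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "FormatError",
    "read_expression",
    "write_expression",
    "aggregate_to_gene",
    "filter_by_mean_tpm",
    "quantile_strata",
    "read_clinical",
    "write_clinical",
    "read_transcript_gene_map",
    "read_gmt",
    "write_gmt",
    "read_fasta",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionMatrix:
    """A non-negative feature x sample expression matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    unit:
        ``"tpm"`` for within-sample normalized values, ``"count"`` for raw
        (integral) counts.
    """

    data: pd.DataFrame
    unit: str = "tpm"

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "count"):
            raise FormatError(f"unknown expression unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise FormatError("expression values must be finite and non-negative")
        if self.unit == "count" and not np.allclose(values, np.round(values)):
            raise FormatError("count matrix contains non-integral values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, feature_id: str) -> pd.Series:
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self.data.loc[feature_id]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[ids], unit=self.unit)


@dataclass
class ClinicalTable:
    """Per-sample right-censored follow-up: time in days and event flag."""

    data: pd.DataFrame  # columns: sample_id, time_days, event

    def __post_init__(self) -> None:
        required = ["sample_id", "time_days", "event"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        df = self.data[required].copy()
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        if not np.all(df["time_days"].to_numpy() > 0):
            raise FormatError("follow-up times must be strictly positive")
        ev = df["event"].to_numpy()
        if not np.all(np.isin(ev, (0, 1))):
            raise FormatError("event indicator must be 0 or 1")
        df["event"] = df["event"].astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def aligned(self, sample_ids: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        """Times and events in the order of ``sample_ids``."""
        indexed = self.data.set_index("sample_id")
        ids = list(sample_ids)
        missing = [s for s in ids if s not in indexed.index]
        if missing:
            raise KeyError(f"samples without clinical records: {missing[:5]}")
        sub = indexed.loc[ids]
        return sub["time_days"].to_numpy(float), sub["event"].to_numpy(int)


@dataclass
class GeneSetCollection:
    """Mapping of term id to (term name, set of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def name(self, term: str) -> str:
        return self.sets[term][0]


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, unit: str = "tpm") -> ExpressionMatrix:
    """Read a tab-separated feature x sample expression matrix.

    The first column holds feature ids, the header row sample ids.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate sample ids in header: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit=unit)


def write_expression(matrix: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write a matrix in the canonical TSV layout read by :func:`read_expression`."""
    df = matrix.data
    if matrix.unit == "count":
        df = df.astype(int)
        df.to_csv(path, sep="\t", index_label="feature_id")
    else:
        df.to_csv(path, sep="\t", index_label="feature_id", float_format=float_format)


def read_transcript_gene_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping transcript id to gene id (many-to-one)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise FormatError("transcript-gene map must have exactly two columns")
    tx, gene = df.columns
    if df[tx].duplicated().any():
        raise FormatError("a transcript maps to more than one gene")
    return dict(zip(df[tx], df[gene]))


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: term, description, then member genes."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: term has no genes")
            term, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"GMT line {lineno}: term {term!r} has an empty gene set")
            if term in sets:
                raise FormatError(f"GMT line {lineno}: duplicate term {term!r}")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection:
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA records as an id -> sequence mapping (order preserved)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


# ---------------------------------------------------------------------------
# preprocessing


def aggregate_to_gene(tx_matrix: ExpressionMatrix, tx_gene_map: Mapping[str, str]) -> ExpressionMatrix:
    """Sum transcript rows into gene rows.

    The gene's expression value is the sum of its transcripts' values in
    each sample. Gene order follows first appearance of each gene among
    the transcript rows.
    """
    unmapped = [t for t in tx_matrix.feature_ids if t not in tx_gene_map]
    if unmapped:
        raise KeyError(f"transcripts without gene mapping: {unmapped[:10]}")
    genes = [tx_gene_map[t] for t in tx_matrix.feature_ids]
    order = list(dict.fromkeys(genes))
    summed = tx_matrix.data.groupby(genes, sort=False).sum()
    summed = summed.loc[order]
    summed.index.name = tx_matrix.data.index.name
    return ExpressionMatrix(summed, unit=tx_matrix.unit)


def filter_by_mean_tpm(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep rows whose arithmetic mean is strictly above ``threshold``.

    The strict inequality means rows sitting exactly at the threshold are
    dropped. Row order is preserved.
    """
    if matrix.unit != "tpm":
        raise ValueError("mean-TPM filtering requires a TPM matrix")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = matrix.data.mean(axis=1) > threshold
    if not keep.any():
        warnings.warn("mean-TPM filter removed every feature", stacklevel=2)
    return ExpressionMatrix(matrix.data.loc[keep], unit=matrix.unit)


def quantile_strata(values: pd.Series, fraction: float = 0.25) -> tuple[list[str], list[str]]:
    """Split samples into top- and bottom-``fraction`` expression strata.

    Returns ``(high, low)`` sample-id lists, each of size
    ``floor(fraction * n)``. Ties at a stratum boundary are broken by
    stable input order, so the split is deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(values)
    k = int(np.floor(fraction * n))
    if k < 1 or n < int(np.ceil(1.0 / fraction)):
        raise ValueError(f"too few samples ({n}) for fraction {fraction}")
    order = np.argsort(values.to_numpy(), kind="stable")
    ids = np.asarray(values.index)
    low = list(ids[order[:k]])
    high = list(ids[order[-k:]])
    return high, low
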