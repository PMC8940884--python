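"""Flat-file I/O for the pipeline: count tables, sample metadata, trees, edge lists.

All tabular formats are TSV. Count tables are oriented samples-in-rows,
taxa-in-columns everywhere; on-disk files carry labels, never positions.
Trees are newick and are represented in memory as :class:`skbio.TreeNode`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "SampleMetadata",
    "FormatError",
    "DuplicateLabelError",
    "SchemaError",
    "PLANTS",
    "SAMPLE_TYPES",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "write_edge_list",
]

PLANTS = ("wheat", "faba_bean")
SAMPLE_TYPES = ("soil", "rhizosphere", "rhizoplane")


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


class DuplicateLabelError(FormatError):
    """Raised when sample or taxon labels are not unique."""


class SchemaError(FormatError):
    """Raised when a required column is missing from a metadata file."""


@dataclass
class CountTable:
    """A samples x taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique row labels.
    taxon_ids : sequence of str
        Unique column labels (ASV identifiers).
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integers.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise FormatError("counts must be integers")
        self.counts = counts.astype(np.int64).reshape(
            len(self.sample_ids), len(self.taxon_ids)
        )
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        for kind, labels in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if labels.count(x) > 1})
                raise DuplicateLabelError(f"duplicate {kind} ids: {dupes}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return CountTable(list(ids), list(self.taxon_ids), self.counts[idx])

    def select_taxa(self, ids: Sequence[str]) -> "CountTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in ids]
        return CountTable(list(self.sample_ids), list(ids), self.counts[:, idx])

    def presence(self) -> np.ndarray:
        """Boolean presence/absence matrix (count > 0)."""
        return self.counts > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample experimental annotations: plant, compartment, replicate."""

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.records
        required = {"plant", "sample_type", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise DuplicateLabelError(f"duplicate sample ids: {dupes}")
        bad_plant = set(df["plant"]) - set(PLANTS)
        if bad_plant:
            raise ValueError(f"unknown plant values: {sorted(bad_plant)}")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValueError(f"unknown sample_type values: {sorted(bad_type)}")
        reps = df["replicate"].astype(int)
        if (reps < 1).any():
            raise ValueError("replicate must be a positive integer")
        self.records = df.assign(replicate=reps)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.records.index]

    def group_labels(self, table: CountTable, factors: Sequence[str]) -> list[str]:
        """Per-sample composite group label ('wheat/rhizosphere') in table order."""
        self.validate_against(table)
        sub = self.records.loc[table.sample_ids, list(factors)].astype(str)
        return ["/".join(row) for row in sub.to_numpy()]

    def validate_against(self, table: CountTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def subset(self, **conditions) -> list[str]:
        """Sample ids matching all equality conditions, e.g. sample_type='soil'."""
        mask = np.ones(len(self.records), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.records[col] == val).to_numpy()
        return [str(s) for s in self.records.index[mask]]


def read_count_table(path) -> CountTable:
    """Read a TSV count table (first column sample ids, header taxon ids)."""
    if hasattr(path, "read"):
        path = _io.StringIO(path.read())
        header = path.readline()
        path.seek(0)
    else:
        with open(path) as fh:
            header = fh.readline()
    taxa_fields = header.rstrip("\n").split("\t")[1:]
    if len(set(taxa_fields)) != len(taxa_fields):
        dupes = sorted({t for t in taxa_fields if taxa_fields.count(t) > 1})
        raise DuplicateLabelError(f"duplicate taxon ids: {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    try:
        counts = df.to_numpy(dtype=np.float64) if df.size else np.empty(df.shape)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in count table {path}: {exc}") from exc
    if np.isnan(counts).any():
        raise FormatError(f"missing value in count table {path}")
    if np.any(counts != np.floor(counts)):
        raise FormatError(f"non-integer count in {path}")
    if (counts < 0).any():
        raise FormatError(f"negative count in {path}")
    return CountTable(
        [str(s) for s in df.index], [str(t) for t in df.columns], counts
    )


def write_count_table(table: CountTable, path) -> None:
    """Write a CountTable as TSV; lossless round trip with read_count_table."""
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV with columns sample_id, plant, sample_type, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise SchemaError(f"metadata file {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.records.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths default to 0."""
    try:
        if hasattr(path, "read"):
            tree = TreeNode.read(path, format="newick")
        else:
            tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse error hierarchy
        raise FormatError(f"cannot parse newick tree {path}: {exc}") from exc
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise FormatError("negative branch length in tree")
    leaves = [leaf.name for leaf in tree.tips()]
    if len(set(leaves)) != len(leaves):
        raise DuplicateLabelError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_edge_list(network, path) -> None:
    """Export a co-occurrence network as a Cytoscape-importable TSV edge list.

    Columns: source, target, coefficient (>= 6 significant digits), sign.
    """
    rows = [
        {
            "source": a,
            "target": b,
            "coefficient": float(f"{r:.8g}"),
            "sign": "positive" if r > 0 else "negative",
        }
        for a, b, r in network.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "coefficient", "sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
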