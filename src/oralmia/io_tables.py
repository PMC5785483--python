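"""Readers, writers and core data containers for on-disk pipeline artifacts.

Every reader validates strictly and raises :class:`ParseError` (naming the
offending line where possible) rather than coercing malformed input; every
writer/reader pair round-trips valid objects exactly (floats to full repr
precision).

Formats
-------
* OTU table: TSV, header ``otu_id <sample ids...> [taxonomy]``, integer
  counts, optional semicolon-separated lineage in the last column
  (classic QIIME-style flat table).
* Sample metadata: TSV with one row per sample; empty fields mean "absent".
* Phylogeny: Newick with branch lengths (quoted labels and arbitrary
  nesting supported; parsing backed by scikit-bio).
* Distance matrix: TSV with sample ids as both header row and first column.
* Networks: GraphML (via networkx) and a Cytoscape-ready edge-list TSV.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "GROUPS",
    "HABITATS",
    "CLINICAL_VARIABLES",
    "ParseError",
    "ValidationError",
    "OtuTable",
    "SampleRecord",
    "PhyloTree",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_graphml",
    "write_edge_list",
    "metadata_frame",
]

GROUPS = ("ASD", "control")
HABITATS = ("saliva", "plaque")
#: Clinical covariates carried in sample metadata, in canonical column order.
CLINICAL_VARIABLES = (
    "age",
    "bmi",
    "abc_score",
    "dmft",
    "dmfs",
    "pli",
    "gi",
    "bi",
    "bop",
    "pd",
)


class ParseError(ValueError):
    """Malformed on-disk input."""


class ValidationError(ValueError):
    """In-memory object violates a container invariant."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Integer count matrix (OTUs x samples) with optional taxonomy lineages.

    Parameters
    ----------
    otu_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integers; every sample must contain at least one read.
    taxonomy : mapping of otu_id -> lineage
        Semicolon-joined ``phylum;class;order;family;genus;species`` prefix;
        any suffix may be absent. Keys must be a subset of ``otu_ids``.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.counts.size and (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.counts.size and (self.counts.sum(axis=0) == 0).any():
            empty = [
                s
                for s, tot in zip(self.sample_ids, self.counts.sum(axis=0))
                if tot == 0
            ]
            raise ValidationError(f"samples with zero total count: {empty}")
        unknown = set(self.taxonomy) - set(self.otu_ids)
        if unknown:
            raise ValidationError(f"taxonomy keys not in otu_ids: {sorted(unknown)}")
        self._otu_index = {o: i for i, o in enumerate(self.otu_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by OTU id, columns = sample ids."""
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def sample_counts(self, sample_id: str) -> pd.Series:
        """One sample's counts as a Series indexed by OTU id."""
        return pd.Series(
            self.counts[:, self._sample_index[sample_id]],
            index=self.otu_ids,
            name=sample_id,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return OtuTable(
            self.otu_ids, list(sample_ids), self.counts[:, idx], dict(self.taxonomy)
        )

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = [self._otu_index[o] for o in otu_ids]
        return OtuTable(
            list(otu_ids),
            self.sample_ids,
            self.counts[idx, :],
            {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy},
        )


def read_otu_table(path: str | Path) -> OtuTable:
    """Parse a TSV OTU table; see module docstring for the dialect."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}:1: header must name at least one sample")
    if header[0] not in ("otu_id", "#OTU ID", "OTU_ID"):
        raise ParseError(f"{path}:1: first header field must be 'otu_id', got {header[0]!r}")
    has_tax = header[-1].lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    ncol = len(header)
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    taxonomy: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ParseError(
                f"{path}:{lineno}: expected {ncol} fields, got {len(parts)}"
            )
        otu = parts[0]
        if otu in taxonomy or otu in otu_ids:
            raise ParseError(f"{path}:{lineno}: duplicate OTU id {otu!r}")
        raw = parts[1:-1] if has_tax else parts[1:]
        row = []
        for sample, cell in zip(sample_ids, raw):
            try:
                value = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"for OTU {otu!r}, sample {sample!r}"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}:{lineno}: negative count {value} "
                    f"for OTU {otu!r}, sample {sample!r}"
                )
            row.append(value)
        otu_ids.append(otu)
        rows.append(row)
        if has_tax and parts[-1]:
            taxonomy[otu] = parts[-1]
    try:
        return OtuTable(otu_ids, list(sample_ids), np.asarray(rows, dtype=np.int64), taxonomy)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for i, otu in enumerate(table.otu_ids):
            counts = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{otu}\t{counts}\t{table.taxonomy.get(otu, '')}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """Per-sample labels and clinical covariates.

    ``group`` and ``habitat`` come from closed vocabularies; clinical indices
    are non-negative when present and ``None`` when absent (``abc_score`` is
    recorded for ASD subjects only).
    """

    sample_id: str
    subject_id: str
    group: str
    habitat: str
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    abc_score: float | None = None
    dmft: float | None = None
    dmfs: float | None = None
    pli: float | None = None
    gi: float | None = None
    bi: float | None = None
    bop: float | None = None
    pd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group {self.group!r} not in {GROUPS}"
            )
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"sample {self.sample_id!r}: habitat {self.habitat!r} not in {HABITATS}"
            )
        for name in CLINICAL_VARIABLES:
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name}={value!r} must be >= 0"
                )


#: Canonical metadata column order.
META_COLUMNS = ("sample_id", "subject_id", "group", "habitat", "age", "sex") + tuple(
    v for v in CLINICAL_VARIABLES if v not in ("age",)
)


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Parse a metadata TSV into validated :class:`SampleRecord` rows."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    missing = [c for c in ("sample_id", "subject_id", "group", "habitat") if c not in header]
    if missing:
        raise ParseError(f"{path}:1: missing required columns {missing}")
    records: list[SampleRecord] = []
    known = {f.name for f in fields(SampleRecord)}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        kwargs: dict[str, object] = {}
        for col, cell in zip(header, parts):
            if col not in known:
                continue
            if col in ("sample_id", "subject_id", "group", "habitat", "sex"):
                kwargs[col] = cell if cell != "" else None
            else:
                if cell == "":
                    kwargs[col] = None
                else:
                    try:
                        kwargs[col] = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric value {cell!r} for {col!r}"
                        ) from None
        try:
            records.append(SampleRecord(**kwargs))  # type: ignore[arg-type]
        except (ValidationError, TypeError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(META_COLUMNS) + "\n")
        for rec in records:
            cells = []
            for col in META_COLUMNS:
                value = getattr(rec, col)
                cells.append("" if value is None else (repr(value) if isinstance(value, float) else str(value)))
            fh.write("\t".join(cells) + "\n")


def metadata_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample id (None -> NaN)."""
    df = pd.DataFrame([{c: getattr(r, c) for c in META_COLUMNS} for r in records])
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Rooted tree with branch lengths whose leaves are OTU ids.

    Thin validated wrapper around a :class:`skbio.TreeNode`; the wrapped root
    is available as :attr:`root` for traversal.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        leaves = [tip.name for tip in root.tips()]
        if len(leaves) != len(set(leaves)):
            raise ValidationError("duplicate leaf labels in tree")
        if any(name is None for name in leaves):
            raise ValidationError("unlabelled leaf in tree")
        for node in root.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")
        self.leaf_names: list[str] = leaves

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            root = TreeNode.read(io.StringIO(text))
        except Exception as exc:  # skbio raises format-specific errors
            raise ParseError(f"invalid Newick: {exc}") from exc
        return cls(root)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue()

    def __len__(self) -> int:
        return len(self.leaf_names)

    def branch_leaf_matrix(
        self, otu_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Branch lengths and branch x OTU incidence for the given leaf order.

        Returns ``(lengths, incidence)`` where row ``b`` covers one non-root
        node and ``incidence[b, i]`` is True iff ``otu_ids[i]`` is a leaf of
        the subtree below that branch.  Every ``otu_id`` must be a tree leaf.
        """
        index = {o: i for i, o in enumerate(otu_ids)}
        missing = [o for o in otu_ids if o not in set(self.leaf_names)]
        if missing:
            raise ValidationError(f"OTUs absent from tree: {missing[:5]}")
        n = len(otu_ids)
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        membership: dict[int, np.ndarray] = {}
        for node in self.root.postorder(include_self=True):
            if node.is_tip():
                row = np.zeros(n, dtype=bool)
                if node.name in index:
                    row[index[node.name]] = True
            else:
                row = np.zeros(n, dtype=bool)
                for child in node.children:
                    row |= membership[id(child)]
            membership[id(node)] = row
            if node is not self.root:
                lengths.append(float(node.length))
                rows.append(row)
        return np.asarray(lengths, dtype=float), np.vstack(rows) if rows else np.zeros((0, n), bool)


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix over samples with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValidationError("matrix shape does not match sample ids")
        if (self.data < 0).any():
            raise ValidationError("negative distances")
        if not np.allclose(self.data, self.data.T, atol=1e-12, rtol=0):
            raise ValidationError("matrix not symmetric within 1e-12")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise ValidationError("nonzero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.data[i, j])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\t" + "\t".join(dm.sample_ids) + "\n")
        for sid, row in zip(dm.sample_ids, dm.data):
            fh.write(sid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    ids = lines[0].split("\t")[1:]
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(ids) + 1:
            raise ParseError(f"{path}:{lineno}: ragged row")
        rows.append([float(x) for x in parts[1:]])
    try:
        return DistanceMatrix(ids, np.asarray(rows))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def write_graphml(graph, path: str | Path) -> None:
    """Write a networkx graph as GraphML (Cytoscape-importable)."""
    import networkx as nx

    nx.write_graphml(graph, str(path))


def write_edge_list(graph, path: str | Path) -> None:
    """Cytoscape-ready edge list TSV: source, target, rho, sign."""
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\trho\tsign\n")
        for u, v, attrs in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{attrs['rho']!r}\t{attrs['sign']}\n")
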