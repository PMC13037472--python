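"""Validated domain types and readers/writers for the pipeline's file formats.

Formats handled: tab-separated count tables and metadata ('#' comment lines
ignored), newick trees with branch lengths, aligned FASTA, and TSV/JSON result
records with fixed float formatting so repeated writes are byte-identical.
"""
from __future__ import annotations

import dataclasses
import io
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode
from skbio.io import UnrecognizedFormatError

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "Phylogeny",
    "AlignedSequenceSet",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_fasta",
    "write_fasta",
    "write_results",
]

#: significant digits used for every float we serialize
FLOAT_FORMAT = "%.6g"

_ALLOWED_BASES = frozenset("ACGTN-")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclasses.dataclass
class FeatureTable:
    """A taxa-by-samples count matrix.

    ``counts`` holds non-negative integers while ``is_transformed`` is False;
    after a CLR transform it holds reals and ``is_transformed`` is True.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    is_transformed: bool = False

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) == 0:
            raise ValueError("feature table has no samples")
        if not self.is_transformed:
            if np.any(counts < 0):
                i, j = np.argwhere(counts < 0)[0]
                raise ValueError(
                    f"negative count at taxon {self.taxon_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                i, j = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at taxon {self.taxon_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(float)
        self.counts = counts

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_transformed: bool = False) -> "FeatureTable":
        return cls(
            taxon_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            counts=df.to_numpy(),
            is_transformed=is_transformed,
        )

    def select_taxa(self, keep: Sequence[str]) -> "FeatureTable":
        idx = [self.taxon_ids.index(t) for t in keep]
        return FeatureTable(list(keep), list(self.sample_ids), self.counts[idx, :], self.is_transformed)

    def select_samples(self, keep: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return FeatureTable(list(self.taxon_ids), list(keep), self.counts[:, idx], self.is_transformed)


@dataclasses.dataclass
class SampleMetadata:
    """Mapping of sample id to group label, with optional host id and coordinates."""

    groups: dict[str, str]
    host: dict[str, str] = dataclasses.field(default_factory=dict)
    coords: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, g in self.groups.items():
            if not str(g):
                raise ValueError(f"empty group label for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def group_labels(self, sample_ids: Sequence[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing}")
        return [self.groups[s] for s in sample_ids]

    def check_samples(self, table: FeatureTable) -> list[str]:
        """Warn about table samples absent from the metadata; return them."""
        missing = [s for s in table.sample_ids if s not in self.groups]
        if missing:
            warnings.warn(f"samples missing from metadata: {missing}", stacklevel=2)
        return missing


@dataclasses.dataclass
class Phylogeny:
    """A rooted tree with branch lengths and a focal/reference tip partition."""

    tree: TreeNode
    focal: frozenset[str]

    def __post_init__(self) -> None:
        self.focal = frozenset(self.focal)
        tips = self.tip_names
        _check_unique(tips, "tip")
        tipset = set(tips)
        missing = sorted(self.focal - tipset)
        if missing:
            raise ValueError(f"focal labels missing from tree: {missing}")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on node {node.name!r}")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def reference(self) -> frozenset[str]:
        return frozenset(self.tip_names) - self.focal

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))


@dataclasses.dataclass
class AlignedSequenceSet:
    """Gapped nucleotide alignment: id -> sequence over {A,C,G,T,N,-}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty sequence set")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - _ALLOWED_BASES
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in sequence {sid!r}")
            self.sequences[sid] = seq.upper()

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path: str | Path, taxa_as_columns: bool = False) -> FeatureTable:
    """Read a TSV count table (first column taxon ids, header sample ids).

    Set ``taxa_as_columns=True`` only if the file is explicitly known to be
    transposed; orientation is never auto-detected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.size == 0:
        raise ValueError(f"empty feature table: {path}")
    if taxa_as_columns:
        df = df.T
    idx = list(df.index.astype(str))
    cols = list(df.columns.astype(str))
    _check_unique(idx, "taxon")
    _check_unique(cols, "sample")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, c in enumerate(df.columns):
        for i, v in enumerate(df[c]):
            try:
                f = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count {v!r} at taxon {idx[i]!r}, sample {cols[j]!r}"
                ) from None
            if f < 0:
                raise ValueError(f"negative count at taxon {idx[i]!r}, sample {cols[j]!r}")
            if f != int(f):
                raise ValueError(f"non-integer count at taxon {idx[i]!r}, sample {cols[j]!r}")
            counts[i, j] = int(f)
    return FeatureTable(idx, cols, counts)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    float_format = FLOAT_FORMAT if table.is_transformed else None
    df.to_csv(path, sep="\t", index_label="taxon_id", float_format=float_format)


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata: first column sample id, 'group' column required."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("metadata needs at least sample id and group columns")
    sid_col = df.columns[0]
    group_col = "group" if "group" in df.columns else df.columns[1]
    sids = list(df[sid_col].astype(str))
    _check_unique(sids, "sample")
    groups = dict(zip(sids, df[group_col].astype(str)))
    host = {}
    if "host_id" in df.columns:
        host = dict(zip(sids, df["host_id"].astype(str)))
    coords = {}
    if {"latitude", "longitude"} <= set(df.columns):
        for s, la, lo in zip(sids, df["latitude"], df["longitude"]):
            if pd.notna(la) and pd.notna(lo):
                coords[s] = (float(la), float(lo))
    return SampleMetadata(groups=groups, host=host, coords=coords)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    rows = []
    for sid, g in metadata.groups.items():
        row = {"sample_id": sid, "group": g}
        if sid in metadata.host:
            row["host_id"] = metadata.host[sid]
        if sid in metadata.coords:
            row["latitude"], row["longitude"] = metadata.coords[sid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# trees


def read_tree(path: str | Path, focal_labels: Iterable[str] = ()) -> Phylogeny:
    """Read a newick tree; unrooted (multifurcating-root) input is midpoint-rooted.

    Missing branch lengths are treated as 0 with a warning (a common dialect
    artifact); tips named in ``focal_labels`` are tagged focal.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except (UnrecognizedFormatError, Exception) as exc:  # skbio raises format errors
        if exc.__class__.__name__ in ("NewickFormatError", "UnrecognizedFormatError") or \
                "newick" in str(exc).lower() or "Could not" in str(exc):
            raise ValueError(f"unparsable newick in {path}: {exc}") from exc
        raise
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} branches lacked lengths in {path}; treated as 0", stacklevel=2
        )
    if len(tree.children) > 2:
        # multifurcating root = unrooted convention; root at the midpoint
        tree = tree.root_at_midpoint()
    return Phylogeny(tree=tree, focal=frozenset(str(x) for x in focal_labels))


def write_tree(phylogeny: Phylogeny, path: str | Path) -> None:
    phylogeny.tree.write(str(path), format="newick")


def write_focal_labels(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in sorted(phylogeny.focal)))


def read_focal_labels(path: str | Path) -> frozenset[str]:
    return frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> AlignedSequenceSet:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return AlignedSequenceSet(sequences=seqs)


def write_fasta(seqs: AlignedSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# generic result records


def _format_value(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer)):
        return int(v)
    if isinstance(v, (float, np.floating)):
        return float(FLOAT_FORMAT % float(v))
    return v


def write_results(records: Sequence[Mapping], path: str | Path, format: str = "tsv") -> None:
    """Write result records with stable column order and fixed float precision.

    Identical inputs always produce byte-identical files.
    """
    records = [dict(r) for r in records]
    columns: list[str] = []
    for r in records:
        for k in r:
            if k not in columns:
                columns.append(k)
    if format.lower() == "tsv":
        with open(path, "w", newline="\n") as fh:
            fh.write("\t".join(columns) + "\n")
            for r in records:
                cells = []
                for c in columns:
                    v = r.get(c, "")
                    if isinstance(v, (float, np.floating)):
                        cells.append(FLOAT_FORMAT % float(v))
                    else:
                        cells.append(str(v))
                fh.write("\t".join(cells) + "\n")
    elif format.lower() == "json":
        canon = [{k: _format_value(v) for k, v in r.items()} for r in records]
        with open(path, "w", newline="\n") as fh:
            json.dump(canon, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> list[dict]:
    if format.lower() == "json":
        with open(path) as fh:
            return json.load(fh)
    df = pd.read_csv(path, sep="\t")
    return df.to_dict(orient="records")
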