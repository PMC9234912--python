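"""Readers and writers for every external artifact.

Canonical dialects:

* matrices — TSV, cell (1,1) is ``feature_id``, header row of sample IDs,
  numeric body with ``.`` decimal separator (comma decimals rejected);
* metadata — TSV with ``sample_id`` first column, a ``group`` column and one
  column per batch factor;
* gene sets — standard GMT (``name<TAB>description<TAB>member...``);
* gene lists — one ID per line, ``#`` comments allowed;
* networks — edge-list TSV with columns ``source_id, source_layer, target_id,
  target_layer, pearson_r, p_value`` in deterministic sorted order.

All reader/writer pairs round-trip bit-identically for IDs and to ≤1e-12 for
numerics; absent cells are an error, never silently coerced to zero.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GeneSetCollection, Layer, OmicsMatrix, SampleMetadata, Scale

__all__ = [
    "read_expression_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_list",
    "write_gene_list",
    "write_network",
    "read_network",
    "write_json",
    "file_sha256",
]

_MATRIX_CORNER = "feature_id"
_FLOAT_FMT = "%.17g"  # exact float round-trip


def read_expression_matrix(path, layer: Layer | str, scale: Scale | str) -> OmicsMatrix:
    """Read a features × samples TSV matrix into an :class:`OmicsMatrix`.

    Raises a parse error naming the offending row/column for malformed numeric
    cells, and a validation error for duplicate feature or sample IDs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups[:5]}")
    parsed = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col]
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise ValueError(
                    f"{path}: missing cell at feature {df.index[i]!r}, sample {col!r}")
            text = str(cell).strip()
            if "," in text:
                raise ValueError(
                    f"{path}: comma decimal separator at feature {df.index[i]!r}, "
                    f"sample {col!r}: {text!r}")
            try:
                parsed[i, j] = float(text)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed numeric cell at feature {df.index[i]!r}, "
                    f"sample {col!r}: {text!r}") from exc
    out = pd.DataFrame(parsed, index=df.index, columns=df.columns)
    return OmicsMatrix(out, Layer(layer), Scale(scale))


def write_matrix(m: OmicsMatrix, path) -> None:
    path = Path(path)
    df = m.data.copy()
    df.index.name = _MATRIX_CORNER
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path, group_col: str = "group",
                  batch_cols: tuple[str, ...] = ()) -> SampleMetadata:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    table.index = table.index.astype(str)
    if not batch_cols:
        batch_cols = tuple(c for c in table.columns if c != group_col)
    return SampleMetadata(table, group_col=group_col, batch_cols=batch_cols)


def write_metadata(meta: SampleMetadata, path) -> None:
    table = meta.table.copy()
    table.index.name = "sample_id"
    table.to_csv(path, sep="\t")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file; each line needs ≥3 tab-separated fields.

    Duplicate members inside one set are deduplicated (first occurrence kept),
    so set sizes reflect unique members.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need ≥3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: dict[str, None] = {}
            for g in fields[2:]:
                if g.strip():
                    members.setdefault(g.strip(), None)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gene_sets(gsc: GeneSetCollection, path) -> None:
    with open(Path(path), "w") as fh:
        for name, (desc, members) in gsc.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path) -> list[str]:
    """One ID per line; blank lines and ``#`` comments skipped; order kept."""
    out: dict[str, None] = {}
    with open(Path(path)) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.setdefault(line, None)
    return list(out)


def write_gene_list(genes, path) -> None:
    with open(Path(path), "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


_NETWORK_COLS = ["source_id", "source_layer", "target_id",
                 "target_layer", "pearson_r", "p_value"]


def write_network(network, path) -> None:
    """Write a bipartite correlation network as a sorted edge-list TSV."""
    edges = network.edges.copy()
    edges = edges.sort_values(["source_id", "target_id"], kind="mergesort")
    edges.to_csv(Path(path), sep="\t", index=False,
                 columns=_NETWORK_COLS, float_format=_FLOAT_FMT)


def read_network(path) -> pd.DataFrame:
    """Read an edge-list TSV back as a DataFrame (not a full network object)."""
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip",
                     dtype={"source_id": str, "target_id": str})
    missing = [c for c in _NETWORK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: network file lacks columns {missing}")
    return df


def write_json(obj, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(Path(path), "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
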