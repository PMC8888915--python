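"""Readers and writers for every external format the pipeline touches.

All tables are tab-separated UTF-8 with a header row and a "." decimal
separator. Count tables are canonically taxa x samples; an explicit
``orientation`` flag (never auto-detection) handles transposed input.
Trees travel as newick, networks as GraphML or edge-list TSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

from .containers import (
    CountMatrix,
    GuildTable,
    SampleMetadata,
    ValidationError,
    warn,
)

FLOAT_FORMAT = "%.10g"  # fixed float rendering => byte-stable outputs


class ParseError(ValueError):
    """Raised when an input file cannot be parsed under the pinned dialect."""


# ---------------------------------------------------------------------------
# count tables

def read_count_table(path, orientation: str = "taxa_rows") -> CountMatrix:
    """Read a TSV count table into a CountMatrix (taxa x samples).

    Parameters
    ----------
    path
        Tab-separated text; first column row identifiers, header row column
        identifiers, numeric cells.
    orientation
        ``"taxa_rows"`` if rows are taxa (canonical OTU-table layout) or
        ``"samples_rows"`` if rows are samples; the result is always
        normalized to taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or pd.Index(df.columns).duplicated().any():
        raise ParseError(f"{path}: duplicate row or column identifier")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        if bad.any().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ParseError(
                f"{path}: non-numeric cell {df.iat[i, j]!r} at "
                f"(row {df.index[i]!r}, column {df.columns[j]!r})"
            )
        df, arr = coerced, coerced.to_numpy()
    nonint = (arr % 1 != 0) | (arr < 0) | ~np.isfinite(arr)
    if nonint.any():
        i, j = np.argwhere(nonint)[0]
        raise ParseError(
            f"{path}: cell {arr[i, j]!r} at (row {df.index[i]!r}, "
            f"column {df.columns[j]!r}) is not a nonnegative integer"
        )
    df = df.astype(np.int64)
    if orientation == "samples_rows":
        df = df.T
    return CountMatrix.from_dataframe(df)


def write_count_table(matrix: CountMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# sample metadata / guild tables

def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in SampleMetadata.REQUIRED})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_guild_table(path) -> GuildTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GuildTable(df)


def write_guild_table(guilds: GuildTable, path) -> None:
    guilds.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees

def read_newick(path) -> skbio.TreeNode:
    """Read a single rooted newick tree with branch lengths.

    Missing branch lengths default to 0 with a warning; duplicate leaf
    labels are an error.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse-error types
        raise ParseError(f"{path}: cannot parse newick ({exc})") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"{path}: duplicate leaf labels {dup}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(f"{path}: negative branch length on {node.name!r}")
    if n_missing:
        warn(f"{path}: {n_missing} branch length(s) missing; defaulted to 0")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def parse_newick(text: str) -> skbio.TreeNode:
    """Parse a newick string (same validation as :func:`read_newick`)."""
    buf = _io.StringIO(text)
    try:
        tree = skbio.TreeNode.read(buf, format="newick")
    except Exception as exc:
        raise ParseError(f"cannot parse newick ({exc})") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate leaf labels {dup}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# networks

def write_network(network, path, format: str = "graphml") -> None:
    """Serialize a co-occurrence network.

    GraphML carries node attributes (taxon_id, degree, closeness,
    betweenness, keystone flag when computed) and per-edge rho and p;
    the edge-list TSV has columns source, target, rho, p.
    """
    graph = network.graph
    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "edge_list_tsv":
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"]}
            for u, v, d in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "p"]).to_csv(
            path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
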