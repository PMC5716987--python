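"""Readers and writers for the formats the pipeline touches.

OTU tables and sample metadata are tab-separated; trees are Newick;
co-occurrence networks go out as GraphML (Gephi-readable) plus a TSV edge
list. No science lives here — only validation and (de)serialization.

The canonical in-memory orientation of an OTU table is samples-as-rows; the
reader transposes only when told to via ``otus_as_rows``, never by guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "OtuTable",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_tree_newick",
    "write_tree_newick",
    "write_network_graphml",
    "read_network_graphml",
    "write_edge_list",
]


class FormatError(ValueError):
    """An input file or table violates the expected format."""


@dataclass
class OtuTable:
    """A samples × OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are OTUs. Values must be non-negative
        integers (integer-valued floats are cast).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise FormatError("OTU table needs at least one sample and one OTU")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicate OTU ids: {dup}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric counts in OTU table: {exc}") from exc
        if not np.isfinite(values).all():
            raise FormatError("non-finite counts in OTU table")
        if (values < 0).any():
            raise FormatError("negative counts in OTU table")
        if not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integers")
        self.data = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, samples: Sequence[str] | None = None,
               otus: Sequence[str] | None = None) -> "OtuTable":
        df = self.data
        if samples is not None:
            missing = set(samples) - set(df.index)
            if missing:
                raise KeyError(f"unknown sample ids: {sorted(missing)}")
            df = df.loc[list(samples)]
        if otus is not None:
            missing = set(otus) - set(df.columns)
            if missing:
                raise KeyError(f"unknown OTU ids: {sorted(missing)}")
            df = df[list(otus)]
        return OtuTable(df.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample treatment label and numeric covariates.

    ``data`` is indexed by sample id, has a ``group`` column (treatment
    label) and any number of numeric covariate columns (pH, SOC, TN, AP,
    AK, Ivt, MC, yield, P_max, t_max, Q_T, K, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str)
        if "group" not in df.columns:
            raise FormatError("metadata needs a 'group' column")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        for col in df.columns:
            if col == "group":
                continue
            df[col] = pd.to_numeric(df[col], errors="raise")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["group"])

    def check_covers(self, table: OtuTable) -> None:
        """Every sample in *table* must have a metadata row."""
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")


def read_otu_table(path: str | Path, otus_as_rows: bool = False) -> OtuTable:
    """Read a tab-separated count table.

    The first column holds row identifiers. With the default orientation the
    rows are samples; pass ``otus_as_rows=True`` for the transposed layout.
    """
    _check_unique_header(path, "OTU table")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse OTU table {path}: {exc}") from exc
    if otus_as_rows:
        df = df.T
    return OtuTable(df)


def _check_unique_header(path: str | Path, what: str) -> None:
    # pandas silently renames duplicated header columns, so check ourselves
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                cols = line.rstrip("\n").split("\t")[1:]
                dup = {c for c in cols if cols.count(c) > 1}
                if dup:
                    raise FormatError(
                        f"duplicate column ids in {what}: {sorted(dup)}")
                return


def write_otu_table(table: OtuTable, path: str | Path,
                    otus_as_rows: bool = False) -> None:
    df = table.data.T if otus_as_rows else table.data
    df.to_csv(path, sep="\t", index_label="sample_id" if not otus_as_rows else "otu_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse metadata {path}: {exc}") from exc
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_tree_newick(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Tips without a branch length get length 0 (logged). Underscores in
    labels are kept verbatim.
    """
    try:
        tree = TreeNode.read(str(path), format="newick",
                             convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError("negative branch length in tree")
    if n_missing:
        log.warning("%d branches without length set to 0", n_missing)
    return tree


def parse_tree_newick(newick: str) -> TreeNode:
    """Parse a Newick string (same semantics as :func:`read_tree_newick`)."""
    import io as _io

    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick",
                             convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def write_tree_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def _network_graph(network) -> nx.Graph:
    """Accept either a CooccurrenceNetwork or a bare networkx graph."""
    return network.graph if hasattr(network, "graph") else network


def write_network_graphml(network, path: str | Path) -> None:
    """Write a Gephi-readable GraphML with degree/sign/rho/p attributes."""
    g = _network_graph(network).copy()
    for node, deg in g.degree():
        g.nodes[node]["otu_id"] = str(node)
        g.nodes[node]["degree"] = int(deg)
    for u, v, attrs in g.edges(data=True):
        rho = float(attrs.get("rho", 0.0))
        attrs["rho"] = rho
        attrs["p"] = float(attrs.get("p", float("nan")))
        attrs["sign"] = "negative" if rho < 0 else "positive"
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(network, path: str | Path) -> None:
    """TSV edge list mirroring the GraphML (source, target, rho, sign, p)."""
    g = _network_graph(network)
    rows = []
    for u, v, attrs in sorted(g.edges(data=True)):
        rho = float(attrs.get("rho", 0.0))
        rows.append({
            "source": u,
            "target": v,
            "rho": rho,
            "sign": "negative" if rho < 0 else "positive",
            "p": float(attrs.get("p", float("nan"))),
        })
    pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "p"]).to_csv(
        path, sep="\t", index=False)
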