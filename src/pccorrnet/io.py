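"""Reading matrices and labels; writing the Cytoscape-ready tables."""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    EDGE_COLUMNS,
    NODE_COLUMNS,
    NetworkTables,
    OmicMatrix,
    SampleLabels,
    ValidationError,
)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


def _detect_sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab"):
        return "\t"
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in first else ","


def read_matrix(
    path,
    orientation: str = "samples_as_rows",
    missing_token: str | None = None,
    delimiter: str | None = None,
) -> OmicMatrix:
    """Read a TSV/CSV matrix with a header row and an id first column.

    Whatever the on-disk orientation, the returned matrix has samples as
    rows.  Cells equal to ``missing_token`` (and empty cells) become NaN;
    any other non-numeric cell raises ParseError naming row and column.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _detect_sep(path, delimiter)
    header = path.read_text().splitlines()[0].split(sep)[1:]
    if len(header) != len(set(header)):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate column names in {path.name}: {dup[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if missing_token is not None:
        df = df.replace(missing_token, np.nan)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path.name}"
        )
    if orientation == "features_as_rows":
        numeric = numeric.T
    return OmicMatrix.from_dataframe(numeric)


def read_labels(path, delimiter: str | None = None) -> SampleLabels:
    """Read a two-column (sample, group) table with a header row."""
    path = Path(path)
    sep = _detect_sep(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"label file {path.name} needs two columns (sample, group)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise ValidationError("duplicate sample id in label file")
    return SampleLabels(mapping)


def write_network_tables(net: NetworkTables, out_dir, prefix: str = "") -> tuple[Path, Path]:
    """Write edges.tsv and nodes.tsv (6+ significant digits, fixed order)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / f"{prefix}edges.tsv"
    node_path = out_dir / f"{prefix}nodes.tsv"
    if net.n_edges == 0:
        warnings.warn("writing an empty network (headers only)")
    net.edges.to_csv(edge_path, sep="\t", index=False, float_format="%.8g")
    net.nodes.to_csv(node_path, sep="\t", index=False, float_format="%.8g")
    return edge_path, node_path


def read_network_tables(edge_path, node_path, metadata: dict | None = None) -> NetworkTables:
    """Round-trip reader for tables written by :func:`write_network_tables`."""
    edges = pd.read_csv(edge_path, sep="\t")
    nodes = pd.read_csv(node_path, sep="\t")
    if edges.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    if nodes.empty:
        nodes = pd.DataFrame(columns=NODE_COLUMNS)
    return NetworkTables(edges=edges, nodes=nodes, metadata=metadata or {})


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def export_graphml(net: NetworkTables, path) -> Path:
    """Optional GraphML export of the same graph, via networkx."""
    import networkx as nx

    g = nx.Graph(**{k: str(v) for k, v in net.metadata.items()})
    for row in net.nodes.itertuples(index=False):
        g.add_node(row.feature, loading=float(row.loading), group=str(row.group),
                   color=str(row.color), degree=int(row.degree))
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight), sign=str(row.sign))
    path = Path(path)
    nx.write_graphml(g, path)
    return path
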