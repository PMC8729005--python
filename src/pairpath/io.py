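"""Readers and writers for the plain-text formats the tool exchanges:
labeled matrix CSV, samples x features CSV, tidy TSV tables, JSON metadata,
and GraphML / edge-list exports of the support graph.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .ggm import CorrMatrix, PartialCorrMatrix
from .pps import PathDecomposition, PPSTable


def read_data_csv(path) -> pd.DataFrame:
    """Samples x features table: header row of feature names, optionally a
    leading ``sample_id`` column; every cell numeric, no missing values."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValidationError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValidationError(
                f"{path}:{lineno}: ragged row ({len(row)} cells, expected "
                f"{width})")
    has_index = header[0].strip().lower() in {"", "sample_id", "sample"}
    features = header[1:] if has_index else header
    features = [f.strip() for f in features]
    dupes = sorted({f for f in features if features.count(f) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate feature names: {dupes}")
    samples, body = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        cells = row[1:] if has_index else row
        samples.append(row[0] if has_index else f"s{lineno - 1}")
        parsed = []
        for col, cell in zip(features, cells):
            cell = cell.strip()
            if cell == "":
                raise ValidationError(
                    f"{path}:{lineno}: missing value in column {col!r}")
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column "
                    f"{col!r}") from None
        body.append(parsed)
    return pd.DataFrame(body, index=samples, columns=features)


def write_data_csv(data: pd.DataFrame, path) -> None:
    df = data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def _read_labeled_matrix(path) -> tuple[tuple[str, ...], np.ndarray]:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    row_labels = tuple(str(x) for x in df.index)
    col_labels = tuple(str(x) for x in df.columns)
    if row_labels != col_labels:
        raise ValidationError(
            f"{path}: row and column labels differ "
            f"(rows {row_labels[:3]}..., columns {col_labels[:3]}...)")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError(f"{path}: matrix is not square: {values.shape}")
    return row_labels, values


def read_partial_matrix_csv(path, require_valid: bool = True) -> PartialCorrMatrix:
    """Labeled square partial-correlation matrix (first row/column labels)."""
    labels, values = _read_labeled_matrix(path)
    return PartialCorrMatrix(labels, values, require_valid=require_valid)


def read_correlation_matrix_csv(path) -> CorrMatrix:
    labels, values = _read_labeled_matrix(path)
    return CorrMatrix(labels, values)


def write_matrix_csv(matrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.labels),
                      columns=list(matrix.labels))
    df.to_csv(path, float_format="%.17g")


def write_graph_edgelist_tsv(graph: nx.Graph, path) -> None:
    """Weighted edge list: node_a, node_b, partial_correlation."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node_a", "node_b", "partial_correlation"])
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            writer.writerow([a, b, repr(graph.edges[a, b]["partial_correlation"])])


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def _decomposition_rows(table: PPSTable):
    d = table.decomposition
    for path, t, g, s in zip(d.paths, d.taus, d.gammas, table.scores):
        yield {"pair_a": table.pair[0], "pair_b": table.pair[1],
               "path": "|".join(path), "length": len(path) - 1,
               "tau": t, "gamma": g, "pps": s}


def write_pps_tsv(table: PPSTable, path) -> None:
    pd.DataFrame(list(_decomposition_rows(table))).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def pps_to_dict(table: PPSTable) -> dict:
    return {
        "pair": list(table.pair),
        "k": table.k,
        "status": table.status,
        "cancellation": table.cancellation,
        "reconstructed_correlation":
            table.decomposition.reconstructed_correlation,
        "paths": list(_decomposition_rows(table)),
    }


def decomposition_to_dict(d: PathDecomposition) -> dict:
    return {
        "pair": list(d.pair),
        "k": d.k,
        "reconstructed_correlation": d.reconstructed_correlation,
        "paths": [{"path": "|".join(p), "length": len(p) - 1,
                   "tau": t, "gamma": g}
                  for p, t, g in zip(d.paths, d.taus, d.gammas)],
    }


def write_json(obj, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan_tsv(path):
    """Rehydrate a max-subscore scan table written by ``write_table_tsv``."""
    from .workflows import MaxPPSScan
    df = pd.read_csv(path, sep="\t")
    required = {"pair_a", "pair_b", "best_path", "best_score", "k"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: not a scan table; missing columns "
                              f"{sorted(missing)}")
    k = int(df["k"].iloc[0]) if len(df) else 0
    return MaxPPSScan(df, k, f"loaded:{path}", 0)
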