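"""Plain-text readers and writers for networks, features, labels, predictions.

All files are delimiter-separated text; the delimiter is auto-detected
per file between tab and comma (tab wins when a tab character appears in
the first non-empty line).  The feature file defines the gene universe;
node order is lexicographic by gene identifier and fixed at load time.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import GeneGraph

__all__ = [
    "read_network",
    "write_network",
    "write_predictions",
    "read_predictions",
]


def _detect_sep(path: str | os.PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: file is empty")


def _read_features(path: str | os.PathLike) -> pd.DataFrame:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r} in feature file")
    feat = df.drop(columns=[gene_col])
    for col in feat.columns:
        coerced = pd.to_numeric(feat[col], errors="coerce")
        bad = coerced.isna() & feat[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric feature value {feat[col].iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing feature value at row {row + 2}, column {col!r}")
        feat[col] = coerced
    feat.index = genes.to_list()
    return feat.sort_index()


def _read_edges(path: str | os.PathLike, known: set[str]) -> list[tuple[str, str]]:
    sep = _detect_sep(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            rows.append(parts[:2])
    # optional header: first data line whose two fields are both unknown gene
    # ids, while a later line exists, is treated as a header row
    if rows and rows[0][0] not in known and rows[0][1] not in known and len(rows) > 1:
        rows = rows[1:]
    edges = []
    for u, v in rows:
        for g in (u, v):
            if g not in known:
                raise ValueError(f"{path}: edge references unknown gene id {g!r}")
        if u == v:
            continue  # self-loops dropped
        edges.append((u, v) if u < v else (v, u))
    return sorted(set(edges))


def _read_labels(path: str | os.PathLike, known: set[str]) -> dict[str, float]:
    sep = _detect_sep(path)
    labels: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            g, val = parts[0], parts[1]
            if not labels and lineno == 1 and val not in ("0", "1"):
                continue  # header row
            if g not in known:
                raise ValueError(f"{path}: label references unknown gene id {g!r}")
            if val not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {val!r}")
            labels[g] = float(val)
    return labels


def read_network(
    edge_path: str | os.PathLike,
    feature_path: str | os.PathLike,
    label_path: str | os.PathLike | None = None,
) -> GeneGraph:
    """Load a gene-gene network into a :class:`~ecdcdgi.graph.GeneGraph`.

    The feature file (first column gene id, remaining columns numeric)
    defines the gene universe; genes absent from the edge file are kept as
    isolated nodes.  Duplicate edges collapse, self-loops are dropped, and
    an edge or label naming a gene without features is a hard error.
    Genes missing from the label file (or all genes, when ``label_path``
    is None) are marked unlabeled.
    """
    feat = _read_features(feature_path)
    node_ids = feat.index.to_list()
    known = set(node_ids)
    idx = {g: i for i, g in enumerate(node_ids)}
    edges = _read_edges(edge_path, known)
    n = len(node_ids)
    if edges:
        ii = np.array([idx[u] for u, v in edges] + [idx[v] for u, v in edges])
        jj = np.array([idx[v] for u, v in edges] + [idx[u] for u, v in edges])
        A = sp.csr_array((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    else:
        A = sp.csr_array((n, n))
    y = np.full(n, np.nan)
    if label_path is not None:
        for g, val in _read_labels(label_path, known).items():
            y[idx[g]] = val
    return GeneGraph(node_ids=node_ids, A=A, X=feat.to_numpy(dtype=float), y=y)


def write_network(
    graph: GeneGraph,
    edge_path: str | os.PathLike,
    feature_path: str | os.PathLike,
    label_path: str | os.PathLike,
    sep: str = "\t",
) -> None:
    """Write a graph back out as edge / feature / label files (round-trippable)."""
    A = sp.triu(sp.coo_array(graph.A))
    with open(edge_path, "w") as fh:
        fh.write(sep.join(["source", "target"]) + "\n")
        pairs = sorted(
            (graph.node_ids[i], graph.node_ids[j]) for i, j in zip(A.row, A.col)
        )
        for u, v in pairs:
            fh.write(f"{u}{sep}{v}\n")
    feat = pd.DataFrame(
        graph.X,
        index=pd.Index(graph.node_ids, name="gene_id"),
        columns=[f"f{k}" for k in range(graph.n_features)],
    )
    feat.to_csv(feature_path, sep=sep, float_format="%.17g")  # exact round trip
    with open(label_path, "w") as fh:
        fh.write(sep.join(["gene_id", "label"]) + "\n")
        for i, g in enumerate(graph.node_ids):
            if not np.isnan(graph.y[i]):
                fh.write(f"{g}{sep}{int(graph.y[i])}\n")


def prediction_ranks(node_ids, probabilities) -> np.ndarray:
    """1-based ranks by descending probability, ties broken by ascending gene id."""
    order = sorted(range(len(node_ids)), key=lambda i: (-probabilities[i], node_ids[i]))
    ranks = np.empty(len(node_ids), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def write_predictions(path, node_ids, logits, probabilities) -> None:
    """Write a 4-column prediction table: gene_id, score, probability, rank.

    ``score`` is the raw readout logit (can be negative), ``probability``
    its sigmoid; rank is 1-based by descending probability with ties
    broken by ascending gene id.
    """
    node_ids = list(node_ids)
    logits = np.asarray(logits, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if not (len(node_ids) == len(logits) == len(probabilities)):
        raise ValueError("node_ids, logits and probabilities must have equal length")
    if ((probabilities < 0) | (probabilities > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    ranks = prediction_ranks(node_ids, probabilities)
    order = np.argsort(ranks)
    with open(path, "w") as fh:
        fh.write("gene_id\tscore\tprobability\trank\n")
        for i in order:
            fh.write(
                f"{node_ids[i]}\t{logits[i]:.10g}\t{probabilities[i]:.10g}\t{ranks[i]}\n"
            )


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction table written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
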