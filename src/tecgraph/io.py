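"""File ingestion and emission: matrices, embeddings, labels, domains,
dendrograms."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .tec_o import BinInfo, ContactMap
from .tec_u import Dendrogram

__all__ = [
    "read_contact_matrix",
    "write_contact_matrix",
    "read_embedding",
    "write_labels",
    "read_labels",
    "write_domains",
    "dendrogram_to_newick",
    "dendrogram_to_json",
]


def read_contact_matrix(path, fmt: str = "auto",
                        bins: BinInfo | None = None) -> ContactMap:
    """Load a square contact matrix from whitespace-delimited text or an
    ``.npz`` container.

    NaNs are replaced by 0 with a warning.  Mild asymmetry (relative
    magnitude below 1e-6) is repaired by averaging with the transpose;
    anything grosser is an error.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "npz" if path.suffix == ".npz" else "tsv"
    if fmt == "npz":
        with np.load(path) as z:
            m = z[z.files[0]]
    else:
        m = np.loadtxt(path)
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is not square {m.shape}")
    if np.isnan(m).any():
        warnings.warn(f"{path}: NaN entries replaced by 0")
        m = np.nan_to_num(m, nan=0.0)
    if (m < 0).any():
        raise ValueError(f"{path}: negative entries")
    scale = np.abs(m).max() or 1.0
    if np.abs(m - m.T).max() / scale > 1e-6:
        raise ValueError(f"{path}: matrix is grossly asymmetric")
    return ContactMap((m + m.T) / 2.0, bins=bins)


def write_contact_matrix(cm: ContactMap, path, fmt: str = "auto"):
    path = Path(path)
    if fmt == "auto":
        fmt = "npz" if path.suffix == ".npz" else "tsv"
    if fmt == "npz":
        np.savez_compressed(path, matrix=cm.matrix)
    else:
        np.savetxt(path, cm.matrix, fmt="%.10g", delimiter="\t")


def read_embedding(path) -> np.ndarray:
    """Sample-by-dimension CSV, samples in rows; a header row and a
    non-numeric first (row-name) column are detected and dropped."""
    df = pd.read_csv(path, header=None)
    # header detection: first row non-numeric
    try:
        pd.to_numeric(df.iloc[0])
    except (ValueError, TypeError):
        df = pd.read_csv(path)
    first = df.iloc[:, 0]
    if first.dtype == object:
        df = df.iloc[:, 1:]
    try:
        X = df.astype(float).to_numpy()
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric embedding values ({e})")
    if not np.isfinite(X).all():
        bad = int(np.argwhere(~np.isfinite(X))[0][0])
        raise ValueError(f"{path}: non-finite value at data row {bad}")
    return X


def write_labels(labels, path, sample_names=None):
    n = len(labels)
    names = sample_names if sample_names is not None else range(n)
    df = pd.DataFrame({"sample": list(names), "cluster": list(labels)})
    df.to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    return pd.read_csv(path)["cluster"].to_numpy()


def write_domains(records, path):
    """BED-like TSV: chrom, start, end, name, level (0-based half-open)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec['chrom']}\t{rec['start']}\t{rec['end']}\t"
                     f"{rec['name']}\t{rec['level']}\n")


def dendrogram_to_newick(d: Dendrogram) -> str:
    def emit(nid: int) -> str:
        nd = d.nodes[nid]
        if nd.children is None:
            return f"L{nid}"
        a, b = nd.children
        return f"({emit(a)},{emit(b)})"

    return emit(d.root_id) + ";"


def dendrogram_to_json(d: Dendrogram) -> str:
    def emit(nid: int) -> dict:
        nd = d.nodes[nid]
        out = {"id": nid, "samples": sorted(nd.vertex_set)}
        if nd.children is not None:
            out["children"] = [emit(c) for c in nd.children]
        return out

    return json.dumps(emit(d.root_id), indent=1)
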