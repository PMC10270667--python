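"""Plain-text file formats: matrices, manifests, distance and estimate tables.

All outputs are tidy CSV with documented columns, re-ingestible by the same
functions.  Matrix files are dense square numeric text (comma, tab or
whitespace separated) with an optional header row/column of node labels.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ConnectionMatrix, validate_connection_matrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "load_scans",
    "write_distance_table",
    "read_distance_table",
]

DIST_COLUMNS = [
    "subject_1", "task", "rep_1", "subject_2", "rep_2", "metric", "value", "degenerate",
]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_matrix(path, delimiter: str | None = None):
    """Read a dense square matrix from text; returns ``(matrix, labels)``.

    The delimiter (comma, tab or whitespace) is sniffed from the first line
    unless given.  A header row and/or label column is auto-detected from
    non-numeric cells; ``labels`` is None when absent.  Ragged or
    non-numeric data raises with the offending 1-based line number.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    if delimiter is None:
        first = lines[0]
        delimiter = "," if "," in first else ("\t" if "\t" in first else None)

    rows = [ln.split(delimiter) if delimiter else ln.split() for ln in lines]
    rows = [[tok.strip() for tok in r if tok.strip() != ""] for r in rows]

    has_header = any(not _is_number(tok) for tok in rows[0][1:]) or (
        len(rows) > 1 and len(rows[0]) == len(rows[1]) - 1
    )
    labels = None
    if has_header:
        labels = rows[0][1:] if len(rows[0]) == len(rows[1]) else rows[0]
        rows = rows[1:]
    has_label_col = all(not _is_number(r[0]) for r in rows)
    if has_label_col:
        if labels is None:
            labels = [r[0] for r in rows]
        rows = [r[1:] for r in rows]

    width = len(rows[0])
    data = np.empty((len(rows), width))
    for i, r in enumerate(rows):
        lineno = i + (2 if has_header else 1)
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} ({len(r)} fields, expected {width})"
            )
        try:
            data[i] = [float(tok) for tok in r]
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at line {lineno}: {exc}")
    if data.shape[0] != data.shape[1]:
        raise ValueError(f"{path}: matrix is {data.shape[0]}x{data.shape[1]}, not square")
    return data, labels


def write_matrix(path, matrix: np.ndarray, labels=None, delimiter: str = ","):
    """Write a dense square matrix as text (with optional node labels)."""
    matrix = np.asarray(matrix)
    path = Path(path)
    with path.open("w") as fh:
        if labels is not None:
            fh.write(delimiter.join(["node"] + [str(l) for l in labels]) + "\n")
        for i, row in enumerate(matrix):
            cells = [format(v, ".17g") for v in row]
            if labels is not None:
                cells = [str(labels[i])] + cells
            fh.write(delimiter.join(cells) + "\n")


def read_manifest(path) -> pd.DataFrame:
    """Read a scan manifest CSV: subject_id, task_id, repetition_id, path."""
    man = pd.read_csv(path, dtype=str)
    required = {"subject_id", "task_id", "repetition_id", "path"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    dup = man.duplicated(["subject_id", "task_id", "repetition_id"])
    if dup.any():
        raise ValueError("manifest contains duplicate (subject, task, repetition) triples")
    base = Path(path).parent
    man["path"] = [
        str(p) if os.path.isabs(p) else str(base / p) for p in man["path"]
    ]
    for p in man["path"]:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
    return man


def load_scans(manifest: pd.DataFrame | str | Path) -> list[ConnectionMatrix]:
    """Load and validate every scan listed in a manifest."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    scans = []
    for row in manifest.itertuples(index=False):
        values, _ = read_matrix(row.path)
        scans.append(
            validate_connection_matrix(
                values, row.subject_id, row.task_id, row.repetition_id
            )
        )
    return scans


def write_distance_table(path, table: pd.DataFrame) -> None:
    table[DIST_COLUMNS].to_csv(path, index=False)


def read_distance_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={c: str for c in ("subject_1", "task", "rep_1", "subject_2", "rep_2")},
    )
    missing = set(DIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"distance table lacks columns: {sorted(missing)}")
    return df
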