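"""Delimited-text formats for matrices, cohorts, and result tables."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BoldCohort

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_cohort",
    "load_cohort",
]


def read_matrix(path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Parse a delimited-text (tab or comma, auto-detected) dense matrix.

    Ragged rows, non-numeric cells, and shape mismatches raise with the
    offending row/column (1-based).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = "," if "," in lines[0] else None  # None -> any whitespace/tab
    rows = []
    width = None
    for i, line in enumerate(lines, start=1):
        cells = line.split(delim)
        cells = [c for c in (c.strip() for c in cells) if c != ""]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row at line {i} "
                f"({len(cells)} cells, expected {width})"
            )
        row = []
        for j, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at line {i}, column {j}"
                ) from None
        rows.append(row)
    m = np.asarray(rows, dtype=float)
    if expected_shape is not None and m.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: shape {m.shape} does not match expected {tuple(expected_shape)}"
        )
    return m


def write_matrix(path, matrix: np.ndarray, delimiter: str = "\t") -> None:
    """Write a dense matrix as delimited text with full float precision."""
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in m:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def save_cohort(cohort: BoldCohort, out_dir) -> Path:
    """Write one matrix file per subject plus a manifest table.

    Layout: ``<out_dir>/<subject>.tsv`` (rows = nodes, columns =
    timepoints) and ``<out_dir>/manifest.tsv`` with subject id, group,
    file, TR and timepoint count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, group, series in zip(cohort.subject_ids, cohort.group_labels, cohort.series):
        fname = f"{sid}.tsv"
        write_matrix(out_dir / fname, series)
        rows.append({"subject": sid, "group": group, "file": fname,
                     "tr_seconds": cohort.tr_seconds,
                     "n_timepoints": series.shape[1]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    (out_dir / "node_ids.txt").write_text("\n".join(cohort.node_ids) + "\n")
    return out_dir / "manifest.tsv"


def load_cohort(cohort_dir) -> BoldCohort:
    """Load a cohort written by :func:`save_cohort`, validating the manifest.

    All subjects must share the TR and the timepoint count recorded in the
    manifest; each series file must match its declared shape.
    """
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t")
    required = {"subject", "group", "file", "tr_seconds", "n_timepoints"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    trs = manifest["tr_seconds"].unique()
    if trs.size != 1:
        raise ValueError(f"subjects disagree on TR: {trs.tolist()}")
    t_counts = manifest["n_timepoints"].unique()
    if t_counts.size != 1:
        raise ValueError(
            f"subjects disagree on retained timepoints: {t_counts.tolist()}"
        )
    series = []
    for _, row in manifest.iterrows():
        m = read_matrix(cohort_dir / row["file"])
        if m.shape[1] != row["n_timepoints"]:
            raise ValueError(
                f"{row['file']}: {m.shape[1]} timepoints, manifest says "
                f"{row['n_timepoints']}"
            )
        series.append(m)
    node_file = cohort_dir / "node_ids.txt"
    if node_file.exists():
        node_ids = node_file.read_text().split()
    else:
        node_ids = [f"node-{i + 1:03d}" for i in range(series[0].shape[0])]
    return BoldCohort(
        series=tuple(series),
        tr_seconds=float(trs[0]),
        group_labels=tuple(manifest["group"]),
        node_ids=tuple(node_ids),
        subject_ids=tuple(manifest["subject"]),
    )
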