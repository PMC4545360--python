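"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated.  Expression tables come in two dialects: a plain
TSV whose first column holds probe ids, and the GEO Series-Matrix style,
where metadata lines start with ``!`` and the expression table sits between
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.  Each
expression table is accompanied by a two-column sample sheet assigning every
sample to ``control`` or ``case``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .linking import ANNOTATION_COLUMNS, AliasTable
from .sam import CASE, CONTROL, ExperimentMatrix

__all__ = [
    "read_experiment",
    "write_experiment",
    "read_annotation",
    "read_alias_table",
    "read_truth",
]

_GROUPS = {CONTROL, CASE}


def _read_series_matrix(path: Path) -> pd.DataFrame:
    """Expression table from a Series-Matrix-style file."""
    rows: list[list[str]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.lower().startswith("!series_matrix_table_end"):
                break
            if in_table:
                rows.append([f.strip().strip('"') for f in stripped.split("\t")])
    if not rows:
        raise ValueError(f"no series_matrix table found in {path}")
    header, *data = rows
    frame = pd.DataFrame(data, columns=header)
    frame = frame.set_index(header[0])
    return frame.apply(pd.to_numeric, errors="coerce")


def _is_series_matrix(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("!")
    return False


def read_experiment(
    expr_path: str | os.PathLike,
    samplesheet_path: str | os.PathLike,
    experiment_id: str | None = None,
    platform_id: str = "platform",
    strict: bool = True,
) -> ExperimentMatrix:
    """Load one two-group experiment from an expression TSV + sample sheet.

    The sheet must cover every expression column and use only the labels
    ``control`` and ``case``; duplicated probe ids are an error.
    """
    expr_path = Path(expr_path)
    if _is_series_matrix(expr_path):
        frame = _read_series_matrix(expr_path)
    else:
        frame = pd.read_csv(expr_path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicated probe ids in {expr_path}: {dupes[:5]}")

    sheet = pd.read_csv(samplesheet_path, sep="\t")
    if sheet.shape[1] < 2:
        raise ValueError("sample sheet needs (sample, group) columns")
    sheet_map = dict(zip(sheet.iloc[:, 0].astype(str), sheet.iloc[:, 1].astype(str)))
    bad_groups = set(sheet_map.values()) - _GROUPS
    if bad_groups:
        raise ValueError(f"unknown group labels in sample sheet: {sorted(bad_groups)}")
    missing = [s for s in frame.columns if str(s) not in sheet_map]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")

    groups = np.array([sheet_map[str(s)] for s in frame.columns], dtype=object)
    return ExperimentMatrix(
        probe_ids=[str(p) for p in frame.index],
        values=frame.to_numpy(dtype=float),
        groups=groups,
        experiment_id=experiment_id or expr_path.stem.split(".")[0],
        platform_id=platform_id,
        sample_ids=[str(s) for s in frame.columns],
        strict=strict,
    )


def write_experiment(
    matrix: ExperimentMatrix,
    expr_path: str | os.PathLike,
    samplesheet_path: str | os.PathLike,
) -> None:
    frame = pd.DataFrame(
        matrix.values, index=pd.Index(matrix.probe_ids, name="probe"), columns=matrix.sample_ids
    )
    frame.to_csv(expr_path, sep="\t", float_format="%.6f")
    sheet = pd.DataFrame({"sample": matrix.sample_ids, "group": matrix.groups})
    sheet.to_csv(samplesheet_path, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", dtype={"platform": str, "probe": str, "symbol": str}, keep_default_na=False
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {missing}")
    frame["symbol"] = frame["symbol"].fillna("")
    frame["chromosome"] = frame["chromosome"].replace("", None)
    frame["position"] = pd.to_numeric(frame["position"], errors="coerce")
    return frame


def read_alias_table(path: str | os.PathLike) -> AliasTable:
    frame = pd.read_csv(path, sep="\t")
    return AliasTable.from_frame(frame)


def read_truth(path: str | os.PathLike) -> tuple[set[str], dict[str, int]]:
    frame = pd.read_csv(path, sep="\t")
    genes = [str(g) for g in frame["gene"]]
    directions = {g: int(d) for g, d in zip(genes, frame["direction"])}
    return set(genes), directions
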