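"""Delimited-text input with schema validation, plus TAC table reading."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .quantify import TimeActivityCurve

logger = logging.getLogger(__name__)

CALIBRATION_COLUMNS = ("subject_id", "group", "standard_suvr", "method_value")
LONGITUDINAL_COLUMNS = ("subject_id", "baseline_cl", "followup_cl", "interval")

_NUMERIC = {
    "calibration": ("standard_suvr", "method_value"),
    "longitudinal": ("baseline_cl", "followup_cl", "interval"),
}
_REQUIRED = {"calibration": CALIBRATION_COLUMNS, "longitudinal": LONGITUDINAL_COLUMNS}


def read_cohort_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a cohort table (comma-separated, header row).

    Parameters
    ----------
    path : path-like
        CSV file to read.
    kind : {"calibration", "longitudinal"}
        Schema to validate against.

    Returns
    -------
    pandas.DataFrame
        Validated records.  Malformed rows (non-numeric cells, non-positive
        intervals) are dropped; their 1-based file line numbers are logged
        and recorded in ``df.attrs["rejected_lines"]``.

    Raises
    ------
    SchemaError
        If a required column is missing, or no valid rows remain.
    """
    if kind not in _REQUIRED:
        raise ValueError(f"kind must be one of {sorted(_REQUIRED)}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")

    rejected: list[tuple[int, str]] = []
    numeric = _NUMERIC[kind]
    converted = {}
    bad = np.zeros(len(df), dtype=bool)
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna().to_numpy()
        converted[col] = vals
    if kind == "longitudinal":
        bad |= (converted["interval"] <= 0).fillna(True).to_numpy()
    for i in np.flatnonzero(bad):
        line_no = int(i) + 2  # header is line 1
        rejected.append((line_no, "non-numeric cell or non-positive interval"))
        logger.warning("%s: rejected line %d (%s)", path, line_no, rejected[-1][1])
    out = df.loc[~bad].copy()
    for col in numeric:
        out[col] = converted[col].loc[~bad].astype(float)
    if out.empty:
        raise SchemaError(f"{path}: no valid rows after validation")
    out = out.reset_index(drop=True)
    out.attrs["rejected_lines"] = rejected
    return out


def read_tac_table(path):
    """Read a TAC table: columns frame_mid_time_min, frame_duration_min, then
    one activity column per region.  Returns ``{region: TimeActivityCurve}``."""
    df = pd.read_csv(path)
    for col in ("frame_mid_time_min", "frame_duration_min"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column: {col}")
    mid = df["frame_mid_time_min"].to_numpy(float)
    dur = df["frame_duration_min"].to_numpy(float)
    regions = [c for c in df.columns if c not in ("frame_mid_time_min", "frame_duration_min")]
    if not regions:
        raise SchemaError(f"{path}: no region activity columns found")
    return {r: TimeActivityCurve(mid, dur, df[r].to_numpy(float)) for r in regions}


def read_mixing_matrix(path):
    """Read a square mixing matrix with a header of region names.

    Returns ``(region_names, matrix)``.
    """
    df = pd.read_csv(path)
    names = list(df.columns)
    m = df.to_numpy(float)
    if m.shape[0] != m.shape[1]:
        raise SchemaError(f"{path}: mixing matrix must be square, got {m.shape}")
    return names, m
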