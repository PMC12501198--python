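"""Time-series CSV input and measure-report output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .decompose import MeasureReport

__all__ = ["read_timeseries", "write_report", "read_report"]


def read_timeseries(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV of rows = time points, columns = variables.

    A header row is auto-detected (any non-numeric token in the first line);
    headerless files get generated column names v0..v{V-1}.  Ragged rows and
    missing values raise with the offending line identified.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",")]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t != "")
    try:
        df = pd.read_csv(path, header=0 if has_header else None, engine="python")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if not has_header:
        df.columns = [f"v{i}" for i in range(df.shape[1])]
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0]) + 1 + int(has_header)
        raise ValueError(f"missing value in {path} at data line {bad}")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"non-numeric column in {path}")
    return df


def write_report(report: MeasureReport, path: Union[str, Path], format: str = "json") -> None:
    """Serialize a MeasureReport as JSON (fixed key names, with an ``atoms``
    sub-map) or as a flat two-column CSV."""
    path = Path(path)
    d = report.to_dict()
    if format == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    elif format == "csv":
        rows = [(k, v) for k, v in d.items() if k not in ("atoms", "backend")]
        rows += [(f"atom:{lab}", v) for lab, v in d["atoms"].items()]
        pd.DataFrame(rows, columns=["measure", "bits"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; use 'json' or 'csv'")


def read_report(path: Union[str, Path]) -> MeasureReport:
    """Round-trip counterpart of ``write_report`` for the JSON format."""
    return MeasureReport.from_dict(json.loads(Path(path).read_text()))
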