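"""Reading reaction-time files and serializing reports.

Input is plain text — one numeric observation (ms) per line — or any
delimited file with a column selector.  Output reports are JSON with
stable field names; histograms and bin scans serialize as TSV.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .fitting import FitResult, HistogramDensity
from .gof import BinScanRow, GofReport, TrimReport

__all__ = ["read_rt_file", "write_report", "report_to_dict"]


def read_rt_file(path, column: Optional[Union[str, int]] = None) -> np.ndarray:
    """Load an RT sample from a text file.

    With ``column=None`` the file must hold one number per line (blank
    lines are skipped).  Otherwise the file is parsed as a delimited
    table (comma/tab/whitespace sniffed by pandas) and `column` selects
    a column by name or zero-based integer index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if column is None:
        values = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                text = raw.strip()
                if not text:
                    continue
                try:
                    values.append(float(text))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse {text!r} as a number"
                    ) from None
        if not values:
            raise ValueError(f"{path}: no observations found")
        return np.asarray(values, dtype=float)

    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    if isinstance(column, int) or (isinstance(column, str) and column.isdigit()):
        idx = int(column)
        if idx >= df.shape[1]:
            raise ValueError(f"{path}: column index {idx} out of range")
        series = df.iloc[:, idx]
    else:
        if column not in df.columns:
            raise ValueError(
                f"{path}: no column named {column!r}; available: {list(df.columns)}"
            )
        series = df[column]
    values = pd.to_numeric(series, errors="raise").to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"{path}: no observations found in column {column!r}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: column {column!r} contains non-finite values")
    return values


def report_to_dict(result) -> dict:
    """Dict form of any report object, with the package version attached."""
    from . import __version__

    if isinstance(result, (FitResult, GofReport, TrimReport)):
        d = result.to_dict()
    elif isinstance(result, dict):
        d = dict(result)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    d["version"] = __version__
    return d


def _scan_rows_tsv(rows: Sequence[BinScanRow]) -> str:
    lines = ["nbins\tmu\tsigma\ttau\tp\tconverged\terror"]
    for r in rows:
        if r.params is not None:
            mu, sigma, tau = r.params
            vals = [f"{mu:.6g}", f"{sigma:.6g}", f"{tau:.6g}"]
        else:
            vals = ["", "", ""]
        p = "" if r.p is None else f"{r.p:.6g}"
        err = r.error or ""
        lines.append(f"{r.nbins}\t" + "\t".join(vals) + f"\t{p}\t{r.converged}\t{err}")
    return "\n".join(lines) + "\n"


def _hist_tsv(hist: HistogramDensity) -> str:
    lines = ["bin_left\tbin_right\tdensity"]
    for lo, hi, d in zip(hist.edges[:-1], hist.edges[1:], hist.densities):
        lines.append(f"{lo:.8g}\t{hi:.8g}\t{d:.8g}")
    return "\n".join(lines) + "\n"


def write_report(result, path=None, fmt: str = "json") -> None:
    """Serialize a report to `path` (or stdout when `path` is None).

    JSON for fit/GoF/trim reports and dicts; TSV for histograms and
    lists of bin-scan rows.
    """
    if isinstance(result, HistogramDensity):
        text = _hist_tsv(result)
    elif isinstance(result, (list, tuple)) and all(
        isinstance(r, BinScanRow) for r in result
    ):
        text = _scan_rows_tsv(result)
    elif fmt == "json":
        text = json.dumps(report_to_dict(result), indent=2) + "\n"
    else:
        d = report_to_dict(result)
        lines = ["\t".join(str(k) for k in d), "\t".join(str(v) for v in d.values())]
        text = "\n".join(lines) + "\n"
    if path is None:
        sys.stdout.write(text)
    else:
        Path(path).write_text(text)
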