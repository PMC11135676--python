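"""Tab-separated table I/O for every pipeline stage.

All tables are TSV: tab-delimited, UTF-8, header row, "." decimal.  Output
files may begin with ``#`` provenance comment lines (package version,
config hash, seed), which readers skip.  Loaders validate the schema and
name the offending column or row on failure.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import FlowSample
from .footprint import Trace
from .kinetics import GrowthCurve, ProductionCurve

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "load_growth_curves",
    "load_production_curves",
    "load_flow_samples",
    "load_trace",
]


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a TSV table, skipping ``#`` comment lines; check required columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise SchemaError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write a TSV table with optional ``#`` provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for line in header_comments or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {bad[0]}")
    return values.to_numpy(dtype=float)


def load_growth_curves(path) -> list[GrowthCurve]:
    """Load OD600 curves from a TSV with columns strain, replicate, time_h,
    od600.  Rows with od600 <= 0 are rejected with their row index."""
    df = read_table(path, required=("strain", "replicate", "time_h", "od600"))
    od = _numeric(df, "od600", path)
    bad = np.nonzero(od <= 0)[0]
    if bad.size:
        raise SchemaError(f"{path}: od600 <= 0 in column 'od600', row {bad[0]}")
    _numeric(df, "time_h", path)
    curves = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                replicate=str(rep),
                times=grp["time_h"].to_numpy(dtype=float),
                od600=grp["od600"].to_numpy(dtype=float),
            )
        )
    return curves


def load_production_curves(path) -> list[ProductionCurve]:
    """Load A410 curves from a TSV with columns strain, replicate, time_h, a410."""
    df = read_table(path, required=("strain", "replicate", "time_h", "a410"))
    _numeric(df, "a410", path)
    _numeric(df, "time_h", path)
    curves = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            ProductionCurve(
                strain=str(strain),
                replicate=str(rep),
                times=grp["time_h"].to_numpy(dtype=float),
                a410=grp["a410"].to_numpy(dtype=float),
            )
        )
    return curves


def load_flow_samples(path) -> list[FlowSample]:
    """Load event-level fluorescence from a TSV with columns sample_id,
    strain, is_control, fluorescence (one row per event)."""
    df = read_table(path, required=("sample_id", "strain", "is_control", "fluorescence"))
    _numeric(df, "fluorescence", path)
    samples = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        is_control = bool(grp["is_control"].astype(bool).iloc[0])
        samples.append(
            FlowSample(
                sample_id=str(sample_id),
                strain=str(grp["strain"].iloc[0]),
                events=grp["fluorescence"].to_numpy(dtype=float),
                is_control=is_control,
            )
        )
    return samples


def load_trace(path, label: str) -> Trace:
    """Load one electropherogram from a TSV with columns scan,
    sample_signal, ladder_signal."""
    df = read_table(path, required=("scan", "sample_signal", "ladder_signal"))
    return Trace(
        scan=_numeric(df, "scan", path),
        sample_signal=_numeric(df, "sample_signal", path),
        ladder_signal=_numeric(df, "ladder_signal", path),
        label=label,
    )
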