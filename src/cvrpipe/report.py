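"""Report tables and the run manifest.

Builds the per-subject summary tables (subject rows plus a mean (SE) row,
optionally median +/- IQR for skewed counts), the tidy regional CSVs, the
fractional-distribution CSV, and a JSON manifest recording every
parameter, seed and the software version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .regional import FrequencyDistribution
from .stats import mean_se, median_iqr

__all__ = [
    "summarize_subjects",
    "percent_change_columns",
    "distribution_frame",
    "build_report",
]


def summarize_subjects(
    df: pd.DataFrame,
    value_columns: list[str] | None = None,
    subject_column: str = "subject",
    median_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Append mean and SE rows (and optional median/IQR rows) to a table.

    The appended ``mean`` row is the arithmetic mean of the subject rows;
    NaN entries (e.g. an unreadable measurement) are dropped column-wise.
    """
    if value_columns is None:
        value_columns = [c for c in df.columns if c != subject_column]
    out = df.copy()
    stats_rows = {}
    for stat in ("mean", "se"):
        stats_rows[stat] = {subject_column: stat}
    for col in value_columns:
        vals = df[col].dropna().to_numpy(float)
        m, se = mean_se(vals)
        stats_rows["mean"][col] = m
        stats_rows["se"][col] = se
    extra = [pd.Series(stats_rows["mean"]), pd.Series(stats_rows["se"])]
    if median_columns:
        med_row = {subject_column: "median"}
        iqr_row = {subject_column: "iqr"}
        for col in median_columns:
            vals = df[col].dropna().to_numpy(float)
            med, iqr = median_iqr(vals)
            med_row[col] = med
            iqr_row[col] = iqr
        extra += [pd.Series(med_row), pd.Series(iqr_row)]
    return pd.concat([out, pd.DataFrame(extra)], ignore_index=True)


def percent_change_columns(df: pd.DataFrame, pairs: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Add percent-change columns computed from (pre, post) column pairs."""
    out = df.copy()
    for new, (pre, post) in pairs.items():
        out[new] = 100.0 * (out[post] - out[pre]) / out[pre]
    return out


def distribution_frame(dist: FrequencyDistribution, session: str = "") -> pd.DataFrame:
    """Tidy frame of a fractional CVR distribution (one row per bin)."""
    centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
    return pd.DataFrame(
        {
            "session": session,
            "bin_center": centers,
            "fraction": dist.fractions,
            "distribution_mean": dist.mean,
        }
    )


def build_report(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    manifest: dict | None = None,
) -> dict:
    """Write report CSVs and a JSON manifest; return the manifest.

    ``tables`` maps file stems to DataFrames.  Missing stages are simply
    absent from the report; a manifest is always written so a partial run
    still leaves a complete record of its parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (tables or {}).items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path.name)
    record = {
        "software": f"cvrpipe {__version__}",
        "tables": written,
        **(manifest or {}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(record, fh, indent=2, default=_json_default)
    return record


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
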