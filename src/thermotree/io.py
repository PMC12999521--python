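"""Table readers/writers, schema validation, and QC filtering.

All tabular interfaces are UTF-8 CSV with ``.`` decimals; trees travel as
Newick.  Output tables carry a ``#`` comment header recording the package
version, seed, and configuration hash so every result is reproducible from
(version, seed, config).  Readers validate required columns up front
(:class:`~thermotree.errors.SchemaError` naming the missing ones) and
report unparseable rows with line numbers; unknown columns pass through
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .tdt import TemperatureSeries

__all__ = [
    "QCPolicy",
    "read_assays",
    "read_plots",
    "read_series",
    "read_tm",
    "write_table",
    "write_series",
    "apply_qc",
]

ASSAY_COLUMNS = [
    "individual_id",
    "plot_id",
    "elevation",
    "direction",
    "shocked",
    "ct_value",
]
PLOT_COLUMNS = ["plot_id", "elevation", "bio1", "bio5"]
SERIES_COLUMNS = ["plot_id", "timestamp", "value", "kind", "qc"]
TM_COLUMNS = ["species_id", "family", "order", "protein_id", "tm"]

CTMAX_RANGE = (25.0, 60.0)
CTMIN_RANGE = (-10.0, 28.0)


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    return pd.read_csv(path, comment="#")


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns: {', '.join(missing)}"
        )


def read_assays(path) -> pd.DataFrame:
    """Read and validate an assay record table."""
    df = _read_csv(path)
    _require(df, ASSAY_COLUMNS, path)
    df["elevation"] = pd.to_numeric(df["elevation"], errors="raise")
    df["ct_value"] = pd.to_numeric(df["ct_value"], errors="raise")
    for direction, (lo, hi) in (("ctmax", CTMAX_RANGE), ("ctmin", CTMIN_RANGE)):
        sel = df["direction"] == direction
        bad = df.loc[sel & ((df["ct_value"] < lo) | (df["ct_value"] > hi))]
        if not bad.empty:
            warnings.warn(
                f"{path}: {len(bad)} {direction} values outside [{lo}, {hi}]",
                stacklevel=2,
            )
    return df


def read_plots(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, PLOT_COLUMNS, path)
    for col in df.columns:
        if col != "plot_id":
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_series(path) -> list:
    """Read a temperature-series table into one series per plot x kind."""
    df = _read_csv(path)
    _require(df, SERIES_COLUMNS, path)
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = np.flatnonzero(parsed.isna().to_numpy())
    if bad.size:
        raise SchemaError(
            f"{path}: unparseable timestamps at data rows "
            f"{', '.join(map(str, (bad + 2)[:10]))}"
        )
    df = df.assign(timestamp=parsed)
    out = []
    for (plot, kind), grp in df.groupby(["plot_id", "kind"], sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            TemperatureSeries(
                plot_id=plot,
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                values=grp["value"].to_numpy(float),
                kind=kind,
                qc=grp["qc"].astype(str).to_numpy(),
            )
        )
    return out


def read_tm(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, TM_COLUMNS, path)
    df["tm"] = pd.to_numeric(df["tm"], errors="raise")
    return df


def write_table(
    df: pd.DataFrame, path, seed=None, config_hash=None
) -> None:
    """Write a CSV with a provenance comment header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# thermotree v{__version__}"
    if seed is not None:
        header += f" seed={seed}"
    if config_hash is not None:
        header += f" config={config_hash}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def write_series(series_list, path, seed=None, config_hash=None) -> None:
    frames = [s.to_frame() for s in series_list]
    write_table(pd.concat(frames, ignore_index=True), path, seed, config_hash)


@dataclass(frozen=True)
class QCPolicy:
    """Which quality flags to retain; the default keeps best-quality only."""

    keep_flags: frozenset = field(default_factory=lambda: frozenset({"0b00"}))
    action: str = "drop"

    def __post_init__(self):
        if not self.keep_flags:
            raise ValueError("keep_flags must be non-empty")
        if self.action not in ("drop", "warn"):
            raise ValueError("action must be 'drop' or 'warn'")


def apply_qc(series: TemperatureSeries, policy: QCPolicy) -> TemperatureSeries:
    """Retain only values whose QC flag is in the keep set.

    With ``action='warn'`` the series is returned unchanged and flagged
    values are only reported.  Dropping everything is a warning, not an
    error.
    """
    if series.qc is None:
        raise ValueError("series has no qc flags")
    keep = np.isin(series.qc, list(policy.keep_flags))
    n_drop = int((~keep).sum())
    if policy.action == "warn":
        if n_drop:
            warnings.warn(
                f"plot {series.plot_id}: {n_drop} values fail QC (kept)",
                stacklevel=2,
            )
        return series
    if n_drop == len(series):
        warnings.warn(
            f"plot {series.plot_id}: all values dropped by QC", stacklevel=2
        )
    return TemperatureSeries(
        plot_id=series.plot_id,
        timestamps=series.timestamps[keep],
        values=series.values[keep],
        kind=series.kind,
        qc=series.qc[keep],
    )
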