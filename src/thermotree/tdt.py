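"""Thermal-death-time (TDT) engine.

The TDT model links constant exposure temperature ``T`` to the time until
heat coma through a log-linear law::

    log10(t_coma) = (T_L - T) / z + log10(t_ref)

where ``z`` (degC per tenfold change in time) is the thermal sensitivity,
and ``T_L`` is the static temperature causing coma at the reference time
``t_ref`` (1 min by default).  Ramping assays measure a *dynamic* critical
temperature instead; assuming injury accumulates at rate ``1 / t_coma(T)``
and coma occurs when accumulated injury reaches 1, a linear ramp from
``start_temp`` at rate ``r`` knocks the insect down at ``ct_dyn``
satisfying::

    (z / (r ln10 t_ref)) * (10^((ct_dyn - T_L)/z) - 10^((start - T_L)/z)) = 1

which this module inverts in closed form to recover ``T_L`` from ``ct_dyn``.
Downstream, any temperature series can be classified against the exposure
threshold (8 h by default): a value is *critical* when the predicted coma
time at that constant temperature is at or below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    ImplausibleSensitivityError,
    MissingMetadataError,
)

__all__ = [
    "TDTParams",
    "TemperatureSeries",
    "fit_z",
    "dynamic_to_static",
    "simulate_ramp_knockdown",
    "t_coma",
    "critical_temperature",
    "classify_critical",
    "project_series",
    "community_sensitivity",
    "summarize_coma",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class TDTParams:
    """Static tolerance landscape: sensitivity ``z`` and anchor ``T_L``."""

    z: float
    t_l: float
    t_ref: float = 1.0

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.t_ref <= 0:
            raise ValueError("t_ref must be > 0")


@dataclass
class TemperatureSeries:
    """Timestamped temperatures for one plot and measurement kind."""

    plot_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    kind: str = "air15cm"
    qc: np.ndarray | None = None

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, float)
        if len(self.timestamps) != self.values.size:
            raise ValueError("timestamps and values must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("temperature values must be finite")
        if self.values.size > 1 and not (np.diff(self.timestamps.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.qc is not None:
            self.qc = np.asarray(self.qc)
            if self.qc.size != self.values.size:
                raise ValueError("qc flags must align with values")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "plot_id": self.plot_id,
                "timestamp": self.timestamps,
                "value": self.values,
                "kind": self.kind,
            }
        )
        df["qc"] = self.qc if self.qc is not None else "0b00"
        return df


# ---------------------------------------------------------------------------
# parameter estimation and conversions
# ---------------------------------------------------------------------------


def fit_z(knockdowns: pd.DataFrame, t_ref: float = 1.0) -> TDTParams:
    """Estimate (z, T_L) from a static knockdown table.

    Ordinary least squares of log10(time_min) on temp_c; ``z = -1/slope``
    and ``T_L`` is the temperature at which the fitted time equals
    ``t_ref``.  Requires at least two distinct temperatures and a negative
    slope (times must shorten as temperature rises).
    """
    temp = np.asarray(knockdowns["temp_c"], float)
    time = np.asarray(knockdowns["time_min"], float)
    if np.unique(temp).size < 2:
        raise ValueError("need at least two distinct temperatures")
    slope, intercept = np.polyfit(temp, np.log10(time), 1)
    if slope >= 0:
        raise ImplausibleSensitivityError(
            f"knockdown time does not decrease with temperature (slope={slope:.3g})"
        )
    z = -1.0 / slope
    t_l = (np.log10(t_ref) - intercept) / slope
    return TDTParams(z=z, t_l=t_l, t_ref=t_ref)


def dynamic_to_static(
    ct_dyn: float,
    ramp_rate: float,
    z: float,
    t_ref: float = 1.0,
    start_temp: float = 28.0,
    approx: bool = False,
) -> float:
    """Convert a ramping-assay CT_max into the static anchor ``T_L``.

    Inverts the injury-accumulation integral for a linear ramp (module
    docstring).  With ``approx=True`` the sub-threshold injury accumulated
    before the ramp start is dropped, giving the familiar closed form
    ``T_L = ct_dyn - z log10(r t_ref ln10 / z)``; the two agree closely
    whenever ``start_temp <= ct_dyn - 3z``.
    """
    if ramp_rate <= 0:
        raise ValueError("ramp_rate must be > 0")
    if ct_dyn <= start_temp:
        raise ValueError("ct_dyn must exceed start_temp")
    if approx:
        return ct_dyn - z * np.log10(ramp_rate * t_ref * LN10 / z)
    gap = 10.0 ** (ct_dyn / z) - 10.0 ** (start_temp / z)
    return z * np.log10(z * gap / (ramp_rate * LN10 * t_ref))


def simulate_ramp_knockdown(
    params: TDTParams,
    ramp_rate: float,
    start_temp: float = 28.0,
    dt_min: float = 0.001,
    max_temp_above_tl: float = 30.0,
) -> float:
    """Forward-simulate a linear ramp and return the knockdown temperature.

    Numerically accumulates injury at rate ``1 / t_coma(T(t))`` on a fine
    time grid (trapezoid rule) until it reaches 1.  Used as an independent
    check on the closed-form :func:`dynamic_to_static` inversion.
    """
    t_end = (params.t_l + max_temp_above_tl - start_temp) / ramp_rate
    times = np.arange(0.0, t_end + dt_min, dt_min)
    temps = start_temp + ramp_rate * times
    rate = 1.0 / t_coma(temps, params)
    injury = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt_min)]
    )
    if injury[-1] < 1.0:
        raise RuntimeError("ramp ended before injury reached 1; extend the grid")
    return float(np.interp(1.0, injury, temps))


def t_coma(T, params: TDTParams):
    """Predicted minutes to heat coma at constant temperature ``T``."""
    return params.t_ref * 10.0 ** ((params.t_l - np.asarray(T, float)) / params.z)


def critical_temperature(params: TDTParams, threshold_min: float = 480.0) -> float:
    """Constant temperature at which coma occurs within ``threshold_min``."""
    return params.t_l - params.z * np.log10(threshold_min / params.t_ref)


def classify_critical(
    series: TemperatureSeries,
    params: TDTParams,
    threshold_min: float = 480.0,
):
    """Flag values whose coma time is at or below the threshold.

    Returns ``(mask, fraction)`` where the fraction is over *all* retained
    values (night temperatures included).
    """
    if len(series) == 0:
        raise EmptyInputError(f"series for plot {series.plot_id} is empty")
    mask = series.values >= critical_temperature(params, threshold_min) - 1e-12
    return mask, float(mask.mean())


def project_series(
    series: TemperatureSeries, bio5_now: float, bio5_future: float
) -> TemperatureSeries:
    """Shift every value by the bio5 anomaly; timestamps unchanged."""
    if bio5_now is None or bio5_future is None or (
        not np.isfinite(bio5_now) or not np.isfinite(bio5_future)
    ):
        raise MissingMetadataError(
            f"bio5 normals missing for plot {series.plot_id}"
        )
    return TemperatureSeries(
        plot_id=series.plot_id,
        timestamps=series.timestamps,
        values=series.values + (bio5_future - bio5_now),
        kind=series.kind,
        qc=None if series.qc is None else series.qc.copy(),
    )


def community_sensitivity(
    lowland_ctmax,
    quantiles=(0.10, 0.25, 0.50),
    ramp_rate: float = 0.5,
    z: float = 3.0,
    t_ref: float = 1.0,
    start_temp: float = 28.0,
) -> dict:
    """Community CT_max quantiles converted to static tolerance landscapes.

    Mirrors the gradient-wide "most heat-sensitive / more heat-sensitive /
    average" grouping: each requested quantile of the lowland CT_max sample
    is converted through :func:`dynamic_to_static` into one
    :class:`TDTParams` applied across all plots.  Keys are ``q10``/``q25``/
    ``median`` style labels.
    """
    values = np.asarray(lowland_ctmax, float)
    out = {}
    for q in quantiles:
        label = "median" if abs(q - 0.5) < 1e-12 else f"q{int(round(q * 100))}"
        ct_q = float(np.quantile(values, q))
        out[label] = TDTParams(
            z=z,
            t_l=dynamic_to_static(ct_q, ramp_rate, z, t_ref, start_temp),
            t_ref=t_ref,
        )
    return out


def summarize_coma(
    series_list,
    sensitivities: dict,
    plot_normals: pd.DataFrame,
    scenarios=("current",),
    threshold_min: float = 480.0,
) -> pd.DataFrame:
    """Fractions of critical temperatures per plot x kind x scenario x group.

    ``plot_normals`` must contain ``plot_id``, ``bio5`` (current normal) and
    one ``bio5_<scenario>`` column per non-current scenario; the anomaly
    ``bio5_<scenario> - bio5`` is added to each series before
    classification (surface series use the same air-derived anomaly).
    """
    normals = plot_normals.set_index("plot_id")
    rows = []
    for series in series_list:
        if series.plot_id not in normals.index:
            raise MissingMetadataError(f"no normals for plot {series.plot_id}")
        meta = normals.loc[series.plot_id]
        for scenario in scenarios:
            if scenario == "current":
                shifted = series
            else:
                col = f"bio5_{scenario}"
                if col not in normals.columns:
                    raise MissingMetadataError(
                        f"missing column {col} in plot normals"
                    )
                shifted = project_series(series, meta["bio5"], meta[col])
            for name, params in sensitivities.items():
                _, frac = classify_critical(shifted, params, threshold_min)
                rows.append(
                    {
                        "plot_id": series.plot_id,
                        "kind": series.kind,
                        "scenario": scenario,
                        "sensitivity": name,
                        "fraction_critical": frac,
                        "n": len(series),
                    }
                )
    return pd.DataFrame(rows)
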