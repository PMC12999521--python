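"""Community summaries of ramping-assay records.

Turns per-individual critical-temperature (CT) measurements into the
plot-level summaries used downstream: means and quantiles per plot and
assay direction, elevational trends (ordinary least squares or a
penalized spline with basis dimension 5), thermal tolerance ranges and
safety margins against climate normals, heat/cold-shock (plasticity)
effects per elevation band with a tolerance-oriented sign convention, and
a one-way observer ANOVA.

Quantiles use linear interpolation between order statistics (numpy's
default, the common "type 7" rule) everywhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, MissingMetadataError

__all__ = [
    "TrendFit",
    "summarize_plots",
    "fit_elevation_trend",
    "thermal_range_and_margin",
    "shock_effect",
    "observer_anova",
    "ELEVATION_BANDS",
]

# half-open elevation bands: lowland < 600, mid [600, 1200), high >= 1200 masl
ELEVATION_BANDS = (600.0, 1200.0)
_BAND_LABELS = ("low", "mid", "high")


def summarize_plots(records: pd.DataFrame, normals: pd.DataFrame) -> pd.DataFrame:
    """One row per plot x direction with n, mean, median, q10, q25 of CT.

    ``normals`` must provide ``plot_id``, ``elevation``, ``bio1``, ``bio5``
    for every plot appearing in ``records``.
    """
    plots_seen = set(records["plot_id"].unique())
    norm = normals.set_index("plot_id")
    missing = sorted(plots_seen - set(norm.index))
    if missing:
        raise MissingMetadataError(
            f"plots without climate normals: {', '.join(map(str, missing))}"
        )
    rows = []
    for (plot, direction), grp in records.groupby(["plot_id", "direction"]):
        ct = grp["ct_value"].to_numpy(float)
        meta = norm.loc[plot]
        rows.append(
            {
                "plot_id": plot,
                "direction": direction,
                "elevation": float(meta["elevation"]),
                "n": ct.size,
                "mean": float(ct.mean()),
                "median": float(np.quantile(ct, 0.5)),
                "q10": float(np.quantile(ct, 0.10)),
                "q25": float(np.quantile(ct, 0.25)),
                "bio1": float(meta["bio1"]),
                "bio5": float(meta["bio5"]),
            }
        )
    return pd.DataFrame(rows).sort_values(["plot_id", "direction"]).reset_index(
        drop=True
    )


@dataclass
class TrendFit:
    """Elevational (or MAT) trend: linear OLS or penalized spline."""

    mode: str
    slope: float | None
    intercept: float | None
    fvalue: float
    pvalue: float
    grid_x: np.ndarray
    grid_y: np.ndarray
    edf: float | None = None

    def predict(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, float), self.grid_x, self.grid_y)


def fit_elevation_trend(
    x, y, mode: str = "linear", grid: np.ndarray | None = None
) -> TrendFit:
    """Fit CT against elevation or mean annual temperature.

    ``linear`` returns OLS slope/intercept with the overall F test;
    ``spline_k5`` fits a cubic regression spline with basis dimension 5,
    the penalty weight chosen by generalized cross-validation, and reports
    the fitted curve on a grid (the F/p values are those of the spline
    terms' joint significance against the constant model).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) < 1e-12:
        raise DegenerateDesignError("predictor is constant")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 200)

    if mode == "linear":
        if x.size < 3:
            raise ValueError("need >= 3 points for a linear trend")
        if np.ptp(y) < 1e-15:
            return TrendFit("linear", 0.0, float(y[0]), 0.0, 1.0, grid,
                            np.full_like(grid, float(y[0])))
        res = stats.linregress(x, y)
        fval = res.rvalue**2 / max(1 - res.rvalue**2, 1e-300) * (x.size - 2)
        yhat = res.intercept + res.slope * grid
        return TrendFit("linear", float(res.slope), float(res.intercept),
                        float(fval), float(res.pvalue), grid, yhat)

    if mode == "spline_k5":
        if x.size < 6:
            raise ValueError("need >= 6 points for the spline trend")
        from statsmodels.gam.smooth_basis import BSplines

        order = np.argsort(x)
        xs, ys = x[order], y[order]
        bs = BSplines(xs[:, None], df=[5], degree=[3], include_intercept=True)
        B = np.column_stack([np.ones(xs.size), bs.basis])
        P = np.zeros((B.shape[1], B.shape[1]))
        P[1:, 1:] = bs.penalty_matrices[0]  # curvature penalty
        n = xs.size
        BtB, Bty = B.T @ B, B.T @ ys

        def fit_pls(alpha: float):
            coef = np.linalg.solve(BtB + alpha * P, Bty)
            H_trace = np.trace(np.linalg.solve(BtB + alpha * P, BtB))
            resid = ys - B @ coef
            rss = float(resid @ resid)
            gcv = n * rss / max(n - H_trace, 1e-8) ** 2
            return coef, rss, H_trace, gcv

        # GCV over a log-spaced penalty grid (flat fallback for exact fits)
        alphas = np.geomspace(1e-8, 1e8, 33) * max(np.trace(BtB), 1.0)
        fits = [fit_pls(a) for a in alphas]
        best = int(np.argmin([f[3] for f in fits]))
        coef, rss, edf, _ = fits[best]
        grid_clipped = np.clip(grid, xs.min(), xs.max())
        Bg = np.column_stack(
            [np.ones(grid.size), bs.transform(grid_clipped[:, None])]
        )
        yhat = Bg @ coef
        # F test of the smooth against the constant model
        ss0 = float(((ys - ys.mean()) ** 2).sum())
        df1 = max(edf - 1.0, 1e-8)
        df2 = max(n - edf, 1e-8)
        if rss <= 1e-12 * max(ss0, 1.0):
            fval = np.inf if ss0 > 0 else 0.0
            pval = 0.0 if ss0 > 0 else 1.0
        else:
            fval = ((ss0 - rss) / df1) / (rss / df2)
            pval = float(stats.f.sf(fval, df1, df2))
        return TrendFit("spline_k5", None, None, float(fval), pval, grid,
                        np.asarray(yhat, float), edf=float(edf))

    raise ValueError(f"unknown trend mode: {mode}")


def thermal_range_and_margin(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-plot tolerance range and safety margins.

    range = mean CT_max - mean CT_min; margins subtract the bio1 / bio5
    normals from mean CT_max.  Plots lacking either assay direction are
    skipped with a warning.
    """
    rows = []
    for plot, grp in summaries.groupby("plot_id"):
        by_dir = grp.set_index("direction")
        if "ctmax" not in by_dir.index:
            warnings.warn(f"plot {plot} lacks ctmax; skipped", stacklevel=2)
            continue
        hot = by_dir.loc["ctmax"]
        row = {
            "plot_id": plot,
            "elevation": float(hot["elevation"]),
            "margin_bio1": float(hot["mean"] - hot["bio1"]),
            "margin_bio5": float(hot["mean"] - hot["bio5"]),
        }
        if "ctmin" in by_dir.index:
            row["range"] = float(hot["mean"] - by_dir.loc["ctmin", "mean"])
        else:
            warnings.warn(f"plot {plot} lacks ctmin; range omitted", stacklevel=2)
            row["range"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _band_label(elevation: np.ndarray, bands) -> np.ndarray:
    idx = np.digitize(elevation, bands, right=False)
    return np.asarray(_BAND_LABELS)[idx]


def shock_effect(
    records: pd.DataFrame, bands=ELEVATION_BANDS
) -> pd.DataFrame:
    """Plasticity effect per elevation band and direction.

    The effect is oriented so that positive always means *increased
    tolerance*: shocked minus control means for CT_max, control minus
    shocked for CT_min.  Bands missing either group are omitted with a
    warning.  ``se`` is the standard error of the difference in means.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["band", "direction", "effect_c", "se", "n_shocked",
                     "n_control"]
        )
    df = records.copy()
    df["band"] = _band_label(df["elevation"].to_numpy(float), bands)
    rows = []
    for (band, direction), grp in df.groupby(["band", "direction"]):
        yes = grp.loc[grp["shocked"] == "yes", "ct_value"].to_numpy(float)
        no = grp.loc[grp["shocked"] == "no", "ct_value"].to_numpy(float)
        if yes.size == 0 or no.size == 0:
            warnings.warn(
                f"band {band}/{direction}: missing shocked or control group",
                stacklevel=2,
            )
            continue
        effect = yes.mean() - no.mean()
        if direction == "ctmin":
            effect = -effect
        se = np.sqrt(
            (yes.var(ddof=1) / yes.size if yes.size > 1 else 0.0)
            + (no.var(ddof=1) / no.size if no.size > 1 else 0.0)
        )
        rows.append(
            {
                "band": band,
                "direction": direction,
                "effect_c": float(effect),
                "se": float(se),
                "n_shocked": yes.size,
                "n_control": no.size,
            }
        )
    return pd.DataFrame(rows)


def observer_anova(records: pd.DataFrame):
    """One-way fixed-effects ANOVA of CT on observer: (F, df1, df2, p)."""
    groups = [
        grp["ct_value"].to_numpy(float)
        for _, grp in records.groupby("observer")
    ]
    if len(groups) < 2:
        raise ValueError("need at least two observers")
    if any(g.size < 2 for g in groups):
        raise ValueError("each observer needs at least two records")
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        fval = 0.0 if ss_between == 0 else np.inf
    else:
        fval = (ss_between / df1) / (ss_within / df2)
    pval = float(stats.f.sf(fval, df1, df2)) if np.isfinite(fval) else 0.0
    return float(fval), df1, df2, pval
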