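"""Protein melting-temperature (T_m) summaries and their link to CT_max.

Works on pre-computed per-protein T_m tables (one row per species x
protein).  The heat-sensitive proteome of a species is summarized by the
mean T_m of the proteins at or below the species' 25% T_m quantile;
family-level statistics average species first.  The T_m <-> CT_max
relationship across families is tested with unweighted and
species-count-weighted linear models, and order/family variation in T_m
with nested fixed-effect F tests on species means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "sensitive_quantile_mean",
    "family_tm_vs_ctmax",
    "tm_variance_tests",
]


def sensitive_quantile_mean(records: pd.DataFrame, q: float = 0.25) -> pd.Series:
    """Per-species mean T_m of the heat-sensitive (lowest-q) proteins.

    For each species, proteins whose T_m falls at or below the species'
    q-th empirical quantile (linear interpolation between order
    statistics) are averaged.  ``q = 1`` reduces to the ordinary mean.
    Species with no proteins are skipped with a warning.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    out = {}
    for species, grp in records.groupby("species_id"):
        tm = grp["tm"].to_numpy(float)
        if tm.size == 0:
            warnings.warn(f"species {species} has no proteins; skipped",
                          stacklevel=2)
            continue
        if tm.size < 4:
            warnings.warn(
                f"species {species} has only {tm.size} proteins", stacklevel=2
            )
        threshold = np.quantile(tm, q)
        out[species] = float(tm[tm <= threshold + 1e-12].mean())
    return pd.Series(out, name=f"tm_q{int(round(q * 100))}_mean")


def family_tm_vs_ctmax(
    family_tm: pd.Series, family_ctmax: pd.Series, weights: pd.Series
) -> dict:
    """Linear models of family mean CT_max on family T_m.

    Returns ``{"unweighted": ..., "weighted": ...}``, each a dict with
    slope, intercept and r2.  Weights are proportional to the number of
    species with genomic data per family.
    """
    idx = family_tm.index.intersection(family_ctmax.index)
    if len(idx) < 3:
        raise ValueError("need at least 3 families with both statistics")
    x = family_tm.reindex(idx).to_numpy(float)
    y = family_ctmax.reindex(idx).to_numpy(float)
    w = weights.reindex(idx).to_numpy(float)
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        raise ValueError("weights must be finite with positive sum")
    X = sm.add_constant(x)
    out = {}
    for name, ww in (("unweighted", np.ones_like(w)), ("weighted", w)):
        res = sm.WLS(y, X, weights=ww).fit()
        out[name] = {
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "r2": float(res.rsquared),
            "pvalue": float(res.pvalues[1]),
        }
    return out


def tm_variance_tests(records: pd.DataFrame) -> dict:
    """Nested fixed-effect F tests for order and family-within-order.

    Species are the exchangeable unit: per-species mean T_m values are
    computed first, then a sequential (type I) ANOVA of
    ``tm ~ order + family`` is run, so the family F statistic is the
    family-within-order effect.  Returns F and p for both terms with
    their degrees of freedom.
    """
    species = (
        records.groupby(["species_id", "family", "order"])["tm"]
        .mean()
        .reset_index()
    )
    if species["order"].nunique() < 2 or species["family"].nunique() < 2:
        raise ValueError("need >= 2 orders and >= 2 families")
    model = smf.ols("tm ~ C(order) + C(family)", data=species).fit()
    table = sm.stats.anova_lm(model, typ=1)
    return {
        "F_order": float(table.loc["C(order)", "F"]),
        "df_order": (
            int(table.loc["C(order)", "df"]),
            int(table.loc["Residual", "df"]),
        ),
        "p_order": float(table.loc["C(order)", "PR(>F)"]),
        "F_family": float(table.loc["C(family)", "F"]),
        "df_family": (
            int(table.loc["C(family)", "df"]),
            int(table.loc["Residual", "df"]),
        ),
        "p_family": float(table.loc["C(family)", "PR(>F)"]),
    }
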