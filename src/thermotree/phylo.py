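"""Phylogenetic comparative statistics for continuous traits.

Implements the comparative toolkit used on the CT_max supertree: ancestral
state reconstruction under Brownian motion (BM), the phylogenetic signal
statistics Pagel's lambda and Blomberg's K, a Moran's-I correlogram over
patristic distance classes, phylogenetic generalized least squares (PGLS)
under BM / Ornstein-Uhlenbeck (OU) / independent-observation covariance,
the OU evolutionary optimum theta, AIC model comparison, and a
likelihood-based partial-r2 variance partition.

All methods operate on dense tip covariance matrices built from a
:class:`~thermotree.trees.CalibratedTree`.  The OU covariance defaults to
the stationary (random-root) form

    C_ij = sigma2 / (2 alpha) * exp(-alpha d_ij)

with ``d_ij`` the patristic distance; the non-stationary fixed-root form is
available behind a flag.  Likelihoods are Gaussian; scale parameters are
profiled out analytically and only lambda (bounded scalar) or alpha
(log-scale grid plus bounded refinement) are searched numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .errors import (
    InvalidComparisonError,
    NumericalDegeneracyError,
    OptimizationFailureError,
)
from .trees import CalibratedTree

__all__ = [
    "PhyloFit",
    "LambdaFit",
    "KResult",
    "ancestral_states",
    "pagel_lambda",
    "blomberg_k",
    "phylo_correlogram",
    "pgls_fit",
    "fit_ou_optimum",
    "compare_models",
    "variance_partition",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class PhyloFit:
    """A fitted phylogenetic regression."""

    model: str  # "BM" | "OU" | "star"
    coef: pd.Series
    sigma2: float
    loglik: float
    aic: float
    n: int
    alpha: float | None = None
    theta: float | None = None
    boundary: bool = False
    partial_r2: dict = field(default_factory=dict)


@dataclass
class LambdaFit:
    lambda_hat: float
    loglik: float
    loglik0: float
    p_value: float


@dataclass
class KResult:
    k_hat: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _align_trait(tree: CalibratedTree, trait) -> np.ndarray:
    labels = tree.tip_labels
    if isinstance(trait, pd.Series):
        missing = [lab for lab in labels if lab not in trait.index]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        y = trait.reindex(labels).to_numpy(float)
    else:
        y = np.asarray(trait, float)
        if y.shape != (len(labels),):
            raise ValueError("trait length does not match number of tips")
    if not np.all(np.isfinite(y)):
        bad = [labels[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise ValueError(f"non-finite trait values at tips: {bad[:5]}")
    return y


def _design(tree: CalibratedTree, predictors) -> tuple[np.ndarray, list]:
    labels = tree.tip_labels
    if predictors is None or (
        hasattr(predictors, "shape") and getattr(predictors, "empty", False)
    ):
        return np.ones((len(labels), 1)), ["intercept"]
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame(
            {"x": np.asarray(predictors, float)}, index=labels
        )
    X = predictors.reindex(labels)
    if X.isna().any().any():
        raise ValueError("predictors incomplete for some tips")
    names = ["intercept"] + list(X.columns)
    return np.column_stack([np.ones(len(labels)), X.to_numpy(float)]), names


def _chol(V: np.ndarray):
    if not np.allclose(V, V.T, atol=1e-10):
        raise NumericalDegeneracyError("covariance matrix is not symmetric")
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(
            "covariance matrix is not positive definite"
        ) from exc


def _profile_gls(X: np.ndarray, y: np.ndarray, R: np.ndarray):
    """GLS with the scale profiled out of a correlation-like matrix ``R``.

    Model: y ~ N(X beta, s R).  Returns (beta, s_hat, loglik, cho_factor).
    """
    n = y.size
    cf = _chol(R)
    Ri_X = cho_solve(cf, X)
    Ri_y = cho_solve(cf, y)
    XtRiX = X.T @ Ri_X
    try:
        beta = np.linalg.solve(XtRiX, X.T @ Ri_y)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError("singular design in GLS") from exc
    resid = y - X @ beta
    q = float(resid @ cho_solve(cf, resid))
    s = max(q / n, 1e-300)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    loglik = -0.5 * (n * np.log(2 * np.pi * s) + n + logdet)
    return beta, s, loglik, cf


def _ou_correlation(D: np.ndarray, alpha: float) -> np.ndarray:
    R = np.exp(-alpha * D)
    np.fill_diagonal(R, 1.0)
    return R


def _ou_fixed_root(C: np.ndarray, D: np.ndarray, alpha: float) -> np.ndarray:
    """Non-stationary OU started at the root value (no stationary root draw).

    cov_ij = exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij)) / (2 alpha), up to
    the profiled scale; ``s_ij`` is the shared path length in ``C``.
    """
    return np.exp(-alpha * D) * (1.0 - np.exp(-2.0 * alpha * C))


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def ancestral_states(tree: CalibratedTree, trait) -> pd.DataFrame:
    """ML ancestral states under Brownian motion, in GLS form.

    For internal node *a* with tip covariance vector ``c_a`` (shared path
    length between *a* and each tip), the estimate is the best linear
    unbiased prediction ``mu + c_a' C^{-1} (y - mu)`` about the GLS root
    mean ``mu``; the variance includes the uncertainty in ``mu``.

    Returns a DataFrame indexed by internal node label (unlabelled nodes
    get ``node_<k>`` in preorder) with columns ``estimate`` and
    ``variance``.
    """
    y = _align_trait(tree, trait)
    labels, C = tree.bm_covariance()
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cf = _chol(C) if n > 1 else None
    one = np.ones(n)
    if cf is None:
        raise ValueError("ancestral states need at least 2 tips")
    Ci_1 = cho_solve(cf, one)
    mu = float(one @ cho_solve(cf, y) / (one @ Ci_1))
    resid = y - mu
    Ci_r = cho_solve(cf, resid)
    s2 = max(float(resid @ Ci_r) / n, 1e-300)
    denom = float(one @ Ci_1)

    depths = tree.node_depths()
    # tip sets per internal node
    below: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [index[node.taxon.label]]
        else:
            below[node] = [i for ch in node.child_nodes() for i in below[ch]]

    rows = []
    counter = 0
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        counter += 1
        label = node.label or f"node_{counter}"
        tips_below = below[node]
        rep = tips_below[0]
        c = C[rep, :].copy()
        c[tips_below] = depths[node]
        Ci_c = cho_solve(cf, c)
        est = mu + float(c @ Ci_r)
        var = s2 * (
            depths[node]
            - float(c @ Ci_c)
            + (1.0 - float(one @ Ci_c)) ** 2 / denom
        )
        rows.append({"node": label, "estimate": est, "variance": max(var, 0.0)})
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------


def pagel_lambda(tree: CalibratedTree, trait) -> LambdaFit:
    """ML estimate of Pagel's lambda with a LRT against lambda = 0.

    lambda scales the off-diagonal entries of the BM covariance; the
    likelihood is maximized over lambda in [0, 1] by bounded scalar search
    (mean and scale profiled out) and the p-value uses the chi-square(1)
    reference for 2 (logL_hat - logL_0).
    """
    y = _align_trait(tree, trait)
    labels, C = tree.bm_covariance()
    n = len(labels)
    if n < 10:
        warnings.warn("fewer than 10 tips: lambda estimate will be unstable",
                      stacklevel=2)
    X = np.ones((n, 1))
    dC = np.diag(C).copy()

    def negll(lam: float) -> float:
        V = lam * C
        np.fill_diagonal(V, dC)
        try:
            return -_profile_gls(X, y, V)[2]
        except NumericalDegeneracyError:
            return np.inf

    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    candidates = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, float(res.x))]
    fun, lam_hat = min(candidates, key=lambda t: t[0])
    if not np.isfinite(fun):
        raise OptimizationFailureError("non-finite likelihood for all lambda")
    ll_hat, ll0 = -fun, -candidates[0][0]
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    return LambdaFit(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        loglik0=ll0,
        p_value=float(stats.chi2.sf(lrt, df=1)),
    )


def blomberg_k(
    tree: CalibratedTree, trait, n_perm: int = 1000, seed: int | None = None
) -> KResult:
    """Blomberg's K with a tip-permutation significance test.

    K = (MSE0 / MSE) / [(tr C - n / (1'C^-1 1)) / (n - 1)], with MSE0 the
    mean square about the phylogenetically corrected mean and MSE the GLS
    mean square.  The one-tailed p-value is the smoothed fraction of
    permutations with K at least as large as observed, ``(b + 1)/(m + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = _align_trait(tree, trait)
    labels, C = tree.bm_covariance()
    n = len(labels)
    cf = _chol(C)
    one = np.ones(n)
    Ci_1 = cho_solve(cf, one)
    denom = float(one @ Ci_1)
    expected = (np.trace(C) - n / denom) / (n - 1)

    def k_stat(v: np.ndarray) -> float:
        mu = float(one @ cho_solve(cf, v) / denom)
        r = v - mu
        mse0 = float(r @ r) / (n - 1)
        mse = float(r @ cho_solve(cf, r)) / (n - 1)
        return (mse0 / mse) / expected

    k_obs = k_stat(y)
    rng = np.random.default_rng(seed)
    hits = sum(k_stat(rng.permutation(y)) >= k_obs for _ in range(n_perm))
    return KResult(
        k_hat=k_obs,
        p_value=(hits + 1) / (n_perm + 1),
        n_permutations=n_perm,
    )


def phylo_correlogram(
    tree: CalibratedTree,
    trait,
    n_classes: int = 4,
    n_perm: int = 199,
    seed: int | None = None,
) -> pd.DataFrame:
    """Moran's I per patristic-distance class with permutation p-values.

    Pair weights are the reciprocal patristic distance, restricted to
    equal-frequency distance classes.  p-values are one-tailed (greater),
    with (b+1)/(m+1) smoothing.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    y = _align_trait(tree, trait)
    labels, D = tree.patristic_matrix()
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    dists = D[iu]
    if dists.size < n_classes:
        raise ValueError("not enough tip pairs for the requested classes")
    if np.ptp(dists) < 1e-12:
        warnings.warn("all patristic distances equal; using a single class",
                      stacklevel=2)
        n_classes = 1
        edges = np.array([dists.min() - 1e-9, dists.max() + 1e-9])
    else:
        edges = np.quantile(dists, np.linspace(0, 1, n_classes + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9

    rng = np.random.default_rng(seed)
    z = y - y.mean()
    zz = float(z @ z)
    rows = []
    for c in range(n_classes):
        in_class = (D > edges[c]) & (D <= edges[c + 1])
        np.fill_diagonal(in_class, False)
        W = np.where(in_class, 1.0 / np.maximum(D, 1e-300), 0.0)
        w_sum = W.sum()
        if w_sum == 0:
            continue

        def moran(v: np.ndarray) -> float:
            vz = v - v.mean()
            return (n / w_sum) * float(vz @ W @ vz) / max(float(vz @ vz), 1e-300)

        i_obs = moran(y)
        hits = sum(moran(rng.permutation(y)) >= i_obs for _ in range(n_perm))
        rows.append(
            {
                "class": c,
                "d_min": edges[c],
                "d_max": edges[c + 1],
                "moran_i": i_obs,
                "p_value": (hits + 1) / (n_perm + 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PGLS and OU fitting
# ---------------------------------------------------------------------------

_ALPHA_GRID_POINTS = 25


def pgls_fit(
    tree: CalibratedTree,
    trait,
    predictors=None,
    cov_model: str = "BM",
    stationary: bool = True,
) -> PhyloFit:
    """Phylogenetic regression under BM, OU, or star covariance.

    * ``star``: ordinary least squares (independent tips).
    * ``BM``: covariance proportional to shared path lengths.
    * ``OU``: stationary covariance ``sigma2/(2 alpha) exp(-alpha d_ij)``
      (or the fixed-root form with ``stationary=False``); ``alpha`` is
      found by a log-spaced grid search refined with bounded scalar
      minimization.

    AIC counts coefficients + sigma2 (+ alpha for OU).  For an
    intercept-only OU fit the intercept is reported as the evolutionary
    optimum ``theta``.
    """
    y = _align_trait(tree, trait)
    X, names = _design(tree, predictors)
    n = y.size
    labels, C = tree.bm_covariance()
    model = cov_model.upper() if cov_model.lower() != "star" else "star"

    if model == "star":
        beta, s, ll, _ = _profile_gls(X, y, np.eye(n))
        k = X.shape[1] + 1
        fit = PhyloFit("star", pd.Series(beta, index=names), s, ll,
                       2 * k - 2 * ll, n)
    elif model == "BM":
        beta, s, ll, _ = _profile_gls(X, y, C)
        k = X.shape[1] + 1
        fit = PhyloFit("BM", pd.Series(beta, index=names), s, ll,
                       2 * k - 2 * ll, n)
    elif model == "OU":
        d = np.diag(C)
        D = d[:, None] + d[None, :] - 2 * C
        depth = float(d.max())
        lo, hi = 1e-4 / depth, 5e3 / depth

        def build(alpha: float) -> np.ndarray:
            return (
                _ou_correlation(D, alpha)
                if stationary
                else _ou_fixed_root(C, D, alpha)
            )

        def negll(log_alpha: float) -> float:
            try:
                return -_profile_gls(X, y, build(np.exp(log_alpha)))[2]
            except NumericalDegeneracyError:
                return np.inf

        grid = np.log(np.geomspace(lo, hi, _ALPHA_GRID_POINTS))
        vals = np.array([negll(g) for g in grid])
        if not np.isfinite(vals).any():
            raise OptimizationFailureError(
                "OU likelihood non-finite across the alpha grid"
            )
        best = int(np.nanargmin(vals))
        bl = grid[max(best - 1, 0)]
        bu = grid[min(best + 1, grid.size - 1)]
        res = minimize_scalar(negll, bounds=(bl, bu), method="bounded",
                              options={"xatol": 1e-8})
        cand = min([(vals[best], grid[best]), (res.fun, float(res.x))],
                   key=lambda t: t[0])
        alpha = float(np.exp(cand[1]))
        boundary = best in (0, grid.size - 1)
        if boundary:
            warnings.warn("alpha estimate at the search boundary", stacklevel=2)
        beta, s, ll, _ = _profile_gls(X, y, build(alpha))
        sigma2 = 2 * alpha * s if stationary else s
        k = X.shape[1] + 2
        fit = PhyloFit("OU", pd.Series(beta, index=names), sigma2, ll,
                       2 * k - 2 * ll, n, alpha=alpha, boundary=boundary)
        if X.shape[1] == 1:
            fit.theta = float(beta[0])
    else:
        raise ValueError(f"unknown covariance model: {cov_model}")
    return fit


def fit_ou_optimum(tree: CalibratedTree, trait, stationary: bool = True) -> PhyloFit:
    """Intercept-only OU fit; the intercept is the evolutionary optimum theta.

    theta_hat equals the GLS mean (1'V^-1 y)/(1'V^-1 1) at the fitted alpha;
    alpha and sigma2 are obtained by profile likelihood.
    """
    y = _align_trait(tree, trait)
    if np.ptp(y) < 1e-12:
        # degenerate constant trait: optimum is that constant
        n = y.size
        return PhyloFit(
            "OU",
            pd.Series([float(y[0])], index=["intercept"]),
            0.0,
            np.nan,
            np.nan,
            n,
            alpha=np.nan,
            theta=float(y[0]),
        )
    if y.size < 10:
        warnings.warn("fewer than 10 tips: theta estimate will be unstable",
                      stacklevel=2)
    return pgls_fit(tree, trait, None, "OU", stationary=stationary)


def compare_models(fits) -> pd.DataFrame:
    """Rank fits by AIC with a deterministic alphabetical tie-break."""
    fits = list(fits)
    ns = {fit.n for fit in fits}
    if len(ns) > 1:
        raise InvalidComparisonError(
            f"fits computed on different sample sizes: {sorted(ns)}"
        )
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values(["aic", "model"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def variance_partition(
    tree: CalibratedTree,
    trait,
    predictors: pd.DataFrame,
    cov_model: str = "OU",
) -> dict:
    """Likelihood-based partial r2 per component.

    For each predictor, the reduced model drops that column (keeping the
    covariance model, alpha refit); for the phylogeny component the
    covariance is replaced by the star (independence) model while keeping
    all predictors.  partial r2 = 1 - exp(-(2/n)(logL_full - logL_reduced)).
    """
    full = pgls_fit(tree, trait, predictors, cov_model)
    n = full.n
    out = {}

    def partial(reduced_ll: float) -> float:
        return 1.0 - np.exp(-(2.0 / n) * (full.loglik - reduced_ll))

    star = pgls_fit(tree, trait, predictors, "star")
    out["phylogeny"] = partial(star.loglik)
    for col in predictors.columns:
        rest = predictors.drop(columns=[col])
        try:
            reduced = pgls_fit(
                tree, trait, rest if not rest.empty else None, cov_model
            )
            out[col] = partial(reduced.loglik)
        except (NumericalDegeneracyError, OptimizationFailureError):
            warnings.warn(f"reduced model without {col} failed", stacklevel=2)
            out[col] = np.nan
    return out
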