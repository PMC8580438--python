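"""Regression layer: abiotic factors, spatial autoregressions, path suite.

The environmental table is collapsed into three varimax factors (to remove
collinearity while keeping loadings interpretable).  Diversity per cell is
then regressed on the abiotic factor scores, with or without the province
loadings as additional predictors.  All coefficients are reported as beta
(standardized) coefficients so their magnitudes are comparable; each model
is fitted twice — a maximum-likelihood spatial-error autoregression over a
k-nearest-neighbour weights matrix, and its OLS companion (which supplies
the adjusted R-squared and the significance flags for the tables).

A path-regression suite emulates a structural equation model: every key
variable (selected from factor loadings and uniqueness), every province
loading and the diversity metric is in turn regressed on all the others
(provinces are never regressed on each other, as their loadings are
mathematically coupled), and each significant slope becomes a signed,
directed edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .bioregion import FactorSolution, varimax_fa, BioregionError
from .ingest import ENV_VARIABLES

__all__ = [
    "AbioticFactors",
    "TermResult",
    "RegressionResult",
    "PathGraph",
    "SpatialWeights",
    "knn_weights",
    "abiotic_fa",
    "sar_fit",
    "model_suite",
    "select_key_variables",
    "path_suite",
    "ModelError",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS = ("fisher_alpha", "simpson_D", "cJ1", "sqs")


class ModelError(ValueError):
    pass


@dataclass
class AbioticFactors:
    """Varimax factor solution of the environmental variables (R-mode)."""

    loadings: pd.DataFrame        # variables x factors
    scores: pd.DataFrame          # cells x factors, unit variance
    uniqueness: pd.Series         # 1 - communality, per variable
    solution: FactorSolution


@dataclass
class TermResult:
    name: str
    beta: float          # OLS standardized slope (the tables' beta)
    p: float             # OLS p-value
    significant: bool
    sar_beta: float = np.nan
    sar_p: float = np.nan


@dataclass
class RegressionResult:
    model_label: str
    terms: list[TermResult]
    adjusted_R2: float           # from the OLS companion
    r2: float
    spatial_param: float = np.nan   # SAR lambda (error) or rho (lag)
    spatial_param_p: float = np.nan  # likelihood-ratio test vs OLS
    n: int = 0

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "beta": t.beta,
                    "p": t.p,
                    "significant": t.significant,
                    "sar_beta": t.sar_beta,
                    "sar_p": t.sar_p,
                }
                for t in self.terms
            ]
        )


@dataclass
class PathGraph:
    """Directed significant-slope graph from the path-regression suite."""

    nodes: list[str]
    edges: list[tuple[str, str, int, float]]  # (from, to, sign, p)
    n_tests: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["from", "to", "sign", "p"])


# ---------------------------------------------------------------------------
# Abiotic factor analysis
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ModelError("constant column cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def abiotic_fa(
    env_table: pd.DataFrame, n_factors: int = 3, method: str = "minres"
) -> AbioticFactors:
    """Three-factor varimax solution of the environmental variables.

    Variables are standardized; the factor model is fitted on their
    correlation matrix (delegating to the same extraction/rotation machinery
    as the Q-mode bioregionalization), and per-cell scores are computed by
    the regression (Thurstone) method and rescaled to unit variance.
    """
    cols = [c for c in ENV_VARIABLES if c in env_table.columns]
    if not cols:
        cols = list(env_table.columns)
    X = env_table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ModelError("env table has missing values")
    sd = X.std(axis=0, ddof=1)
    const = [cols[i] for i in np.where(sd == 0)[0]]
    if const:
        raise ModelError(f"constant environmental variable(s): {const}")
    Z = _standardize(X)
    R = np.corrcoef(Z, rowvar=False)
    corr = pd.DataFrame(R, index=cols, columns=cols)
    sol = varimax_fa(corr, n_factors, method=method)
    L = sol.loadings.to_numpy()
    scores = Z @ np.linalg.solve(R, L)
    scores = scores - scores.mean(axis=0)
    ssd = scores.std(axis=0, ddof=1)
    ssd[ssd == 0] = 1.0
    scores = scores / ssd
    score_df = pd.DataFrame(
        scores, index=env_table.index, columns=sol.loadings.columns
    )
    return AbioticFactors(
        loadings=sol.loadings,
        scores=score_df,
        uniqueness=sol.uniqueness,
        solution=sol,
    )


# ---------------------------------------------------------------------------
# Spatial weights and SAR fitting
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Row-standardized spatial weights matrix over cell centers."""

    W: np.ndarray
    index: pd.Index


def knn_weights(coords: pd.DataFrame, k: int = 5) -> SpatialWeights:
    """Row-standardized k-nearest-neighbour weights from cell centers.

    ``coords`` must have columns ``center_lat``/``center_lon`` (or exactly
    two coordinate columns); distances are Euclidean in degrees, adequate at
    the half-degree coastal scale used here.
    """
    if {"center_lat", "center_lon"}.issubset(coords.columns):
        P = coords[["center_lat", "center_lon"]].to_numpy(dtype=float)
    else:
        P = coords.to_numpy(dtype=float)
    n = P.shape[0]
    if n <= k:
        raise ModelError(f"need more than k={k} cells, got {n}")
    D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        nn = np.argsort(D[i], kind="stable")[:k]
        W[i, nn] = 1.0
    W = W / W.sum(axis=1, keepdims=True)
    return SpatialWeights(W=W, index=coords.index)


def _ols(y: np.ndarray, X: np.ndarray):
    Xc = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, Xc).fit()


def _sar_error_ml(y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """ML spatial error model via the concentrated log-likelihood in lambda."""
    n = y.shape[0]
    I = np.eye(n)
    Xc = sm.add_constant(X, has_constant="add")

    def negll(lam: float) -> float:
        A = I - lam * W
        ys, Xs = A @ y, A @ Xc
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = float(e @ e) / n
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - logdet

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(res.x)
    A = I - lam * W
    ys, Xs = A @ y, A @ Xc
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    e = ys - Xs @ beta
    sigma2 = float(e @ e) / n
    cov = sigma2 * np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * norm.sf(np.abs(z))
    ll = -res.fun
    return beta, p, lam, ll


def _sar_lag_ml(y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """ML spatial lag model (autoregressive response)."""
    n = y.shape[0]
    I = np.eye(n)
    Xc = sm.add_constant(X, has_constant="add")
    XtXi = np.linalg.pinv(Xc.T @ Xc)

    def negll(rho: float) -> float:
        A = I - rho * W
        ys = A @ y
        beta = XtXi @ (Xc.T @ ys)
        e = ys - Xc @ beta
        sigma2 = float(e @ e) / n
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - logdet

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    rho = float(res.x)
    ys = (I - rho * W) @ y
    beta = XtXi @ (Xc.T @ ys)
    e = ys - Xc @ beta
    sigma2 = float(e @ e) / n
    cov = sigma2 * XtXi
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * norm.sf(np.abs(z))
    ll = -res.fun
    return beta, p, rho, ll


def sar_fit(
    y: pd.Series,
    X: pd.DataFrame,
    coords: Optional[pd.DataFrame] = None,
    model: str = "error",
    k_neighbors: int = 5,
    alpha: float = 0.001,
    log_y: bool = False,
    weights: Optional[SpatialWeights] = None,
    label: str = "model",
) -> RegressionResult:
    """Spatial autoregression plus its OLS companion, on standardized scales.

    The response (optionally log-transformed first) and every predictor are
    scaled to unit variance, so all slopes are beta coefficients.  The
    spatial error model (default; ``model="lag"`` for the autoregressive
    response form) is fitted by maximum likelihood over a row-standardized
    k-nearest-neighbour weights matrix; the spatial parameter's p-value is a
    likelihood-ratio test against the OLS fit.  Adjusted R-squared and the
    ``significant`` flags come from the OLS companion, which is numerically
    almost identical whenever spatial autocorrelation is weak.
    """
    if X.isna().any().any() or y.isna().any():
        raise ModelError("NaN in model inputs")
    n = len(y)
    if n < 10:
        raise ModelError("need at least 10 cells")
    yv = y.to_numpy(dtype=float)
    if log_y:
        if (yv <= 0).any():
            raise ModelError("log transform requires positive response")
        yv = np.log(yv)
    ys = _standardize(yv[:, None])[:, 0]
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=1)
    zero = [X.columns[i] for i in np.where(sd == 0)[0]]
    if zero:
        raise ModelError(f"constant predictor column(s): {zero}")
    Xs = _standardize(Xv)
    rank = np.linalg.matrix_rank(np.c_[np.ones(n), Xs])
    if rank < Xs.shape[1] + 1:
        corr = np.corrcoef(Xs, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ModelError(
            f"singular design; most collinear pair: {X.columns[i]!r} and "
            f"{X.columns[j]!r}"
        )

    ols = _ols(ys, Xs)
    ols_beta = ols.params[1:]
    ols_p = ols.pvalues[1:]

    sar_beta = np.full(Xs.shape[1], np.nan)
    sar_p = np.full(Xs.shape[1], np.nan)
    spatial_param, spatial_p = np.nan, np.nan
    if weights is None and coords is not None:
        weights = knn_weights(coords.loc[X.index], k=k_neighbors)
    if weights is not None:
        fitter = _sar_error_ml if model == "error" else _sar_lag_ml
        if model not in ("error", "lag"):
            raise ModelError(f"unknown SAR family {model!r}")
        beta, p, spatial_param, ll = fitter(ys, Xs, weights.W)
        sar_beta, sar_p = beta[1:], p[1:]
        lr = 2.0 * (ll - ols.llf)
        spatial_p = float(chi2.sf(max(lr, 0.0), df=1))

    terms = [
        TermResult(
            name=str(c),
            beta=float(ols_beta[i]),
            p=float(ols_p[i]),
            significant=bool(ols_p[i] < alpha),
            sar_beta=float(sar_beta[i]),
            sar_p=float(sar_p[i]),
        )
        for i, c in enumerate(X.columns)
    ]
    return RegressionResult(
        model_label=label,
        terms=terms,
        adjusted_R2=float(ols.rsquared_adj),
        r2=float(ols.rsquared),
        spatial_param=float(spatial_param),
        spatial_param_p=float(spatial_p),
        n=n,
    )


# ---------------------------------------------------------------------------
# Model suites (abiotic-only and abiotic+province layouts)
# ---------------------------------------------------------------------------

def model_suite(
    diversity_table: pd.DataFrame,
    abiotic: AbioticFactors,
    province_loadings: Optional[pd.DataFrame] = None,
    coords: Optional[pd.DataFrame] = None,
    metrics: Sequence[str] = DEFAULT_METRICS,
    alpha: float = 0.001,
    log_response: bool = True,
    k_neighbors: int = 5,
    sar_model: str = "error",
) -> dict[str, RegressionResult]:
    """One regression per diversity metric against the abiotic factors,
    optionally augmented with the province loadings.

    Without ``province_loadings`` the predictors are the three abiotic factor
    scores (the abiotic-only table layout); with them, the K province
    loadings come first (the combined layout).  Inputs must share the same
    cell set.
    """
    idx = diversity_table.index
    for name, other in (("abiotic scores", abiotic.scores.index),
                        ("province loadings",
                         None if province_loadings is None
                         else province_loadings.index)):
        if other is None:
            continue
        if not idx.equals(other):
            missing = idx.symmetric_difference(other).tolist()
            raise ModelError(
                f"cell sets misaligned between diversity table and {name}: "
                f"{missing[:10]}"
            )

    predictors = abiotic.scores.rename(
        columns=lambda c: c.replace("factor", "abiotic")
    )
    if province_loadings is not None:
        prov = province_loadings.rename(
            columns=lambda c: str(c).replace("factor", "province")
        )
        predictors = pd.concat([prov, predictors], axis=1)

    weights = None
    if coords is not None:
        weights = knn_weights(coords.loc[idx], k=k_neighbors)

    out: dict[str, RegressionResult] = {}
    for metric in metrics:
        if metric not in diversity_table.columns:
            raise ModelError(f"metric {metric!r} not in diversity table")
        y = diversity_table[metric]
        ok = y.notna()
        res = sar_fit(
            y[ok],
            predictors.loc[ok],
            weights=weights if ok.all() else None,
            coords=None if ok.all() or coords is None else coords,
            model=sar_model,
            alpha=alpha,
            log_y=log_response,
            label=metric,
        )
        out[metric] = res
    return out


# ---------------------------------------------------------------------------
# Key-variable selection
# ---------------------------------------------------------------------------

def select_key_variables(
    abiotic: AbioticFactors,
    key_set_size: int = 7,
    include_latitude: bool = True,
) -> list[str]:
    """Key abiotic variables: top loading per factor, then top uniqueness.

    For each abiotic factor the variable with the highest absolute loading
    is taken; the set is then topped up with the variables of highest
    uniqueness (variance not captured by any factor) until it holds
    ``key_set_size`` names — latitude counting toward that size when
    included.  Ties break by the variable table order.
    """
    order = {v: i for i, v in enumerate(abiotic.loadings.index)}
    chosen: list[str] = []
    for col in abiotic.loadings.columns:
        col_abs = abiotic.loadings[col].abs()
        best = sorted(
            col_abs.index, key=lambda v: (-col_abs[v], order[v])
        )[0]
        if best not in chosen:
            chosen.append(best)
    budget = key_set_size - (1 if include_latitude else 0)
    uniq = abiotic.uniqueness
    for v in sorted(uniq.index, key=lambda v: (-uniq[v], order[v])):
        if len(chosen) >= budget:
            break
        if v not in chosen:
            chosen.append(v)
    chosen.sort(key=lambda v: order[v])
    return (["latitude"] if include_latitude else []) + chosen


# ---------------------------------------------------------------------------
# Path-regression suite (SEM emulation)
# ---------------------------------------------------------------------------

def path_suite(
    key_variables: pd.DataFrame,
    province_loadings: pd.DataFrame,
    diversity: pd.Series,
    alpha: float = 0.01,
) -> PathGraph:
    """Directed significant-slope graph over key variables, provinces and
    diversity.

    Each node in turn is the dependent variable of one multiple regression
    on all permitted other nodes; province loadings are never regressed on
    one another (they are mathematically coupled: scoring high on one forces
    low scores elsewhere).  An edge ``from -> to`` with its slope sign is
    recorded whenever the slope's p-value is below ``alpha``.  No
    multiple-testing correction is applied; ``n_tests`` reports how many
    slopes were tested so the false-edge budget is explicit.
    """
    if not key_variables.index.equals(province_loadings.index) or not (
        key_variables.index.equals(diversity.index)
    ):
        raise ModelError("path_suite inputs must share one cell index")
    div_name = diversity.name or "diversity"
    prov_cols = [str(c) for c in province_loadings.columns]
    env_cols = [str(c) for c in key_variables.columns]
    data = pd.concat(
        [key_variables, province_loadings, diversity.rename(div_name)], axis=1
    )
    data.columns = env_cols + prov_cols + [div_name]
    nodes = list(data.columns)

    edges: list[tuple[str, str, int, float]] = []
    n_tests = 0
    Z = pd.DataFrame(
        _standardize(data.to_numpy(dtype=float)), index=data.index,
        columns=data.columns,
    )
    for dep in nodes:
        preds = [
            c for c in nodes
            if c != dep and not (dep in prov_cols and c in prov_cols)
        ]
        fit = _ols(Z[dep].to_numpy(), Z[preds].to_numpy())
        pvals = fit.pvalues[1:]
        betas = fit.params[1:]
        n_tests += len(preds)
        for c, b, p in zip(preds, betas, pvals):
            if p < alpha:
                edges.append((c, dep, int(np.sign(b)) or 1, float(p)))
    return PathGraph(nodes=nodes, edges=edges, n_tests=n_tests)
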