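"""Factor-analytic bioregionalization of a cell x species matrix.

Biogeographic provinces are represented *continuously*: the cell x cell
correlation matrix of (binarized) species incidence is factored in Q-mode
and rotated with varimax, so each cell gets a loading on each latent
province.  Cells loading highly on the same factor occupy the same
ecological space; middling loadings mark transition zones.  The module also
provides the companion tools used to validate a province scheme:

* parallel analysis for choosing the number of factors,
* PAM (k-medoids) clustering as a hard-boundary cross-check,
* correspondence analysis to display cluster distinctness in ordination
  space.

The same factor machinery is reused in R-mode on the environmental variables
(see :mod:`provdiv.models`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorSolution",
    "ClusterSolution",
    "cell_correlation",
    "varimax_fa",
    "parallel_analysis",
    "pam",
    "correspondence_analysis",
    "dissimilarity",
    "bioregionalize",
    "BioregionError",
]


class BioregionError(ValueError):
    pass


@dataclass
class FactorSolution:
    """Varimax-rotated factor solution of a correlation matrix.

    ``loadings`` is observations x factors (cells in Q-mode, variables in
    R-mode), bounded in [-1, 1]; ``eigenvalues`` is the full scree of the
    correlation matrix; ``communalities`` (row sums of squared loadings) are
    invariant under the orthogonal rotation.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    communalities: pd.Series
    n_factors: int
    rotation: str = "varimax"
    method: str = "pa"

    @property
    def uniqueness(self) -> pd.Series:
        return 1.0 - self.communalities

    def dominant(self) -> pd.Series:
        """Index of the factor with the largest absolute loading per row."""
        return self.loadings.abs().idxmax(axis=1)

    def max_loading(self) -> pd.Series:
        return self.loadings.abs().max(axis=1)


@dataclass
class ClusterSolution:
    """PAM (k-medoids) partition of a dissimilarity matrix."""

    k: int
    medoids: list
    assignment: pd.Series
    total_cost: float


# ---------------------------------------------------------------------------
# Q-mode preparation
# ---------------------------------------------------------------------------

def cell_correlation(matrix: pd.DataFrame, binarize: bool = True) -> pd.DataFrame:
    """Product-moment correlation between cell incidence vectors.

    Rows are cells, columns species; with ``binarize`` (default) counts are
    reduced to presence/absence first.  A cell whose vector has zero variance
    (empty, or present in every species column) cannot be correlated and is
    reported by name.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise BioregionError("need at least 3 cells and 2 species")
    X = matrix.to_numpy(dtype=float)
    if binarize:
        X = (X > 0).astype(float)
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = [matrix.index[i] for i in bad[:5]]
        raise BioregionError(f"zero-variance cell vector(s): {names}")
    R = np.corrcoef(X)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# Factor extraction + varimax rotation
# ---------------------------------------------------------------------------

def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (initial communality estimates)."""
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        Rinv = np.linalg.pinv(R)
    d = np.diag(Rinv)
    # near-singular R can leave non-positive diagonal entries in the inverse;
    # fall back to a neutral starting communality there
    with np.errstate(divide="ignore", invalid="ignore"):
        smc = np.where(d > 0, 1.0 - 1.0 / d, 0.5)
    return np.clip(smc, 0.0, 0.999)


def _loadings_from_reduced(R: np.ndarray, diag: np.ndarray, k: int) -> np.ndarray:
    Rr = R.copy()
    np.fill_diagonal(Rr, diag)
    vals, vecs = np.linalg.eigh(Rr)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _extract_pa(R: np.ndarray, k: int, tol: float = 1e-6, max_iter: int = 200):
    """Iterated principal-axis extraction (communality iteration from SMC)."""
    h = _smc(R)
    for _ in range(max_iter):
        L = _loadings_from_reduced(R, h, k)
        h_new = np.clip((L ** 2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    return _loadings_from_reduced(R, h, k)


def _extract_minres(R: np.ndarray, k: int):
    """Unweighted least squares on off-diagonal residuals over uniquenesses."""
    p = R.shape[0]
    mask = ~np.eye(p, dtype=bool)

    def objective(u: np.ndarray) -> float:
        L = _loadings_from_reduced(R, 1.0 - u, k)
        resid = R - L @ L.T
        return float((resid[mask] ** 2).sum())

    u0 = 1.0 - _smc(R)
    res = minimize(
        objective, u0, method="L-BFGS-B", bounds=[(1e-4, 1.0)] * p,
        options={"maxiter": 500},
    )
    return _loadings_from_reduced(R, 1.0 - res.x, k)


def varimax_fa(
    corr: pd.DataFrame,
    n_factors: int,
    method: str = "pa",
    rotation_tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> FactorSolution:
    """Factor the correlation matrix and varimax-rotate the loadings.

    Extraction is iterated principal-axis (``method="pa"``, default — fast
    enough for Q-mode problems with hundreds of cells) or minimum-residual
    (``method="minres"``, an explicit ULS fit over uniquenesses, preferable
    for small R-mode problems).  After rotation each factor's sign is fixed
    so its largest-magnitude loading is positive, and factors are ordered by
    explained variance (column sum of squared loadings).
    """
    if n_factors < 1:
        raise BioregionError("n_factors must be >= 1")
    if n_factors >= corr.shape[0]:
        raise BioregionError("n_factors must be < number of observations")
    R = corr.to_numpy(dtype=float)
    if method == "pa":
        L = _extract_pa(R, n_factors)
    elif method == "minres":
        L = _extract_minres(R, n_factors)
    else:
        raise BioregionError(f"unknown extraction method {method!r}")

    if n_factors > 1:
        try:
            L, _ = rotate_factors(
                L, "varimax", tol=rotation_tol, max_tries=max_sweeps
            )
        except Exception as exc:  # non-convergence surfaces as an error
            raise BioregionError(f"varimax rotation failed: {exc}") from exc

    # sign convention and variance ordering
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    order = np.argsort(-(L ** 2).sum(axis=0), kind="stable")
    L = L[:, order]

    eigvals = np.sort(np.linalg.eigvalsh(R))[::-1]
    loadings = pd.DataFrame(
        L, index=corr.index,
        columns=[f"factor{j + 1}" for j in range(n_factors)],
    )
    communalities = pd.Series((L ** 2).sum(axis=1), index=corr.index)
    return FactorSolution(
        loadings=loadings,
        eigenvalues=eigvals,
        communalities=communalities,
        n_factors=n_factors,
        rotation="varimax",
        method=method,
    )


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

def _safe_corr_rows(X: np.ndarray) -> np.ndarray:
    """Row correlation tolerating zero-variance rows (set to 0 off-diagonal)."""
    sd = X.std(axis=1)
    ok = sd > 0
    R = np.zeros((X.shape[0], X.shape[0]))
    if ok.sum() >= 2:
        R[np.ix_(ok, ok)] = np.corrcoef(X[ok])
    np.fill_diagonal(R, 1.0)
    return R


def parallel_analysis(
    matrix: pd.DataFrame,
    n_random: int = 100,
    quantile: float = 0.95,
    rng: np.random.Generator | None = None,
    binarize: bool = True,
) -> int:
    """Number of factors whose eigenvalues beat permuted-data screes.

    The observed scree comes from the Q-mode correlation of the (binarized)
    matrix.  Null screes come from ``n_random`` matrices in which each
    *cell's* incidence vector is independently permuted across species.  In
    Q-mode the cells are the variables being correlated, so Horn's procedure
    permutes each variable (cell) independently; this preserves every cell's
    prevalence, which matters when sampling effort — and hence occupancy —
    varies strongly between cells.  Factors are retained while the observed
    eigenvalue exceeds the per-rank ``quantile`` of the null distribution,
    stopping at the first failure.
    """
    rng = np.random.default_rng(rng)
    X = matrix.to_numpy(dtype=float)
    if binarize:
        X = (X > 0).astype(float)
    obs = np.sort(np.linalg.eigvalsh(_safe_corr_rows(X)))[::-1]
    null = np.empty((n_random, X.shape[0]))
    Xp = X.copy()
    for r in range(n_random):
        for i in range(Xp.shape[0]):
            rng.shuffle(Xp[i, :])
        null[r] = np.sort(np.linalg.eigvalsh(_safe_corr_rows(Xp)))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    n_keep = 0
    for o, t in zip(obs, thresh):
        if o > t:
            n_keep += 1
        else:
            break
    return n_keep


# ---------------------------------------------------------------------------
# PAM clustering
# ---------------------------------------------------------------------------

def dissimilarity(matrix: pd.DataFrame, metric: str = "sorensen") -> pd.DataFrame:
    """Pairwise cell dissimilarity on presence/absence.

    ``sorensen`` is the Sorensen/Dice dissimilarity (Bray-Curtis on
    presences); ``jaccard`` is available as an alternative.
    """
    X = (matrix.to_numpy() > 0)
    scipy_metric = {"sorensen": "dice", "jaccard": "jaccard"}.get(metric)
    if scipy_metric is None:
        raise BioregionError(f"unknown dissimilarity metric {metric!r}")
    D = squareform(pdist(X, metric=scipy_metric))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def _pam_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(
    dissim: pd.DataFrame | np.ndarray,
    k: int,
    rng: np.random.Generator | None = None,
) -> ClusterSolution:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Small instances (at most 10000 candidate medoid sets) are solved by
    exhaustive enumeration, guaranteeing the exact optimum there; BUILD+SWAP
    can stop in a local optimum of the single-swap neighbourhood, especially
    on non-metric dissimilarities.  Fully deterministic: ties in BUILD, SWAP
    and assignment are broken by the lowest index, and the enumerated optimum
    is the lexicographically smallest optimal set.  ``rng`` is accepted for
    interface symmetry but unused by the deterministic search.  Cost never
    increases across SWAP iterations.
    """
    if isinstance(dissim, pd.DataFrame):
        ids = list(dissim.index)
        D = dissim.to_numpy(dtype=float)
    else:
        D = np.asarray(dissim, dtype=float)
        ids = list(range(D.shape[0]))
    n = D.shape[0]
    if k <= 0:
        raise BioregionError("k must be positive")
    if k > n:
        raise BioregionError(f"k={k} exceeds number of objects n={n}")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise BioregionError("dissimilarity matrix must be square symmetric")

    from math import comb
    if comb(n, k) <= 10000:
        import itertools

        best_cost, best_set = np.inf, None
        for med in itertools.combinations(range(n), k):
            c = D[:, med].min(axis=1).sum()
            if c < best_cost - 1e-12:
                best_cost, best_set = c, med
        medoids = list(best_set)
        return _pam_solution(D, ids, k, medoids)

    # BUILD: start from the most central object, then greedily add the
    # object giving the largest cost decrease.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, None
        current = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    # SWAP: best single medoid/non-medoid exchange until no improvement.
    cost = _pam_cost(D, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1:]
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = _pam_cost(D, others + [h])
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost = _pam_cost(D, medoids)
            improved = True

    return _pam_solution(D, ids, k, medoids)


def _pam_solution(D: np.ndarray, ids: list, k: int, medoids: list) -> ClusterSolution:
    n = D.shape[0]
    medoids = sorted(medoids)
    assign_pos = np.array([medoids[int(np.argmin(D[i, medoids]))] for i in range(n)])
    assignment = pd.Series(
        [ids[a] for a in assign_pos], index=pd.Index(ids, name="cell_id"),
        name="medoid",
    )
    return ClusterSolution(
        k=k,
        medoids=[ids[m] for m in medoids],
        assignment=assignment,
        total_cost=_pam_cost(D, medoids),
    )


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------

def correspondence_analysis(
    matrix: pd.DataFrame, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Row (cell) scores and inertia shares from a correspondence analysis.

    Standard CA: SVD of the standardized residuals of the relative-frequency
    table; row coordinates are returned in principal coordinates for the
    first ``n_axes`` axes (fewer, with a warning, if the residual rank is
    lower).  The chi-square inertia share of each returned axis accompanies
    the scores.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise BioregionError("correspondence analysis requires a non-negative matrix")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise BioregionError("all-zero rows/columns are not allowed")
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    sv = sv[keep]
    U = U[:, keep]
    rank = sv.size
    if rank == 0:
        warnings.warn("matrix is rank-1 (independence): total inertia 0")
        coords = pd.DataFrame(index=matrix.index)
        return coords, np.array([])
    axes = min(n_axes, rank)
    if axes < n_axes:
        warnings.warn(f"only {axes} CA axis/axes available (residual rank {rank})")
    coords = (U[:, :axes] * sv[:axes]) / np.sqrt(r)[:, None]
    inertia = sv ** 2
    shares = inertia[:axes] / inertia.sum()
    out = pd.DataFrame(
        coords, index=matrix.index, columns=[f"axis{j+1}" for j in range(axes)]
    )
    return out, shares


# ---------------------------------------------------------------------------
# Convenience wrapper
# ---------------------------------------------------------------------------

def bioregionalize(
    matrix: pd.DataFrame,
    n_factors: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "pa",
    n_random: int = 100,
) -> FactorSolution:
    """Binarize, correlate in Q-mode and factor the cell x species matrix.

    With ``n_factors=None`` the count is chosen by parallel analysis (at
    least 1 factor is always extracted so a solution exists).
    """
    if n_factors is None:
        n_factors = max(1, parallel_analysis(matrix, n_random=n_random, rng=rng))
    corr = cell_correlation(matrix, binarize=True)
    return varimax_fa(corr, n_factors, method=method)
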