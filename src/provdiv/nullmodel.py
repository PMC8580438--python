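"""Temperature-range null model of province structure.

To test whether factor-analytic provinces are an artifact of species simply
tracking temperature, presence-absence worlds are rebuilt in which each
species may occur only in cells whose mean annual SST lies inside the
temperature range it occupies in the real data, and each cell receives
exactly its observed species count by uniform sampling from that candidate
pool.  Re-running the bioregionalization and the combined
(provinces + abiotic) regression on many such worlds shows what province
loadings and coefficients look like when geography contributes nothing
beyond the thermal niche.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioregion import cell_correlation, varimax_fa
from .models import AbioticFactors, abiotic_fa, sar_fit, SpatialWeights, knn_weights

__all__ = [
    "temp_ranges",
    "simulate_null",
    "null_experiment",
    "NullModelError",
]


class NullModelError(ValueError):
    pass


def temp_ranges(matrix: pd.DataFrame, env_table: pd.DataFrame) -> pd.DataFrame:
    """Observed thermal range per species: min/max cell SST over occupancy.

    Single-cell species get a degenerate range (t_min == t_max).  Raises if a
    species occupies no cell with a temperature value.
    """
    if "sst_mean" not in env_table.columns:
        raise NullModelError("env table lacks 'sst_mean'")
    sst = env_table.loc[matrix.index, "sst_mean"]
    if sst.isna().any():
        bad = sst.index[sst.isna()].tolist()
        raise NullModelError(f"cells without temperature: {bad[:5]}")
    P = (matrix.to_numpy() > 0)
    if (P.sum(axis=0) == 0).any():
        bad = [matrix.columns[j] for j in np.where(P.sum(axis=0) == 0)[0]]
        raise NullModelError(f"species with no occupied cell: {bad[:5]}")
    t = sst.to_numpy(dtype=float)
    tmin = np.array([t[P[:, j]].min() for j in range(P.shape[1])])
    tmax = np.array([t[P[:, j]].max() for j in range(P.shape[1])])
    return pd.DataFrame(
        {"t_min": tmin, "t_max": tmax},
        index=pd.Index(matrix.columns, name="species"),
    )


def simulate_null(
    matrix: pd.DataFrame,
    ranges: pd.DataFrame,
    env_table: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One temperature-constrained null presence-absence world.

    For every cell, the candidate pool is the set of species whose thermal
    range contains the cell's mean annual SST; the cell's observed species
    count is drawn uniformly without replacement from that pool (the whole
    pool, deterministically, when the quota equals the pool size).
    """
    sst = env_table.loc[matrix.index, "sst_mean"].to_numpy(dtype=float)
    quotas = (matrix.to_numpy() > 0).sum(axis=1)
    tmin = ranges["t_min"].to_numpy()
    tmax = ranges["t_max"].to_numpy()
    n_cells, n_species = matrix.shape
    out = np.zeros((n_cells, n_species), dtype=np.int8)
    for i in range(n_cells):
        pool = np.where((tmin <= sst[i]) & (sst[i] <= tmax))[0]
        if pool.size < quotas[i]:
            raise NullModelError(
                f"cell {matrix.index[i]!r}: candidate pool {pool.size} smaller "
                f"than quota {quotas[i]}"
            )
        take = pool if pool.size == quotas[i] else rng.choice(
            pool, size=quotas[i], replace=False
        )
        out[i, take] = 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def null_experiment(
    matrix: pd.DataFrame,
    env_table: pd.DataFrame,
    diversity_table: pd.DataFrame,
    coords: pd.DataFrame | None,
    n_reps: int,
    n_factors: int,
    seed: int,
    metric: str = "fisher_alpha",
    abiotic: AbioticFactors | None = None,
    log_response: bool = True,
    alpha: float = 0.001,
    use_sar: bool = True,
    k_neighbors: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the null world and re-run bioregionalization + regression.

    Per replicate: simulate a temperature-constrained world, derive province
    loadings with a Q-mode varimax factor analysis at the *observed* factor
    count, and fit the combined provinces + abiotic regression of the
    observed diversity metric.  Observed diversity is reused (the null
    targets biogeography, not the diversity estimates themselves).

    Returns ``(replicates, summary)``: one row per replicate x coefficient,
    and per-coefficient mean/sd/quantiles plus the fraction of replicates in
    which the term was significant.  Deterministic given ``seed`` (one
    master seed spawns per-replicate streams).
    """
    if n_reps < 1:
        raise NullModelError("n_reps must be >= 1")
    if abiotic is None:
        abiotic = abiotic_fa(env_table.loc[matrix.index])
    ranges = temp_ranges(matrix, env_table)
    weights: SpatialWeights | None = None
    if use_sar and coords is not None:
        weights = knn_weights(coords.loc[matrix.index], k=k_neighbors)

    y = diversity_table.loc[matrix.index, metric]
    ab_scores = abiotic.scores.loc[matrix.index].rename(
        columns=lambda c: c.replace("factor", "abiotic")
    )

    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for rep, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        try:
            world = simulate_null(matrix, ranges, env_table, rng)
            corr = cell_correlation(world, binarize=True)
            sol = varimax_fa(corr, n_factors, method="pa")
            prov = sol.loadings.rename(
                columns=lambda c: c.replace("factor", "province")
            )
            X = pd.concat([prov, ab_scores], axis=1)
            res = sar_fit(
                y, X, weights=weights, alpha=alpha, log_y=log_response,
                label=f"replicate{rep}",
            )
        except Exception as exc:
            raise NullModelError(f"replicate {rep} failed: {exc}") from exc
        for t in res.terms:
            rows.append(
                {
                    "replicate": rep,
                    "term": t.name,
                    "beta": t.beta,
                    "p": t.p,
                    "significant": t.significant,
                    "adjusted_R2": res.adjusted_R2,
                }
            )
    reps_df = pd.DataFrame(rows)
    summary = (
        reps_df.groupby("term")
        .agg(
            beta_mean=("beta", "mean"),
            beta_sd=("beta", "std"),
            beta_q025=("beta", lambda s: s.quantile(0.025)),
            beta_q50=("beta", "median"),
            beta_q975=("beta", lambda s: s.quantile(0.975)),
            significant_fraction=("significant", "mean"),
        )
        .reset_index()
    )
    return reps_df, summary
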