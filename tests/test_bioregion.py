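"""Unit tests for the factor-analytic and clustering bioregionalization."""

import numpy as np
import pandas as pd
import pytest

from provdiv import bioregion
from provdiv.bioregion import BioregionError


def block_matrix(n_per_block=8, n_blocks=3, n_species_per_block=30, noise=0, seed=0):
    """Cell x species counts with perfect compositional blocks (+ optional noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blocks):
        for _ in range(n_per_block):
            row = np.zeros(n_blocks * n_species_per_block, dtype=int)
            lo = b * n_species_per_block
            row[lo:lo + n_species_per_block] = rng.integers(
                1, 10, n_species_per_block
            )
            if noise:
                extra = rng.integers(0, row.size, noise)
                row[extra] += 1
            rows.append(row)
    idx = [f"cell{i}" for i in range(n_blocks * n_per_block)]
    cols = [f"sp{j}" for j in range(n_blocks * n_species_per_block)]
    return pd.DataFrame(rows, index=idx, columns=cols)


class TestCellCorrelation:
    def test_block_structure(self):
        corr = bioregion.cell_correlation(block_matrix())
        within = corr.iloc[0, 1]
        between = corr.iloc[0, 10]
        assert within > 0.9 and between < 0.0

    def test_zero_variance_cell_rejected(self):
        m = block_matrix()
        m.iloc[0, :] = 1  # present everywhere: zero variance after binarizing
        with pytest.raises(BioregionError, match="cell0"):
            bioregion.cell_correlation(m)


class TestVarimaxFA:
    def test_recovers_planted_provinces(self, small_world, small_matrix):
        matrix, _ = small_matrix
        sol = bioregion.varimax_fa(bioregion.cell_correlation(matrix), 3)
        labels = small_world.truth.labels.loc[matrix.index]
        core = labels != "transition"
        dom = sol.loadings.abs().idxmax(axis=1)
        # perfect correspondence between dominant factor and true province
        table = pd.crosstab(labels[core], dom[core]).to_numpy()
        assert (table > 0).sum() == 3  # one nonzero cell per row/column
        # transition cells have depressed maximum loadings on average
        ml = sol.loadings.abs().max(axis=1)
        assert ml[core].mean() > ml[~core].mean()

    def test_sign_convention(self):
        sol = bioregion.varimax_fa(
            bioregion.cell_correlation(block_matrix(noise=3)), 3
        )
        for col in sol.loadings:
            v = sol.loadings[col]
            assert v[v.abs().idxmax()] > 0

    def test_factors_ordered_by_variance(self):
        sol = bioregion.varimax_fa(
            bioregion.cell_correlation(block_matrix(noise=3)), 3
        )
        var = (sol.loadings ** 2).sum(axis=0)
        assert var.is_monotonic_decreasing

    def test_methods_agree_on_clean_blocks(self):
        corr = bioregion.cell_correlation(block_matrix(noise=3))
        pa = bioregion.varimax_fa(corr, 3, method="pa")
        mr = bioregion.varimax_fa(corr, 3, method="minres")
        dom_pa = pa.loadings.abs().idxmax(axis=1)
        dom_mr = mr.loadings.abs().idxmax(axis=1)
        # same partition of cells (factor labels may permute)
        table = pd.crosstab(dom_pa, dom_mr).to_numpy()
        assert (np.sort(table, axis=None)[:-3] == 0).all()

    def test_too_many_factors_rejected(self):
        corr = bioregion.cell_correlation(block_matrix())
        with pytest.raises(BioregionError):
            bioregion.varimax_fa(corr, corr.shape[0] + 1)


class TestParallelAnalysis:
    def test_recovers_planted_province_count(self, small_matrix):
        matrix, _ = small_matrix
        k = bioregion.parallel_analysis(matrix, rng=np.random.default_rng(0))
        assert k == 3

    def test_pure_noise_retains_few(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            (rng.random((20, 200)) < 0.3).astype(int),
            index=[f"c{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(200)],
        )
        k = bioregion.parallel_analysis(m, rng=np.random.default_rng(0))
        assert k <= 2

    def test_deterministic_given_rng(self, small_matrix):
        matrix, _ = small_matrix
        k1 = bioregion.parallel_analysis(
            matrix, n_random=30, rng=np.random.default_rng(5)
        )
        k2 = bioregion.parallel_analysis(
            matrix, n_random=30, rng=np.random.default_rng(5)
        )
        assert k1 == k2


class TestPam:
    def test_tiny_known_instance(self):
        # two clear pairs
        D = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        sol = bioregion.pam(D, 2)
        assert sol.total_cost == pytest.approx(0.2)
        assign = sol.assignment
        assert assign[0] == assign[1] and assign[2] == assign[3]
        assert assign[0] != assign[2]

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        A = rng.random((15, 15))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        s1 = bioregion.pam(D, 3)
        s2 = bioregion.pam(D, 3)
        assert s1.medoids == s2.medoids

    def test_invalid_k(self):
        D = np.zeros((3, 3))
        with pytest.raises(BioregionError):
            bioregion.pam(D, 0)
        with pytest.raises(BioregionError):
            bioregion.pam(D, 4)

    def test_recovers_blocks_from_dissimilarity(self):
        m = block_matrix(noise=3)
        sol = bioregion.pam(bioregion.dissimilarity(m), 3)
        assign = sol.assignment
        for b in range(3):
            block = assign.iloc[b * 8:(b + 1) * 8]
            assert block.nunique() == 1


class TestDissimilarity:
    def test_sorensen_range_and_diagonal(self):
        d = bioregion.dissimilarity(block_matrix())
        v = d.to_numpy()
        assert np.allclose(np.diag(v), 0)
        assert (v >= -1e-12).all() and (v <= 1 + 1e-12).all()

    def test_jaccard_geq_sorensen(self):
        m = block_matrix(noise=5)
        ds = bioregion.dissimilarity(m, metric="sorensen").to_numpy()
        dj = bioregion.dissimilarity(m, metric="jaccard").to_numpy()
        assert (dj >= ds - 1e-12).all()

    def test_unknown_metric(self):
        with pytest.raises(BioregionError):
            bioregion.dissimilarity(block_matrix(), metric="euclid")


class TestCorrespondenceAnalysis:
    def test_block_separation(self):
        m = block_matrix(noise=3)
        scores, inertia = bioregion.correspondence_analysis(m)
        assert scores.shape == (24, 2)
        assert 0 < inertia[0] <= 1 and inertia.sum() <= 1 + 1e-9
        # the two leading axes separate the three blocks
        centroids = scores.groupby(
            np.repeat(np.arange(3), 8)
        ).mean()
        spread = ((centroids - centroids.mean()) ** 2).sum(axis=1)
        assert (spread > 1e-4).all()
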