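"""Unit tests for abiotic factors, spatial regressions and the path suite."""

import numpy as np
import pandas as pd
import pytest

from provdiv import models
from provdiv.models import ModelError


def three_group_env(n=150, seed=0):
    """Nine variables in three orthogonal correlated groups + coordinates."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(n, 3))
    cols = {}
    names = []
    for g in range(3):
        for j in range(3):
            name = f"g{g}v{j}"
            names.append(name)
            cols[name] = f[:, g] + 0.25 * rng.normal(size=n)
    idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    env = pd.DataFrame(cols, index=idx)
    coords = pd.DataFrame(
        {
            "center_lat": np.repeat(np.arange(15), 10) * 0.5,
            "center_lon": np.tile(np.arange(10), 15) * 0.5,
        },
        index=idx,
    )
    return env, coords, f


class TestAbioticFA:
    def test_groups_load_on_own_factor(self):
        env, _, _ = three_group_env()
        ab = models.abiotic_fa(env, n_factors=3)
        dom = ab.loadings.abs().idxmax(axis=1)
        for g in range(3):
            group = dom[[f"g{g}v{j}" for j in range(3)]]
            assert group.nunique() == 1
            peak = ab.loadings.loc[f"g{g}v0"].abs().max()
            assert peak > 0.9
        assert dom.nunique() == 3

    def test_scores_unit_variance(self):
        env, _, _ = three_group_env()
        ab = models.abiotic_fa(env, n_factors=3)
        assert np.allclose(ab.scores.std(ddof=1), 1.0, atol=1e-6)

    def test_scores_track_latent_factors(self):
        env, _, f = three_group_env()
        ab = models.abiotic_fa(env, n_factors=3)
        corr = np.abs(np.corrcoef(ab.scores.to_numpy().T, f.T)[:3, 3:])
        # each latent factor is recovered by exactly one score column
        assert (corr.max(axis=1) > 0.95).all()


class TestSelectKeyVariables:
    def test_group_representatives_selected(self):
        env, _, _ = three_group_env()
        ab = models.abiotic_fa(env, n_factors=3)
        keys = models.select_key_variables(ab, key_set_size=4)
        assert keys[0] == "latitude"
        groups = {k[:2] for k in keys[1:]}
        assert groups == {"g0", "g1", "g2"}

    def test_without_latitude(self):
        env, _, _ = three_group_env()
        ab = models.abiotic_fa(env, n_factors=3)
        keys = models.select_key_variables(
            ab, key_set_size=3, include_latitude=False
        )
        assert "latitude" not in keys and len(keys) == 3


class TestKnnWeights:
    def test_row_standardized_no_self(self):
        _, coords, _ = three_group_env()
        w = models.knn_weights(coords, k=5)
        W = w.W
        assert np.allclose(W.sum(axis=1), 1.0)
        assert np.allclose(np.diag(W), 0.0)
        assert ((W > 0).sum(axis=1) == 5).all()


class TestSarFit:
    def test_recovers_known_slope(self):
        env, coords, f = three_group_env(seed=3)
        rng = np.random.default_rng(1)
        x = pd.Series(f[:, 0], index=env.index, name="x")
        y = 0.8 * x + 0.6 * rng.normal(size=len(x))
        y = pd.Series(y, index=env.index, name="y")
        res = models.sar_fit(y, x.to_frame(), coords=coords)
        t = res.terms[0]
        # standardized beta = 0.8 / sqrt(0.8^2 + 0.6^2) = 0.8
        assert t.beta == pytest.approx(0.8, abs=0.1)
        assert t.significant

    def test_null_predictor_not_significant(self):
        env, coords, _ = three_group_env(seed=4)
        rng = np.random.default_rng(2)
        x = pd.DataFrame({"x": rng.normal(size=150)}, index=env.index)
        y = pd.Series(rng.normal(size=150), index=env.index)
        res = models.sar_fit(y, x, coords=coords)
        assert not res.terms[0].significant

    def test_detects_spatial_autocorrelation(self):
        _, coords, _ = three_group_env(seed=5)
        rng = np.random.default_rng(3)
        w = models.knn_weights(coords, k=5)
        n = len(coords)
        eps = rng.normal(size=n)
        u = np.linalg.solve(np.eye(n) - 0.7 * w.W, eps)  # SAR(0.7) errors
        y = pd.Series(u, index=coords.index)
        x = pd.DataFrame({"x": rng.normal(size=n)}, index=coords.index)
        res = models.sar_fit(y, x, weights=w)
        assert res.spatial_param > 0.3
        assert res.spatial_param_p < 0.01

    def test_collinear_design_rejected(self):
        _, coords, _ = three_group_env()
        rng = np.random.default_rng(0)
        v = rng.normal(size=150)
        X = pd.DataFrame({"a": v, "b": 2 * v}, index=coords.index)
        y = pd.Series(rng.normal(size=150), index=coords.index)
        with pytest.raises(ModelError):
            models.sar_fit(y, X, coords=coords)

    def test_log_response(self):
        _, coords, _ = three_group_env()
        rng = np.random.default_rng(6)
        x = pd.DataFrame({"x": rng.normal(size=150)}, index=coords.index)
        y = pd.Series(np.exp(0.5 * x["x"] + 0.1 * rng.normal(size=150)),
                      index=coords.index)
        res = models.sar_fit(y, x, coords=coords, log_y=True)
        assert res.terms[0].beta > 0.9  # near-deterministic on the log scale


class TestModelSuite:
    def test_output_structure(self, default_world, default_matrix):
        from provdiv import diversity as div_mod
        from provdiv.pipeline import _coords_from_index

        matrix, env = default_matrix
        div = div_mod.diversity_table(matrix)
        ab = models.abiotic_fa(env)
        coords = _coords_from_index(matrix.index)
        suite = models.model_suite(div, ab, None, coords=coords,
                                   metrics=("fisher_alpha",))
        res = suite["fisher_alpha"]
        assert [t.name for t in res.terms] == ["abiotic1", "abiotic2", "abiotic3"]
        assert -1 <= res.adjusted_R2 <= 1
        frame = res.to_frame()
        assert list(frame["term"]) == ["abiotic1", "abiotic2", "abiotic3"]

    def test_misaligned_provinces_rejected(self, default_matrix):
        from provdiv import diversity as div_mod
        from provdiv.pipeline import _coords_from_index

        matrix, env = default_matrix
        div = div_mod.diversity_table(matrix)
        ab = models.abiotic_fa(env)
        coords = _coords_from_index(matrix.index)
        bad = pd.DataFrame(
            np.zeros((3, 2)), index=["a", "b", "c"], columns=["factor1", "factor2"]
        )
        with pytest.raises(ModelError):
            models.model_suite(div, ab, bad, coords=coords,
                              metrics=("fisher_alpha",))


class TestPathSuite:
    @staticmethod
    def _inputs(seed, n=120, signal=False):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
        key = pd.DataFrame(
            rng.normal(size=(n, 3)), columns=["v1", "v2", "latitude"], index=idx
        )
        prov = pd.DataFrame(
            rng.normal(size=(n, 2)), columns=["province1", "province2"], index=idx
        )
        if signal:
            div = pd.Series(
                1.2 * prov["province1"] + 0.2 * rng.normal(size=n),
                index=idx, name="alpha",
            )
        else:
            div = pd.Series(rng.normal(size=n), index=idx, name="alpha")
        return key, prov, div

    def test_detects_planted_edge(self):
        key, prov, div = self._inputs(0, signal=True)
        g = models.path_suite(key, prov, div)
        edges = {(e[0], e[1]): e[2] for e in g.edges}
        assert edges.get(("province1", "alpha")) == 1 or \
            edges.get(("alpha", "province1")) == 1

    def test_provinces_never_regressed_on_provinces(self):
        key, prov, div = self._inputs(1, signal=True)
        g = models.path_suite(key, prov, div)
        for frm, to, *_ in g.edges:
            assert not (frm.startswith("province") and to.startswith("province"))

    def test_edge_frame_columns(self):
        key, prov, div = self._inputs(2, signal=True)
        frame = models.path_suite(key, prov, div).to_frame()
        assert list(frame.columns) == ["from", "to", "sign", "p"]
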