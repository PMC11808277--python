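"""Regression layer: screening, OLS, selection, LMG, a-scan, Moran's I."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fpdiv
from fpdiv.containers import ValidationError
from fpdiv.inference import (
    backward_select,
    fit_ols,
    haversine_matrix,
    lmg_importance,
    morans_i,
    scan_a,
    spearman_screen,
)
from fpdiv.null import NullSpec


class TestSpearmanScreen:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "negx": -x, "z": rng.normal(size=20)})
        res = spearman_screen(df, threshold=0.7)
        assert res.correlations.loc["x", "x"] == pytest.approx(1.0)
        assert res.correlations.loc["x", "negx"] == pytest.approx(-1.0)
        flagged = {frozenset(p[:2]) for p in res.flagged_pairs}
        assert frozenset(("x", "negx")) in flagged

    def test_removal_prefers_most_connected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        df = pd.DataFrame({
            "hub": base,
            "a": base + rng.normal(0, 0.1, 30),
            "b": -base + rng.normal(0, 0.1, 30),
            "c": rng.normal(size=30),
        })
        res = spearman_screen(df, threshold=0.7)
        assert res.removal_proposals[0] == "hub"

    def test_constant_covariate_flagged_nan(self):
        df = pd.DataFrame({"k": [1.0, 1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0, 4.0]})
        res = spearman_screen(df)
        assert np.isnan(res.correlations.loc["k", "x"])


class TestOls:
    def test_perfect_fit(self):
        x = pd.DataFrame({"v": np.arange(10.0)})
        y = 2.0 + 3.0 * x["v"]
        res = fit_ols(y, x)
        assert res.rsquared == pytest.approx(1.0)
        assert res.rsquared_adj == pytest.approx(1.0)
        assert res.params["v"] == pytest.approx(3.0)

    def test_adjusted_r2_identity(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = x["a"] + rng.normal(size=40)
        res = fit_ols(y, x)
        n, k = 40, 3
        expected = 1 - (1 - res.rsquared) * (n - 1) / (n - k - 1)
        assert res.rsquared_adj == pytest.approx(expected, abs=1e-12)
        assert res.rsquared_adj <= res.rsquared

    def test_null_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"v": rng.normal(size=2000)})
        y = rng.normal(size=2000)
        res = fit_ols(y, x)
        assert abs(res.rsquared_adj) < 0.01

    def test_normal_equations_closed_form(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.normal(size=30)
        res = fit_ols(y, x)
        design = np.column_stack([np.ones(30), x.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        x = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(ValidationError, match="collinear"):
            fit_ols(np.random.default_rng(0).normal(size=10), x)


class TestBackwardSelect:
    def test_all_significant_is_fixed_point(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        y = 2 * x["a"] - 3 * x["b"] + rng.normal(0, 0.5, 80)
        res = backward_select(y, x, alpha=0.05)
        assert res.covariates == ["a", "b"]
        assert res.removal_trace == []

    def test_noise_covariate_removed_first(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame({"signal": rng.normal(size=60), "noise": rng.normal(size=60)})
        y = 3 * x["signal"] + rng.normal(0, 0.5, 60)
        res = backward_select(y, x, alpha=0.05)
        assert res.covariates == ["signal"]
        assert res.removal_trace[0][0] == "noise"

    def test_everything_removed_gives_intercept_only(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="intercept-only"):
            res = backward_select(y, x, alpha=1e-6)
        assert res.covariates == []
        assert len(res.removal_trace) == 2


def brute_force_lmg(y, x):
    """Oracle: average sequential R^2 increments over all k! orderings."""
    cols = list(x.columns)
    k = len(cols)

    def r2(sub):
        if not sub:
            return 0.0
        d = np.column_stack([np.ones(len(y)), x[list(sub)].to_numpy()])
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        resid = y - d @ beta
        return 1 - resid @ resid / ((y - y.mean()) ** 2).sum()

    shares = dict.fromkeys(cols, 0.0)
    orderings = list(itertools.permutations(cols))
    for order in orderings:
        seen = []
        for c in order:
            shares[c] += r2(seen + [c]) - r2(seen)
            seen.append(c)
    return {c: v / len(orderings) for c, v in shares.items()}


class TestLmg:
    def test_single_covariate_share_is_r2(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame({"v": rng.normal(size=50)})
        y = x["v"].to_numpy() + rng.normal(0, 1, 50)
        res = lmg_importance(y, x)
        full = fit_ols(y, x)
        assert res.loc["v", "lmg_share"] == pytest.approx(full.rsquared, abs=1e-12)
        assert res.loc["v", "lmg_percent_of_r2"] == pytest.approx(100.0)

    def test_orthogonal_covariates_get_marginal_r2(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(9)
        y = a + 0.5 * b + rng.normal(0, 0.3, n)
        x = pd.DataFrame({"a": a, "b": b})
        res = lmg_importance(y, x)
        ra = fit_ols(y, x[["a"]]).rsquared
        rb = fit_ols(y, x[["b"]]).rsquared
        assert res.loc["a", "lmg_share"] == pytest.approx(ra, abs=1e-10)
        assert res.loc["b", "lmg_share"] == pytest.approx(rb, abs=1e-10)

    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 3), (2, 4), (3, 5)])
    def test_matches_brute_force_orderings(self, seed, k):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(30, k)), columns=[f"v{i}" for i in range(k)])
        y = x.to_numpy() @ rng.normal(size=k) + rng.normal(0, 1, 30)
        res = lmg_importance(y, x)
        oracle = brute_force_lmg(y, x)
        for c in x.columns:
            assert res.loc[c, "lmg_share"] == pytest.approx(oracle[c], abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_shares_sum_to_r2(self, seed):
        rng = np.random.default_rng(seed + 20)
        k = int(rng.integers(2, 6))
        x = pd.DataFrame(rng.normal(size=(40, k)), columns=[f"v{i}" for i in range(k)])
        y = rng.normal(size=40)
        res = lmg_importance(y, x)
        full = fit_ols(y, x)
        assert res["lmg_share"].sum() == pytest.approx(full.rsquared, abs=1e-10)


class TestMoran:
    def _coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "longitude": rng.uniform(108, 111, n),
            "latitude": rng.uniform(18, 20, n),
        })

    def test_expected_value(self):
        coords = self._coords(9)
        res = morans_i(np.random.default_rng(1).normal(size=9), coords)
        assert res.expected == pytest.approx(-0.125)

    def test_haversine_one_degree_on_equator(self):
        lon = np.array([0.0, 1.0])
        lat = np.array([0.0, 0.0])
        d = haversine_matrix(lon, lat)
        assert d[0, 1] == pytest.approx(2 * np.pi * 6_378_137 / 360, abs=0.01)
        assert d[0, 1] == pytest.approx(111_319.49, abs=0.01)

    def test_constant_values_undefined(self):
        res = morans_i(np.ones(6), self._coords(6))
        assert np.isnan(res.observed)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=8)
        coords = self._coords(8, 2)
        r1 = morans_i(v, coords)
        r2 = morans_i(v + 100.0, coords)
        assert r1.observed == pytest.approx(r2.observed, abs=1e-12)

    def test_coincident_sites_rejected(self):
        coords = pd.DataFrame({"longitude": [110.0, 110.0, 111.0, 112.0],
                               "latitude": [19.0, 19.0, 19.5, 20.0]})
        with pytest.raises(ValidationError, match="coincident"):
            morans_i(np.arange(4.0), coords)

    def test_spatially_smooth_field_detected(self):
        """Values equal to longitude are strongly autocorrelated."""
        coords = self._coords(20, 5)
        res = morans_i(coords["longitude"].to_numpy(), coords)
        assert res.observed > res.expected
        assert res.p < 0.05


class TestScanA:
    def test_degenerate_grid_returns_that_a(self):
        study = fpdiv.generate_study(n_sites=14, pool_size=25, seed=3,
                                     richness_range=(6, 12))
        tree, traits, comm = fpdiv.align_labels(study.tree, study.traits, study.community)
        fd, _ = fpdiv.functional_distance(traits)
        pdm = fpdiv.patristic_distances(tree)
        cov = study.env.covariates.loc[comm.sites]
        res = scan_a(comm, fd, pdm, cov[["HII", "ALT"]],
                     NullSpec(n_iterations=29, seed=1), a_grid=np.array([0.4]))
        assert res.a_star == 0.4
        assert res.max_adj_r2 == res.adj_r2[0]

    def test_max_attained_at_a_star(self):
        study = fpdiv.generate_study(n_sites=14, pool_size=25, seed=4,
                                     richness_range=(6, 12))
        tree, traits, comm = fpdiv.align_labels(study.tree, study.traits, study.community)
        fd, _ = fpdiv.functional_distance(traits)
        pdm = fpdiv.patristic_distances(tree)
        cov = study.env.covariates.loc[comm.sites]
        res = scan_a(comm, fd, pdm, cov[["HII", "ALT"]],
                     NullSpec(n_iterations=29, seed=1),
                     a_grid=np.array([0.0, 0.5, 1.0]))
        i = list(res.a_grid).index(res.a_star)
        assert res.adj_r2[i] == res.max_adj_r2
        assert res.max_adj_r2 == np.nanmax(res.adj_r2)
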