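"""The lasso-penalized maximum-entropy model: fitting, prediction, reports."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from ottersdm import MaxEnt, synth
from ottersdm.maxent import FrozenMaxEnt


def penalized_objective(lam, F_pres, F_part, penalties):
    """Exact objective, written independently of the fitting code."""
    lam = np.atleast_1d(np.asarray(lam, float))
    nll = (-F_pres.mean(axis=0) @ lam
           + logsumexp(F_part @ lam) - np.log(F_part.shape[0]))
    return nll + penalties @ np.abs(lam)


def training_matrices(res):
    """(F_pres, F_part) as used by the fit, rebuilt via projection."""
    from ottersdm.features import project_features

    model = res.model
    m = model.presence_X.shape[0]
    X = np.vstack([model.presence_X, model.background_X])
    F = project_features(X, model.spec, res.columns)
    return F[:m], (F if model.add_presences_to_background else F[m:])


def simple_data(seed=0, m=40, n=300, p=2, informative=True):
    rng = np.random.default_rng(seed)
    B = rng.uniform(0, 100, size=(n, p))
    if informative:
        w = np.exp(2.5 * B[:, 0] / 100)
        idx = rng.choice(n, size=m, p=w / w.sum())
    else:
        idx = rng.choice(n, size=m)
    return B[idx], B


class TestFit:
    def test_constant_covariates_give_uniform_model(self):
        P = np.full((10, 2), 5.0)
        B = np.full((100, 2), 5.0)
        res = MaxEnt(P, B).fit()
        raw = res.predict(B, transform="raw")
        assert np.allclose(raw, raw[0])
        assert res.k_nonzero == 0

    def test_huge_penalty_zeroes_all_coefficients(self):
        P, B = simple_data(1)
        res = MaxEnt(P, B, rm=1e6).fit()
        assert np.all(res.params == 0.0)

    def test_single_linear_feature_matches_1d_search(self):
        # 1-D oracle: golden-section search on the exact penalized objective
        P, B = simple_data(2, m=20, n=200, p=1)
        res = MaxEnt(P, B, feature_set="L", rm=1.0).fit(tol=1e-9)
        F_pres, F_part = training_matrices(res)
        sol = minimize_scalar(
            lambda lam: penalized_objective(lam, F_pres, F_part, res.penalties),
            bounds=(-50.0, 50.0), method="bounded",
            options={"xatol": 1e-10})
        assert res.params[0] == pytest.approx(sol.x, abs=1e-4)

    def test_objective_nonincreasing_every_sweep(self):
        for seed in range(5):
            P, B = simple_data(seed, p=3)
            res = MaxEnt(P, B, feature_set="LQ").fit()
            path = np.array(res.objective_path)
            assert np.all(np.diff(path) <= 1e-12)

    def test_kkt_conditions_satisfied(self):
        for fs in ("L", "LQ", "LQH"):
            P, B = simple_data(3, p=2)
            res = MaxEnt(P, B, feature_set=fs, hinge_knots=8).fit()
            assert res.kkt_violation() < 1e-4

    def test_matches_dense_grid_search_up_to_3_features(self):
        # oracle equivalence: exhaustive grid on the exact objective
        P, B = simple_data(4, m=30, n=250, p=3)
        res = MaxEnt(P, B, feature_set="L", rm=1.0).fit(tol=1e-8)
        F_pres, F_part = training_matrices(res)
        assert len(res.columns) == 3
        axis = np.linspace(-6, 6, 49)
        grid = np.array(list(itertools.product(axis, axis, axis)))
        a = F_pres.mean(axis=0)
        grid_best = np.inf
        for chunk in np.array_split(grid, 50):
            eta = F_part @ chunk.T
            nll = -chunk @ a + logsumexp(eta, axis=0) - np.log(F_part.shape[0])
            obj = nll + np.abs(chunk) @ res.penalties
            grid_best = min(grid_best, obj.min())
        assert res.objective <= grid_best + 1e-3

    def test_sparsity_nonincreasing_in_rm(self):
        # lasso path sanity over the tuning grid's multipliers
        for seed in range(10):
            P, B = simple_data(seed + 10, m=50, n=300, p=3)
            ks = [MaxEnt(P, B, feature_set="LQ", rm=rm).fit().k_nonzero
                  for rm in (1, 2, 3, 4, 5)]
            assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_sign_recovery_on_virtual_species(self):
        # coefficients (+3, -3, 0): signs recovered, zero covariate smallest
        wins = 0
        for seed in range(20):
            stack = synth.gen_landscape(
                seed, 40, 40, 131.0,
                [("a", "percent_cover", 4.0), ("b", "percent_cover", 4.0),
                 ("c", "percent_cover", 4.0)])
            dom = synth.gen_survey_design(stack, 2, 2)
            pres, _ = synth.gen_species(stack, dom, {"a": 3.0, "b": -3.0, "c": 0.0},
                                        500, seed=100 + seed)
            bg = synth.sample_background(dom, stack, 800, seed=200 + seed)
            P = stack.values_at_cells(pres.rows, pres.cols)
            B = stack.values_at_cells(bg.rows, bg.cols)
            res = MaxEnt(P, B, covariates=stack.names, feature_set="L").fit()
            coef = {c.covariate: lam for c, lam in zip(res.columns, res.params)}
            ok = (coef["a"] > 0 and coef["b"] < 0
                  and abs(coef["c"]) < abs(coef["a"])
                  and abs(coef["c"]) < abs(coef["b"]))
            wins += ok
        assert wins >= 19

    def test_input_validation(self):
        with pytest.raises(Exception):
            MaxEnt(np.ones((1, 2)), np.ones((10, 2)))  # too few presences
        with pytest.raises(Exception):
            MaxEnt(np.ones((5, 2)), np.ones((10, 3)))  # width mismatch
        P, B = simple_data(5)
        P[0, 0] = np.nan
        with pytest.raises(Exception):
            MaxEnt(P, B)


class TestPredict:
    def test_raw_sums_to_one_over_background(self):
        P, B = simple_data(6)
        res = MaxEnt(P, B, add_presences_to_background=False).fit()
        assert res.predict(B, "raw").sum() == pytest.approx(1.0, abs=1e-8)
        res2 = MaxEnt(P, B).fit()  # presences folded into the partition sample
        total = res2.predict(np.vstack([P, B]), "raw").sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_cloglog_in_unit_interval(self):
        P, B = simple_data(7)
        res = MaxEnt(P, B, feature_set="LQ").fit()
        scores = res.predict(B, "cloglog")
        assert np.all((scores > 0) & (scores < 1))

    def test_uniform_model_constant_cloglog(self):
        P = np.full((10, 1), 2.0)
        B = np.full((50, 1), 2.0)
        res = MaxEnt(P, B).fit()
        scores = res.predict(B, "cloglog")
        assert np.allclose(scores, scores[0])
        # entropy of the uniform background distribution makes this 1 - 1/e
        assert scores[0] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-10)

    def test_cloglog_preserves_raw_ranking(self):
        P, B = simple_data(8, n=1000)
        res = MaxEnt(P, B, feature_set="LQ").fit()
        raw = res.predict(B, "raw")
        clog = res.predict(B, "cloglog")
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(clog))

    def test_predict_grid_masks_and_values(self, small_stack, small_species,
                                           small_background, small_sample):
        P, B, names = small_sample
        res = MaxEnt(P, B, covariates=names).fit()
        surface = res.predict_grid(small_stack)
        valid = ~small_stack.nodata_mask
        assert surface.values[valid].min() > 0
        assert surface.values[valid].max() < 1

    def test_serialization_round_trip(self, tmp_path, small_sample):
        P, B, names = small_sample
        res = MaxEnt(P, B, covariates=names, feature_set="LQ").fit()
        path = tmp_path / "model.json"
        res.save(path)
        frozen = FrozenMaxEnt.load(path)
        for transform in ("raw", "cloglog"):
            np.testing.assert_allclose(frozen.predict(B, transform),
                                       res.predict(B, transform), rtol=1e-12)


class TestReports:
    def test_single_covariate_contribution_is_100(self):
        P, B = simple_data(9, p=1)
        res = MaxEnt(P, B, feature_set="L").fit()
        assert res.percent_contribution().iloc[0] == pytest.approx(100.0)

    def test_noise_covariate_gets_zero_contribution(self):
        rng = np.random.default_rng(10)
        P, B = simple_data(10, m=60, n=400, p=1)
        P = np.column_stack([P, rng.uniform(0, 1, P.shape[0])])
        B = np.column_stack([B, rng.uniform(0, 1, B.shape[0])])
        res = MaxEnt(P, B, covariates=["signal", "noise"], rm=2.0).fit()
        contrib = res.percent_contribution()
        coef_noise = [lam for c, lam in zip(res.columns, res.params)
                      if c.covariate == "noise"]
        if all(l == 0 for l in coef_noise):  # shrunk away entirely
            assert contrib["noise"] == 0.0

    def test_contributions_sum_to_100(self):
        for seed in range(20):
            P, B = simple_data(seed + 30, p=3)
            res = MaxEnt(P, B, feature_set="LQ").fit()
            total = res.percent_contribution().sum()
            if res.k_nonzero:
                assert total == pytest.approx(100.0, abs=0.1)

    def test_permutation_importance_zero_for_unused_covariate(self):
        P, B = simple_data(11, p=1)
        rng = np.random.default_rng(11)
        P = np.column_stack([P, np.full(P.shape[0], 1.0)])
        B = np.column_stack([B, np.full(B.shape[0], 1.0)])
        res = MaxEnt(P, B, covariates=["signal", "flat"]).fit()
        imp = res.permutation_importance(n_iter=5, seed=0)
        assert imp["flat"] == 0.0
        assert imp["signal"] == pytest.approx(100.0)

    def test_importance_normalized(self, small_sample):
        P, B, names = small_sample
        res = MaxEnt(P, B, covariates=names).fit()
        imp = res.permutation_importance(n_iter=10, seed=1)
        assert imp.sum() == pytest.approx(100.0, abs=0.1)

    def test_default_permutation_iterations(self):
        import inspect
        from ottersdm.maxent import MaxEntResults
        sig = inspect.signature(MaxEntResults.permutation_importance)
        assert sig.parameters["n_iter"].default == 120

    def test_positive_linear_model_monotone_curve(self):
        P, B = simple_data(12, p=1)
        res = MaxEnt(P, B, feature_set="L").fit()
        assert res.params[0] > 0
        curve = res.response_curves()["x0"]["cloglog"].to_numpy()
        assert np.all(np.diff(curve) > 0)
        assert res.relationship_directions()["x0"] == "Positive"

    def test_absent_covariate_flat_curve_na(self):
        P, B = simple_data(13, p=1)
        P = np.column_stack([P, np.full(P.shape[0], 3.0)])
        B = np.column_stack([B, np.full(B.shape[0], 3.0)])
        res = MaxEnt(P, B, covariates=["signal", "flat"]).fit()
        curves = res.response_curves()
        assert curves["flat"]["cloglog"].nunique() == 1
        assert res.relationship_directions()["flat"] == "NA"

    def test_direction_recovery_on_virtual_species(self, small_stack,
                                                   small_species, small_sample):
        P, B, names = small_sample
        _, truth = small_species
        res = MaxEnt(P, B, covariates=names).fit()
        dirs = res.relationship_directions()
        assert dirs["bathymetry"] == "Positive"
        assert dirs["shell_litter"] == "Negative"

    def test_summary_mentions_spec(self, small_sample):
        P, B, names = small_sample
        res = MaxEnt(P, B, covariates=names, feature_set="L", rm=2.0).fit()
        text = res.summary()
        assert "rm = 2" in text and "bathymetry" in text
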