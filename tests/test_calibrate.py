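"""Calibration harness: splits, PLS, engines, repeated CV, trimming."""

import numpy as np
import pytest

from rootnirs import (
    CVProtocol,
    EngineSpec,
    TreatmentSpec,
    aggregate_readings,
    fit_engine,
    fit_pls,
    repeated_cv,
    residual_trim_refit,
    select_pls_components,
    select_treatment,
    split_dataset,
)
from rootnirs.calibrate import fold_assignments, trait_vector
from rootnirs.exceptions import DegenerateInputError, SizingError


def svd_pls_oracle(X, y, n_components):
    """Independent PLS1 reference: weights from the SVD of the deflated
    cross-covariance matrix X'y, classic score/loading deflation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_components):
        U, s, _ = np.linalg.svd(Xc.T @ yc.reshape(-1, 1), full_matrices=False)
        if s[0] < 1e-12:
            break
        w = U[:, 0]
        t = Xc @ w
        tt = t @ t
        p = Xc.T @ t / tt
        q = (yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.column_stack(W), np.column_stack(P), np.asarray(Q)
    coef = W @ np.linalg.inv(P.T @ W) @ Q
    return coef, y_mean - x_mean @ coef


class TestSplitDataset:
    def test_exact_80_20(self, rng):
        ids = np.array([f"p{i}" for i in range(100)])
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        cal, hold = split_dataset(X, y, ids, CVProtocol(seed=1))
        assert len(cal[2]) == 80 and len(hold[2]) == 20
        assert set(cal[2]) | set(hold[2]) == set(ids)
        assert set(cal[2]) & set(hold[2]) == set()

    def test_seeded_determinism(self, rng):
        ids = np.array([f"p{i}" for i in range(50)])
        X, y = rng.normal(size=(50, 3)), rng.normal(size=50)
        a = split_dataset(X, y, ids, CVProtocol(seed=9))
        b = split_dataset(X, y, ids, CVProtocol(seed=9))
        c = split_dataset(X, y, ids, CVProtocol(seed=10))
        assert np.array_equal(a[0][2], b[0][2])
        assert not np.array_equal(a[0][2], c[0][2])

    def test_too_few_plots(self, rng):
        with pytest.raises(SizingError):
            split_dataset(rng.normal(size=(5, 3)), np.zeros(5),
                          np.arange(5), CVProtocol())


class TestAggregateReadings:
    def test_mean_per_plot(self, quiet_config):
        from rootnirs import simulate_spectra, simulate_traits

        traits = simulate_traits(quiet_config)
        ds = simulate_spectra(traits, "mashed", quiet_config)
        plot_ids, X = aggregate_readings(ds)
        assert len(plot_ids) == traits["plot_id"].nunique()
        # noise-free replicate readings equal their mean
        first = ds.meta["plot_id"] == plot_ids[0]
        assert np.allclose(X[0], ds.absorbance[first.to_numpy()].mean(axis=0))


class TestPLS:
    def test_exact_recovery_of_linear_response(self, rng):
        X = rng.normal(size=(30, 6))
        beta = rng.normal(size=6)
        y = X @ beta + 2.0
        model = fit_pls(X, y, 6)
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_single_latent_factor_needs_one_component(self, rng):
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=8)) + 0.0
        y = 3 * t + 1
        one = fit_pls(X, y, 1).predict(X)
        full = fit_pls(X, y, 8).predict(X)
        assert np.allclose(one, full, atol=1e-6)

    def test_coefficients_match_svd_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(8, 5))
            y = rng.normal(size=8)
            for a in (1, 2, 3):
                model = fit_pls(X, y, a)
                coef, intercept = svd_pls_oracle(X, y, a)
                assert np.allclose(model.coef_, coef, atol=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(20, 10))
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(0, 0.1, 20)
        mine = fit_pls(X, y, 4).predict(X)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y).predict(X).ravel()
        assert np.allclose(mine, ref, atol=1e-6)

    def test_zero_variance_response_errors(self, rng):
        with pytest.raises(DegenerateInputError):
            fit_pls(rng.normal(size=(10, 4)), np.ones(10), 2)


class TestSelectPLSComponents:
    def test_rank_two_response_selects_two(self, rng):
        t1, t2 = rng.normal(size=60), rng.normal(size=60)
        loadings1, loadings2 = rng.normal(size=12), rng.normal(size=12)
        X = np.outer(t1, loadings1) + np.outer(t2, loadings2)
        y = t1 + t2
        assert select_pls_components(X, y, CVProtocol(seed=2), 8) == 2

    def test_pure_noise_selects_one(self, rng):
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        assert select_pls_components(X, y, CVProtocol(seed=3), 8) == 1

    def test_cap_respected(self, rng):
        X = rng.normal(size=(40, 20))
        y = X @ rng.normal(size=20)
        assert select_pls_components(X, y, CVProtocol(seed=4), 3) <= 3


class TestFitEngine:
    def test_xgb_parameter_echo(self, rng):
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        model = fit_engine(X, y, EngineSpec("xgb"), seed=0)
        assert model.params == dict(
            engine="xgb", nrounds=200, max_depth=5, eta=0.3, gamma=5.0,
            subsample=0.7, colsample_bytree=0.7, min_child_weight=1,
        )

    def test_svm_parameter_echo(self, rng):
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        model = fit_engine(X, y, EngineSpec("svm"))
        assert model.params["kernel"] == "rbf"
        assert model.params["C"] == 1.0

    @pytest.mark.parametrize("engine", ["pls", "svm", "xgb"])
    def test_constant_response_predicts_constant(self, engine, rng):
        X = rng.normal(size=(25, 6))
        y = np.full(25, 4.2)
        model = fit_engine(X, y, EngineSpec(engine), seed=1)
        assert np.allclose(model.predict(X), 4.2, atol=1e-3 if engine == "svm" else 1e-6)


class TestRepeatedCV:
    def test_bit_reproducible_for_fixed_seed(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.5, 40)
        prot = CVProtocol(seed=11)
        a = repeated_cv(X, y, EngineSpec("pls"), prot, n_components=4)
        b = repeated_cv(X, y, EngineSpec("pls"), prot, n_components=4)
        assert np.array_equal(a.oof_predictions, b.oof_predictions)
        assert a.metrics == b.metrics

    def test_noise_free_linear_response_r_near_one(self, rng):
        X = rng.normal(size=(50, 6))
        y = X @ rng.normal(size=6) + 3
        res = repeated_cv(X, y, EngineSpec("pls"), CVProtocol(seed=12), n_components=6)
        assert res.metrics.r >= 0.999

    def test_metrics_average_over_five_repetitions(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 1, 40)
        res = repeated_cv(X, y, EngineSpec("pls"), CVProtocol(seed=13), n_components=3)
        assert len(res.per_repeat_metrics) == 5
        assert res.metrics.rmse == pytest.approx(
            np.mean([m.rmse for m in res.per_repeat_metrics])
        )

    def test_fold_assignments_engine_agnostic(self):
        prot = CVProtocol(seed=14)
        assert np.array_equal(fold_assignments(60, prot), fold_assignments(60, prot))


class TestResidualTrimRefit:
    def test_trim_count_is_floor(self, rng):
        X = rng.normal(size=(47, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.3, 47)
        run = residual_trim_refit(
            X, y, np.arange(47), EngineSpec("pls"), CVProtocol(seed=15)
        )
        assert len(run.trimmed_ids) == int(np.floor(0.2 * 47))
        assert set(run.trimmed_ids) <= set(run.calibration_ids)

    def test_zero_trim_equals_repeated_cv(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.5, 40)
        prot = CVProtocol(seed=16, trim_fraction=0.0)
        run = residual_trim_refit(X, y, np.arange(40), EngineSpec("pls"), prot)
        ref = repeated_cv(X, y, EngineSpec("pls"), prot,
                          n_components=run.chosen_pls_components)
        assert run.trimmed_ids == []
        assert np.array_equal(run.cv_predictions, ref.oof_predictions)
        assert run.metrics_cv == ref.metrics

    def test_corrupted_samples_are_trimmed(self, rng):
        """Samples with grossly corrupted responses carry the largest
        cross-validated residuals and land in the trimmed set."""
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8)
        bad = rng.choice(60, size=12, replace=False)
        y = y.copy()
        y[bad] += 10 * y.std()
        run = residual_trim_refit(
            X, y, np.arange(60), EngineSpec("pls"), CVProtocol(seed=17)
        )
        recovered = len(set(run.trimmed_ids) & set(bad)) / len(bad)
        assert recovered >= 0.8

    def test_trim_leaves_enough_samples(self, rng):
        X, y = rng.normal(size=(12, 4)), rng.normal(size=12)
        with pytest.raises(SizingError):
            residual_trim_refit(X, y, np.arange(12), EngineSpec("pls"),
                                CVProtocol(seed=18, trim_fraction=0.5))


class TestSelectTreatment:
    @staticmethod
    def _run(treatment, sample_type, r, rmse):
        from rootnirs.calibrate import CalibrationRun
        from rootnirs.metrics import MetricSet

        m = MetricSet(r=r, r2=r * r, rmse=rmse, bias_additive=0.0, slope=1.0,
                      rpd=1.0, rpiq=1.0, n=50)
        return CalibrationRun(
            trait="DMCo", sample_type=sample_type, treatment=TreatmentSpec(treatment),
            engine=EngineSpec("pls"), calibration_ids=[], trimmed_ids=[],
            holdout_ids=[], cv_predictions=np.zeros((1, 1)),
            holdout_predictions=np.zeros(0), metrics_cv=m, metrics_val=None,
            chosen_pls_components=2,
        )

    def test_dominant_treatment_wins(self):
        runs = [
            self._run("raw", "fresh", 0.6, 2.0),
            self._run("snv", "fresh", 0.8, 1.5),
            self._run("raw", "mashed", 0.7, 1.8),
            self._run("snv", "mashed", 0.9, 1.2),
        ]
        assert select_treatment(runs).name == "snv"

    def test_exact_tie_broken_by_name_order(self):
        runs = [
            self._run("sg_snv", "fresh", 0.8, 1.5),
            self._run("d1", "fresh", 0.8, 1.5),
        ]
        # d1 precedes sg_snv in the fixed treatment order
        assert select_treatment(runs).name == "d1"

    def test_non_pls_runs_are_ignored(self):
        from rootnirs.calibrate import CalibrationRun

        pls_run = self._run("raw", "fresh", 0.6, 2.0)
        xgb_run = CalibrationRun(
            trait="DMCo", sample_type="fresh", treatment=TreatmentSpec("snv"),
            engine=EngineSpec("xgb"), calibration_ids=[], trimmed_ids=[],
            holdout_ids=[], cv_predictions=np.zeros((1, 1)),
            holdout_predictions=np.zeros(0),
            metrics_cv=self._run("snv", "fresh", 0.99, 0.1).metrics_cv,
            metrics_val=None, chosen_pls_components=None,
        )
        # the screening stage only ever consults PLS runs
        assert select_treatment([pls_run, xgb_run]).name == "raw"


@pytest.mark.parametrize("engine", ["pls", "svm", "xgb"])
def test_cv_accuracy_degrades_with_channel_noise(engine):
    """Raising the generator's channel noise weakly lowers mean CV R for
    every engine (5-point noise ladder, replicate seeds averaged)."""
    import dataclasses

    from scipy.stats import spearmanr

    from rootnirs import SimulationConfig, simulate_spectra, simulate_traits

    ladder = (0.001, 0.01, 0.03, 0.06, 0.1)
    protocol = CVProtocol(seed=99, n_repeats=2)
    mean_r = []
    for noise in ladder:
        rs = []
        for seed in (300, 301, 302):
            cfg = SimulationConfig(
                n_clones=30, n_envs=1, n_reps=2,
                noise_sd={"fresh": noise, "mashed": noise},
                readings_per_plot={"fresh": 1, "mashed": 1},
                seed=seed,
            )
            traits = simulate_traits(cfg)
            ds = simulate_spectra(traits, "mashed", cfg)
            plot_ids, X = aggregate_readings(ds)
            y = trait_vector(traits, plot_ids, "DMCo")
            res = repeated_cv(X, y, EngineSpec(engine), protocol)
            rs.append(res.metrics.r)
        mean_r.append(np.mean(rs))
    rho = spearmanr(ladder, mean_r).statistic
    assert rho <= -0.8, (engine, mean_r)


def test_plot_grouping_keeps_readings_together(small_study, protocol):
    """Splitting happens on plot-level rows, so a plot's readings can never
    straddle the partitions."""
    cal, hold = split_dataset(
        small_study["X"], small_study["y"], small_study["plot_ids"], protocol
    )
    meta = small_study["ds"].meta
    cal_set, hold_set = set(cal[2]), set(hold[2])
    for plot, group in meta.groupby("plot_id"):
        assert (plot in cal_set) != (plot in hold_set)
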