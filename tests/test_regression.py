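import numpy as np
import pandas as pd
import pytest

from rowlai import (
    Dataset,
    ModelReport,
    evaluate,
    feature_dataset,
    fit_plsr,
    fit_smlr,
    fit_svr,
    r_squared,
    split_by_variety,
)


class TestSplitByVariety:
    def test_80_varieties_gives_60_20(self):
        ds = feature_dataset(n_varieties=80, seed=0)
        train, test = split_by_variety(ds, seed=1)
        assert len(np.unique(train.variety)) == 60
        assert len(np.unique(test.variety)) == 20
        assert train.n == 120 and test.n == 40

    def test_4_varieties_gives_3_1(self):
        ds = feature_dataset(n_varieties=4, seed=0)
        train, test = split_by_variety(ds, seed=0)
        assert len(np.unique(train.variety)) == 3
        assert len(np.unique(test.variety)) == 1

    def test_replicates_never_split_across_sides(self):
        ds = feature_dataset(n_varieties=17, seed=3)
        for seed in range(200):
            train, test = split_by_variety(ds, seed=seed)
            assert not (set(train.variety) & set(test.variety))
            assert train.n + test.n == ds.n

    def test_deterministic_given_seed(self):
        ds = feature_dataset(n_varieties=10, seed=0)
        a1, _ = split_by_variety(ds, seed=5)
        a2, _ = split_by_variety(ds, seed=5)
        np.testing.assert_array_equal(a1.variety, a2.variety)

    def test_too_few_varieties(self):
        ds = feature_dataset(n_varieties=3, seed=0)
        with pytest.raises(ValueError, match="varieties"):
            split_by_variety(ds, seed=0)


class TestSmlr:
    def test_exact_recovery_single_feature(self):
        ds = feature_dataset(n_varieties=30, seed=1)
        ds = Dataset(ds.X, 3.0 * ds.X["lpi"].to_numpy(), ds.variety, ds.replicate)
        report = fit_smlr(ds)
        assert report.selected_features == ["lpi"]
        assert report.hyperparameters["coefficients"]["lpi"] == pytest.approx(3.0, abs=1e-8)
        assert report.hyperparameters["coefficients"]["const"] == pytest.approx(0.0, abs=1e-8)

    def test_two_feature_recovery_with_small_noise(self):
        ds = feature_dataset(n_varieties=40, seed=2)
        rng = np.random.default_rng(2)
        y = 2.0 * ds.X["lpi"].to_numpy() + 1.0 * ds.X["vci"].to_numpy()
        y = y + rng.normal(0, 1e-3, ds.n)
        report = fit_smlr(Dataset(ds.X, y, ds.variety, ds.replicate))
        assert set(report.selected_features) == {"lpi", "vci"}

    def test_pure_noise_usually_selects_nothing_much(self):
        # per-feature selection rate on noise targets stays near alpha
        ds = feature_dataset(n_varieties=25, seed=3)
        rng = np.random.default_rng(3)
        counts = {f: 0 for f in ds.feature_names}
        runs = 120
        import warnings

        for _ in range(runs):
            y = rng.normal(0, 1, ds.n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = fit_smlr(Dataset(ds.X, y, ds.variety, ds.replicate))
            for f in report.selected_features:
                counts[f] += 1
        for f, c in counts.items():
            assert c / runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / runs)

    def test_intercept_only_fallback(self):
        ds = feature_dataset(n_varieties=10, seed=4)
        y = np.full(ds.n, 2.5)
        with pytest.warns(UserWarning, match="intercept-only"):
            report = fit_smlr(Dataset(ds.X, y, ds.variety, ds.replicate))
        assert report.selected_features == []
        np.testing.assert_allclose(report.predict(ds.X), 2.5)


class TestPlsr:
    def test_rank_one_design_one_component_suffices(self):
        # all features affine in one latent factor: X has rank 1 after
        # centering, so a single PLS component reproduces any linear target
        rng = np.random.default_rng(5)
        n = 60
        t = rng.uniform(0, 1, n)
        names = ["lpi", "h_mean", "h_std", "h_skew", "h_q3", "vci", "hull_volume", "cap"]
        X = pd.DataFrame({nm: (i + 1.0) * t + i for i, nm in enumerate(names)})
        ds = Dataset(X, 2.0 * t + 1.0, np.repeat(np.arange(30), 2), np.tile([1, 2], 30))
        pinned = fit_plsr(ds, n_components=1)
        assert pinned.train_r2 >= 0.99
        report = fit_plsr(ds, seed=0)
        assert report.cv_r2 >= 0.99

    def test_full_rank_equals_ols(self):
        ds = feature_dataset(n_varieties=30, seed=6, driver="all", noise_sd=0.1)
        report = fit_plsr(ds, n_components=8)
        X1 = np.column_stack([np.ones(ds.n), ds.X.to_numpy()])
        beta, *_ = np.linalg.lstsq(X1, ds.y, rcond=None)
        ols_pred = X1 @ beta
        np.testing.assert_allclose(report.predict(ds.X), ols_pred, atol=1e-6)

    def test_stable_under_collinearity(self):
        # h_std tracks h_mean at |r| > 0.9 by construction
        ds = feature_dataset(n_varieties=40, seed=7, driver="all")
        assert abs(np.corrcoef(ds.X["h_std"], ds.X["h_mean"])[0, 1]) > 0.9
        report = fit_plsr(ds, seed=0)
        assert np.all(np.isfinite(report.predict(ds.X)))


class TestSvr:
    def test_linear_kernel_on_linear_target(self):
        ds = feature_dataset(n_varieties=30, seed=8)
        y = 1.0 + 2.0 * ds.X["lpi"].to_numpy() - 0.5 * ds.X["vci"].to_numpy()
        ds = Dataset(ds.X, y, ds.variety, ds.replicate)
        train, test = split_by_variety(ds, seed=0)
        report = fit_svr(train, kernel="linear", seed=0)
        r2, rmse = evaluate(report, test)
        assert r2 >= 0.99

    def test_rbf_on_smooth_monotone_response(self):
        ds = feature_dataset(n_varieties=60, seed=9, noise_sd=0.05)
        train, test = split_by_variety(ds, seed=0)
        report = fit_svr(train, kernel="rbf", seed=0)
        r2, _ = evaluate(report, test)
        assert r2 >= 0.9

    def test_constant_target_no_crash(self):
        ds = feature_dataset(n_varieties=10, seed=10)
        ds = Dataset(ds.X, np.full(ds.n, 1.0), ds.variety, ds.replicate)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = fit_svr(ds, kernel="rbf", seed=0)
            r2, _ = evaluate(report, ds)
        assert r2 == 0.0

    def test_unknown_kernel(self):
        ds = feature_dataset(n_varieties=10, seed=0)
        with pytest.raises(ValueError, match="kernel"):
            fit_svr(ds, kernel="laplacian")


class TestEvaluate:
    def _report_for(self, pred):
        return ModelReport(family="stub", _predict=lambda X: np.asarray(pred))

    def _test_ds(self, y):
        n = len(y)
        X = pd.DataFrame({"lpi": np.zeros(n)})
        return Dataset(X, np.asarray(y, float), np.arange(n), np.ones(n))

    def test_perfect_predictions(self):
        r2, rmse = evaluate(self._report_for([1.0, 2.0, 3.0]), self._test_ds([1, 2, 3]))
        assert r2 == pytest.approx(1.0) and rmse == 0.0

    def test_mean_only_predictions(self):
        r2, _ = evaluate(self._report_for([2.0, 2.0, 2.0]), self._test_ds([1, 2, 3]))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r2, rmse = evaluate(self._report_for([1.0, 2.0, 4.0]), self._test_ds([1, 2, 3]))
        assert rmse == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-12)
        assert r2 == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_target_convention(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r2 = r_squared([1.0, 1.0], [1.0, 2.0])
        assert r2 == 0.0


class TestNoiseDegradation:
    def test_all_families_strong_at_low_noise_and_degrade(self):
        """Test R² is high when features are nearly noiseless and falls,
        on average across seeds, as feature noise grows."""
        import warnings

        families = {
            "smlr": fit_smlr,
            "plsr": lambda tr, seed: fit_plsr(tr, seed=seed),
            "svr-rbf": lambda tr, seed: fit_svr(tr, kernel="rbf", seed=seed),
        }
        noise_levels = [0.005, 0.1, 0.4]
        means = {fam: [] for fam in families}
        for fam, fit in families.items():
            for noise in noise_levels:
                scores = []
                for seed in range(8):
                    ds = feature_dataset(
                        n_varieties=30, seed=seed, noise_sd=noise, driver="lpi", link="linear"
                    )
                    train, test = split_by_variety(ds, seed=seed)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        report = (
                            fit(train) if fam == "smlr" else fit(train, seed)
                        )
                        r2, _ = evaluate(report, test)
                    scores.append(r2)
                means[fam].append(np.mean(scores))
        for fam, curve in means.items():
            assert curve[0] >= 0.9, fam
            assert curve[0] > curve[1] > curve[2], (fam, curve)
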