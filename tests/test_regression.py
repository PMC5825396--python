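import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crosscell as cc
from crosscell.model_core import ValidationError
from crosscell.regression import (
    apply_preprocess,
    fit_preprocess,
    inverse_preprocess,
    make_folds,
    simpls,
)

from conftest import latent_factor_data

no_log = lambda c: False  # noqa: E731


class TestPreprocess:
    def test_training_matrix_zscored(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(np.exp(rng.normal(0, 0.3, (50, 4))),
                          columns=["APD90", "CaTA", "Vpeak", "Vrest"])
        z, stats = fit_preprocess(df)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        assert np.allclose(z.std(axis=0, ddof=1), 1.0)
        # durations/amplitudes logged, voltages not
        assert stats.log.tolist() == [True, True, False, False]

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(np.exp(rng.normal(0, 0.3, (30, 3))),
                          columns=["APD90", "CaD50", "rate"])
        z, stats = fit_preprocess(df)
        back = inverse_preprocess(z, stats)
        assert np.allclose(back.to_numpy(), df.to_numpy(), rtol=1e-10)

    def test_stored_stats_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (20, 2)), columns=["Vrest", "Vpeak"])
        z, stats = fit_preprocess(df)
        assert np.allclose(apply_preprocess(df, stats), z)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"Vpeak": np.ones(10), "Vrest": np.arange(10.0)})
        with pytest.raises(ValidationError, match="Vpeak"):
            fit_preprocess(df)

    def test_nonpositive_log_column_rejected(self):
        df = pd.DataFrame({"APD90": [-1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="APD90"):
            fit_preprocess(df)


class TestSimpls:
    def test_full_rank_equals_least_squares_oracle(self):
        """At n_components = rank(X), PLSR predictions match an independent
        normal-equations solve on a 30x5 random fixture."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 5))
        y = rng.normal(size=(30, 3))
        x -= x.mean(0)
        y -= y.mean(0)
        b_pls = simpls(x, y, 5)
        b_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert np.abs(x @ b_pls - x @ b_ols).max() < 1e-8

    def test_noiseless_linear_map_recovered_exactly(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 6))
        b_true = rng.normal(size=(6, 2))
        y = x @ b_true
        xdf = pd.DataFrame(x, columns=list("abcdef"))
        ydf = pd.DataFrame(y, columns=list("uv"))
        model = cc.fit_plsr(xdf, ydf, 6, log_policy=no_log)
        pred = model.predict(xdf)
        assert np.abs(pred.to_numpy() - y).max() < 1e-8 * np.abs(y).max()

    def test_univariate_single_component_is_simple_regression_slope(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 1))
        y = 2.5 * x + rng.normal(scale=0.1, size=(50, 1))
        xc, yc = x - x.mean(), y - y.mean()
        b = simpls(xc, yc, 1)
        slope = float(np.cov(xc[:, 0], yc[:, 0])[0, 1] / np.var(xc[:, 0], ddof=1))
        assert b[0, 0] == pytest.approx(slope, rel=1e-10)

    def test_agrees_with_sklearn_on_univariate_target(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(6)
        x = rng.normal(size=(60, 8))
        y = rng.normal(size=(60, 1))
        xc, yc = x - x.mean(0), y - y.mean(0)
        for a in (1, 3, 5):
            ours = xc @ simpls(xc, yc, a)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(
                xc, yc).predict(xc)
            assert np.abs(ours - ref).max() < 1e-8

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 2))
        with pytest.raises(ValidationError):
            simpls(x, y, 4)

    def test_training_cell_prediction_reproduces_fit(self):
        xdf, ydf = latent_factor_data(seed=8, n_rows=60)
        model = cc.fit_plsr(xdf, ydf, 3, log_policy=no_log)
        p1 = model.predict(xdf.iloc[[7]])
        p2 = model.predict(xdf).iloc[[7]]
        assert np.abs(p1.to_numpy() - p2.to_numpy()).max() < 1e-10


class TestPressCV:
    def test_600_rows_5_folds_gives_folds_of_120(self):
        assign = make_folds(600, 5, seed=0)
        assert np.bincount(assign).tolist() == [120] * 5

    def test_press_matches_brute_force_refit(self):
        """PRESS equals an independently coded per-fold refit loop on a
        12-sample toy with 3 folds."""
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        y = pd.DataFrame(rng.normal(size=(12, 2)), columns=list("uv"))
        rep = cc.press_cv(x, y, n_components=3, k_folds=3, seed=11,
                          log_policy=no_log)
        assign = make_folds(12, 3, seed=11)
        press = 0.0
        for k in range(3):
            tr, te = assign != k, assign == k
            xm, xs = x[tr].mean(), x[tr].std(ddof=1)
            ym, ys = y[tr].mean(), y[tr].std(ddof=1)
            zx, zy = (x[tr] - xm) / xs, (y[tr] - ym) / ys
            b, *_ = np.linalg.lstsq(zx.to_numpy(), zy.to_numpy(), rcond=None)
            zt = ((x[te] - xm) / xs).to_numpy()
            resid = zt @ b - ((y[te] - ym) / ys).to_numpy()
            press += float((resid ** 2).sum())
        assert rep.press == pytest.approx(press, rel=1e-9)

    def test_perfect_linear_data_heldout_r2_one(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = pd.DataFrame(x.to_numpy() @ rng.normal(size=(4, 2)),
                         columns=list("uv"))
        rep = cc.press_cv(x, y, 4, k_folds=5, seed=1, log_policy=no_log)
        assert np.all(rep.r2_per_output.to_numpy() > 1 - 1e-6)

    def test_fold_smaller_than_components_rejected(self):
        x = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 5)),
                         columns=list("abcde"))
        y = pd.DataFrame(np.random.default_rng(2).normal(size=(6, 1)),
                         columns=["u"])
        with pytest.raises(ValidationError):
            cc.press_cv(x, y, 5, k_folds=2, seed=0, log_policy=no_log)

    def test_deterministic_given_seed(self):
        xdf, ydf = latent_factor_data(seed=12, n_rows=60)
        a = cc.press_cv(xdf, ydf, 3, seed=5, log_policy=no_log)
        b = cc.press_cv(xdf, ydf, 3, seed=5, log_policy=no_log)
        assert a.press == b.press
        assert np.array_equal(a.fold_assignment, b.fold_assignment)


class TestSelectComponents:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_latent_dimension_recovered(self, seed, recovery_tally):
        """Data with exactly 3 latent factors: the PRESS rule should find 3
        in at least 4 of 5 seeded replicates (asserted in aggregate)."""
        xdf, ydf = latent_factor_data(n_rows=500, n_latent=3, noise=0.05,
                                      seed=seed)
        n, _ = cc.select_components(xdf, ydf, seed=seed, log_policy=no_log,
                                    max_components=8)
        recovery_tally.append(n == 3)

    def test_noiseless_rank_one_map_needs_one_component(self):
        rng = np.random.default_rng(13)
        t = rng.normal(size=(200, 1))
        x = pd.DataFrame(t @ rng.normal(size=(1, 5)),
                         columns=[f"x{i}" for i in range(5)])
        y = pd.DataFrame(t @ rng.normal(size=(1, 2)), columns=list("uv"))
        n, _ = cc.select_components(x, y, seed=0, log_policy=no_log,
                                    max_components=4)
        assert n == 1

    def test_zero_tolerance_is_strict_argmin(self):
        xdf, ydf = latent_factor_data(n_rows=200, seed=14)
        n, reports = cc.select_components(xdf, ydf, seed=0, tol=0.0,
                                          log_policy=no_log, max_components=6)
        press = [r.press for r in reports]
        assert n == int(np.argmin(press)) + 1


@pytest.fixture(scope="session")
def recovery_tally():
    tally = []
    yield tally
    assert sum(tally) >= 4, f"latent dimension found in only {sum(tally)}/5 seeds"


class TestAdjustedR2:
    def test_formula_value(self):
        assert cc.adjusted_r2(0.9, 600, 5) == pytest.approx(0.89916, abs=1e-5)

    def test_perfect_fit_stays_one(self):
        assert cc.adjusted_r2(1.0, 100, 7) == pytest.approx(1.0)

    @given(r2=st.floats(0.0, 1.0), n=st.integers(10, 1000),
           p=st.integers(1, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_exceeds_raw_r2(self, r2, n, p):
        assert cc.adjusted_r2(r2, n, p) <= r2 + 1e-12

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            cc.adjusted_r2(0.5, 5, 5)


class TestChangePrediction:
    def test_zero_change_vector_predicts_zero(self, small_paired_runs):
        src, tgt = small_paired_runs
        fit = cc.build_cross_model(src, tgt, "pace1", n_components=5, seed=3)
        zero = pd.Series(0.0, index=pd.MultiIndex.from_tuples(
            fit.model.x_stats.columns))
        pred = fit.model.predict_change(zero)
        assert np.abs(pred.to_numpy()).max() == 0.0
        pct = fit.model.change_to_percent(pred)
        assert np.abs(pct.to_numpy()).max() == 0.0

    def test_column_mismatch_reports_missing(self, small_paired_runs):
        src, tgt = small_paired_runs
        fit = cc.build_cross_model(src, tgt, "pace1", n_components=5, seed=3)
        bad = pd.Series(0.0, index=pd.MultiIndex.from_tuples(
            fit.model.x_stats.columns[:-1]))
        with pytest.raises(ValidationError, match="mismatch"):
            fit.model.predict_change(bad)

    def test_model_json_round_trip(self, small_paired_runs, tmp_path):
        src, tgt = small_paired_runs
        fit = cc.build_cross_model(src, tgt, "pace1", n_components=5, seed=3)
        path = tmp_path / "model.json"
        fit.model.save(path)
        loaded = cc.CrossCellModel.load(path)
        assert np.allclose(loaded.b_cross, fit.model.b_cross)
        x = src.features.loc[src.normal_mask(), fit.model.x_stats.columns]
        pd.testing.assert_frame_equal(loaded.predict(x), fit.model.predict(x))


class TestSensitivities:
    def test_power_law_exponents_recovered(self):
        """y = prod p_j^a_j over a 500-cell log-normal draw: recovered
        coefficients match the exponents to +/-0.02."""
        rng = np.random.default_rng(15)
        p = pd.DataFrame(np.exp(rng.normal(0, 0.2624, (500, 5))),
                         columns=list("ABCDE"))
        a_true = {"A": 0.5, "B": -1.2, "C": 0.0, "D": 2.0, "E": -0.3}
        y = pd.DataFrame({
            "out": np.prod([p[c] ** a for c, a in a_true.items()], axis=0)})
        coef = cc.compute_sensitivities(p, y)["out"]
        for c, a in a_true.items():
            assert coef[c] == pytest.approx(a, abs=0.02)

    def test_inert_parameter_coefficient_near_zero(self):
        rng = np.random.default_rng(16)
        p = pd.DataFrame(np.exp(rng.normal(0, 0.2624, (400, 3))),
                         columns=list("ABC"))
        y = pd.DataFrame({"out": p["A"] ** 1.5})
        coef = cc.compute_sensitivities(p, y)["out"]
        assert abs(coef["B"]) < 0.02
        assert abs(coef["C"]) < 0.02

    def test_gkr_coefficient_negative_for_adult_apd90(self, paired_600_runs):
        """Blocking the rapid delayed rectifier lengthens the adult AP, so
        the APD90-vs-GKr population sensitivity must be negative."""
        table, _, tgt = paired_600_runs
        ok = tgt.normal_mask(["pace1"])
        coef = cc.compute_sensitivities(
            table.data.loc[ok], tgt.all_features["pace1"].loc[ok][["APD90"]])
        assert coef.loc["GKr", "APD90"] < -0.1
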