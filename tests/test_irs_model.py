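"""Regression family: design construction, OLS recovery, splitting, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irsolv.irs_model import (
    MODEL_POWERS,
    FittedModel,
    IRSDataset,
    ModelSpec,
    decomposition_report,
    design_matrix,
    evaluate,
    fit,
    predict,
    signed_power,
    train_test_split,
)
from irsolv.synth_fixtures import SyntheticDatasetSpec, generate_regression_dataset


def make_dataset(n=50, seed=0, noise=0.0, coefficients=(0.45, 0.012),
                 model="IRS3_2", **kw):
    spec = SyntheticDatasetSpec(n_rows=n, noise_sigma=noise, seed=seed,
                                coefficients=coefficients, **kw)
    return generate_regression_dataset(spec, ModelSpec(name=model))


class TestSignedPower:
    @pytest.mark.parametrize(
        "x,p,expected",
        [(-4, 2, -16.0), (-4, 1.5, -8.0), (0, 3, 0.0), (2, 1, 2.0), (-2, 1, -2.0),
         (3, 2.5, 3 ** 2.5)],
    )
    def test_signed_convention(self, x, p, expected):
        assert signed_power(x, p) == pytest.approx(expected, rel=1e-14)

    def test_absolute_convention(self):
        assert signed_power(-4, 2, convention="absolute") == 16.0

    def test_vectorized(self):
        np.testing.assert_allclose(
            signed_power(np.array([-4.0, 4.0]), 1.5), [-8.0, 8.0]
        )

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            signed_power(2.0, 0.5)


class TestDesignMatrix:
    def test_irs1_single_row(self):
        ds = IRSDataset.from_arrays(["a"], [-10.0], [200.0], dG_exp=[-3.0])
        X, y, names = design_matrix(ds, ModelSpec(name="IRS1"))
        np.testing.assert_allclose(X, [[-10.0, 200.0, 1.0]])
        assert names == ["dG_int^1", "sasa", "intercept"]
        np.testing.assert_allclose(y, [-3.0 - (-10.0)])

    def test_irs32_power_columns(self):
        ds = IRSDataset.from_arrays(["a"], [-4.0], [100.0], dG_exp=[0.0])
        X, _, _ = design_matrix(ds, ModelSpec(name="IRS3_2"))
        np.testing.assert_allclose(X[0, :2], [-4.0, -8.0])

    def test_irs2_matches_hand_built_matrix(self):
        rng = np.random.default_rng(21)
        dg = rng.normal(-8, 6, 5)
        sasa = rng.uniform(100, 400, 5)
        exp = rng.normal(-5, 2, 5)
        ds = IRSDataset.from_arrays([str(i) for i in range(5)], dg, sasa, dG_exp=exp)
        X, y, _ = design_matrix(ds, ModelSpec(name="IRS2"))
        hand = np.column_stack(
            [dg, np.sign(dg) * dg ** 2, sasa, np.ones(5)]
        )
        np.testing.assert_allclose(X, hand, atol=1e-12)
        np.testing.assert_allclose(y, exp - dg, atol=1e-12)

    def test_missing_response_listed(self):
        df = pd.DataFrame(
            {"solute_id": ["a", "b"], "dG_int": [-5.0, -6.0],
             "sasa": [200.0, 250.0], "dG_exp": [1.0, np.nan]}
        )
        with pytest.raises(ValueError, match=r"\[1\]"):
            design_matrix(IRSDataset(df), ModelSpec(name="IRS1"))

    def test_invalid_powers_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(name="IRS1", powers=(2.0, 1.0))
        with pytest.raises(ValueError):
            ModelSpec(name="IRS1", powers=(0.5,))
        with pytest.raises(ValueError):
            ModelSpec(name="NOPE")


class TestFit:
    @pytest.mark.parametrize("model", sorted(MODEL_POWERS))
    def test_noiseless_recovery_exact(self, model):
        k = len(MODEL_POWERS[model])
        coeffs = tuple(0.4 / 10 ** i for i in range(k))
        ds, truth = make_dataset(n=60, seed=22, noise=0.0, coefficients=coeffs,
                                 model=model)
        fitted = fit(ds, ModelSpec(name=model))
        np.testing.assert_allclose(fitted.coefficients, truth["coefficients"],
                                   atol=1e-8)
        assert fitted.gamma == pytest.approx(truth["gamma"], abs=1e-8)
        assert fitted.b == pytest.approx(truth["b"], abs=1e-8)

    def test_underdetermined_rejected(self):
        ds, _ = make_dataset(n=60, seed=23)
        tiny = ds.subset(range(3))
        with pytest.raises(ValueError, match="underdetermined"):
            fit(tiny, ModelSpec(name="IRS3_2"))

    def test_collinear_design_names_columns(self):
        # constant sasa column duplicates the intercept
        ds = IRSDataset.from_arrays(
            ["a", "b", "c", "d", "e"],
            [-5.0, -6.0, -7.0, -8.0, -9.0],
            [200.0] * 5,
            dG_exp=[0.0, 1.0, 2.0, 3.0, 4.0],
        )
        with pytest.raises(ValueError, match="collinear.*(sasa|intercept)"):
            fit(ds, ModelSpec(name="IRS1"))

    def test_ill_conditioned_design_warns_not_errors(self):
        ds, _ = make_dataset(
            n=80, seed=24, noise=0.5,
            coefficients=(0.4, 0.04, 0.004, 0.0004), model="IRS4",
            dg_int_mean=-60.0, dg_int_sd=25.0,
        )
        with pytest.warns(UserWarning, match="condition"):
            fitted = fit(ds, ModelSpec(name="IRS4"))
        assert np.isfinite(fitted.coefficients).all()

    def test_noisy_recovery_within_99_ci(self):
        ds, truth = make_dataset(n=280, seed=25, noise=1.0,
                                 coefficients=(0.45, 0.012), model="IRS2")
        fitted = fit(ds, ModelSpec(name="IRS2"))
        true_params = np.array(truth["coefficients"] + [truth["gamma"], truth["b"]])
        est = np.concatenate([fitted.coefficients, [fitted.gamma, fitted.b]])
        # 99% half-width ~ 2.576 sigma at n=280
        assert (np.abs(est - true_params) <= 2.576 * fitted.stderr).all()

    def test_model_json_round_trip(self):
        ds, _ = make_dataset(n=40, seed=26)
        fitted = fit(ds)
        back = FittedModel.from_dict(fitted.to_dict())
        np.testing.assert_allclose(back.coefficients, fitted.coefficients)
        assert back.gamma == fitted.gamma
        assert back.b == fitted.b
        assert back.spec == fitted.spec


class TestPredict:
    def test_zero_coefficients_give_identity(self):
        ds, _ = make_dataset(n=10, seed=27)
        model = FittedModel(spec=ModelSpec(name="IRS1"), coefficients=[0.0],
                            gamma=0.0, b=0.0, n_train=10)
        pred = predict(model, ds)
        np.testing.assert_allclose(pred["dG_sol"], ds.column("dG_int"), atol=1e-12)
        np.testing.assert_allclose(pred["dG_reo"], 0.0, atol=1e-12)

    def test_minus_one_alpha_cancels(self):
        ds, _ = make_dataset(n=10, seed=28)
        model = FittedModel(spec=ModelSpec(name="IRS1", include_sasa=False,
                                           include_intercept=False),
                            coefficients=[-1.0], gamma=0.0, b=0.0, n_train=10)
        pred = predict(model, ds)
        np.testing.assert_allclose(pred["dG_sol"], 0.0, atol=1e-12)

    def test_training_residuals_reproduced(self):
        ds, _ = make_dataset(n=60, seed=29, noise=1.0)
        fitted = fit(ds)
        pred = predict(fitted, ds)
        resid = ds.column("dG_exp") - pred["dG_sol"].to_numpy()
        assert fitted.training_metrics.rmse == pytest.approx(
            np.sqrt((resid ** 2).mean()), rel=1e-10
        )
        assert fitted.training_metrics.mae == pytest.approx(
            np.abs(resid).mean(), rel=1e-10
        )


class TestSplit:
    def test_canonical_280_73_protocol(self):
        ds, _ = make_dataset(n=353, seed=30, noise=1.0)
        train, test = train_test_split(ds, test_fraction=73 / 353, seed=1)
        assert (len(train), len(test)) == (280, 73)

    def test_same_seed_reproduces_split(self):
        ds, _ = make_dataset(n=100, seed=31, noise=1.0)
        a = train_test_split(ds, 0.2, seed=5)
        b = train_test_split(ds, 0.2, seed=5)
        assert list(a[0].df["solute_id"]) == list(b[0].df["solute_id"])
        assert list(a[1].df["solute_id"]) == list(b[1].df["solute_id"])

    def test_union_is_everything_and_disjoint(self):
        ds, _ = make_dataset(n=100, seed=32, noise=1.0)
        train, test = train_test_split(ds, 0.2, seed=6)
        ids = set(train.df["solute_id"]) | set(test.df["solute_id"])
        assert len(ids) == 100
        assert not set(train.df["solute_id"]) & set(test.df["solute_id"])

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, fraction):
        ds, _ = make_dataset(n=20, seed=33)
        with pytest.raises(ValueError):
            train_test_split(ds, fraction, seed=0)


class TestEvaluate:
    def test_perfect_prediction(self):
        obs = np.array([1.0, -2.0, 3.0])
        m = evaluate(obs, obs)
        assert (m.pearson_r, m.mae, m.rmse) == (pytest.approx(1.0), 0.0, 0.0)

    def test_constant_offset(self):
        obs = np.array([1.0, -2.0, 3.0])
        m = evaluate(obs + 1.0, obs)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(1.0)

    def test_hand_computed_three_points(self):
        m = evaluate([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert m.pearson_r == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(5 / 3))

    def test_zero_variance_warns_and_returns_nan_r(self):
        with pytest.warns(UserWarning, match="variance"):
            m = evaluate([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert np.isnan(m.pearson_r)
        assert m.mae == pytest.approx(2 / 3)  # residuals {-1, 0, 1}

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2, max_size=50,
        )
    )
    def test_rmse_dominates_mae(self, pairs):
        pred, obs = (np.array(v) for v in zip(*pairs))
        if np.std(pred) == 0 or np.std(obs) == 0:
            return
        m = evaluate(pred, obs)
        assert m.rmse >= m.mae >= 0.0
        assert -1.0 - 1e-12 <= m.pearson_r <= 1.0 + 1e-12


class TestModelOrderBehaviour:
    def test_training_rmse_non_increasing_with_order(self):
        ds, _ = make_dataset(n=120, seed=34, noise=2.0,
                             coefficients=(0.4, 0.02, 0.002), model="IRS3")
        rmses = [fit(ds, ModelSpec(name=m)).training_metrics.rmse
                 for m in ("IRS1", "IRS2", "IRS3", "IRS4")]
        assert all(a >= b - 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_quartic_overfits_beyond_second_order(self):
        wins = 0
        n_rep = 30
        for rep in range(n_rep):
            ds, _ = make_dataset(n=60, seed=1000 + rep, noise=1.5,
                                 coefficients=(0.45, 0.012), model="IRS2")
            train, test = train_test_split(ds, 0.25, seed=rep)
            obs = test.column("dG_exp")
            rmse = {}
            for m in ("IRS2", "IRS4"):
                fitted = fit(train, ModelSpec(name=m))
                pred = predict(fitted, test)
                rmse[m] = evaluate(pred["dG_sol"].to_numpy(), obs).rmse
            if rmse["IRS4"] >= rmse["IRS2"]:
                wins += 1
        assert wins > n_rep / 2


class TestDecompositionReport:
    def _dataset_with_decomposition(self, n=20, seed=35):
        ds, _ = make_dataset(n=n, seed=seed, noise=1.0)
        rng = np.random.default_rng(seed)
        ts = np.abs(rng.normal(1.0, 0.5, n))
        df = ds.df.copy()
        df["minus_TdS_int"] = ts
        df["dH_int"] = df["dG_int"] - ts
        return IRSDataset(df)

    def test_components_sum_to_dg_sol(self):
        ds = self._dataset_with_decomposition()
        model = fit(ds)
        rep = decomposition_report(ds, model)
        total = (rep["dH_int"] + rep["minus_TdS_int"] + rep["f_poly"]
                 + rep["gamma_sasa"] + rep["b"])
        np.testing.assert_allclose(total, rep["dG_sol"], atol=1e-9)
        np.testing.assert_allclose(rep["error"], rep["dG_exp"] - rep["dG_sol"],
                                   atol=1e-12)

    def test_sorted_by_experimental_energy(self):
        rep = decomposition_report(self._dataset_with_decomposition(),
                                   fit(self._dataset_with_decomposition()))
        assert (np.diff(rep["dG_exp"]) >= 0).all()

    def test_entropy_terms_stay_non_negative(self):
        rep = decomposition_report(self._dataset_with_decomposition(),
                                   fit(self._dataset_with_decomposition()))
        assert (rep["minus_TdS_int"] >= 0).all()

    def test_missing_fields_named(self):
        ds, _ = make_dataset(n=20, seed=36, noise=1.0)
        model = fit(ds)
        with pytest.raises(ValueError, match="dH_int"):
            decomposition_report(ds, model)
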