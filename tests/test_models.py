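"""The three LUR families: exact recoveries, diagnostics, selection rules,
and the shared column-alignment contract."""

import numpy as np
import pandas as pd
import pytest

from lurok.models import (
    PLSSpec,
    RFSpec,
    SLRSpec,
    compute_vif,
    fit_lur,
    fit_pls,
    fit_rf,
    fit_slr,
    pls_score_correlations,
    rf_importance,
)
from lurok.validation import r2_mse, rmse


def linear_dataset(seed=0, n=40, p=6, noise=0.0, betas=(5.0, -3.0)):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"v{j}" for j in range(p)]
    )
    y = 20.0 + sum(b * X[f"v{j}"] for j, b in enumerate(betas))
    y = y + rng.standard_normal(n) * noise
    return X, y.to_numpy()


class TestPLS:
    def test_exact_linear_recovery_two_scores(self):
        X, y = linear_dataset(noise=0.0, p=2)
        model = fit_pls(X, y, PLSSpec(n_scores=2))
        assert r2_mse(y, model.predict(X)) == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_pls_equals_ols(self):
        X, y = linear_dataset(seed=1, noise=2.0)
        model = fit_pls(X, y, PLSSpec(n_scores=X.shape[1]))
        A = np.column_stack([np.ones(len(y)), X.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(model.predict(X), A @ coef, atol=1e-6)

    def test_deterministic_predictions(self):
        X, y = linear_dataset(seed=2, noise=3.0)
        p1 = fit_pls(X, y).predict(X)
        p2 = fit_pls(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_response_rejected(self):
        X, _ = linear_dataset()
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.full(len(X), 7.0))

    def test_zero_variance_column_dropped_with_warning(self):
        X, y = linear_dataset(noise=1.0)
        X = X.assign(dead=1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_pls(X, y)
        assert "dead" not in model.columns

    def test_more_scores_never_fit_worse_in_sample(self):
        X, y = linear_dataset(seed=3, noise=4.0)
        rmses = [
            rmse(y, fit_pls(X, y, PLSSpec(k)).predict(X)) for k in range(1, 6)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_first_score_correlates_nonnegatively_with_response(self):
        X, y = linear_dataset(seed=4, noise=2.0)
        model = fit_pls(X, y)
        t1 = model.scores(X)[:, 0]
        assert np.corrcoef(t1, y)[0, 1] >= 0


class TestPLSScoreCorrelations:
    def test_orthogonal_covariate_has_zero_correlation(self):
        rng = np.random.default_rng(5)
        n = 50
        x1 = rng.standard_normal(n)
        x1 -= x1.mean()
        ortho = rng.standard_normal(n)
        ortho -= ortho.mean()
        ortho -= ortho @ x1 / (x1 @ x1) * x1  # exactly uncorrelated with x1
        y = 3 * x1
        # with a single informative covariate the first score is x1 itself
        X = pd.DataFrame({"v0": x1, "v1": ortho})
        model = fit_pls(X, y, PLSSpec(1))
        corr = pls_score_correlations(model, X)
        assert abs(corr["v0"]) == pytest.approx(1.0, abs=1e-8)
        assert abs(corr["v1"]) < 1e-8

    def test_values_in_unit_interval_and_dominant_variable_wins(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.standard_normal((40, 6)), columns=[f"v{j}" for j in range(6)]
            )
            y = 6 * X["v0"].to_numpy() + rng.standard_normal(40) * 0.5
            model = fit_pls(X, y)
            corr = pls_score_correlations(model, X)
            assert (corr.abs() <= 1 + 1e-12).all()
            wins += corr.abs().idxmax() == "v0"
        assert wins >= 18


class TestRF:
    def test_constant_response_predicts_constant(self):
        X, _ = linear_dataset(seed=6)
        model = fit_rf(X, np.full(len(X), 12.0), RFSpec(ntree=50))
        np.testing.assert_allclose(model.predict(X), 12.0)

    def test_same_seed_identical_predictions(self):
        X, y = linear_dataset(seed=7, noise=2.0)
        p1 = fit_rf(X, y, RFSpec(seed=3)).predict(X)
        p2 = fit_rf(X, y, RFSpec(seed=3)).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_oob_r2_on_strong_linear_signal(self):
        # R²_true = 0.9: var(signal)=9, noise variance 1
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=[f"v{j}" for j in range(5)])
        y = 3.0 * X["v0"].to_numpy() + rng.standard_normal(200)
        model = fit_rf(X, y)
        assert model.forest.oob_score_ > 0.5

    def test_predictions_bounded_by_training_range(self):
        X, y = linear_dataset(seed=9, noise=5.0)
        model = fit_rf(X, y, RFSpec(ntree=100))
        Xnew = X * 10  # far outside the training hull
        pred = model.predict(Xnew)
        assert pred.min() >= y.min() - 1e-9 and pred.max() <= y.max() + 1e-9

    def test_oob_index_reconstruction_matches_sklearn(self):
        from lurok.models import _oob_indices_per_tree

        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((60, 4)),
                         columns=list("abcd"))
        y = X["a"].to_numpy() + rng.standard_normal(60) * 0.1
        model = fit_rf(X, y, RFSpec(ntree=80, seed=5))
        oob = _oob_indices_per_tree(model.forest, 60)
        # rebuild the OOB prediction from our index reconstruction
        Xa = X.to_numpy()
        sums = np.zeros(60)
        counts = np.zeros(60)
        for tree, idx in zip(model.forest.estimators_, oob):
            sums[idx] += tree.predict(Xa[idx])
            counts[idx] += 1
        mask = counts > 0
        np.testing.assert_allclose(
            sums[mask] / counts[mask], model.forest.oob_prediction_[mask],
            rtol=1e-10,
        )


class TestRFImportance:
    def test_signal_variable_ranks_first_and_null_is_noise(self):
        first = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.standard_normal((60, 5)),
                             columns=[f"v{j}" for j in range(5)])
            y = 4.0 * X["v0"].to_numpy() + rng.standard_normal(60) * 0.3
            model = fit_rf(X, y, RFSpec(ntree=150, seed=seed))
            imp = rf_importance(model, X)
            first += imp.loc[0, "variable"] == "v0"
            # pure-noise variables: importance within a few SE of zero
            null = imp[imp["variable"] != "v0"]
            assert (null["inc_mse"] < 4 * null["se"] + 1e-9).all()
        assert first >= 18

    def test_top_k_view(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((50, 12)),
                         columns=[f"v{j}" for j in range(12)])
        y = X["v0"].to_numpy() + rng.standard_normal(50) * 0.1
        model = fit_rf(X, y, RFSpec(ntree=60))
        assert len(rf_importance(model, X, top_k=10)) == 10


class TestVIF:
    def test_orthogonal_standardized_variables(self):
        n = 40
        x1 = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        x2 = np.tile([1.0, -1.0], n // 2)
        vif = compute_vif(pd.DataFrame({"a": x1, "b": x2}))
        np.testing.assert_allclose(vif, 1.0, atol=1e-10)

    def test_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(30)
        vif = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vif).all()

    def test_closed_form_at_correlation_0p8(self):
        rng = np.random.default_rng(14)
        u = rng.standard_normal(100)
        v = rng.standard_normal(100)
        # orthonormalize, then mix to an exact sample correlation of 0.8
        u = (u - u.mean()) / u.std()
        v = v - v.mean()
        v -= (v @ u) / (u @ u) * u
        v /= v.std()
        x2 = 0.8 * u + np.sqrt(1 - 0.64) * v
        vif = compute_vif(pd.DataFrame({"a": u, "b": x2}))
        np.testing.assert_allclose(vif, 1.0 / (1.0 - 0.64), rtol=1e-10)

    def test_single_variable_is_one(self):
        vif = compute_vif(pd.DataFrame({"a": np.arange(10.0)}), ["a"])
        assert vif["a"] == 1.0


class TestSLR:
    def test_dominant_predictor_selected_alone(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.standard_normal((40, 6)),
                         columns=[f"v{j}" for j in range(6)])
        y = 30.0 + 5.0 * X["v0"].to_numpy()
        model = fit_slr(X, y, expected_sign={"v0": "+"})
        assert model.selected_variables == ["v0"]
        assert model.coef[0] == pytest.approx(5.0, abs=1e-8)

    def test_duplicated_signal_columns_pruned_by_vif(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(40)
        X = pd.DataFrame({
            "a": x,
            "b": x + rng.standard_normal(40) * 1e-4,
            "c": rng.standard_normal(40),
        })
        y = 4 * x + X["c"].to_numpy() * 3.5 + rng.standard_normal(40) * 0.1
        model = fit_slr(X, y, SLRSpec(r2_gain_threshold=1e-6))
        assert sum(v in ("a", "b") for v in model.selected_variables) <= 1
        assert (model.vifs <= 3.0 + 1e-9).all()

    def test_no_sign_plausible_start_raises_with_diagnostic(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame({"v0": rng.standard_normal(30)})
        y = 5.0 * X["v0"].to_numpy()
        with pytest.raises(ValueError, match="sign-plausible"):
            fit_slr(X, y, expected_sign={"v0": "-"})

    def test_forward_r2_nondecreasing_along_trace(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame(rng.standard_normal((50, 6)),
                         columns=[f"v{j}" for j in range(6)])
        y = (2 * X["v0"] + 1.5 * X["v1"] - X["v2"]).to_numpy() + rng.standard_normal(50)
        model = fit_slr(X, y, SLRSpec(r2_gain_threshold=0.01))
        r2s = [t["r2"] for t in model.trace if t["decision"] == "selected"]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_sign_disabled_allows_any_direction(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame({"v0": rng.standard_normal(30),
                          "v1": rng.standard_normal(30)})
        y = -3.0 * X["v0"].to_numpy()
        model = fit_slr(X, y, SLRSpec(enforce_sign=False),
                        expected_sign={"v0": "+", "v1": "+"})
        assert model.selected_variables == ["v0"]


class TestDispatchContract:
    @pytest.mark.parametrize("family", ["PLS", "RF", "SLR"])
    def test_column_order_invariance(self, family):
        X, y = linear_dataset(seed=20, noise=1.0)
        spec = {"PLS": PLSSpec(3), "RF": RFSpec(ntree=50, seed=1), "SLR": None}[family]
        model = fit_lur(family, X, y, spec)
        shuffled = X[list(X.columns[::-1])]
        np.testing.assert_allclose(model.predict(X), model.predict(shuffled))

    def test_dispatch_matches_direct_fit(self):
        X, y = linear_dataset(seed=21, noise=1.0)
        np.testing.assert_allclose(
            fit_lur("PLS", X, y, PLSSpec(2)).predict(X),
            fit_pls(X, y, PLSSpec(2)).predict(X),
        )

    def test_unknown_family_rejected(self):
        X, y = linear_dataset()
        with pytest.raises(ValueError, match="unknown model family"):
            fit_lur("GBM", X, y)

    def test_missing_column_named_in_error(self):
        X, y = linear_dataset(seed=22)
        model = fit_lur("PLS", X, y, PLSSpec(2))
        with pytest.raises(ValueError, match="v0"):
            model.predict(X.drop(columns=["v0"]))
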