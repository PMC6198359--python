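import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import spermclock as sc
from spermclock import InputError, ValidationError
from spermclock.model import elastic_net_objective


def frame_of(X):
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


def lbfgs_enet_oracle(X, y, alpha, lam):
    """Independent convex solve: split b = u - v, u,v >= 0, smooth L-BFGS-B."""
    n, p = X.shape

    def objective(z):
        u, v, b0 = z[:p], z[p:2 * p], z[2 * p]
        b = u - v
        r = y - b0 - X @ b
        return 0.5 * r @ r / n + lam * (alpha * (u + v).sum()
                                        + 0.5 * (1 - alpha) * (b ** 2).sum())

    z0 = np.zeros(2 * p + 1)
    z0[-1] = y.mean()
    res = minimize(objective, z0, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p) + [(None, None)],
                   options=dict(maxiter=50000, ftol=1e-15, gtol=1e-12))
    return res.fun


class TestFit:
    def test_noiseless_ols_limit(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        ages = 20.0 + 10.0 * x
        model = sc.fit_elastic_net(frame_of(x[:, None]), ages, alpha=0.5, lam=0.0)
        assert model.intercept == pytest.approx(20.0, abs=1e-8)
        assert model.coefficients[0] == pytest.approx(10.0, abs=1e-8)

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 5))
        ages = rng.uniform(20, 45, 40)
        model = sc.fit_elastic_net(frame_of(X), ages, alpha=0.5, lam=1e6)
        assert (model.coefficients == 0.0).all()
        assert model.intercept == pytest.approx(ages.mean())

    def test_matches_convex_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n, p = 30, 10
            X = rng.normal(size=(n, p))
            Xs = (X - X.mean(0)) / X.std(0)
            y = Xs @ rng.normal(size=p) + rng.normal(size=n) + 30
            alpha, lam = 0.5, 0.1
            model = sc.fit_elastic_net(frame_of(Xs), y, alpha=alpha, lam=lam)
            ours = elastic_net_objective(Xs, y, model.coefficients,
                                         model.intercept, alpha, lam)
            oracle = lbfgs_enet_oracle(Xs, y, alpha, lam)
            assert ours - oracle <= 1e-6

    def test_lambda_zero_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=50)
        model = sc.fit_elastic_net(frame_of(X), y, alpha=0.5, lam=0.0)
        Xd = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(model.intercept, beta[0], rtol=1e-6)
        assert np.allclose(model.coefficients, beta[1:], rtol=1e-6)

    def test_objective_nondecreasing_in_lambda(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=40)
        objs = []
        for lam in [0.0, 0.01, 0.1, 0.5, 2.0]:
            m = sc.fit_elastic_net(frame_of(X), y, alpha=0.5, lam=lam)
            Xs = (X - X.mean(0)) / X.std(0)
            coef_std = m.coefficients * X.std(0)
            objs.append(elastic_net_objective(Xs, y, coef_std,
                                              m.intercept + coef_std @ (X.mean(0) / X.std(0)),
                                              0.5, lam))
        assert all(b >= a - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_deterministic_refit(self, small_features, small_cohort):
        a = sc.fit_elastic_net(small_features.values, small_cohort.truth.ages, lam=0.05)
        b = sc.fit_elastic_net(small_features.values, small_cohort.truth.ages, lam=0.05)
        assert (a.coefficients == b.coefficients).all()
        assert a.intercept == b.intercept

    def test_input_errors(self):
        with pytest.raises(InputError):
            sc.fit_elastic_net(frame_of(np.ones((1, 2))), [30.0])
        with pytest.raises(ValidationError):
            sc.fit_elastic_net(frame_of(np.array([[np.nan], [1.0]])), [30.0, 40.0])

    def test_sign_recovery_at_low_noise(self):
        """Signal slopes keep their sign in the fitted clock across seeds."""
        hits = total = 0
        for seed in range(10):
            config = sc.SimulationConfig(
                n_samples=80, n_signal_regions=12, n_hyper=3,
                n_background_probes=0, probe_noise_sd=0.01, bio_age_sd=0.3,
                seed=100 + seed)
            cohort = sc.simulate_cohort(config)
            feats = sc.build_features(cohort.betas, cohort.manifest, cohort.regions)
            lam, _ = sc.select_lambda_cv(feats.values, cohort.truth.ages, k=5,
                                         seed=seed)
            model = sc.fit_elastic_net(feats.values, cohort.truth.ages, lam=lam)
            truth = cohort.truth.region_truth.set_index("name")["slope"]
            for region, coef in zip(model.region_names, model.coefficients):
                if coef != 0.0:
                    total += 1
                    hits += int(np.sign(coef) == np.sign(truth[region]))
        assert total > 0
        assert hits / total >= 0.95


class TestLambdaSelection:
    def test_noiseless_grid_picks_zero(self):
        rng = np.random.default_rng(5)
        x = rng.random(30)
        ages = 20 + 10 * x
        lam, _ = sc.select_lambda_cv(frame_of(x[:, None]), ages,
                                     lambda_grid=[0.0], k=5, seed=0)
        assert lam == 0.0

    def test_duplicate_grid_idempotent(self, small_features, small_cohort):
        ages = small_cohort.truth.ages
        grid = [0.01, 0.1, 1.0]
        lam_a, _ = sc.select_lambda_cv(small_features.values, ages,
                                       lambda_grid=grid, k=5, seed=2)
        lam_b, _ = sc.select_lambda_cv(small_features.values, ages,
                                       lambda_grid=grid + grid, k=5, seed=2)
        assert lam_a == lam_b

    def test_matches_manual_cv_loop(self, small_features, small_cohort):
        """Selected lambda equals the argmin of a hand-rolled CV over the same folds."""
        from spermclock._folds import kfold_indices

        ages = small_cohort.truth.ages
        X = small_features.values
        grid = [0.003, 0.03, 0.3, 3.0]
        seed, k = 7, 5
        lam, curve = sc.select_lambda_cv(X, ages, lambda_grid=grid, k=k, seed=seed)

        folds = kfold_indices(len(ages), k, np.random.default_rng(seed))
        mse = {}
        for g in grid:
            errs = np.empty(len(ages))
            for test_idx in folds:
                train_mask = np.ones(len(ages), dtype=bool)
                train_mask[test_idx] = False
                m = sc.fit_elastic_net(X.iloc[train_mask], ages.iloc[train_mask],
                                       alpha=0.5, lam=g)
                pred = sc.predict_age(m, X.iloc[test_idx])
                errs[test_idx] = (pred.to_numpy() - ages.iloc[test_idx].to_numpy()) ** 2
            mse[g] = errs.mean()
        assert lam == min(mse, key=mse.get)

    def test_k_larger_than_n_rejected(self, small_features, small_cohort):
        with pytest.raises(InputError):
            sc.select_lambda_cv(small_features.values.iloc[:5],
                                small_cohort.truth.ages.iloc[:5], k=10, seed=0)


class TestPredict:
    def test_all_zero_features_give_intercept(self):
        model = sc.ClockModel(["a", "b"], np.array([2.0, -1.0]), 33.0, 0.5, 0.1,
                              np.array([0.0, 0.0]))
        feats = pd.DataFrame(np.zeros((4, 2)), columns=["a", "b"])
        assert (sc.predict_age(model, feats) == 33.0).all()

    def test_column_permutation_invariance(self, small_features, small_cohort):
        model = sc.fit_elastic_net(small_features.values, small_cohort.truth.ages,
                                   lam=0.05)
        base = sc.predict_age(model, small_features.values)
        shuffled = small_features.values[list(reversed(small_features.region_names))]
        assert (sc.predict_age(model, shuffled).to_numpy() == base.to_numpy()).all()

    def test_matches_manual_dot_product(self, small_features, small_cohort):
        model = sc.fit_elastic_net(small_features.values, small_cohort.truth.ages,
                                   lam=0.05)
        pred = sc.predict_age(model, small_features.values)
        X = small_features.values[model.region_names].to_numpy()
        manual = np.array([model.intercept + float(row @ model.coefficients)
                           for row in X])
        assert np.allclose(pred.to_numpy(), manual, atol=1e-12)

    def test_missing_columns_imputed_with_training_means(self, small_features,
                                                         small_cohort):
        model = sc.fit_elastic_net(small_features.values, small_cohort.truth.ages,
                                   lam=0.05)
        partial = small_features.values.drop(columns=small_features.region_names[:3])
        pred = sc.predict_age(model, partial)
        filled = small_features.values.copy()
        for j, name in enumerate(model.region_names[:3]):
            filled[name] = model.feature_means[j]
        expected = sc.predict_age(model, filled)
        assert np.allclose(pred.to_numpy(), expected.to_numpy())

    def test_zero_overlap_rejected(self):
        model = sc.ClockModel(["a"], np.array([1.0]), 0.0, 0.5, 0.1, np.array([0.5]))
        with pytest.raises(InputError):
            sc.predict_age(model, pd.DataFrame({"z": [0.1]}))
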