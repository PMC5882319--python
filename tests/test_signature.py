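"""Unit tests for the model-selection engine."""

import numpy as np
import pytest
from scipy import optimize, stats

from gepsig.signature import (
    GAConfig,
    SignatureModel,
    SVRParams,
    candidate_score,
    classify,
    cross_validate,
    fit_svr,
    ga_select,
    inverse_transform_scores,
    partition_cutoff,
    score_samples,
    standardize_response,
)

from conftest import make_matrix


class TestStandardizeResponse:
    def test_unit_mean_square_identity(self):
        y, scale = standardize_response(np.array([1.0, 1.0, 1.0, 1.0]))
        assert np.allclose(y, 1.0)
        assert scale == pytest.approx(1.0)

    def test_hand_computed(self):
        y, scale = standardize_response(np.array([3.0, 4.0]))
        assert np.allclose(y, [0.84853, 1.13137], atol=1e-5)

    def test_norm_property_random(self, rng):
        for _ in range(50):
            d = rng.normal(size=rng.integers(2, 40))
            y, scale = standardize_response(d)
            assert np.linalg.norm(y) ** 2 / y.size == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(d * scale, y)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            standardize_response(np.zeros(4))


class TestFitSVR:
    def test_constant_response_predicted_within_epsilon(self, rng):
        m = make_matrix(rng.normal(size=(4, 10)))
        reg = fit_svr(m, m.probe_ids, np.full(10, 2.5))
        assert np.allclose(reg.predict(m), 2.5, atol=0.1 + 1e-9)

    def test_matches_brute_force_dual_qp(self, rng):
        # 3-sample, 1-feature toy problem against an independently solved
        # epsilon-SVR dual (SLSQP on the Wolfe dual)
        m = make_matrix(np.array([[-1.0, 0.0, 1.0]]))
        y = np.array([-0.8, 0.3, 0.9])
        params = SVRParams(C=1.0, epsilon=0.1, gamma=0.5)
        reg = fit_svr(m, ["p0"], y, params)

        x = ((np.array([-1.0, 0.0, 1.0]) - reg.feature_mean) / reg.feature_sd).ravel()
        K = np.exp(-0.5 * (x[:, None] - x[None, :]) ** 2)

        def neg_dual(a):
            return 0.5 * a @ K @ a - a @ y + 0.1 * np.abs(a).sum()

        res = optimize.minimize(
            neg_dual,
            np.zeros(3),
            constraints=[{"type": "eq", "fun": lambda a: a.sum()}],
            bounds=[(-1.0, 1.0)] * 3,
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        a = res.x
        # intercept from a strictly interior support vector
        interior = np.nonzero((np.abs(a) > 1e-6) & (np.abs(a) < 1.0 - 1e-6))[0]
        i = interior[0]
        b = y[i] - (K @ a)[i] - 0.1 * np.sign(a[i])
        oracle_pred = K @ a + b
        assert np.allclose(reg.predict(m), oracle_pred, atol=1e-3)

    def test_training_fit_improves_with_regularization(self, rng):
        m = make_matrix(rng.normal(size=(3, 25)))
        y = m.values.to_numpy().sum(axis=0) + 0.3 * rng.normal(size=25)
        errs = []
        for C in (0.01, 0.1, 1.0, 10.0, 100.0):
            reg = fit_svr(m, m.probe_ids, y, SVRParams(C=C, epsilon=0.01, gamma=0.1))
            errs.append(np.sqrt(np.mean((reg.predict(m) - y) ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_empty_subset_and_bad_params_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            fit_svr(random_matrix, [], np.zeros(12))
        with pytest.raises(ValueError):
            fit_svr(random_matrix, random_matrix.probe_ids,
                    np.zeros(12), SVRParams(C=-1))


class TestScores:
    def test_midpoint_and_range_and_order(self, rng):
        m = make_matrix(rng.normal(size=(5, 40)))
        y = rng.normal(size=40)
        reg = fit_svr(m, m.probe_ids, y)
        pred = reg.predict(m)
        s = score_samples(reg, m, float(pred.mean()), float(pred.std()))
        assert np.all((s > 0) & (s < 1))
        assert stats.spearmanr(s, pred).statistic == pytest.approx(1.0)
        # a sample whose prediction equals the training mean scores 0.5
        z = (pred - pred.mean()) / pred.std()
        closest = np.argmin(np.abs(z))
        assert abs(s[closest] - 0.5) <= abs(z[closest])

    def test_missing_probe_listed(self, rng):
        m = make_matrix(rng.normal(size=(3, 10)))
        reg = fit_svr(m, m.probe_ids, np.arange(10.0))
        other = make_matrix(rng.normal(size=(2, 4)), probe_ids=["p0", "p1"])
        with pytest.raises(KeyError, match="p2"):
            reg.predict(other)


class TestInverseTransform:
    def test_monotone_and_symmetric(self, rng):
        x = rng.normal(size=31)
        t = inverse_transform_scores(x)
        assert stats.spearmanr(x, t).statistic == pytest.approx(1.0)
        # antisymmetric Blom quantiles: sorted values mirror about 0.5
        ts = np.sort(t)
        assert np.allclose(ts + ts[::-1], 1.0, atol=1e-12)

    def test_ties_share_value(self):
        t = inverse_transform_scores(np.array([1.0, 2.0, 2.0, 3.0]))
        assert t[1] == t[2]

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            inverse_transform_scores(np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            inverse_transform_scores(np.array([1.0]))


class TestPartitionCutoff:
    def test_hand_computed_split(self):
        c = partition_cutoff(
            np.array([0.1, 0.2, 0.8, 0.9]), np.array([-1.0, -1.0, 2.0, 2.0])
        )
        assert c == pytest.approx(0.5)

    def test_two_samples_midpoint(self):
        assert partition_cutoff(np.array([0.2, 0.6]), np.array([0.0, 1.0])) == pytest.approx(0.4)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            s = np.round(rng.uniform(size=n), 2)
            d = rng.normal(size=n)
            if np.unique(s).size < 2 or np.unique(d).size < 2:
                continue
            # oracle: evaluate every adjacent-midpoint split directly
            cands = np.unique(s)
            best, best_red = None, -np.inf
            total = ((d - d.mean()) ** 2).sum()
            for a, b in zip(cands[:-1], cands[1:]):
                c = (a + b) / 2
                l, r = d[s <= c], d[s > c]
                red = total - ((l - l.mean()) ** 2).sum() - ((r - r.mean()) ** 2).sum()
                if red > best_red + 1e-12:
                    best, best_red = c, red
            assert partition_cutoff(s, d) == pytest.approx(best)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partition_cutoff(np.array([0.1, 0.9]), np.array([1.0, 1.0]))

    def test_min_leaf_constrains_split(self):
        s = np.linspace(0, 1, 10)
        d = np.array([0.0] * 9 + [5.0])
        unconstrained = partition_cutoff(s, d)
        assert unconstrained > 0.9  # isolates the single extreme value
        constrained = partition_cutoff(s, d, min_leaf=3)
        assert constrained <= s[-3]


class TestCrossValidate:
    def test_learnable_problem_low_rmse(self, rng):
        n = 60
        x = rng.normal(size=(2, n))
        y = 0.5 * x[0] - 0.5 * x[1]
        m = make_matrix(x)
        rep = cross_validate(m, m.probe_ids, y, folds=20, holdout=0.10, seed=1,
                             params=SVRParams(C=10.0, epsilon=0.01, gamma=0.05))
        assert rep.mean_rmse < 0.05

    def test_pure_noise_rmse_near_one(self, rng):
        n = 100
        m = make_matrix(rng.normal(size=(5, n)))
        y = rng.standard_normal(n)
        rep = cross_validate(m, m.probe_ids, y, folds=30, holdout=0.10, seed=2)
        assert 0.8 <= rep.mean_rmse <= 1.2

    def test_report_shape(self, rng):
        m = make_matrix(rng.normal(size=(3, 30)))
        rep = cross_validate(m, m.probe_ids, rng.normal(size=30), folds=50, seed=3)
        assert len(rep.rmse) == 50
        assert rep.mean_rmse == pytest.approx(np.mean(rep.rmse), abs=1e-12)

    def test_bad_holdout_rejected(self, rng):
        m = make_matrix(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError):
            cross_validate(m, m.probe_ids, np.zeros(5), holdout=0.01, seed=0)


class TestGASelect:
    def _toy(self, rng, n=40, pool=6):
        x = rng.normal(size=(pool, n))
        y = 1.2 * x[0] + (0.8 * x[1] if pool > 1 else 0.0) + 0.2 * rng.normal(size=n)
        t = np.exp(-y) * rng.exponential(1.0, n) + 0.01
        e = np.ones(n, dtype=int)
        return make_matrix(x), y, t, e

    def test_single_probe_pool(self, rng):
        m, y, t, e = self._toy(rng, pool=1)
        sel, score = ga_select(
            m, y, t, e, GAConfig(population=4, generations=2,
                                 subset_min=1, subset_max=1, seed=0)
        )
        assert sel == ["p0"]

    def test_pool_smaller_than_min_rejected(self, rng):
        m, y, t, e = self._toy(rng, pool=3)
        with pytest.raises(ValueError):
            ga_select(m, y, t, e, GAConfig(subset_min=10, subset_max=12, seed=0))

    def test_elitism_returns_at_least_initial_best(self, rng):
        m, y, t, e = self._toy(rng)
        cfg = GAConfig(population=10, generations=5, subset_min=1, subset_max=2, seed=3)
        _, score = ga_select(m, y, t, e, cfg)
        # fitness of the returned model must beat every random individual
        init_rng = np.random.default_rng(99)
        for _ in range(10):
            size = int(init_rng.integers(1, 3))
            subset = [f"p{i}" for i in init_rng.choice(6, size, replace=False)]
            other = candidate_score(m, subset, y, t, e, seed=cfg.seed)
            assert not other.better_than(score)

    def test_reproducible_from_seed(self, rng):
        m, y, t, e = self._toy(rng)
        cfg = GAConfig(population=12, generations=6, subset_min=1, subset_max=2, seed=7)
        sel1, sc1 = ga_select(m, y, t, e, cfg)
        sel2, sc2 = ga_select(m, y, t, e, cfg)
        assert sel1 == sel2
        assert sc1 == sc2


class TestClassifyModel:
    def _model(self, rng, cutoff=0.5):
        m = make_matrix(rng.normal(size=(4, 30)))
        y = rng.normal(size=30)
        reg = fit_svr(m, m.probe_ids, y)
        pred = reg.predict(m)
        raw = 1 / (1 + np.exp(-(pred - pred.mean()) / pred.std()))
        transformed = inverse_transform_scores(raw)
        order = np.argsort(raw)
        uniq = np.concatenate([[True], np.diff(raw[order]) > 0])
        return m, SignatureModel(
            regressor=reg,
            response_scale=1.0,
            pred_mean=float(pred.mean()),
            pred_sd=float(pred.std()),
            transform_x=raw[order][uniq],
            transform_y=transformed[order][uniq],
            cutoff=cutoff,
        )

    def test_boundary_sample_is_favorable(self, rng):
        m, model = self._model(rng)
        scores = model.transformed_scores(m)
        model.cutoff = float(scores[0])  # put one sample exactly at the cutoff
        classes = classify(model, m)
        assert classes.iloc[0] == "Favorable"

    def test_monotone_transform_invariance(self, rng):
        m, model = self._model(rng)
        base = classify(model, m)
        scores = model.transformed_scores(m)
        for f in (lambda v: v**3, np.tanh, lambda v: 2 * v + 1):
            remapped = model.cutoff  # transform cutoff alongside scores
            lab = np.where(f(scores) > f(np.array([remapped]))[0],
                           "Non-favorable", "Favorable")
            assert (lab == base.to_numpy()).all()

    def test_serialization_roundtrip(self, rng, tmp_path):
        m, model = self._model(rng)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SignatureModel.load(path)
        assert loaded.probe_ids == model.probe_ids
        assert np.allclose(loaded.transformed_scores(m), model.transformed_scores(m))
        assert loaded.cutoff == model.cutoff
        # byte-identical re-serialization
        assert loaded.to_json() == model.to_json()
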