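import numpy as np
import pytest
from scipy.optimize import minimize

from firerisk.features import FeatureConfig, build_features
from firerisk.maxent import (
    PresenceSample,
    auc,
    fit,
    predict,
    sample_background,
    solve_maxent,
    split_sample,
)
from firerisk.raster import Grid, Layer, Stack

# spec'd 3-cell instance: one linear feature (0, 0.5, 1), presence mean 0.75
F3 = np.array([[0.0], [0.5], [1.0]])
P3 = np.array([[0.5], [1.0]])
LAMBDA3 = 2.0 * np.log((1.0 + np.sqrt(13.0)) / 2.0)  # root of the moment condition


def random_tiny_instance(rng, penalized):
    """Well-posed tiny maxent instance: (F_background, F_presence, beta).

    The background feature matrix is resampled until ``[F, 1]`` has no
    near-flat direction (otherwise the optimum is not unique).  Unpenalized
    instances get a presence sample with full support over the background so
    the presence mean lies strictly inside the moment polytope and the
    optimum is finite.
    """
    while True:
        n = int(rng.integers(8, 26))
        k = int(rng.integers(1, 4))
        F = rng.random((n, k))
        if np.linalg.svd(np.column_stack([F, np.ones(n)]),
                         compute_uv=False)[-1] >= 0.1:
            break
    if penalized:
        Fp = F[rng.integers(0, n, int(rng.integers(2, 15)))]
        beta = rng.random(k) * 0.1
    else:
        idx = np.concatenate([np.arange(n), rng.integers(0, n, int(rng.integers(0, 11)))])
        Fp = F[idx]
        beta = np.zeros(k)
    return F, Fp, beta


def oracle_weights(F, Fp, beta):
    """High-precision L-BFGS-B on the split-variable convex reformulation."""
    k = F.shape[1]
    fbar = Fp.mean(axis=0)

    def obj(z):
        l = z[:k] - z[k:]
        eta = F @ l
        mx = eta.max()
        return mx + np.log(np.exp(eta - mx).sum()) - fbar @ l + beta @ (z[:k] + z[k:])

    def grad(z):
        l = z[:k] - z[k:]
        eta = F @ l
        q = np.exp(eta - eta.max())
        q /= q.sum()
        g = F.T @ q - fbar
        return np.concatenate([g + beta, -g + beta])

    res = minimize(obj, np.zeros(2 * k), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * k),
                   options={"maxiter": 20000, "ftol": 1e-17, "gtol": 1e-14})
    return res.x[:k] - res.x[k:]


class TestSolver:
    def test_constant_feature_gives_uniform(self):
        F = np.ones((4, 1))
        lam, info = solve_maxent(F, np.ones((3, 1)), np.zeros(1))
        assert np.allclose(info["q"], 0.25)

    def test_three_cell_closed_form(self):
        lam, info = solve_maxent(F3, P3, np.zeros(1), max_iter=5000, tol=1e-14)
        assert lam[0] == pytest.approx(LAMBDA3, abs=1e-6)
        assert np.allclose(info["q"], [0.1162, 0.2676, 0.6162], atol=1e-4)

    def test_kkt_active_at_beta(self):
        """With beta = 0.05 the moment constraint is tight at the optimum."""
        lam, info = solve_maxent(F3, P3, np.array([0.05]), max_iter=5000, tol=1e-14)
        e_q = float(F3[:, 0] @ info["q"])
        assert abs(e_q - 0.75) == pytest.approx(0.05, abs=1e-6)

    def test_moment_matching_when_unpenalized(self):
        rng = np.random.default_rng(7)
        F = rng.random((20, 3))
        Fp = F[rng.integers(0, 20, 12)]
        lam, info = solve_maxent(F, Fp, np.zeros(3), max_iter=10000, tol=1e-15)
        assert np.allclose(F.T @ info["q"], Fp.mean(axis=0), atol=1e-6)

    def test_constraint_satisfaction_with_penalty(self):
        rng = np.random.default_rng(8)
        F = rng.random((25, 3))
        Fp = F[rng.integers(0, 25, 10)]
        beta = np.array([0.02, 0.05, 0.1])
        lam, info = solve_maxent(F, Fp, beta, max_iter=10000, tol=1e-15)
        gap = np.abs(F.T @ info["q"] - Fp.mean(axis=0))
        assert np.all(gap <= beta + 1e-6)

    def test_matches_convex_oracle(self):
        """Well-posed random tiny instances agree with L-BFGS-B to 1e-4."""
        rng = np.random.default_rng(9)
        for i in range(10):
            F, Fp, beta = random_tiny_instance(rng, penalized=bool(i % 2))
            lam, _ = solve_maxent(F, Fp, beta, max_iter=10000, tol=1e-15)
            assert np.abs(lam - oracle_weights(F, Fp, beta)).max() < 1e-4


def tiny_stack():
    """3x1 grid carrying the closed-form instance as a linear feature."""
    grid = Grid(1, 3)
    layer = Layer(grid=grid, name="x", values=np.array([[0.0, 0.5, 1.0]]))
    return Stack([layer])


def tiny_fit(**kw):
    stack = tiny_stack()
    pres = PresenceSample([0, 0], [1, 2], [2005, 2005], [8, 9])
    bg = np.array([[0, 0], [0, 1], [0, 2]])
    exp = build_features(stack, FeatureConfig(quadratic=False, hinge=False))
    kw.setdefault("reg_multiplier", 0.0)
    kw.setdefault("max_iter", 5000)
    kw.setdefault("tol", 1e-14)
    kw.setdefault("collapse_duplicates", False)
    return stack, fit(pres, bg, exp, stack, **kw)


class TestFitPredict:
    def test_fit_recovers_closed_form(self):
        _, model = tiny_fit()
        assert model.weights[0] == pytest.approx(LAMBDA3, abs=1e-6)
        assert model.converged

    def test_fit_deterministic(self):
        _, m1 = tiny_fit()
        _, m2 = tiny_fit()
        assert np.array_equal(m1.weights, m2.weights)

    def test_logistic_hand_value(self):
        """p3 = tau e^H q3 / (1 - tau + tau e^H q3) ~ 0.603."""
        stack, model = tiny_fit()
        out = predict(model, stack, output="logistic", clamp=False)
        assert out.values[0, 2] == pytest.approx(0.603, abs=1e-3)

    def test_raw_renormalizes_to_one(self):
        stack, model = tiny_fit()
        out = predict(model, stack, output="raw")
        assert out.valid_values.sum() == pytest.approx(1.0)
        assert np.allclose(out.values[0], [0.1162, 0.2676, 0.6162], atol=1e-4)

    def test_uniform_model_logistic_is_half(self):
        """Entropy of a uniform q cancels: p = tau = 0.5 everywhere."""
        grid = Grid(2, 2)
        stack = Stack([Layer(grid=grid, name="x",
                             values=np.array([[1.0, 2.0], [3.0, 4.0]]))])
        pres = PresenceSample([0, 0, 1, 1], [0, 1, 0, 1],
                              [2005] * 4, [8] * 4)
        bg = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        exp = build_features(stack, FeatureConfig(quadratic=False, hinge=False))
        model = fit(pres, bg, exp, stack, reg_multiplier=0.0, max_iter=5000,
                    tol=1e-14, collapse_duplicates=False)
        # presences cover the whole background uniformly -> uniform q
        out = predict(model, stack, output="logistic")
        assert np.allclose(out.values, 0.5, atol=1e-6)

    def test_logistic_monotone_in_raw(self):
        stack, model = tiny_fit()
        raw = predict(model, stack, output="raw").values.ravel()
        logi = predict(model, stack, output="logistic").values.ravel()
        assert np.array_equal(np.argsort(raw), np.argsort(logi))

    def test_missing_variable_raises(self):
        stack, model = tiny_fit()
        other = Stack([Layer(grid=stack.grid, name="y",
                             values=np.zeros(stack.grid.shape))])
        with pytest.raises(KeyError):
            predict(model, other)

    def test_too_few_presences_rejected(self):
        stack = tiny_stack()
        exp = build_features(stack, FeatureConfig(quadratic=False, hinge=False))
        one = PresenceSample([0], [1], [2005], [8])
        with pytest.raises(ValueError):
            fit(one, np.array([[0, 0]]), exp, stack)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_enumerated_pairs(self):
        # pairs won: (0.9 beats all 3) + (0.4 beats 0.3, 0.1) = 5 of 6
        assert auc([0.9, 0.4], [0.5, 0.3, 0.1]) == pytest.approx(5 / 6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestSplitSample:
    def make(self, m):
        return PresenceSample(np.arange(m), np.zeros(m, dtype=int),
                              np.full(m, 2005), np.full(m, 8))

    def test_75_25(self):
        train, test = split_sample(self.make(100), 0.25, seed=0)
        assert (train.m, test.m) == (75, 25)

    def test_partition_disjoint_exhaustive(self):
        pres = self.make(40)
        train, test = split_sample(pres, 0.25, seed=1)
        ids = np.concatenate([train.rows, test.rows])
        assert np.array_equal(np.sort(ids), np.arange(40))

    def test_same_seed_same_split(self):
        pres = self.make(40)
        a = split_sample(pres, 0.25, seed=5)[1].rows
        b = split_sample(pres, 0.25, seed=5)[1].rows
        assert np.array_equal(a, b)

    def test_every_record_eventually_tested(self):
        pres = self.make(40)
        seen = set()
        for seed in range(1, 51):
            seen.update(split_sample(pres, 0.25, seed=seed)[1].rows.tolist())
        assert seen == set(range(40))

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            split_sample(self.make(10), 1.5, seed=0)


def test_sample_background_is_subsample_when_large():
    grid = Grid(200, 200)
    bg = sample_background(grid, max_n=10_000, seed=3)
    assert bg.shape == (10_000, 2)
    assert len(np.unique(bg, axis=0)) == 10_000
    again = sample_background(grid, max_n=10_000, seed=3)
    assert np.array_equal(bg, again)


def test_sample_background_all_cells_when_small(grid5):
    assert sample_background(grid5).shape == (25, 2)
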