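"""MARS engine: OLS, forward hinge search, GCV pruning, CV stabilization.

The pruning oracle here is an independent implementation: exhaustive subset
enumeration with normal-equation OLS and a locally written GCV formula.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from tfscribe import mars
from tfscribe.mars import BasisTerm, FitConfig, MarsModel


# ---------------------------------------------------------------------------
# Independent oracle helpers (normal equations, not the package's lstsq path)
# ---------------------------------------------------------------------------

def oracle_rss(cols, y):
    D = np.column_stack([np.ones(len(y))] + cols)
    beta = np.linalg.solve(D.T @ D + 1e-12 * np.eye(D.shape[1]), D.T @ y)
    r = y - D @ beta
    return float(r @ r)


def oracle_gcv(terms, X, y, penalty):
    n = len(y)
    cols = [t.evaluate(X[:, t.variable]) for t in terms]
    rss = oracle_rss(cols, y) if cols else float(((y - y.mean()) ** 2).sum())
    knots = len({(t.variable, t.knot) for t in terms if t.form != "linear"})
    c = (len(terms) + 1) + penalty * knots
    if c >= n:
        return np.inf
    return (rss / n) / (1 - c / n) ** 2


def oracle_min_gcv(terms, X, y, penalty):
    best = np.inf
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            best = min(best, oracle_gcv(list(sub), X, y, penalty))
    return best


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        coef, r2, resid = mars.ols_fit(x[:, None], 2 * x + 1)
        np.testing.assert_allclose(coef, [1.0, 2.0], atol=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_response(self):
        x = np.array([-1.0, 1, -1, 1])
        y = np.array([1.0, 1, -1, -1])
        coef, r2, _ = mars.ols_fit(x[:, None], y)
        assert coef[1] == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        coef, r2, resid = mars.ols_fit(X, y)
        D = np.column_stack([np.ones(30), X])
        want = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(coef, want, atol=1e-8)

    def test_rank_deficient_warns(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, x])
        with pytest.warns(UserWarning, match="rank"):
            mars.ols_fit(X, x)


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

class TestForward:
    def test_noise_free_hinge_found_exactly(self):
        x = np.linspace(0, 10, 201)
        y = np.maximum(0.0, x - 5.0)
        cfg = FitConfig(endspan=3, max_knot_candidates=10**6, max_terms=10)
        terms = mars.mars_forward(x[:, None], y, cfg)
        assert terms[0].form.startswith("hinge") and terms[0].knot == pytest.approx(5.0)
        model = mars.mars_prune(terms, x[:, None], y, cfg)
        assert np.abs(model.predict(x[:, None]) - y).max() < 1e-9

    def test_endspan_half_n_forces_linear(self, rng):
        x = rng.normal(size=40)
        y = np.maximum(0, x) + rng.normal(0, 0.1, 40)
        terms = mars.mars_forward(x[:, None], y, FitConfig(endspan=20, max_terms=6))
        assert all(t.form == "linear" for t in terms)

    def test_linear_only_mode_has_no_hinges(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.maximum(0, X[:, 0]) + rng.normal(0, 0.1, 100)
        terms = mars.mars_forward(X, y, FitConfig(linear_only=True, endspan=2))
        assert terms and all(t.form == "linear" for t in terms)

    def test_constant_response_intercept_only(self):
        X = np.arange(20.0)[:, None]
        assert mars.mars_forward(X, np.full(20, 3.0), FitConfig(endspan=2)) == []

    def test_training_r2_monotone_along_forward_path(self, rng):
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.5, 80)
        cfg = FitConfig(endspan=5, max_terms=8)
        terms = mars.mars_forward(X, y, cfg)
        rss_path = [
            mars._fit_subset(terms[:k], X, y, cfg.penalty)[2] for k in range(len(terms) + 1)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(rss_path, rss_path[1:]))


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

class TestPrune:
    def test_pure_noise_prunes_to_intercept(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = rng.normal(size=60)
        cfg = FitConfig(endspan=5, max_terms=5)
        terms = mars.mars_forward(X, y, cfg)
        model = mars.mars_prune(terms, X, y, cfg)
        assert oracle_min_gcv(terms, X, y, cfg.penalty) == pytest.approx(model.gcv, rel=1e-9)

    def test_noise_free_hinge_retained(self):
        x = np.linspace(0, 10, 201)
        y = 2.0 * np.maximum(0.0, x - 4.0)
        cfg = FitConfig(endspan=3, max_knot_candidates=10**6)
        model = mars.fit_mars(x[:, None], y, cfg)
        assert any(t.form == "hinge_plus" and t.knot == pytest.approx(4.0) for t in model.terms)
        assert model.r2 == pytest.approx(1.0)

    def test_gcv_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(15, 41))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            cfg = FitConfig(max_terms=4, endspan=int(rng.integers(0, 4)), max_knot_candidates=8)
            terms = mars.mars_forward(X, y, cfg)
            model = mars.mars_prune(terms, X, y, cfg)
            assert model.gcv == pytest.approx(oracle_min_gcv(terms, X, y, cfg.penalty), rel=1e-9)

    def test_penalty_zero_gcv_ordering_equals_rss_at_fixed_size(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ np.array([1.0, 0.5]) + rng.normal(0, 0.3, 30)
        cfg = FitConfig(max_terms=4, endspan=2, penalty=0.0, max_knot_candidates=6)
        terms = mars.mars_forward(X, y, cfg)
        for size in range(1, len(terms) + 1):
            subs = list(itertools.combinations(terms, size))
            gcvs = [mars._fit_subset(list(s), X, y, 0.0)[3] for s in subs]
            rsss = [mars._fit_subset(list(s), X, y, 0.0)[2] for s in subs]
            assert np.argsort(gcvs).tolist() == np.argsort(rsss).tolist()

    def test_returned_gcv_never_worse_than_full_model(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.maximum(0, X[:, 0] - 0.2) + rng.normal(0, 0.3, 100)
        cfg = FitConfig(endspan=5, max_terms=8)
        terms = mars.mars_forward(X, y, cfg)
        model = mars.mars_prune(terms, X, y, cfg)
        full = mars._fit_subset(list(terms), X, y, cfg.penalty)[3]
        assert model.gcv <= full + 1e-12


# ---------------------------------------------------------------------------
# Cross-validated selection
# ---------------------------------------------------------------------------

class TestCvSelect:
    def test_strong_linear_driver_always_retained(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(2, 1, size=(850, 5))
        y = X[:, 1] + rng.normal(0, 0.1 * X[:, 1].std(), 850)
        model = mars.cv_select(X, y, FitConfig(endspan=100), folds=10, repeats=2, seed=0)
        assert 1 in model.selected_tfs

    @pytest.mark.parametrize("seed", range(10))
    def test_pure_noise_gives_intercept_only(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        with pytest.warns(UserWarning, match="retention"):
            model = mars.cv_select(X, y, FitConfig(endspan=20), folds=5, repeats=2, seed=seed)
        assert model.terms == []

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(2, 1, size=(300, 4))
        y = np.maximum(0, X[:, 0] - 8) + rng.normal(0, 2, 300)
        cfg = FitConfig(endspan=30)
        a = mars.cv_select(X, y, cfg, folds=5, repeats=2, seed=42)
        b = mars.cv_select(X, y, cfg, folds=5, repeats=2, seed=42)
        assert a.to_json() == b.to_json()

    def test_linear_only_on_linear_truth_matches_ols(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = X @ beta + rng.normal(0, 0.05, 400)
        model = mars.cv_select(X, y, FitConfig(linear_only=True, endspan=10),
                               folds=5, repeats=2, seed=0)
        coef, _, _ = mars.ols_fit(X, y)
        got = {t.variable: t.coefficient for t in model.terms}
        for v in range(3):
            assert got[v] == pytest.approx(coef[v + 1], abs=1e-8)

    def test_requires_enough_rows(self):
        with pytest.raises(ValueError):
            mars.cv_select(np.zeros((10, 2)), np.zeros(10), folds=10)


# ---------------------------------------------------------------------------
# Relative importance
# ---------------------------------------------------------------------------

class TestRelativeImportance:
    def test_single_variable_weight_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 1))
        y = 2 * x[:, 0] + rng.normal(0, 0.1, 100)
        model = mars.fit_mars(x, y, FitConfig(linear_only=True, endspan=5))
        imp = mars.relative_importance(model, x, y)
        assert imp == {0: pytest.approx(1.0)}

    def test_symmetric_drivers_split_evenly(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(850, 2))
        y = X[:, 0] + X[:, 1] + rng.normal(0, 0.3, 850)
        model = mars.fit_mars(X, y, FitConfig(linear_only=True, endspan=50))
        imp = mars.relative_importance(model, X, y)
        assert imp[0] == pytest.approx(0.5, abs=0.1)
        assert imp[1] == pytest.approx(0.5, abs=0.1)

    def test_weights_sum_to_one(self, rng):
        X = rng.lognormal(2, 1, size=(300, 4))
        y = X[:, 0] + 0.2 * X[:, 2] + rng.normal(0, 1, 300)
        model = mars.fit_mars(X, y, FitConfig(endspan=30))
        imp = mars.relative_importance(model, X, y)
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-12)


class TestSerialization:
    def test_model_json_round_trip(self, rng):
        X = pd.DataFrame(rng.lognormal(2, 1, size=(200, 3)), columns=["a", "b", "c"])
        y = X["a"] + rng.normal(0, 1, 200)
        model = mars.fit_mars(X, y, FitConfig(endspan=20))
        back = MarsModel.from_json(model.to_json())
        np.testing.assert_allclose(back.predict(X), model.predict(X), rtol=1e-12)
        assert back.var_names == model.var_names

    def test_basis_term_validation(self):
        with pytest.raises(ValueError):
            BasisTerm(variable=0, form="linear", knot=1.0)
        with pytest.raises(ValueError):
            BasisTerm(variable=0, form="hinge_plus")
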