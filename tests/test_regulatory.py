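"""Collinearity, substitution, interactions, importance, promoter scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfscribe import regulatory, scenarios, synthetic
from tfscribe.mars import FitConfig, MarsModel, fit_mars
from tfscribe.regulatory import InteractionResult


# ---------------------------------------------------------------------------
# Collinearity report
# ---------------------------------------------------------------------------

class TestCollinearity:
    def test_p_matches_pearsonr_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        report = regulatory.collinearity(X)
        for a in "abcd":
            for b in "abcd":
                if a >= b:
                    continue
                want = stats.pearsonr(X[a], X[b])
                assert report.r.loc[a, b] == pytest.approx(want.statistic, rel=1e-9)
                assert report.p.loc[a, b] == pytest.approx(want.pvalue, rel=1e-6)

    def test_r_0878_at_n5_is_p_005(self):
        # closed form: |r| = 0.878 at n = 5 sits on the two-sided 5% boundary
        t = 0.878 * np.sqrt(3 / (1 - 0.878**2))
        p = 2 * stats.t.sf(t, df=3)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_zero_correlation_p_one(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        y = np.array([1.0, -1, 0, -1, 1])  # exactly orthogonal to x
        X = pd.DataFrame({"a": x, "b": y})
        report = regulatory.collinearity(X)
        assert report.p.loc["a", "b"] == pytest.approx(1.0)

    def test_planted_rho_highly_significant(self):
        truth = synthetic.SyntheticTruth(
            n_genes=1000, n_tfs=4, conditions=("c",), active_tfs=(),
            coefficients={}, collinear_pairs=((0, 1, 0.9),), seed=3,
        )
        X = synthetic.generate_binding_matrix(truth, "c").values
        report = regulatory.collinearity(X)
        assert report.p.loc["TF00", "TF01"] < 1e-10

    def test_symmetry_and_diagonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        report = regulatory.collinearity(X)
        np.testing.assert_allclose(report.r.to_numpy(), report.r.to_numpy().T)
        np.testing.assert_allclose(np.diag(report.r), 1.0)

    def test_zero_variance_column_missing(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        report = regulatory.collinearity(X)
        assert np.isnan(report.r.loc["a", "b"])

    def test_stars(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X["b"] = X["a"] + rng.normal(0, 0.1, 30)
        report = regulatory.collinearity(X)
        assert report.stars("a", "b") == "***"


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

class TestInteractionResult:
    def test_improvement_ratio_arithmetic(self):
        r = InteractionResult("a", "b", r2_additive=0.40, r2_multiplicative=0.44)
        assert r.delta_r2 == pytest.approx(0.04)
        assert r.improvement_ratio == pytest.approx(1.10)
        assert r.flagged  # ratio meets the >= 1.10 threshold exactly

    def test_below_threshold_not_flagged(self):
        assert not InteractionResult("a", "b", 0.40, 0.4399).flagged
        assert not InteractionResult("a", "b", 0.09, 0.2).flagged  # weak additive base

    def test_nested_models_never_lose_r2(self, rng):
        X = pd.DataFrame(rng.lognormal(2, 1, size=(300, 3)), columns=list("abc"))
        y = pd.Series(X["a"] + rng.normal(0, 5, 300))
        X["b"] = X["a"] * np.exp(rng.normal(0, 0.3, 300))
        report = regulatory.collinearity(X)
        for r in regulatory.interaction_scan(X, y, report):
            assert r.r2_multiplicative >= r.r2_additive - 1e-12

    def test_improvement_ratio_scale_invariant(self, rng):
        X = pd.DataFrame(rng.lognormal(2, 1, size=(400, 2)), columns=["a", "b"])
        X["b"] = X["a"] * np.exp(rng.normal(0, 0.4, 400))
        y = pd.Series(X["a"] * X["b"] * 0.01 + X["a"] + rng.normal(0, 3, 400))
        report = regulatory.collinearity(X)
        base = regulatory.interaction_scan(X, y, report)[0]
        scaled = regulatory.interaction_scan(X * 7.0, y * 3.0,
                                             regulatory.collinearity(X * 7.0))[0]
        assert scaled.improvement_ratio == pytest.approx(base.improvement_ratio, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_interaction_flagged(self, seed):
        assert scenarios.interaction_trial(seed)["planted_flagged"]

    @pytest.mark.parametrize("seed", range(3))
    def test_additive_truth_not_flagged(self, seed):
        assert scenarios.interaction_trial(seed, gamma=0.0)["n_flagged"] == 0


# ---------------------------------------------------------------------------
# TF importance
# ---------------------------------------------------------------------------

class TestTfImportance:
    def test_single_activator_score_is_r2(self, rng):
        x = rng.lognormal(2, 1, size=(300, 1))
        y = pd.Series(2 * x[:, 0] + rng.normal(0, 10, 300))
        X = pd.DataFrame(x, columns=["tf"])
        model = fit_mars(X, y, FitConfig(linear_only=True, endspan=30))
        (score,) = regulatory.tf_importance(model, X, y)
        assert score.score == pytest.approx(model.r2)

    def test_repressor_negative_score(self, rng):
        x = rng.lognormal(2, 1, size=(300, 1))
        y = pd.Series(100.0 - 2 * x[:, 0] + rng.normal(0, 5, 300))
        X = pd.DataFrame(x, columns=["tf"])
        model = fit_mars(X, y, FitConfig(linear_only=True, endspan=30))
        (score,) = regulatory.tf_importance(model, X, y)
        assert score.score < 0

    def test_abs_scores_bounded_by_r2(self, rng):
        X = pd.DataFrame(rng.lognormal(2, 1, size=(400, 4)),
                         columns=[f"t{i}" for i in range(4)])
        y = pd.Series(X["t0"] + 0.5 * X["t2"] + rng.normal(0, 8, 400))
        model = fit_mars(X, y, FitConfig(endspan=40))
        scores = regulatory.tf_importance(model, X, y)
        assert sum(abs(s.score) for s in scores) <= model.r2 + 1e-9
        for s in scores:
            assert abs(s.score) <= model.r2 + 1e-12


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------

class TestSubstitution:
    @pytest.mark.parametrize("seed", range(3))
    def test_collinear_partner_pulled_in(self, seed):
        res = scenarios.substitution_trial(seed)
        assert res["partner_found"] or res["decoy_substituted"] is False

    def test_empty_model_gives_empty_list(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=100))
        model = MarsModel(intercept=0.0, terms=[], gcv=1.0, r2=0.0)
        report = regulatory.collinearity(X)
        assert regulatory.substitution_test(X, y, model, report) == []


# ---------------------------------------------------------------------------
# Promoter scans and the trio
# ---------------------------------------------------------------------------

class TestSegmentScan:
    def test_causal_region_localized(self):
        sc = scenarios.localized_binding_tracks(0, causal_center=-350, causal_width=100)
        prof = regulatory.segment_scan({"TF": sc["track"]}, sc["tss"], sc["y"])
        col = prof["TF"]
        causal = col[(col.index >= -460) & (col.index <= -240)]
        elsewhere = col[(col.index < -600) | (col.index > 200)]
        assert causal.max() > 0.5
        assert elsewhere.abs().max() < 0.1

    def test_repressor_profile_negative(self):
        sc = scenarios.localized_binding_tracks(1)
        y_flipped = -sc["y"] + 2 * float(sc["y"].mean())
        prof = regulatory.segment_scan({"TF": sc["track"]}, sc["tss"], y_flipped)
        assert prof["TF"].min() < -0.5

    def test_tiling_drops_partial_segment(self):
        segs = regulatory.tile_segments((-100, 100), 75)
        assert segs == [(-100, -26), (-25, 49), (50, 124)][:2]


class TestRegionExtension:
    def test_plateau_at_causal_halfwidth(self):
        sc = scenarios.localized_binding_tracks(2, causal_center=-200, causal_width=10)
        curve, plateau = regulatory.region_extension_scan(
            {"TF": sc["track"]}, sc["tss"], sc["y"], step_bp=50, max_halfwidth=600,
            config=FitConfig(linear_only=True, endspan=20),
        )
        # peak spans [-205, -195]: first window covering it has half-width 250
        assert plateau == 250

    def test_curve_monotone_up_to_plateau_noise_free(self):
        sc = scenarios.localized_binding_tracks(3, causal_center=-200, causal_width=10,
                                                background_rate=0.0)
        y = sc["y"]
        curve, plateau = regulatory.region_extension_scan(
            {"TF": sc["track"]}, sc["tss"], y, step_bp=50, max_halfwidth=400,
            config=FitConfig(linear_only=True, endspan=20),
        )
        upto = curve.loc[:plateau]
        assert (upto.diff().dropna() >= -1e-9).all()


class TestTrio:
    def make_trio(self, repress: bool, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        latent = rng.lognormal(1, 1, n)
        X = pd.DataFrame(
            {f"tf{i}": latent * np.exp(rng.normal(0, 0.3, n)) for i in range(3)},
            index=[f"g{i}" for i in range(n)],
        )
        base = 50.0
        effect = -2.0 if repress else 2.0
        y = pd.Series(base + effect * latent + rng.normal(0, 2, n), index=X.index)
        return X, y

    def test_coordinated_repression_called(self):
        X, y = self.make_trio(repress=True)
        assert regulatory.trio_detection(X, y)["coordinated_repression"]

    def test_independent_tfs_no_call(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.lognormal(1, 1, (200, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(50, 5, 200))
        assert not regulatory.trio_detection(X, y)["coordinated_repression"]

    def test_activation_pattern_not_called_repression(self):
        X, y = self.make_trio(repress=False)
        assert not regulatory.trio_detection(X, y)["coordinated_repression"]

    def test_too_few_genes_rejected(self):
        X = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError, match="10"):
            regulatory.trio_detection(X, pd.Series(np.ones(5)))


class TestRepresentationComparison:
    def test_mars_at_least_linear_on_hinge_truth(self):
        r_mars, r_lin = scenarios.mars_vs_linear(0)
        assert r_mars >= r_lin - 1e-9

    def test_compare_representations_table_shape(self, small_truth, small_bundle):
        by_rep = {"promoter_sum": {c: small_bundle.binding[c].values
                                   for c in small_truth.conditions}}
        out = regulatory.compare_representations(
            by_rep, small_bundle.expression, FitConfig(endspan=20)
        )
        assert "promoter_sum_mars" in out.index
        assert "mean" in out.columns
        assert out.loc["promoter_sum", "mean"] > 0.5
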