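"""Planted-truth benchmark scenarios for validating the pipeline's claims.

Each scenario fixes a generative condition with a known answer (a hinge
knot, a substitutable driver pair, a multiplicative interaction, a planted
cluster count, a causally active promoter region) and exposes a runner that
measures how reliably the corresponding analysis recovers it.  These are the
study conditions of the synthetic benchmark; they are used by the test
suite, the analysis drivers and the acceptance script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chip, regulatory, synthetic
from .mars import FitConfig, cv_select


# ---------------------------------------------------------------------------
# Hinge recovery
# ---------------------------------------------------------------------------

def hinge_recovery_trial(seed: int, n: int = 850, knot: float = 8.0, beta: float = 1.0,
                         noise_frac: float = 0.2, endspan: int = 100) -> dict:
    """Fit a single-TF threshold effect at realistic noise; report the
    recovered knot and whether all above-threshold slopes are positive."""
    rng = np.random.default_rng(seed)
    x = np.exp(2.0 + rng.standard_normal(n))
    signal = beta * np.maximum(0.0, x - knot)
    y = signal + rng.normal(0.0, noise_frac * signal.std(), n)
    model = cv_select(x[:, None], y, FitConfig(endspan=endspan), folds=5, repeats=2, seed=seed)
    knots = [t.knot for t in model.terms if t.knot is not None]
    knot_err = min((abs(k - knot) for k in knots), default=np.inf)
    plus = [t.coefficient for t in model.terms if t.form == "hinge_plus"]
    signs_ok = bool(plus) and all(c > 0 for c in plus)
    return {
        "knot_error": float(knot_err),
        "data_range": float(x.max() - x.min()),
        "signs_ok": signs_ok,
        "r2": model.r2,
    }


# ---------------------------------------------------------------------------
# Substitution of collinear drivers
# ---------------------------------------------------------------------------

def substitution_truth(seed: int, rho: float = 0.95) -> synthetic.SyntheticTruth:
    """A dominant driver with a weaker collinear co-driver among 19 decoys.

    At rho = 0.95 the pair shares almost all of its variation; the noise
    level puts the co-driver's conditional contribution below the stable
    selection threshold while leaving its marginal signal strong -- the
    redundancy situation the substitution test is designed to expose."""
    return synthetic.SyntheticTruth(
        n_genes=850,
        n_tfs=21,
        conditions=("cond",),
        active_tfs=(0, 1),
        coefficients={0: 1.0, 1: 0.15},
        collinear_pairs=((0, 1, rho),),
        noise_sd=40.0,
        seed=seed,
    )


def substitution_trial(seed: int, rho: float = 0.95) -> dict:
    """Does dropping the selected driver pull in its collinear partner, and do
    independent decoys ever substitute?"""
    truth = substitution_truth(seed, rho)
    binding = synthetic.generate_binding_matrix(truth, "cond")
    y = synthetic.generate_expression(truth, binding)
    X = binding.values
    cfg = FitConfig(endspan=100)
    model = cv_select(X, y, cfg, folds=5, repeats=2, seed=seed)
    report = regulatory.collinearity(X)
    pairs = regulatory.substitution_test(X, y, model, report, cfg, seed=seed,
                                         folds=5, repeats=1)
    driver_names = {truth.tf_names[0], truth.tf_names[1]}
    partner_found = any(t in driver_names and u in driver_names for t, u in pairs)
    decoy_found = any(u not in driver_names for _, u in pairs)
    return {
        "selected": model.selected_names,
        "pairs": pairs,
        "partner_found": partner_found,
        "decoy_substituted": decoy_found,
    }


# ---------------------------------------------------------------------------
# Multiplicative interactions
# ---------------------------------------------------------------------------

def interaction_truth(seed: int, gamma: float = 0.05) -> synthetic.SyntheticTruth:
    """A correlated TF pair with additive effects plus a product interaction."""
    return synthetic.SyntheticTruth(
        n_genes=850,
        n_tfs=21,
        conditions=("cond",),
        active_tfs=(0, 1),
        coefficients={0: 0.6, 1: 0.6},
        collinear_pairs=((0, 1, 0.6),),
        interaction_pair=(0, 1, gamma) if gamma else None,
        noise_sd=25.0,
        seed=seed,
    )


def interaction_trial(seed: int, gamma: float = 0.05) -> dict:
    """Scan all significantly correlated pairs; report whether the planted
    pair is flagged and whether anything is flagged under additive truth."""
    truth = interaction_truth(seed, gamma)
    binding = synthetic.generate_binding_matrix(truth, "cond")
    y = synthetic.generate_expression(truth, binding)
    X = binding.values
    report = regulatory.collinearity(X)
    results = regulatory.interaction_scan(X, y, report)
    planted = {truth.tf_names[0], truth.tf_names[1]}
    planted_flagged = any(r.flagged and {r.tf_a, r.tf_b} == planted for r in results)
    n_flagged = sum(r.flagged for r in results)
    return {"planted_flagged": planted_flagged, "n_flagged": n_flagged,
            "results": results}


# ---------------------------------------------------------------------------
# Representation ordering
# ---------------------------------------------------------------------------

def representation_tracks(seed: int, n_genes: int = 300, n_tfs: int = 3,
                          background_rate: float = 1.0) -> dict:
    """Coverage tracks where sub-threshold binding contributes to expression.

    Per gene and TF:

    * one strong, easily detectable peak at -100 bp whose height varies only
      slightly between genes (it marks the binding site but carries little
      of the expression signal);
    * one broad sub-threshold pileup centered on the peak (inside the
      +/-50 bp peak window) whose coverage never reaches twice the
      background, so the SNR > 2 caller cannot see it;
    * one broad sub-threshold pileup at +300 bp, inside the promoter but
      outside any peak window.

    Expression is the total promoter signal, so the summit-only
    representation misses most of the variance, the peak-window sum recovers
    the near-peak share, and the promoter sum recovers everything.
    """
    rng = np.random.default_rng([seed, 77])
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    tss = synthetic.make_tss_table(gene_ids, spacing=3000)
    tracks = {}
    promoter_total = {}
    for k in range(n_tfs):
        strong = 28.0 + 4.0 * rng.uniform(size=n_genes)
        weak1 = 0.9 * rng.uniform(size=n_genes)  # coverage stays < 2x background
        weak2 = 0.9 * rng.uniform(size=n_genes)
        strong_track = synthetic.generate_coverage_track(
            tss, {g: [-100] for g in gene_ids},
            {g: [strong[i]] for i, g in enumerate(gene_ids)},
            background_rate=background_rate, peak_width=10,
            rng=np.random.default_rng([seed, 88, k]),
        )
        weak1_track = synthetic.generate_coverage_track(
            tss, {g: [-100] for g in gene_ids},
            {g: [weak1[i]] for i, g in enumerate(gene_ids)},
            background_rate=0.0, peak_width=100,
        )
        weak2_track = synthetic.generate_coverage_track(
            tss, {g: [300] for g in gene_ids},
            {g: [weak2[i]] for i, g in enumerate(gene_ids)},
            background_rate=0.0, peak_width=200,
        )
        combined = {
            c: strong_track.coverage[c] + weak1_track.coverage[c] + weak2_track.coverage[c]
            for c in strong_track.chroms
        }
        tracks[f"TF{k:02d}"] = chip.CoverageTrack(combined)
        promoter_total[f"TF{k:02d}"] = 10 * strong + 100 * weak1 + 200 * weak2
    total = pd.DataFrame(promoter_total, index=gene_ids)
    y = pd.Series(
        total.sum(axis=1).to_numpy() + rng.normal(0, 0.05 * total.sum(axis=1).std(), n_genes),
        index=gene_ids, name="expression",
    )
    return {"tracks": tracks, "tss": tss, "y": y}


def representation_comparison(seed: int = 0, min_snr: float = 2.0) -> pd.Series:
    """Prediction correlation of the three binding representations on the
    sub-threshold-contribution scenario (linear selection throughout)."""
    sc = representation_tracks(seed)
    tss, y = sc["tss"], sc["y"]
    cfg = FitConfig(endspan=20, linear_only=True)
    mats = {}
    for rep in ("promoter_sum", "peak_window", "peak_signal"):
        per_tf = {}
        for tf, track in sc["tracks"].items():
            if rep == "promoter_sum":
                per_tf[tf] = chip.promoter_sum(track, tss, (500, 500))
            else:
                peaks = chip.annotate_peaks(chip.detect_peaks(track, min_snr=min_snr), tss)
                if rep == "peak_window":
                    per_tf[tf] = chip.peak_window_sum(track, peaks, tss)
                else:
                    per_tf[tf] = chip.peak_signal_sum(peaks, tss)
        X = pd.DataFrame(per_tf).loc[y.index]
        mats[rep] = regulatory.prediction_correlation(X, y, cfg)
    return pd.Series(mats)


def mars_vs_linear(seed: int = 0) -> tuple[float, float]:
    """Prediction correlation of spline vs linear-only fits on hinge truth."""
    truth = synthetic.SyntheticTruth(
        n_genes=850, n_tfs=8, conditions=("cond",),
        active_tfs=(0, 1, 2),
        coefficients={0: 1.0, 1: 0.8, 2: 0.9},
        knots={0: 10.0, 1: 12.0, 2: 15.0},
        noise_sd=8.0, seed=seed,
    )
    binding = synthetic.generate_binding_matrix(truth, "cond")
    y = synthetic.generate_expression(truth, binding)
    r_mars = regulatory.prediction_correlation(binding.values, y, FitConfig(endspan=100))
    r_lin = regulatory.prediction_correlation(
        binding.values, y, FitConfig(endspan=100, linear_only=True)
    )
    return r_mars, r_lin


# ---------------------------------------------------------------------------
# Cluster-count recovery
# ---------------------------------------------------------------------------

def planted_clusters(seed: int, k: int = 4, n: int = 800, d: int = 4,
                     separation_sd: float = 6.0) -> pd.DataFrame:
    """Well-separated spherical Gaussian clusters of expression-like profiles.

    Cluster centers (nonnegative, unit norm) are drawn apart by at least
    ``separation_sd`` within-cluster standard deviations; points are the
    centers plus isotropic noise, clipped to stay positive.
    """
    rng = np.random.default_rng(seed)
    noise_sd = 0.05
    # nonnegative expression-like centers on the unit sphere
    centers = np.abs(rng.normal(size=(k, d)))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    for _ in range(200):
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= separation_sd * noise_sd:
            break
        centers = np.abs(rng.normal(size=(k, d)))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    labels = rng.integers(0, k, size=n)
    X = np.maximum(centers[labels] + rng.normal(0, noise_sd, size=(n, d)), 1e-6)
    return pd.DataFrame(X, index=[f"gene{i:04d}" for i in range(n)],
                        columns=[f"cond{j}" for j in range(d)])


# ---------------------------------------------------------------------------
# Promoter-region localization
# ---------------------------------------------------------------------------

def localized_binding_tracks(seed: int, n_genes: int = 300,
                             causal_center: int = -350, causal_width: int = 100,
                             background_rate: float = 0.5) -> dict:
    """One TF whose causal binding is confined to a promoter sub-region."""
    rng = np.random.default_rng([seed, 5])
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    tss = synthetic.make_tss_table(gene_ids, spacing=3000)
    heights = np.exp(1.0 + 0.8 * rng.standard_normal(n_genes)) + 2.0
    track = synthetic.generate_coverage_track(
        tss,
        {g: [causal_center] for g in gene_ids},
        {g: [heights[i]] for i, g in enumerate(gene_ids)},
        background_rate=background_rate,
        peak_width=causal_width,
        rng=np.random.default_rng([seed, 6]),
    )
    signal = heights * causal_width
    y = pd.Series(signal + rng.normal(0, 0.1 * signal.std(), n_genes),
                  index=gene_ids, name="expression")
    return {"track": track, "tss": tss, "y": y}
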