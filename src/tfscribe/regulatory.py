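"""Statistics layered on the fitted binding->expression models.

Covers: comparison of binding representations by prediction correlation,
signed TF-importance scores, TF-TF binding collinearity with product-moment
significance, substitution testing of collinear TFs in variable selection,
additive-vs-multiplicative pair interactions, promoter segment scans,
symmetric region-extension scans, and detection of coordinated TF trios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chip import CoverageTrack, TSSRecord
from .mars import FitConfig, MarsModel, cv_select, fit_mars, ols_fit, relative_importance


@dataclass(frozen=True)
class ImportanceScore:
    """Signed TF importance: R2 x relative importance x sign.

    Positive = activation, negative = repression; |score| <= model R2.
    """

    tf: str
    condition: str
    cluster: str
    score: float


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlation of TF binding with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str, float, float]]:
        out = []
        tfs = list(self.r.columns)
        for i, a in enumerate(tfs):
            for b in tfs[i + 1 :]:
                pv = self.p.loc[a, b]
                if np.isfinite(pv) and pv < alpha:
                    out.append((a, b, float(self.r.loc[a, b]), float(pv)))
        return out

    def stars(self, a: str, b: str) -> str:
        pv = self.p.loc[a, b]
        if not np.isfinite(pv):
            return ""
        return "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""


@dataclass(frozen=True)
class InteractionResult:
    """Additive vs multiplicative pair regression comparison.

    improvement_ratio = (delta_r2 + r2_additive) / r2_additive; the pair is
    flagged when the additive model already explains >10% of variance and the
    multiplicative term improves it by at least 10%.
    """

    tf_a: str
    tf_b: str
    r2_additive: float
    r2_multiplicative: float

    @property
    def delta_r2(self) -> float:
        return max(self.r2_multiplicative - self.r2_additive, 0.0)

    @property
    def improvement_ratio(self) -> float:
        if self.r2_additive <= 0:
            return np.inf if self.delta_r2 > 0 else 1.0
        return (self.delta_r2 + self.r2_additive) / self.r2_additive

    @property
    def flagged(self) -> bool:
        # tiny slack so the >= 1.10 boundary is robust to float rounding
        return self.r2_additive > 0.1 and self.improvement_ratio >= 1.10 - 1e-12


# ---------------------------------------------------------------------------
# Representation comparison
# ---------------------------------------------------------------------------

def prediction_correlation(X: pd.DataFrame, y: pd.Series, config: FitConfig,
                           cv: bool = False, seed: int | None = None, **cv_kw) -> float:
    """Pearson correlation between model predictions and observed response."""
    model = cv_select(X, y, config, seed=seed, **cv_kw) if cv else fit_mars(X, y, config)
    pred = model.predict(X)
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


def compare_representations(
    binding_by_representation: Mapping[str, Mapping[str, pd.DataFrame]],
    fpkm: pd.DataFrame,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Prediction correlation per representation and condition, plus the mean.

    Non-MARS representations are fitted with linear-only selection so the
    comparisons differ only in the data, not the selection machinery; the
    ``promoter_sum_mars`` entry (added automatically when a ``promoter_sum``
    representation is present) allows splines.
    """
    config = config or FitConfig()
    reps = dict(binding_by_representation)
    rows = {}
    for rep, by_cond in reps.items():
        rows[rep] = {}
        for cond in fpkm.columns:
            if cond not in by_cond:
                warnings.warn(f"representation {rep} missing condition {cond}; omitted")
                rows[rep][cond] = np.nan
                continue
            X = by_cond[cond]
            y = fpkm.loc[X.index, cond]
            lin = FitConfig(**{**config.__dict__, "linear_only": True})
            rows[rep][cond] = prediction_correlation(X, y, lin)
        if rep == "promoter_sum":
            rows["promoter_sum_mars"] = {
                cond: prediction_correlation(by_cond[cond], fpkm.loc[by_cond[cond].index, cond], config)
                for cond in fpkm.columns
                if cond in by_cond
            }
    out = pd.DataFrame(rows).T
    out["mean"] = out.mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# TF importance
# ---------------------------------------------------------------------------

def _net_slope(model: MarsModel, X: np.ndarray, variable: int) -> float:
    """Sum over the variable's terms of coefficient x average basis slope."""
    x = X[:, variable]
    net = 0.0
    for t in model.terms:
        if t.variable != variable:
            continue
        if t.form == "linear":
            net += t.coefficient
        elif t.form == "hinge_plus":
            net += t.coefficient * float(np.mean(x > t.knot))
        else:  # hinge_minus: d/dx max(0, t - x) = -1 below the knot
            net += -t.coefficient * float(np.mean(x < t.knot))
    return net


def tf_importance(
    model: MarsModel, X: pd.DataFrame, y: pd.Series,
    condition: str = "", cluster: str = "all", penalty: float = 2.0,
) -> list[ImportanceScore]:
    """Signed importance per selected TF: R2 x relative importance x sign."""
    if not model.terms:
        return []
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = model.var_names or [f"x{v}" for v in range(Xa.shape[1])]
    rel = relative_importance(model, Xa, y, penalty=penalty)
    out = []
    for v, w in sorted(rel.items()):
        net = _net_slope(model, Xa, v)
        if net == 0.0:
            warnings.warn(f"zero net slope for {names[v]}; using largest-coefficient term sign")
            terms_v = [t for t in model.terms if t.variable == v]
            t = max(terms_v, key=lambda t: abs(t.coefficient))
            net = t.coefficient * (-1.0 if t.form == "hinge_minus" else 1.0)
        sign = 1.0 if net > 0 else -1.0
        out.append(ImportanceScore(tf=names[v], condition=condition, cluster=cluster,
                                   score=float(model.r2 * w * sign)))
    return out


# ---------------------------------------------------------------------------
# Collinearity and substitution
# ---------------------------------------------------------------------------

def collinearity(X: pd.DataFrame, genes: Sequence[str] | None = None) -> CollinearityReport:
    """Pairwise Pearson r between TF binding columns with two-sided p-values
    from the product-moment t reference, t = r*sqrt((n-2)/(1-r^2))."""
    sub = X.loc[list(genes)] if genes is not None else X
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 genes for correlation significance")
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(vals, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rr), np.nan, np.where(np.abs(rr) >= 1.0, 0.0, p))
    np.fill_diagonal(p, 0.0)
    cols = list(X.columns)
    return CollinearityReport(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


def substitution_test(
    X: pd.DataFrame,
    y: pd.Series,
    base_model: MarsModel,
    report: CollinearityReport,
    config: FitConfig | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    folds: int = 10,
    repeats: int = 5,
    retain_frac: float = 0.5,
) -> list[tuple[str, str]]:
    """Collinear-substitution test: can a selected TF be replaced?

    For each TF t in the base selection and each TF u with significantly
    correlated binding (p < alpha) not already selected, refit the selection
    with t removed from the candidates; (t, u) is substitutable if u enters
    the refit's selection.
    """
    config = config or FitConfig()
    selected = set(base_model.selected_names)
    pairs = []
    for t in sorted(selected):
        partners = [
            u for u in X.columns
            if u != t and u not in selected
            and np.isfinite(report.p.loc[t, u]) and report.p.loc[t, u] < alpha
        ]
        if not partners:
            continue
        X_wo = X.drop(columns=[t])
        refit = cv_select(X_wo, y, config, folds=folds, repeats=repeats,
                          retain_frac=retain_frac, seed=seed)
        newly = set(refit.selected_names)
        pairs.extend((t, u) for u in partners if u in newly)
    return pairs


def interaction_scan(
    X: pd.DataFrame,
    y: pd.Series,
    report: CollinearityReport,
    alpha: float = 0.05,
    center: bool = False,
) -> list[InteractionResult]:
    """Additive vs multiplicative OLS for every significantly correlated pair.

    The product term uses raw (uncentered) signals by default, matching a
    literal multiplication of TF binding; ``center=True`` is available for
    diagnostics.
    """
    out = []
    yv = np.asarray(y, dtype=float)
    for a, b, _, _ in report.significant_pairs(alpha):
        xa = X[a].to_numpy(dtype=float)
        xb = X[b].to_numpy(dtype=float)
        if center:
            xa, xb = xa - xa.mean(), xb - xb.mean()
        _, r2_add, _ = ols_fit(np.column_stack([xa, xb]), yv)
        _, r2_mul, _ = ols_fit(np.column_stack([xa, xb, xa * xb]), yv)
        out.append(InteractionResult(tf_a=a, tf_b=b, r2_additive=float(r2_add),
                                     r2_multiplicative=float(max(r2_mul, r2_add))))
    return out


# ---------------------------------------------------------------------------
# Promoter segment and region scans
# ---------------------------------------------------------------------------

def segment_signal(
    track: CoverageTrack, tss: Sequence[TSSRecord], rel_start: int, rel_end: int,
) -> pd.Series:
    """Coverage summed over [rel_start, rel_end] relative to each TSS in gene
    orientation (negative = upstream; mirrored for minus-strand genes)."""
    out = {}
    for rec in tss:
        vec = track.coverage.get(rec.chrom)
        if vec is None:
            out[rec.gene_id] = np.nan
            continue
        if rec.strand == "+":
            lo, hi = rec.tss + rel_start, rec.tss + rel_end
        else:
            lo, hi = rec.tss - rel_end, rec.tss - rel_start
        lo, hi = max(lo, 1), min(hi, len(vec))
        out[rec.gene_id] = float(vec[lo - 1 : hi].sum()) if hi >= lo else 0.0
    return pd.Series(out)


def tile_segments(rel_range: tuple[int, int] = (-1000, 1000), segment_bp: int = 75) -> list[tuple[int, int]]:
    """Tile [start, end] with fixed-width segments, dropping a final partial."""
    start, end = rel_range
    segs = []
    pos = start
    while pos + segment_bp - 1 <= end:
        segs.append((pos, pos + segment_bp - 1))
        pos += segment_bp
    return segs


def segment_scan(
    tracks_by_tf: Mapping[str, CoverageTrack],
    tss: Sequence[TSSRecord],
    y: pd.Series,
    segment_bp: int = 75,
    rel_range: tuple[int, int] = (-1000, 1000),
) -> pd.DataFrame:
    """Signed explanatory power (r^2 x sign of slope) of each TF's binding in
    each promoter segment, from simple per-segment OLS against expression.
    Rows are indexed by segment midpoint."""
    segs = tile_segments(rel_range, segment_bp)
    genes = list(y.index)
    yv = y.to_numpy(dtype=float)
    data = {}
    for tf, track in tracks_by_tf.items():
        col = []
        for lo, hi in segs:
            x = segment_signal(track, tss, lo, hi).reindex(genes).to_numpy(dtype=float)
            if np.nanstd(x) == 0 or np.isnan(x).all():
                col.append(0.0)
                continue
            coef, r2, _ = ols_fit(x[:, None], yv)
            col.append(float(r2 * np.sign(coef[1])) if coef[1] != 0 else 0.0)
        data[tf] = col
    midpoints = [(lo + hi) / 2.0 for lo, hi in segs]
    return pd.DataFrame(data, index=pd.Index(midpoints, name="segment_midpoint"))


def region_extension_scan(
    tracks_by_tf: Mapping[str, CoverageTrack],
    tss: Sequence[TSSRecord],
    y: pd.Series,
    step_bp: int = 50,
    max_halfwidth: int = 1000,
    config: FitConfig | None = None,
) -> tuple[pd.Series, int]:
    """R^2 of a selected multiple regression on promoter sums in symmetric
    windows of growing half-width; returns the curve and the smallest
    half-width within 1% of its maximum."""
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    config = config or FitConfig(linear_only=True)
    genes = list(y.index)
    halfwidths = list(range(step_bp, max_halfwidth + 1, step_bp))
    r2s = []
    for hw in halfwidths:
        X = pd.DataFrame(
            {tf: segment_signal(track, tss, -hw, hw).reindex(genes) for tf, track in tracks_by_tf.items()}
        )
        model = fit_mars(X, y, config)
        r2s.append(model.r2)
    curve = pd.Series(r2s, index=pd.Index(halfwidths, name="halfwidth_bp"), name="r2")
    best = curve.max()
    plateau = int(curve.index[curve >= best * 0.99][0])
    return curve, plateau


# ---------------------------------------------------------------------------
# Coordinated trio detection
# ---------------------------------------------------------------------------

def trio_detection(X_window: pd.DataFrame, y: pd.Series, seed: int | None = 0,
                   min_trio_corr: float = 0.2, be_alpha: float = 0.01) -> dict:
    """Split genes into two groups on the joint standardized profile of three
    TFs' window binding plus expression; report per-group trio binding
    inter-correlation and binding-vs-expression correlation.

    A "coordinated repression" call requires substantial positive mean
    pairwise binding correlation among the trio (``> min_trio_corr``) and a
    significantly negative correlation between mean binding and expression
    (product-moment p ``< be_alpha``) within the high-binding group; the
    significance requirement keeps selection-induced correlations in random
    data from producing spurious calls.
    """
    from sklearn.cluster import KMeans

    if X_window.shape[1] != 3:
        raise ValueError("trio detection requires exactly 3 TF columns")
    if len(X_window) < 10:
        raise ValueError("need at least 10 genes for trio detection")
    joint = pd.concat([X_window, y.rename("expression")], axis=1).dropna()
    Z = (joint - joint.mean()) / joint.std(ddof=0).replace(0, 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z.to_numpy())
    labels = pd.Series(km.labels_, index=joint.index)

    groups = {}
    mean_binding_z = Z.iloc[:, :3].mean(axis=1)
    high_group = int(mean_binding_z.groupby(labels).mean().idxmax())
    for g in (0, 1):
        idx = labels[labels == g].index
        sub = joint.loc[idx]
        bcols = sub.iloc[:, :3]
        corrs = bcols.corr().to_numpy()
        iu = np.triu_indices(3, k=1)
        trio_corr = float(np.nanmean(corrs[iu]))
        mean_b = bcols.mean(axis=1)
        if mean_b.std() == 0 or sub["expression"].std() == 0 or len(sub) < 3:
            be_corr, be_p = 0.0, 1.0
        else:
            res = stats.pearsonr(mean_b, sub["expression"])
            be_corr, be_p = float(res.statistic), float(res.pvalue)
        groups[g] = {
            "genes": list(idx),
            "n": len(idx),
            "trio_binding_correlation": trio_corr,
            "binding_expression_correlation": be_corr,
            "binding_expression_p": be_p,
            "high_binding": g == high_group,
        }
    hb = groups[high_group]
    call = (
        hb["trio_binding_correlation"] > min_trio_corr
        and hb["binding_expression_correlation"] < 0
        and hb["binding_expression_p"] < be_alpha
    )
    return {"groups": groups, "coordinated_repression": bool(call)}
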