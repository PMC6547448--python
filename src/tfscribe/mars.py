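"""Multivariate adaptive regression splines (MARS), additive degree-1.

The model is ``y = b0 + sum_j b_j * B_j(x)`` where each basis term ``B_j`` is
either a plain linear term in one predictor or a hinge ``max(0, x - t)`` /
``max(0, t - x)`` with knot ``t``.  Terms are grown greedily (forward pass,
hinges added as mirrored pairs at observed-value knots respecting an endspan
constraint) and pruned backward under the generalized cross-validation score

    GCV(M) = (RSS/n) / (1 - C(M)/n)^2,   C(M) = #coefficients + penalty * #knots,

the standard smoothing parameterization for additive MARS.  ``linear_only``
mode restricts the basis to linear terms, which reduces the procedure to
best-subset-flavoured variable selection for ordinary multiple regression.

``cv_select`` stabilizes the structure by refitting across repeated k-fold
splits and retaining only predictors (and hinge forms) that recur in a
majority of fits, then refitting the retained structure on all data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

_EPS = 1e-12


@dataclass(frozen=True)
class BasisTerm:
    """One basis function: a linear or hinge transform of a single predictor."""

    variable: int
    form: str  # "linear" | "hinge_plus" | "hinge_minus"
    knot: float | None = None
    coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in {"linear", "hinge_plus", "hinge_minus"}:
            raise ValueError(f"unknown form {self.form!r}")
        if (self.knot is None) != (self.form == "linear"):
            raise ValueError("knot must be present iff the term is a hinge")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.form == "linear":
            return x
        if self.form == "hinge_plus":
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)

    def describe(self, names: Sequence[str] | None = None) -> str:
        name = names[self.variable] if names else f"x{self.variable}"
        if self.form == "linear":
            return name
        if self.form == "hinge_plus":
            return f"h({name} - {self.knot:g})"
        return f"h({self.knot:g} - {name})"


@dataclass
class FitConfig:
    """Knobs of the MARS fit.

    endspan: minimum ordered observations between any knot and either data
        extreme (suppresses boundary knots); penalty: GCV cost per knot;
    max_terms: forward-pass cap, default min(21, n // 10) resolved at fit
        time; max_knot_candidates: at most this many evenly spaced admissible
        observed values are tried as knots per variable.
    """

    max_terms: int | None = None
    endspan: int = 100
    penalty: float = 2.0
    linear_only: bool = False
    max_knot_candidates: int = 64
    rel_tol: float = 1e-6
    prune_exhaustive_limit: int = 8

    def __post_init__(self) -> None:
        if self.endspan < 0 or self.penalty < 0:
            raise ValueError("endspan and penalty must be >= 0")
        if self.max_terms is not None and self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")

    def resolved_max_terms(self, n: int) -> int:
        return self.max_terms if self.max_terms is not None else max(1, min(21, n // 10))


@dataclass
class MarsModel:
    """A fitted additive spline model."""

    intercept: float
    terms: list[BasisTerm]
    gcv: float
    r2: float
    deletion_trace: list[float] = field(default_factory=list)
    var_names: list[str] | None = None

    @property
    def selected_tfs(self) -> set[int]:
        return {t.variable for t in self.terms}

    @property
    def selected_names(self) -> list[str]:
        if self.var_names is None:
            return [f"x{v}" for v in sorted(self.selected_tfs)]
        return [self.var_names[v] for v in sorted(self.selected_tfs)]

    def basis_matrix(self, X: np.ndarray) -> np.ndarray:
        X = _as_array(X)
        if not self.terms:
            return np.empty((X.shape[0], 0))
        return np.column_stack([t.evaluate(X[:, t.variable]) for t in self.terms])

    def predict(self, X) -> np.ndarray:
        X = _as_array(X)
        out = np.full(X.shape[0], self.intercept)
        for t in self.terms:
            out += t.coefficient * t.evaluate(X[:, t.variable])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "gcv": self.gcv,
                "r2": self.r2,
                "deletion_trace": self.deletion_trace,
                "var_names": self.var_names,
                "terms": [
                    {
                        "variable": t.variable,
                        "name": (self.var_names[t.variable] if self.var_names else f"x{t.variable}"),
                        "form": t.form,
                        "knot": t.knot,
                        "coefficient": t.coefficient,
                    }
                    for t in self.terms
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MarsModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            terms=[
                BasisTerm(variable=t["variable"], form=t["form"], knot=t["knot"], coefficient=t["coefficient"])
                for t in d["terms"]
            ],
            gcv=d["gcv"],
            r2=d["r2"],
            deletion_trace=d.get("deletion_trace", []),
            var_names=d.get("var_names"),
        )


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _names_of(X) -> list[str] | None:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return None


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def ols_fit(X, y, add_intercept: bool = True):
    """Least-squares fit; returns (coefficients, r2, residuals).

    With ``add_intercept`` the first coefficient is the intercept.  A
    rank-deficient design yields the minimum-norm solution with a warning.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    D = np.column_stack([np.ones(len(y)), X]) if add_intercept else X
    if np.isnan(D).any() or np.isnan(y).any():
        raise ValueError("missing values in regression inputs")
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn("rank-deficient design: returning minimum-norm solution")
    resid = y - D @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef, r2, resid


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def knot_candidates(x: np.ndarray, endspan: int, cap: int | None = None) -> np.ndarray:
    """Admissible knots: observed values with >= endspan observations strictly
    below and strictly above, thinned to at most ``cap`` evenly spaced values."""
    xs = np.sort(np.unique(x))
    below = np.searchsorted(np.sort(x), xs, side="left")
    above = len(x) - np.searchsorted(np.sort(x), xs, side="right")
    ok = xs[(below >= endspan) & (above >= endspan)]
    if cap is not None and len(ok) > cap:
        idx = np.unique(np.linspace(0, len(ok) - 1, cap).round().astype(int))
        ok = ok[idx]
    return ok


class _ForwardState:
    """Incremental orthonormal basis for fast RSS-reduction screening.

    Caches the projections of every candidate column onto the current basis so
    each forward step only projects candidates onto the newly added direction.
    """

    def __init__(self, n: int, cand_mats: list[np.ndarray]):
        self.Q = np.ones((n, 1)) / np.sqrt(n)
        self.cand_mats = cand_mats
        # per candidate matrix: rows of Q^T @ C, grown as columns are added
        self.P: list[list[np.ndarray]] = [[self.Q[:, 0] @ C] if C.size else [] for C in cand_mats]

    def projections(self, v: int) -> np.ndarray:
        return np.array(self.P[v]) if self.P[v] else np.empty((0, 0))

    def add_column(self, col: np.ndarray) -> bool:
        u = col - self.Q @ (self.Q.T @ col)
        u = u - self.Q @ (self.Q.T @ u)  # reorthogonalize
        norm = np.linalg.norm(u)
        if norm < 1e-9 * max(1.0, np.linalg.norm(col)):
            return False
        q = u / norm
        self.Q = np.column_stack([self.Q, q])
        for v, C in enumerate(self.cand_mats):
            if C.size:
                self.P[v].append(q @ C)
        return True

    def residual(self, y: np.ndarray) -> np.ndarray:
        return y - self.Q @ (self.Q.T @ y)


def mars_forward(X, y, config: FitConfig | None = None) -> list[BasisTerm]:
    """Greedy forward pass: repeatedly add the linear term or mirrored hinge
    pair that most reduces RSS, until ``max_terms`` or the relative RSS
    improvement falls below ``rel_tol``.  Returns unfitted candidate terms."""
    config = config or FitConfig()
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    max_terms = config.resolved_max_terms(n)

    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= _EPS:
        return []

    # per-variable candidate hinge bases, precomputed once
    cand: list[dict] = []
    for v in range(p):
        x = Xa[:, v]
        knots = (
            np.empty(0)
            if config.linear_only
            else knot_candidates(x, config.endspan, config.max_knot_candidates)
        )
        Hp = np.maximum(0.0, x[:, None] - knots[None, :]) if len(knots) else np.empty((n, 0))
        Hm = np.maximum(0.0, knots[None, :] - x[:, None]) if len(knots) else np.empty((n, 0))
        cand.append(
            {
                "x": x,
                "knots": knots,
                "Hp": Hp,
                "Hm": Hm,
                "C": np.hstack([Hp, Hm, x[:, None]]),
                "pp": (Hp**2).sum(axis=0),
                "mm": (Hm**2).sum(axis=0),
                "pm": (Hp * Hm).sum(axis=0),
                "xx": float(x @ x),
            }
        )

    state = _ForwardState(n, [c["C"] for c in cand])
    terms: list[BasisTerm] = []
    has_linear = set()
    used_knots: set[tuple[int, float]] = set()

    while len(terms) < max_terms:
        r = state.residual(y)
        rss = float(r @ r)
        if rss <= _EPS * tss:
            break
        best = None  # (reduction, kind, var, knot)
        for v in range(p):
            c = cand[v]
            K = len(c["knots"])
            P_all = state.projections(v)  # m x (2K + 1), last column is x
            if v not in has_linear and c["xx"] > 0:
                q = P_all[:, -1]
                denom = c["xx"] - float(q @ q)
                if denom > _EPS * c["xx"]:
                    red = float(c["x"] @ r) ** 2 / denom
                    if best is None or red > best[0] * (1 + 1e-12):
                        best = (red, "linear", v, None)
            if K:
                Pp, Pm = P_all[:, :K], P_all[:, K : 2 * K]
                app = c["pp"] - (Pp**2).sum(axis=0)
                amm = c["mm"] - (Pm**2).sum(axis=0)
                apm = c["pm"] - (Pp * Pm).sum(axis=0)
                bp = c["Hp"].T @ r
                bm = c["Hm"].T @ r
                scale = np.maximum(c["pp"], c["mm"]) + _EPS
                det = app * amm - apm**2
                with np.errstate(divide="ignore", invalid="ignore"):
                    red_pair = (amm * bp**2 - 2 * apm * bp * bm + app * bm**2) / det
                    red_p = np.where(app > _EPS * scale, bp**2 / app, 0.0)
                    red_m = np.where(amm > _EPS * scale, bm**2 / amm, 0.0)
                red = np.where(det > _EPS * scale**2, red_pair, np.maximum(red_p, red_m))
                red = np.nan_to_num(red, nan=0.0, posinf=0.0, neginf=0.0)
                for j in np.argsort(-red, kind="stable"):
                    if (v, float(c["knots"][j])) in used_knots:
                        continue
                    if best is None or red[j] > best[0] * (1 + 1e-12):
                        best = (float(red[j]), "hinge", v, float(c["knots"][j]))
                    break
        if best is None or best[0] <= config.rel_tol * rss:
            break
        _, kind, v, knot = best
        if kind == "linear":
            terms.append(BasisTerm(variable=v, form="linear"))
            has_linear.add(v)
            state.add_column(cand[v]["x"])
        else:
            used_knots.add((v, knot))
            x = cand[v]["x"]
            for form, col in (
                ("hinge_plus", np.maximum(0.0, x - knot)),
                ("hinge_minus", np.maximum(0.0, knot - x)),
            ):
                if len(terms) < max_terms and state.add_column(col):
                    terms.append(BasisTerm(variable=v, form=form, knot=knot))
    return terms


# ---------------------------------------------------------------------------
# GCV and backward pruning
# ---------------------------------------------------------------------------

def n_knots(terms: Sequence[BasisTerm]) -> int:
    """Distinct (variable, knot) pairs among hinge terms (a mirrored pair = 1)."""
    return len({(t.variable, t.knot) for t in terms if t.form != "linear"})


def gcv_score(rss: float, n: int, n_coefficients: int, n_knots_: int, penalty: float) -> float:
    """GCV(M) = (RSS/n) / (1 - C/n)^2 with C = #coefficients + penalty * #knots."""
    c = n_coefficients + penalty * n_knots_
    if c >= n:
        return np.inf
    return (rss / n) / (1.0 - c / n) ** 2


def _fit_subset(terms: list[BasisTerm], Xa: np.ndarray, y: np.ndarray, penalty: float):
    n = len(y)
    if terms:
        B = np.column_stack([t.evaluate(Xa[:, t.variable]) for t in terms])
        coef, r2, resid = ols_fit(B, y)
    else:
        coef = np.array([y.mean()])
        resid = y - y.mean()
        r2 = 0.0
    rss = float(resid @ resid)
    gcv = gcv_score(rss, n, len(terms) + 1, n_knots(terms), penalty)
    return coef, r2, rss, gcv


def mars_prune(terms: Sequence[BasisTerm], X, y, config: FitConfig | None = None) -> MarsModel:
    """Backward deletion under GCV with refit at every step.

    At each step the term whose removal gives the lowest GCV is deleted; the
    returned model is the one along the deletion path (including the full and
    intercept-only models) with minimal GCV.  Model sizes with C(M) >= n are
    excluded from consideration with a warning.

    For small candidate sets (``len(terms) <= config.prune_exhaustive_limit``)
    all term subsets are enumerated and the global GCV minimizer is returned,
    which removes the occasional suboptimality of the greedy path at
    negligible cost; the deletion trace still records the greedy path.
    """
    config = config or FitConfig()
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    names = _names_of(X)

    current = list(terms)
    _, r2, rss, gcv = _fit_subset(current, Xa, y, config.penalty)
    if not np.isfinite(gcv):
        warnings.warn(f"model with {len(current)} terms has C(M) >= n; excluded from GCV path")
    trace = [gcv]
    best_subset, best_gcv = list(current), gcv
    while current:
        step_best = None
        for i in range(len(current)):
            subset = current[:i] + current[i + 1 :]
            _, _, _, g = _fit_subset(subset, Xa, y, config.penalty)
            if step_best is None or g < step_best[0]:
                step_best = (g, subset)
        g, current = step_best
        trace.append(g)
        if g < best_gcv:
            best_gcv, best_subset = g, list(current)

    if len(terms) <= config.prune_exhaustive_limit:
        from itertools import combinations

        for size in range(len(terms) + 1):
            for subset in combinations(terms, size):
                _, _, _, g = _fit_subset(list(subset), Xa, y, config.penalty)
                if g < best_gcv:
                    best_gcv, best_subset = g, list(subset)

    coef, r2, rss, gcv = _fit_subset(best_subset, Xa, y, config.penalty)
    fitted = [
        BasisTerm(variable=t.variable, form=t.form, knot=t.knot, coefficient=float(coef[i + 1]))
        for i, t in enumerate(best_subset)
    ]
    return MarsModel(
        intercept=float(coef[0]),
        terms=fitted,
        gcv=float(gcv),
        r2=float(max(r2, 0.0)),
        deletion_trace=[float(g) for g in trace],
        var_names=names,
    )


def fit_mars(X, y, config: FitConfig | None = None) -> MarsModel:
    """Forward pass followed by GCV backward pruning."""
    config = config or FitConfig()
    return mars_prune(mars_forward(X, y, config), X, y, config)


# ---------------------------------------------------------------------------
# Cross-validated structure selection
# ---------------------------------------------------------------------------

def cv_select(
    X,
    y,
    config: FitConfig | None = None,
    folds: int = 10,
    repeats: int = 5,
    retain_frac: float = 0.5,
    seed: int | None = None,
    significance_alpha: float = 0.01,
) -> MarsModel:
    """Stabilized MARS: keep only variables/hinges recurring across CV refits.

    A MARS model is fitted on each fold-complement of ``repeats`` shuffled
    k-fold splits.  A variable is retained if selected in more than
    ``retain_frac`` of the fits; its hinge form is retained if a hinge on it
    appeared in more than ``retain_frac`` of the fits (knot = median of the
    per-fit knots).  The retained structure is refitted on all data.

    Fold refits share the data, so a chance correlation in one dataset is
    selected consistently and frequency alone cannot reject it; the final
    refit therefore also drops any variable whose terms are jointly
    insignificant (partial F-test at ``significance_alpha``), keeping only
    robustly supported predictors.  Set ``significance_alpha=1`` to disable.
    """
    config = config or FitConfig()
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    names = _names_of(X)
    if n < 2 * folds:
        raise ValueError(f"need n >= 2*folds, got n={n}, folds={folds}")
    rng = np.random.default_rng(seed)

    n_fits = 0
    sel_count = np.zeros(p)
    hinge_count = np.zeros(p)
    knots_seen: dict[int, list[float]] = {v: [] for v in range(p)}
    for _ in range(repeats):
        perm = rng.permutation(n)
        for fold in range(folds):
            train = np.sort(perm[np.arange(n) % folds != fold])
            m = fit_mars(Xa[train], y[train], config)
            n_fits += 1
            for v in m.selected_tfs:
                sel_count[v] += 1
            hinged = {t.variable for t in m.terms if t.form != "linear"}
            for v in hinged:
                hinge_count[v] += 1
                knots_seen[v].extend(t.knot for t in m.terms if t.variable == v and t.knot is not None)

    retained = [v for v in range(p) if sel_count[v] / n_fits > retain_frac]
    if not retained:
        warnings.warn("no variable passed CV retention; returning intercept-only model")
        return mars_prune([], Xa if names is None else X, y, config)

    final_terms: list[BasisTerm] = []
    for v in retained:
        if not config.linear_only and hinge_count[v] / n_fits > retain_frac:
            knot = float(np.median(knots_seen[v]))
            final_terms.append(BasisTerm(variable=v, form="hinge_plus", knot=knot))
            final_terms.append(BasisTerm(variable=v, form="hinge_minus", knot=knot))
        else:
            final_terms.append(BasisTerm(variable=v, form="linear"))

    # drop hinge sides that only add GCV, but never a retained variable
    final_terms = _prune_sides(final_terms, Xa, y, config.penalty)
    final_terms = _drop_insignificant_variables(final_terms, Xa, y, significance_alpha)
    if not final_terms:
        warnings.warn("no retained variable is jointly significant; intercept-only model")
        return mars_prune([], Xa if names is None else X, y, config)

    coef, r2, rss, gcv = _fit_subset(final_terms, Xa, y, config.penalty)
    fitted = [
        BasisTerm(variable=t.variable, form=t.form, knot=t.knot, coefficient=float(coef[i + 1]))
        for i, t in enumerate(final_terms)
    ]
    return MarsModel(
        intercept=float(coef[0]),
        terms=fitted,
        gcv=float(gcv),
        r2=float(max(r2, 0.0)),
        deletion_trace=[float(gcv)],
        var_names=names,
    )


def _drop_insignificant_variables(
    terms: list[BasisTerm], Xa: np.ndarray, y: np.ndarray, alpha: float
) -> list[BasisTerm]:
    """Backward elimination by partial F-test: repeatedly drop the variable
    whose terms contribute least, until every variable is significant."""
    from scipy import stats as _stats

    if alpha >= 1:
        return terms
    current = list(terms)
    n = len(y)
    while current:
        _, _, rss_full, _ = _fit_subset(current, Xa, y, 0.0)
        df_resid = n - (len(current) + 1)
        if df_resid <= 0 or rss_full <= 0:
            break
        worst = None  # (p_value, variable)
        for v in sorted({t.variable for t in current}):
            reduced = [t for t in current if t.variable != v]
            _, _, rss_red, _ = _fit_subset(reduced, Xa, y, 0.0)
            q = len(current) - len(reduced)
            f = ((rss_red - rss_full) / q) / (rss_full / df_resid)
            p = float(_stats.f.sf(max(f, 0.0), q, df_resid))
            if worst is None or p > worst[0]:
                worst = (p, v)
        if worst is None or worst[0] <= alpha:
            break
        current = [t for t in current if t.variable != worst[1]]
    return current


def _prune_sides(terms: list[BasisTerm], Xa: np.ndarray, y: np.ndarray, penalty: float) -> list[BasisTerm]:
    """Backward GCV deletion restricted to hinge terms whose variable keeps
    at least one other term, so CV-retained variables stay in the model."""
    current = list(terms)
    _, _, _, best = _fit_subset(current, Xa, y, penalty)
    improved = True
    while improved:
        improved = False
        for i, t in enumerate(current):
            if t.form == "linear":
                continue
            rest = current[:i] + current[i + 1 :]
            if not any(u.variable == t.variable for u in rest):
                continue
            _, _, _, g = _fit_subset(rest, Xa, y, penalty)
            if g < best:
                best, current, improved = g, rest, True
                break
    return current


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def relative_importance(model: MarsModel, X, y, penalty: float = 2.0) -> dict[int, float]:
    """Per-variable weight in [0, 1] summing to 1: the GCV increase when all
    of a variable's terms are removed (with refit), normalized over the
    selected variables."""
    if not model.terms:
        raise ValueError("model has no selected variables")
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    _, _, _, base_gcv = _fit_subset(list(model.terms), Xa, y, penalty)
    raw = {}
    for v in sorted(model.selected_tfs):
        subset = [t for t in model.terms if t.variable != v]
        _, _, _, g = _fit_subset(subset, Xa, y, penalty)
        raw[v] = max(float(g - base_gcv), 0.0)
    total = sum(raw.values())
    if total <= 0:
        k = len(raw)
        return {v: 1.0 / k for v in raw}
    return {v: r / total for v, r in raw.items()}
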