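"""Historical PLSR soft sensor for volumetric product activity.

A partial-least-squares regression on the batch-wise-unfolded process history
(plus the design factors) predicts the analytically costly volumetric enzyme
activity.  Model selection is fully cross-validated: a greedy forward
variable-selection routine adds one (variable, time) candidate at a time and
monitors the mean 10-fold cross-validation error; the error metric is the
target-normalized RMSECV

    RMSECV = sqrt( mean_i ((y_pred_i - y_act_i) / y_act_i)^2 )

reported as a fraction (x100 for percent).  A history sweep repeats the whole
selection at increasing history horizons to locate the earliest time at which
the process outcome is predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import UnfoldedMatrix

__all__ = [
    "PLSRegressor",
    "CVResult",
    "SelectionResult",
    "HistorySweep",
    "fit_plsr",
    "rmsecv",
    "cross_validate",
    "forward_select_variables",
    "build_candidates",
    "history_sweep",
]


class PLSRegressor:
    """NIPALS partial least squares regression for a single response.

    X columns are autoscaled and y centered internally.  For a univariate
    response the NIPALS weight vector has the closed form w = X'y/||X'y||
    per component, followed by deflation of X; models for all component
    counts 1..n_components are nested and available at prediction time
    (``predict(..., n_components=k)``), which makes inner component-count
    selection cheap.
    """

    _param_names = ("n_components",)

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **p):
        for k, v in p.items():
            if k != "n_components":
                raise ValueError(f"invalid parameter {k!r}")
            self.n_components = v
        return self

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if n != len(y):
            raise ValueError("X and y length mismatch")
        if n < self.n_components + 2:
            raise ValueError("need rows >= n_components + 2")
        if np.ptp(y) == 0.0:
            raise ValueError("zero-variance response")
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.x_sd_ = np.where(sd <= 1e-12, 1.0, sd)
        self.y_mean_ = float(y.mean())
        Xw = (X - self.x_mean_) / self.x_sd_
        yw = y - self.y_mean_
        k_max = min(self.n_components, p, n - 1)
        W = np.zeros((p, k_max))
        P = np.zeros((p, k_max))
        Q = np.zeros(k_max)
        k_eff = 0
        for k in range(k_max):
            w = Xw.T @ yw
            nw = np.linalg.norm(w)
            if nw <= 1e-12:
                break  # residual response orthogonal to X
            w /= nw
            t = Xw @ w
            tt = float(t @ t)
            if tt <= 1e-12:
                break
            p_load = Xw.T @ t / tt
            q = float(yw @ t / tt)
            Xw = Xw - np.outer(t, p_load)
            yw = yw - q * t
            W[:, k] = w
            P[:, k] = p_load
            Q[k] = q
            k_eff += 1
        if k_eff == 0:
            raise ValueError("no PLS component could be extracted")
        self.weights_ = W[:, :k_eff]
        self.loadings_ = P[:, :k_eff]
        self.y_loadings_ = Q[:k_eff]
        self.n_components_ = k_eff
        # rotation R maps scaled X directly to scores: T = Xw R
        self.rotation_ = self.weights_ @ np.linalg.inv(
            np.triu(self.loadings_.T @ self.weights_)
        )
        self.coef_ = self.rotation_ @ self.y_loadings_
        return self

    def _scale(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.x_mean_) / self.x_sd_

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        Xw = self._scale(X)
        if n_components is None or n_components >= self.n_components_:
            return Xw @ self.coef_ + self.y_mean_
        k = max(1, n_components)
        coef_k = self.rotation_[:, :k] @ self.y_loadings_[:k]
        return Xw @ coef_k + self.y_mean_

    def predict_all(self, X) -> np.ndarray:
        """(n, k_eff) prediction matrix for all nested component counts."""
        Xw = self._scale(X)
        T = Xw @ self.rotation_
        contrib = T * self.y_loadings_
        return np.cumsum(contrib, axis=1) + self.y_mean_


def fit_plsr(X, y, n_latent: int = 2) -> PLSRegressor:
    """Fit a PLSR model on an unfolded matrix / ndarray / DataFrame."""
    if isinstance(X, UnfoldedMatrix):
        X = X.values
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    return PLSRegressor(n_components=n_latent).fit(X, y)


def rmsecv(y_act, y_pred) -> float:
    """Target-normalized root-mean-square error (fraction; x100 = percent)."""
    y_act = np.asarray(y_act, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_act.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if np.any(y_act == 0):
        raise ValueError("y_act contains zeros; relative error undefined")
    rel = (y_pred - y_act) / y_act
    return float(np.sqrt(np.mean(rel**2)))


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels 0..folds-1 with sizes differing by <= 1."""
    base = np.arange(n) % folds
    return base[rng.permutation(n)]


@dataclass
class CVResult:
    y_pred: np.ndarray  # cross-validated prediction per row
    fold_assignment: np.ndarray
    per_fold_rmsecv: np.ndarray
    mean_rmsecv: float
    sd_rmsecv: float
    pooled_rmsecv: float
    components_per_fold: list


def _pick_components(X, y, k_max: int, inner_folds: int,
                     rng: np.random.Generator) -> int:
    """Inner-CV choice of the PLS component count on a training split."""
    n = len(y)
    inner_folds = min(inner_folds, n - 2)
    if inner_folds < 2 or k_max <= 1:
        return max(1, k_max)
    fold = _fold_assignment(n, inner_folds, rng)
    preds = np.full((n, k_max), np.nan)
    for f in range(inner_folds):
        tr = fold != f
        if tr.sum() < 3:
            continue
        k_fit = min(k_max, int(tr.sum()) - 2, X.shape[1])
        try:
            m = PLSRegressor(n_components=k_fit).fit(X[tr], y[tr])
        except ValueError:
            continue
        pa = m.predict_all(X[~tr])
        preds[~tr, : pa.shape[1]] = pa
        if pa.shape[1] < k_max:  # pad with the deepest available model
            preds[~tr, pa.shape[1]:] = pa[:, [-1]]
    errs = np.nanmean((preds - y[:, None]) ** 2, axis=0)
    if np.all(np.isnan(errs)):
        return 1
    return int(np.nanargmin(errs)) + 1


def cross_validate(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    n_latent: int | str = "auto",
    n_latent_max: int = 10,
    inner_folds: int = 5,
) -> CVResult:
    """Seeded k-fold cross-validation of a PLSR model.

    Fold sizes differ by at most one; each fold is predicted by a model fit
    on the remainder.  With ``n_latent='auto'`` the component count is chosen
    per training fold by an inner CV (capped at ``n_latent_max``).  Reports
    the per-fold RMSECV (mean/sd across folds) and the pooled RMSECV over all
    cross-validated predictions.
    """
    X = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float).ravel()
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds {n} rows")
    rng = np.random.default_rng(seed)
    fold = _fold_assignment(n, folds, rng)
    y_pred = np.empty(n)
    per_fold = []
    comps = []
    for f in range(folds):
        tr = fold != f
        Xtr, ytr = X[tr], y[tr]
        k_cap = min(n_latent_max, Xtr.shape[1], int(tr.sum()) - 2)
        if n_latent == "auto":
            k = _pick_components(Xtr, ytr, max(1, k_cap), inner_folds, rng)
        else:
            k = min(int(n_latent), max(1, k_cap))
        model = PLSRegressor(n_components=k).fit(Xtr, ytr)
        y_pred[~tr] = model.predict(X[~tr])
        per_fold.append(rmsecv(y[~tr], y_pred[~tr]))
        comps.append(model.n_components_)
    per_fold = np.asarray(per_fold)
    return CVResult(
        y_pred=y_pred,
        fold_assignment=fold,
        per_fold_rmsecv=per_fold,
        mean_rmsecv=float(per_fold.mean()),
        sd_rmsecv=float(per_fold.std(ddof=1)) if folds > 1 else 0.0,
        pooled_rmsecv=rmsecv(y, y_pred),
        components_per_fold=comps,
    )


def build_candidates(
    m: UnfoldedMatrix,
    design_factors: pd.DataFrame | None = None,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Candidate column table for variable selection.

    Columns are keyed ``(variable, time)``; design factors (numeric factors
    as-is, the categorical feed profile one-hot encoded) are offered
    alongside with time -1 so they sort before any measurement.
    """
    df = m.to_frame()
    if variables is not None:
        keep = [c for c in df.columns if c[0] in variables]
        df = df[keep]
    df.columns = [(v, float(t)) for v, t in df.columns]
    # constant columns (e.g. a variable censored at its detection limit for
    # every run at early times) carry no information
    keep = [c for c in df.columns if df[c].nunique() > 1]
    df = df[keep]
    if design_factors is not None:
        fac = design_factors.loc[df.index]
        add = {}
        for col in ("mu_set", "S0", "hunger_h"):
            if col in fac.columns:
                add[(col, -1.0)] = fac[col].to_numpy(float)
        if "profile" in fac.columns:
            for lev in sorted(fac["profile"].unique()):
                add[(f"profile={lev}", -1.0)] = (
                    (fac["profile"] == lev).to_numpy(float)
                )
        df = pd.concat([pd.DataFrame(add, index=df.index), df], axis=1)
    return df


@dataclass
class SelectionResult:
    selected: list  # ordered candidate keys
    rmsecv_trace: list  # best mean RMSECV after each addition
    mean_rmsecv: float
    sd_rmsecv: float
    seed: int
    cv: CVResult | None = None


def forward_select_variables(
    candidates: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    n_latent: int | str = "auto",
    n_latent_max: int = 10,
    inner_folds: int = 5,
    max_steps: int | None = None,
) -> SelectionResult:
    """Greedy forward selection minimizing the mean k-fold RMSECV.

    At each step every remaining candidate is evaluated joined to the current
    selection (same fold assignment throughout, derived from ``seed``); the
    best candidate joins if it improves the running minimum, ties going to
    the earlier measurement time and then lexicographic variable name.  The
    reported trace is therefore non-increasing.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate column")
    y = np.asarray(y, float).ravel()
    order = sorted(candidates.columns, key=lambda c: (c[1], str(c[0]))
                   if isinstance(c, tuple) else (0.0, str(c)))
    remaining = list(order)
    selected: list = []
    trace: list = []
    best_overall = np.inf
    best_cv: CVResult | None = None
    step = 0
    while remaining:
        if max_steps is not None and step >= max_steps:
            break
        best_cand, best_err, best_cv_step = None, np.inf, None
        for cand in remaining:
            cols = selected + [cand]
            try:
                cv = cross_validate(candidates[cols], y, folds=folds, seed=seed,
                                    n_latent=n_latent, n_latent_max=n_latent_max,
                                    inner_folds=inner_folds)
            except ValueError:
                continue  # degenerate candidate set (e.g. constant block)
            if cv.mean_rmsecv < best_err:
                best_err = cv.mean_rmsecv
                best_cand = cand
                best_cv_step = cv
        # improvement must exceed float noise to count
        if best_cand is None or best_err >= best_overall * (1.0 - 1e-9) - 1e-12:
            break
        selected.append(best_cand)
        remaining.remove(best_cand)
        trace.append(best_err)
        best_overall = best_err
        best_cv = best_cv_step
        step += 1
    if not selected:
        # degenerate: nothing improved over nothing; keep the single best
        raise RuntimeError("forward selection could not select any variable")
    return SelectionResult(
        selected=selected,
        rmsecv_trace=trace,
        mean_rmsecv=float(best_overall),
        sd_rmsecv=float(best_cv.sd_rmsecv) if best_cv is not None else 0.0,
        seed=seed,
        cv=best_cv,
    )


@dataclass
class HistorySweep:
    horizons: list
    mean_rmsecv: list
    sd_rmsecv: list
    selections: list  # SelectionResult per horizon

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "horizon_h": self.horizons,
            "mean_rmsecv": self.mean_rmsecv,
            "sd_rmsecv": self.sd_rmsecv,
            "n_selected": [len(s.selected) for s in self.selections],
        })


def history_sweep(
    unfolded: UnfoldedMatrix,
    y,
    horizons: Sequence[float],
    design_factors: pd.DataFrame | None = None,
    folds: int = 10,
    seed: int = 0,
    **select_kwargs,
) -> HistorySweep:
    """Forward-selected PLSR error as a function of history length.

    Each horizon truncates the unfolded matrix to columns with time <=
    horizon and reruns the selection with the identical fold seed, so the
    RMSECV distributions are comparable across horizons.
    """
    hs, means, sds, sels = [], [], [], []
    for h in horizons:
        sub = unfolded.truncate(h)
        if len(sub.grid()) < 2:
            import warnings
            warnings.warn(f"horizon {h} h has <2 grid points; skipped")
            continue
        cands = build_candidates(sub, design_factors)
        sel = forward_select_variables(cands, y, folds=folds, seed=seed,
                                       **select_kwargs)
        hs.append(float(h))
        means.append(sel.mean_rmsecv)
        sds.append(sel.sd_rmsecv)
        sels.append(sel)
    return HistorySweep(horizons=hs, mean_rmsecv=means, sd_rmsecv=sds,
                        selections=sels)
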