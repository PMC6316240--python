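"""Multivariate campaign diagnostics on the batch-wise-unfolded matrix.

PCA of the autoscaled unfolded matrix gives a low-dimensional score space in
which abnormal reactors separate (flagged by Hotelling's T² against an
F-distribution limit) and similarly behaving reactors group (k-means in
score space).  The resulting clusters are then explained in terms of the
experimental design factors by a classification tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cart import CartClassifier
from .preprocess import UnfoldedMatrix, autoscale

__all__ = [
    "BatchPCA",
    "ScoreKMeans",
    "OutlierResult",
    "ClusterResult",
    "fit_pca",
    "detect_outliers",
    "cluster_scores",
    "characterize_clusters",
]


class BatchPCA:
    """PCA by singular value decomposition of the autoscaled unfolded matrix.

    scikit-learn-style estimator: ``fit`` / ``transform``; fitted attributes
    ``loadings_`` (p x k, orthonormal columns), ``scores_`` (n x k),
    ``explained_variance_`` (non-increasing, n-1 normalized) and
    ``explained_variance_ratio_``.  The sign of each component is fixed by
    making its largest-magnitude loading element positive.
    """

    _param_names = ("n_components",)

    def __init__(self, n_components: int | None = 2):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **p):
        for k, v in p.items():
            if k != "n_components":
                raise ValueError(f"invalid parameter {k!r}")
            self.n_components = v
        return self

    @staticmethod
    def _as_matrix(m) -> tuple[np.ndarray, list]:
        if isinstance(m, UnfoldedMatrix):
            if not m.scaled:
                m = autoscale(m)
            return m.values, list(m.run_ids)
        arr = np.asarray(m, float)
        return arr, list(range(arr.shape[0]))

    def fit(self, m):
        X, run_ids = self._as_matrix(m)
        n, p = X.shape
        k = self.n_components if self.n_components is not None else min(n - 1, p)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if n <= k:
            raise ValueError("need more rows than components")
        # column means may be nonzero if a raw ndarray is passed; center then
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        if k > rank:
            warnings.warn(
                f"n_components={k} exceeds matrix rank {rank}; truncating",
                stacklevel=2,
            )
            k = rank
        # deterministic sign: largest-|loading| element positive
        for j in range(k):
            i = np.argmax(np.abs(Vt[j]))
            if Vt[j, i] < 0:
                Vt[j] *= -1.0
                U[:, j] *= -1.0
        self.n_components_ = k
        self.loadings_ = Vt[:k].T
        self.scores_ = U[:, :k] * s[:k]
        self.explained_variance_ = s[:k] ** 2 / (n - 1)
        total = float(np.sum(s**2)) / (n - 1)
        self.explained_variance_ratio_ = (
            self.explained_variance_ / total if total > 0 else
            np.zeros(k)
        )
        self.run_ids_ = run_ids
        self.n_samples_ = n
        return self

    def transform(self, m) -> np.ndarray:
        X, _ = self._as_matrix(m)
        return (X - self.mean_) @ self.loadings_

    def fit_transform(self, m) -> np.ndarray:
        return self.fit(m).scores_

    def reconstruct(self) -> np.ndarray:
        """Training-data reconstruction from the retained components."""
        return self.scores_ @ self.loadings_.T + self.mean_


def n_components_for_variance(
    m, threshold: float = 0.8, cap: int = 5
) -> int:
    """Smallest component count explaining >= threshold variance, capped."""
    X, _ = BatchPCA._as_matrix(m)
    n = X.shape[0]
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    return max(1, min(k, cap, n - 1))


def fit_pca(m, n_components: int | None = None) -> BatchPCA:
    """Fit PCA on an (auto-scaled) unfolded matrix.

    With ``n_components=None`` the smallest number of components explaining
    at least 80% of the variance is retained, capped at 5.
    """
    if n_components is None:
        n_components = n_components_for_variance(m)
    return BatchPCA(n_components=n_components).fit(m)


@dataclass
class OutlierResult:
    run_ids: list
    t2: np.ndarray
    limit: float
    flags: np.ndarray  # bool

    def flagged_runs(self) -> list:
        return [r for r, f in zip(self.run_ids, self.flags) if f]


def detect_outliers(model: BatchPCA, alpha: float = 0.01) -> OutlierResult:
    """Hotelling's T² outlier flags on the retained score space.

    T²_i = sum_j t_ij²/lambda_j with the F-distribution control limit
    k(n-1)/(n-k) * F_{k, n-k}(1 - alpha).
    """
    n, k = model.scores_.shape
    if n < 5:
        raise ValueError("need at least 5 runs for outlier detection")
    lam = model.explained_variance_
    if np.any(lam <= 0):
        raise ValueError("degenerate component variance")
    t2 = np.sum(model.scores_**2 / lam, axis=1)
    limit = k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)
    return OutlierResult(run_ids=list(model.run_ids_), t2=t2,
                         limit=float(limit), flags=t2 > limit)


class ScoreKMeans:
    """Seeded k-means with greedy furthest-point initialization.

    Each of ``n_init`` restarts draws a random first centre (from the seeded
    generator), completes the seeding greedily (next centre = point furthest
    from the chosen set) and runs Lloyd iterations; the best restart by
    inertia wins.  Restarts that converge with an empty cluster are consumed
    from the pool.  Deterministic under a fixed seed.
    """

    _param_names = ("k", "seed", "n_init", "max_iter")

    def __init__(self, k: int = 3, seed: int = 0, n_init: int = 50,
                 max_iter: int = 200):
        self.k = k
        self.seed = seed
        self.n_init = n_init
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {p: getattr(self, p) for p in self._param_names}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray):
        X = np.asarray(X, float)
        n = X.shape[0]
        if self.k >= n + 1:
            raise ValueError("k must be <= number of points")
        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(self.n_init):
            centers = self._seed_centers(X, rng)
            labels, centers, inertia, ok, n_iter = self._lloyd(X, centers)
            if not ok:
                continue  # empty cluster: restart consumed
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia, n_iter)
        if best is None:
            raise RuntimeError("all k-means restarts ended with empty clusters")
        self.labels_, self.cluster_centers_, self.inertia_, self.n_iter_ = best
        return self

    def fit_predict(self, X) -> np.ndarray:
        return self.fit(X).labels_

    def _seed_centers(self, X: np.ndarray, rng) -> np.ndarray:
        n = X.shape[0]
        first = int(rng.integers(n))
        idx = [first]
        d2 = np.sum((X - X[first]) ** 2, axis=1)
        while len(idx) < self.k:
            nxt = int(np.argmax(d2))
            idx.append(nxt)
            d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
        return X[idx].copy()

    def _lloyd(self, X, centers):
        labels = None
        for it in range(1, self.max_iter + 1):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2, axis=1)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            counts = np.bincount(labels, minlength=self.k)
            if np.any(counts == 0):
                return labels, centers, np.inf, False, it
            for j in range(self.k):
                centers[j] = X[labels == j].mean(axis=0)
        inertia = float(((X - centers[labels]) ** 2).sum())
        return labels, centers, inertia, True, it


@dataclass
class ClusterResult:
    assignments: dict  # run_id -> label
    centroids: np.ndarray
    inertia: float
    k: int
    seed: int

    def labels_for(self, run_ids) -> np.ndarray:
        return np.asarray([self.assignments[r] for r in run_ids])

    def sizes(self) -> dict:
        out: dict = {}
        for lab in self.assignments.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def cluster_scores(model: BatchPCA, k: int = 3, seed: int = 0,
                   n_init: int = 50) -> ClusterResult:
    """k-means clustering of the retained PCA scores."""
    km = ScoreKMeans(k=k, seed=seed, n_init=n_init).fit(model.scores_)
    return ClusterResult(
        assignments=dict(zip(model.run_ids_, km.labels_.tolist())),
        centroids=km.cluster_centers_,
        inertia=km.inertia_,
        k=k,
        seed=seed,
    )


def characterize_clusters(
    assignments: dict,
    design_factors: pd.DataFrame,
    min_leaf: int = 1,
    factors: tuple = ("profile", "mu_set", "S0", "hunger_h"),
) -> CartClassifier:
    """Explain cluster labels by the design factors with a classification tree.

    ``design_factors`` is indexed by run_id with the factor columns; only
    runs present in ``assignments`` are used (outliers are typically removed
    beforehand).
    """
    run_ids = [r for r in design_factors.index if r in assignments]
    if len({assignments[r] for r in run_ids}) < 1:
        raise ValueError("no labelled runs")
    X = design_factors.loc[run_ids, list(factors)]
    y = np.asarray([assignments[r] for r in run_ids])
    return CartClassifier(min_leaf=min_leaf).fit(X, y)
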