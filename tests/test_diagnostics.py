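"""PCA, Hotelling T², k-means and cluster characterization.

Small-instance equivalence is checked against independent oracles: a direct
eigendecomposition of the covariance matrix, and scikit-learn's PCA/KMeans
(the library is used only as a cross-check here, never in the implementation).
"""

import numpy as np
import pandas as pd
import pytest

from mbrkit.cart import CartClassifier, CartRegressor
from mbrkit.diagnostics import (
    BatchPCA,
    ScoreKMeans,
    characterize_clusters,
    cluster_scores,
    detect_outliers,
    fit_pca,
)


class TestBatchPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        X = np.outer(u, v)
        with pytest.warns(UserWarning, match="truncating"):
            model = BatchPCA(n_components=3).fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(7, 4))
        model = BatchPCA(n_components=4).fit(X)
        assert np.allclose(model.reconstruct(), X, atol=1e-8)

    def test_eigen_oracle_equivalence(self, rng):
        """Scores/loadings match a brute-force covariance eigendecomposition."""
        X = rng.normal(size=(6, 4))
        model = BatchPCA(n_components=3).fit(X)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        assert np.allclose(model.explained_variance_, w[:3], atol=1e-10)
        for j in range(3):
            dot = abs(model.loadings_[:, j] @ V[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_sklearn_cross_check(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        X = rng.normal(size=(10, 6))
        ours = BatchPCA(n_components=3).fit(X)
        sk = SkPCA(n_components=3).fit(X)
        assert np.allclose(ours.explained_variance_, sk.explained_variance_,
                           atol=1e-10)
        for j in range(3):
            assert abs(ours.loadings_[:, j] @ sk.components_[j]) == pytest.approx(
                1.0, abs=1e-8)

    def test_loadings_orthonormal_and_variance_sorted(self, rng):
        X = rng.normal(size=(12, 7))
        m = BatchPCA(n_components=5).fit(X)
        G = m.loadings_.T @ m.loadings_
        assert np.allclose(G, np.eye(5), atol=1e-8)
        assert np.all(np.diff(m.explained_variance_) <= 1e-12)
        # deterministic sign: largest-magnitude element positive
        for j in range(5):
            col = m.loadings_[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_scores_are_projected_data(self, rng):
        X = rng.normal(size=(9, 5))
        m = BatchPCA(n_components=2).fit(X)
        assert np.allclose(m.scores_, (X - m.mean_) @ m.loadings_, atol=1e-10)


class TestDetectOutliers:
    def test_displaced_row_flagged(self, rng):
        X = rng.normal(size=(20, 6))
        model = BatchPCA(n_components=2).fit(X)
        pooled = np.sqrt(model.explained_variance_[0])
        X2 = X.copy()
        X2[7] += 10 * pooled * model.loadings_[:, 0]
        model2 = BatchPCA(n_components=2).fit(X2)
        res = detect_outliers(model2, alpha=0.01)
        assert res.flags[7]
        assert res.flags.sum() == 1

    def test_near_identical_rows_unflagged(self, rng):
        X = np.ones((10, 4)) + 1e-6 * rng.normal(size=(10, 4))
        model = BatchPCA(n_components=2).fit(X)
        res = detect_outliers(model, alpha=0.01)
        assert not res.flags.any()

    def test_minimum_rows(self, rng):
        X = rng.normal(size=(4, 3))
        model = BatchPCA(n_components=2).fit(X)
        with pytest.raises(ValueError, match="at least 5"):
            detect_outliers(model)


class TestScoreKMeans:
    def _blobs(self, rng, k=3, n=15, sep=20.0):
        centers = rng.normal(size=(k, 2)) * sep
        X = np.vstack([c + rng.normal(size=(n, 2)) for c in centers])
        labels = np.repeat(np.arange(k), n)
        return X, labels

    def test_separated_blobs_recovered(self, rng):
        X, truth = self._blobs(rng)
        km = ScoreKMeans(k=3, seed=0).fit(X)
        # perfect recovery up to label permutation
        mapping = {}
        for lab in range(3):
            got = km.labels_[truth == lab]
            assert len(set(got)) == 1
            mapping[lab] = got[0]
        assert len(set(mapping.values())) == 3

    def test_k1_inertia_is_total_scatter(self, rng):
        X = rng.normal(size=(12, 3))
        km = ScoreKMeans(k=1, seed=0, n_init=1).fit(X)
        assert km.inertia_ == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(30, 2))
        a = ScoreKMeans(k=4, seed=3).fit(X)
        b = ScoreKMeans(k=4, seed=3).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert a.inertia_ == b.inertia_

    def test_sklearn_inertia_cross_check(self, rng):
        from sklearn.cluster import KMeans

        X, _ = self._blobs(rng, sep=8.0)
        ours = ScoreKMeans(k=3, seed=0, n_init=50).fit(X)
        sk = KMeans(n_clusters=3, n_init=20, random_state=0).fit(X)
        assert ours.inertia_ == pytest.approx(sk.inertia_, rel=1e-6)


class TestCharacterizeClusters:
    def _factors(self):
        rows = []
        rid = 1
        for mu in (0.0875, 0.175, 0.35):
            for prof in ("exponential", "linear"):
                for _ in range(4):
                    rows.append((rid, prof, mu, 20.0, 0.0))
                    rid += 1
        return pd.DataFrame(
            rows, columns=["run_id", "profile", "mu_set", "S0", "hunger_h"]
        ).set_index("run_id")

    def test_separable_by_one_factor(self):
        fac = self._factors()
        assignments = {r: int(fac.loc[r, "mu_set"] == 0.35) for r in fac.index}
        tree = characterize_clusters(assignments, fac)
        assert tree.depth_ == 1
        assert tree.tree_.feature == "mu_set"
        assert tree.score(fac[["profile", "mu_set", "S0", "hunger_h"]],
                          [assignments[r] for r in fac.index]) == 1.0

    def test_random_labels_give_stump(self):
        fac = self._factors()
        rng = np.random.default_rng(0)
        labels = rng.permutation([0, 1] * 12)
        assignments = dict(zip(fac.index, labels))
        tree = characterize_clusters(assignments, fac,
                                     min_leaf=len(fac) // 3)
        assert tree.depth_ <= 1  # nothing systematic to split on

    def test_label_permutation_invariance(self):
        fac = self._factors()
        a = {r: int(fac.loc[r, "mu_set"] == 0.35) for r in fac.index}
        b = {r: 1 - v for r, v in a.items()}
        X = fac[["profile", "mu_set", "S0", "hunger_h"]]
        ta = characterize_clusters(a, fac)
        tb = characterize_clusters(b, fac)
        ya = [a[r] for r in fac.index]
        yb = [b[r] for r in fac.index]
        assert ta.score(X, ya) == tb.score(X, yb)


class TestCartAgainstSklearn:
    def test_training_accuracy_matches(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = (X["a"] + 0.3 * X["b"] > 0).astype(int).to_numpy()
        ours = CartClassifier(min_leaf=5).fit(X, y)
        sk = DecisionTreeClassifier(min_samples_leaf=5, random_state=0).fit(X, y)
        acc_ours = ours.score(X, y)
        acc_sk = (sk.predict(X) == y).mean()
        assert acc_ours == pytest.approx(acc_sk, abs=0.05)

    def test_regressor_matches_sklearn_sse(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=list("ab"))
        y = np.where(X["a"] > 0, 5.0, -5.0) + 0.1 * rng.normal(size=60)
        ours = CartRegressor(min_leaf=10, min_gain=0.0).fit(X, y)
        sk = DecisionTreeRegressor(min_samples_leaf=10, random_state=0).fit(X, y)
        sse_ours = ((ours.predict(X) - y) ** 2).sum()
        sse_sk = ((sk.predict(X) - y) ** 2).sum()
        assert sse_ours <= sse_sk * 1.1


@pytest.fixture(scope="module")
def aligned_pca(campaign):
    from mbrkit.preprocess import autoscale, batch_wise_unfold, grid_campaign

    gridded = grid_campaign(campaign, align="feed_start", grid_start=0.0,
                            horizon=12.0)
    unf = batch_wise_unfold(gridded)
    return unf, fit_pca(autoscale(unf))


class TestCampaignDiagnostics:
    """Score-space structure of the default synthetic campaign."""

    def test_failure_run_most_distant(self, aligned_pca):
        """The injected failure run has the largest mean score distance."""
        _, pca = aligned_pca
        S = pca.scores_
        d = ((S[:, None, :] - S[None, :, :]) ** 2).sum(-1) ** 0.5
        mean_dist = d.sum(1) / (len(S) - 1)
        worst = pca.run_ids_[int(np.argmax(mean_dist))]
        assert worst == 46

    def test_outlier_monotone_in_severity(self, campaign):
        """Scaling down the failure makes it no more detectable."""
        from mbrkit.preprocess import autoscale, batch_wise_unfold, grid_campaign
        from mbrkit.simulate import inject_sensor_failure

        t2_by_factor = {}
        for gf in (0.9, 0.55):
            camp_traj = dict(campaign.trajectories)
            base = camp_traj[46]
            camp_traj[46] = inject_sensor_failure(
                base, onset=0.5, seed=0, growth_factor=gf)
            # rebuild the failure run's measurements noiselessly
            from mbrkit.simulate import sample_measurements

            tab = campaign.measurements[campaign.measurements.run_id != 46]
            extra = sample_measurements(
                camp_traj[46], campaign.sample_times[46],
                campaign.params.noiseless(), seed=0)
            camp = _CampaignView(campaign, pd.concat([tab, extra]), camp_traj)
            gridded = grid_campaign(camp, align="feed_start", grid_start=0.0,
                                    horizon=12.0)
            pca = fit_pca(autoscale(batch_wise_unfold(gridded)))
            res = detect_outliers(pca, alpha=0.01)
            t2_by_factor[gf] = res.t2[pca.run_ids_.index(46)] / res.limit
        assert t2_by_factor[0.55] > t2_by_factor[0.9]


class _CampaignView:
    """Lightweight stand-in exposing the campaign surface used by gridding."""

    def __init__(self, base, measurements, trajectories):
        self.measurements = measurements
        self.trajectories = trajectories
        self.plans = base.plans
        self.run_ids = base.run_ids
        self.params = base.params
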