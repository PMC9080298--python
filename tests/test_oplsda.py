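"""NIPALS PLS2, OPLS-DA, VIP, cross-validation and projection."""

import numpy as np
import pandas as pd
import pytest

import moaprofile as mp
import moaprofile.preprocess as pp
from moaprofile.oplsda import DummyY, assign_classes, fit_pls2_nipals


def pls1_oracle(X, y, n_components):
    """Textbook PLS1 written independently: explicit per-component loop with
    scalar y, no shared code with the PLS2 path."""
    X = X.copy()
    y = y.copy().astype(float)
    W, T, P, C = [], [], [], []
    for _ in range(n_components):
        w = X.T @ y
        w = w / np.sqrt((w * w).sum())
        t = X @ w
        c = float(y @ t / (t @ t))
        p = X.T @ t / (t @ t)
        W.append(w)
        T.append(t)
        P.append(p)
        C.append(c)
        X = X - np.outer(t, p)
        y = y - t * c
    return (np.column_stack(W), np.column_stack(T),
            np.column_stack(P), np.array(C))


class TestNipalsPls2:
    def test_single_column_y_matches_pls1_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 10))
        X -= X.mean(axis=0)
        y = rng.normal(size=25)
        y -= y.mean()
        pls = fit_pls2_nipals(X, y[:, None], 3)
        W, T, P, C = pls1_oracle(X, y, 3)
        for a in range(3):
            sign = np.sign(W[:, a] @ pls.W[:, a])
            np.testing.assert_allclose(pls.W[:, a], sign * W[:, a], atol=1e-8)
            np.testing.assert_allclose(pls.T[:, a], sign * T[:, a], atol=1e-8)
            np.testing.assert_allclose(pls.P[:, a], sign * P[:, a], atol=1e-8)

    def test_self_prediction(self):
        # Y equal to the first X column: one component explains nearly all Y
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(20, 6))
        raw -= raw.mean(axis=0)
        X = np.linalg.qr(raw)[0]  # orthonormal, zero-mean columns
        y = X[:, [0]].copy()
        pls = fit_pls2_nipals(X, y, 1)
        resid = y - np.outer(pls.T[:, 0], pls.C[:, 0])
        r2y = 1 - (resid ** 2).sum() / (y ** 2).sum()
        assert r2y > 0.999

    def test_axis_aligned_weights(self):
        # orthogonal X columns, y equal to the first: w -> e1
        X = np.array([
            [1, 1, 1], [-1, 1, 1], [1, -1, 1], [-1, -1, 1],
            [1, 1, -1], [-1, 1, -1], [1, -1, -1], [-1, -1, -1],
        ], dtype=float)
        y = X[:, [0]].copy()
        pls = fit_pls2_nipals(X, y, 1)
        np.testing.assert_allclose(np.abs(pls.W[:, 0]), [1, 0, 0], atol=1e-10)

    def test_nonconvergence_raises(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        X -= X.mean(0)
        Y = rng.normal(size=(15, 2))
        Y -= Y.mean(0)
        with pytest.raises(RuntimeError, match="converge"):
            fit_pls2_nipals(X, Y, 2, tol=0.0, max_iter=2)


class TestOplsda:
    def random_instance(self, seed, n=30, p=15, k=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        labels = np.array([f"c{i % k}" for i in range(n)])
        return X, labels

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_orth_reduces_to_pls2(self, seed):
        X, labels = self.random_instance(seed)
        dummy = DummyY.from_labels(labels)
        model = mp.fit_oplsda(X, dummy, n_orth=0)
        pls = fit_pls2_nipals(X, dummy.centered, model.n_pred)
        y_opls = X @ model.B + dummy.mean
        y_pls = X @ pls.B + dummy.mean
        np.testing.assert_allclose(y_opls, y_pls, atol=1e-8)

    def test_four_classes_default_components(self, small_model):
        assert small_model.n_classes == 4
        assert small_model.n_pred == 3

    def test_orthogonal_augmentation_leaves_predictive_scores(self):
        # planting strong variation orthogonal to Y: the orthogonal filter
        # strips it so predictive scores are unchanged, while PCA swings to
        # the planted direction
        rng = np.random.default_rng(8)
        n, p = 40, 12
        labels = np.array(["a", "b"] * (n // 2))
        dummy = DummyY.from_labels(labels)
        yc = dummy.centered[:, 0]
        v1 = np.eye(p)[0]
        v2 = np.eye(p)[1]
        g = rng.normal(size=n)
        g -= g.mean()
        g -= yc * (g @ yc) / (yc @ yc)  # orthogonal to the class contrast
        noise = 1e-6 * rng.normal(size=(n, p))
        X_base = 2.0 * np.outer(yc, v1) + noise
        X_aug = X_base + 5.0 * np.outer(g, v2)
        base = mp.fit_oplsda(X_base - X_base.mean(0), dummy, n_orth=0, n_pred=1)
        aug = mp.fit_oplsda(X_aug - X_aug.mean(0), dummy, n_orth=1, n_pred=1)
        sign = np.sign(base.T[:, 0] @ aug.T[:, 0])
        assert np.abs(base.T[:, 0] - sign * aug.T[:, 0]).max() < 1e-6
        pca_base = np.linalg.svd(X_base - X_base.mean(0), full_matrices=False)[0][:, 0]
        pca_aug = np.linalg.svd(X_aug - X_aug.mean(0), full_matrices=False)[0][:, 0]
        assert abs(np.corrcoef(pca_base, pca_aug)[0, 1]) < 0.5

    def test_orthogonality_invariants(self, small_model):
        m = small_model
        assert np.abs(m.T.T @ m.T_o).max() < 1e-8 * np.abs(m.T).max() ** 2
        np.testing.assert_allclose(m.W.T @ m.W, np.eye(m.n_pred), atol=1e-8)

    def test_r2y_monotone_in_components(self):
        X, labels = self.random_instance(5, n=40, p=20, k=4)
        r2 = [mp.fit_oplsda(X, labels, n_orth=0, n_pred=a).r2y
              for a in range(1, 6)]
        assert all(np.diff(r2) >= -1e-10)

    def test_sample_permutation_only_reorders_scores(self):
        X, labels = self.random_instance(9)
        model = mp.fit_oplsda(X, labels, n_orth=1)
        perm = np.random.default_rng(0).permutation(len(labels))
        model_p = mp.fit_oplsda(X[perm], labels[perm], n_orth=1)
        assert model_p.r2y == pytest.approx(model.r2y, abs=1e-10)
        np.testing.assert_allclose(np.abs(model_p.T), np.abs(model.T[perm]),
                                   atol=1e-8)

    def test_binary_assignment_matches_sklearn_plsda(self):
        # independent oracle: sklearn's PLS regression on the same dummy
        from sklearn.cross_decomposition import PLSRegression

        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, p = 16, 8
            X = rng.normal(size=(n, p))
            labels = np.array(["a", "b"] * (n // 2))
            X[labels == "a"] += rng.normal(0, 0.5, p)
            X -= X.mean(axis=0)
            dummy = DummyY.from_labels(labels)
            mine = mp.fit_oplsda(X, dummy, n_orth=0, n_pred=1)
            _, _, y_hat = mp.predict(mine, X, return_frame=False)
            sk = PLSRegression(n_components=1, scale=False).fit(X, dummy.centered)
            y_sk = sk.predict(X) + dummy.mean
            assert (np.argmax(y_hat, axis=1) == np.argmax(y_sk, axis=1)).all()

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        labels = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            mp.fit_oplsda(X, labels)


class TestVip:
    def test_mean_square_is_one(self, small_model):
        v = mp.vip(small_model)
        assert (v ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_feature(self):
        rng = np.random.default_rng(4)
        n, p = 60, 25
        X = rng.normal(size=(n, p))
        labels = np.array(["a", "b"] * (n // 2))
        X[labels == "a", 0] += 10.0
        X -= X.mean(axis=0)
        model = mp.fit_oplsda(X, labels, n_orth=0, n_pred=1)
        v = mp.vip(model)
        assert v[0] == pytest.approx(np.sqrt(p), rel=0.05)
        assert v[0] == v.max()


class TestCrossValidate:
    def test_separable_classes_high_q2(self):
        cfg = mp.SyntheticConfig(seed=41, n_cell_lines=3, drugs_per_class=2,
                                 n_features_rp=60, n_features_hilic=50,
                                 markers_per_class=6, effect_size=2.0)
        rp, hi, meta, _ = mp.generate_study(cfg)
        _, log_fused = mp.run_preprocess(rp, hi, meta)
        treated = meta[meta["condition"] == "treated"]["sample_id"].tolist()
        labels = meta.set_index("sample_id").loc[treated, "moa_class"].to_numpy()
        cv = mp.cross_validate(log_fused.loc[treated], labels, n_orth=0, seed=1)
        assert cv.q2 > 0.9

    def test_permuted_labels_low_q2(self, small_prep, treated_split):
        _, log_fused = small_prep
        ids, labels = treated_split
        rng = np.random.default_rng(7)
        q2s = []
        for s in range(5):
            perm = rng.permutation(labels)
            q2s.append(mp.cross_validate(log_fused.loc[ids], perm,
                                         n_orth=0, seed=s).q2)
        assert np.mean(q2s) <= 0.1

    def test_fold_exceeding_class_size_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 5))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="folds"):
            mp.cross_validate(X, labels, folds=5, scale=False)

    def test_deterministic_under_seed(self, small_prep, treated_split):
        _, log_fused = small_prep
        ids, labels = treated_split
        a = mp.cross_validate(log_fused.loc[ids], labels, n_orth=1, seed=3)
        b = mp.cross_validate(log_fused.loc[ids], labels, n_orth=1, seed=3)
        assert a.q2 == b.q2
        np.testing.assert_array_equal(a.y_pred_cv, b.y_pred_cv)


class TestPredict:
    def test_training_self_consistency(self, small_model, small_prep, treated_split):
        _, log_fused = small_prep
        ids, labels = treated_split
        _, _, y_hat = mp.predict(small_model, log_fused.loc[ids])
        assigned = assign_classes(small_model, y_hat)
        # projecting the training data reproduces the fitted responses
        scaled = pp.pareto_scale(log_fused.loc[ids])
        Xs = scaled.X.to_numpy()
        for a in range(small_model.n_orth):
            t_o = Xs @ small_model.W_o[:, a]
            Xs = Xs - np.outer(t_o, small_model.P_o[:, a])
        y_fit = Xs @ small_model.B + small_model.y_mean
        np.testing.assert_allclose(y_hat.to_numpy(), y_fit, atol=1e-10)
        assert (assigned == labels).mean() >= 0.95

    def test_duplicate_sample_identical_scores(self, small_model, small_prep,
                                               treated_split):
        _, log_fused = small_prep
        ids, _ = treated_split
        X = log_fused.loc[[ids[0], ids[0]]]
        t, _, y = mp.predict(small_model, X)
        np.testing.assert_array_equal(t.iloc[0].to_numpy(), t.iloc[1].to_numpy())
        np.testing.assert_array_equal(y.iloc[0].to_numpy(), y.iloc[1].to_numpy())

    def test_feature_mismatch_reported(self, small_model, small_prep, treated_split):
        _, log_fused = small_prep
        ids, _ = treated_split
        X = log_fused.loc[ids].iloc[:, :-2]
        with pytest.raises(ValueError, match="missing"):
            mp.predict(small_model, X)

    def test_held_out_class_lands_in_its_region(self, small_config, small_model,
                                                small_prep):
        from conftest import make_new_set_matrix

        _, log_fused = small_prep
        X_new, _ = make_new_set_matrix(small_config, log_fused.columns,
                                       "microtubule", 12)
        t, _, y_hat = mp.predict(small_model, X_new)
        train_t = small_model.T[
            np.asarray(small_model.train_labels) == "microtubule"]
        mean_new = t.to_numpy()[:, :2].mean(axis=0)
        lo = train_t[:, :2].min(axis=0)
        hi = train_t[:, :2].max(axis=0)
        assert np.all(mean_new >= lo) and np.all(mean_new <= hi)


class TestPersistence:
    def test_json_round_trip(self, small_model, small_prep, treated_split, tmp_path):
        _, log_fused = small_prep
        ids, _ = treated_split
        path = tmp_path / "model.json"
        small_model.to_json(path)
        back = mp.OplsModel.from_json(path)
        _, _, y_a = mp.predict(small_model, log_fused.loc[ids[:5]])
        _, _, y_b = mp.predict(back, log_fused.loc[ids[:5]])
        np.testing.assert_allclose(y_a.to_numpy(), y_b.to_numpy(), atol=1e-12)
        assert back.levels == small_model.levels
        assert back.n_orth == small_model.n_orth
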