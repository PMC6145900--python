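"""Radiomics features, random forest, and the clinical logistic benchmark."""

import numpy as np
import pandas as pd
import pytest

from nodenet3d.baselines import (
    GLCM_DIRECTIONS,
    extract_radiomics,
    glcm_features,
    glcm_matrix,
    logistic_benchmark,
    normalize_features,
    rf_fit,
)


def digital_ball(n=21, r=8.0):
    g = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3, indexing="ij")
    return np.sqrt(sum(x**2 for x in g)) <= r


class TestRadiomicsShape:
    def test_ball_sphericity_near_one(self, rng):
        mask = digital_ball()
        roi = rng.normal(50, 5, size=mask.shape) * mask
        feats = extract_radiomics(roi, mask, (1.0, 1.0, 1.0))
        assert 0.95 <= feats["shape_sphericity"] <= 1.02

    def test_extents_and_diameter(self, rng):
        mask = np.zeros((20, 20, 10), bool)
        mask[2:12, 4:9, 1:4] = True  # 10 x 5 x 3 voxels
        roi = rng.normal(size=mask.shape) * mask
        feats = extract_radiomics(roi, mask, (2.0, 1.0, 3.0))
        assert feats["shape_extent_x_mm"] == pytest.approx(20.0)
        assert feats["shape_extent_y_mm"] == pytest.approx(5.0)
        assert feats["shape_extent_z_mm"] == pytest.approx(9.0)
        assert feats["shape_volume_mm3"] == pytest.approx(10 * 5 * 3 * 6.0)

    def test_degenerate_mask_rejected(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError):
            extract_radiomics(np.ones((4, 4, 4)), mask, (1, 1, 1))


class TestRadiomicsFirstOrder:
    def test_constant_roi(self, ):
        mask = np.zeros((6, 6, 3), bool)
        mask[1:5, 1:5, :] = True
        roi = np.where(mask, 42.0, 0.0)
        feats = extract_radiomics(roi, mask, (1, 1, 1))
        assert feats["fo_variance"] == 0.0
        assert feats["glcm_joint_energy"] == pytest.approx(1.0)
        assert feats["fo_range"] == 0.0


class TestGLCM:
    def test_checkerboard_contrast_matches_manual_tabulation(self):
        """4x4 two-level checkerboard, distance 1, direction-averaged."""
        board = np.indices((4, 4)).sum(axis=0) % 2  # levels 0/1
        roi = board[:, :, None].astype(float)
        mask = np.ones((4, 4, 1), bool)
        feats = glcm_features(roi, mask, n_bins=2, value_range=(0.0, 2.0))
        # manual tabulation over the 4 in-plane directions:
        per_dir = []
        for d in GLCM_DIRECTIONS:
            pairs = []
            for x in range(4):
                for y in range(4):
                    nx, ny, nz = x + d[0], y + d[1], d[2]
                    if 0 <= nx < 4 and 0 <= ny < 4 and nz == 0:
                        pairs.append((board[x, y], board[nx, ny]))
            if pairs:
                contrast = np.mean([(a - b) ** 2 for a, b in pairs])
                per_dir.append(contrast)
        assert feats["glcm_contrast"] == pytest.approx(np.mean(per_dir))

    def test_symmetric_matrix(self, rng):
        q = rng.integers(0, 4, size=(5, 5, 3))
        q[0, 0, 0] = -1  # an out-of-mask voxel
        mat = glcm_matrix(q, (1, 0, 0), 4)
        np.testing.assert_array_equal(mat, mat.T)

    def test_translation_invariance(self, rng):
        base = rng.normal(50, 20, size=(8, 8, 4))
        mask = np.zeros((16, 16, 10), bool)
        roi = np.zeros((16, 16, 10))

        def place(ox, oy, oz):
            m = np.zeros_like(mask)
            r = np.zeros_like(roi)
            m[ox : ox + 8, oy : oy + 8, oz : oz + 4] = True
            r[ox : ox + 8, oy : oy + 8, oz : oz + 4] = base
            return extract_radiomics(r, m, (1, 1, 1))

        a = place(0, 0, 0)
        b = place(5, 6, 3)
        mesh_based = {"shape_surface_mm2", "shape_sphericity", "shape_max_diameter_mm"}
        for k in a:
            if k in mesh_based:  # marching-cubes vertices carry grid-offset rounding
                assert a[k] == pytest.approx(b[k], rel=1e-5), k
            else:
                assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_quarter_turn_invariance_of_averaged_features(self, rng):
        """90-degree in-plane rotation permutes the 13 directions -> averages fixed."""
        vol = rng.normal(0, 1, size=(9, 9, 5))
        mask = rng.random((9, 9, 5)) < 0.7
        mask[4, 4, 2] = True
        a = glcm_features(vol, mask, n_bins=8, value_range=(-3, 3))
        vol_r = np.rot90(vol, k=1, axes=(0, 1)).copy()
        mask_r = np.rot90(mask, k=1, axes=(0, 1)).copy()
        b = glcm_features(vol_r, mask_r, n_bins=8, value_range=(-3, 3))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k


class TestRandomForest:
    def test_linearly_separable_training_accuracy(self, rng):
        X = np.r_[rng.normal(0, 1, (30, 2)), rng.normal(5, 1, (30, 2))]
        y = np.r_[np.zeros(30), np.ones(30)]
        clf = rf_fit(X, y, n_estimators=100, seed=0)
        assert clf.score(X, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rf_fit(np.zeros((10, 2)), np.zeros(10), n_estimators=10)

    def test_ensemble_size_stability(self, rng):
        """A big and a moderate forest agree closely on held-out AUC."""
        from nodenet3d.evaluate import roc_auc

        n = 240
        X = rng.normal(size=(n, 6))
        logits = X[:, 0] * 1.5 + X[:, 1] - 0.5 * X[:, 2]
        y = (logits + rng.normal(0, 1.2, n) > 0).astype(int)
        Xtr, ytr, Xte, yte = X[:160], y[:160], X[160:], y[160:]
        aucs = []
        for n_est in (200, 2000):
            clf = rf_fit(Xtr, ytr, n_estimators=n_est, seed=3)
            aucs.append(roc_auc(clf.predict_proba(Xte)[:, 1], yte))
        assert abs(aucs[0] - aucs[1]) < 0.02

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p1 = rf_fit(X, y, n_estimators=50, seed=5).predict_proba(X)
        p2 = rf_fit(X, y, n_estimators=50, seed=5).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_permuted_labels_near_chance(self):
        from nodenet3d.evaluate import roc_auc

        aucs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 5))
            y = r.integers(0, 2, 200)  # independent of X
            clf = rf_fit(X[:140], y[:140], n_estimators=200, seed=seed)
            aucs.append(roc_auc(clf.predict_proba(X[140:])[:, 1], y[140:]))
        assert 0.38 <= np.mean(aucs) <= 0.62


def make_benchmark_frame(rng, n=400, beta_inter=-0.15):
    d = np.exp(rng.normal(np.log(16), 0.4, n)).clip(4, 60)
    h = (rng.random(n) < 0.3).astype(int)
    z = -3.2 + 0.16 * d + h * (1.8 + beta_inter * d)
    y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
    df = pd.DataFrame(
        {
            "roi_diameter_mm": d,
            "hpv_p16": h,
            "primary_site": rng.choice(["a", "b", "c"], n),
            "clinical_t": rng.choice(["T1", "T2"], n),
            "clinical_n": rng.choice(["N0", "N1", "N2"], n),
        }
    )
    return df, y


class TestLogisticBenchmark:
    def test_recovers_negative_interaction_sign(self):
        hits = 0
        for rep in range(5):
            rng = np.random.default_rng(200 + rep)
            df, y = make_benchmark_frame(rng, n=600)
            res = logistic_benchmark(df, y, endpoint="ene", n_bootstrap=20, seed=rep)
            if res.interaction_coef is not None and res.interaction_coef < 0:
                hits += 1
        assert hits >= 4

    def test_zero_variance_covariate_excluded(self, rng):
        df, y = make_benchmark_frame(rng, n=300)
        df["clinical_t"] = "T2"
        with pytest.warns(UserWarning, match="zero variance"):
            res = logistic_benchmark(df, y, endpoint="ene", n_bootstrap=5, seed=0)
        assert all("clinical_t" not in c for c in res.design_columns)

    def test_screen_is_monotone_in_threshold(self, rng):
        df, y = make_benchmark_frame(rng, n=400)
        res_strict = logistic_benchmark(
            df, y, endpoint="ene", screen_alpha=0.01, n_bootstrap=5, seed=1
        )
        res_loose = logistic_benchmark(
            df, y, endpoint="ene", screen_alpha=0.20, n_bootstrap=5, seed=1
        )
        strict_sel = {c for c in res_strict.screen_p if res_strict.screen_p[c] < 0.01}
        loose_sel = {c for c in res_loose.screen_p if res_loose.screen_p[c] < 0.20}
        assert strict_sel <= loose_sel

    def test_ene_restricted_to_centimetre_nodes(self, rng):
        df, y = make_benchmark_frame(rng, n=300)
        small = df["roi_diameter_mm"] < 10
        y = y.copy()
        y[small] = 0
        res = logistic_benchmark(df, y, endpoint="ene", n_bootstrap=5, seed=2)
        assert len(res.probabilities) == int((~small).sum())

    def test_nm_endpoint_uses_all_nodes(self, rng):
        df, y = make_benchmark_frame(rng, n=300)
        res = logistic_benchmark(df, y, endpoint="nm", n_bootstrap=5, seed=3)
        assert len(res.probabilities) == 300

    def test_prediction_on_new_frame(self, rng):
        df, y = make_benchmark_frame(rng, n=400)
        res = logistic_benchmark(df, y, endpoint="nm", n_bootstrap=5, seed=4)
        df2, _ = make_benchmark_frame(np.random.default_rng(9), n=50)
        p = res.predict(df2)
        assert p.shape == (50,)
        assert ((p > 0) & (p < 1)).all()

    def test_bootstrap_intervals_bracket_point_estimates_mostly(self, rng):
        df, y = make_benchmark_frame(rng, n=500)
        res = logistic_benchmark(df, y, endpoint="ene", n_bootstrap=50, seed=5)
        inside = sum(
            lo <= res.params[c] <= hi for c, (lo, hi) in res.bootstrap_ci.items()
        )
        assert inside >= len(res.bootstrap_ci) - 1


class TestNormalization:
    def test_unit_variance_and_reusable_scale(self, rng):
        df = pd.DataFrame(rng.normal(3, 7, size=(50, 4)), columns=list("abcd"))
        scaled, scale = normalize_features(df)
        np.testing.assert_allclose(scaled.std(ddof=0), 1.0, atol=1e-12)
        test = pd.DataFrame(rng.normal(3, 7, size=(10, 4)), columns=list("abcd"))
        scaled_test, _ = normalize_features(test, scale)
        np.testing.assert_allclose(scaled_test, test / scale)
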