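"""Comparison models: radiomics + random forest, and the clinical logistic benchmark.

Radiomics
---------
:func:`extract_radiomics` computes a core set of ~30 standard features from a
resampled ROI and mask: shape (volume, surface area, sphericity, maximum 3D
diameter, per-axis extents, elongation, flatness), first-order intensity
statistics, and grey-level co-occurrence (GLCM) texture features on 32
fixed-width bins at distance 1, averaged over the 13 unique 3D directions
with the symmetric co-occurrence convention.  Feature values are normalised
to unit variance at the cohort level before modelling.  The random-forest
classifier (Gini impurity, bootstrap per tree, no per-split feature
subsampling) is fit on the combined training+validation partitions and
scored on the untouched test partition, separately per endpoint.

Clinical benchmark
------------------
A logistic regression over pretreatment covariates (HPV/p16, primary site,
clinical T/N stage, ROI short-axis diameter).  Covariates pass a univariable
screen at P < 0.10 (likelihood-ratio test for multi-level categoricals);
survivors enter the multivariable model; the HPV x diameter interaction is
tested and retained when P < 0.05; 100 bootstrap refits give percentile
coefficient intervals.  The ENE model is fit only to nodes with ROI diameter
>= 10 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import marching_cubes, mesh_surface_area
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "GLCM_DIRECTIONS",
    "extract_radiomics",
    "features_matrix",
    "normalize_features",
    "rf_fit",
    "LogisticBenchmarkResult",
    "logistic_benchmark",
]

#: The 13 unique 3D neighbour directions (one per +/- pair).
GLCM_DIRECTIONS = [
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
]


# ---------------------------------------------------------------------------
# Radiomics
# ---------------------------------------------------------------------------


def _shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    sp = np.asarray(spacing, dtype=np.float64)
    voxel_vol = float(np.prod(sp))
    coords = np.argwhere(mask).astype(np.float64)
    volume = coords.shape[0] * voxel_vol

    # Mild Gaussian smoothing before meshing suppresses the voxel staircase,
    # giving a surface-area estimate close to the continuous shape's.  The
    # padding must cover the smoothing kernel so position cannot leak in.
    from scipy import ndimage as _ndi

    padded = np.pad(mask.astype(np.float64), 5)
    smoothed = _ndi.gaussian_filter(padded, sigma=1.0)
    level = 0.5 if smoothed.max() > 0.5 > smoothed.min() else smoothed.mean()
    verts, faces, _, _ = marching_cubes(smoothed, level=level, spacing=tuple(sp))
    surface = float(mesh_surface_area(verts, faces))
    # Sphericity uses the mesh-enclosed volume (divergence theorem) so that
    # numerator and denominator describe the same surface.
    tets = verts[faces]
    mesh_volume = float(
        np.abs(np.einsum("ij,ij->i", tets[:, 0], np.cross(tets[:, 1], tets[:, 2])).sum()) / 6.0
    )
    sphericity = float(np.pi ** (1 / 3) * (6 * mesh_volume) ** (2 / 3) / surface)

    mm = coords * sp
    # Max 3D diameter over convex hull vertices (equals max pairwise distance).
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull_pts = mm[ConvexHull(mm).vertices]
    except QhullError:
        hull_pts = mm
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_diam = float(np.sqrt((diff**2).sum(-1)).max()) if len(hull_pts) > 1 else 0.0

    extents = (coords.max(axis=0) - coords.min(axis=0) + 1) * sp
    centered = mm - mm.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1] if len(mm) > 1 else np.zeros(3)
    eig = np.clip(eig, 0, None)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    return {
        "shape_volume_mm3": volume,
        "shape_surface_mm2": surface,
        "shape_sphericity": sphericity,
        "shape_max_diameter_mm": max_diam,
        "shape_extent_x_mm": float(extents[0]),
        "shape_extent_y_mm": float(extents[1]),
        "shape_extent_z_mm": float(extents[2]),
        "shape_elongation": elongation,
        "shape_flatness": flatness,
    }


def _firstorder_features(vals: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    p10, p25, p75, p90 = np.percentile(vals, [10, 25, 75, 90])
    hist, _ = np.histogram(vals, bins=n_bins)
    probs = hist[hist > 0] / vals.size
    robust = vals[(vals >= p10) & (vals <= p90)]
    return {
        "fo_mean": float(vals.mean()),
        "fo_median": float(np.median(vals)),
        "fo_variance": float(vals.var()),
        "fo_skewness": float(stats.skew(vals)) if vals.var() > 0 else 0.0,
        "fo_kurtosis": float(stats.kurtosis(vals, fisher=False)) if vals.var() > 0 else 0.0,
        "fo_energy": float((vals**2).sum()),
        "fo_entropy": float(-(probs * np.log2(probs)).sum()),
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(p75 - p25),
        "fo_range": float(vals.max() - vals.min()),
        "fo_rmad": float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
    }


def _quantize(roi: np.ndarray, mask: np.ndarray, n_bins: int, value_range) -> np.ndarray:
    """In-mask fixed-width quantization to levels 0..n_bins-1; -1 outside mask."""
    vals = roi.astype(np.float64)
    if value_range is None:
        lo, hi = vals[mask].min(), vals[mask].max()
    else:
        lo, hi = value_range
    width = (hi - lo) / n_bins if hi > lo else 1.0
    q = np.floor((np.clip(vals, lo, hi) - lo) / width).astype(int)
    q = np.clip(q, 0, n_bins - 1)
    q[~mask] = -1
    return q


def glcm_matrix(quantized: np.ndarray, direction: tuple[int, int, int], n_bins: int) -> np.ndarray:
    """Symmetric co-occurrence counts at distance 1 along one direction.

    Only voxel pairs with both members inside the mask (level >= 0) count.
    """
    dx, dy, dz = direction
    a = quantized
    sl_a = tuple(
        slice(max(0, -d), a.shape[i] - max(0, d)) for i, d in enumerate((dx, dy, dz))
    )
    sl_b = tuple(
        slice(max(0, d), a.shape[i] - max(0, -d)) for i, d in enumerate((dx, dy, dz))
    )
    left, right = a[sl_a].ravel(), a[sl_b].ravel()
    ok = (left >= 0) & (right >= 0)
    left, right = left[ok], right[ok]
    mat = np.zeros((n_bins, n_bins), dtype=np.float64)
    np.add.at(mat, (left, right), 1.0)
    return mat + mat.T  # symmetric convention


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    px = p.sum(axis=1)
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = np.sqrt(((i - mu_i) ** 2 * p).sum())
    sd_j = np.sqrt(((j - mu_j) ** 2 * p).sum())
    nz = p > 0
    corr = (
        float((((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j))
        if sd_i > 0 and sd_j > 0
        else 1.0
    )
    return {
        "glcm_contrast": float(((i - j) ** 2 * p).sum()),
        "glcm_correlation": corr,
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_joint_entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "glcm_homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "glcm_dissimilarity": float((np.abs(i - j) * p).sum()),
        "glcm_cluster_shade": float((((i + j) - mu_i - mu_j) ** 3 * p).sum()),
        "glcm_cluster_prominence": float((((i + j) - mu_i - mu_j) ** 4 * p).sum()),
    }


def glcm_features(
    roi: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    value_range=None,
) -> dict[str, float]:
    """Direction-averaged GLCM features (directions with no pairs are skipped)."""
    q = _quantize(roi, mask, n_bins, value_range)
    per_dir = []
    for d in GLCM_DIRECTIONS:
        mat = glcm_matrix(q, d, n_bins)
        total = mat.sum()
        if total > 0:
            per_dir.append(_glcm_features_single(mat / total))
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs in mask")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def extract_radiomics(
    roi: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    n_bins: int = 32,
    hu_range: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Compute the core radiomic feature vector from in-mask voxels.

    ``hu_range`` fixes the GLCM quantization range (e.g. the clipped
    soft-tissue window); when None the in-mask min/max is used, which is the
    right choice for already-standardised intensities.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("radiomics requires a mask with at least 2 voxels")
    vals = np.asarray(roi, dtype=np.float64)[mask]
    feats = {}
    feats.update(_shape_features(mask, spacing))
    feats.update(_firstorder_features(vals, n_bins))
    feats.update(glcm_features(roi, mask, n_bins, hu_range))
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite radiomic features: {bad}")
    return feats


def features_matrix(feature_dicts: list[dict[str, float]]) -> pd.DataFrame:
    return pd.DataFrame(feature_dicts)


def normalize_features(
    df: pd.DataFrame, scale: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort-level unit-variance scaling; returns (scaled, scale) for reuse on test."""
    if scale is None:
        scale = df.std(ddof=0).replace(0.0, 1.0)
    return df / scale, scale


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


def rf_fit(
    features: pd.DataFrame | np.ndarray,
    targets,
    n_estimators: int = 10_000,
    seed: int = 0,
) -> RandomForestClassifier:
    """Gini random forest with bootstrap per tree and all features per split."""
    y = np.asarray(targets).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("random forest requires both classes in the targets")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        criterion="gini",
        max_features=None,  # every feature considered at each split
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(np.asarray(features, dtype=np.float64), y)
    return clf


# ---------------------------------------------------------------------------
# Clinical logistic benchmark
# ---------------------------------------------------------------------------

_CONTINUOUS = {"roi_diameter_mm"}


def _design(df: pd.DataFrame, covariates: list[str], interaction: bool) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        if c in _CONTINUOUS or np.issubdtype(df[c].dtype, np.number):
            cols[c] = df[c].astype(float)
        else:
            dummies = pd.get_dummies(df[c].astype(str), prefix=c, drop_first=True)
            for name in dummies:
                cols[name] = dummies[name].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    if interaction:
        X["hpv_p16:roi_diameter_mm"] = df["hpv_p16"].astype(float) * df[
            "roi_diameter_mm"
        ].astype(float)
    X.insert(0, "const", 1.0)
    return X


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """ML logit fit; falls back to a lightly L2-penalised fit on separation."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.bse)) and np.abs(res.params).max() < 1e3:
                return res, False
        except Exception:
            pass
        res = sm.Logit(y, X.to_numpy()).fit_regularized(
            disp=0, alpha=1e-3, L1_wt=0.0, maxiter=500
        )
        return res, True


def _univariable_p(df: pd.DataFrame, y: np.ndarray, covariate: str) -> float:
    """Likelihood-ratio p-value of one covariate vs the intercept-only model."""
    import statsmodels.api as sm

    X = _design(df, [covariate], interaction=False)
    if X.shape[1] == 1:  # zero-variance covariate contributed no columns
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0, maxiter=200)
        except Exception:
            return 1.0
    lr = 2 * (full.llf - null.llf)
    dof = X.shape[1] - 1
    return float(stats.chi2.sf(max(lr, 0.0), df=dof))


@dataclass
class LogisticBenchmarkResult:
    endpoint: str
    selected: list[str]
    screen_p: dict[str, float]
    params: dict[str, float]
    bootstrap_ci: dict[str, tuple[float, float]]
    interaction_coef: float | None
    interaction_p: float | None
    interaction_retained: bool
    probabilities: np.ndarray
    penalized: bool
    design_columns: list[str] = field(default_factory=list)
    interaction_in_model: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.selected, self.interaction_in_model)
        X = X.reindex(columns=self.design_columns, fill_value=0.0)
        beta = np.array([self.params[c] for c in self.design_columns])
        z = X.to_numpy() @ beta
        return 1.0 / (1.0 + np.exp(-z))


def logistic_benchmark(
    df: pd.DataFrame,
    targets,
    endpoint: str = "ene",
    covariates: list[str] | None = None,
    screen_alpha: float = 0.10,
    interaction_alpha: float = 0.05,
    n_bootstrap: int = 100,
    min_diameter_mm: float = 10.0,
    seed: int = 0,
) -> LogisticBenchmarkResult:
    """Screen-then-fit clinical logistic model for one endpoint.

    For the ENE endpoint the fit is restricted to nodes with ROI diameter
    >= ``min_diameter_mm``.  Zero-variance covariates are excluded with a
    warning.  Returned probabilities cover the (restricted) fitting rows.
    """
    df = df.reset_index(drop=True)
    y = np.asarray(targets).astype(int)
    if endpoint == "ene":
        keep = df["roi_diameter_mm"].to_numpy(dtype=float) >= min_diameter_mm
        df, y = df.loc[keep].reset_index(drop=True), y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("endpoint has a single class after restriction")

    covariates = covariates or [
        c for c in ("roi_diameter_mm", "hpv_p16", "primary_site", "clinical_t", "clinical_n")
        if c in df.columns
    ]
    usable = []
    for c in covariates:
        if df[c].nunique() < 2:
            warnings.warn(f"covariate {c!r} has zero variance; excluded from screening")
            continue
        usable.append(c)

    screen_p = {c: _univariable_p(df, y, c) for c in usable}
    selected = [c for c in usable if screen_p[c] < screen_alpha]
    if not selected:
        selected = ["roi_diameter_mm"] if "roi_diameter_mm" in usable else usable[:1]

    # Interaction testable whenever both constituents exist with variance.
    interaction_coef = interaction_p = None
    interaction_testable = (
        "hpv_p16" in df.columns
        and "roi_diameter_mm" in df.columns
        and df["hpv_p16"].nunique() > 1
        and df["roi_diameter_mm"].nunique() > 1
    )
    retained = False
    if interaction_testable:
        Xi = _design(df, sorted(set(selected) | {"hpv_p16", "roi_diameter_mm"}), True)
        res_i, pen_i = _fit_logit(Xi, y)
        k = list(Xi.columns).index("hpv_p16:roi_diameter_mm")
        interaction_coef = float(res_i.params[k])
        if hasattr(res_i, "bse") and np.isfinite(res_i.bse[k]) and res_i.bse[k] > 0:
            zstat = res_i.params[k] / res_i.bse[k]
            interaction_p = float(2 * stats.norm.sf(abs(zstat)))
        else:
            interaction_p = 1.0
        retained = interaction_p < interaction_alpha

    model_covs = sorted(set(selected) | ({"hpv_p16", "roi_diameter_mm"} if retained else set()))
    X = _design(df, model_covs, retained)
    res, penalized = _fit_logit(X, y)
    params = dict(zip(X.columns, np.asarray(res.params, dtype=float)))

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(y), size=len(y))
        if len(np.unique(y[idx])) < 2:
            continue
        try:
            res_b, _ = _fit_logit(X.iloc[idx], y[idx])
            boot.append(np.asarray(res_b.params, dtype=float))
        except Exception:
            continue
    if boot:
        arr = np.vstack(boot)
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
        ci = {c: (float(l), float(h)) for c, l, h in zip(X.columns, lo, hi)}
    else:
        ci = {c: (float("nan"), float("nan")) for c in X.columns}

    beta = np.array([params[c] for c in X.columns])
    probs = 1.0 / (1.0 + np.exp(-(X.to_numpy() @ beta)))
    return LogisticBenchmarkResult(
        endpoint=endpoint,
        selected=model_covs,
        screen_p=screen_p,
        params=params,
        bootstrap_ci=ci,
        interaction_coef=interaction_coef,
        interaction_p=interaction_p,
        interaction_retained=retained,
        probabilities=probs,
        penalized=penalized,
        design_columns=list(X.columns),
        interaction_in_model=retained,
    )
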