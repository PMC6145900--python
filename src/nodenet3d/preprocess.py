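"""ROI preprocessing: from raw mask + CT volume to the two network inputs.

The chain, applied per node:

1. convex hull of the segmented voxels (fills concavities left by manual
   slice-wise contouring),
2. circumferential dilation by a fixed voxel radius to capture the perinodal
   fat planes that carry extranodal-extension information,
3. in-plane resampling of volume (bicubic) and mask (bilinear, re-binarised
   at 0.5) to a common pixel spacing,
4. masked extraction (voxelwise product — background exactly zero),
5. HU clipping to the soft-tissue window and per-ROI standardisation,
6. two outputs: the *dimension-preserving* input (ROI centred in a fixed
   zero-padded bounding box, so absolute node size stays encoded) and the
   *size-invariant* input (ROI cropped tight and resized to a fixed cube,
   so shape and texture are encoded independent of size).

The short-axis ROI diameter — used as a covariate by the benchmark models —
is measured on the dilated, resampled mask, so it runs a fixed margin larger
than a radiologist's short-axis calliper measurement; relative differences
between nodes are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .io import AnnotatedVolume, Covariates, NodeSegmentation, label_to_target

__all__ = [
    "PreprocessSpec",
    "NodeSample",
    "convex_hull_mask",
    "dilate_mask",
    "resample_axial",
    "extract_roi",
    "clip_normalize",
    "embed_in_box",
    "make_small_input",
    "roi_short_axis_diameter",
    "preprocess_node",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Parameters of the preprocessing chain.

    Defaults follow the full-resolution protocol: 10-voxel dilation, 0.75 mm
    in-plane target spacing, HU clip window (-400, +400), bounding box
    118 x 118 x 32 and small-input cube 32^3.  ``resample_z`` additionally
    resamples the slice axis to ``target_spacing_mm`` (off by default; the
    main protocol resamples in the axial plane only).  ``hull_per_slice``
    switches the convex hull from volumetric to per-axial-slice.
    """

    dilation_px: int = 10
    target_spacing_mm: float = 0.75
    hu_clip: tuple[float, float] = (-400.0, 400.0)
    box_shape: tuple[int, int, int] = (118, 118, 32)
    small_shape: tuple[int, int, int] = (32, 32, 32)
    resample_z: bool = False
    hull_per_slice: bool = False

    def __post_init__(self) -> None:
        if self.hu_clip[0] >= self.hu_clip[1]:
            raise ValueError("hu_clip must satisfy low < high")
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be non-negative")
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")
        for shp in (self.box_shape, self.small_shape):
            if len(shp) != 3 or any(s <= 0 for s in shp):
                raise ValueError(f"shapes must be three positive ints, got {shp}")

    @classmethod
    def desk(cls) -> "PreprocessSpec":
        """Reduced-scale spec for CPU-sized experiments (box 32x32x16)."""
        return cls(
            dilation_px=2,
            target_spacing_mm=1.5,
            box_shape=(32, 32, 16),
            small_shape=(16, 16, 16),
        )


@dataclass
class NodeSample:
    """The preprocessed pair of network inputs for one lymph node."""

    box_input: np.ndarray
    small_input: np.ndarray
    target: tuple[int, int]
    covariates: Covariates
    roi_diameter_mm: float
    node_id: str
    patient_id: str = ""
    degenerate: bool = False

    @property
    def nm(self) -> int:
        return self.target[0]

    @property
    def ene(self) -> int:
        return self.target[1]


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def convex_hull_mask(mask: np.ndarray, per_slice: bool = False) -> np.ndarray:
    """Fill ``mask`` to the convex hull of its foreground voxel centers.

    A voxel belongs to the output iff its center lies inside (or on) the 3D
    convex hull of the input foreground voxel centers; the output is always a
    superset of the input.  ``per_slice=True`` computes independent 2D hulls
    on each axial slice instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("convex_hull_mask: empty mask")
    if per_slice:
        out = np.zeros_like(mask)
        for z in range(mask.shape[2]):
            if mask[:, :, z].any():
                out[:, :, z] = _hull_fill(mask[:, :, z])
        return out
    return _hull_fill(mask)


def _hull_fill(mask: np.ndarray) -> np.ndarray:
    pts = np.argwhere(mask).astype(np.float64)
    out = np.zeros_like(mask)
    # Work inside the tight bounding box only.
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int) + 1
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # Degenerate (rank-deficient) point set: points on a line or plane.
        inside = _degenerate_hull_membership(pts, cand)
    else:
        # A point is inside iff it satisfies every facet half-space.
        eq = hull.equations  # (nfacet, ndim+1): n . x + b <= 0 inside
        inside = np.all(cand @ eq[:, :-1].T + eq[:, -1] <= 1e-9, axis=1)
    idx = cand[inside].astype(int)
    out[tuple(idx.T)] = True
    return out | mask


def _degenerate_hull_membership(pts: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Hull membership for rank-deficient point clouds (point/segment/polygon)."""
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    rank = int(np.sum(s > 1e-9))
    basis = vt[:rank] if rank else np.zeros((0, pts.shape[1]))
    # Candidates must lie in the affine subspace spanned by the points ...
    resid = (cand - center) - (cand - center) @ basis.T @ basis
    in_plane = np.linalg.norm(resid, axis=1) <= 1e-9
    if rank == 0:
        return in_plane
    proj_pts = (pts - center) @ basis.T
    proj_cand = (cand - center) @ basis.T
    if rank == 1:
        lo, hi = proj_pts.min(), proj_pts.max()
        within = (proj_cand[:, 0] >= lo - 1e-9) & (proj_cand[:, 0] <= hi + 1e-9)
        return in_plane & within
    hull = ConvexHull(proj_pts)
    eq = hull.equations
    within = np.all(proj_cand @ eq[:, :-1].T + eq[:, -1] <= 1e-9, axis=1)
    return in_plane & within


def dilate_mask(mask: np.ndarray, px: int) -> np.ndarray:
    """Morphological dilation by a discrete Euclidean ball of radius ``px`` voxels.

    Implemented exactly via the Euclidean distance transform of the
    background: a voxel is foreground after dilation iff its distance to the
    nearest input foreground voxel is <= px.
    """
    if px < 0:
        raise ValueError("dilation radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if px == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= px + 1e-9


def resample_axial(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing_mm: float,
    resample_z: bool = False,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample volume (bicubic) and mask (bilinear, threshold 0.5) in-plane.

    The slice axis is left untouched unless ``resample_z``.  Returns the
    resampled volume, the re-binarised mask and the new spacing.  A nonempty
    input mask always yields a nonempty output mask (the voxel at the maximum
    of the interpolated occupancy is kept if thresholding empties it).
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    sx, sy, sz = spacing
    factors = [sx / target_spacing_mm, sy / target_spacing_mm, 1.0]
    new_spacing = (target_spacing_mm, target_spacing_mm, sz)
    if resample_z:
        factors[2] = sz / target_spacing_mm
        new_spacing = (target_spacing_mm, target_spacing_mm, target_spacing_mm)
    if np.allclose(factors, 1.0):
        return volume.astype(np.float32), mask.astype(bool), new_spacing
    vol_r = ndimage.zoom(volume.astype(np.float64), factors, order=3, mode="nearest")
    mask_r = ndimage.zoom(mask.astype(np.float64), factors, order=1, mode="constant")
    mask_b = mask_r >= 0.5
    if mask.any() and not mask_b.any():
        mask_b[np.unravel_index(np.argmax(mask_r), mask_r.shape)] = True
    return vol_r.astype(np.float32), mask_b, new_spacing


def extract_roi(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Voxelwise product of volume and binary mask; background exactly zero."""
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    return np.where(np.asarray(mask, dtype=bool), volume, 0.0).astype(np.float32)


def clip_normalize(
    roi: np.ndarray,
    mask: np.ndarray,
    hu_clip: tuple[float, float] = (-400.0, 400.0),
) -> tuple[np.ndarray, bool]:
    """Clip in-mask HU to the soft-tissue window, then standardise in-mask.

    In-mask values are clipped to ``hu_clip`` and transformed to zero mean and
    unit variance over the mask; background stays exactly zero.  A constant
    in-mask ROI (zero variance) yields all zeros and the degenerate flag.
    Applying the operation twice equals applying it once (standardising
    already-standardised data is the identity up to floating point).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("clip_normalize: empty mask")
    vals = np.clip(roi[mask].astype(np.float64), hu_clip[0], hu_clip[1])
    sd = vals.std()
    out = np.zeros_like(roi, dtype=np.float32)
    if sd == 0:
        return out, True
    out[mask] = ((vals - vals.mean()) / sd).astype(np.float32)
    return out, False


def _tight_bbox(arr: np.ndarray) -> tuple[slice, ...]:
    nz = np.nonzero(arr)
    if len(nz[0]) == 0:
        raise ValueError("empty ROI")
    return tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)


def embed_in_box(roi: np.ndarray, box_shape: tuple[int, int, int]) -> np.ndarray:
    """Center the tight ROI extent in a zero-padded box of fixed shape.

    Odd padding remainders put the smaller margin first (floor of the half
    margin on the low side of each axis).
    """
    bbox = _tight_bbox(roi)
    tight = roi[bbox]
    out = np.zeros(box_shape, dtype=roi.dtype)
    slices = []
    for axis, (n, b) in enumerate(zip(tight.shape, box_shape)):
        if n > b:
            raise ValueError(
                f"ROI extent {n} exceeds bounding box {b} on axis {'xyz'[axis]}"
            )
        lo = (b - n) // 2
        slices.append(slice(lo, lo + n))
    out[tuple(slices)] = tight
    return out


def _resize3d(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Resize with bicubic interpolation in-plane and linear along z.

    Target sample i maps to source coordinate (i + 0.5) * n/m - 0.5 (pixel-
    area alignment, the convention of standard image resizers).
    """
    coords = []
    for n_src, n_dst in zip(arr.shape, shape):
        if n_src == 1:
            coords.append(np.zeros(n_dst))
        else:
            coords.append((np.arange(n_dst) + 0.5) * n_src / n_dst - 0.5)
    cx, cy, cz = coords
    # Pass 1: bicubic in-plane, identity along z.
    gx, gy, gz = np.meshgrid(cx, cy, np.arange(arr.shape[2]), indexing="ij")
    pass1 = ndimage.map_coordinates(
        arr.astype(np.float64), [gx, gy, gz], order=3, mode="nearest"
    )
    # Pass 2: linear along z only.
    gx2, gy2, gz2 = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), cz, indexing="ij"
    )
    out = ndimage.map_coordinates(pass1, [gx2, gy2, gz2], order=1, mode="nearest")
    return out.astype(np.float32)


def make_small_input(roi: np.ndarray, small_shape: tuple[int, int, int] = (32, 32, 32)) -> np.ndarray:
    """Crop the ROI to its tight extent and resize to the fixed small cube.

    The anisotropic per-axis resize removes absolute size information: two
    ROIs that differ only by a uniform scale factor map to (nearly) the same
    small input.
    """
    bbox = _tight_bbox(roi)
    return _resize3d(roi[bbox], small_shape)


def roi_short_axis_diameter(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Short-axis diameter: min over axes of (max foreground extent x spacing)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("roi_short_axis_diameter: empty mask")
    nz = np.nonzero(mask)
    extents = [
        (int(a.max()) - int(a.min()) + 1) * s for a, s in zip(nz, spacing)
    ]
    return float(min(extents))


# ---------------------------------------------------------------------------
# Full per-node chain
# ---------------------------------------------------------------------------


def preprocess_node(
    volume: AnnotatedVolume,
    segmentation: NodeSegmentation,
    covariates: Covariates | None = None,
    spec: PreprocessSpec | None = None,
) -> NodeSample:
    """Run the full preprocessing chain for one node.

    hull -> dilate -> resample -> extract -> clip+normalise -> {box, small};
    the ROI diameter is measured on the dilated, resampled mask and written
    into the returned covariates.
    """
    spec = spec or PreprocessSpec()
    covariates = covariates if covariates is not None else volume.covariates

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as exc:
            raise ValueError(f"preprocess_node[{name}] ({segmentation.node_id}): {exc}") from exc

    hull = stage("convex_hull", convex_hull_mask, segmentation.mask, spec.hull_per_slice)
    dilated = stage("dilate", dilate_mask, hull, spec.dilation_px)
    vol_r, mask_r, spacing_r = stage(
        "resample",
        resample_axial,
        volume.voxels,
        dilated,
        volume.spacing,
        spec.target_spacing_mm,
        spec.resample_z,
    )
    roi = stage("extract", extract_roi, vol_r, mask_r)
    norm, degenerate = stage("clip_normalize", clip_normalize, roi, mask_r, spec.hu_clip)
    if degenerate:
        # Constant ROI carries no texture; keep geometry via the mask itself.
        norm = mask_r.astype(np.float32)
    box = stage("embed_in_box", embed_in_box, norm, spec.box_shape)
    small = stage("make_small_input", make_small_input, norm, spec.small_shape)
    diameter = stage("diameter", roi_short_axis_diameter, mask_r, spacing_r)
    covs = replace(covariates, roi_diameter_mm=diameter)
    return NodeSample(
        box_input=box,
        small_input=small,
        target=segmentation.target,
        covariates=covs,
        roi_diameter_mm=diameter,
        node_id=segmentation.node_id,
        patient_id=volume.patient_id,
        degenerate=degenerate,
    )
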