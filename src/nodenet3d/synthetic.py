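"""Seeded synthetic neck-CT phantoms with labelled lymph nodes.

The generator emulates the class-conditional statistics of surgical HNSCC
node cohorts so that every pipeline stage can be exercised without patient
data:

* class mix defaults to 58.2% negative / 23.4% NM without ENE / 18.4% NM
  with ENE;
* ROI diameters are truncated lognormals with class medians 10 / 16 / 23 mm
  (ranges 4-20 / 6-42 / 10-64 mm);
* negative nodes are smooth homogeneous ellipsoids; metastatic nodes gain a
  hypodense (necrotic) core; ENE nodes additionally have a spiculated
  boundary (radial sinusoidal perturbation) and an elevated-HU perinodal rim
  emulating fat stranding — the radiologic correlates of capsule breach;
* the final ENE label among metastatic nodes is drawn from a logistic model
  in diameter and HPV/p16 status with a negative HPV x diameter interaction,
  and no node below 10 mm ever carries ENE;
* backgrounds are fat (~ -100 HU) with muscle blobs (~ +50 HU) and Gaussian
  noise; all structure HU lie within [-200, +200] before noise, inside the
  informative part of the soft-tissue clip window.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import AnnotatedVolume, Covariates, NodeSegmentation
from .preprocess import NodeSample, PreprocessSpec, preprocess_node
from .splits import stratified_split

__all__ = ["PhantomSpec", "generate_node", "sample_cohort_table", "generate_cohort", "make_desk_dataset"]

_CLASSES = ("negative", "nm_no_ene", "nm_ene")

# Rough primary-site / stage frequencies of a surgical HNSCC cohort.
_SITES = (("oral_cavity", 0.38), ("oropharynx", 0.27), ("larynx", 0.19), ("salivary", 0.06), ("other", 0.10))
_TSTAGES = (("T1", 0.14), ("T2", 0.26), ("T3", 0.14), ("T4", 0.16), ("unknown", 0.30))
_NSTAGES = (("N0", 0.28), ("N1", 0.13), ("N2", 0.32), ("N3", 0.05), ("unknown", 0.22))


@dataclass(frozen=True)
class PhantomSpec:
    """All generator parameters; defaults reproduce the study-scale conditions."""

    n_patients: int = 270
    nodes_per_patient: tuple[int, int] = (1, 5)
    class_mix: tuple[float, float, float] = (0.582, 0.234, 0.184)
    diameter_medians_mm: tuple[float, float, float] = (10.0, 16.0, 23.0)
    diameter_ranges_mm: tuple[tuple[float, float], ...] = ((4, 20), (6, 42), (10, 64))
    diameter_sigmas: tuple[float, float, float] = (0.30, 0.35, 0.35)
    volume_shape: tuple[int, int, int] = (128, 128, 40)
    spacing: tuple[float, float, float] = (0.75, 0.75, 3.0)
    fat_hu: float = -100.0
    muscle_hu: float = 50.0
    noise_sd: float = 12.0
    node_hu: float = 60.0
    node_texture_sd: float = 6.0
    necrosis_hu: float = -10.0
    necrosis_core_frac: float = 0.55
    ene_spiculation_amp: float = 0.25
    ene_spiculation_lobes: int = 5
    ene_rim_hu: float = 10.0
    ene_rim_width_frac: float = 0.25
    hpv_prevalence: float = 0.28
    # ENE-given-NM logistic label model (diameter in mm, hpv binary):
    # logit p = b0 + b_d * d + h * (b_h + b_hd * d); b_hd < 0 is the
    # negative HPV x diameter interaction.
    label_beta0: float = -3.6
    label_beta_diam: float = 0.17
    label_beta_hpv: float = 2.0
    label_beta_interaction: float = -0.15
    min_ene_diameter_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        m = self.diameter_medians_mm
        if not (m[0] < m[1] < m[2]):
            raise ValueError("diameter medians must be ordered negative < NM < ENE")

    @classmethod
    def desk(cls, seed: int = 0) -> "PhantomSpec":
        """Reduced-scale phantoms sized for the 32x32x16 desk pipeline."""
        return cls(
            n_patients=60,
            nodes_per_patient=(1, 3),
            diameter_medians_mm=(8.0, 12.0, 16.0),
            diameter_ranges_mm=((4, 12), (6, 20), (10, 24)),
            volume_shape=(64, 64, 24),
            spacing=(1.5, 1.5, 3.0),
            seed=seed,
        )


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float
) -> float:
    mu = np.log(median)
    for _ in range(1000):
        d = float(np.exp(rng.normal(mu, sigma)))
        if lo <= d <= hi:
            return d
    return float(np.clip(np.exp(mu), lo, hi))


def _draw_diameter(rng: np.random.Generator, spec: PhantomSpec, cls_idx: int) -> float:
    return _truncated_lognormal(
        rng,
        spec.diameter_medians_mm[cls_idx],
        spec.diameter_sigmas[cls_idx],
        *spec.diameter_ranges_mm[cls_idx],
    )


def ene_probability(diameter_mm, hpv, spec: PhantomSpec):
    """The label model: P(ENE | metastatic, diameter, HPV); zero below 10 mm."""
    d = np.asarray(diameter_mm, dtype=np.float64)
    h = np.asarray(hpv, dtype=np.float64)
    z = (
        spec.label_beta0
        + spec.label_beta_diam * d
        + h * (spec.label_beta_hpv + spec.label_beta_interaction * d)
    )
    p = 1.0 / (1.0 + np.exp(-z))
    return np.where(d < spec.min_ene_diameter_mm, 0.0, p)


def _categorical(rng: np.random.Generator, table) -> str:
    names, probs = zip(*table)
    probs = np.array(probs) / sum(probs)
    return str(names[rng.choice(len(names), p=probs)])


def sample_cohort_table(n_nodes: int, spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-node label/covariate table (no voxel data).

    Per node: a tentative class from ``class_mix`` fixes the diameter
    distribution; among metastatic nodes the final ENE label is re-drawn from
    the logistic label model given diameter and HPV, so ENE concentrates on
    large, HPV-negative nodes while the marginal class mix stays near the
    target.  This is the single source of truth for labels — the voxel
    generator consumes these rows.
    """
    rows = []
    mix = np.array(spec.class_mix)
    for i in range(n_nodes):
        hpv = int(rng.random() < spec.hpv_prevalence)
        cls = int(rng.choice(3, p=mix))
        d = _draw_diameter(rng, spec, cls)
        nm = int(cls > 0)
        if nm:
            ene = int(rng.random() < ene_probability(d, hpv, spec))
        else:
            ene = 0
        rows.append(
            {
                "node_id": f"n{i:05d}",
                "hpv_p16": hpv,
                "primary_site": _categorical(rng, _SITES),
                "clinical_t": _categorical(rng, _TSTAGES),
                "clinical_n": _categorical(rng, _NSTAGES),
                "true_diameter_mm": d,
                "nm": nm,
                "ene": ene,
                "label": _CLASSES[nm + ene],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Voxel-level generation
# ---------------------------------------------------------------------------


def generate_node(
    cls: str,
    diameter_mm: float,
    spec: PhantomSpec,
    rng: np.random.Generator,
    check_range: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one node patch: ``(mask, intensity)`` on a local grid.

    The intensity patch is NaN outside the voxels the node owns (its interior
    plus, for ENE, the perinodal stranding rim); compositing replaces only
    those voxels.  The short axis of the ellipsoid equals ``diameter_mm``.

    ``check_range=False`` skips the per-class diameter validation; the cohort
    generator uses it because the logistic ENE label model can re-assign a
    metastatic node's class after its diameter was drawn.
    """
    cls_idx = _CLASSES.index(cls)
    lo, hi = spec.diameter_ranges_mm[cls_idx]
    if check_range and not lo <= diameter_mm <= hi:
        raise ValueError(f"diameter {diameter_mm} mm outside class {cls} range {(lo, hi)}")
    sp = np.asarray(spec.spacing)
    r_short = diameter_mm / 2.0
    # Short axis along x; other semi-axes up to 35% longer.
    ratios = np.array([1.0, 1.0 + 0.35 * rng.random(), 1.0 + 0.2 * rng.random()])
    semi = r_short * ratios  # mm per axis

    is_ene = cls == "nm_ene"
    pad_mm = semi.max() * (1.0 + (spec.ene_spiculation_amp + spec.ene_rim_width_frac if is_ene else 0.1)) + 2 * sp.max()
    half = np.ceil(pad_mm / sp).astype(int)
    shape = 2 * half + 1
    grids = np.meshgrid(*[(np.arange(s) - h) for s, h in zip(shape, half)], indexing="ij")
    xyz_mm = [g * s for g, s in zip(grids, sp)]
    rho = np.sqrt(sum((x / a) ** 2 for x, a in zip(xyz_mm, semi)))

    boundary = np.ones_like(rho)
    if is_ene:
        theta = np.arctan2(xyz_mm[1], xyz_mm[0])
        rr = np.sqrt(xyz_mm[0] ** 2 + xyz_mm[1] ** 2 + xyz_mm[2] ** 2)
        phi = np.arccos(np.divide(xyz_mm[2], rr, out=np.zeros_like(rr), where=rr > 0))
        k = spec.ene_spiculation_lobes
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        boundary = 1.0 + spec.ene_spiculation_amp * np.sin(k * theta + ph1) * np.sin(
            k * phi + ph2
        )
    mask = rho <= boundary

    intensity = np.full(shape, np.nan)
    tex = rng.normal(0.0, spec.node_texture_sd, size=shape)
    intensity[mask] = spec.node_hu + tex[mask]
    if cls_idx > 0:  # necrotic core in all metastatic nodes
        core = rho <= spec.necrosis_core_frac * boundary
        intensity[core] = spec.necrosis_hu + tex[core]
    if is_ene:  # perinodal fat stranding: elevated HU just outside the capsule
        rim = (~mask) & (rho <= boundary * (1.0 + spec.ene_rim_width_frac))
        intensity[rim] = spec.ene_rim_hu + tex[rim]
    return mask, intensity


def _background(shape, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    vol = np.full(shape, spec.fat_hu, dtype=np.float64)
    # a few muscle blobs
    for _ in range(rng.integers(2, 5)):
        center = rng.uniform(0.2, 0.8, size=3) * np.array(shape)
        radii = rng.uniform(0.1, 0.25, size=3) * np.array(shape)
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        rho = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
        vol[rho <= 1] = spec.muscle_hu
    return vol


def generate_cohort(
    spec: PhantomSpec | None = None,
    seed: int | None = None,
    table: pd.DataFrame | None = None,
) -> tuple[list[AnnotatedVolume], pd.DataFrame]:
    """Generate per-patient volumes with embedded, non-overlapping nodes.

    Returns ``(volumes, node_table)``; the table carries per-node ground truth
    (class, true diameter, covariates).  Nodes are assigned to patients in
    order, 1-5 per patient, covariates shared within a patient.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if table is None:
        lo, hi = spec.nodes_per_patient
        n_per_patient = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_patients)]
        table = sample_cohort_table(sum(n_per_patient), spec, rng)
    else:
        table = table.copy()
        n_per_patient = None
        lo, hi = spec.nodes_per_patient
        counts = []
        remaining = len(table)
        while remaining > 0:
            k = int(min(remaining, rng.integers(lo, hi + 1)))
            counts.append(k)
            remaining -= k
        n_per_patient = counts

    volumes = []
    row_iter = table.itertuples()
    patient_ids = []
    sp = np.asarray(spec.spacing)
    for p_idx, n_nodes in enumerate(n_per_patient):
        pid = f"p{p_idx:04d}"
        rows = [next(row_iter) for _ in range(n_nodes)]
        vol = _background(spec.volume_shape, spec, rng)
        placed: list[tuple[np.ndarray, float]] = []  # (center mm, radius mm)
        nodes = []
        for row in rows:
            mask, patch = generate_node(row.label, row.true_diameter_mm, spec, rng, check_range=False)
            half = (np.array(mask.shape) - 1) // 2
            radius_mm = float((half * sp).max())
            center = None
            for _ in range(200):
                c_vox = np.array(
                    [
                        rng.integers(h, s - h) if s - h > h else h
                        for s, h in zip(spec.volume_shape, half)
                    ]
                )
                c_mm = c_vox * sp
                if all(
                    np.linalg.norm(c_mm - pc) > 0.8 * (radius_mm + pr)
                    for pc, pr in placed
                ):
                    center = c_vox
                    break
            if center is None:
                raise RuntimeError(
                    f"cannot place node {row.node_id} (diameter {row.true_diameter_mm:.0f} mm) "
                    f"in a {spec.volume_shape} volume"
                )
            placed.append((center * sp, radius_mm))
            sl = tuple(slice(c - h, c + h + 1) for c, h in zip(center, half))
            region = vol[sl]
            write = ~np.isnan(patch)
            region[write] = patch[write]
            full_mask = np.zeros(spec.volume_shape, dtype=bool)
            full_mask[sl] = mask
            nodes.append(NodeSegmentation(mask=full_mask, label=row.label, node_id=row.node_id))
            patient_ids.append((row.node_id, pid))
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
        first = rows[0]
        volumes.append(
            AnnotatedVolume(
                voxels=vol.astype(np.float32),
                spacing=tuple(sp),
                patient_id=pid,
                nodes=nodes,
                covariates=Covariates(
                    hpv_p16=int(first.hpv_p16),
                    primary_site=first.primary_site,
                    clinical_t=first.clinical_t,
                    clinical_n=first.clinical_n,
                ),
            )
        )
    pid_map = dict(patient_ids)
    table["patient_id"] = table["node_id"].map(pid_map)
    return volumes, table


# ---------------------------------------------------------------------------
# Desk-scale end-to-end dataset
# ---------------------------------------------------------------------------


def make_desk_dataset(
    n_per_class: int = 60,
    seed: int = 0,
    phantom_spec: PhantomSpec | None = None,
    preprocess_spec: PreprocessSpec | None = None,
) -> dict:
    """Generate, preprocess and split a balanced desk-scale cohort.

    One node per patient volume, ``n_per_class`` nodes per class, preprocessed
    with the desk spec (box 32x32x16, small 16^3) and split 64/16/20 by
    largest remainder.  Returns a dict with the three NodeSample partitions
    plus the ground-truth table.
    """
    if n_per_class < 20:
        raise ValueError("n_per_class must be >= 20")
    pspec = phantom_spec or PhantomSpec.desk(seed=seed)
    prespec = preprocess_spec or PreprocessSpec.desk()
    rng = np.random.default_rng(seed)

    rows = []
    i = 0
    for cls_idx, cls in enumerate(_CLASSES):
        for _ in range(n_per_class):
            rows.append(
                {
                    "node_id": f"n{i:05d}",
                    "hpv_p16": int(rng.random() < pspec.hpv_prevalence),
                    "primary_site": _categorical(rng, _SITES),
                    "clinical_t": _categorical(rng, _TSTAGES),
                    "clinical_n": _categorical(rng, _NSTAGES),
                    "true_diameter_mm": _draw_diameter(rng, pspec, cls_idx),
                    "nm": int(cls_idx > 0),
                    "ene": int(cls_idx == 2),
                    "label": cls,
                }
            )
            i += 1
    table = pd.DataFrame(rows).sample(frac=1.0, random_state=seed).reset_index(drop=True)
    one_per_patient = replace(pspec, nodes_per_patient=(1, 1))
    volumes, table = generate_cohort(one_per_patient, seed=seed + 1, table=table)

    samples: dict[str, NodeSample] = {}
    for vol in volumes:
        for seg in vol.nodes:
            samples[seg.node_id] = preprocess_node(vol, seg, spec=prespec)
    label_map = dict(zip(table["node_id"], table["label"]))
    plan = stratified_split(label_map, test_frac=0.20, val_frac=0.20, seed=seed)
    out = {
        part: [samples[nid] for nid in sorted(plan.ids(part))]
        for part in ("train", "validation", "test")
    }
    out["table"] = table
    out["split"] = plan
    return out
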