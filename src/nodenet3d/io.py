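"""Reading and writing CT volumes, node masks and the internal cohort fixture.

Conventions
-----------
Voxel grids are indexed ``(x, y, z)`` with 0-based integer indices; the axial
plane is ``(x, y)`` and ``z`` is the slice axis.  Intensities are Hounsfield
units (HU) stored as signed floats — the DICOM rescale (slope/intercept) is the
only transformation applied at read time; clipping and normalisation belong to
the preprocessing stage.  A segmentation mask always shares the grid of its
parent volume.

The *fixture* format is an internal compressed ``.npz`` archive holding the
voxel grid, spacing, per-node masks, labels and covariates of one or more
patients.  It is the unit of exchange between pipeline stages and supports
lazy per-node access (``numpy.load`` reads archive members on demand).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LABELS",
    "Covariates",
    "NodeSegmentation",
    "AnnotatedVolume",
    "label_to_target",
    "read_volume",
    "write_volume",
    "write_fixture",
    "read_fixture",
    "FixtureReader",
]

#: Pathology label vocabulary, ordered negative < NM without ENE < NM with ENE.
LABELS = ("negative", "nm_no_ene", "nm_ene")

_LABEL_TARGET = {"negative": (0, 0), "nm_no_ene": (1, 0), "nm_ene": (1, 1)}


def label_to_target(label: str) -> tuple[int, int]:
    """Map a pathology label to the multi-label ``(nm, ene)`` target.

    ``(0, 1)`` — extranodal extension without nodal metastasis — is not a
    valid state and cannot be produced.
    """
    try:
        return _LABEL_TARGET[label]
    except KeyError:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}") from None


@dataclass
class Covariates:
    """Per-patient clinical covariates used by the benchmark models.

    HPV/p16 status is binary; patients without testing are coded negative.
    ``roi_diameter_mm`` is filled in by preprocessing (short-axis diameter of
    the dilated ROI) and is therefore optional at construction.
    """

    hpv_p16: int = 0
    primary_site: str = "unknown"
    clinical_t: str = "unknown"
    clinical_n: str = "unknown"
    roi_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.hpv_p16 not in (0, 1):
            raise ValueError("hpv_p16 must be 0 or 1 (unknown coded negative)")

    def to_dict(self) -> dict:
        return {
            "hpv_p16": int(self.hpv_p16),
            "primary_site": self.primary_site,
            "clinical_t": self.clinical_t,
            "clinical_n": self.clinical_n,
            "roi_diameter_mm": self.roi_diameter_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Covariates":
        return cls(**d)


@dataclass
class NodeSegmentation:
    """A single lymph-node mask with its pathology label."""

    mask: np.ndarray
    label: str
    node_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise ValueError(f"node {self.node_id}: mask has no foreground voxel")
        if self.label not in LABELS:
            raise ValueError(f"node {self.node_id}: unknown label {self.label!r}")

    @property
    def target(self) -> tuple[int, int]:
        return label_to_target(self.label)


@dataclass
class AnnotatedVolume:
    """A CT voxel grid in HU with spacing metadata and node segmentations."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str
    nodes: list[NodeSegmentation] = field(default_factory=list)
    covariates: Covariates = field(default_factory=Covariates)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (x, y, z) grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        for node in self.nodes:
            if node.mask.shape != self.voxels.shape:
                raise ValueError(
                    f"node {node.node_id}: mask shape {node.mask.shape} "
                    f"!= volume shape {self.voxels.shape}"
                )


# ---------------------------------------------------------------------------
# Standard-format readers
# ---------------------------------------------------------------------------


def read_volume(path: str | Path, patient_id: str | None = None) -> AnnotatedVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    NIfTI voxel order is taken as stored ``(x, y, z)`` with pixdim spacing.
    For a DICOM series the slices are sorted by ``ImagePositionPatient`` along
    the slice normal (falling back to ``InstanceNumber``), stored values are
    rescaled to HU with the per-slice slope/intercept, and z-spacing is the
    inter-slice distance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_dicom_series(path, patient_id)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        return _read_nifti(path, patient_id)
    raise ValueError(f"unrecognised volume format: {path}")


def _read_nifti(path: Path, patient_id: str | None) -> AnnotatedVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid spacing metadata {zooms}")
    return AnnotatedVolume(
        voxels=data,
        spacing=tuple(float(z) for z in zooms),
        patient_id=patient_id or path.stem.replace(".nii", ""),
    )


def _read_dicom_series(path: Path, patient_id: str | None) -> AnnotatedVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise ValueError(f"unreadable DICOM file {f}: {exc}") from exc
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found under {path}")

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError(f"{path}: DICOM series lacks PixelSpacing metadata")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1 and hasattr(first, "ImagePositionPatient"):
        zs = [float(ds.ImagePositionPatient[2]) for ds in slices]
        dz = float(np.median(np.diff(zs)))
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
    if dz <= 0:
        raise ValueError(f"{path}: cannot determine slice spacing")

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM pixel_array is (row, col) = (y, x); transpose to (x, y) per plane.
    vol = np.stack([p.T for p in planes], axis=-1)
    return AnnotatedVolume(
        voxels=vol,
        spacing=(col_sp, row_sp, dz),
        patient_id=patient_id or str(getattr(first, "PatientID", path.name)),
    )


def write_volume(volume: AnnotatedVolume, path: str | Path) -> None:
    """Write the voxel grid (and spacing) as NIfTI; masks exportable separately."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Export a binary mask as a NIfTI label map (uint8)."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Internal fixture archive
# ---------------------------------------------------------------------------


def write_fixture(volumes: AnnotatedVolume | list[AnnotatedVolume], path: str | Path) -> None:
    """Serialise one or more annotated volumes into a compressed archive.

    Layout: per patient ``<pid>/voxels``, ``<pid>/spacing``; per node
    ``<pid>/mask/<node_id>``; one JSON manifest carrying patient order, node
    labels and covariates.  Round-trips voxels bit-exactly.
    """
    if isinstance(volumes, AnnotatedVolume):
        volumes = [volumes]
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    manifest: dict = {"patients": []}
    for vol in volumes:
        pid = vol.patient_id
        if any(p["patient_id"] == pid for p in manifest["patients"]):
            raise ValueError(f"duplicate patient_id {pid!r} in fixture")
        arrays[f"{pid}/voxels"] = vol.voxels
        arrays[f"{pid}/spacing"] = np.asarray(vol.spacing, dtype=np.float64)
        entry = {
            "patient_id": pid,
            "covariates": vol.covariates.to_dict(),
            "nodes": [],
        }
        for node in vol.nodes:
            arrays[f"{pid}/mask/{node.node_id}"] = np.packbits(node.mask.astype(np.uint8))
            entry["nodes"].append(
                {"node_id": node.node_id, "label": node.label, "shape": list(node.mask.shape)}
            )
        manifest["patients"].append(entry)
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest).encode("utf-8"), dtype=np.uint8
    ).copy()
    try:
        with open(path, "wb") as fh:
            np.savez_compressed(fh, **arrays)
    except OSError as exc:
        raise OSError(f"cannot write fixture to {path}: {exc}") from exc


class FixtureReader:
    """Lazy view over a fixture archive.

    Voxel grids and masks are decompressed only when accessed, so a cohort
    fixture with hundreds of nodes supports cheap per-node lookup by id.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._npz = np.load(self.path, allow_pickle=False)
        raw = self._npz["__manifest__"].tobytes().decode("utf-8")
        self.manifest = json.loads(raw)
        self._node_index: dict[str, tuple[str, dict]] = {}
        for entry in self.manifest["patients"]:
            for node in entry["nodes"]:
                self._node_index[node["node_id"]] = (entry["patient_id"], node)

    @property
    def patient_ids(self) -> list[str]:
        return [p["patient_id"] for p in self.manifest["patients"]]

    @property
    def node_ids(self) -> list[str]:
        return list(self._node_index)

    def node_label(self, node_id: str) -> str:
        return self._node_index[node_id][1]["label"]

    def load_patient(self, patient_id: str) -> AnnotatedVolume:
        entry = next(p for p in self.manifest["patients"] if p["patient_id"] == patient_id)
        voxels = self._npz[f"{patient_id}/voxels"]
        spacing = tuple(self._npz[f"{patient_id}/spacing"])
        nodes = [self._load_node_seg(patient_id, n) for n in entry["nodes"]]
        return AnnotatedVolume(
            voxels=voxels,
            spacing=spacing,
            patient_id=patient_id,
            nodes=nodes,
            covariates=Covariates.from_dict(entry["covariates"]),
        )

    def load_node(self, node_id: str) -> tuple[np.ndarray, NodeSegmentation, tuple, Covariates]:
        """Return ``(voxels, segmentation, spacing, covariates)`` for one node."""
        pid, meta = self._node_index[node_id]
        entry = next(p for p in self.manifest["patients"] if p["patient_id"] == pid)
        seg = self._load_node_seg(pid, meta)
        return (
            self._npz[f"{pid}/voxels"],
            seg,
            tuple(self._npz[f"{pid}/spacing"]),
            Covariates.from_dict(entry["covariates"]),
        )

    def _load_node_seg(self, pid: str, meta: dict) -> NodeSegmentation:
        shape = tuple(meta["shape"])
        packed = self._npz[f"{pid}/mask/{meta['node_id']}"]
        mask = np.unpackbits(packed, count=int(np.prod(shape))).reshape(shape).astype(bool)
        return NodeSegmentation(mask=mask, label=meta["label"], node_id=meta["node_id"])

    def close(self) -> None:
        self._npz.close()

    def __enter__(self) -> "FixtureReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_fixture(path: str | Path) -> list[AnnotatedVolume]:
    """Eagerly load every patient volume from a fixture archive."""
    with FixtureReader(path) as reader:
        return [reader.load_patient(pid) for pid in reader.patient_ids]
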