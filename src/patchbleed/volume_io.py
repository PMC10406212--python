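"""Volume containers, NIfTI I/O and intensity standardization.

The pipeline operates on skull-stripped, co-registered 3D volumes of three
MRI contrasts (T1w, T2w, T2*), plus integer mask/label volumes sharing the
same grid.  Internally every volume is stored in a fixed axis order with
the axial (highest in-plane resolution) plane on the first two axes and
the through-plane axis last; voxel coordinates are 0-based.

Intensities are linearly standardized to the range [0, 100] inside the
brain mask before any sampling, training or post-processing step; the
post-processing intensity-ratio rule assumes this scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import CoRegistrationError, DataError, DegenerateInputError

MODALITIES = ("T1w", "T2w", "T2star")

#: axis index of the through-plane (slice) direction in internal order
AXIAL_AXIS = 2


class Tissue(IntEnum):
    """Integer codes of the tissue-label volume."""

    BACKGROUND = 0
    CSF = 1
    CORTICAL_GM = 2
    DEEP_GM = 3
    WM = 4
    CEREBELLAR_GM = 5
    CEREBELLAR_WM = 6


#: brain-region categories a retained lesion can be assigned to
REGION_TISSUES = (
    Tissue.CORTICAL_GM,
    Tissue.DEEP_GM,
    Tissue.WM,
    Tissue.CEREBELLAR_GM,
    Tissue.CEREBELLAR_WM,
)


@dataclass
class ContrastVolume:
    """A single 3D scalar image of one MRI contrast.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; the axial plane is ``data[:, :, k]``.
    spacing : tuple of float
        Voxel size in mm per axis, all components > 0.
    modality : {"T1w", "T2w", "T2star"}
    axial_axis : int
        Index of the through-plane axis (always 2 in internal order).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    axial_axis: int = AXIAL_AXIS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise DataError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be three positive floats, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise DataError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if not np.isfinite(self.data).all():
            raise DataError(f"{self.modality} volume contains NaN/Inf voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SubjectCase:
    """All co-registered volumes of one participant.

    Grids of every member must agree in shape and spacing (the
    co-registration contract).  ``microbleed_gt`` is the voxel-wise manual
    ground truth used for training and evaluation; ``vessel_mask`` and
    ``lesion_manifest`` are extra annotations produced by the phantom
    generator so tests can reason about confounders unambiguously.
    """

    subject_id: str
    t1: ContrastVolume
    t2: ContrastVolume
    t2star: ContrastVolume
    brain_mask: np.ndarray
    tissue_labels: np.ndarray
    wmh_mask: np.ndarray | None = None
    microbleed_gt: np.ndarray | None = None
    vessel_mask: np.ndarray | None = None
    lesion_manifest: list[dict] | None = None

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=np.int16)
        for name in ("wmh_mask", "microbleed_gt", "vessel_mask"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v).astype(bool))
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2star.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.t2star.spacing

    def validate(self) -> None:
        shape, spacing = self.t2star.shape, self.t2star.spacing
        for vol in (self.t1, self.t2):
            if vol.shape != shape:
                raise CoRegistrationError(
                    f"{self.subject_id}: {vol.modality} shape {vol.shape} != T2* shape {shape}"
                )
            if not np.allclose(vol.spacing, spacing):
                raise CoRegistrationError(
                    f"{self.subject_id}: {vol.modality} spacing {vol.spacing} != {spacing}"
                )
        for name in ("brain_mask", "tissue_labels", "wmh_mask", "microbleed_gt", "vessel_mask"):
            grid = getattr(self, name)
            if grid is not None and grid.shape != shape:
                raise CoRegistrationError(
                    f"{self.subject_id}: {name} shape {grid.shape} != {shape}"
                )
        if self.microbleed_gt is not None and np.any(self.microbleed_gt & ~self.brain_mask):
            raise DataError(f"{self.subject_id}: microbleed ground truth outside brain mask")
        if np.any((self.tissue_labels == Tissue.BACKGROUND) & self.brain_mask):
            raise DataError(f"{self.subject_id}: background tissue label inside brain mask")


def standardize_intensity(
    vol: ContrastVolume,
    mask: np.ndarray,
    clip_percentiles: tuple[float, float] | None = None,
) -> ContrastVolume:
    """Linearly map intensities inside ``mask`` onto the range [0, 100].

    The minimum maps to 0 and the maximum to 100; voxels outside the mask
    are set to 0.  The map is strictly monotone on the masked voxels and
    idempotent.  With ``clip_percentiles=(lo, hi)`` the linear map is
    anchored at those in-mask percentiles instead of min/max and values
    are clipped to [0, 100] afterwards (off by default).

    Raises
    ------
    DegenerateInputError
        If the image is constant inside the mask (no linear map exists).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise CoRegistrationError("mask shape does not match volume")
    inside = vol.data[mask]
    if inside.size < 2:
        raise DegenerateInputError("mask selects fewer than 2 voxels")
    if clip_percentiles is None:
        lo, hi = float(inside.min()), float(inside.max())
    else:
        plo, phi = clip_percentiles
        if not 0.0 <= plo < phi <= 100.0:
            raise DegenerateInputError(f"invalid clip percentiles {clip_percentiles}")
        lo, hi = (float(x) for x in np.percentile(inside, [plo, phi]))
    if hi <= lo:
        raise DegenerateInputError("image is constant inside the mask; no linear map exists")
    out = np.zeros_like(vol.data)
    out[mask] = (vol.data[mask] - lo) * (100.0 / (hi - lo))
    if clip_percentiles is not None:
        np.clip(out, 0.0, 100.0, out=out)
    return replace(vol, data=out)


# ---------------------------------------------------------------------------
# NIfTI round-trip


_CASE_ROLES = {
    "t1": "t1.nii.gz",
    "t2": "t2.nii.gz",
    "t2star": "t2star.nii.gz",
    "brain_mask": "brain_mask.nii.gz",
    "tissue_labels": "tissue_labels.nii.gz",
    "wmh_mask": "wmh_mask.nii.gz",
    "microbleed_gt": "microbleed_gt.nii.gz",
    "vessel_mask": "vessel_mask.nii.gz",
}


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _load_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not Path(path).exists():
        raise DataError(f"missing volume file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"{path}: expected 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_case(case: SubjectCase, out_dir: str | Path) -> Path:
    """Write all volumes of a case as NIfTI plus a JSON sidecar of roles.

    Scalar contrasts are stored as float32, masks as uint8 and tissue
    labels as int16, so integer volumes round-trip exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(case.spacing)
    sidecar: dict = {"subject_id": case.subject_id, "files": {}}
    for role, vol in (("t1", case.t1), ("t2", case.t2), ("t2star", case.t2star)):
        fname = _CASE_ROLES[role]
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), aff), str(out_dir / fname))
        sidecar["files"][role] = fname
    int_vols = {
        "brain_mask": case.brain_mask.astype(np.uint8),
        "tissue_labels": case.tissue_labels.astype(np.int16),
    }
    for role in ("wmh_mask", "microbleed_gt", "vessel_mask"):
        grid = getattr(case, role)
        if grid is not None:
            int_vols[role] = grid.astype(np.uint8)
    for role, arr in int_vols.items():
        fname = _CASE_ROLES[role]
        nib.save(nib.Nifti1Image(arr, aff), str(out_dir / fname))
        sidecar["files"][role] = fname
    if case.lesion_manifest is not None:
        sidecar["lesion_manifest"] = case.lesion_manifest
    sidecar_path = out_dir / "case.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def load_case(case_dir: str | Path, subject_id: str | None = None) -> SubjectCase:
    """Load a SubjectCase from a directory written by :func:`save_case`.

    The JSON sidecar ``case.json`` lists the role of each NIfTI file.
    Shape or spacing disagreements between the contrasts are rejected.
    """
    case_dir = Path(case_dir)
    sidecar_path = case_dir / "case.json"
    if not sidecar_path.exists():
        raise DataError(f"missing case sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    files = sidecar["files"]
    for role in ("t1", "t2", "t2star", "brain_mask", "tissue_labels"):
        if role not in files:
            raise DataError(f"case sidecar lacks required role {role!r}")

    def vol(role: str, modality: str) -> ContrastVolume:
        data, spacing = _load_volume(case_dir / files[role])
        return ContrastVolume(data=data, spacing=spacing, modality=modality)

    grids = {}
    for role in ("brain_mask", "tissue_labels", "wmh_mask", "microbleed_gt", "vessel_mask"):
        if role in files:
            grids[role], _ = _load_volume(case_dir / files[role])
    return SubjectCase(
        subject_id=subject_id or sidecar.get("subject_id", case_dir.name),
        t1=vol("t1", "T1w"),
        t2=vol("t2", "T2w"),
        t2star=vol("t2star", "T2star"),
        brain_mask=grids["brain_mask"],
        tissue_labels=grids["tissue_labels"],
        wmh_mask=grids.get("wmh_mask"),
        microbleed_gt=grids.get("microbleed_gt"),
        vessel_mask=grids.get("vessel_mask"),
        lesion_manifest=sidecar.get("lesion_manifest"),
    )
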