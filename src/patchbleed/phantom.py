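"""Synthetic multi-contrast brain phantoms with known microbleed ground truth.

The generator emulates the statistical structure of the study data rather
than MR physics: an ellipsoidal "brain" with peripheral CSF, a cortical
gray-matter rind, central deep gray matter, ventricular CSF, white matter,
and a posterior-inferior cerebellar compartment.  Into the tissue it
places

* roughly spherical microbleeds, hypointense on T2*, drawn in three size
  classes — small (1-4 voxels), medium (5-15 voxels), large (>15 voxels);
* elongated vessel-like confounders near the cortical surface, equally
  hypointense on T2* but longer than the 10 mm lesion-diameter cutoff, so
  they behave exactly like the false positives the post-processing stage
  is designed to remove.

Contrast polarity matches the real data: CSF is hyperintense on T2w/T2*
and dark on T1w, microbleeds are hypointense on T2*.  All contrasts are
linearly standardized to [0, 100] over the brain mask, and the mean T2*
intensity inside a microbleed is far below the mean of its 2-voxel shell,
so true lesions survive intensity-ratio pruning by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .volume_io import ContrastVolume, SubjectCase, Tissue, standardize_intensity

SIZE_CLASSES = ("small", "medium", "large")
#: inclusive voxel-count bounds per size class
SIZE_CLASS_BOUNDS = {"small": (1, 4), "medium": (5, 15), "large": (16, 24)}

#: mean intensity per (tissue, modality) on the nominal 0-100 scale,
#: ordered (T2star, T2w, T1w)
DEFAULT_TISSUE_INTENSITIES: dict[int, tuple[float, float, float]] = {
    int(Tissue.CSF): (85.0, 90.0, 10.0),
    int(Tissue.CORTICAL_GM): (60.0, 60.0, 45.0),
    int(Tissue.DEEP_GM): (55.0, 58.0, 50.0),
    int(Tissue.WM): (45.0, 48.0, 70.0),
    int(Tissue.CEREBELLAR_GM): (60.0, 60.0, 45.0),
    int(Tissue.CEREBELLAR_WM): (45.0, 48.0, 70.0),
}


@dataclass
class PhantomParams:
    """Parameters of one synthetic subject.

    The defaults mirror the T2* acquisition grid anisotropy (~1 x 1 x 3 mm)
    at a desk-scale matrix, and a lesion load typical of an aging cohort
    with low microbleed counts per scan.
    """

    shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_microbleeds_per_class: tuple[int, int, int] = (2, 2, 1)
    n_vessels: int = 3
    vessel_length_mm: tuple[float, float] = (12.0, 16.0)
    tissue_intensity_table: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_INTENSITIES)
    )
    microbleed_intensity: tuple[float, float, float] = (12.0, 40.0, 45.0)
    vessel_intensity: tuple[float, float, float] = (18.0, 40.0, 45.0)
    noise_sd: float = 3.0
    #: Gaussian partial-volume blur (mm) applied to the noise-free
    #: intensity image; emulates the point-spread/partial-volume mixing
    #: that makes thin CSF and 1-4 voxel lesions blend with their
    #: surroundings at ~1 mm resolution.
    partial_volume_mm: float = 0.5
    n_wmh: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_microbleeds_per_class) or self.n_vessels < 0:
            raise ConfigError("lesion/vessel counts must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("spacing must be positive")
        tbl = self.tissue_intensity_table
        t2s = 0  # T2* channel index
        mb = self.microbleed_intensity[t2s]
        for t in (Tissue.WM, Tissue.CORTICAL_GM, Tissue.DEEP_GM):
            if mb >= tbl[int(t)][t2s]:
                raise ConfigError("microbleeds must be hypointense on T2* vs GM/WM")
        for t in (Tissue.WM, Tissue.CORTICAL_GM):
            if tbl[int(Tissue.CSF)][t2s] <= tbl[int(t)][t2s]:
                raise ConfigError("CSF must be hyperintense on T2* vs GM/WM")


def _anatomy(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Build brain mask and tissue labels on the given grid."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.44 * nx, 0.44 * ny, 0.44 * nz
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)
    brain = r <= 1.0
    labels = np.zeros(shape, dtype=np.int16)

    cerebellum = brain & (y >= cy + 0.42 * ay) & (z <= cz)
    rim = brain & (r > 0.93)                      # peripheral (sulcal) CSF
    rind = brain & (r > 0.78) & (r <= 0.93)       # cortical ribbon
    interior = brain & (r <= 0.78)

    labels[interior] = Tissue.WM
    labels[interior & cerebellum] = Tissue.CEREBELLAR_WM
    labels[rind] = Tissue.CORTICAL_GM
    labels[rind & cerebellum] = Tissue.CEREBELLAR_GM

    # central deep GM nuclei and two lateral ventricles
    deep = (
        (((x - cx) / 16) ** 2 + ((y - (cy - 2)) / 12) ** 2 + ((z - cz) / 4.5) ** 2) <= 1.0
    ) & interior & ~cerebellum
    labels[deep] = Tissue.DEEP_GM
    for sx in (-1.0, 1.0):
        vent = (
            ((x - (cx + sx * 9)) / 4.5) ** 2
            + ((y - (cy - 4)) / 8) ** 2
            + ((z - cz) / 2.2) ** 2
        ) <= 1.0
        labels[vent & interior] = Tissue.CSF
    labels[rim] = Tissue.CSF
    return brain, labels


def _sphere_lesion(
    center: tuple[int, int, int],
    n_voxels: int,
    allowed: np.ndarray,
    spacing: tuple[float, float, float],
) -> np.ndarray | None:
    """Voxel mask of the ``n_voxels`` allowed voxels nearest to ``center``
    in mm, i.e. an approximately spherical lesion on the anisotropic grid.
    Returns None if the ball would have to stretch beyond a compact
    neighborhood (placement rejected)."""
    shape = allowed.shape
    # local window large enough for any lesion size used here
    rad = (8, 8, 3)
    sl = tuple(
        slice(max(0, c - r), min(s, c + r + 1)) for c, r, s in zip(center, rad, shape)
    )
    sub_allowed = allowed[sl]
    coords = np.argwhere(sub_allowed)
    if len(coords) < n_voxels:
        return None
    offset = np.array([s.start for s in sl])
    d = np.linalg.norm((coords + offset - np.array(center)) * np.array(spacing), axis=1)
    order = np.argsort(d, kind="stable")
    chosen = coords[order[:n_voxels]] + offset
    # compactness guard: the chosen ball must not be forced around obstacles
    if d[order[n_voxels - 1]] > 1.5 * (3.0 * n_voxels * np.prod(spacing) / (4 * np.pi)) ** (1 / 3) + max(spacing):
        return None
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(chosen.T)] = True
    # single connected component under 26-connectivity
    _, k = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if k != 1:
        return None
    return mask


def _place_microbleeds(
    labels: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    gm_wm = np.isin(
        labels,
        [Tissue.CORTICAL_GM, Tissue.DEEP_GM, Tissue.WM, Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM],
    )
    gt = np.zeros(labels.shape, dtype=bool)
    manifest: list[dict] = []
    forbidden = np.zeros(labels.shape, dtype=bool)
    lesion_id = 0
    for cls, count in zip(SIZE_CLASSES, params.n_microbleeds_per_class):
        lo, hi = SIZE_CLASS_BOUNDS[cls]
        for _ in range(count):
            n_vox = int(rng.integers(lo, hi + 1))
            placed = False
            for _attempt in range(300):
                cand = np.argwhere(gm_wm & ~forbidden)
                if len(cand) == 0:
                    break
                center = tuple(cand[rng.integers(len(cand))])
                mask = _sphere_lesion(center, n_vox, gm_wm & ~forbidden, params.spacing)
                if mask is None:
                    continue
                gt |= mask
                # clearance so that components, their 2-voxel shells and
                # any detection halo stay unambiguous between lesions
                forbidden |= ndimage.binary_dilation(mask, np.ones((3, 3, 3)), iterations=5)
                lesion_id += 1
                manifest.append(
                    {
                        "id": lesion_id,
                        "center": [int(c) for c in center],
                        "n_voxels": n_vox,
                        "size_class": cls,
                        "tissue": int(labels[center]),
                    }
                )
                placed = True
                break
            if not placed:
                raise DataError(
                    f"could not place a {cls} microbleed ({n_vox} voxels); volume too small"
                )
    return gt, manifest


def _place_vessels(
    labels: np.ndarray,
    brain: np.ndarray,
    gt: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """In-plane elongated hypointense confounders hugging the cortex."""
    vessels = np.zeros(labels.shape, dtype=bool)
    if params.n_vessels == 0:
        return vessels
    # wide berth around true lesions: false positives on vessels must be
    # unambiguous, even after partial-volume halos inflate detections
    keepout = ndimage.binary_dilation(gt, np.ones((3, 3, 3)), iterations=6)
    cortical = np.isin(labels, [Tissue.CORTICAL_GM, Tissue.CEREBELLAR_GM])
    nx, ny, _ = labels.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    placed = 0
    for _attempt in range(500):
        if placed >= params.n_vessels:
            break
        cand = np.argwhere(cortical & ~keepout)
        if len(cand) == 0:
            break
        mx, my, mz = cand[rng.integers(len(cand))]
        theta = rng.uniform(0, np.pi)
        ux, uy = np.cos(theta), np.sin(theta)
        half = rng.uniform(*params.vessel_length_mm) / 2.0  # in-plane spacing ~1 mm
        # distance from each in-plane voxel to the segment through (mx,my)
        t = np.clip((xx - mx) * ux + (yy - my) * uy, -half, half)
        d = np.hypot(xx - mx - t * ux, yy - my - t * uy)
        seg = (d <= 1.0) & brain[:, :, mz] & (labels[:, :, mz] != Tissue.CSF)
        if seg.sum() < 2 * half:  # clipped too much by the brain boundary
            continue
        if np.any(seg & keepout[:, :, mz]):
            continue
        vessels[:, :, mz] |= seg
        keepout[:, :, mz] |= ndimage.binary_dilation(seg, np.ones((3, 3)), iterations=3)
        placed += 1
    if placed < params.n_vessels:
        raise DataError(f"could only place {placed}/{params.n_vessels} vessel confounders")
    return vessels


def generate_case(params: PhantomParams, subject_id: str = "phantom-000") -> SubjectCase:
    """Generate one synthetic subject; identical params+seed give an
    identical case bit for bit."""
    rng = np.random.default_rng(params.seed)
    brain, labels = _anatomy(params.shape)
    gt, manifest = _place_microbleeds(labels, params, rng)
    vessels = _place_vessels(labels, brain, gt, params, rng)

    wmh = None
    if params.n_wmh > 0:
        wmh = np.zeros(params.shape, dtype=bool)
        wm = labels == Tissue.WM
        for _ in range(params.n_wmh):
            cand = np.argwhere(wm & ~gt & ~vessels)
            center = tuple(cand[rng.integers(len(cand))])
            blob = _sphere_lesion(center, int(rng.integers(8, 20)), wm, params.spacing)
            if blob is not None:
                wmh |= blob

    vols = {}
    for ch, modality in enumerate(("T2star", "T2w", "T1w")):
        img = np.zeros(params.shape, dtype=np.float32)
        for tissue, means in params.tissue_intensity_table.items():
            img[labels == tissue] = means[ch]
        if wmh is not None and modality == "T2w":
            img[wmh] += 25.0
        img[gt] = params.microbleed_intensity[ch]
        img[vessels] = params.vessel_intensity[ch]
        if params.partial_volume_mm > 0:
            sigma = tuple(params.partial_volume_mm / s for s in params.spacing)
            img = ndimage.gaussian_filter(img, sigma=sigma)
        img += rng.normal(0.0, params.noise_sd, size=params.shape).astype(np.float32)
        vol = ContrastVolume(data=img, spacing=params.spacing, modality=modality)
        vols[modality] = standardize_intensity(vol, brain)

    return SubjectCase(
        subject_id=subject_id,
        t1=vols["T1w"],
        t2=vols["T2w"],
        t2star=vols["T2star"],
        brain_mask=brain,
        tissue_labels=labels,
        wmh_mask=wmh,
        microbleed_gt=gt,
        vessel_mask=vessels,
        lesion_manifest=manifest,
    )


#: default per-class lesion-count ranges (inclusive) for cohort sampling;
#: every subject carries at least one medium lesion, matching a cohort
#: selected for the presence of microbleeds
DEFAULT_COHORT_RANGES = {"small": (0, 3), "medium": (1, 3), "large": (0, 2), "vessels": (1, 4)}


def generate_cohort(
    n_subjects: int,
    base_params: PhantomParams | None = None,
    seed: int = 0,
    count_ranges: dict[str, tuple[int, int]] | None = None,
) -> list[SubjectCase]:
    """Generate ``n_subjects`` phantoms with per-subject lesion loads drawn
    from ``count_ranges`` and per-subject seeds derived from ``seed``."""
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    base = base_params if base_params is not None else PhantomParams()
    ranges = dict(DEFAULT_COHORT_RANGES)
    if count_ranges:
        ranges.update(count_ranges)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    draw = np.random.default_rng(master.integers(0, 2**31 - 1))
    cases = []
    for i in range(n_subjects):
        counts = tuple(
            int(draw.integers(ranges[c][0], ranges[c][1] + 1)) for c in SIZE_CLASSES
        )
        n_vessels = int(draw.integers(ranges["vessels"][0], ranges["vessels"][1] + 1))
        params = replace(
            base,
            n_microbleeds_per_class=counts,
            n_vessels=n_vessels,
            seed=int(child_seeds[i]),
        )
        cases.append(generate_case(params, subject_id=f"sub-{i:03d}"))
    return cases
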