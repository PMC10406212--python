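"""False-positive pruning, size cutoff and region categorization.

Candidate lesions are refined with local intensity rules on the T2*
volume (standardized to [0, 100]):

1.  Each lesion is dilated by two voxels; the dilated ring minus the
    lesion is its *shell*, the local intensity reference.
2.  Border voxels whose contrast against the shell is too weak are
    removed, and the test is repeated until a fixed point: a border voxel
    is kept iff ``mean(shell T2*) / voxel T2* >= ratio_threshold``, i.e.
    only voxels sufficiently darker than their surround survive.  (The
    reciprocal reading — remove when voxel/shell is below the threshold —
    is available as ``literal_ratio=True`` for auditing, but with
    thresholds above 1 it would delete every hypointense lesion.)
3.  Lesions whose maximum diameter exceeds 10 mm are discarded (large
    hemorrhages and elongated vessel-like structures); there is no
    minimum size, so single-voxel lesions are kept.
4.  Survivors are assigned the brain region (cortical GM, deep GM, WM,
    cerebellar GM, cerebellar WM) they overlap most; deep GM may use a
    stricter ratio threshold than the rest, so the region is determined
    *before* pruning.

White-matter-hyperintensity corrections are applied to the tissue labels
first: WMH voxels labeled cortical/deep GM become WM, and WMH voxels
labeled cerebellar GM become cerebellar WM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .inference import LesionMap, label_components
from .volume_io import ContrastVolume, REGION_TISSUES, SubjectCase, Tissue

#: region priority for overlap ties (highest first)
REGION_PRIORITY = (
    Tissue.DEEP_GM,
    Tissue.CORTICAL_GM,
    Tissue.WM,
    Tissue.CEREBELLAR_GM,
    Tissue.CEREBELLAR_WM,
)

UNCATEGORIZED = -1


@dataclass
class PruningParams:
    """Parameters of the false-positive pruning stage."""

    dilation_voxels: int = 2
    ratio_threshold: float = 1.2
    max_diameter_mm: float = 10.0
    literal_ratio: bool = False

    def __post_init__(self) -> None:
        if self.dilation_voxels < 1:
            raise ConfigError("dilation_voxels must be >= 1")
        if self.ratio_threshold <= 0 or self.max_diameter_mm <= 0:
            raise ConfigError("ratio_threshold and max_diameter_mm must be > 0")


def correct_tissue_labels(tissue: np.ndarray, wmh: np.ndarray) -> np.ndarray:
    """Relabel WMH voxels: cortical/deep GM -> WM, cerebellar GM ->
    cerebellar WM.  All other voxels are unchanged."""
    tissue = np.asarray(tissue)
    wmh = np.asarray(wmh).astype(bool)
    if tissue.shape != wmh.shape:
        raise DataError("tissue and WMH grids must share a grid")
    out = tissue.copy()
    out[wmh & np.isin(tissue, [Tissue.CORTICAL_GM, Tissue.DEEP_GM])] = Tissue.WM
    out[wmh & (tissue == Tissue.CEREBELLAR_GM)] = Tissue.CEREBELLAR_WM
    return out


def _lesion_mask(voxels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(np.asarray(voxels).T)] = True
    return mask


def dilate_shell(
    voxels: np.ndarray,
    shape: tuple[int, int, int],
    dilation_voxels: int = 2,
) -> np.ndarray:
    """Shell of a lesion: ``dilation_voxels`` iterations of unit
    (26-connected) dilation minus the lesion itself, clipped to the grid.
    Returns the (n, 3) shell voxel coordinates."""
    voxels = np.asarray(voxels)
    if len(voxels) == 0:
        raise DataError("empty lesion has no shell")
    mask = _lesion_mask(voxels, shape)
    dilated = ndimage.binary_dilation(mask, np.ones((3, 3, 3)), iterations=dilation_voxels)
    return np.argwhere(dilated & ~mask)


def _border_voxels(mask: np.ndarray) -> np.ndarray:
    """Lesion voxels with at least one non-lesion 26-neighbor."""
    interior = ndimage.binary_erosion(mask, np.ones((3, 3, 3)), border_value=0)
    return np.argwhere(mask & ~interior)


def prune_lesion(
    voxels: np.ndarray,
    t2star: ContrastVolume,
    params: PruningParams,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Iterative border-voxel removal by the shell intensity-ratio test.

    At each pass the shell of the *current* lesion is recomputed and every
    border voxel failing the contrast test is removed; the process stops
    at a fixed point (each pass removes at least one voxel, so it ends in
    at most |lesion| passes).  Returns the (possibly empty) retained
    voxel coordinates.
    """
    data = t2star.data
    shape = data.shape
    current = np.asarray(voxels)
    if len(current) == 0:
        return current.reshape(0, 3)
    while len(current):
        mask = _lesion_mask(current, shape)
        shell = dilate_shell(current, shape, params.dilation_voxels)
        if brain_mask is not None:
            inside = brain_mask[tuple(shell.T)]
            shell = shell[inside]
        if len(shell) == 0:
            raise DataError("lesion has no shell (fills the grid / brain mask)")
        shell_mean = float(data[tuple(shell.T)].mean())
        border = _border_voxels(mask)
        vals = data[tuple(border.T)].astype(np.float64)
        if params.literal_ratio:
            # printed form: remove when voxel/shell < threshold
            with np.errstate(divide="ignore"):
                remove = np.where(shell_mean > 0, vals / shell_mean, np.inf) < params.ratio_threshold
        else:
            # consistent form: keep only voxels darker than the shell by
            # the threshold factor (shell/voxel >= threshold)
            ratio = np.full(len(vals), np.inf)
            pos = vals > 0
            ratio[pos] = shell_mean / vals[pos]
            remove = ratio < params.ratio_threshold
        if not remove.any():
            break
        drop = {tuple(v) for v in border[remove]}
        current = np.array([v for v in current if tuple(v) not in drop], dtype=int)
        if len(current) == 0:
            break
    return current.reshape(-1, 3) if len(current) else np.empty((0, 3), dtype=int)


def lesion_diameter_mm(voxels: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Maximum pairwise voxel-center distance in mm plus one voxel extent.

    The extent is that of a voxel cuboid *along the direction of the
    farthest pair* (sum of |u_k| * spacing_k over axes), so an in-plane
    pair on an anisotropic grid is not inflated by the slice thickness.
    A single voxel has diameter max(spacing), hence nonzero."""
    pts = np.asarray(voxels, dtype=float) * np.asarray(spacing)
    if len(pts) == 0:
        raise DataError("empty lesion")
    if len(pts) == 1:
        return float(max(spacing))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(d2.argmax()), d2.shape)
    dist = float(np.sqrt(d2[i, j]))
    u = (pts[i] - pts[j]) / dist
    extent = float(np.abs(u) @ np.asarray(spacing))
    return dist + extent


def apply_size_cutoff(
    voxels: np.ndarray,
    spacing: tuple[float, float, float],
    max_diameter_mm: float = 10.0,
) -> bool:
    """Keep (True) iff the lesion diameter is at most ``max_diameter_mm``
    (inclusive).  There is no minimum size: 1-voxel lesions pass whenever
    a voxel fits the cutoff."""
    return lesion_diameter_mm(voxels, spacing) <= max_diameter_mm


def categorize_region(voxels: np.ndarray, tissue: np.ndarray) -> int:
    """Region with the largest voxel overlap among the five categories;
    ties break by the fixed priority deep GM > cortical GM > WM >
    cerebellar GM > cerebellar WM.  Returns ``UNCATEGORIZED`` for lesions
    overlapping none of them (e.g. only CSF/background)."""
    voxels = np.asarray(voxels)
    if len(voxels) == 0:
        raise DataError("empty lesion")
    labels = tissue[tuple(voxels.T)]
    best, best_count = UNCATEGORIZED, 0
    for region in REGION_PRIORITY:
        count = int(np.sum(labels == region))
        if count > best_count:
            best, best_count = int(region), count
    return best


def postprocess_map(
    seg: np.ndarray,
    case: SubjectCase,
    params: PruningParams | None = None,
    per_region_thresholds: dict[int, float] | None = None,
    connectivity: int = 26,
) -> LesionMap:
    """Full post-processing: label components, categorize, prune with the
    region's threshold, apply the size cutoff, and return the retained
    lesions with region labels.

    ``per_region_thresholds`` maps Tissue codes to ratio thresholds
    (e.g. ``{Tissue.DEEP_GM: 1.4}``); regions not listed use
    ``params.ratio_threshold``.  Output voxels are always a subset of the
    input segmentation.
    """
    params = params or PruningParams()
    seg = np.asarray(seg).astype(bool)
    if seg.shape != case.shape:
        raise DataError("segmentation grid does not match case")
    tissue = case.tissue_labels
    if case.wmh_mask is not None:
        tissue = correct_tissue_labels(tissue, case.wmh_mask)
    initial = label_components(seg, connectivity)
    out = np.zeros(case.shape, dtype=np.int32)
    lesions: dict[int, np.ndarray] = {}
    regions: dict[int, int] = {}
    next_id = 1
    for lid in sorted(initial.lesions):
        voxels = initial.lesions[lid]
        region = categorize_region(voxels, tissue)
        if region == UNCATEGORIZED:
            continue
        threshold = params.ratio_threshold
        if per_region_thresholds and region in per_region_thresholds:
            threshold = per_region_thresholds[region]
        local = PruningParams(
            dilation_voxels=params.dilation_voxels,
            ratio_threshold=threshold,
            max_diameter_mm=params.max_diameter_mm,
            literal_ratio=params.literal_ratio,
        )
        kept = prune_lesion(voxels, case.t2star, local, brain_mask=case.brain_mask)
        if len(kept) == 0:
            continue
        # pruning may disconnect a candidate (e.g. two lesions bridged by
        # weak-contrast voxels); re-split and size-filter each remnant
        remnant = np.zeros(case.shape, dtype=bool)
        remnant[tuple(kept.T)] = True
        for piece in label_components(remnant, connectivity).lesions.values():
            if not apply_size_cutoff(piece, case.spacing, params.max_diameter_mm):
                continue
            out[tuple(piece.T)] = next_id
            lesions[next_id] = piece
            regions[next_id] = region
            next_id += 1
    return LesionMap(labels=out, lesions=lesions, connectivity=connectivity, regions=regions)


def lesion_report(lesion_map: LesionMap, case: SubjectCase) -> "pd.DataFrame":
    """Per-lesion summary table: id, voxel count, volume, region, mean
    T2* intensity."""
    import pandas as pd

    voxel_volume = float(np.prod(case.spacing))
    region_names = {int(t): t.name for t in Tissue}
    rows = []
    for lid, voxels in sorted(lesion_map.lesions.items()):
        region = (lesion_map.regions or {}).get(lid, UNCATEGORIZED)
        rows.append(
            {
                "lesion_id": lid,
                "n_voxels": len(voxels),
                "volume_mm3": len(voxels) * voxel_volume,
                "region": region_names.get(region, "uncategorized"),
                "mean_t2star": float(case.t2star.data[tuple(voxels.T)].mean()),
                "diameter_mm": lesion_diameter_mm(voxels, case.spacing),
            }
        )
    return pd.DataFrame(rows)
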