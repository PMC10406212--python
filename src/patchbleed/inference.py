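"""Voxel-wise application of the patch classifier and 3D reconstruction.

Every voxel of the search mask is classified from the axial patch
centered on it (stride 1, zero-padded at volume borders), the positive
decisions are reconstructed into a 3D binary map, and connected
components become candidate lesions.  The search mask defaults to the
brain mask and can be restricted by excluding CSF and T2*-hyperintense
voxels, which cannot contain microbleeds and dominate runtime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import ConfigError, DataError
from .volume_io import SubjectCase, Tissue


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ConfigError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass
class LesionMap:
    """3D integer-labeled connected components.

    ``labels`` holds 0 for background and 1..K for lesions; ``lesions``
    maps each id to its (n, 3) voxel-coordinate array.  Components are
    numbered in lexicographic order of their minimum voxel coordinate,
    so labeling is deterministic.
    """

    labels: np.ndarray
    lesions: dict[int, np.ndarray]
    connectivity: int = 26
    regions: dict[int, int] | None = None  # lesion id -> Tissue code

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def binary(self) -> np.ndarray:
        return self.labels > 0


def label_components(binary: np.ndarray, connectivity: int = 26) -> LesionMap:
    """Label maximal connected components of a binary grid."""
    binary = np.asarray(binary).astype(bool)
    raw, k = ndimage.label(binary, structure=_structure(connectivity))
    # renumber by lexicographic minimum voxel coordinate for determinism
    order = []
    for lid in range(1, k + 1):
        coords = np.argwhere(raw == lid)
        key = tuple(coords[np.lexsort(coords.T[::-1])][0])
        order.append((key, lid, coords))
    order.sort(key=lambda t: t[0])
    labels = np.zeros_like(raw)
    lesions: dict[int, np.ndarray] = {}
    for new_id, (_key, _old, coords) in enumerate(order, start=1):
        labels[tuple(coords.T)] = new_id
        lesions[new_id] = coords
    return LesionMap(labels=labels, lesions=lesions, connectivity=connectivity)


def restrict_search_mask(
    case: SubjectCase,
    exclude_csf: bool = True,
    hyperintensity_percentile: float | None = 99.0,
) -> np.ndarray:
    """Brain mask minus voxels that cannot contain a microbleed:
    CSF-labeled voxels and the brightest T2* voxels (above the given
    in-brain percentile).  Always a subset of the brain mask."""
    mask = case.brain_mask.copy()
    if exclude_csf:
        mask &= case.tissue_labels != Tissue.CSF
    if hyperintensity_percentile is not None:
        cut = float(np.percentile(case.t2star.data[case.brain_mask], hyperintensity_percentile))
        mask &= case.t2star.data <= cut
    return mask


def segment_volume(
    case: SubjectCase,
    model,
    patch_size: int = 28,
    decision_threshold: float = 0.5,
    search_mask: np.ndarray | None = None,
    batch_size: int = 2048,
) -> np.ndarray:
    """Classify every voxel of the search mask from its centered axial
    patch and return the binary microbleed map.

    ``model`` is anything with ``predict_proba`` over (n, 3, p, p) patch
    stacks (column 1 = positive probability).  Voxels outside the search
    mask are 0.  Classification is stateless, so the voxel order cannot
    affect the result.
    """
    if not 0.0 < decision_threshold < 1.0:
        raise ConfigError("decision_threshold must be in (0, 1)")
    nx, ny, nz = case.shape
    if patch_size > nx or patch_size > ny:
        raise DataError(f"patch_size {patch_size} exceeds in-plane grid {(nx, ny)}")
    mask = case.brain_mask if search_mask is None else np.asarray(search_mask).astype(bool)
    out = np.zeros(case.shape, dtype=bool)
    half = patch_size // 2
    pad = ((half, patch_size - half), (half, patch_size - half))
    channels = (case.t2star.data, case.t2.data, case.t1.data)
    for z in range(nz):
        coords = np.argwhere(mask[:, :, z])
        if len(coords) == 0:
            continue
        # padded slices so that window[x, y] is the patch centered on (x, y)
        windows = [
            sliding_window_view(np.pad(c[:, :, z], pad), (patch_size, patch_size))
            for c in channels
        ]
        for start in range(0, len(coords), batch_size):
            chunk = coords[start : start + batch_size]
            patches = np.stack(
                [w[chunk[:, 0], chunk[:, 1]] for w in windows], axis=1
            )  # (b, 3, p, p)
            prob_pos = model.predict_proba(patches)[:, 1]
            keep = chunk[prob_pos >= decision_threshold]
            out[keep[:, 0], keep[:, 1], z] = True
    return out
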