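"""Balanced, leakage-free patch datasets for the two classification tasks.

Two tasks share the same machinery:

* ``"csf"`` — CSF-vs-tissue pretraining: positive patches are centered on
  a CSF voxel, background patches on a GM or WM voxel.
* ``"microbleed"`` — the target task: positive patches are centered on a
  ground-truth microbleed voxel, background patches on any brain voxel
  outside the microbleed mask.

Patches are 2D multi-contrast windows from the axial plane (the plane
with the highest resolution), with channels ordered (T2*, T2w, T1w).
Half of every emitted dataset is positive and half background.  Splits
are performed at the participant level so no subject contributes patches
to more than one of train/validation/test, optionally stratified by the
subject's largest-lesion size class.  Rotation augmentation rotates the
full axial slice about the positive voxel before extraction, so patch
corners contain novel content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .phantom import SIZE_CLASS_BOUNDS
from .volume_io import SubjectCase, Tissue

TASKS = ("csf", "microbleed")
#: channel order of every patch
CHANNEL_MODALITIES = ("T2star", "T2w", "T1w")


@dataclass
class PatchRecord:
    """One labeled 2D multi-contrast patch."""

    subject_id: str
    center: tuple[int, int, int]
    label: int  # 1 = positive, 0 = background
    task: str
    patch_size: int
    channels: np.ndarray  # (3, patch_size, patch_size), order (T2*, T2w, T1w)
    angle: float = 0.0  # rotation used for augmentation, degrees

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.shape != (3, self.patch_size, self.patch_size):
            raise DataError(
                f"channels shape {self.channels.shape} != (3, {self.patch_size}, {self.patch_size})"
            )


@dataclass
class DatasetSplit:
    """Participant-level partition into train/validation/test."""

    train: set[str]
    val: set[str]
    test: set[str]
    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        sets = [self.train, self.val, self.test]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise DataError("split sets must be pairwise disjoint")

    def subset(self, cases: list[SubjectCase], which: str) -> list[SubjectCase]:
        ids = getattr(self, which)
        return [c for c in cases if c.subject_id in ids]


def _case_channels(case: SubjectCase) -> tuple[np.ndarray, ...]:
    return (case.t2star.data, case.t2.data, case.t1.data)


def extract_patch(case: SubjectCase, center: tuple[int, int, int], patch_size: int) -> np.ndarray:
    """Axial window of each contrast centered on ``center``.

    For even sizes the center voxel sits at in-patch index
    ``patch_size // 2``; windows reaching past the volume border are
    zero-padded.
    """
    x, y, z = (int(c) for c in center)
    half = patch_size // 2
    lo_x, lo_y = x - half, y - half
    out = np.zeros((3, patch_size, patch_size), dtype=np.float32)
    nx, ny, nz = case.shape
    if not (0 <= z < nz):
        raise DataError(f"center slice {z} outside volume")
    sx = slice(max(0, lo_x), min(nx, lo_x + patch_size))
    sy = slice(max(0, lo_y), min(ny, lo_y + patch_size))
    px = slice(sx.start - lo_x, sx.stop - lo_x)
    py = slice(sy.start - lo_y, sy.stop - lo_y)
    for ch, vol in enumerate(_case_channels(case)):
        out[ch, px, py] = vol[sx, sy, z]
    return out


def largest_lesion_class(case: SubjectCase) -> str:
    """Stratification key: size class of the subject's largest lesion
    ('none' if the subject has no microbleeds)."""
    if case.microbleed_gt is None or not case.microbleed_gt.any():
        return "none"
    labeled, k = ndimage.label(case.microbleed_gt, structure=np.ones((3, 3, 3)))
    largest = int(max(np.sum(labeled == i) for i in range(1, k + 1)))
    for cls in ("large", "medium", "small"):
        lo, _hi = SIZE_CLASS_BOUNDS[cls]
        if largest >= lo:
            return cls
    return "small"


def _allocate(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items to three sets."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_by_subject(
    cases: list[SubjectCase],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    stratify_by_size_class: bool = False,
    seed: int = 0,
) -> DatasetSplit:
    """Random participant-level split into train/validation/test.

    With stratification, subjects are grouped by their largest-lesion size
    class and each group is allocated to the three sets with the requested
    proportions, so lesion-size composition is approximately preserved.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must be positive and sum to 1, got {fractions}")
    ids = [c.subject_id for c in cases]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate subject ids")
    if len(ids) < 3:
        raise DataError("need at least 3 subjects to form three sets")
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    if stratify_by_size_class:
        strata: dict[str, list[str]] = {}
        for c in cases:
            strata.setdefault(largest_lesion_class(c), []).append(c.subject_id)
        for key in sorted(strata):
            members = sorted(strata[key])
            rng.shuffle(members)
            sizes = _allocate(len(members), fractions)
            i = 0
            for s, size in enumerate(sizes):
                parts[s].extend(members[i : i + size])
                i += size
    else:
        members = sorted(ids)
        rng.shuffle(members)
        sizes = _allocate(len(members), fractions)
        i = 0
        for s, size in enumerate(sizes):
            parts[s].extend(members[i : i + size])
            i += size
    return DatasetSplit(train=set(parts[0]), val=set(parts[1]), test=set(parts[2]),
                        fractions=tuple(fractions))


def _positive_mask(case: SubjectCase, task: str) -> np.ndarray:
    if task == "csf":
        return case.tissue_labels == Tissue.CSF
    if task == "microbleed":
        if case.microbleed_gt is None:
            raise DataError(f"{case.subject_id}: microbleed task needs ground truth")
        return case.microbleed_gt
    raise ConfigError(f"unknown task {task!r}; expected one of {TASKS}")


def _background_mask(case: SubjectCase, task: str) -> np.ndarray:
    if task == "csf":
        return np.isin(
            case.tissue_labels,
            [Tissue.CORTICAL_GM, Tissue.DEEP_GM, Tissue.WM,
             Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM],
        )
    return case.brain_mask & ~_positive_mask(case, task)


def sample_task_patches(
    cases: list[SubjectCase],
    task: str,
    n_total: int,
    patch_size: int,
    seed: int = 0,
) -> list[PatchRecord]:
    """Sample a balanced patch set: n_total/2 positive-centered and
    n_total/2 background-centered records pooled over ``cases``.

    Background centers are drawn without replacement; positive centers are
    drawn without replacement while unique positive voxels last, then with
    replacement (microbleed voxels are scarce — augmentation, not repeated
    sampling, is the protocol's remedy, but small phantom cohorts
    may still need it).
    """
    if n_total % 2:
        raise ConfigError("n_total must be even (half positive, half background)")
    if not cases:
        raise DataError("no cases to sample from")
    rng = np.random.default_rng(seed)
    n_half = n_total // 2

    def pool(mask_fn) -> tuple[np.ndarray, np.ndarray]:
        coords, owner = [], []
        for i, case in enumerate(cases):
            m = mask_fn(case, task)
            c = np.argwhere(m)
            coords.append(c)
            owner.append(np.full(len(c), i))
        return np.concatenate(coords), np.concatenate(owner)

    pos_coords, pos_owner = pool(_positive_mask)
    bg_coords, bg_owner = pool(_background_mask)
    if len(pos_coords) == 0:
        raise DataError(f"no positive voxels available for task {task!r}")
    if len(bg_coords) < n_half:
        raise DataError("not enough background voxels")

    if len(pos_coords) >= n_half:
        pos_idx = rng.choice(len(pos_coords), size=n_half, replace=False)
    else:
        pos_idx = np.concatenate(
            [
                rng.permutation(len(pos_coords)),
                rng.choice(len(pos_coords), size=n_half - len(pos_coords), replace=True),
            ]
        )
    bg_idx = rng.choice(len(bg_coords), size=n_half, replace=False)

    records = []
    for label, idx, coords, owner in (
        (1, pos_idx, pos_coords, pos_owner),
        (0, bg_idx, bg_coords, bg_owner),
    ):
        for i in idx:
            case = cases[int(owner[i])]
            center = tuple(int(v) for v in coords[i])
            records.append(
                PatchRecord(
                    subject_id=case.subject_id,
                    center=center,
                    label=label,
                    task=task,
                    patch_size=patch_size,
                    channels=extract_patch(case, center, patch_size),
                )
            )
    return records


def _rotate_slice_about(img2d: np.ndarray, center_xy: tuple[int, int], angle_deg: float) -> np.ndarray:
    """Rotate a 2D slice about an arbitrary point, bilinear, zero fill."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = np.asarray(center_xy, dtype=float)
    offset = center - rot @ center
    return ndimage.affine_transform(img2d, rot, offset=offset, order=1, mode="constant", cval=0.0)


def augment_rotations(
    case: SubjectCase,
    center: tuple[int, int, int],
    k: int,
    patch_size: int,
    seed: int = 0,
    task: str = "microbleed",
) -> list[PatchRecord]:
    """k rotated positive patches about ``center``.

    The full axial slice is rotated about the positive voxel (angles
    uniform in [0, 360) degrees, bilinear interpolation, zero fill) before
    the patch is cut, so rotation exposes slice content outside the
    original window.
    """
    if k < 0:
        raise ConfigError("k must be >= 0")
    x, y, z = (int(c) for c in center)
    if not case.brain_mask[x, y, z]:
        raise DataError("rotation center outside brain mask")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 360.0, size=k)
    half = patch_size // 2
    records = []
    for angle in angles:
        channels = np.zeros((3, patch_size, patch_size), dtype=np.float32)
        for ch, vol in enumerate(_case_channels(case)):
            rotated = _rotate_slice_about(vol[:, :, z], (x, y), float(angle))
            lo_x, lo_y = x - half, y - half
            nx, ny = rotated.shape
            sx = slice(max(0, lo_x), min(nx, lo_x + patch_size))
            sy = slice(max(0, lo_y), min(ny, lo_y + patch_size))
            channels[ch, sx.start - lo_x : sx.stop - lo_x, sy.start - lo_y : sy.stop - lo_y] = (
                rotated[sx, sy]
            )
        records.append(
            PatchRecord(
                subject_id=case.subject_id,
                center=(x, y, z),
                label=1,
                task=task,
                patch_size=patch_size,
                channels=channels,
                angle=float(angle),
            )
        )
    return records


def build_training_patches(
    cases: list[SubjectCase],
    task: str,
    n_total: int,
    patch_size: int,
    augment_k: int = 0,
    seed: int = 0,
) -> list[PatchRecord]:
    """Balanced patch set with optional rotation augmentation.

    Each positive record gains ``augment_k`` rotated copies, and an equal
    number of novel background patches is added to keep the dataset
    balanced.  Use only for training sets; validation/test sets are never
    augmented.
    """
    base = sample_task_patches(cases, task, n_total, patch_size, seed=seed)
    if augment_k == 0:
        return base
    by_id = {c.subject_id: c for c in cases}
    rng = np.random.default_rng(seed + 1)
    out = list(base)
    positives = [r for r in base if r.label == 1]
    for r in positives:
        out.extend(
            augment_rotations(
                by_id[r.subject_id], r.center, augment_k, patch_size,
                seed=int(rng.integers(2**31 - 1)), task=task,
            )
        )
    # novel background patches to rebalance
    n_extra = augment_k * len(positives)
    extra = sample_task_patches(cases, task, 2 * n_extra, patch_size,
                                seed=int(rng.integers(2**31 - 1)))
    out.extend([r for r in extra if r.label == 0])
    return out


def records_to_arrays(records: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack records into (X, y, subject_ids) arrays, X of shape
    (n, 3, patch_size, patch_size)."""
    X = np.stack([r.channels for r in records])
    y = np.array([r.label for r in records], dtype=np.int64)
    subjects = np.array([r.subject_id for r in records])
    return X, y, subjects
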