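"""Patch-level and per-lesion validation metrics.

Patch level (counts of patch classifications):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Per lesion, counts refer to whole 3D connected components: a manual
lesion counts as detected (TP) if *any* of its voxels overlap any
automatic lesion; FN are undetected manual lesions; FP are automatic
lesions overlapping no manual lesion.  From these,

    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    Dice        = 2 TP / ((TP + FN) + (TP + FP))

the Dice index being the harmonic mean of sensitivity and precision at
the lesion-count level.  Specificity is undefined per lesion (there is
no count of true-negative lesions), so precision is reported instead.
Undefined ratios (zero denominators) are reported as NaN with a warning,
never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .inference import LesionMap
from .volume_io import REGION_TISSUES


@dataclass
class ConfusionCounts:
    """Patch-level confusion counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")


@dataclass
class LesionMatchResult:
    """Lesion-level detection counts and the matched id pairs."""

    TP: int
    FP: int
    FN: int
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)  # (auto, manual)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def patch_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from patch-level counts."""
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise DataError("all confusion counts are zero")
    accuracy = (c.TP + c.TN) / total
    sensitivity = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    specificity = _ratio(c.TN, c.TN + c.FP, "specificity")
    return accuracy, sensitivity, specificity


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(y_true & y_pred)),
        TN=int(np.sum(~y_true & ~y_pred)),
        FP=int(np.sum(~y_true & y_pred)),
        FN=int(np.sum(y_true & ~y_pred)),
    )


def match_lesions(auto: LesionMap, manual: LesionMap) -> LesionMatchResult:
    """Any-overlap matching between automatic and manual lesion maps.

    Each manual lesion is judged independently: one overlapping voxel
    with any automatic lesion makes it a TP.  An automatic lesion is a
    FP only if it overlaps no manual lesion, so a single automatic blob
    covering two manual lesions contributes two TPs and no FP.
    """
    if auto.labels.shape != manual.labels.shape:
        raise DataError("lesion maps must share a grid")
    both = (auto.labels > 0) & (manual.labels > 0)
    pairs = set()
    if both.any():
        a = auto.labels[both]
        m = manual.labels[both]
        pairs = set(zip(a.tolist(), m.tolist()))
    matched_manual = {m for _a, m in pairs}
    matched_auto = {a for a, _m in pairs}
    return LesionMatchResult(
        TP=len(matched_manual),
        FP=auto.n_lesions - len(matched_auto),
        FN=manual.n_lesions - len(matched_manual),
        matched_pairs=sorted(pairs),
    )


def lesion_metrics(m: LesionMatchResult) -> tuple[float, float, float]:
    """(sensitivity, precision, dice) at the lesion-count level.

    Two empty maps (no lesions anywhere) count as perfect trivial
    agreement: all three metrics are 1.
    """
    if m.TP == 0 and m.FP == 0 and m.FN == 0:
        return 1.0, 1.0, 1.0
    sensitivity = _ratio(m.TP, m.TP + m.FN, "lesion sensitivity")
    precision = _ratio(m.TP, m.TP + m.FP, "lesion precision")
    dice = 2 * m.TP / ((m.TP + m.FN) + (m.TP + m.FP))
    return sensitivity, precision, dice


# ---------------------------------------------------------------------------
# cohort evaluation


def _region_of_lesion(voxels: np.ndarray, tissue: np.ndarray) -> int:
    from .postprocess import categorize_region

    return categorize_region(voxels, tissue)


@dataclass
class MetricsReport:
    """Lesion-level results overall and per region, under both pooled
    and per-subject-mean aggregation."""

    lesion_table: pd.DataFrame
    patch_table: pd.DataFrame | None = None

    def to_json(self) -> str:
        out = {"lesion": self.lesion_table.to_dict(orient="records")}
        if self.patch_table is not None:
            out["patch"] = self.patch_table.to_dict(orient="records")
        import json

        return json.dumps(out, indent=2)


def evaluate_cohort(
    cases: list[tuple[LesionMap, LesionMap, np.ndarray]],
    per_region: bool = True,
) -> MetricsReport:
    """Lesion-level evaluation over a cohort.

    ``cases`` is a list of (auto_map, manual_map, tissue_labels).  Both
    pooled counts (summing TP/FP/FN over subjects before computing the
    metrics) and per-subject means (computing metrics per subject and
    averaging) are reported, overall and per region.  A lesion's region
    is its majority-overlap tissue category; per-region matching judges
    manual lesions of that region against the full automatic map and
    charges FPs to the automatic lesion's own region.
    """
    if not cases:
        raise DataError("no cases to evaluate")
    scopes = ["overall"]
    if per_region:
        scopes += [t.name for t in REGION_TISSUES]
    per_case: dict[str, list[LesionMatchResult]] = {s: [] for s in scopes}
    for auto, manual, tissue in cases:
        full = match_lesions(auto, manual)
        per_case["overall"].append(full)
        if not per_region:
            continue
        auto_regions = {lid: _region_of_lesion(v, tissue) for lid, v in auto.lesions.items()}
        manual_regions = {lid: _region_of_lesion(v, tissue) for lid, v in manual.lesions.items()}
        matched_auto = {a for a, _m in full.matched_pairs}
        for region in REGION_TISSUES:
            man_ids = {lid for lid, r in manual_regions.items() if r == region}
            # count each matched manual lesion once even with several partners
            tp = len({m for _a, m in full.matched_pairs if m in man_ids})
            fn = len(man_ids) - tp
            fp = sum(
                1
                for lid, r in auto_regions.items()
                if r == region and lid not in matched_auto
            )
            per_case[region.name].append(LesionMatchResult(TP=tp, FP=fp, FN=fn))
    rows = []
    for scope, results in per_case.items():
        tp = sum(r.TP for r in results)
        fp = sum(r.FP for r in results)
        fn = sum(r.FN for r in results)
        if tp + fp + fn == 0 and scope != "overall":
            rows.append({"scope": scope, "aggregation": "pooled", "TP": 0, "FP": 0, "FN": 0,
                         "sensitivity": np.nan, "precision": np.nan, "dice": np.nan,
                         "no_lesions": True})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens, prec, dice = lesion_metrics(LesionMatchResult(TP=tp, FP=fp, FN=fn))
            per_subj = np.array([lesion_metrics(r) for r in results], dtype=float)
        rows.append({"scope": scope, "aggregation": "pooled", "TP": tp, "FP": fp, "FN": fn,
                     "sensitivity": sens, "precision": prec, "dice": dice, "no_lesions": False})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means = np.nanmean(per_subj, axis=0)
        rows.append({"scope": scope, "aggregation": "per_subject_mean",
                     "TP": tp, "FP": fp, "FN": fn,
                     "sensitivity": float(means[0]), "precision": float(means[1]),
                     "dice": float(means[2]), "no_lesions": False})
    return MetricsReport(lesion_table=pd.DataFrame(rows))
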