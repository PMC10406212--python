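"""End-to-end phantom experiments.

These functions run the full pipeline — synthetic cohort, participant-
level split, CSF pretraining, microbleed fine-tuning, voxel-wise
segmentation of held-out subjects, false-positive post-processing, and
evaluation — at desk scale, and return the quantities a validation run
cares about.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .classifier import (
    CenterThresholdClassifier,
    TrainingConfig,
    build_classifier,
    finetune_microbleed,
    pretrain_csf,
)
from .inference import label_components, restrict_search_mask, segment_volume
from .metrics import (
    LesionMatchResult,
    confusion_from_predictions,
    lesion_metrics,
    match_lesions,
    patch_metrics,
)
from .patch_sampler import (
    build_training_patches,
    records_to_arrays,
    sample_task_patches,
    split_by_subject,
)
from .phantom import PhantomParams, generate_case, generate_cohort
from .postprocess import PruningParams, postprocess_map

#: validation accuracy the transfer-benefit comparison measures
#: time-to-target against; chosen between the accuracy plateau reported
#: for from-scratch training (<=0.96) and the transfer-learned models
#: (>=0.99)
TRANSFER_TARGET_ACCURACY = 0.99


def oracle_reconstruction_check(n_subjects: int = 5, seed: int = 0) -> dict:
    """Validate the voxel-wise reconstruction plumbing.

    On noise-free, vessel-free phantoms a center-voxel intensity
    threshold is an oracle for the ground-truth label, so sliding-window
    segmentation followed by component labeling must reproduce the
    ground truth exactly (per-lesion sensitivity = precision = Dice = 1).
    """
    params = PhantomParams(noise_sd=0.0, n_vessels=0)
    rng = np.random.default_rng(seed)
    sens, prec, dice, exact = [], [], [], []
    for i in range(n_subjects):
        case = generate_case(
            PhantomParams(
                noise_sd=0.0,
                n_vessels=0,
                n_microbleeds_per_class=params.n_microbleeds_per_class,
                seed=int(rng.integers(2**31 - 1)),
            ),
            subject_id=f"oracle-{i:03d}",
        )
        # microbleeds are by far the darkest tissue on noise-free T2*
        cutoff = float(case.t2star.data[case.microbleed_gt].max()) + 1e-3
        model = CenterThresholdClassifier(cutoff=cutoff)
        seg = segment_volume(case, model, patch_size=28)
        auto = label_components(seg)
        manual = label_components(case.microbleed_gt)
        s, p, d = lesion_metrics(match_lesions(auto, manual))
        sens.append(s)
        prec.append(p)
        dice.append(d)
        exact.append(bool(np.array_equal(seg, case.microbleed_gt)))
    return {
        "n_subjects": n_subjects,
        "lesion_sensitivity": float(np.mean(sens)),
        "lesion_precision": float(np.mean(prec)),
        "lesion_dice": float(np.mean(dice)),
        "voxel_exact_match": all(exact),
    }


def run_phantom_benchmark(
    seed: int = 0,
    n_subjects: int = 12,
    patch_size: int = 28,
    n_csf_patches: int = 6000,
    n_mb_patches: int = 600,
    augment_k: int = 9,
    freeze_layers: int = 2,
    ratio_threshold: float = 1.2,
    n_eval_subjects: int | None = None,
    transfer_repeats: int = 3,
) -> dict:
    """Full two-stage pipeline on a synthetic cohort.

    Trains with the protocol's best patch size (28), mini-batch 40,
    learning rate 0.006, 10 epochs, SGDM 0.9.  The CSF stage trains all
    layers; the microbleed stage freezes the first ``freeze_layers``
    weighted layers of the compact backbone.  Segmentation of held-out
    (test-split) subjects is evaluated per lesion before and after
    post-processing, with the phantom's vessel confounders injected into
    the raw segmentation so the false-positive pruning stage is exercised
    unambiguously.  The transfer benefit is quantified by paired runs:
    for each of ``transfer_repeats`` seeds, the two-stage transfer model
    and an identical protocol with the pre-training step ablated (random
    initialization, same freezing, data and seed) are trained, and their
    validation-accuracy curves are averaged over repeats.
    """
    master = np.random.default_rng(seed)
    s_cohort, s_split, s_csf, s_mb, s_model = (int(master.integers(2**31 - 1)) for _ in range(5))

    cohort = generate_cohort(n_subjects, seed=s_cohort)
    split = split_by_subject(cohort, (0.6, 0.2, 0.2), stratify_by_size_class=True, seed=s_split)
    train_cases = split.subset(cohort, "train")
    val_cases = split.subset(cohort, "val")
    test_cases = split.subset(cohort, "test")

    # --- patch data for both stages ----------------------------------
    csf_train = build_training_patches(train_cases, "csf", n_csf_patches, patch_size, seed=s_csf)
    csf_val = sample_task_patches(val_cases, "csf", max(200, n_csf_patches // 5),
                                  patch_size, seed=s_csf + 1)
    X_tr, y_tr, _ = records_to_arrays(csf_train)
    X_va, y_va, _ = records_to_arrays(csf_val)
    mb_train = build_training_patches(train_cases, "microbleed", n_mb_patches, patch_size,
                                      augment_k=augment_k, seed=s_mb)
    mb_val = sample_task_patches(val_cases, "microbleed", 600, patch_size, seed=s_mb + 1)
    mb_test = sample_task_patches(test_cases, "microbleed", 400, patch_size, seed=s_mb + 2)
    Xm_tr, ym_tr, _ = records_to_arrays(mb_train)
    Xm_va, ym_va, _ = records_to_arrays(mb_val)
    Xm_te, ym_te, _ = records_to_arrays(mb_test)

    # --- paired transfer-vs-scratch runs ------------------------------
    # Each repeat: (a) CSF pretraining then fine-tuning with frozen
    # early layers, (b) the identical protocol from random init (the
    # pre-training step ablated).  Results are averaged over repeats, as
    # the study protocol prescribes for its training experiments.
    model = None
    csf_val_accuracy = None
    transfer_curves, scratch_curves = [], []
    for r in range(transfer_repeats):
        cfg = TrainingConfig(patch_size=patch_size, freeze_layers=freeze_layers,
                             mini_batch=40, learning_rate=0.006, epochs=10,
                             seed=s_model + 1000 * r)
        transfer = build_classifier(cfg)
        pretrain_csf(transfer, X_tr, y_tr)
        if r == 0:
            csf_val_accuracy = transfer.score(X_va, y_va)
        finetune_microbleed(transfer, Xm_tr, ym_tr, Xm_va, ym_va)
        transfer_curves.append([h["val_accuracy"] for h in transfer.history_
                                if h["stage"] == "finetune_microbleed"])
        scratch = build_classifier(cfg)
        scratch.fit(Xm_tr, ym_tr, Xm_va, ym_va, freeze=freeze_layers, stage="scratch")
        scratch_curves.append([h["val_accuracy"] for h in scratch.history_
                               if h["stage"] == "scratch"])
        if r == 0:
            model = transfer  # the segmentation model

    transfer_curve = np.mean(transfer_curves, axis=0)
    scratch_curve = np.mean(scratch_curves, axis=0)

    def epochs_to(curve: np.ndarray, target: float) -> float:
        hits = np.nonzero(curve >= target)[0]
        return float(hits[0] + 1) if len(hits) else float("inf")

    counts = confusion_from_predictions(ym_te, model.predict(Xm_te))
    acc, sens_patch, spec_patch = patch_metrics(counts)

    # --- held-out segmentation and post-processing -------------------
    eval_cases = test_cases[:n_eval_subjects] if n_eval_subjects else test_cases
    pre_results, post_results = [], []
    tp_before = fp_before = tp_after = fp_after = 0
    for case in eval_cases:
        search = restrict_search_mask(case)
        seg = segment_volume(case, model, patch_size=patch_size, search_mask=search)
        manual = label_components(case.microbleed_gt)
        pre_results.append(match_lesions(label_components(seg), manual))
        # inject the vessel confounders as known false positives
        seg_fp = seg | case.vessel_mask
        before = match_lesions(label_components(seg_fp), manual)
        post_map = postprocess_map(
            seg_fp, case, PruningParams(ratio_threshold=ratio_threshold),
        )
        after = match_lesions(post_map, manual)
        tp_before += before.TP
        fp_before += before.FP
        tp_after += after.TP
        fp_after += after.FP
        post_results.append(after)

    def pooled(results: list[LesionMatchResult]) -> tuple[float, float, float]:
        agg = LesionMatchResult(
            TP=sum(r.TP for r in results),
            FP=sum(r.FP for r in results),
            FN=sum(r.FN for r in results),
        )
        return lesion_metrics(agg)

    sens_pre, prec_pre, dice_pre = pooled(pre_results)
    sens_post, prec_post, dice_post = pooled(post_results)

    return {
        "n_subjects": n_subjects,
        "n_train_subjects": len(train_cases),
        "n_eval_subjects": len(eval_cases),
        "csf_val_accuracy": float(csf_val_accuracy),
        "patch_accuracy": float(acc),
        "patch_sensitivity": float(sens_patch),
        "patch_specificity": float(spec_patch),
        "n_test_patches": int(len(ym_te)),
        "lesion_sensitivity_raw": float(sens_pre),
        "lesion_precision_raw": float(prec_pre),
        "lesion_dice_raw": float(dice_pre),
        "lesion_sensitivity_post": float(sens_post),
        "lesion_precision_post": float(prec_post),
        "lesion_dice_post": float(dice_post),
        "fp_before_postprocess": int(fp_before),
        "fp_after_postprocess": int(fp_after),
        "tp_before_postprocess": int(tp_before),
        "tp_after_postprocess": int(tp_after),
        "transfer_repeats": transfer_repeats,
        "transfer_mean_curve": [float(v) for v in transfer_curve],
        "scratch_mean_curve": [float(v) for v in scratch_curve],
        "transfer_mean_val_accuracy": float(transfer_curve.mean()),
        "scratch_mean_val_accuracy": float(scratch_curve.mean()),
        "transfer_final_val_accuracy": float(transfer_curve[-1]),
        "scratch_final_val_accuracy": float(scratch_curve[-1]),
        "epochs_to_target_transfer": epochs_to(transfer_curve, TRANSFER_TARGET_ACCURACY),
        "epochs_to_target_scratch": epochs_to(scratch_curve, TRANSFER_TARGET_ACCURACY),
    }
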