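"""Orchestration: mouse-level cross-validation and the unified two-stage
deployment (mask CNN -> skull-strip -> iVOI CNN -> PET quantification).

Folds split at the mouse level so both scans of a mouse land on the same side
of every train/test split — slices of one animal never leak between training
and testing.  Within a fold: the skull-stripping model is trained on the
training mice, applied to the test mice, and its postprocessed mask strips the
test MR; the iVOI model is trained on ground-truth-stripped training MR and
applied to the stripped test MR; quantification then runs the three VOI routes
(DL, iGT, GT) on the test scans.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImageVolume, LabelVolume, REGION_NAMES
from .deformation import warp_volume
from .metrics import score_masks
from .phantom import SubjectRecord
from .postprocess import postprocess_chain
from .quant import DL, GT, IGT, compare_methods, quantify, records_frame
from .quasi3d import IVOI, MASK, TrainConfig, predict, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_mice: frozenset[str]
    test_mice: frozenset[str]


def make_folds(mouse_ids: list[str], k: int, seed: int = 0) -> list[FoldSplit]:
    """Seeded shuffle then contiguous chunking into k near-equal folds.

    Test sets partition the mouse set; fold sizes differ by at most one.
    """
    ids = list(dict.fromkeys(mouse_ids))
    n = len(ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be between 1 and the number of mice ({n})")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    base, extra = divmod(n, k)
    folds, start = [], 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        test = frozenset(order[start : start + size])
        folds.append(
            FoldSplit(fold_index=fold, train_mice=frozenset(ids) - test, test_mice=test)
        )
        start += size
    return folds


def _split_records(cohort: list[SubjectRecord], fold: FoldSplit):
    train_rec = [r for r in cohort if r.mouse_id in fold.train_mice]
    test_rec = [r for r in cohort if r.mouse_id in fold.test_mice]
    leak = {r.mouse_id for r in train_rec} & {r.mouse_id for r in test_rec}
    if leak:
        raise RuntimeError(f"train/test leakage for mice {sorted(leak)}")
    return train_rec, test_rec


def run_fold(
    cohort: list[SubjectRecord],
    fold: FoldSplit,
    mask_config: TrainConfig,
    ivoi_config: TrainConfig | None = None,
    strip_source: str = "predicted",
    gt_space: str = "template",
    label_template: LabelVolume | None = None,
):
    """Train and evaluate one fold; returns (scores_df, quant_df, artifacts).

    ``strip_source`` selects whether the iVOI model sees MR stripped by the
    predicted mask (deployment behaviour, default) or the ground-truth mask.
    ``gt_space='template'`` computes the GT quantification route on PET warped
    into template space (requires ``label_template``); ``'individual'`` falls
    back to the iGT labels in native space.
    """
    if strip_source not in ("predicted", "truth"):
        raise ValueError("strip_source must be 'predicted' or 'truth'")
    train_rec, test_rec = _split_records(cohort, fold)
    if not train_rec or not test_rec:
        raise ValueError(f"fold {fold.fold_index}: empty train or test set")

    mask_model, mask_hist = train(train_rec, MASK, mask_config)
    score_rows, quant_records = [], []
    predicted_masks, predicted_ivois = {}, {}

    ivoi_model, ivoi_hist = (None, None)
    if ivoi_config is not None:
        ivoi_model, ivoi_hist = train(train_rec, IVOI, ivoi_config)

    for rec in test_rec:
        key = (rec.mouse_id, rec.session)
        prob = predict(rec.mr, mask_model)
        pred_mask = postprocess_chain(prob, task="mask", spacing_mm=rec.mr.spacing_mm)
        predicted_masks[key] = pred_mask
        s = score_masks(pred_mask, rec.brain_mask_gt, rec.mr.spacing_mm, "brain_mask")
        score_rows.append({"fold": fold.fold_index, **key_dict(rec), **s.__dict__})

        if ivoi_model is not None:
            strip = pred_mask.data if strip_source == "predicted" else rec.brain_mask_gt.data
            stripped = ImageVolume(rec.mr.data * strip, rec.mr.spacing_mm)
            iprob = predict(stripped, ivoi_model)
            pred_ivoi = postprocess_chain(iprob, task="ivoi", spacing_mm=rec.mr.spacing_mm)
            predicted_ivois[key] = pred_ivoi
            for code, region in REGION_NAMES.items():
                s = score_masks(
                    pred_ivoi.data == code, rec.ivoi_gt.data == code, rec.mr.spacing_mm, region
                )
                score_rows.append({"fold": fold.fold_index, **key_dict(rec), **s.__dict__})
            quant_records += quantify(
                rec.pet, pred_ivoi, rec.injected_dose_kbq, rec.body_weight_g,
                rec.mouse_id, rec.session, DL,
            )
        quant_records += quantify(
            rec.pet, rec.ivoi_gt, rec.injected_dose_kbq, rec.body_weight_g,
            rec.mouse_id, rec.session, IGT,
        )
        quant_records += quantify(
            *_gt_route(rec, gt_space, label_template),
            rec.injected_dose_kbq, rec.body_weight_g, rec.mouse_id, rec.session, GT,
        )

    artifacts = {
        "mask_model": mask_model,
        "mask_history": mask_hist,
        "ivoi_model": ivoi_model,
        "ivoi_history": ivoi_hist,
        "predicted_masks": predicted_masks,
        "predicted_ivois": predicted_ivois,
    }
    return pd.DataFrame(score_rows), records_frame(quant_records), artifacts


def _gt_route(rec: SubjectRecord, gt_space: str, label_template: LabelVolume | None):
    """PET volume + labels for the template-based ground-truth quantification."""
    if gt_space == "individual" or label_template is None:
        return rec.pet, rec.ivoi_gt
    # spatial normalization: pull the native PET onto the template grid
    pet_t = warp_volume(rec.pet, rec.forward_field, interp="linear")
    return pet_t, label_template


def key_dict(rec: SubjectRecord) -> dict:
    return {"mouse_id": rec.mouse_id, "session": rec.session}


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-fold and pooled mean +/- SD per structure and metric (table layout).

    The pooled rows are the mean and SD over the per-fold means.
    """
    metrics = ["dsc", "assd_mm", "sen", "spe", "ppv"]
    per_fold = scores.groupby(["fold", "structure"])[metrics].mean().reset_index()
    rows = []
    for (fold, structure), grp in per_fold.groupby(["fold", "structure"]):
        for m in metrics:
            sd = scores[(scores["fold"] == fold) & (scores["structure"] == structure)][m].std(ddof=1)
            rows.append(
                {"fold": str(fold), "structure": structure, "metric": m,
                 "mean": float(grp[m].iloc[0]), "sd": float(sd) if np.isfinite(sd) else 0.0}
            )
    for structure, grp in per_fold.groupby("structure"):
        for m in metrics:
            rows.append(
                {"fold": "total", "structure": structure, "metric": m,
                 "mean": float(grp[m].mean()),
                 "sd": float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0}
            )
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: list[SubjectRecord],
    mask_config: TrainConfig,
    ivoi_config: TrainConfig | None = None,
    k: int = 6,
    seed: int = 0,
    outdir: str | Path | None = None,
    strip_source: str = "predicted",
    gt_space: str = "template",
    label_template: LabelVolume | None = None,
):
    """Full cross-validated experiment; returns a report dict.

    A failing fold is logged and skipped; the remaining folds proceed.  When
    ``outdir`` is given, every table plus the config snapshot is written there.
    """
    mouse_ids = sorted({r.mouse_id for r in cohort})
    folds = make_folds(mouse_ids, k, seed)
    all_scores, all_quant, failures = [], [], []
    for fold in folds:
        try:
            scores, quant, _ = run_fold(
                cohort, fold, mask_config, ivoi_config,
                strip_source=strip_source, gt_space=gt_space, label_template=label_template,
            )
            all_scores.append(scores)
            all_quant.append(quant)
        except Exception as exc:  # noqa: BLE001 - fold isolation is deliberate
            logger.error("fold %d failed: %s", fold.fold_index, exc)
            failures.append({"fold": fold.fold_index, "error": str(exc)})
    if not all_scores:
        raise RuntimeError(f"all folds failed: {failures}")
    scores = pd.concat(all_scores, ignore_index=True)
    quant = pd.concat(all_quant, ignore_index=True)
    summary = summarize_scores(scores)
    comparison = compare_methods(quant) if quant["method"].nunique() >= 2 else None

    report = {
        "folds": folds,
        "scores": scores,
        "summary": summary,
        "quant": quant,
        "comparison": comparison,
        "failures": failures,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(outdir / "segmentation_scores.csv", index=False)
        summary.to_csv(outdir / "segmentation_summary.csv", index=False)
        quant.to_csv(outdir / "quant_records.csv", index=False)
        if comparison is not None:
            comparison.to_dir(outdir)
        snapshot = {
            "k": k,
            "seed": seed,
            "strip_source": strip_source,
            "gt_space": gt_space,
            "mask_config": mask_config.__dict__,
            "ivoi_config": ivoi_config.__dict__ if ivoi_config else None,
            "failures": failures,
        }
        (outdir / "run_config.json").write_text(json.dumps(snapshot, indent=2, default=str))
    return report
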