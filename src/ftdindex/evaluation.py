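"""ROC/AUC analysis, Youden threshold selection and the two-stage decision rule.

Classification uses the rule ``score > threshold``; candidate thresholds sit
midway between consecutive distinct scores, with -inf/+inf sentinels.  AUC is
the Mann-Whitney concordance probability with ties counted one half.  The
Youden-optimal threshold maximizes sensitivity + specificity - 1, breaking
ties toward the higher-sensitivity operating point (missing an FTD case is
costlier than a false positive in this differential).

The two-stage rule first gates on the exogenous AD-RAI score (<= threshold
means no dementia-typical atrophy, call NC) and only then separates FTD from
AD by the FTDI threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import (
    IncompleteInputError,
    InvalidInputError,
    PipelineStageError,
    UndefinedROCError,
)

DEFAULT_FTDI_THRESHOLD = 1.08
DEFAULT_ADRAI_THRESHOLD = 0.75


@dataclass
class ROCResult:
    """Empirical ROC curve plus its Youden-optimal operating point."""

    points: list  # (threshold, sensitivity, specificity), ascending threshold
    auc: float
    youden_threshold: float
    sens_at_youden: float
    spec_at_youden: float


@dataclass
class Decision:
    """Outcome of the two-stage differential-diagnosis rule."""

    label: str  # NC | FTD | AD
    stage1_positive: bool
    rationale: str


def _as_arrays(scores, positive):
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if scores.shape != positive.shape or scores.ndim != 1:
        raise InvalidInputError("scores and labels must be 1-D arrays of equal length")
    if positive.all() or not positive.any():
        raise UndefinedROCError("ROC needs at least one positive and one negative")
    return scores, positive


def confusion_at(scores, positive, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule ``score > threshold``."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    sens = float((scores[positive] > threshold).mean()) if positive.any() else float("nan")
    neg = ~positive
    spec = float((scores[neg] <= threshold).mean()) if neg.any() else float("nan")
    return sens, spec


def roc_auc(scores, positive) -> ROCResult:
    """Empirical ROC over all distinct cutpoints, with AUC and Youden point.

    AUC equals the probability that a random positive outscores a random
    negative, ties counted one half.
    """
    scores, positive = _as_arrays(scores, positive)
    auc = float(roc_auc_score(positive, scores))
    uniq = np.unique(scores)
    thresholds = np.concatenate(([-math.inf], (uniq[:-1] + uniq[1:]) / 2.0, [math.inf]))
    points = []
    for t in thresholds:
        sens, spec = confusion_at(scores, positive, t)
        points.append((float(t), sens, spec))
    best = None
    for t, sens, spec in points:
        j = sens + spec - 1.0
        key = (j, sens, -t if math.isfinite(t) else -math.inf)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t_best, sens_best, spec_best = best
    return ROCResult(
        points=points,
        auc=auc,
        youden_threshold=float(t_best),
        sens_at_youden=sens_best,
        spec_at_youden=spec_best,
    )


def youden_threshold(roc: ROCResult) -> float:
    """The cutpoint maximizing Youden's J = sensitivity + specificity - 1."""
    return roc.youden_threshold


def decide(
    ad_rai: float,
    ftdi: float | None,
    adrai_threshold: float = DEFAULT_ADRAI_THRESHOLD,
    ftdi_threshold: float = DEFAULT_FTDI_THRESHOLD,
) -> Decision:
    """Two-stage differential diagnosis: AD-RAI gate, then FTDI split.

    ``ad_rai <= adrai_threshold`` calls NC without consulting FTDI; beyond the
    gate, ``ftdi > ftdi_threshold`` calls FTD and anything else (including
    equality) calls AD.  A missing FTDI at stage 2 is an error.
    """
    if ad_rai < 0:
        raise InvalidInputError("ad_rai must be >= 0")
    if ad_rai <= adrai_threshold:
        return Decision(
            label="NC",
            stage1_positive=False,
            rationale=f"AD-RAI {ad_rai:.3g} <= {adrai_threshold:.3g}: no dementia-typical atrophy",
        )
    if ftdi is None:
        raise IncompleteInputError(
            "stage 2 reached (AD-RAI above gate) but FTDI is missing/flagged"
        )
    if ftdi > ftdi_threshold:
        return Decision(
            label="FTD",
            stage1_positive=True,
            rationale=f"FTDI {ftdi:.3g} > {ftdi_threshold:.3g}: frontotemporal-dominant atrophy",
        )
    return Decision(
        label="AD",
        stage1_positive=True,
        rationale=f"FTDI {ftdi:.3g} <= {ftdi_threshold:.3g}: AD-dominant atrophy",
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------

def evaluate_pipeline(
    train_records,
    validation_records,
    alpha: float = 0.05,
    weight_mode: str = "sum",
    clamp_validation: bool = True,
    use_youden_threshold: bool = True,
    ftdi_threshold: float = DEFAULT_FTDI_THRESHOLD,
    adrai_threshold: float = DEFAULT_ADRAI_THRESHOLD,
    panel=None,
    return_model: bool = False,
):
    """Full run: measures -> dominant sets -> FTDI fit -> train/validation ROC.

    The model is fitted on the training cohort only; the validation cohort is
    scored with the frozen training extrema (lower clamp on) and judged at the
    training-derived threshold.  An AD-RAI ROC (dementia vs NC) on the
    training cohort completes the report.  Errors are re-raised tagged with
    the failing stage.
    """
    from .ftdi import fit_ftdi, score_cohort
    from .group_stats import identify_dominant_sets
    from .volumetry import DEFAULT_MEASURES, build_measure_matrix

    if panel is None:
        panel = DEFAULT_MEASURES

    def _stage(name, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc

    train_matrix = _stage("volumetry", lambda: build_measure_matrix(train_records, panel))
    val_matrix = _stage(
        "volumetry", lambda: build_measure_matrix(validation_records, panel)
    )
    dominant = _stage("group_stats", lambda: identify_dominant_sets(train_matrix, alpha=alpha))
    model = _stage(
        "ftdi_model",
        lambda: fit_ftdi(
            train_matrix,
            dominant,
            weight_mode=weight_mode,
            ftdi_threshold=ftdi_threshold,
            adrai_threshold=adrai_threshold,
        ),
    )

    def _train_block():
        scores_df = score_cohort(model, train_matrix, clamp=False)
        mask = scores_df["group"].isin(["AD", "FTD"]) & scores_df["ftdi"].notna()
        sub = scores_df[mask]
        roc = roc_auc(sub["ftdi"].to_numpy(), (sub["group"] == "FTD").to_numpy())
        thr = roc.youden_threshold if use_youden_threshold else model.ftdi_threshold
        sens, spec = confusion_at(
            sub["ftdi"].to_numpy(), (sub["group"] == "FTD").to_numpy(), thr
        )
        return scores_df, roc, thr, sens, spec

    train_scores, train_roc, thr, train_sens, train_spec = _stage("evaluation", _train_block)
    if use_youden_threshold:
        model.ftdi_threshold = float(thr)

    def _val_block():
        scores_df = score_cohort(model, val_matrix, clamp=clamp_validation)
        mask = scores_df["group"].isin(["AD", "FTD"]) & scores_df["ftdi"].notna()
        sub = scores_df[mask]
        roc = roc_auc(sub["ftdi"].to_numpy(), (sub["group"] == "FTD").to_numpy())
        sens, spec = confusion_at(
            sub["ftdi"].to_numpy(),
            (sub["group"] == "FTD").to_numpy(),
            model.ftdi_threshold,
        )
        return scores_df, roc, sens, spec

    val_scores, val_roc, val_sens, val_spec = _stage("evaluation", _val_block)

    def _adrai_block():
        adrai = np.array([r.ad_rai for r in train_records], dtype=float)
        dementia = np.array([r.group in ("AD", "FTD") for r in train_records])
        roc = roc_auc(adrai, dementia)
        sens, spec = confusion_at(adrai, dementia, adrai_threshold)
        return roc, sens, spec

    adrai_roc, adrai_sens, adrai_spec = _stage("evaluation", _adrai_block)

    report = {
        "train": {
            "ftdi_auc": train_roc.auc,
            "sensitivity": train_sens,
            "specificity": train_spec,
            "youden_threshold": train_roc.youden_threshold,
            "threshold_used": model.ftdi_threshold,
            "n_ftd": int((train_matrix.groups == "FTD").sum()),
            "n_ad": int((train_matrix.groups == "AD").sum()),
            "n_flagged": int(train_scores["flag"].notna().sum()),
        },
        "validation": {
            "ftdi_auc": val_roc.auc,
            "sensitivity": val_sens,
            "specificity": val_spec,
            "threshold_used": model.ftdi_threshold,
            "n_ftd": int((val_matrix.groups == "FTD").sum()),
            "n_ad": int((val_matrix.groups == "AD").sum()),
            "n_flagged": int(val_scores["flag"].notna().sum()),
        },
        "adrai": {
            "auc": adrai_roc.auc,
            "sensitivity": adrai_sens,
            "specificity": adrai_spec,
            "threshold": adrai_threshold,
        },
        "dominant_sets": dominant.to_dict(),
        "weights": dict(model.weights),
    }
    if return_model:
        return report, model
    return report
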