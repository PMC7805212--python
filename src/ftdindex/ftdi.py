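"""The frontotemporal dementia index (FTDI): normalization, weights, scoring.

For measure *i* and subject *j*, with R_i(j) the raw derived measure, the
training cohort (all three groups) fixes per-measure extrema and

    R'_i(j) = (R_i(j) - min(R_i)) / (max(R_i) - min(R_i)).

Each dominant measure gets a weight from the raw values of the FTD and AD
training subjects,

    w_i = |sum_FTD R_i - sum_AD R_i| / (sum_FTD R_i + sum_AD R_i),

and a subject's index is the weighted-sum ratio

    FTDI(j) = sum_{i in FTD dominant} w_i R'_i(j) / sum_{i in AD dominant} w_i R'_i(j).

FTDI > ``ftdi_threshold`` (default 1.08) calls FTD; equality or below calls
AD.  On external cohorts the training extrema are reused and normalized
values below zero are clamped to zero (values above one pass through).  A
zero denominator yields an explicitly flagged missing score, never an
infinity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, ModelSchemaError, SchemaError, ZeroRangeError
from .group_stats import DominantSets
from .volumetry import MeasureMatrix

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def fit_normalizer(
    matrix: MeasureMatrix, measures: Sequence[str] | None = None
) -> tuple[dict, dict]:
    """Per-measure min and max over every training subject (NC included)."""
    measures = list(measures) if measures is not None else list(matrix.measure_names)
    train_min, train_max = {}, {}
    for m in measures:
        col = matrix.column(m)
        lo, hi = float(col.min()), float(col.max())
        if not hi > lo:
            raise ZeroRangeError(
                f"measure {m!r} is constant in the training matrix; "
                "min-max normalization is undefined"
            )
        train_min[m], train_max[m] = lo, hi
    return train_min, train_max


def normalize(value: float, train_min: float, train_max: float, clamp: bool = False) -> float:
    """Min-max normalize against training extrema.

    With ``clamp`` (external-cohort mode) results below 0 are set to 0; values
    above 1 are deliberately not clamped.
    """
    if not train_max > train_min:
        raise ZeroRangeError(f"train_max ({train_max}) must exceed train_min ({train_min})")
    r = (value - train_min) / (train_max - train_min)
    if clamp and r < 0:
        return 0.0
    return r


def compute_weight(ftd_values, ad_values, mode: str = "sum") -> float:
    """Normalized absolute difference of raw R_i between FTD and AD subjects.

    ``mode="sum"`` follows the defining equation literally (sums over
    subjects, which conflates group size with effect when sizes differ);
    ``mode="mean"`` uses group means instead and is size-balanced.
    """
    ftd = np.asarray(ftd_values, dtype=float)
    ad = np.asarray(ad_values, dtype=float)
    if ftd.size == 0 or ad.size == 0:
        raise InvalidInputError("both FTD and AD value lists must be non-empty")
    if (ftd < 0).any() or (ad < 0).any():
        raise InvalidInputError("raw measures must be non-negative")
    if mode == "sum":
        a, b = float(ftd.sum()), float(ad.sum())
    elif mode == "mean":
        a, b = float(ftd.mean()), float(ad.mean())
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    if a + b == 0:
        return 0.0
    return abs(a - b) / (a + b)


@dataclass
class FTDIModel:
    """Fitted FTDI model: extrema, weights, dominant sets and thresholds."""

    measure_names: list
    train_min: dict
    train_max: dict
    weights: dict
    dominant: DominantSets
    ftdi_threshold: float = 1.08
    adrai_threshold: float = 0.75
    weight_mode: str = "sum"
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        dom_union = self.dominant.all_measures
        if list(self.measure_names) != dom_union:
            raise ModelSchemaError("measure_names must equal the ordered dominant union")
        if not self.dominant.ftd_dominant or not self.dominant.ad_dominant:
            raise ModelSchemaError("both dominant sets must be non-empty")
        for m in self.measure_names:
            if m not in self.train_min or m not in self.train_max:
                raise ModelSchemaError(f"missing extrema for measure {m!r}")
            if not self.train_max[m] > self.train_min[m]:
                raise ModelSchemaError(f"train_max <= train_min for measure {m!r}")
            w = self.weights.get(m)
            if w is None or not 0 <= w <= 1:
                raise ModelSchemaError(f"weight for {m!r} must lie in [0, 1]")


@dataclass
class FTDIScore:
    """One subject's index value, or an explicit flag when undefined."""

    value: float | None
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def fit_ftdi(
    matrix: MeasureMatrix,
    dominant: DominantSets,
    weight_mode: str = "sum",
    include_nc_extrema: bool = True,
    ftdi_threshold: float = 1.08,
    adrai_threshold: float = 0.75,
    training_metadata: Mapping | None = None,
) -> FTDIModel:
    """Fit the FTDI model on a training matrix containing all three groups.

    Extrema are taken over every training subject (NC included, unless
    ``include_nc_extrema`` is disabled for sensitivity analysis); weights use
    the FTD and AD subjects only.  The fit is a pure function of its inputs.
    """
    for m in dominant.all_measures:
        if m not in matrix.measure_names:
            raise SchemaError(f"dominant set references absent measure {m!r}")
    extrema_matrix = matrix
    if not include_nc_extrema:
        extrema_matrix = matrix.subset(np.isin(matrix.groups, ["AD", "FTD"]))
    train_min, train_max = fit_normalizer(extrema_matrix, dominant.all_measures)
    n_ftd = int((matrix.groups == "FTD").sum())
    n_ad = int((matrix.groups == "AD").sum())
    if weight_mode == "sum" and n_ftd != n_ad:
        warnings.warn(
            f"FTD (n={n_ftd}) and AD (n={n_ad}) group sizes differ; sum-based "
            "weights conflate group size with effect — consider weight_mode='mean'",
            stacklevel=2,
        )
    weights = {
        m: compute_weight(
            matrix.group_values(m, "FTD"), matrix.group_values(m, "AD"), mode=weight_mode
        )
        for m in dominant.all_measures
    }
    logger.info("FTDI weights: %s", {m: round(w, 5) for m, w in weights.items()})
    meta = {"m_ftd": n_ftd, "n_ftd_plus_ad": n_ftd + n_ad, "created": None}
    if training_metadata:
        meta.update(training_metadata)
    return FTDIModel(
        measure_names=dominant.all_measures,
        train_min=train_min,
        train_max=train_max,
        weights=weights,
        dominant=dominant,
        ftdi_threshold=ftdi_threshold,
        adrai_threshold=adrai_threshold,
        weight_mode=weight_mode,
        training_metadata=meta,
    )


def score_ftdi(
    model: FTDIModel, subject_measures: Mapping[str, float], clamp: bool = False
) -> FTDIScore:
    """Score one subject from its raw measure values.

    ``clamp`` enables the external-cohort lower clamp of normalized values.
    A zero denominator returns a flagged, explicitly missing score.
    """
    missing = [m for m in model.measure_names if m not in subject_measures]
    if missing:
        raise SchemaError(f"subject is missing model measures: {missing}")
    num = 0.0
    for m in model.dominant.ftd_dominant:
        num += model.weights[m] * normalize(
            subject_measures[m], model.train_min[m], model.train_max[m], clamp
        )
    den = 0.0
    for m in model.dominant.ad_dominant:
        den += model.weights[m] * normalize(
            subject_measures[m], model.train_min[m], model.train_max[m], clamp
        )
    if den == 0.0:
        return FTDIScore(value=None, flag="zero_denominator")
    return FTDIScore(value=num / den)


def score_cohort(model: FTDIModel, matrix: MeasureMatrix, clamp: bool = False) -> pd.DataFrame:
    """Score every subject of a matrix; returns subject_id, group, ftdi, flag."""
    rows = []
    for j, sid in enumerate(matrix.subject_ids):
        measures = {m: matrix.values[j, matrix.measure_names.index(m)]
                    for m in model.measure_names}
        s = score_ftdi(model, measures, clamp=clamp)
        rows.append(
            {"subject_id": sid, "group": matrix.groups[j], "ftdi": s.value, "flag": s.flag}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def model_to_json(model: FTDIModel) -> str:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "measure_names": list(model.measure_names),
        "train_min": model.train_min,
        "train_max": model.train_max,
        "weights": model.weights,
        "dominant": model.dominant.to_dict(),
        "ftdi_threshold": model.ftdi_threshold,
        "adrai_threshold": model.adrai_threshold,
        "weight_mode": model.weight_mode,
        "training_metadata": model.training_metadata,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def save_model(model: FTDIModel, path) -> None:
    Path(path).write_text(model_to_json(model))


def model_from_json(text: str) -> FTDIModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"model document is not valid JSON: {exc}") from None
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelSchemaError(f"unsupported schema_version {version!r}")
    required = (
        "measure_names", "train_min", "train_max", "weights", "dominant",
        "ftdi_threshold", "adrai_threshold",
    )
    for key in required:
        if key not in doc:
            raise ModelSchemaError(f"model document missing field {key!r}")
    try:
        dominant = DominantSets.from_dict(doc["dominant"])
    except (KeyError, TypeError) as exc:
        raise ModelSchemaError(f"invalid dominant sets: {exc}") from None
    return FTDIModel(
        measure_names=list(doc["measure_names"]),
        train_min={k: float(v) for k, v in doc["train_min"].items()},
        train_max={k: float(v) for k, v in doc["train_max"].items()},
        weights={k: float(v) for k, v in doc["weights"].items()},
        dominant=dominant,
        ftdi_threshold=float(doc["ftdi_threshold"]),
        adrai_threshold=float(doc["adrai_threshold"]),
        weight_mode=doc.get("weight_mode", "sum"),
        training_metadata=doc.get("training_metadata", {}),
    )


def load_model(path) -> FTDIModel:
    return model_from_json(Path(path).read_text())
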