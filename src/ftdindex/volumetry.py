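"""Subject-level brain volumetry and the derived measures the analysis runs on.

A :class:`VolumetricRecord` holds one subject's raw volumetric report (absolute
structure volumes, per-lobe CSF and parenchyma volumes, total intracranial
volume), the exogenous AD-RAI score and demographics.  Three derived measures
are computed from it:

* **relative volume** — structure (or lobe parenchyma) volume as a percentage
  of total intracranial volume (ICV), correcting for head size;
* **lobar atrophy ratio** — 100 x CSF / parenchyma within a lobe;
* **QMTA** — quantitative medial temporal atrophy, the inferior lateral
  ventricle volume over the hippocampus volume.

:func:`build_measure_matrix` assembles the subjects x measures grid
(:class:`MeasureMatrix`) that the group statistics and the FTDI model consume.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

GROUPS = ("NC", "AD", "FTD")
COHORTS = ("train", "validation")
SEXES = ("male", "female")
LOBES = ("frontal", "temporal", "parietal", "occipital", "cingulate", "insular")
SIDES = ("left", "right")

#: Structures every record must report (absolute volumes in mL).
REQUIRED_STRUCTURES = (
    "hippocampus_total",
    "caudate_left",
    "inferior_lateral_ventricle",
    "lateral_ventricle",
    "ventricular_system",
    "brain_parenchyma",
    "amygdala_left",
    "amygdala_right",
)


@dataclass
class VolumetricRecord:
    """One subject's raw volumetry, exogenous AD-RAI score and demographics.

    All volumes are in mL.  ``lobe_volumes`` maps ``(lobe, side)`` to a
    ``(csf, parenchyma)`` pair.  ``mta_score`` is the visual medial-temporal
    atrophy rating (0-4 in 0.5 steps, averaged over hemispheres) and is carried
    as metadata only.
    """

    subject_id: str
    group: str
    cohort: str
    age: float
    sex: str
    education: float
    icv: float
    structure_volumes: dict
    lobe_volumes: dict
    ad_rai: float
    mta_score: float | None = None
    triplet_id: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.cohort not in COHORTS:
            raise InvalidInputError(f"unknown cohort {self.cohort!r}")
        if self.sex not in SEXES:
            raise InvalidInputError(f"unknown sex {self.sex!r}")
        if not self.icv > 0:
            raise InvalidInputError(f"{self.subject_id}: icv must be > 0, got {self.icv}")
        for name, vol in self.structure_volumes.items():
            if vol < 0:
                raise InvalidInputError(f"{self.subject_id}: structure {name} volume < 0")
            if vol > self.icv:
                raise InvalidInputError(
                    f"{self.subject_id}: structure {name} volume exceeds ICV"
                )
        for key, (csf, par) in self.lobe_volumes.items():
            if csf < 0:
                raise InvalidInputError(f"{self.subject_id}: lobe {key} CSF < 0")
            if not par > 0:
                raise InvalidInputError(f"{self.subject_id}: lobe {key} parenchyma <= 0")
        if self.ad_rai < 0:
            raise InvalidInputError(f"{self.subject_id}: ad_rai must be >= 0")
        if self.mta_score is not None and not 0 <= self.mta_score <= 4:
            raise InvalidInputError(f"{self.subject_id}: mta_score outside [0, 4]")


def relative_volume(absolute: float, icv: float) -> float:
    """Structure volume as a percentage of total intracranial volume.

    The percent scale matches the magnitudes the analysis expects (total
    hippocampus around 0.45 in healthy elderly).
    """
    if not icv > 0:
        raise InvalidInputError(f"icv must be > 0, got {icv}")
    if absolute < 0:
        raise InvalidInputError(f"absolute volume must be >= 0, got {absolute}")
    return 100.0 * absolute / icv


def lobe_atrophy(csf: float, parenchyma: float) -> float:
    """Lobar atrophy ratio: 100 x CSF volume / parenchyma volume within a lobe."""
    if not parenchyma > 0:
        raise InvalidInputError(f"parenchyma must be > 0, got {parenchyma}")
    if csf < 0:
        raise InvalidInputError(f"csf must be >= 0, got {csf}")
    return 100.0 * csf / parenchyma


def qmta(inferior_lateral_ventricle: float, hippocampus: float) -> float:
    """Quantitative medial temporal atrophy: inferior lateral ventricle / hippocampus."""
    if not hippocampus > 0:
        raise InvalidInputError(f"hippocampus volume must be > 0, got {hippocampus}")
    if inferior_lateral_ventricle < 0:
        raise InvalidInputError("inferior lateral ventricle volume must be >= 0")
    return inferior_lateral_ventricle / hippocampus


@dataclass(frozen=True)
class MeasureDefinition:
    """Recipe for one derived measure.

    ``kind`` is one of ``relative_volume`` (of ``structure`` or of the
    parenchyma of ``lobe``/``side``), ``lobe_atrophy`` (of ``lobe``/``side``)
    or ``qmta``.
    """

    name: str
    kind: str
    structure: str | None = None
    lobe: str | None = None
    side: str | None = None

    def evaluate(self, record: VolumetricRecord) -> float:
        try:
            if self.kind == "relative_volume":
                if self.structure is not None:
                    return relative_volume(
                        record.structure_volumes[self.structure], record.icv
                    )
                _, par = record.lobe_volumes[(self.lobe, self.side)]
                return relative_volume(par, record.icv)
            if self.kind == "lobe_atrophy":
                csf, par = record.lobe_volumes[(self.lobe, self.side)]
                return lobe_atrophy(csf, par)
            if self.kind == "qmta":
                return qmta(
                    record.structure_volumes["inferior_lateral_ventricle"],
                    record.structure_volumes["hippocampus_total"],
                )
        except KeyError as exc:
            raise SchemaError(
                f"subject {record.subject_id}: measure {self.name!r} needs "
                f"missing volumetry entry {exc.args[0]!r}"
            ) from None
        raise SchemaError(f"unknown measure kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind}
        if self.structure:
            d["structure"] = self.structure
        if self.lobe:
            d["lobe"], d["side"] = self.lobe, self.side
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MeasureDefinition":
        return cls(
            name=d["name"],
            kind=d["kind"],
            structure=d.get("structure"),
            lobe=d.get("lobe"),
            side=d.get("side"),
        )


def _rel(name, structure=None, lobe=None, side=None):
    return MeasureDefinition(name, "relative_volume", structure=structure, lobe=lobe, side=side)


def _atr(name, lobe, side):
    return MeasureDefinition(name, "lobe_atrophy", lobe=lobe, side=side)


#: The default analysis panel: the measures with a significant AD-vs-FTD
#: difference in the training comparisons (relative volumes and lobar atrophy
#: ratios), in their conventional reporting order.
DEFAULT_MEASURES: tuple[MeasureDefinition, ...] = (
    _rel("hippocampus", structure="hippocampus_total"),
    _rel("caudate_left", structure="caudate_left"),
    _atr("frontal_left_atrophy", "frontal", "left"),
    _atr("frontal_right_atrophy", "frontal", "right"),
    _atr("occipital_right_atrophy", "occipital", "right"),
    _rel("frontal_left", lobe="frontal", side="left"),
    _rel("occipital_right", lobe="occipital", side="right"),
    _rel("parietal_left", lobe="parietal", side="left"),
    _rel("parietal_right", lobe="parietal", side="right"),
    _rel("insular_left", lobe="insular", side="left"),
    _rel("insular_right", lobe="insular", side="right"),
)

#: The full quantitative panel (adds the measures that separate dementia from
#: controls but not AD from FTD: temporal lobes and QMTA).
FULL_MEASURES: tuple[MeasureDefinition, ...] = DEFAULT_MEASURES + (
    _rel("temporal_left", lobe="temporal", side="left"),
    _rel("temporal_right", lobe="temporal", side="right"),
    MeasureDefinition("qmta", "qmta"),
)


@dataclass
class MeasureMatrix:
    """Subjects x derived-measures grid with group labels and optional matching.

    Rows preserve the input record order.  ``triplet_ids``, when present, link
    each subject to its matched NC/AD/FTD triple.
    """

    measure_names: list[str]
    values: np.ndarray
    subject_ids: list[str]
    groups: np.ndarray
    triplet_ids: list | None = None
    definitions: tuple[MeasureDefinition, ...] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.values.shape != (len(self.subject_ids), len(self.measure_names)):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.measure_names)} measures"
            )
        if np.isnan(self.values).any():
            raise SchemaError("measure matrix contains missing values")
        if len(set(self.measure_names)) != len(self.measure_names):
            raise SchemaError("duplicate measure names")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, measure: str) -> np.ndarray:
        try:
            idx = self.measure_names.index(measure)
        except ValueError:
            raise SchemaError(f"unknown measure {measure!r}") from None
        return self.values[:, idx]

    def group_values(self, measure: str, group: str) -> np.ndarray:
        return self.column(measure)[self.groups == group]

    def subset(self, mask: np.ndarray) -> "MeasureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MeasureMatrix(
            measure_names=list(self.measure_names),
            values=self.values[mask],
            subject_ids=[s for s, m in zip(self.subject_ids, mask) if m],
            groups=self.groups[mask],
            triplet_ids=(
                [t for t, m in zip(self.triplet_ids, mask) if m]
                if self.triplet_ids is not None
                else None
            ),
            definitions=self.definitions,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.measure_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.groups)
        if self.triplet_ids is not None:
            df.insert(2, "triplet_id", self.triplet_ids)
        return df


def build_measure_matrix(
    records: Sequence[VolumetricRecord],
    measures: Sequence[MeasureDefinition] = DEFAULT_MEASURES,
) -> MeasureMatrix:
    """Assemble the subjects x measures matrix from raw volumetry records.

    Column order follows ``measures``; row order preserves ``records``.
    A missing structure or lobe raises :class:`SchemaError` naming the subject
    and the measure.
    """
    names = [m.name for m in measures]
    if len(set(names)) != len(names):
        raise SchemaError("measure definitions must have unique names")
    values = np.empty((len(records), len(measures)), dtype=float)
    for j, rec in enumerate(records):
        for i, m in enumerate(measures):
            values[j, i] = m.evaluate(rec)
    triplet_ids = [r.triplet_id for r in records]
    if any(t is None for t in triplet_ids):
        triplet_ids = None
    return MeasureMatrix(
        measure_names=names,
        values=values,
        subject_ids=[r.subject_id for r in records],
        groups=np.array([r.group for r in records], dtype=object),
        triplet_ids=triplet_ids,
        definitions=tuple(measures),
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_LOBE_COL = re.compile(
    rf"^({'|'.join(LOBES)})_({'|'.join(SIDES)})_(csf|parenchyma)_ml$"
)
_BASE_COLS = (
    "subject_id",
    "group",
    "cohort",
    "age",
    "sex",
    "education",
    "icv_ml",
    "ad_rai",
)
_OPTIONAL_COLS = ("mta_score", "triplet_id")


def records_to_dataframe(records: Sequence[VolumetricRecord]) -> pd.DataFrame:
    """Flatten records into the wide one-subject-per-row CSV schema."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "cohort": r.cohort,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
            "icv_ml": r.icv,
            "ad_rai": r.ad_rai,
            "mta_score": r.mta_score,
            "triplet_id": r.triplet_id,
        }
        for name, vol in r.structure_volumes.items():
            row[f"{name}_ml"] = vol
        for (lobe, side), (csf, par) in r.lobe_volumes.items():
            row[f"{lobe}_{side}_csf_ml"] = csf
            row[f"{lobe}_{side}_parenchyma_ml"] = par
        rows.append(row)
    return pd.DataFrame(rows)


def write_volumetry_csv(records: Sequence[VolumetricRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_volumetry_csv(path) -> list[VolumetricRecord]:
    """Read subject volumetry from the wide CSV schema.

    The header row is required.  Unknown columns are ignored with a logged
    warning; missing required columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _BASE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"volumetry CSV missing required columns: {missing}")
    known: set[str] = set(_BASE_COLS) | set(_OPTIONAL_COLS)
    structure_cols: dict[str, str] = {}
    lobe_cols: dict[str, tuple[str, str, str]] = {}
    for col in df.columns:
        if col in known:
            continue
        m = _LOBE_COL.match(col)
        if m:
            lobe_cols[col] = (m.group(1), m.group(2), m.group(3))
            known.add(col)
        elif col.endswith("_ml"):
            structure_cols[col] = col[: -len("_ml")]
            known.add(col)
        else:
            logger.warning("ignoring unknown column %r in %s", col, path)
    records = []
    for _, row in df.iterrows():
        structures = {name: float(row[col]) for col, name in structure_cols.items()}
        lobes: dict[tuple[str, str], list] = {}
        for col, (lobe, side, part) in lobe_cols.items():
            pair = lobes.setdefault((lobe, side), [np.nan, np.nan])
            pair[0 if part == "csf" else 1] = float(row[col])
        lobe_volumes = {}
        for key, (csf, par) in lobes.items():
            if np.isnan(csf) or np.isnan(par):
                raise SchemaError(
                    f"subject {row['subject_id']}: lobe {key} needs both csf and "
                    "parenchyma columns"
                )
            lobe_volumes[key] = (csf, par)
        mta = row.get("mta_score")
        triplet = row.get("triplet_id")
        records.append(
            VolumetricRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                cohort=str(row["cohort"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                icv=float(row["icv_ml"]),
                structure_volumes=structures,
                lobe_volumes=lobe_volumes,
                ad_rai=float(row["ad_rai"]),
                mta_score=None if pd.isna(mta) else float(mta),
                triplet_id=None if (triplet is None or pd.isna(triplet)) else str(triplet),
            )
        )
    return records


def write_measure_matrix(matrix: MeasureMatrix, csv_path, sidecar_json_path=None) -> None:
    """Write the matrix as CSV with a sidecar JSON of measure definitions."""
    matrix.to_dataframe().to_csv(csv_path, index=False)
    if sidecar_json_path is None:
        sidecar_json_path = Path(str(csv_path)).with_suffix(".measures.json")
    if matrix.definitions is not None:
        Path(sidecar_json_path).write_text(
            json.dumps([m.to_dict() for m in matrix.definitions], indent=2) + "\n"
        )
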