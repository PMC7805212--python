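"""Synthetic matched NC/AD/FTD cohorts from published median/IQR summaries.

The real study cohorts are access-restricted, so every downstream stage is
exercised on synthetic subjects whose per-group, per-measure marginals match
the printed summary table: each measure is drawn as a zero-truncated normal
with the group median as center and sigma = IQR / 1.349 (the normal
IQR-to-sigma factor).  Two latent factors give the data the dependence
structure the analysis assumes:

* a per-subject *severity* factor (loading ``latent_loading``) shared by all
  of a subject's measures, signed so atrophy-direction measures rise and
  tissue volumes fall together;
* a per-triplet *frailty* factor (loading ``triplet_correlation``) shared by
  the matched NC/AD/FTD triple, which is what makes the paired tests paired.

Independent noise is scaled so the marginal standard deviation stays at
sigma.  Raw volumetry (absolute volumes, lobar CSF/parenchyma, ICV) is
back-computed from the drawn relative measures so the volumetry module
round-trips exactly.  Generation is a pure function of the master seed;
per-group and per-measure substreams are derived by hashing stream labels, so
adding a measure never perturbs existing columns.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _params
from .exceptions import ConfigError
from .volumetry import (
    DEFAULT_MEASURES,
    GROUPS,
    LOBES,
    SIDES,
    MeasureDefinition,
    MeasureMatrix,
    VolumetricRecord,
    build_measure_matrix,
)

#: Normal-distribution IQR in units of sigma: Phi^-1(0.75) - Phi^-1(0.25).
IQR_TO_SD = 1.349

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class GroupMeasureParams:
    """Median and inter-quartile range of one measure in one group."""

    measure_name: str
    group: str
    median: float
    iqr: float

    def __post_init__(self):
        if self.iqr < 0:
            raise ConfigError(f"{self.measure_name}/{self.group}: iqr must be >= 0")
        if self.median < 0:
            raise ConfigError(f"{self.measure_name}/{self.group}: median must be >= 0")

    @property
    def sigma(self) -> float:
        return self.iqr / IQR_TO_SD


@dataclass
class Demographics:
    age_mean: float = 64.55
    age_sd: float = 10.15
    education_mean: float = 15.45
    education_sd: float = 2.98
    male_fraction: float = 25 / 47


@dataclass
class SimulationConfig:
    """Everything needed to draw one cohort; a pure function of ``seed``."""

    n_per_group: int = 47
    seed: int = 0
    params: list = field(default_factory=list)
    adrai_params: list = field(default_factory=list)
    mta_params: list = field(default_factory=list)
    icv: dict = field(default_factory=dict)  # group -> (mean mL, sd mL)
    demographics: Demographics = field(default_factory=Demographics)
    latent_loading: float = 0.3
    triplet_correlation: float = 0.2
    groups: tuple = GROUPS
    cohort: str = "train"

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if not (0 <= self.latent_loading < 1 and 0 <= self.triplet_correlation < 1):
            raise ConfigError("latent_loading and triplet_correlation must lie in [0, 1)")
        if self.latent_loading ** 2 + self.triplet_correlation ** 2 >= 1:
            raise ConfigError("latent_loading^2 + triplet_correlation^2 must be < 1")

    @property
    def measure_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.params:
            if p.measure_name not in seen:
                seen.append(p.measure_name)
        return seen

    def measure_params(self, measure: str, group: str) -> GroupMeasureParams:
        for p in self.params:
            if p.measure_name == measure and p.group == group:
                return p
        raise ConfigError(f"no parameters for measure {measure!r} in group {group!r}")

    def validate(self) -> None:
        for measure in self.measure_names:
            for group in self.groups:
                self.measure_params(measure, group)
        for group in self.groups:
            if group not in self.icv:
                raise ConfigError(f"no ICV parameters for group {group!r}")
            if not any(p.group == group for p in self.adrai_params):
                raise ConfigError(f"no AD-RAI parameters for group {group!r}")

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "n_per_group": self.n_per_group,
            "seed": self.seed,
            "latent_loading": self.latent_loading,
            "triplet_correlation": self.triplet_correlation,
            "groups": list(self.groups),
            "cohort": self.cohort,
            "icv": {g: list(v) for g, v in self.icv.items()},
            "demographics": asdict(self.demographics),
            "params": [asdict(p) for p in self.params],
            "adrai_params": [asdict(p) for p in self.adrai_params],
            "mta_params": [asdict(p) for p in self.mta_params],
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        doc = json.loads(text)
        return cls(
            n_per_group=doc["n_per_group"],
            seed=doc["seed"],
            params=[GroupMeasureParams(**p) for p in doc["params"]],
            adrai_params=[GroupMeasureParams(**p) for p in doc["adrai_params"]],
            mta_params=[GroupMeasureParams(**p) for p in doc.get("mta_params", [])],
            icv={g: tuple(v) for g, v in doc["icv"].items()},
            demographics=Demographics(**doc["demographics"]),
            latent_loading=doc["latent_loading"],
            triplet_correlation=doc["triplet_correlation"],
            groups=tuple(doc["groups"]),
            cohort=doc.get("cohort", "train"),
        )


def _table_params(table: dict, groups: Sequence[str]) -> list[GroupMeasureParams]:
    return [
        GroupMeasureParams(measure, g, *table[measure][g])
        for measure in table
        for g in groups
    ]


def default_nacc_params(
    n_per_group: int = 47,
    seed: int = 0,
    latent_loading: float = 0.3,
    triplet_correlation: float = 0.2,
) -> SimulationConfig:
    """Training-cohort configuration: every published measure row, all groups."""
    return SimulationConfig(
        n_per_group=n_per_group,
        seed=seed,
        params=_table_params(_params.TABLE_MEASURES, GROUPS),
        adrai_params=[GroupMeasureParams("ad_rai", g, *_params.ADRAI[g]) for g in GROUPS],
        mta_params=[GroupMeasureParams("mta_score", g, *_params.MTA[g]) for g in GROUPS],
        icv=dict(_params.ICV_TRAIN),
        demographics=Demographics(**_params.DEMOGRAPHICS_TRAIN),
        latent_loading=latent_loading,
        triplet_correlation=triplet_correlation,
        groups=GROUPS,
        cohort="train",
    )


def default_validation_params(
    n_per_group: int = 50,
    seed: int = 0,
    latent_loading: float = 0.3,
    triplet_correlation: float = 0.2,
) -> SimulationConfig:
    """Validation stand-in: AD and FTD only, unmatched, reusing the training
    measure rows (the study prints no per-measure validation summaries)."""
    groups = ("AD", "FTD")
    return SimulationConfig(
        n_per_group=n_per_group,
        seed=seed,
        params=_table_params(_params.TABLE_MEASURES, groups),
        adrai_params=[GroupMeasureParams("ad_rai", g, *_params.ADRAI[g]) for g in groups],
        mta_params=[GroupMeasureParams("mta_score", g, *_params.MTA[g]) for g in groups],
        icv=dict(_params.ICV_VALIDATION),
        demographics=Demographics(**_params.DEMOGRAPHICS_VALIDATION),
        latent_loading=latent_loading,
        triplet_correlation=triplet_correlation,
        groups=groups,
        cohort="validation",
    )


def measure_sign(name: str) -> int:
    """Disease-direction loading sign: +1 for measures that grow with atrophy
    (atrophy ratios, QMTA, AD-RAI, ventricles), -1 for tissue volumes."""
    if name.endswith("_atrophy") or name in ("qmta", "ad_rai") or "ventricle" in name:
        return 1
    return -1


def _rng(seed: int, *labels: str) -> np.random.Generator:
    keys = [int(seed)] + [zlib.crc32(lab.encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _draw_truncated(
    rng: np.random.Generator,
    n: int,
    median: float,
    sigma: float,
    base: np.ndarray,
    noise_scale: float,
) -> np.ndarray:
    """median + sigma*(base + noise_scale*eps), re-drawing eps until >= 0."""
    eps = rng.standard_normal(n)
    vals = median + sigma * (base + noise_scale * eps)
    if sigma == 0:
        return np.maximum(vals, 0.0)
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = vals < 0
        if not bad.any():
            return vals
        eps = rng.standard_normal(int(bad.sum()))
        vals[bad] = median + sigma * (base[bad] + noise_scale * eps)
    raise ConfigError(
        f"rejection sampling failed to produce non-negative draws "
        f"(median={median}, sigma={sigma})"
    )


def _draw_measure_group(
    config: SimulationConfig,
    params: GroupMeasureParams,
    z: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    lam, rho = config.latent_loading, config.triplet_correlation
    c = math.sqrt(max(0.0, 1.0 - lam * lam - rho * rho))
    s = measure_sign(params.measure_name)
    base = s * (lam * z + rho * t)
    rng = _rng(config.seed, params.group, params.measure_name)
    return _draw_truncated(
        rng, config.n_per_group, params.median, params.sigma, base, c
    )


def _latents(config: SimulationConfig, group: str) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_per_group
    z = _rng(config.seed, group, "subject-severity").standard_normal(n)
    if _matched(config):
        t = _rng(config.seed, "triplet-frailty").standard_normal(n)
    else:
        t = _rng(config.seed, group, "frailty").standard_normal(n)
    return z, t


def _matched(config: SimulationConfig) -> bool:
    return set(GROUPS) <= set(config.groups)


def simulate_adrai(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Draw only the exogenous AD-RAI score, per group (zero-truncated)."""
    out = {}
    for group in config.groups:
        p = next(q for q in config.adrai_params if q.group == group)
        z, t = _latents(config, group)
        out[group] = _draw_measure_group(config, p, z, t)
    return out


def simulate_cohort(
    config: SimulationConfig,
    panel: Sequence[MeasureDefinition] = DEFAULT_MEASURES,
) -> tuple[list[VolumetricRecord], MeasureMatrix]:
    """Draw a full cohort and return raw records plus the derived matrix.

    Training-style configs (all three groups) produce matched triplets sharing
    a ``triplet_id`` and one set of demographic draws; two-group configs are
    unmatched.  The returned matrix is built over ``panel`` via the volumetry
    module, so derived measures round-trip the raw volumetry exactly.
    """
    config.validate()
    n = config.n_per_group
    matched = _matched(config)
    demo = config.demographics

    # measure draws per group
    drawn: dict[str, dict[str, np.ndarray]] = {}
    latents = {g: _latents(config, g) for g in config.groups}
    for group in config.groups:
        z, t = latents[group]
        drawn[group] = {
            m: _draw_measure_group(config, config.measure_params(m, group), z, t)
            for m in config.measure_names
        }
        drawn[group]["ad_rai"] = _draw_measure_group(
            config, next(p for p in config.adrai_params if p.group == group), z, t
        )
        if config.mta_params:
            raw = _draw_measure_group(
                config, next(p for p in config.mta_params if p.group == group), z, t
            )
            drawn[group]["mta_score"] = np.clip(np.round(raw * 2) / 2, 0.0, 4.0)

    # demographics: one draw per triplet when matched, per group otherwise
    def _demo_draws(*labels):
        rng_age = _rng(config.seed, *labels, "age")
        rng_edu = _rng(config.seed, *labels, "education")
        rng_sex = _rng(config.seed, *labels, "sex")
        age = _draw_truncated(rng_age, n, demo.age_mean, demo.age_sd, np.zeros(n), 1.0)
        edu = _draw_truncated(
            rng_edu, n, demo.education_mean, demo.education_sd, np.zeros(n), 1.0
        )
        sex = np.where(rng_sex.uniform(size=n) < demo.male_fraction, "male", "female")
        return age, edu, sex

    if matched:
        shared_demo = _demo_draws("demographics")
        demo_by_group = {g: shared_demo for g in config.groups}
    else:
        demo_by_group = {g: _demo_draws("demographics", g) for g in config.groups}

    icv_by_group = {}
    for group in config.groups:
        mean, sd = config.icv[group]
        icv_by_group[group] = _draw_truncated(
            _rng(config.seed, group, "icv"), n, mean, sd, np.zeros(n), 1.0
        )

    records: list[VolumetricRecord] = []
    for j in range(n):
        for group in config.groups:
            vals = {m: drawn[group][m][j] for m in drawn[group]}
            icv = icv_by_group[group][j]
            records.append(
                _assemble_record(config, group, j, vals, icv, demo_by_group[group], matched)
            )
    matrix = build_measure_matrix(records, panel)
    return records, matrix


def _assemble_record(config, group, j, vals, icv, demo_draws, matched):
    """Back-compute raw volumetry from the drawn relative measures."""
    age, edu, sex = demo_draws

    def rel_ml(pct):  # percent of ICV -> mL
        return pct / 100.0 * icv

    structures = {
        name: rel_ml(pct) for name, pct in _params.NOMINAL_STRUCTURE_REL.items()
    }
    structures["hippocampus_total"] = rel_ml(vals["hippocampus"])
    structures["caudate_left"] = rel_ml(vals["caudate_left"])
    structures["inferior_lateral_ventricle"] = (
        vals["qmta"] * structures["hippocampus_total"] if "qmta" in vals else rel_ml(0.22)
    )

    lobes = {}
    for lobe in LOBES:
        for side in SIDES:
            rel_name = f"{lobe}_{side}"
            atr_name = f"{lobe}_{side}_atrophy"
            pct = vals.get(rel_name, _params.NOMINAL_LOBE_REL.get((lobe, side), 2.0))
            par = rel_ml(pct)
            atr = vals.get(atr_name, _params.NOMINAL_LOBE_ATROPHY.get((lobe, side), 30.0))
            lobes[(lobe, side)] = (atr / 100.0 * par, par)

    return VolumetricRecord(
        subject_id=f"{config.cohort}-{group}-{j:03d}",
        group=group,
        cohort=config.cohort,
        age=float(age[j]),
        sex=str(sex[j]),
        education=float(edu[j]),
        icv=float(icv),
        structure_volumes=structures,
        lobe_volumes=lobes,
        ad_rai=float(vals["ad_rai"]),
        mta_score=float(vals["mta_score"]) if "mta_score" in vals else None,
        triplet_id=f"T{j:03d}" if matched else None,
    )
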