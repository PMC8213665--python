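"""Synthetic cohorts, rating schedules and simulated raters.

Everything the original study's data provided can be generated here, so
the whole pipeline is testable without MRI or human raters:

* a normative reference population (default n = 461, mean age 70.09,
  SD 12.05, 51.4% female — the size and demographics of the study's
  dementia-free reference cohort);
* a 45-subject test cohort (15 controls, 16 AD, 14 FTD) in which disease
  is a multiplicative regional volume reduction: AD concentrated on
  hippocampal/temporal regions, FTD on frontal/insular regions, with a
  mild global reduction elsewhere.  Default multipliers are 0.80 focal /
  0.95 elsewhere, emulating the subtle atrophy of a young,
  short-duration clinical cohort;
* per-rater randomised episode schedules (each scan twice, once per
  condition, in a rater-specific pseudorandom order);
* simulated raters whose normal/abnormal call is a Bernoulli draw from
  condition-specific sensitivity/specificity, with a sub-diagnosis
  accuracy given a correct 'abnormal' call and a discretised-Gaussian
  confidence model on the 1-5 scale.

Volumes follow the same generating law the normative model assumes:
volume = b0 + b_age*age + b_sex*sex + b_tiv*tiv + N(0, sigma), in mL,
sex coded 0 = female / 1 = male.  All generators are deterministic under
a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io import CONDITIONS, RatingRecord, SubjectVolumes
from .normative import GM_KEY, WM_KEY, NormativeModel, _SEX_CODE


@dataclass
class RegionModel:
    """Generating law for one region: volume ~ b0 + b_age*age + b_sex*sex
    + b_tiv*tiv + N(0, sigma), in mL."""
    intercept: float
    beta_age: float
    beta_sex: float
    beta_tiv: float
    sigma: float

    def mean(self, age: float, sex01: float, tiv: float) -> float:
        return (self.intercept + self.beta_age * age + self.beta_sex * sex01
                + self.beta_tiv * tiv)


#: Default regional generating parameters (mL). Intercepts/slopes are set
#: so a 70-year-old with an average head gets volumes of realistic
#: magnitude (hippocampus ~3 mL, lobar GM tens of mL, total GM ~620 mL).
DEFAULT_REGION_MODELS: dict[str, RegionModel] = {
    "hippocampus_left":    RegionModel(2.50, -0.016, 0.10, 0.0012, 0.30),
    "hippocampus_right":   RegionModel(2.55, -0.016, 0.10, 0.0012, 0.30),
    "temporal_lobe_left":  RegionModel(30.0, -0.12, 1.5, 0.025, 5.0),
    "temporal_lobe_right": RegionModel(30.5, -0.12, 1.5, 0.025, 5.0),
    "frontal_lobe_left":   RegionModel(40.0, -0.18, 2.0, 0.035, 7.0),
    "frontal_lobe_right":  RegionModel(40.5, -0.18, 2.0, 0.035, 7.0),
    "parietal_lobe_left":  RegionModel(28.0, -0.14, 1.5, 0.026, 5.0),
    "parietal_lobe_right": RegionModel(28.5, -0.14, 1.5, 0.026, 5.0),
    "occipital_lobe_left": RegionModel(20.0, -0.06, 1.0, 0.014, 3.5),
    "occipital_lobe_right": RegionModel(20.5, -0.06, 1.0, 0.014, 3.5),
    "insula_left":         RegionModel(4.0, -0.020, 0.20, 0.0030, 0.8),
    "insula_right":        RegionModel(4.1, -0.020, 0.20, 0.0030, 0.8),
    "caudate_left":        RegionModel(2.2, -0.012, 0.10, 0.0015, 0.4),
    "caudate_right":       RegionModel(2.25, -0.012, 0.10, 0.0015, 0.4),
    # parenchyma scales ~proportionally with TIV so BPF stays in (0, 1)
    # across the whole head-size range
    GM_KEY:                RegionModel(60.0, -2.0, 5.0, 0.50, 30.0),
    WM_KEY:                RegionModel(30.0, -0.8, 4.0, 0.36, 28.0),
}

#: Regions showing focal atrophy per disease.
AD_FOCAL_REGIONS = ("hippocampus_left", "hippocampus_right",
                    "temporal_lobe_left", "temporal_lobe_right")
FTD_FOCAL_REGIONS = ("frontal_lobe_left", "frontal_lobe_right",
                     "insula_left", "insula_right")


def _atrophy_multipliers(focal: Sequence[str], focal_mult: float,
                         global_mult: float,
                         regions: Iterable[str]) -> dict[str, float]:
    return {r: (focal_mult if r in focal else global_mult) for r in regions}


@dataclass
class GroupSpec:
    """Demographics and atrophy for one cohort group."""
    name: str
    n: int
    age_mean: float
    age_sd: float
    p_female: float
    atrophy: dict[str, float] = field(default_factory=dict)  # region -> multiplier
    mmse_mean: float | None = None
    mmse_sd: float | None = None
    duration_mean: float | None = None
    duration_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"group {self.name}: n must be positive")
        if self.age_sd <= 0:
            raise ValidationError(f"group {self.name}: age SD must be positive")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValidationError(f"group {self.name}: p_female outside [0, 1]")
        for region, m in self.atrophy.items():
            if not 0.0 < m <= 1.0:
                raise ValidationError(
                    f"group {self.name}: atrophy multiplier {m} for {region!r} "
                    f"outside (0, 1]")


@dataclass
class CohortSpec:
    """Full generating specification for a cohort."""
    groups: list[GroupSpec]
    region_models: dict[str, RegionModel] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MODELS))
    age_range: tuple[float, float] = (30.0, 95.0)
    tiv_mean_female: float = 1320.0
    tiv_mean_male: float = 1460.0
    tiv_sd: float = 110.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort spec has no groups")
        for rm in self.region_models.values():
            if rm.sigma <= 0:
                raise ValidationError("region model sigma must be positive")
        if self.tiv_sd <= 0:
            raise ValidationError("TIV SD must be positive")


def default_normative_spec(n: int = 461) -> CohortSpec:
    """The dementia-free reference cohort: n = 461, age 70.09 (12.05),
    51.4% female."""
    return CohortSpec(groups=[GroupSpec(
        name="control", n=n, age_mean=70.09, age_sd=12.05, p_female=0.514)])


def default_test_cohort_spec(focal_mult: float = 0.80,
                             global_mult: float = 0.95) -> CohortSpec:
    """The 45-scan test cohort: 15 controls / 16 AD / 14 FTD with the
    published group demographics and default atrophy multipliers."""
    regions = list(DEFAULT_REGION_MODELS)
    return CohortSpec(groups=[
        GroupSpec("control", 15, 60.0, 8.7, 11 / 15),
        GroupSpec("AD", 16, 61.7, 6.6, 7 / 16,
                  atrophy=_atrophy_multipliers(AD_FOCAL_REGIONS, focal_mult,
                                               global_mult, regions),
                  mmse_mean=20.5, mmse_sd=6.4, duration_mean=2.7, duration_sd=1.6),
        GroupSpec("FTD", 14, 59.9, 7.3, 3 / 14,
                  atrophy=_atrophy_multipliers(FTD_FOCAL_REGIONS, focal_mult,
                                               global_mult, regions),
                  mmse_mean=22.0, mmse_sd=9.1, duration_mean=3.5, duration_sd=2.4),
    ])


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _simulate_group(spec: CohortSpec, group: GroupSpec, rng: np.random.Generator,
                    id_prefix: str) -> list[SubjectVolumes]:
    lo, hi = spec.age_range
    ages = _truncnorm(rng, group.age_mean, group.age_sd, lo, hi, group.n)
    female = rng.random(group.n) < group.p_female
    tiv_mean = np.where(female, spec.tiv_mean_female, spec.tiv_mean_male)
    tiv = rng.normal(tiv_mean, spec.tiv_sd)
    tiv = np.clip(tiv, 900.0, 2100.0)
    subjects = []
    for i in range(group.n):
        sex = "female" if female[i] else "male"
        sex01 = _SEX_CODE[sex]
        volumes = {}
        for region, rm in spec.region_models.items():
            v = rm.mean(ages[i], sex01, tiv[i]) + rng.normal(0.0, rm.sigma)
            v *= group.atrophy.get(region, 1.0)
            volumes[region] = max(v, 0.05)  # physical floor; vanishing tissue
        mmse = None
        if group.mmse_mean is not None:
            mmse = int(np.clip(round(rng.normal(group.mmse_mean, group.mmse_sd)),
                               0, 30))
        duration = None
        if group.duration_mean is not None:
            duration = float(max(rng.normal(group.duration_mean,
                                            group.duration_sd), 0.2))
        subjects.append(SubjectVolumes(
            subject_id=f"{id_prefix}{i + 1:04d}", age=float(ages[i]), sex=sex,
            tiv=float(tiv[i]), volumes=volumes, group=group.name,
            mmse=mmse, disease_duration=duration))
    return subjects


def simulate_normative_population(spec: CohortSpec | None = None,
                                  seed: int = 0) -> list[SubjectVolumes]:
    """Draw a normative reference cohort (deterministic under ``seed``)."""
    spec = spec or default_normative_spec()
    rng = np.random.default_rng(seed)
    subjects: list[SubjectVolumes] = []
    for gi, group in enumerate(spec.groups):
        subjects.extend(_simulate_group(spec, group, rng, f"ref{gi}_"))
    return subjects


def simulate_test_cohort(spec: CohortSpec | None = None,
                         seed: int = 0) -> list[SubjectVolumes]:
    """Draw the labelled patient/control test cohort."""
    spec = spec or default_test_cohort_spec()
    rng = np.random.default_rng(seed)
    subjects: list[SubjectVolumes] = []
    for group in spec.groups:
        subjects.extend(_simulate_group(spec, group, rng, f"{group.name}_"))
    return subjects


def simulate_from_model(model: NormativeModel, n: int, seed: int = 0,
                        spec: CohortSpec | None = None) -> list[SubjectVolumes]:
    """Draw fresh subjects from a *fitted* model's own generating process.

    Covariates come from the cohort spec's demographic distributions;
    volumes are the fitted regression means plus N(0, sigma-hat) noise.
    Used for percentile-calibration checks.
    """
    spec = spec or default_normative_spec()
    demo = spec.groups[0]
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range
    ages = _truncnorm(rng, demo.age_mean, demo.age_sd, lo, hi, n)
    female = rng.random(n) < demo.p_female
    tiv = np.clip(rng.normal(np.where(female, spec.tiv_mean_female,
                                      spec.tiv_mean_male), spec.tiv_sd),
                  900.0, 2100.0)
    subjects = []
    for i in range(n):
        sex = "female" if female[i] else "male"
        x = np.array([1.0, ages[i], _SEX_CODE[sex], tiv[i]])
        volumes = {region: max(float(fit.beta @ x + rng.normal(0.0, fit.sigma)),
                               0.05)
                   for region, fit in model.regions.items()}
        subjects.append(SubjectVolumes(
            subject_id=f"gen_{i + 1:05d}", age=float(ages[i]), sex=sex,
            tiv=float(tiv[i]), volumes=volumes, group="control"))
    return subjects


# ---------------------------------------------------------------------------
# episode schedules


def randomise_episodes(scan_ids: Sequence[str], rater_id: str,
                       seed: int = 0) -> list[tuple[str, str]]:
    """A rater-specific pseudorandom order of all scan x condition episodes.

    Each scan appears exactly twice (once per condition).  The stream is
    keyed on (seed, crc32(rater_id)), so the same seed gives every rater
    a distinct, reproducible order.
    """
    if not scan_ids:
        raise ValidationError("empty scan list")
    if len(set(scan_ids)) != len(scan_ids):
        raise ValidationError("duplicate scan ids in schedule request")
    rng = np.random.default_rng([seed, zlib.crc32(rater_id.encode("utf-8"))])
    episodes = [(scan, cond) for scan in scan_ids for cond in CONDITIONS]
    order = rng.permutation(len(episodes))
    return [episodes[i] for i in order]


# ---------------------------------------------------------------------------
# simulated raters


@dataclass
class RaterSpec:
    """Behavioural model of one rater.

    ``sensitivity``/``specificity`` are per condition (probability of
    calling a patient scan abnormal / a control scan normal);
    ``subdiagnosis_accuracy`` is the per-condition probability of the
    correct AD/FTD choice given a correct 'abnormal' call.  Confidence is
    a Gaussian (SD ``confidence_sd``) around a cell mean defined by
    additive shifts for correctness, scan abnormality and report
    availability, rounded and clipped to 1-5.
    """
    rater_id: str
    experience: str
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    subdiagnosis_accuracy: dict[str, float]
    confidence_base: float = 3.0
    confidence_correct_shift: float = 0.9
    confidence_abnormal_shift: float = 0.45
    confidence_report_shift: float = 0.25
    confidence_sd: float = 0.8

    def __post_init__(self) -> None:
        for name, table in (("sensitivity", self.sensitivity),
                            ("specificity", self.specificity),
                            ("subdiagnosis_accuracy", self.subdiagnosis_accuracy)):
            for cond in CONDITIONS:
                p = table.get(cond)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"rater {self.rater_id}: {name}[{cond}] must be a "
                        f"probability, got {p}")
        if self.confidence_sd <= 0:
            raise ValidationError("confidence SD must be positive")

    def confidence_mean(self, correct: bool, truth_abnormal: bool,
                        condition: str) -> float:
        m = (self.confidence_base
             + (self.confidence_correct_shift if correct else 0.0)
             + (self.confidence_abnormal_shift if truth_abnormal else 0.0)
             + (self.confidence_report_shift if condition == "with_report" else 0.0))
        return float(np.clip(m, 1.0, 5.0))


def default_rater_specs() -> list[RaterSpec]:
    """Nine raters (three per experience level) whose generating
    sensitivities/specificities mirror the published group means for
    volume-loss detection (combined sensitivity 71.5% -> 82.2% with the
    report)."""
    def trio(prefix: str, experience: str, sens: tuple[float, float],
             spec: tuple[float, float]) -> list[RaterSpec]:
        return [RaterSpec(
            rater_id=f"{prefix}{i}", experience=experience,
            sensitivity={"without_report": sens[0], "with_report": sens[1]},
            specificity={"without_report": spec[0], "with_report": spec[1]},
            subdiagnosis_accuracy={"without_report": 0.65, "with_report": 0.72},
        ) for i in (1, 2, 3)]

    return (trio("A", "consultant", (0.689, 0.800), (0.756, 0.800))
            + trio("B", "registrar", (0.755, 0.811), (0.822, 0.688))
            + trio("C", "analyst", (0.700, 0.855), (0.777, 0.689)))


def _draw_confidence(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 1, 5))


def simulate_raters(gold: Mapping[str, str], raters: Sequence[RaterSpec],
                    schedules: Mapping[str, Sequence[tuple[str, str]]],
                    seed: int = 0) -> list[RatingRecord]:
    """Simulate every rater working through their episode schedule.

    ``gold`` maps scan -> group; ``schedules`` maps rater id -> episode
    list (from :func:`randomise_episodes`).  Deterministic under ``seed``.
    """
    records: list[RatingRecord] = []
    for spec in raters:
        if spec.rater_id not in schedules:
            raise ValidationError(f"no schedule for rater {spec.rater_id!r}")
        schedule = schedules[spec.rater_id]
        covered = {s for s, _ in schedule}
        if covered != set(gold):
            raise ValidationError(
                f"rater {spec.rater_id!r}: schedule does not cover the cohort")
        rng = np.random.default_rng(
            [seed, zlib.crc32(spec.rater_id.encode("utf-8")), 7])
        for scan, condition in schedule:
            group = gold[scan]
            truth_abnormal = group in ("AD", "FTD")
            if truth_abnormal:
                call_abnormal = rng.random() < spec.sensitivity[condition]
            else:
                call_abnormal = rng.random() >= spec.specificity[condition]
            correct = call_abnormal == truth_abnormal
            conf_norm = _draw_confidence(
                rng, spec.confidence_mean(correct, truth_abnormal, condition),
                spec.confidence_sd)
            if call_abnormal:
                if truth_abnormal:
                    hit = rng.random() < spec.subdiagnosis_accuracy[condition]
                    diagnosis = group if hit else ("FTD" if group == "AD" else "AD")
                else:
                    diagnosis = "AD" if rng.random() < 0.5 else "FTD"
                conf_dx = _draw_confidence(
                    rng, spec.confidence_mean(correct, truth_abnormal, condition),
                    spec.confidence_sd)
                records.append(RatingRecord(
                    rater_id=spec.rater_id, experience=spec.experience,
                    scan_id=scan, condition=condition,
                    normality_call="abnormal", diagnosis_call=diagnosis,
                    confidence_normality=conf_norm, confidence_diagnosis=conf_dx))
            else:
                records.append(RatingRecord(
                    rater_id=spec.rater_id, experience=spec.experience,
                    scan_id=scan, condition=condition,
                    normality_call="normal", diagnosis_call="none",
                    confidence_normality=conf_norm, confidence_diagnosis=None))
    return records


def simulate_study(seed: int = 0, cohort_spec: CohortSpec | None = None,
                   rater_specs: Sequence[RaterSpec] | None = None,
                   ) -> tuple[list[SubjectVolumes], dict[str, str],
                              list[RatingRecord]]:
    """One full synthetic study: test cohort, gold standard, all ratings."""
    cohort = simulate_test_cohort(cohort_spec, seed=seed)
    gold = {s.subject_id: s.group for s in cohort}
    raters = list(rater_specs) if rater_specs is not None else default_rater_specs()
    scan_ids = [s.subject_id for s in cohort]
    schedules = {r.rater_id: randomise_episodes(scan_ids, r.rater_id, seed=seed)
                 for r in raters}
    ratings = simulate_raters(gold, raters, schedules, seed=seed)
    return cohort, gold, ratings
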