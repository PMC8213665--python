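"""Readers, writers and validation for volume tables, rating tables and
region-grouping configs.

All external input passes through this module and comes out canonicalised:
sex as ``male``/``female``, volumes in mL, conditions as
``without_report``/``with_report``.  The core modules never see raw CSV.

CSV dialect is fixed: comma separated, UTF-8, mandatory header, ``.``
decimal separator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import DuplicateRecordError, SchemaError, ValidationError

SEXES = ("female", "male")
GROUPS = ("control", "AD", "FTD", "unknown")
CONDITIONS = ("without_report", "with_report")
EXPERIENCE_LEVELS = ("consultant", "registrar", "analyst")
NORMALITY_CALLS = ("normal", "abnormal")
DIAGNOSIS_CALLS = ("AD", "FTD", "none")

_SEX_ALIASES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
}


def canonical_sex(value: str) -> str:
    """Map {M, F, male, female} (any case) onto ``male``/``female``."""
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValidationError(f"unrecognised sex value {value!r}")
    return _SEX_ALIASES[key]


@dataclass
class SubjectVolumes:
    """One subject's demographics, head size and regional volumes (mL).

    ``volumes`` maps region name -> volume in mL; insertion order is
    meaningful (it drives rose-plot sector order when no region map is
    given). ``tiv`` is total intracranial volume. ``mmse`` and
    ``disease_duration`` are optional because healthy controls have no
    disease duration.
    """

    subject_id: str
    age: float
    sex: str
    tiv: float
    volumes: dict[str, float]
    group: str = "unknown"
    mmse: int | None = None
    disease_duration: float | None = None

    def __post_init__(self) -> None:
        sid = self.subject_id
        if self.sex not in SEXES:
            self.sex = canonical_sex(self.sex)
        if self.group not in GROUPS:
            raise ValidationError(f"subject {sid}: unknown group {self.group!r}")
        if not (18.0 <= float(self.age) <= 110.0):
            raise ValidationError(f"subject {sid}: age {self.age} outside [18, 110]")
        if not self.tiv > 0:
            raise ValidationError(f"subject {sid}: TIV must be positive, got {self.tiv}")
        if not self.volumes:
            raise ValidationError(f"subject {sid}: no region volumes")
        for region, vol in self.volumes.items():
            if not vol > 0:
                raise ValidationError(
                    f"subject {sid}: non-positive volume {vol} for region {region!r}"
                )
            if not self.tiv > vol:
                raise ValidationError(
                    f"subject {sid}: region {region!r} volume {vol} not below TIV {self.tiv}"
                )
        if self.mmse is not None and not (0 <= int(self.mmse) <= 30):
            raise ValidationError(f"subject {sid}: MMSE {self.mmse} outside 0-30")

    @property
    def regions(self) -> list[str]:
        return list(self.volumes)


@dataclass
class RegionMap:
    """Ordered grouping of rose-plot regions into lobes.

    ``groups`` is an ordered list of (lobe, [region, ...]); the flattened
    order is the angular order of sectors on the plot.
    """

    groups: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        names = self.regions
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"region names duplicated across groups: {dupes}")
        if not names:
            raise ValidationError("region map is empty")

    @property
    def regions(self) -> list[str]:
        return [r for _, members in self.groups for r in members]

    @property
    def lobe_of(self) -> dict[str, str]:
        return {r: lobe for lobe, members in self.groups for r in members}

    def to_json(self) -> str:
        payload = {"groups": [{"lobe": l, "regions": rs} for l, rs in self.groups]}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RegionMap":
        payload = json.loads(text)
        try:
            groups = [(g["lobe"], list(g["regions"])) for g in payload["groups"]]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"region map JSON malformed: {exc}") from exc
        return cls(groups)


def default_region_map() -> RegionMap:
    """Default lobe/sub-region layout for the rose plot.

    The exact region set shown on a report is site-configurable; this
    default covers the lobes plus hippocampus and caudate, left/right.
    """
    return RegionMap([
        ("temporal", ["hippocampus_left", "hippocampus_right",
                      "temporal_lobe_left", "temporal_lobe_right"]),
        ("frontal", ["frontal_lobe_left", "frontal_lobe_right"]),
        ("parietal", ["parietal_lobe_left", "parietal_lobe_right"]),
        ("occipital", ["occipital_lobe_left", "occipital_lobe_right"]),
        ("insula", ["insula_left", "insula_right"]),
        ("subcortical", ["caudate_left", "caudate_right"]),
    ])


@dataclass
class RatingRecord:
    """One forced-choice rating episode: rater x scan x condition.

    Step 1 is the normal/abnormal volume-loss call with a 1-5 confidence;
    step 2 (only for 'abnormal') is the AD/FTD differential with its own
    confidence.
    """

    rater_id: str
    experience: str
    scan_id: str
    condition: str
    normality_call: str
    diagnosis_call: str
    confidence_normality: int
    confidence_diagnosis: int | None = None

    def __post_init__(self) -> None:
        where = f"rater {self.rater_id}, scan {self.scan_id}, {self.condition}"
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValidationError(f"{where}: unknown experience {self.experience!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"{where}: unknown condition {self.condition!r}")
        if self.normality_call not in NORMALITY_CALLS:
            raise ValidationError(f"{where}: unknown normality call {self.normality_call!r}")
        if self.diagnosis_call not in DIAGNOSIS_CALLS:
            raise ValidationError(f"{where}: unknown diagnosis {self.diagnosis_call!r}")
        if (self.diagnosis_call == "none") != (self.normality_call == "normal"):
            raise ValidationError(
                f"{where}: diagnosis must be 'none' iff the scan was called normal "
                f"(got {self.normality_call!r} with {self.diagnosis_call!r})"
            )
        if self.confidence_normality not in range(1, 6):
            raise ValidationError(f"{where}: confidence {self.confidence_normality} not in 1-5")
        if self.confidence_diagnosis is not None and self.confidence_diagnosis not in range(1, 6):
            raise ValidationError(
                f"{where}: diagnosis confidence {self.confidence_diagnosis} not in 1-5"
            )


@dataclass
class VolumeTableSchema:
    """Column-name configuration for volume CSVs.

    Any column not named here is auto-detected as a region column, in file
    order. ``volume_units`` may be ``mL`` or ``mm3``; mm3 inputs are divided
    by 1000 on read so the core always works in mL.
    """

    subject_id: str = "subject_id"
    age: str = "age"
    sex: str = "sex"
    tiv: str = "tiv"
    group: str = "group"
    mmse: str = "mmse"
    disease_duration: str = "disease_duration"
    volume_units: str = "mL"

    def demographic_columns(self) -> list[str]:
        return [self.subject_id, self.age, self.sex, self.tiv,
                self.group, self.mmse, self.disease_duration]


def _volume_scale(schema: VolumeTableSchema) -> float:
    if schema.volume_units == "mL":
        return 1.0
    if schema.volume_units in ("mm3", "mm^3"):
        return 1e-3
    raise SchemaError(f"unknown volume units {schema.volume_units!r}")


def read_volume_table(path: str | Path,
                      schema: VolumeTableSchema | None = None) -> list[SubjectVolumes]:
    """Read a per-subject volume CSV into validated :class:`SubjectVolumes`.

    Region columns are every column not declared in ``schema``, kept in
    file order. Raises :class:`SchemaError` if a mandatory column is
    missing and :class:`ValidationError` (naming the subject) on any
    invariant violation.
    """
    schema = schema or VolumeTableSchema()
    df = pd.read_csv(path)
    for col in (schema.subject_id, schema.age, schema.sex, schema.tiv):
        if col not in df.columns:
            raise SchemaError(f"volume table missing mandatory column {col!r}")
    region_cols = [c for c in df.columns if c not in schema.demographic_columns()]
    if not region_cols:
        raise SchemaError("volume table has no region columns")
    scale = _volume_scale(schema)

    subjects: list[SubjectVolumes] = []
    for _, row in df.iterrows():
        mmse = None
        if schema.mmse in df.columns and pd.notna(row[schema.mmse]):
            mmse = int(row[schema.mmse])
        duration = None
        if schema.disease_duration in df.columns and pd.notna(row[schema.disease_duration]):
            duration = float(row[schema.disease_duration])
        group = "unknown"
        if schema.group in df.columns and pd.notna(row[schema.group]):
            group = str(row[schema.group])
        subjects.append(SubjectVolumes(
            subject_id=str(row[schema.subject_id]),
            age=float(row[schema.age]),
            sex=canonical_sex(row[schema.sex]),
            tiv=float(row[schema.tiv]) * scale,
            volumes={c: float(row[c]) * scale for c in region_cols},
            group=group,
            mmse=mmse,
            disease_duration=duration,
        ))
    return subjects


def write_volume_table(subjects: Sequence[SubjectVolumes], path: str | Path) -> None:
    """Write subjects to CSV (mL, canonical column names, full precision)."""
    if not subjects:
        raise ValidationError("nothing to write: empty subject list")
    region_cols = subjects[0].regions
    rows = []
    for s in subjects:
        row: dict[str, object] = {
            "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
            "group": s.group, "tiv": s.tiv,
            "mmse": s.mmse if s.mmse is not None else "",
            "disease_duration": s.disease_duration if s.disease_duration is not None else "",
        }
        row.update({r: s.volumes[r] for r in region_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_RATING_COLUMNS = ["rater_id", "experience", "scan_id", "condition",
                   "normality_call", "diagnosis_call",
                   "confidence_normality", "confidence_diagnosis"]


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Read a rating-episode CSV into validated :class:`RatingRecord` s.

    Duplicate (rater, scan, condition) triples raise
    :class:`DuplicateRecordError`.
    """
    df = pd.read_csv(path)
    for col in _RATING_COLUMNS[:7]:
        if col not in df.columns:
            raise SchemaError(f"ratings table missing mandatory column {col!r}")
    records: list[RatingRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in df.iterrows():
        conf_dx = None
        if "confidence_diagnosis" in df.columns and pd.notna(row["confidence_diagnosis"]):
            conf_dx = int(row["confidence_diagnosis"])
        diagnosis = row["diagnosis_call"]
        if pd.isna(diagnosis) or str(diagnosis).strip() == "":
            diagnosis = "none"
        rec = RatingRecord(
            rater_id=str(row["rater_id"]),
            experience=str(row["experience"]),
            scan_id=str(row["scan_id"]),
            condition=str(row["condition"]),
            normality_call=str(row["normality_call"]),
            diagnosis_call=str(diagnosis),
            confidence_normality=int(row["confidence_normality"]),
            confidence_diagnosis=conf_dx,
        )
        key = (rec.rater_id, rec.scan_id, rec.condition)
        if key in seen:
            raise DuplicateRecordError(f"duplicate episode {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_ratings(records: Sequence[RatingRecord], path: str | Path) -> None:
    if not records:
        raise ValidationError("nothing to write: empty rating list")
    rows = [{
        "rater_id": r.rater_id, "experience": r.experience, "scan_id": r.scan_id,
        "condition": r.condition, "normality_call": r.normality_call,
        "diagnosis_call": r.diagnosis_call,
        "confidence_normality": r.confidence_normality,
        "confidence_diagnosis": r.confidence_diagnosis if r.confidence_diagnosis is not None else "",
    } for r in records]
    pd.DataFrame(rows, columns=_RATING_COLUMNS).to_csv(path, index=False)


def completeness_report(records: Iterable[RatingRecord],
                        scan_ids: Sequence[str]) -> dict[str, tuple[int, int]]:
    """Per rater: (episodes present, episodes expected).

    A complete study shows every scan twice per rater (once per condition),
    so expected = 2 x number of scans.
    """
    expected = 2 * len(scan_ids)
    scans = set(scan_ids)
    counts: dict[str, int] = {}
    for rec in records:
        if rec.scan_id in scans:
            counts[rec.rater_id] = counts.get(rec.rater_id, 0) + 1
    return {rater: (n, expected) for rater, n in sorted(counts.items())}


def gold_standard(subjects: Iterable[SubjectVolumes]) -> dict[str, str]:
    """Map scan id -> confirmed group label, for scoring rater calls."""
    return {s.subject_id: s.group for s in subjects}


def read_gold(path: str | Path) -> dict[str, str]:
    """Read a two-column (scan_id, group) gold-standard CSV."""
    df = pd.read_csv(path)
    for col in ("scan_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"gold table missing column {col!r}")
    gold = {}
    for _, row in df.iterrows():
        group = str(row["group"])
        if group not in GROUPS:
            raise ValidationError(f"scan {row['scan_id']}: unknown group {group!r}")
        gold[str(row["scan_id"])] = group
    return gold


def write_gold(gold: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"scan_id": k, "group": v} for k, v in gold.items()]
    ).to_csv(path, index=False)
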