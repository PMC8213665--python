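"""End-to-end analysis of one complete rating study.

Takes the full episode table plus the gold standard and produces every
summary the study design calls for, shaped like the published tables:

* per-task metric tables (sensitivity / specificity / accuracy by
  experience level, with vs without report, paired p and Cohen's d);
* correct sub-diagnosis percentages for AD and FTD;
* per-rater kappa tables (binary volume-loss and three-class diagnosis)
  with net changes and per-group paired p values;
* cross-rater reliability (Cronbach's alpha, ICC) per condition;
* per-rater and pooled McNemar tests on correct/incorrect counts;
* the confidence mixed ANOVA (skipped, with a note, if any rater has an
  empty cell — e.g. a rater who is never wrong).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import rater_stats as rs
from .exceptions import ValidationError
from .io import CONDITIONS, RatingRecord


@dataclass
class StudyResults:
    """All derived study tables; see module docstring."""

    metrics: dict[str, pd.DataFrame]          # task -> metric table
    subdiagnosis: pd.DataFrame                # correct AD/FTD diagnosis %
    kappa: dict[str, pd.DataFrame]            # 'volume_loss'/'diagnosis'
    kappa_summary: dict[str, dict[str, float]]
    reliability: pd.DataFrame                 # per condition alpha/ICC
    mcnemar: pd.DataFrame                     # per task x rater + pooled
    confidence_anova: dict[str, rs.AnovaEffect] | None
    confidence_anova_note: str = ""

    def to_dict(self) -> dict:
        out = {
            "metrics": {t: df.to_dict(orient="records") for t, df in self.metrics.items()},
            "subdiagnosis": self.subdiagnosis.to_dict(orient="records"),
            "kappa": {t: df.to_dict(orient="records") for t, df in self.kappa.items()},
            "kappa_summary": self.kappa_summary,
            "reliability": self.reliability.to_dict(orient="records"),
            "mcnemar": self.mcnemar.to_dict(orient="records"),
            "confidence_anova": None,
            "confidence_anova_note": self.confidence_anova_note,
        }
        if self.confidence_anova is not None:
            out["confidence_anova"] = {
                name: {"F": e.F, "df": [e.df_num, e.df_den], "p": e.p,
                       "partial_eta_sq": e.partial_eta_sq}
                for name, e in self.confidence_anova.items()}
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float),
                              encoding="utf-8")


def _experience_map(ratings: Sequence[RatingRecord]) -> dict[str, str]:
    exp: dict[str, str] = {}
    for r in ratings:
        if r.rater_id in exp and exp[r.rater_id] != r.experience:
            raise ValidationError(f"rater {r.rater_id!r} has two experience levels")
        exp[r.rater_id] = r.experience
    return exp


def _metric_table(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                  task: str, experience: Mapping[str, str],
                  subdiagnosis: str) -> pd.DataFrame:
    counts = rs.confusion_counts(ratings, gold, task, subdiagnosis)
    raters = sorted(experience)
    levels = sorted(set(experience.values()))
    rows = []
    for metric in rs.METRICS:
        per_cond: dict[str, dict[str, float]] = {}
        for cond in CONDITIONS:
            vals = {}
            for rater in raters:
                triple = rs.metric_triple(counts[(rater, cond)])
                v = getattr(triple, metric)
                if v is None:
                    raise ValidationError(
                        f"{metric} undefined for rater {rater!r} ({cond})")
                vals[rater] = v
            per_cond[cond] = vals
        for level in levels + ["combined"]:
            sel = (raters if level == "combined"
                   else [r for r in raters if experience[r] == level])
            wo = np.array([per_cond["without_report"][r] for r in sel])
            wi = np.array([per_cond["with_report"][r] for r in sel])
            if len(sel) >= 2:
                tt = rs.paired_t_and_d(wo, wi)
                p, d = tt.p, tt.cohens_d
            else:
                p, d = np.nan, np.nan
            if level == "combined":
                gwo = rs.aggregate_group_metrics(per_cond["without_report"], experience)
                gwi = rs.aggregate_group_metrics(per_cond["with_report"], experience)
                mean_wo, sd_wo = gwo.combined_mean, gwo.combined_sd
                mean_wi, sd_wi = gwi.combined_mean, gwi.combined_sd
            else:
                mean_wo, sd_wo = float(wo.mean()), float(wo.std(ddof=1))
                mean_wi, sd_wi = float(wi.mean()), float(wi.std(ddof=1))
            rows.append({"metric": metric, "experience": level,
                         "without_mean": mean_wo, "without_sd": sd_wo,
                         "with_mean": mean_wi, "with_sd": sd_wi,
                         "p_value": p, "cohens_d": d})
    return pd.DataFrame(rows)


def _subdiagnosis_table(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                        ) -> pd.DataFrame:
    """Percent of each disease's scans given the correct sub-diagnosis,
    averaged over raters, per condition."""
    raters = sorted({r.rater_id for r in ratings})
    rows = []
    for disease in ("AD", "FTD"):
        scans = [s for s, g in gold.items() if g == disease]
        per_cond = {}
        for cond in CONDITIONS:
            vals = []
            for rater in raters:
                hits = sum(1 for r in ratings
                           if r.rater_id == rater and r.condition == cond
                           and r.scan_id in scans and r.diagnosis_call == disease)
                vals.append(100.0 * hits / len(scans))
            per_cond[cond] = np.array(vals)
        tt = rs.paired_t_and_d(per_cond["without_report"], per_cond["with_report"])
        rows.append({"disease": disease,
                     "without_mean": float(per_cond["without_report"].mean()),
                     "without_sd": float(per_cond["without_report"].std(ddof=1)),
                     "with_mean": float(per_cond["with_report"].mean()),
                     "with_sd": float(per_cond["with_report"].std(ddof=1)),
                     "p_value": tt.p, "cohens_d": tt.cohens_d})
    return pd.DataFrame(rows)


def _diagnosis_label(rec: RatingRecord) -> str:
    return "normal" if rec.normality_call == "normal" else rec.diagnosis_call


def _gold_label(group: str) -> str:
    return "normal" if group == "control" else group


def rater_kappas(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                 task: str) -> dict[tuple[str, str], float]:
    """Per (rater, condition) kappa against the gold standard.

    ``task='volume_loss'`` scores the binary normal/abnormal call;
    ``'diagnosis'`` the three-class normal/AD/FTD label.
    """
    scans = sorted(gold)
    by_rc: dict[tuple[str, str], dict[str, RatingRecord]] = {}
    for r in ratings:
        by_rc.setdefault((r.rater_id, r.condition), {})[r.scan_id] = r
    out = {}
    for (rater, cond), recs in by_rc.items():
        if task == "volume_loss":
            pred = [recs[s].normality_call for s in scans]
            truth = ["abnormal" if gold[s] in ("AD", "FTD") else "normal"
                     for s in scans]
        elif task == "diagnosis":
            pred = [_diagnosis_label(recs[s]) for s in scans]
            truth = [_gold_label(gold[s]) for s in scans]
        else:
            raise ValidationError(f"unknown kappa task {task!r}")
        res = rs.cohens_kappa(pred, truth)
        out[(rater, cond)] = res.kappa if res.kappa is not None else np.nan
    return out


def _kappa_table(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                 task: str, experience: Mapping[str, str],
                 ) -> tuple[pd.DataFrame, dict[str, float]]:
    kappas = rater_kappas(ratings, gold, task)
    raters = sorted(experience)
    rows = []
    for level in sorted(set(experience.values())):
        members = [r for r in raters if experience[r] == level]
        wo = [kappas[(r, "without_report")] for r in members]
        wi = [kappas[(r, "with_report")] for r in members]
        p = rs.paired_t_and_d(wo, wi).p if len(members) >= 2 else np.nan
        for i, rater in enumerate(members):
            rows.append({"experience": level, "rater": rater,
                         "kappa_without": wo[i], "kappa_with": wi[i],
                         "net_change": wi[i] - wo[i],
                         "group_p_value": p if i == 0 else np.nan})
    df = pd.DataFrame(rows)
    summary = {
        "mean_without": float(df["kappa_without"].mean()),
        "sd_without": float(df["kappa_without"].std(ddof=1)),
        "mean_with": float(df["kappa_with"].mean()),
        "sd_with": float(df["kappa_with"].std(ddof=1)),
        "mean_net_change": float(df["net_change"].mean()),
    }
    return df, summary


def _reliability_table(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                       ) -> pd.DataFrame:
    scans = sorted(gold)
    raters = sorted({r.rater_id for r in ratings})
    rows = []
    for cond in CONDITIONS:
        m = np.zeros((len(scans), len(raters)))
        filled = np.zeros_like(m, dtype=bool)
        for r in ratings:
            if r.condition != cond:
                continue
            m[scans.index(r.scan_id), raters.index(r.rater_id)] = \
                1.0 if r.normality_call == "abnormal" else 0.0
            filled[scans.index(r.scan_id), raters.index(r.rater_id)] = True
        if not filled.all():
            raise ValidationError(f"incomplete rating matrix for {cond}")
        rel = rs.reliability(m)
        rows.append({"condition": cond, "cronbach_alpha": rel.cronbach_alpha,
                     "icc_single": rel.icc_single, "icc_average": rel.icc_average})
    return pd.DataFrame(rows)


def _mcnemar_table(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                   subdiagnosis: str, experience: Mapping[str, str],
                   ) -> pd.DataFrame:
    by_rcs: dict[tuple[str, str, str], RatingRecord] = {
        (r.rater_id, r.condition, r.scan_id): r for r in ratings}
    raters = sorted(experience)
    rows = []
    for task in rs.TASKS:
        scans = sorted(rs._task_scans(gold, task))
        total_b = total_c = 0
        for rater in raters:
            b = c = 0
            for scan in scans:
                truth = rs._is_positive_scan(gold[scan], task)
                wo = by_rcs[(rater, "without_report", scan)]
                wi = by_rcs[(rater, "with_report", scan)]
                ok_wo = rs._positive_call(wo, task, subdiagnosis) == truth
                ok_wi = rs._positive_call(wi, task, subdiagnosis) == truth
                if ok_wo and not ok_wi:
                    b += 1
                elif ok_wi and not ok_wo:
                    c += 1
            res = rs.mcnemar_test(b, c)
            rows.append({"task": task, "rater": rater, "b_lost": b, "c_gained": c,
                         "p_value": res.p, "method": res.method})
            total_b += b
            total_c += c
        pooled = rs.mcnemar_test(total_b, total_c)
        rows.append({"task": task, "rater": "pooled", "b_lost": total_b,
                     "c_gained": total_c, "p_value": pooled.p,
                     "method": pooled.method})
    return pd.DataFrame(rows)


def analyse_study(ratings: Sequence[RatingRecord], gold: Mapping[str, str],
                  subdiagnosis: str = "strict") -> StudyResults:
    """Run the complete study analysis; see module docstring."""
    experience = _experience_map(ratings)
    metrics = {task: _metric_table(ratings, gold, task, experience, subdiagnosis)
               for task in rs.TASKS}
    kappa_tables = {}
    kappa_summary = {}
    for task in ("volume_loss", "diagnosis"):
        df, summary = _kappa_table(ratings, gold, task, experience)
        kappa_tables[task] = df
        kappa_summary[task] = summary
    note = ""
    try:
        anova = rs.confidence_anova(ratings, gold)
    except ValidationError as exc:
        anova = None
        note = str(exc)
    return StudyResults(
        metrics=metrics,
        subdiagnosis=_subdiagnosis_table(ratings, gold),
        kappa=kappa_tables,
        kappa_summary=kappa_summary,
        reliability=_reliability_table(ratings, gold),
        mcnemar=_mcnemar_table(ratings, gold, subdiagnosis, experience),
        confidence_anova=anova,
        confidence_anova_note=note,
    )
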