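"""Statistics for the multi-rater clinical-accuracy study.

Covers the full analysis of a forced-choice reader study in which each
rater assesses every scan twice (with and without the quantitative
report):

* signal-detection metrics (sensitivity / specificity / accuracy, in %)
  per rater, per condition, for three tasks — volume-loss detection and
  the AD-vs-normal / FTD-vs-normal differentials;
* paired comparisons across conditions: McNemar on per-scan counts,
  paired t with Cohen's d on per-rater metrics;
* agreement with the gold standard (Cohen's kappa, binary and
  three-class) and reliability across raters (Cronbach's alpha,
  ICC(3,1) / ICC(3,k) from a two-way mixed ANOVA, consistency form);
* a mixed ANOVA on confidence cell means (within: report x scan
  normality x correctness; between: experience level) with partial
  eta squared effect sizes;
* sample-size planning for a future paired design.

Percentages use the standard ratios x 100.  Cohen's d for the paired
design uses the pooled-SD denominator sqrt((SD1^2 + SD2^2)/2) by default
(matching how the published group tables report d); the
SD-of-differences convention is available via ``d_method``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import QReportError, ValidationError
from .io import CONDITIONS, RatingRecord

TASKS = ("volume_loss", "AD_vs_normal", "FTD_vs_normal")
METRICS = ("sensitivity", "specificity", "accuracy")


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricTriple:
    """Sensitivity / specificity / accuracy in %; None when undefined
    (zero denominator)."""
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def _positive_call(rec: RatingRecord, task: str, subdiagnosis: str) -> bool:
    if task == "volume_loss":
        return rec.normality_call == "abnormal"
    target = "AD" if task == "AD_vs_normal" else "FTD"
    if subdiagnosis == "strict":
        return rec.normality_call == "abnormal" and rec.diagnosis_call == target
    if subdiagnosis == "abnormal_only":
        return rec.normality_call == "abnormal"
    raise QReportError(f"unknown subdiagnosis convention {subdiagnosis!r}")


def _task_scans(gold: Mapping[str, str], task: str) -> set[str]:
    if task == "volume_loss":
        return set(gold)
    target = "AD" if task == "AD_vs_normal" else "FTD"
    return {s for s, g in gold.items() if g in (target, "control")}


def _is_positive_scan(group: str, task: str) -> bool:
    if task == "volume_loss":
        return group in ("AD", "FTD")
    return group == ("AD" if task == "AD_vs_normal" else "FTD")


def confusion_counts(ratings: Iterable[RatingRecord], gold: Mapping[str, str],
                     task: str = "volume_loss", subdiagnosis: str = "strict",
                     ) -> dict[tuple[str, str], ConfusionCounts]:
    """Per (rater, condition) confusion counts for one task.

    ``volume_loss`` scores every scan: a positive scan is any patient
    (AD or FTD) and a positive call is 'abnormal'.  The differential
    tasks restrict to {target disease, control} scans; under the default
    ``strict`` convention a true positive requires the correct
    sub-diagnosis, under ``abnormal_only`` any 'abnormal' call counts.
    """
    if task not in TASKS:
        raise QReportError(f"unknown task {task!r}")
    scans = _task_scans(gold, task)
    out: dict[tuple[str, str], ConfusionCounts] = {}
    for rec in ratings:
        if rec.scan_id not in gold:
            raise ValidationError(f"scan {rec.scan_id!r} missing from gold standard")
        if rec.scan_id not in scans:
            continue
        c = out.setdefault((rec.rater_id, rec.condition), ConfusionCounts())
        truth_pos = _is_positive_scan(gold[rec.scan_id], task)
        call_pos = _positive_call(rec, task, subdiagnosis)
        if truth_pos and call_pos:
            c.tp += 1
        elif truth_pos:
            c.fn += 1
        elif call_pos:
            c.fp += 1
        else:
            c.tn += 1
    return out


def metric_triple(c: ConfusionCounts) -> MetricTriple:
    """Accuracy / sensitivity / specificity as percentages.

    Zero denominators yield None rather than raising: a rater who calls
    everything abnormal has no defined specificity.
    """
    if c.total == 0:
        raise ValidationError("empty confusion counts")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    return MetricTriple(sensitivity=sens, specificity=spec, accuracy=acc)


# ---------------------------------------------------------------------------
# group aggregation


@dataclass
class GroupSummary:
    """Per-experience-group mean/SD plus the combined row.

    The combined mean is the unweighted mean of the group means (equal to
    the grand mean when groups are equally sized); the combined SD is the
    sample SD over all raters.
    """
    group_stats: dict[str, tuple[float, float, int]]  # level -> (mean, sd, n)
    combined_mean: float
    combined_sd: float


def mean_of_group_means(group_means: Sequence[float]) -> float:
    """Unweighted mean of group means — the 'all groups combined' row."""
    return float(np.mean(np.asarray(group_means, float)))


def aggregate_group_metrics(values: Mapping[str, float],
                            experience: Mapping[str, str]) -> GroupSummary:
    """Aggregate a per-rater metric into per-group and combined rows."""
    levels: dict[str, list[float]] = {}
    for rater, v in values.items():
        levels.setdefault(experience[rater], []).append(float(v))
    if not levels or any(len(vs) == 0 for vs in levels.values()):
        raise ValidationError("every experience group needs at least one rater")
    group_stats = {
        lvl: (float(np.mean(vs)),
              float(np.std(vs, ddof=1)) if len(vs) > 1 else 0.0,
              len(vs))
        for lvl, vs in levels.items()
    }
    all_vals = [v for vs in levels.values() for v in vs]
    return GroupSummary(
        group_stats=group_stats,
        combined_mean=mean_of_group_means([m for m, _, _ in group_stats.values()]),
        combined_sd=float(np.std(all_vals, ddof=1)) if len(all_vals) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# paired tests and effect sizes


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float


def cohens_d_from_summary(mean_without: float, sd_without: float,
                          mean_with: float, sd_with: float) -> float:
    """Pooled-SD Cohen's d: (m_with - m_without) / sqrt((SD1^2 + SD2^2)/2)."""
    pooled = math.sqrt((sd_without ** 2 + sd_with ** 2) / 2.0)
    if pooled == 0:
        raise ValidationError("both SDs are zero; d undefined")
    return (mean_with - mean_without) / pooled


def paired_t_and_d(x_without: Sequence[float], x_with: Sequence[float],
                   d_method: str = "pooled") -> TTestResult:
    """Paired t across conditions with Cohen's d.

    ``d_method='pooled'`` divides the mean difference by
    sqrt((SD1^2+SD2^2)/2); ``'diff'`` divides by the SD of the paired
    differences.  Zero-variance differences with a non-zero mean report
    t = +-inf, p = 0.
    """
    a = np.asarray(x_without, float)
    b = np.asarray(x_with, float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need two equal-length vectors of >= 2 paired values")
    diff = b - a
    md = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    n = a.size
    if sd_diff == 0:
        t = 0.0 if md == 0 else math.copysign(math.inf, md)
        p = 1.0 if md == 0 else 0.0
    else:
        t = md / (sd_diff / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    if d_method == "pooled":
        pooled = math.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
        d = 0.0 if (pooled == 0 and md == 0) else (
            math.copysign(math.inf, md) if pooled == 0 else md / pooled)
    elif d_method == "diff":
        d = 0.0 if (sd_diff == 0 and md == 0) else (
            math.copysign(math.inf, md) if sd_diff == 0 else md / sd_diff)
    else:
        raise QReportError(f"unknown d_method {d_method!r}")
    return TTestResult(t=float(t), df=n - 1, p=float(p), cohens_d=float(d))


@dataclass
class McNemarResult:
    statistic: float | None  # chi-square (None in exact mode)
    p: float | None
    method: str  # 'chi2_cc' or 'exact'


def mcnemar_test(b: int, c: int, exact: bool | None = None,
                 correction: bool = True) -> McNemarResult:
    """McNemar test on the two discordant counts.

    Default is the continuity-corrected chi-square (|b-c|-1)^2/(b+c) on
    1 df, switching to the exact two-sided binomial when b + c < 25.
    ``exact`` forces one mode; ``correction=False`` gives the plain
    (b-c)^2/(b+c) statistic.  b + c = 0 returns p = None (undefined).
    """
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(statistic=None, p=None, method="undefined")
    if exact is None:
        exact = n < 25
    if exact:
        p = stats.binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue
        return McNemarResult(statistic=None, p=float(p), method="exact")
    if correction:
        chi2 = max(abs(b - c) - 1.0, 0.0) ** 2 / n
    else:
        chi2 = (b - c) ** 2 / n
    return McNemarResult(statistic=float(chi2), p=float(stats.chi2.sf(chi2, 1)),
                         method="chi2_cc" if correction else "chi2")


# ---------------------------------------------------------------------------
# agreement and reliability


@dataclass
class AgreementResult:
    kappa: float | None
    p_o: float
    p_e: float
    n: int


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Unweighted Cohen's kappa between two label sequences.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the product-marginal chance
    agreement.  If both sides are constant and identical (p_e = 1), kappa
    is undefined (None).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b) or not a:
        raise ValidationError("label sequences must be non-empty and equal length")
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p_o = float(np.trace(table)) / n
    p_e = float(table.sum(axis=1) @ table.sum(axis=0)) / n ** 2
    if p_e >= 1.0 - 1e-15:
        return AgreementResult(kappa=None, p_o=p_o, p_e=p_e, n=n)
    return AgreementResult(kappa=(p_o - p_e) / (1.0 - p_e), p_o=p_o, p_e=p_e, n=n)


def cronbach_alpha(score_matrix: np.ndarray) -> float | None:
    """Cronbach's alpha with raters as items.

    ``score_matrix`` is scans x raters (e.g. abnormal = 1 / normal = 0).
    alpha = k/(k-1) * (1 - sum(item variances) / var(row sums)); None if
    the row-sum variance is zero.
    """
    m = np.asarray(score_matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 scans and >= 2 raters")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return None
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class ICCResult:
    icc_single: float | None   # ICC(3,1), consistency
    icc_average: float | None  # ICC(3,k), consistency
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_two_way_mixed(score_matrix: np.ndarray) -> ICCResult:
    """Consistency ICCs from a two-way mixed ANOVA without interaction.

    Rows are scans (random), columns raters (fixed).
    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E);
    ICC(3,k) = (MS_R - MS_E) / MS_R.
    """
    m = np.asarray(score_matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 scans and >= 2 raters")
    n, k = m.shape
    grand = m.mean()
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = float(k * ((m.mean(axis=1) - grand) ** 2).sum())
    ss_cols = float(n * ((m.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        return ICCResult(None, None, ms_rows, ms_cols, ms_err)
    single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    average = (ms_rows - ms_err) / ms_rows
    return ICCResult(float(single), float(average), ms_rows, ms_cols, ms_err)


@dataclass
class ReliabilityResult:
    cronbach_alpha: float | None
    icc_single: float | None
    icc_average: float | None
    ms_rows: float
    ms_error: float


def reliability(score_matrix: np.ndarray) -> ReliabilityResult:
    """Cronbach's alpha and both consistency ICCs from one matrix."""
    alpha = cronbach_alpha(score_matrix)
    icc = icc_two_way_mixed(score_matrix)
    return ReliabilityResult(alpha, icc.icc_single, icc.icc_average,
                             icc.ms_rows, icc.ms_error)


# ---------------------------------------------------------------------------
# mixed ANOVA on confidence cell means


@dataclass
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss: float
    ss_error: float


def mixed_anova(table: pd.DataFrame, dv: str, subject: str, between: str,
                within: Sequence[str]) -> dict[str, AnovaEffect]:
    """Balanced mixed ANOVA by sums-of-squares partitioning.

    ``table`` is long format with one row per subject x within-cell.
    Within effects (and their interactions with the between factor) are
    tested against the matching effect x subject-within-group error; the
    between factor is tested against subjects-within-groups.  Requires a
    complete, balanced design (missing cells raise; no imputation).
    """
    within = list(within)
    levels = {w: sorted(table[w].unique(), key=str) for w in within}
    subjects = sorted(table[subject].unique(), key=str)
    group_of: dict = {}
    for _, row in table.iterrows():
        g = row[between]
        s = row[subject]
        if s in group_of and group_of[s] != g:
            raise ValidationError(f"subject {s!r} appears in two groups")
        group_of[s] = g
    groups = sorted(set(group_of.values()), key=str)
    if len(groups) < 2:
        raise ValidationError("need >= 2 between-subject groups")
    sizes = [sum(1 for s in subjects if group_of[s] == g) for g in groups]
    if min(sizes) < 2:
        raise ValidationError("need >= 2 subjects per group")

    shape = (len(subjects),) + tuple(len(levels[w]) for w in within)
    Y = np.full(shape, np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    l_idx = [{v: i for i, v in enumerate(levels[w])} for w in within]
    for _, row in table.iterrows():
        pos = (s_idx[row[subject]],) + tuple(l_idx[j][row[w]]
                                             for j, w in enumerate(within))
        if not np.isnan(Y[pos]):
            raise ValidationError(f"duplicate cell for subject {row[subject]!r}")
        Y[pos] = row[dv]
    if np.isnan(Y).any():
        raise ValidationError("design has missing cells; no imputation is done")

    S = len(subjects)
    g_arr = np.array([groups.index(group_of[s]) for s in subjects])
    waxes = tuple(range(1, len(within) + 1))

    def mean_over(keep_axes: tuple[int, ...], per: str) -> np.ndarray:
        """Mean of Y broadcast back to full shape.

        keep_axes: within axes kept; ``per`` is 'all' (collapse subjects),
        'group' (mean within each subject's group) or 'subject'.
        """
        drop = tuple(a for a in waxes if a not in keep_axes)
        if per == "subject":
            m = Y.mean(axis=drop, keepdims=True) if drop else Y.copy()
            return np.broadcast_to(m, shape)
        if per == "group":
            out = np.empty(shape)
            for gi in range(len(groups)):
                sel = g_arr == gi
                m = Y[sel].mean(axis=(0,) + drop, keepdims=True)
                out[sel] = m
            return out
        m = Y.mean(axis=(0,) + drop, keepdims=True)
        return np.broadcast_to(m, shape)

    grand = Y.mean()
    effects: dict[str, AnovaEffect] = {}

    # between factor and its error
    comp_g = mean_over((), "group") - grand
    comp_sg = mean_over((), "subject") - mean_over((), "group")
    ss_g = float((comp_g ** 2).sum())
    ss_sg = float((comp_sg ** 2).sum())
    df_g = len(groups) - 1
    df_sg = S - len(groups)

    def pack(ss: float, df_num: int, ss_err: float, df_den: int) -> AnovaEffect:
        ms, ms_e = ss / df_num, ss_err / df_den
        F = ms / ms_e if ms_e > 0 else (0.0 if ss == 0 else math.inf)
        p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return AnovaEffect(F=float(F), df_num=df_num, df_den=df_den, p=p,
                           partial_eta_sq=float(eta), ss=ss, ss_error=ss_err)

    effects[between] = pack(ss_g, df_g, ss_sg, df_sg)

    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            T = tuple(a + 1 for a in combo)  # axes
            name = "*".join(within[i] for i in combo)
            df_t = int(np.prod([len(levels[within[i]]) - 1 for i in combo]))

            def ie_sum(per: str) -> np.ndarray:
                total = np.zeros(shape)
                for k in range(len(T) + 1):
                    for U in itertools.combinations(T, k):
                        sign = (-1) ** (len(T) - len(U))
                        total = total + sign * mean_over(U, per)
                return total

            comp_t = ie_sum("all")
            comp_tg = ie_sum("group") - ie_sum("all")
            comp_ts = ie_sum("subject") - ie_sum("group")
            ss_t = float((comp_t ** 2).sum())
            ss_tg = float((comp_tg ** 2).sum())
            ss_ts = float((comp_ts ** 2).sum())
            df_ts = df_t * (S - len(groups))
            effects[name] = pack(ss_t, df_t, ss_ts, df_ts)
            effects[f"{name}*{between}"] = pack(ss_tg, df_t * df_g, ss_ts, df_ts)

    return effects


def confidence_cell_means(ratings: Iterable[RatingRecord],
                          gold: Mapping[str, str]) -> pd.DataFrame:
    """Per-rater mean normality-call confidence in each
    report x normality x correctness cell.

    'normality' is the scan's true status; 'correctness' whether the
    rater's normal/abnormal call matched it.  Returns a long table ready
    for :func:`mixed_anova`; raises if any rater has an empty cell (a
    perfect rater has no 'incorrect' cells and cannot enter this ANOVA).
    """
    rows = []
    for rec in ratings:
        truth_abnormal = gold[rec.scan_id] in ("AD", "FTD")
        call_abnormal = rec.normality_call == "abnormal"
        rows.append({
            "rater": rec.rater_id, "experience": rec.experience,
            "report": rec.condition,
            "normality": "abnormal" if truth_abnormal else "normal",
            "correctness": "correct" if call_abnormal == truth_abnormal else "incorrect",
            "confidence": rec.confidence_normality,
        })
    df = pd.DataFrame(rows)
    cells = (df.groupby(["rater", "experience", "report", "normality", "correctness"])
               ["confidence"].mean().reset_index())
    expected = 8  # 2 x 2 x 2 within-cells per rater
    bad = [r for r, sub in cells.groupby("rater") if len(sub) != expected]
    if bad:
        raise ValidationError(f"raters with empty confidence cells: {bad}")
    return cells


def confidence_anova(ratings: Iterable[RatingRecord],
                     gold: Mapping[str, str]) -> dict[str, AnovaEffect]:
    """Four-factor mixed ANOVA on confidence:
    (report x normality x correctness) within, experience between."""
    cells = confidence_cell_means(ratings, gold)
    return mixed_anova(cells, dv="confidence", subject="rater",
                       between="experience",
                       within=["report", "normality", "correctness"])


# ---------------------------------------------------------------------------
# sample-size planning


def paired_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided paired t at effect size d with n pairs."""
    if n < 2:
        return 0.0
    ncp = d * math.sqrt(n)
    crit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(stats.nct.sf(crit, n - 1, ncp) + stats.nct.cdf(-crit, n - 1, ncp))


def paired_t_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                         method: str = "noncentral_t") -> int:
    """Smallest number of pairs (raters) achieving the target power.

    ``noncentral_t`` iterates n upward using exact noncentral-t power;
    ``normal`` is the closed form ceil((z_{1-a/2} + z_{power})^2 / d^2).
    """
    if not d > 0:
        raise ValidationError("effect size must be positive")
    if not (0 < alpha < 1 and 0.5 < power < 1):
        raise ValidationError("alpha in (0,1) and power in (0.5, 1) required")
    if method == "normal":
        za = stats.norm.ppf(1.0 - alpha / 2.0)
        zb = stats.norm.ppf(power)
        return math.ceil((za + zb) ** 2 / d ** 2)
    if method != "noncentral_t":
        raise QReportError(f"unknown method {method!r}")
    n = 2
    while paired_t_power(n, d, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise QReportError("sample size search did not converge")
    return n
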