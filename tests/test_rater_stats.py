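"""Signal-detection metrics, paired tests, agreement, reliability, ANOVA,
power — each against hand-computed values and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qreport.rater_stats as rs
from qreport.exceptions import ValidationError
from qreport.io import RatingRecord


def _record(rater, scan, condition, normality, diagnosis="none", conf=3):
    return RatingRecord(rater_id=rater, experience="consultant", scan_id=scan,
                        condition=condition, normality_call=normality,
                        diagnosis_call=diagnosis, confidence_normality=conf,
                        confidence_diagnosis=conf if diagnosis != "none" else None)


def _study_gold(n_control=15, n_ad=16, n_ftd=14):
    gold = {}
    for i in range(n_control):
        gold[f"c{i}"] = "control"
    for i in range(n_ad):
        gold[f"a{i}"] = "AD"
    for i in range(n_ftd):
        gold[f"f{i}"] = "FTD"
    return gold


class TestConfusionCounts:
    def test_all_abnormal_rater(self):
        gold = _study_gold()
        ratings = [_record("r", s, "with_report", "abnormal",
                           "AD" if g == "AD" else "FTD")
                   for s, g in gold.items()]
        c = rs.confusion_counts(ratings, gold, "volume_loss")[("r", "with_report")]
        assert (c.tp, c.fp, c.tn, c.fn) == (30, 15, 0, 0)

    def test_perfect_rater(self):
        gold = _study_gold()
        ratings = [_record("r", s, "with_report",
                           "abnormal" if g != "control" else "normal",
                           g if g != "control" else "none")
                   for s, g in gold.items()]
        c = rs.confusion_counts(ratings, gold, "volume_loss")[("r", "with_report")]
        assert (c.tp, c.tn, c.fp, c.fn) == (30, 15, 0, 0)
        triple = rs.metric_triple(c)
        assert (triple.sensitivity, triple.specificity, triple.accuracy) == \
            (100.0, 100.0, 100.0)

    def test_differential_task_restricts_scans(self):
        gold = _study_gold()
        ratings = [_record("r", s, "with_report", "abnormal", "AD")
                   for s in gold]
        c = rs.confusion_counts(ratings, gold, "AD_vs_normal")[("r", "with_report")]
        assert c.total == 16 + 15 == 31
        c = rs.confusion_counts(ratings, gold, "FTD_vs_normal")[("r", "with_report")]
        assert c.total == 14 + 15 == 29

    def test_strict_vs_abnormal_only_scoring(self):
        gold = {"a0": "AD", "c0": "control"}
        # abnormal call with the *wrong* sub-diagnosis
        ratings = [_record("r", "a0", "with_report", "abnormal", "FTD"),
                   _record("r", "c0", "with_report", "normal")]
        strict = rs.confusion_counts(ratings, gold, "AD_vs_normal",
                                     subdiagnosis="strict")[("r", "with_report")]
        loose = rs.confusion_counts(ratings, gold, "AD_vs_normal",
                                    subdiagnosis="abnormal_only")[("r", "with_report")]
        assert (strict.tp, strict.fn) == (0, 1)
        assert (loose.tp, loose.fn) == (1, 0)

    def test_scan_missing_from_gold_raises(self):
        with pytest.raises(ValidationError, match="gold"):
            rs.confusion_counts([_record("r", "x", "with_report", "normal")],
                                {"y": "control"}, "volume_loss")

    def test_counts_match_exhaustive_recount(self, rng):
        """Vectorised counting equals a naive per-episode recount."""
        gold = _study_gold()
        scans = list(gold)
        for _ in range(20):
            ratings = []
            for s in scans:
                abnormal = rng.random() < 0.5
                dx = rng.choice(["AD", "FTD"]) if abnormal else "none"
                ratings.append(_record("r", s, "with_report",
                                       "abnormal" if abnormal else "normal", dx))
            for task in rs.TASKS:
                c = rs.confusion_counts(ratings, gold, task)[("r", "with_report")]
                tp = tn = fp = fn = 0
                target = {"volume_loss": ("AD", "FTD"),
                          "AD_vs_normal": ("AD",),
                          "FTD_vs_normal": ("FTD",)}[task]
                for r in ratings:
                    g = gold[r.scan_id]
                    if task != "volume_loss" and g not in target + ("control",):
                        continue
                    truth = g in target
                    if task == "volume_loss":
                        call = r.normality_call == "abnormal"
                    else:
                        call = (r.normality_call == "abnormal"
                                and r.diagnosis_call == target[0])
                    tp += truth and call
                    fn += truth and not call
                    fp += (not truth) and call
                    tn += (not truth) and not call
                assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)


class TestMetricTriple:
    def test_printed_formulas(self):
        assert rs.metric_triple(rs.ConfusionCounts(tp=12, fn=4, tn=1, fp=1)
                                ).sensitivity == pytest.approx(75.0)
        t = rs.metric_triple(rs.ConfusionCounts(tp=9, tn=23, fp=4, fn=9))
        assert t.accuracy == pytest.approx(71.1, abs=0.05)  # 32/45

    def test_zero_denominator_flags_undefined(self):
        t = rs.metric_triple(rs.ConfusionCounts(tp=3, fn=1))
        assert t.specificity is None
        assert t.sensitivity == pytest.approx(75.0)


class TestAggregation:
    def test_combined_row_is_mean_of_group_means(self):
        assert rs.mean_of_group_means([68.9, 75.5, 70.0]) == pytest.approx(71.5, abs=0.05)
        assert rs.mean_of_group_means([80.0, 77.0, 80.0]) == pytest.approx(79.0)

    def test_single_group_combined_equals_group_mean(self):
        summary = rs.aggregate_group_metrics(
            {"a": 70.0, "b": 74.0}, {"a": "consultant", "b": "consultant"})
        assert summary.combined_mean == pytest.approx(72.0)

    def test_combined_sd_is_sd_over_all_raters(self, rng):
        vals = {f"r{i}": float(v) for i, v in enumerate(rng.normal(70, 8, 9))}
        exp = {f"r{i}": lvl for i, lvl in
               enumerate(["consultant"] * 3 + ["registrar"] * 3 + ["analyst"] * 3)}
        summary = rs.aggregate_group_metrics(vals, exp)
        assert summary.combined_sd == pytest.approx(
            np.std(list(vals.values()), ddof=1))


class TestMcNemar:
    def test_continuity_corrected_statistic(self):
        res = rs.mcnemar_test(5, 15, exact=False)
        assert res.statistic == pytest.approx(4.05)  # (10-1)^2/20

    def test_symmetric_counts_give_zero_uncorrected(self):
        res = rs.mcnemar_test(10, 10, exact=False, correction=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        res = rs.mcnemar_test(0, 8, exact=True)
        assert res.p == pytest.approx(2 * 0.5 ** 8, abs=1e-4)  # 0.0078

    def test_no_discordance_undefined(self):
        assert rs.mcnemar_test(0, 0).p is None

    def test_continuity_correction_shrinks_statistic(self, rng):
        for _ in range(50):
            b, c = rng.integers(0, 40, 2)
            if b + c == 0:
                continue
            cc = rs.mcnemar_test(int(b), int(c), exact=False).statistic
            raw = (b - c) ** 2 / (b + c)
            assert cc <= raw + 1e-12
            p = rs.mcnemar_test(int(b), int(c), exact=True).p
            assert 0.0 <= p <= 1.0


class TestPairedT:
    def test_consultant_row_effect_size(self):
        assert rs.cohens_d_from_summary(68.9, 5.0, 80.0, 10.0) == \
            pytest.approx(1.4, abs=0.05)

    def test_identical_vectors(self):
        res = rs.paired_t_and_d([70, 72, 68], [70, 72, 68])
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_hand_computed_differences(self):
        # diffs (5, 6, 6): mean 17/3, sd 1/sqrt(3) -> t = 17
        res = rs.paired_t_and_d([70, 72, 68], [75, 78, 74])
        assert res.t == pytest.approx(17.0)
        assert res.df == 2

    def test_zero_variance_nonzero_shift_is_infinite(self):
        res = rs.paired_t_and_d([70, 72, 68], [75, 77, 73])
        assert np.isinf(res.t) and res.t > 0 and res.p == 0.0

    def test_d_method_diff_uses_sd_of_differences(self):
        res = rs.paired_t_and_d([70, 72, 68], [75, 78, 74], d_method="diff")
        assert res.cohens_d == pytest.approx((17 / 3) / np.std([5, 6, 6], ddof=1))


class TestKappa:
    def test_perfect_agreement(self):
        assert rs.cohens_kappa(list("aabba"), list("aabba")).kappa == \
            pytest.approx(1.0)

    def test_2x2_hand_example(self):
        # agreement table a=20, b=5, c=10, d=10 over 45 items
        a = ["x"] * 20 + ["x"] * 5 + ["y"] * 10 + ["y"] * 10
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 10
        res = rs.cohens_kappa(a, b)
        assert res.p_o == pytest.approx(30 / 45)
        assert res.p_e == pytest.approx((25 * 30 + 20 * 15) / 45 ** 2)
        assert res.kappa == pytest.approx(0.308, abs=5e-4)

    def test_constant_identical_labels_undefined(self):
        assert rs.cohens_kappa(["a", "a"], ["a", "a"]).kappa is None

    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
                    min_size=2, max_size=60))
    def test_relabelling_invariance(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        relabel = {"a": "z", "b": "q", "c": "m"}
        k1 = rs.cohens_kappa(a, b).kappa
        k2 = rs.cohens_kappa([relabel[x] for x in a],
                             [relabel[x] for x in b]).kappa
        if k1 is None:
            assert k2 is None
        else:
            assert k2 == pytest.approx(k1, abs=1e-12)

    def test_kappa_one_only_for_perfect_agreement(self, rng):
        for _ in range(30):
            a = rng.integers(0, 2, 20).tolist()
            b = rng.integers(0, 2, 20).tolist()
            res = rs.cohens_kappa(a, b)
            if res.kappa is not None and res.kappa == pytest.approx(1.0):
                assert a == b


class TestReliability:
    def test_two_identical_raters(self):
        m = np.array([[1, 1], [0, 0], [1, 1], [0, 0], [1, 1]])
        assert rs.cronbach_alpha(m) == pytest.approx(1.0)
        icc = rs.icc_two_way_mixed(m)
        assert icc.icc_single == pytest.approx(1.0)
        assert icc.icc_average == pytest.approx(1.0)

    def test_uncorrelated_items_give_zero_alpha(self):
        m = np.array([[1, 1], [2, 1], [1, 2], [2, 2]], float)
        assert rs.cronbach_alpha(m) == pytest.approx(0.0)

    def test_icc_against_brute_force_mean_squares(self):
        m = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2]], float)
        # independent two-way ANOVA by explicit residuals
        n, k = m.shape
        grand = m.mean()
        rows = m.mean(axis=1, keepdims=True)
        cols = m.mean(axis=0, keepdims=True)
        resid = m - rows - cols + grand
        ms_rows = (k * ((rows - grand) ** 2).sum()) / (n - 1)
        ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
        expect_single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        expect_avg = (ms_rows - ms_err) / ms_rows
        icc = rs.icc_two_way_mixed(m)
        assert icc.icc_single == pytest.approx(expect_single, abs=1e-12)
        assert icc.icc_average == pytest.approx(expect_avg, abs=1e-12)

    def test_alpha_equals_icc3k_identity(self, rng):
        for _ in range(25):
            m = rng.integers(0, 2, size=(12, 5)).astype(float)
            alpha = rs.cronbach_alpha(m)
            icc = rs.icc_two_way_mixed(m)
            if alpha is None or icc.icc_average is None:
                continue
            assert alpha == pytest.approx(icc.icc_average, abs=1e-10)

    def test_average_at_least_single_when_rows_dominate(self, rng):
        for _ in range(20):
            m = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1)) * 2
            icc = rs.icc_two_way_mixed(m)
            if icc.icc_single is not None and icc.ms_rows > icc.ms_error:
                assert icc.icc_average >= icc.icc_single


def _anova_table(rng, effect=None):
    """Balanced 9-subject (3 per experience group) 2x2x2 within table."""
    rows = []
    groups = ["consultant", "registrar", "analyst"]
    for si in range(9):
        g = groups[si // 3]
        base = rng.normal(3.0, 0.3)
        for rep, norm, corr in itertools.product(
                ["without_report", "with_report"], ["normal", "abnormal"],
                ["correct", "incorrect"]):
            y = base + rng.normal(0, 0.2)
            if effect == "report" and rep == "with_report":
                y += 1.0
            rows.append(dict(rater=f"s{si}", experience=g, report=rep,
                             normality=norm, correctness=corr, confidence=y))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_table_gives_zero_f(self):
        rng = np.random.default_rng(0)
        df = _anova_table(rng)
        df["confidence"] = 3.0
        effects = rs.mixed_anova(df, "confidence", "rater", "experience",
                                 ["report", "normality", "correctness"])
        for eff in effects.values():
            assert eff.F == pytest.approx(0.0)

    def test_doubling_leaves_f_and_eta_unchanged(self):
        rng = np.random.default_rng(1)
        df = _anova_table(rng, effect="report")
        e1 = rs.mixed_anova(df, "confidence", "rater", "experience",
                            ["report", "normality", "correctness"])
        df2 = df.assign(confidence=df.confidence * 2)
        e2 = rs.mixed_anova(df2, "confidence", "rater", "experience",
                            ["report", "normality", "correctness"])
        for k in e1:
            assert e2[k].F == pytest.approx(e1[k].F, rel=1e-9)
            assert e2[k].partial_eta_sq == pytest.approx(
                e1[k].partial_eta_sq, rel=1e-9)

    def test_missing_cell_raises(self):
        rng = np.random.default_rng(2)
        df = _anova_table(rng).iloc[:-1]
        with pytest.raises(ValidationError, match="missing"):
            rs.mixed_anova(df, "confidence", "rater", "experience",
                           ["report", "normality", "correctness"])

    def test_report_effect_dominates_when_constructed(self):
        rng = np.random.default_rng(3)
        df = _anova_table(rng, effect="report")
        effects = rs.mixed_anova(df, "confidence", "rater", "experience",
                                 ["report", "normality", "correctness"])
        assert effects["report"].p < 0.001
        assert effects["report"].df_num == 1
        assert effects["report"].df_den == 6
        # all other within effects stay modest
        for name, eff in effects.items():
            if name not in ("report", "experience"):
                assert eff.F < effects["report"].F


class TestSampleSize:
    def test_normal_approximation_closed_form(self):
        assert rs.paired_t_sample_size(0.53, method="normal") == 28

    def test_noncentral_t_iteration(self):
        assert rs.paired_t_sample_size(0.8) == 15

    def test_monotone_in_effect_size(self):
        sizes = [rs.paired_t_sample_size(d) for d in (0.3, 0.5, 0.8, 1.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_nct_never_far_below_normal_approx(self):
        for d in (0.3, 0.5, 0.8, 1.0):
            for power in (0.8, 0.9):
                nct = rs.paired_t_sample_size(d, power=power)
                norm = rs.paired_t_sample_size(d, power=power, method="normal")
                assert nct >= norm - 1

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValidationError):
            rs.paired_t_sample_size(-0.2)
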