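"""Normative model: fitting, percentiles, BPF, QC."""

import json

import numpy as np
import pytest
from scipy import stats

import qreport as q
from qreport.exceptions import (DegenerateDesignError, DegenerateVarianceError,
                                ValidationError)
from qreport.io import SubjectVolumes
from qreport.normative import (GM_KEY, WM_KEY, bpf_percentile_curves, zscore)
from qreport.synthetic import CohortSpec, GroupSpec, RegionModel


def _single_region_cohort(n=461, seed=5, beta=(200.0, -0.5, 10.0, 0.05), sigma=8.0):
    spec = CohortSpec(
        groups=[GroupSpec("control", n, 70.09, 12.05, 0.514)],
        region_models={"roi": RegionModel(*beta, sigma)})
    return q.simulate_normative_population(spec, seed=seed), beta, sigma


def _subject_at_z(model, region, z, age=70.0, sex="female", tiv=1400.0):
    fit = model.regions[region]
    x = np.array([1.0, age, 0.0 if sex == "female" else 1.0, tiv])
    v = float(fit.beta @ x + z * fit.sigma)
    extra = {region: v} if region not in (GM_KEY, WM_KEY) else {}
    vols = {GM_KEY: 600.0, WM_KEY: 480.0, **extra}
    return SubjectVolumes("probe", age, sex, tiv, vols)


class TestFit:
    def test_known_coefficients_recovered_within_3se(self):
        cohort, beta, sigma = _single_region_cohort()
        model = q.fit_normative_model(cohort)
        fit = model.regions["roi"]
        X = np.column_stack([np.ones(len(cohort)),
                             [s.age for s in cohort],
                             [0.0 if s.sex == "female" else 1.0 for s in cohort],
                             [s.tiv for s in cohort]])
        se = fit.sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        z = (fit.beta - np.asarray(beta)) / se
        assert np.all(np.abs(z) < 3.0)
        assert fit.sigma == pytest.approx(sigma, rel=0.10)

    def test_metadata_records_reference_size(self, model):
        assert model.n_reference == 461
        lo, hi = model.age_range
        assert 30.0 <= lo < hi <= 95.0

    def test_constant_volumes_raise_degenerate_variance(self):
        cohort, *_ = _single_region_cohort(n=60)
        for s in cohort:
            s.volumes["roi"] = 100.0
        with pytest.raises(DegenerateVarianceError):
            q.fit_normative_model(cohort)

    def test_constant_age_raises_degenerate_design(self):
        cohort, *_ = _single_region_cohort(n=60)
        for s in cohort:
            s.age = 70.0
        with pytest.raises(DegenerateDesignError):
            q.fit_normative_model(cohort)

    def test_single_sex_rejected(self):
        cohort, *_ = _single_region_cohort(n=60)
        for s in cohort:
            s.sex = "female"
        with pytest.raises(DegenerateDesignError, match="sexes"):
            q.fit_normative_model(cohort)

    def test_too_small_reference_rejected(self):
        cohort, *_ = _single_region_cohort(n=10)
        with pytest.raises(ValidationError, match="too small"):
            q.fit_normative_model(cohort)


class TestPercentile:
    def test_volume_at_predicted_mean_is_50th(self, model):
        subj = _subject_at_z(model, "hippocampus_left", 0.0)
        assert q.percentile(model, subj, "hippocampus_left") == pytest.approx(50.0)
        assert q.percentile(model, subj, "hippocampus_left",
                            variant="logistic_approx") == pytest.approx(50.0)

    def test_standard_normal_quantile(self, model):
        subj = _subject_at_z(model, "hippocampus_left", -1.6449)
        assert q.percentile(model, subj, "hippocampus_left") == \
            pytest.approx(5.0, abs=0.01)

    def test_unknown_region_is_key_error(self, model):
        subj = _subject_at_z(model, "hippocampus_left", 0.0)
        with pytest.raises(KeyError):
            q.percentile(model, subj, "no_such_region")

    def test_strictly_increasing_in_volume(self, model):
        region = "temporal_lobe_left"
        pcts = [q.percentile(model, _subject_at_z(model, region, z), region)
                for z in np.linspace(-3.5, 3.5, 41)]
        assert np.all(np.diff(pcts) > 0)

    def test_covariate_perturbation_moves_percentile_as_signed(self, model):
        # beta_age < 0 in the generator: an older subject with the same
        # volume is *less* atrophic relative to peers -> higher percentile.
        region = "hippocampus_left"
        young = _subject_at_z(model, region, 0.0, age=60.0)
        old = SubjectVolumes("probe2", 80.0, young.sex, young.tiv,
                             dict(young.volumes))
        assert model.regions[region].beta[1] < 0
        assert q.percentile(model, old, region) > q.percentile(model, young, region)

    def test_gaussian_and_logistic_agree_within_2_points(self, model):
        region = "hippocampus_left"
        for z in np.linspace(-3.0, 3.0, 25):
            subj = _subject_at_z(model, region, z)
            g = q.percentile(model, subj, region, variant="gaussian")
            l = q.percentile(model, subj, region, variant="logistic_approx")
            assert abs(g - l) < 2.0

    def test_display_clipping(self, model):
        subj = _subject_at_z(model, "hippocampus_left", -8.0)
        assert q.percentile(model, subj, "hippocampus_left") == 0.01

    def test_generalised_logistic_close_to_gaussian_on_gaussian_residuals(
            self, normative_cohort):
        model = q.fit_normative_model(normative_cohort,
                                      cdf_variant="generalised_logistic")
        region = "hippocampus_left"
        for z in np.linspace(-2.0, 2.0, 17):
            subj = _subject_at_z(model, region, z)
            g = 100.0 * stats.norm.cdf(z)
            assert q.percentile(model, subj, region) == pytest.approx(g, abs=5.0)

    def test_residual_percentiles_uncorrelated_with_covariates(self):
        spec = q.default_normative_spec(n=2000)
        cohort = q.simulate_normative_population(spec, seed=23)
        model = q.fit_normative_model(cohort)
        for region in ("hippocampus_left", "frontal_lobe_right", GM_KEY):
            pcts = np.array([q.percentile(model, s, region) for s in cohort])
            for cov in (np.array([s.age for s in cohort]),
                        np.array([0.0 if s.sex == "female" else 1.0
                                  for s in cohort]),
                        np.array([s.tiv for s in cohort])):
                rho = stats.spearmanr(pcts, cov).statistic
                assert abs(rho) < 0.05


class TestBPF:
    def test_bpf_arithmetic(self):
        subj = SubjectVolumes("a", 70, "female", 1375.0,
                              {GM_KEY: 600.0, WM_KEY: 500.0})
        assert q.brain_parenchymal_fraction(subj) == pytest.approx(0.8)

    def test_parenchyma_cannot_reach_tiv(self):
        subj = SubjectVolumes("a", 70, "female", 1100.0,
                              {GM_KEY: 600.0, WM_KEY: 500.0})
        with pytest.raises(ValidationError, match="TIV"):
            q.brain_parenchymal_fraction(subj)

    def test_subject_at_normative_median_lands_at_50th(self, model):
        fit = model.bpf_fit
        age = 70.0
        target = fit.beta[0] + fit.beta[1] * age  # predicted median BPF
        tiv = 1400.0
        gm = 0.55 * target * tiv
        subj = SubjectVolumes("a", age, "female", tiv,
                              {GM_KEY: gm, WM_KEY: target * tiv - gm})
        assert q.bpf_percentile(model, subj) == pytest.approx(50.0, abs=2.0)

    def test_curves_are_ordered_and_cover_age_range(self, model):
        curves = bpf_percentile_curves(model)
        ages = [a for a, _ in curves[50.0]]
        assert ages[0] == pytest.approx(model.age_range[0])
        assert ages[-1] == pytest.approx(model.age_range[1])
        for lo, hi in zip((5, 25, 50, 75), (25, 50, 75, 95)):
            assert all(v_lo < v_hi for (_, v_lo), (_, v_hi)
                       in zip(curves[float(lo)], curves[float(hi)]))


class TestQC:
    def test_snr_cnr_formulas(self):
        qc = q.qc_metrics(mean_gm=120.0, mean_wm=180.0, sd_background=10.0)
        assert qc == {"snr": 18.0, "cnr": 6.0}
        assert q.qc_metrics(200.0, 200.0, 10.0)["cnr"] == 0.0
        assert q.qc_metrics(120.0, 200.0, 10.0)["snr"] == 20.0

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValidationError):
            q.qc_metrics(120.0, 180.0, 0.0)


class TestSerialisation:
    def test_json_roundtrip_preserves_percentiles(self, model, test_cohort):
        back = q.NormativeModel.from_json(model.to_json())
        subj = test_cohort[0]
        for region in list(model.regions)[:4]:
            assert q.percentile(back, subj, region) == \
                q.percentile(model, subj, region)
        assert back.n_reference == model.n_reference
        assert json.loads(model.to_json())["cdf_variant"] == "gaussian"
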