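"""Normative volumetric model: covariate regression + residual percentiles.

Healthy-control regional volumes are regressed on age, sex and total
intracranial volume (one joint OLS per region); the residual distribution
then converts a patient's volume into a percentile of the dementia-free
population.  Three interchangeable CDFs map the standardised residual
z = (v - beta.x) / sigma to a percentile:

``gaussian``
    100 * Phi(z) — the default.
``logistic_approx``
    100 / (1 + exp(-1.702 z)); the classic logistic approximation to the
    normal ogive (max deviation < 0.01 in probability).
``generalised_logistic``
    100 * (1 + Q exp(-B z))^(-1/nu), a Richards curve whose shape
    parameters (B, nu, Q) are fitted by least squares to the empirical CDF
    of the reference residuals, allowing mild asymmetry.

Sex is coded 0 = female, 1 = male throughout.

The module also computes brain parenchymal fraction, BPF = (GM + WM)/TIV,
with its own age-only normative fit (TIV sits in the BPF denominator, so
regressing BPF on TIV as well would adjust a ratio for its own
denominator), and scan-quality metrics SNR and CNR.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (DegenerateDesignError, DegenerateVarianceError,
                         QReportError, ValidationError)
from .io import RegionMap, SubjectVolumes

CDF_VARIANTS = ("gaussian", "logistic_approx", "generalised_logistic")

#: Percentiles are clipped to this display range so a log-radial axis
#: stays finite.
CLIP_RANGE = (0.01, 99.99)

GM_KEY = "total_gm"
WM_KEY = "total_wm"

_SEX_CODE = {"female": 0.0, "male": 1.0}


@dataclass
class RegionFit:
    """OLS fit for one region: beta = (intercept, age, sex, tiv), sigma."""
    beta: np.ndarray
    sigma: float


@dataclass
class BPFFit:
    """Age-only normative fit for brain parenchymal fraction."""
    beta: np.ndarray  # (intercept, slope_age)
    sigma: float


@dataclass
class NormativeModel:
    """Per-region covariate regressions plus a residual-CDF variant.

    ``glf_params`` holds the Richards-curve shape (B, nu, Q) shared across
    regions; it is fitted only for the ``generalised_logistic`` variant.
    """

    regions: dict[str, RegionFit]
    cdf_variant: str = "gaussian"
    glf_params: tuple[float, float, float] | None = None
    bpf_fit: BPFFit | None = None
    n_reference: int = 0
    age_range: tuple[float, float] = (0.0, 0.0)
    fit_date: str = ""

    def region_names(self) -> list[str]:
        return list(self.regions)

    # -- serialisation -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "cdf_variant": self.cdf_variant,
            "glf_params": list(self.glf_params) if self.glf_params else None,
            "n_reference": self.n_reference,
            "age_range": list(self.age_range),
            "fit_date": self.fit_date,
            "regions": {name: {"beta": fit.beta.tolist(), "sigma": fit.sigma}
                        for name, fit in self.regions.items()},
            "bpf": ({"beta": self.bpf_fit.beta.tolist(), "sigma": self.bpf_fit.sigma}
                    if self.bpf_fit else None),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        p = json.loads(text)
        return cls(
            regions={name: RegionFit(np.asarray(d["beta"], float), float(d["sigma"]))
                     for name, d in p["regions"].items()},
            cdf_variant=p["cdf_variant"],
            glf_params=tuple(p["glf_params"]) if p.get("glf_params") else None,
            bpf_fit=(BPFFit(np.asarray(p["bpf"]["beta"], float), float(p["bpf"]["sigma"]))
                     if p.get("bpf") else None),
            n_reference=int(p["n_reference"]),
            age_range=tuple(p["age_range"]),
            fit_date=p.get("fit_date", ""),
        )


def _design(subjects: Sequence[SubjectVolumes]) -> np.ndarray:
    return np.column_stack([
        np.ones(len(subjects)),
        [s.age for s in subjects],
        [_SEX_CODE[s.sex] for s in subjects],
        [s.tiv for s in subjects],
    ])


def _glf_cdf(z: np.ndarray, B: float, nu: float, Q: float) -> np.ndarray:
    return (1.0 + Q * np.exp(-B * z)) ** (-1.0 / nu)


def fit_normative_model(reference: Sequence[SubjectVolumes],
                        cdf_variant: str = "gaussian") -> NormativeModel:
    """Fit the normative model on a healthy reference population.

    One OLS of volume on (1, age, sex, tiv) per region; sigma is the
    residual standard deviation with denominator n - 4.  For the
    ``generalised_logistic`` variant the Richards shape parameters are
    fitted to the pooled empirical CDF of standardised residuals.

    Requires n >= 30, a common region set, and both sexes present.
    """
    if cdf_variant not in CDF_VARIANTS:
        raise QReportError(f"unknown cdf variant {cdf_variant!r}")
    n = len(reference)
    if n < 30:
        raise ValidationError(f"reference population too small (n={n}, need >= 30)")
    region_set = reference[0].regions
    for s in reference:
        if s.regions != region_set:
            raise ValidationError(f"subject {s.subject_id}: region set differs from reference")
    sexes = {s.sex for s in reference}
    if sexes != {"male", "female"}:
        raise DegenerateDesignError("reference must contain both sexes")

    X = _design(reference)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient "
                                    "(constant age, sex or TIV?)")

    regions: dict[str, RegionFit] = {}
    pooled_z: list[np.ndarray] = []
    for region in region_set:
        y = np.array([s.volumes[region] for s in reference])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        sigma = np.sqrt(rss / (n - X.shape[1]))
        if sigma <= 1e-12 * max(1.0, float(np.abs(y).max())):
            raise DegenerateVarianceError(f"region {region!r} has zero residual variance")
        regions[region] = RegionFit(beta=beta, sigma=float(sigma))
        pooled_z.append(resid / sigma)

    glf = None
    if cdf_variant == "generalised_logistic":
        z = np.sort(np.concatenate(pooled_z))
        ecdf = (np.arange(1, z.size + 1) - 0.5) / z.size
        popt, _ = optimize.curve_fit(
            _glf_cdf, z, ecdf, p0=(1.702, 1.0, 1.0),
            bounds=((1e-3, 1e-3, 1e-3), (20.0, 20.0, 20.0)), maxfev=20000)
        glf = tuple(float(v) for v in popt)

    bpf_fit = None
    if GM_KEY in region_set and WM_KEY in region_set:
        bpf = np.array([brain_parenchymal_fraction(s) for s in reference])
        Xa = X[:, :2]  # intercept + age only
        beta_b, *_ = np.linalg.lstsq(Xa, bpf, rcond=None)
        resid_b = bpf - Xa @ beta_b
        sigma_b = float(np.sqrt(resid_b @ resid_b / (n - 2)))
        if sigma_b <= 0:
            raise DegenerateVarianceError("BPF has zero residual variance")
        bpf_fit = BPFFit(beta=beta_b, sigma=sigma_b)

    ages = [s.age for s in reference]
    return NormativeModel(
        regions=regions, cdf_variant=cdf_variant, glf_params=glf, bpf_fit=bpf_fit,
        n_reference=n, age_range=(float(min(ages)), float(max(ages))),
        fit_date=_dt.date.today().isoformat(),
    )


def _z_to_percentile(z: float | np.ndarray, variant: str,
                     glf_params: tuple[float, float, float] | None) -> np.ndarray:
    z = np.asarray(z, float)
    if variant == "gaussian":
        p = 100.0 * stats.norm.cdf(z)
    elif variant == "logistic_approx":
        p = 100.0 / (1.0 + np.exp(-1.702 * z))
    elif variant == "generalised_logistic":
        if glf_params is None:
            raise QReportError("model has no fitted generalised-logistic parameters")
        p = 100.0 * _glf_cdf(z, *glf_params)
    else:
        raise QReportError(f"unknown cdf variant {variant!r}")
    return np.clip(p, *CLIP_RANGE)


def zscore(model: NormativeModel, subject: SubjectVolumes, region: str) -> float:
    """Covariate-adjusted standardised residual for one region."""
    if region not in model.regions:
        raise KeyError(f"region {region!r} not in normative model")
    fit = model.regions[region]
    if fit.sigma <= 0:
        raise DegenerateVarianceError(f"region {region!r}: sigma must be positive")
    x = np.array([1.0, subject.age, _SEX_CODE[subject.sex], subject.tiv])
    return float((subject.volumes[region] - fit.beta @ x) / fit.sigma)


def percentile(model: NormativeModel, subject: SubjectVolumes, region: str,
               variant: str | None = None) -> float:
    """Subject's volume percentile for one region, clipped to [0.01, 99.99]."""
    z = zscore(model, subject, region)
    return float(_z_to_percentile(z, variant or model.cdf_variant, model.glf_params))


def brain_parenchymal_fraction(subject: SubjectVolumes,
                               gm_key: str = GM_KEY, wm_key: str = WM_KEY) -> float:
    """BPF = (grey matter + white matter) / TIV, a global atrophy index."""
    for key in (gm_key, wm_key):
        if key not in subject.volumes:
            raise ValidationError(f"subject {subject.subject_id}: missing {key!r} volume")
    parenchyma = subject.volumes[gm_key] + subject.volumes[wm_key]
    if parenchyma >= subject.tiv:
        raise ValidationError(
            f"subject {subject.subject_id}: parenchyma {parenchyma} >= TIV {subject.tiv}")
    return parenchyma / subject.tiv


def bpf_percentile(model: NormativeModel, subject: SubjectVolumes) -> float:
    """Percentile of the subject's BPF under the age-only normative fit."""
    if model.bpf_fit is None:
        raise QReportError("model was fitted without total GM/WM; no BPF reference")
    fit = model.bpf_fit
    bpf = brain_parenchymal_fraction(subject)
    z = (bpf - (fit.beta[0] + fit.beta[1] * subject.age)) / fit.sigma
    return float(_z_to_percentile(z, model.cdf_variant, model.glf_params))


def bpf_percentile_curves(model: NormativeModel,
                          percentiles: Sequence[float] = (5, 25, 50, 75, 95),
                          ages: Sequence[float] | None = None,
                          ) -> dict[float, list[tuple[float, float]]]:
    """Normative BPF-vs-age curves at the given population percentiles.

    Under the Gaussian residual model the p-th percentile curve is
    mean(age) + z_p * sigma.  Used for the report's BPF panel.
    """
    if model.bpf_fit is None:
        raise QReportError("model was fitted without total GM/WM; no BPF reference")
    if ages is None:
        lo, hi = model.age_range
        ages = np.linspace(lo, hi, 25)
    fit = model.bpf_fit
    curves: dict[float, list[tuple[float, float]]] = {}
    for p in percentiles:
        zp = stats.norm.ppf(p / 100.0)
        curves[float(p)] = [
            (float(a), float(fit.beta[0] + fit.beta[1] * a + zp * fit.sigma))
            for a in np.asarray(ages, float)]
    return curves


def qc_metrics(mean_gm: float, mean_wm: float, sd_background: float) -> dict[str, float]:
    """Scan-quality metrics from tissue signal statistics.

    snr = mean WM signal / background SD; cnr = |WM - GM| / background SD.
    """
    if sd_background <= 0:
        raise ValidationError(f"background SD must be positive, got {sd_background}")
    return {"snr": mean_wm / sd_background,
            "cnr": abs(mean_wm - mean_gm) / sd_background}


@dataclass
class QReportBundle:
    """Everything needed to render one subject's report.

    ``rose`` is filled in by :func:`qreport.report.build_rose_geometry`;
    ``bpf_curves`` carries the normative BPF-vs-age percentile curves so
    rendering never needs the model itself.
    """

    subject: SubjectVolumes
    percentiles: dict[str, float]
    hippocampus_left: float | None
    hippocampus_right: float | None
    bpf: float
    bpf_percentile: float
    bpf_curves: dict[float, list[tuple[float, float]]]
    qc: dict[str, float] | None
    rose: "object" = None  # RosePlotGeometry; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        for region, p in self.percentiles.items():
            if not (0.0 < p < 100.0):
                raise ValidationError(f"percentile {p} for {region!r} outside (0, 100)")
        if not (0.0 < self.bpf < 1.0):
            raise ValidationError(f"BPF {self.bpf} outside (0, 1)")


def build_bundle(model: NormativeModel, subject: SubjectVolumes,
                 region_map: RegionMap,
                 signal_stats: Mapping[str, float] | None = None) -> QReportBundle:
    """Compute all derived quantities for one subject's report."""
    from . import report as _report  # local import: report depends on nothing here

    missing = [r for r in region_map.regions if r not in model.regions]
    if missing:
        raise KeyError(f"regions missing from normative model: {missing}")
    pcts = {r: percentile(model, subject, r) for r in region_map.regions}
    hippo_l = pcts.get("hippocampus_left")
    hippo_r = pcts.get("hippocampus_right")
    qc = None
    if signal_stats is not None:
        qc = qc_metrics(signal_stats["mean_gm"], signal_stats["mean_wm"],
                        signal_stats["sd_background"])
    bundle = QReportBundle(
        subject=subject,
        percentiles=pcts,
        hippocampus_left=hippo_l,
        hippocampus_right=hippo_r,
        bpf=brain_parenchymal_fraction(subject),
        bpf_percentile=bpf_percentile(model, subject),
        bpf_curves=bpf_percentile_curves(model),
        qc=qc,
    )
    bundle.rose = _report.build_rose_geometry(pcts, region_map)
    return bundle
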