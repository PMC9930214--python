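"""Synthetic patient-level cohort generator.

The original study analysed 410 real patients (210 bypass-surgery, 200
stent-angioplasty) from Shiraz hospitals; no patient-level data are
deposited.  This module generates cohorts with the same *marginal* structure
as the study's descriptive tables, so the costing and questionnaire-scoring
stages run end-to-end without external data:

* age: truncated normal (>= 18 years) at the arm's mean/SD;
* length of stay: gamma with the arm's mean/SD, truncated at half a day,
  with the scale recalibrated so the truncated mean still hits the target;
* billing categories (hospitalization, medication, travel/hotel): gamma
  around the arm's per-capita target (hospital billing is right-skewed and
  nonnegative, hence gamma rather than normal marginals);
* lost productivity: *derived* from length of stay through the wage formula
  (days x 311 / 26), never drawn independently;
* questionnaire dimensions: logit-normal on [0, 100], calibrated so the
  post-minus-pre summary difference centers on the arm's utility target;
* sex / diabetes / hypertension: Bernoulli at the reported shares
  (descriptive payload only; they drive no cost or utility).

Generation is fully determined by (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from . import costing
from .effectiveness import DIMENSIONS, QuestionnaireScore, score_instrument, to_utility
from .parameters import Arm, Instrument

MIN_AGE_YEARS = 18.0
MIN_LOS_DAYS = 0.5


@dataclass(frozen=True)
class ArmCohortSpec:
    """Marginal targets for one arm's synthetic patients."""

    n: int
    age_mean: float
    age_sd: float
    los_mean: float
    los_sd: float
    hospitalization_pc: float          # per-capita targets, USD
    medication_pc: float
    travel_hotel_pc: float
    female_share: float = 0.37
    diabetes_share: float = 0.25
    hypertension_share: float = 0.30
    utility_gain: dict[Instrument, float] = field(default_factory=dict)
    bill_cv: float = 0.5               # coefficient of variation of bills
    pre_summary_mean: float = 50.0     # questionnaire summary before treatment
    dimension_sd_logit: float = 0.6    # per-dimension spread on the logit scale

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("age_sd", "los_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.los_mean < MIN_LOS_DAYS:
            raise ValueError(f"los_mean must be >= {MIN_LOS_DAYS}")
        for name in ("hospitalization_pc", "medication_pc", "travel_hotel_pc"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
            if v == 0 and self.bill_cv > 0:
                raise ValueError(f"{name}: zero mean with positive spread is infeasible")
        if not 0 < self.pre_summary_mean < 100:
            raise ValueError("pre_summary_mean must lie strictly inside (0, 100)")
        for inst, gain in self.utility_gain.items():
            post = self.pre_summary_mean + 100.0 * gain
            if not 0 < post < 100:
                raise ValueError(f"{inst}: post-treatment summary target {post} "
                                 "falls outside (0, 100)")


@dataclass(frozen=True)
class CohortSpec:
    cabg: ArmCohortSpec
    pci: ArmCohortSpec

    def arm(self, arm: Arm) -> ArmCohortSpec:
        return self.cabg if arm is Arm.CABG else self.pci

    def validate(self) -> None:
        self.cabg.validate()
        self.pci.validate()


def default_cohort_spec(n_cabg: int | None = None, n_pci: int | None = None) -> CohortSpec:
    """The study conditions: arm sizes, demographics and length of stay from
    the descriptive tables, per-capita billing targets from the cost ledger,
    and utility-gain targets equal to the stable-state utilities."""
    doc = yaml.safe_load(
        resources.files("cardiocea.data").joinpath("reported.yaml").read_text())
    ledger = doc["cost_ledger"]
    summary = doc["cohort_summary"]
    gains = {  # stable-state utility per (instrument, arm)
        Arm.CABG: {Instrument.SAQ: 0.135, Instrument.SF36: 0.100},
        Arm.PCI: {Instrument.SAQ: 0.063, Instrument.SF36: 0.063},
    }
    arms = {}
    for arm in Arm:
        led, summ = ledger[arm.value], summary[arm.value]
        n_led = led["n"]
        arms[arm] = ArmCohortSpec(
            n=summ["n"],
            age_mean=summ["age_mean"], age_sd=summ["age_sd"],
            los_mean=summ["los_mean"], los_sd=summ["los_sd"],
            hospitalization_pc=led["hospitalization"] / n_led,
            medication_pc=led["medication"] / n_led,
            travel_hotel_pc=led["travel_hotel"] / n_led,
            female_share=summ["female_share"],
            diabetes_share=summ["diabetes_share"],
            hypertension_share=summ["hypertension_share"],
            utility_gain=gains[arm],
        )
    if n_cabg is not None:
        arms[Arm.CABG] = replace(arms[Arm.CABG], n=n_cabg)
    if n_pci is not None:
        arms[Arm.PCI] = replace(arms[Arm.PCI], n=n_pci)
    return CohortSpec(cabg=arms[Arm.CABG], pci=arms[Arm.PCI])


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic subject, consumable by the costing and scoring stages."""

    id: str
    arm: Arm
    age: float
    female: bool
    diabetes: bool
    hypertension: bool
    los_days: float
    hospitalization: float
    medication: float
    travel_hotel: float
    lost_productivity: float
    pre_scores: dict[Instrument, QuestionnaireScore]
    post_scores: dict[Instrument, QuestionnaireScore]


# ---------------------------------------------------------------------------
# samplers


def _truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, max(mean, lower))
    alpha = (lower - mean) / sd
    u = rng.uniform(stats.norm.cdf(alpha), 1.0, size=size)
    return mean + sd * stats.norm.ppf(u)


def _gamma_by_moments(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)


def _truncated_gamma(rng, mean, sd, lower, size):
    """Gamma truncated at ``lower``, scale recalibrated so the truncated
    mean equals ``mean`` (shape kept at the untruncated moment match)."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    shape = (mean / sd) ** 2
    theta0 = sd * sd / mean

    def truncated_mean(theta):
        den = stats.gamma.sf(lower, shape, scale=theta)
        if den <= 0 or not np.isfinite(den):
            return lower  # theta -> 0 limit: conditional mean collapses to the bound
        num = stats.gamma.sf(lower, shape + 1, scale=theta)
        return shape * theta * num / den

    theta = optimize.brentq(lambda t: truncated_mean(t) - mean,
                            1e-9, 2.0 * theta0, xtol=1e-12)
    u = rng.uniform(stats.gamma.cdf(lower, shape, scale=theta), 1.0, size=size)
    return stats.gamma.ppf(u, shape, scale=theta)


@lru_cache(maxsize=256)
def _logit_normal_mu(target: float, sd: float) -> float:
    """Location of a logit-normal whose mean on (0, 1) equals ``target``
    (Gauss-Hermite quadrature + root finding)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(40)
    weights = weights / weights.sum()

    def mean_at(mu):
        return float(weights @ special.expit(mu + sd * nodes))

    return optimize.brentq(lambda mu: mean_at(mu) - target, -30.0, 30.0, xtol=1e-12)


def _dimension_scores(rng, summary_target: float, sd_logit: float,
                      n_patients: int, n_dims: int) -> np.ndarray:
    """(n_patients, n_dims) scores on [0, 100] whose expected summary is
    ``summary_target``."""
    if sd_logit == 0:
        return np.full((n_patients, n_dims), summary_target)
    mu = _logit_normal_mu(summary_target / 100.0, sd_logit)
    z = rng.standard_normal((n_patients, n_dims))
    return 100.0 * special.expit(mu + sd_logit * z)


# ---------------------------------------------------------------------------
# generation


def _generate_arm(spec: ArmCohortSpec, arm: Arm, rng: np.random.Generator,
                  wage: costing.WageModel) -> list[PatientRecord]:
    n = spec.n
    ages = _truncated_normal(rng, spec.age_mean, spec.age_sd, MIN_AGE_YEARS, n)
    los = _truncated_gamma(rng, spec.los_mean, spec.los_sd, MIN_LOS_DAYS, n)
    female = rng.random(n) < spec.female_share
    diabetes = rng.random(n) < spec.diabetes_share
    hypertension = rng.random(n) < spec.hypertension_share
    bills = {
        "hospitalization": _gamma_by_moments(
            rng, spec.hospitalization_pc, spec.bill_cv * spec.hospitalization_pc, n),
        "medication": _gamma_by_moments(
            rng, spec.medication_pc, spec.bill_cv * spec.medication_pc, n),
        "travel_hotel": _gamma_by_moments(
            rng, spec.travel_hotel_pc, spec.bill_cv * spec.travel_hotel_pc, n),
    }
    scores: dict[str, dict[Instrument, np.ndarray]] = {"pre": {}, "post": {}}
    for inst, gain in spec.utility_gain.items():
        inst = Instrument(inst)
        n_dims = len(DIMENSIONS[inst])
        scores["pre"][inst] = _dimension_scores(
            rng, spec.pre_summary_mean, spec.dimension_sd_logit, n, n_dims)
        scores["post"][inst] = _dimension_scores(
            rng, spec.pre_summary_mean + 100.0 * gain, spec.dimension_sd_logit,
            n, n_dims)

    records = []
    for i in range(n):
        pre = {inst: score_instrument(inst, arr[i]) for inst, arr in scores["pre"].items()}
        post = {inst: score_instrument(inst, arr[i]) for inst, arr in scores["post"].items()}
        records.append(PatientRecord(
            id=f"{arm.value}-{i:05d}", arm=arm,
            age=float(ages[i]), female=bool(female[i]),
            diabetes=bool(diabetes[i]), hypertension=bool(hypertension[i]),
            los_days=float(los[i]),
            hospitalization=float(bills["hospitalization"][i]),
            medication=float(bills["medication"][i]),
            travel_hotel=float(bills["travel_hotel"][i]),
            lost_productivity=costing.lost_productivity(float(los[i]), wage),
            pre_scores=pre, post_scores=post))
    return records


def generate(spec: CohortSpec, seed: int,
             wage: costing.WageModel = costing.DEFAULT_WAGE) -> list[PatientRecord]:
    """Generate the full two-arm synthetic cohort; deterministic in (spec, seed)."""
    spec.validate()
    ss = np.random.SeedSequence(seed)
    arm_seeds = ss.spawn(2)
    records: list[PatientRecord] = []
    for arm, child in zip(Arm, arm_seeds):
        records.extend(_generate_arm(spec.arm(arm), arm,
                                     np.random.default_rng(child), wage))
    return records


# ---------------------------------------------------------------------------
# round trip


@dataclass(frozen=True)
class RoundTripReport:
    """Recovered-vs-target comparison of every calibrated cohort statistic."""

    table: pd.DataFrame

    @property
    def max_relative_error(self) -> float:
        return float(self.table["rel_error"].abs().max())

    def within(self, tolerance: float) -> bool:
        return bool((self.table["rel_error"].abs() <= tolerance).all())


def roundtrip_check(records: Sequence[PatientRecord], spec: CohortSpec) -> RoundTripReport:
    """Re-aggregate a generated cohort through the costing and scoring stages
    and report the relative error of each recovered statistic against its
    spec target."""
    rows = []
    for arm in Arm:
        aspec = spec.arm(arm)
        arm_records = [r for r in records if r.arm is arm]
        ledger = costing.aggregate_ledger(arm_records, arm)
        for cat, target in (("hospitalization", aspec.hospitalization_pc),
                            ("medication", aspec.medication_pc),
                            ("travel_hotel", aspec.travel_hotel_pc)):
            rows.append((arm.value, f"per_capita_{cat}", target, ledger.per_capita(cat)))
        mean_los = float(np.mean([r.los_days for r in arm_records]))
        rows.append((arm.value, "mean_los_days", aspec.los_mean, mean_los))
        rows.append((arm.value, "per_capita_lost_productivity",
                     costing.lost_productivity(aspec.los_mean),
                     ledger.per_capita("lost_productivity")))
        rows.append((arm.value, "mean_age", aspec.age_mean,
                     float(np.mean([r.age for r in arm_records]))))
        for inst, gain in aspec.utility_gain.items():
            recovered = float(np.mean([
                to_utility(r.post_scores[inst]) - to_utility(r.pre_scores[inst])
                for r in arm_records]))
            rows.append((arm.value, f"utility_gain_{Instrument(inst).value}",
                         gain, recovered))
    table = pd.DataFrame(rows, columns=["arm", "statistic", "target", "recovered"])
    table["rel_error"] = (table["recovered"] - table["target"]) / table["target"]
    return RoundTripReport(table=table)


# ---------------------------------------------------------------------------
# CSV surface


def to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records to one row per patient (dimension columns prefixed
    ``pre_<instrument>_`` / ``post_<instrument>_``)."""
    rows = []
    for r in records:
        row = {
            "id": r.id, "arm": r.arm.value, "age": r.age, "female": r.female,
            "diabetes": r.diabetes, "hypertension": r.hypertension,
            "los_days": r.los_days, "hospitalization": r.hospitalization,
            "medication": r.medication, "travel_hotel": r.travel_hotel,
            "lost_productivity": r.lost_productivity,
        }
        for when, scores in (("pre", r.pre_scores), ("post", r.post_scores)):
            for inst, score in scores.items():
                for dim, val in zip(DIMENSIONS[inst], score.dimensions):
                    row[f"{when}_{inst.value}_{dim}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Rebuild records from a :func:`to_frame`-layout table."""
    records = []
    instruments = [inst for inst in Instrument
                   if f"pre_{inst.value}_{DIMENSIONS[inst][0]}" in df.columns]
    for _, row in df.iterrows():
        scores = {"pre": {}, "post": {}}
        for when in ("pre", "post"):
            for inst in instruments:
                dims = [row[f"{when}_{inst.value}_{d}"] for d in DIMENSIONS[inst]]
                scores[when][inst] = score_instrument(inst, dims)
        records.append(PatientRecord(
            id=str(row["id"]), arm=Arm(row["arm"]), age=float(row["age"]),
            female=bool(row["female"]), diabetes=bool(row["diabetes"]),
            hypertension=bool(row["hypertension"]), los_days=float(row["los_days"]),
            hospitalization=float(row["hospitalization"]),
            medication=float(row["medication"]),
            travel_hotel=float(row["travel_hotel"]),
            lost_productivity=float(row["lost_productivity"]),
            pre_scores=scores["pre"], post_scores=scores["post"]))
    return records
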