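"""Model parameters: loading, validation, rate/probability conversion and
probabilistic-sensitivity-analysis distribution fitting.

The decision model compares two revascularization strategies for coronary
artery disease -- bypass surgery (CABG) and drug-eluting-stent angioplasty
(PCI) -- with a six-state Markov cohort model.  Every model input is a
:class:`ParamEntry`: a point value plus a low-high range interpreted as a 95%
confidence interval.  The packaged default file (``data/table1.yaml``) holds
the study's base case: per-arm six-month transition probabilities, per-state
utility weights under two quality-of-life instruments (SAQ and SF-36), and
per-state costs in 2014 USD.

For probabilistic sensitivity analysis each ranged entry is assigned a
sampling distribution by moment matching: gamma for costs, beta for
probabilities and utilities (affinely rescaled onto its own range when the
support extends outside [0, 1], e.g. the negative repeat-CABG utility).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Width of a 95% confidence interval in standard-deviation units.
CI_WIDTH_SDS = 3.92


class Arm(str, enum.Enum):
    """Treatment strategy (model arm)."""

    CABG = "cabg"
    PCI = "pci"


class Instrument(str, enum.Enum):
    """Quality-of-life instrument supplying the utility weights."""

    SAQ = "saq"
    SF36 = "sf36"


class ParamKind(str, enum.Enum):
    PROBABILITY = "probability"
    UTILITY = "utility"
    COST = "cost"


#: Canonical state order used by every vector/matrix in the package.
STATE_NAMES = ("stable", "repeat_cabg", "repeat_pci", "cva",
               "cad_death", "other_death")
STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}
DEATH_STATES = ("cad_death", "other_death")
#: States that carry recurring rewards (death states carry none).
LIVING_STATES = ("stable", "repeat_cabg", "repeat_pci", "cva")


class ParameterValidationError(ValueError):
    """A parameter entry is missing, malformed, or violates an invariant."""


# ---------------------------------------------------------------------------
# rate <-> probability


def rate_to_probability(rate: float, time: float) -> float:
    """Convert an occurrence rate into a per-period probability.

    Uses the constant-hazard relation ``p = 1 - exp(-r t)`` with ``r`` the
    occurrence rate per unit time and ``t`` the period length in the same
    units.

    Raises
    ------
    ValueError
        If ``rate`` or ``time`` is negative.
    """
    if rate < 0 or time < 0:
        raise ValueError(f"rate and time must be nonnegative, got r={rate}, t={time}")
    return -math.expm1(-rate * time)


def probability_to_rate(probability: float, time: float) -> float:
    """Inverse of :func:`rate_to_probability`: ``r = -ln(1 - p) / t``."""
    if not 0 <= probability < 1:
        raise ValueError(f"probability must lie in [0, 1), got {probability}")
    if time <= 0:
        raise ValueError(f"time must be positive, got {time}")
    return -math.log1p(-probability) / time


# ---------------------------------------------------------------------------
# parameter entries


@dataclass(frozen=True)
class ParamEntry:
    """One model input: point value plus low-high range.

    The range is interpreted as a 95% confidence interval when fitting a
    sampling distribution (sd = width / 3.92).
    """

    id: str
    mean: float
    low: float
    high: float
    kind: ParamKind

    @property
    def ranged(self) -> bool:
        return self.high > self.low

    @property
    def sd(self) -> float:
        return (self.high - self.low) / CI_WIDTH_SDS

    def validate(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ParameterValidationError(
                f"{self.id}: range must satisfy low <= value <= high "
                f"(got {self.low} <= {self.mean} <= {self.high})")
        if self.kind is ParamKind.COST and self.low < 0:
            raise ParameterValidationError(f"{self.id}: cost low bound must be >= 0")
        if self.kind is ParamKind.PROBABILITY and not (0 <= self.mean <= 1):
            raise ParameterValidationError(
                f"{self.id}: probability value must lie in [0, 1], got {self.mean}")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution assigned to a parameter for PSA.

    ``beta`` draws live on ``loc + scale * Beta(a, b)`` (an affine support,
    identity for entries already inside [0, 1]); ``gamma`` draws on
    ``Gamma(shape, scale)``; ``fixed`` always returns the mean.
    """

    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    a: float = 0.0
    b: float = 0.0
    loc: float = 0.0
    scale: float = 1.0

    @property
    def analytic_mean(self) -> float:
        if self.family == "beta":
            return self.loc + self.scale * self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.scale
        return self.mean

    @property
    def analytic_sd(self) -> float:
        if self.family == "beta":
            ab = self.a + self.b
            return self.scale * math.sqrt(self.a * self.b / (ab * ab * (ab + 1)))
        if self.family == "gamma":
            return self.scale * math.sqrt(self.a)
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return self.loc + self.scale * rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.scale, size=size)
        if size is None:
            return self.mean
        return np.full(size, self.mean)


def _beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(a, b) on [0, 1]; requires sd^2 < mean(1-mean)."""
    var = sd * sd
    feasible = mean * (1.0 - mean)
    if var >= feasible:
        raise ParameterValidationError(
            f"beta moment match infeasible: mean={mean}, sd={sd}")
    nu = feasible / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_distribution(entry: ParamEntry) -> DistributionSpec:
    """Assign a PSA sampling distribution to a parameter entry.

    Costs get a gamma matched to (mean, sd); probabilities and utilities get
    a beta.  Probability ranges are clamped to [0, 1] first (Table-style
    ranges can overshoot 1); utility entries whose support extends outside
    [0, 1] are affinely rescaled onto their own (low, high) before fitting
    and mapped back when sampling, so the analytic mean always equals the
    entry mean on the original scale.
    """
    low, high = entry.low, entry.high
    if entry.kind is ParamKind.PROBABILITY:
        clamped_low, clamped_high = max(low, 0.0), min(high, 1.0)
        if (clamped_low, clamped_high) != (low, high):
            logger.debug("%s: probability range clamped from (%g, %g) to (%g, %g)",
                         entry.id, low, high, clamped_low, clamped_high)
        low, high = clamped_low, clamped_high
    if not (low <= entry.mean <= high):
        raise ParameterValidationError(
            f"{entry.id}: value {entry.mean} outside its (clamped) range ({low}, {high})")
    if high == low:
        return DistributionSpec(family="fixed", mean=entry.mean)
    sd = (high - low) / CI_WIDTH_SDS

    if entry.kind is ParamKind.COST:
        if entry.mean <= 0:
            raise ParameterValidationError(
                f"{entry.id}: gamma fit requires a positive mean, got {entry.mean}")
        shape = (entry.mean / sd) ** 2
        scale = sd * sd / entry.mean
        return DistributionSpec(family="gamma", mean=entry.mean, a=shape, scale=scale)

    # probability or utility -> beta
    if 0.0 <= low and high <= 1.0:
        try:
            a, b = _beta_from_moments(entry.mean, sd)
            return DistributionSpec(family="beta", mean=entry.mean, a=a, b=b)
        except ParameterValidationError:
            pass  # fall through to the rescaled fit
    # rescale onto the entry's own range
    width = high - low
    m = (entry.mean - low) / width
    if not 0.0 < m < 1.0:
        raise ParameterValidationError(
            f"{entry.id}: value must lie strictly inside its range for a "
            f"rescaled beta fit (got {entry.mean} in ({low}, {high}))")
    a, b = _beta_from_moments(m, sd / width)
    return DistributionSpec(family="beta", mean=entry.mean, a=a, b=b,
                            loc=low, scale=width)


# ---------------------------------------------------------------------------
# the full parameter set


@dataclass(frozen=True)
class ModelParameters:
    """The complete model input set, keyed by dotted parameter ids.

    Ids follow ``prob.<arm>.<state>``, ``prob.shared.<name>``,
    ``util.<instrument>.<arm>.<state>`` and ``cost.<arm>.<state>``.
    """

    entries: Mapping[str, ParamEntry]
    annual_discount_rate: float = 0.03
    cycle_length_years: float = 0.5
    entry_age_years: float = 59.0

    def entry(self, param_id: str) -> ParamEntry:
        try:
            return self.entries[param_id]
        except KeyError:
            raise KeyError(f"unknown parameter id: {param_id!r}") from None

    def value(self, param_id: str) -> float:
        return self.entry(param_id).mean

    def ranged_entries(self) -> dict[str, ParamEntry]:
        return {k: e for k, e in self.entries.items() if e.ranged}

    def with_values(self, updates: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with point values replaced (ranges untouched).

        Used by sensitivity analysis; replacement values may sit outside the
        entry's printed range (e.g. gamma tails), so no range check here.
        """
        new = dict(self.entries)
        for pid, val in updates.items():
            new[pid] = replace(self.entry(pid), mean=float(val))
        return replace(self, entries=new)

    # -- vectors in canonical state order ---------------------------------

    def arm_stable_row(self, arm: Arm) -> np.ndarray:
        """The arm's six raw per-cycle probabilities out of the Stable state,
        ordered by destination (canonical state order), not renormalized."""
        return np.array([self.value(f"prob.{arm.value}.{s}") for s in STATE_NAMES])

    def utilities(self, instrument: Instrument, arm: Arm) -> np.ndarray:
        """Per-cycle utility weight by state; death states contribute 0."""
        u = np.zeros(len(STATE_NAMES))
        for s in LIVING_STATES:
            u[STATE_INDEX[s]] = self.value(f"util.{instrument.value}.{arm.value}.{s}")
        return u

    def recurring_costs(self, arm: Arm) -> np.ndarray:
        """Per-cycle cost (USD) by state; death states recur at 0."""
        c = np.zeros(len(STATE_NAMES))
        for s in LIVING_STATES:
            c[STATE_INDEX[s]] = self.value(f"cost.{arm.value}.{s}")
        return c

    def death_transition_costs(self, arm: Arm) -> np.ndarray:
        """One-time cost (USD) charged to the cohort fraction entering each
        death state; zero elsewhere."""
        c = np.zeros(len(STATE_NAMES))
        for s in DEATH_STATES:
            c[STATE_INDEX[s]] = self.value(f"cost.{arm.value}.{s}")
        return c

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_arm_transition_entries(self) -> int:
        return sum(1 for k in self.entries
                   if k.startswith("prob.") and not k.startswith("prob.shared."))

    @property
    def n_utility_entries(self) -> int:
        return sum(1 for k in self.entries if k.startswith("util."))

    @property
    def n_cost_entries(self) -> int:
        return sum(1 for k in self.entries if k.startswith("cost."))


_SHARED_PROBS = ("cad_death_after_stable", "cad_death_after_cva", "death_other_causes")


def _require(section: Mapping, key: str, context: str) -> Mapping:
    if not isinstance(section, Mapping) or key not in section:
        raise ParameterValidationError(f"missing parameter block: {context}.{key}")
    return section[key]


def _read_entry(block: Mapping, key: str, pid: str, kind: ParamKind) -> ParamEntry:
    raw = _require(block, key, pid.rsplit(".", 1)[0])
    try:
        entry = ParamEntry(id=pid, mean=float(raw["value"]), low=float(raw["low"]),
                           high=float(raw["high"]), kind=kind)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterValidationError(f"{pid}: malformed entry ({exc})") from exc
    entry.validate()
    return entry


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load and validate a parameter file (packaged Table-1 default if None).

    Raises :class:`ParameterValidationError` naming the offending id on any
    missing entry, malformed range, or invariant violation.
    """
    if path is None:
        text = resources.files("cardiocea.data").joinpath("table1.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ParameterValidationError("parameter file is not a mapping")

    entries: dict[str, ParamEntry] = {}
    probs = _require(doc, "probabilities", "<root>")
    for arm in Arm:
        block = _require(probs, arm.value, "probabilities")
        for s in STATE_NAMES:
            pid = f"prob.{arm.value}.{s}"
            entries[pid] = _read_entry(block, s, pid, ParamKind.PROBABILITY)
    shared = _require(probs, "shared", "probabilities")
    for name in _SHARED_PROBS:
        pid = f"prob.shared.{name}"
        entries[pid] = _read_entry(shared, name, pid, ParamKind.PROBABILITY)

    utils = _require(doc, "utilities", "<root>")
    for inst in Instrument:
        iblock = _require(utils, inst.value, "utilities")
        for arm in Arm:
            block = _require(iblock, arm.value, f"utilities.{inst.value}")
            for s in LIVING_STATES:
                pid = f"util.{inst.value}.{arm.value}.{s}"
                entries[pid] = _read_entry(block, s, pid, ParamKind.UTILITY)

    costs = _require(doc, "costs", "<root>")
    for arm in Arm:
        block = _require(costs, arm.value, "costs")
        for s in STATE_NAMES:
            pid = f"cost.{arm.value}.{s}"
            entries[pid] = _read_entry(block, s, pid, ParamKind.COST)

    settings = doc.get("settings", {}) or {}
    params = ModelParameters(
        entries=entries,
        annual_discount_rate=float(settings.get("annual_discount_rate", 0.03)),
        cycle_length_years=float(settings.get("cycle_length_years", 0.5)),
        entry_age_years=float(settings.get("entry_age_years", 59.0)),
    )
    # every fitted distribution must be constructible
    for entry in params.entries.values():
        fit_distribution(entry)
    return params


def default_parameters() -> ModelParameters:
    """The packaged base case (Table-1 payload)."""
    return load_parameters(None)
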