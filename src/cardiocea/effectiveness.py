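"""Questionnaire scoring and QALY arithmetic.

Two instruments measure health-related quality of life on 0-100 dimension
scales: the generic SF-36 (eight dimensions) and the disease-specific Seattle
Angina Questionnaire (five dimensions).  A patient's summary score is the
unweighted mean of the dimensions, mapped linearly to a 0-1 utility weight
(the study reports no valuation tariff, so summary/100 is the package's
documented convention).

QALYs gained by an intervention follow the continuously-discounted form

    gain = Qi * (1 - exp(-r * Li)) / r  -  Q * (1 - exp(-r * L)) / r

with pre/post quality weights Q, Qi, affected durations L, Li (years) and
annual discount rate r; the r -> 0 limit is ``Qi*Li - Q*L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .parameters import Instrument

SF36_DIMENSIONS = (
    "physical_function", "role_physical", "bodily_pain", "general_health",
    "energy", "social_function", "role_emotional", "emotional_wellbeing",
)
SAQ_DIMENSIONS = (
    "physical_limitation", "angina_stability", "angina_frequency",
    "treatment_satisfaction", "disease_perception",
)
DIMENSIONS = {Instrument.SF36: SF36_DIMENSIONS, Instrument.SAQ: SAQ_DIMENSIONS}


@dataclass(frozen=True)
class QuestionnaireScore:
    """Dimension scores (0-100 each) for one instrument at one timepoint."""

    instrument: Instrument
    dimensions: tuple[float, ...]

    @property
    def summary(self) -> float:
        """Unweighted mean of the dimension scores, 0-100."""
        return sum(self.dimensions) / len(self.dimensions)


def score_instrument(instrument: Instrument,
                     dimension_scores: Sequence[float]) -> QuestionnaireScore:
    """Validate dimension scores and build a :class:`QuestionnaireScore`.

    Raises ``ValueError`` on a wrong dimension count or out-of-range value.
    """
    instrument = Instrument(instrument)
    expected = len(DIMENSIONS[instrument])
    scores = tuple(float(x) for x in dimension_scores)
    if len(scores) != expected:
        raise ValueError(
            f"{instrument.value} requires {expected} dimension scores, got {len(scores)}")
    for i, x in enumerate(scores):
        if not 0.0 <= x <= 100.0:
            raise ValueError(
                f"{instrument.value} dimension {i} out of range [0, 100]: {x}")
    return QuestionnaireScore(instrument=instrument, dimensions=scores)


def to_utility(score: QuestionnaireScore) -> float:
    """Linear summary -> utility mapping: summary / 100 in [0, 1]."""
    return score.summary / 100.0


@dataclass(frozen=True)
class QalyInputs:
    """Inputs to :func:`qalys_gained`.

    Q/Qi are pre/post-intervention quality weights (negative permitted: the
    model's repeat-surgery utility after angioplasty is below zero); L/Li are
    the affected durations in years; r is the annual discount rate.
    """

    pre_quality: float
    post_quality: float
    pre_years: float
    post_years: float
    discount_rate: float

    def validate(self) -> None:
        if self.pre_years < 0 or self.post_years < 0:
            raise ValueError("durations must be nonnegative")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be nonnegative")
        for q in (self.pre_quality, self.post_quality):
            if not -1.0 <= q <= 1.0:
                raise ValueError(f"quality weight out of [-1, 1]: {q}")


_R_LIMIT = 1e-9


def _discounted_years(years: float, rate: float) -> float:
    if rate < _R_LIMIT:
        return years
    return -math.expm1(-rate * years) / rate


def qalys_gained(inputs: QalyInputs) -> float:
    """Discounted QALY gain of the intervention (may be negative)."""
    inputs.validate()
    return (inputs.post_quality * _discounted_years(inputs.post_years, inputs.discount_rate)
            - inputs.pre_quality * _discounted_years(inputs.pre_years, inputs.discount_rate))


def summarize_frame(df: pd.DataFrame, instrument: Instrument) -> pd.DataFrame:
    """Score a dimension-column table (one row per patient-timepoint).

    The frame must carry one column per dimension of ``instrument``; returns
    the input plus ``summary`` and ``utility`` columns.
    """
    instrument = Instrument(instrument)
    dims = list(DIMENSIONS[instrument])
    missing = [d for d in dims if d not in df.columns]
    if missing:
        raise ValueError(f"missing dimension columns: {missing}")
    out = df.copy()
    scores = df[dims].apply(lambda row: score_instrument(instrument, row), axis=1)
    out["summary"] = [s.summary for s in scores]
    out["utility"] = out["summary"] / 100.0
    return out
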