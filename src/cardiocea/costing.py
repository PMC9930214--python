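"""Patient-perspective cost aggregation.

Costs fall into the study's three-block, four-category structure: direct
medical (hospitalization, medication), direct non-medical (travel and hotel
stay), and indirect (lost productivity of patient and family).  Amounts are
2014 USD; the Central Bank exchange rate of 26,509 rials per dollar converts
billed rial amounts.

Lost productivity uses the 2014 average minimum-maximum wage midpoint of
US$311/month over 26 working days: ``days_hospitalized * 311 / 26``.
Medication bills cover six months; the annual cost (x2) is discounted at 3%
over 10 years as an annuity (payments at the start of each year by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

RIALS_PER_USD = 26509.0

CATEGORIES = ("hospitalization", "medication", "travel_hotel", "lost_productivity")
CATEGORY_BLOCKS = {
    "hospitalization": "direct_medical",
    "medication": "direct_medical",
    "travel_hotel": "direct_nonmedical",
    "lost_productivity": "indirect",
}


@dataclass(frozen=True)
class WageModel:
    """Monthly wage and working days used for lost-productivity costing."""

    monthly_wage: float = 311.0
    working_days_per_month: int = 26

    def __post_init__(self):
        if self.monthly_wage <= 0:
            raise ValueError("monthly wage must be positive")
        if not 1 <= self.working_days_per_month <= 31:
            raise ValueError("working days per month must lie in [1, 31]")


DEFAULT_WAGE = WageModel()


def lost_productivity(days_hospitalized: float, wage: WageModel = DEFAULT_WAGE) -> float:
    """Indirect cost (USD) of a hospital stay: days * monthly wage / working days."""
    if days_hospitalized < 0:
        raise ValueError(f"days must be nonnegative, got {days_hospitalized}")
    return days_hospitalized * wage.monthly_wage / wage.working_days_per_month


def medication_present_value(six_month_cost: float, rate: float = 0.03,
                             years: int = 10, timing: str = "due") -> float:
    """Present value (USD) of a chronic medication stream.

    The six-month bill is doubled to an annual cost, then discounted over
    ``years`` annual payments: at year starts (``timing="due"``, t = 0..y-1,
    the default) or year ends (``timing="arrears"``, t = 1..y).
    """
    if six_month_cost < 0 or rate < 0:
        raise ValueError("cost and rate must be nonnegative")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if timing not in ("due", "arrears"):
        raise ValueError(f"timing must be 'due' or 'arrears', got {timing!r}")
    annual = 2.0 * six_month_cost
    offset = 0 if timing == "due" else 1
    factor = sum((1.0 + rate) ** (-(t + offset)) for t in range(years))
    return annual * factor


def rial_to_usd(amount_irr: float) -> float:
    """Convert 2014 Iranian rials to USD at 26,509 IRR/USD."""
    if amount_irr < 0:
        raise ValueError("amount must be nonnegative")
    return amount_irr / RIALS_PER_USD


def usd_to_rial(amount_usd: float) -> float:
    if amount_usd < 0:
        raise ValueError("amount must be nonnegative")
    return amount_usd * RIALS_PER_USD


@dataclass(frozen=True)
class CostLedger:
    """Category totals (USD) over one arm's patients.

    Internal values are unrounded; the reporting layer rounds totals to one
    decimal and per-capita values to two (matching the study's convention).
    """

    hospitalization: float
    medication: float
    travel_hotel: float
    lost_productivity: float
    n_patients: int

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("ledger requires at least one patient")
        for cat in CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"{cat} total must be nonnegative")

    @property
    def total(self) -> float:
        return sum(getattr(self, cat) for cat in CATEGORIES)

    def per_capita(self, category: str) -> float:
        return getattr(self, category) / self.n_patients

    @property
    def per_capita_total(self) -> float:
        return self.total / self.n_patients

    def __add__(self, other: "CostLedger") -> "CostLedger":
        return CostLedger(
            *(getattr(self, c) + getattr(other, c) for c in CATEGORIES),
            n_patients=self.n_patients + other.n_patients)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "cost_block": CATEGORY_BLOCKS[cat],
            "category": cat,
            "total_usd": round(getattr(self, cat), 1),
            "per_capita_usd": round(self.per_capita(cat), 2),
        } for cat in CATEGORIES]
        rows.append({"cost_block": "total", "category": "total",
                     "total_usd": round(self.total, 1),
                     "per_capita_usd": round(self.per_capita_total, 2)})
        return pd.DataFrame(rows)


def aggregate_ledger(records: Iterable, arm) -> CostLedger:
    """Sum the four billing categories over one arm's patient records.

    ``records`` may be any iterable of objects exposing ``arm`` plus the four
    category attributes in USD (e.g. :class:`cardiocea.cohort.PatientRecord`).
    Raises ``ValueError`` if the arm has no records.
    """
    arm_value = getattr(arm, "value", arm)
    totals = dict.fromkeys(CATEGORIES, 0.0)
    n = 0
    for rec in records:
        rec_arm = getattr(rec.arm, "value", rec.arm)
        if rec_arm != arm_value:
            continue
        n += 1
        for cat in CATEGORIES:
            totals[cat] += float(getattr(rec, cat))
    if n == 0:
        raise ValueError(f"no records for arm {arm_value!r}")
    return CostLedger(**totals, n_patients=n)


def ledger_table(ledgers: dict[str, CostLedger]) -> pd.DataFrame:
    """Side-by-side arm comparison in the study's cost-table layout."""
    frames = []
    for arm_name, ledger in ledgers.items():
        f = ledger.to_frame()
        f.insert(0, "arm", arm_name)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def ledger_from_frame(df: pd.DataFrame, arm) -> CostLedger:
    """Aggregate a billing CSV frame (columns: arm, the four categories,
    optional ``currency`` of 'USD' or 'IRR') into a ledger."""
    arm_value = getattr(arm, "value", arm)
    sub = df[df["arm"].astype(str).str.lower() == arm_value]
    if sub.empty:
        raise ValueError(f"no rows for arm {arm_value!r}")
    totals = {}
    for cat in CATEGORIES:
        vals = sub[cat].astype(float)
        if "currency" in sub.columns:
            irr = sub["currency"].str.upper() == "IRR"
            vals = vals.where(~irr, vals / RIALS_PER_USD)
        totals[cat] = float(vals.sum())
    return CostLedger(**totals, n_patients=len(sub))
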