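"""Cost-effectiveness arithmetic: ICER, ACER, net monetary benefit, the
3xGDP willingness-to-pay threshold rule, and the trial sample-size formula.

Conventions: incrementals are CABG minus PCI.  A strategy is *dominant* when
it is cheaper and more effective (delta cost < 0, delta QALY > 0) and
*dominated* in the reverse case; ratios are reported rounded to the nearest
integer USD/QALY while dominance is always judged on unrounded values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .markov import CohortTrace

#: World Bank GDP per capita (2012 USD) behind the default WTP threshold.
GDP_PER_CAPITA_2012 = 8329.0


class Verdict(str, enum.Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    ICER_BELOW_THRESHOLD = "icer_below_threshold"
    ICER_ABOVE_THRESHOLD = "icer_above_threshold"


@dataclass(frozen=True)
class Icer:
    """Incremental cost-effectiveness ratio with dominance flags.

    ``value`` is ``delta_cost / delta_qaly`` (None when delta_qaly == 0, the
    undefined-ICER case).  Flags are computed on unrounded deltas.
    """

    delta_cost: float
    delta_qaly: float
    value: Optional[float]
    dominant: bool
    dominated: bool

    @property
    def undefined(self) -> bool:
        return self.value is None

    @property
    def reported(self) -> Optional[int]:
        """Integer-rounded ratio (reporting convention), None if undefined."""
        return None if self.value is None else round(self.value)


def icer(delta_cost: float, delta_qaly: float) -> Icer:
    """Incremental cost-effectiveness ratio of CABG versus PCI."""
    value = None if delta_qaly == 0 else delta_cost / delta_qaly
    return Icer(delta_cost=delta_cost, delta_qaly=delta_qaly, value=value,
                dominant=delta_cost < 0 and delta_qaly > 0,
                dominated=delta_cost > 0 and delta_qaly < 0)


def acer(cost: float, qaly: float) -> float:
    """Average cost-effectiveness ratio: total cost per QALY achieved."""
    if qaly <= 0:
        raise ValueError(f"ACER requires positive effectiveness, got {qaly}")
    return cost / qaly


def nmb(wtp: float, qaly: float, cost: float) -> float:
    """Net monetary benefit at a willingness-to-pay: wtp * qaly - cost."""
    return wtp * qaly - cost


def threshold_verdict(result: Icer, gdp_per_capita: float = GDP_PER_CAPITA_2012) -> Verdict:
    """Classify an ICER against the 3xGDP-per-capita threshold.

    Dominance short-circuits; otherwise the strategy is cost-effective iff
    the ICER is strictly below 3xGDP.  An undefined ICER (equal effect, no
    dominance) is conservatively classed as above-threshold.
    """
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be positive")
    if result.dominant:
        return Verdict.DOMINANT
    if result.dominated:
        return Verdict.DOMINATED
    if result.value is not None and result.value < 3.0 * gdp_per_capita:
        return Verdict.ICER_BELOW_THRESHOLD
    return Verdict.ICER_ABOVE_THRESHOLD


@dataclass(frozen=True)
class CEAResult:
    """Paired strategy outcomes with incrementals and the threshold verdict."""

    cost_cabg: float
    qaly_cabg: float
    cost_pci: float
    qaly_pci: float
    wtp: float
    gdp_per_capita: float = GDP_PER_CAPITA_2012

    @property
    def delta_cost(self) -> float:
        return self.cost_cabg - self.cost_pci

    @property
    def delta_qaly(self) -> float:
        return self.qaly_cabg - self.qaly_pci

    @property
    def icer(self) -> Icer:
        return icer(self.delta_cost, self.delta_qaly)

    @property
    def acer_cabg(self) -> float:
        return acer(self.cost_cabg, self.qaly_cabg)

    @property
    def acer_pci(self) -> float:
        return acer(self.cost_pci, self.qaly_pci)

    @property
    def nmb_cabg(self) -> float:
        return nmb(self.wtp, self.qaly_cabg, self.cost_cabg)

    @property
    def nmb_pci(self) -> float:
        return nmb(self.wtp, self.qaly_pci, self.cost_pci)

    @property
    def incremental_nmb(self) -> float:
        return self.nmb_cabg - self.nmb_pci

    @property
    def verdict(self) -> Verdict:
        return threshold_verdict(self.icer, self.gdp_per_capita)

    def to_frame(self) -> pd.DataFrame:
        ic = self.icer
        return pd.DataFrame([
            {"strategy": "PCI", "qalys": self.qaly_pci, "incremental_qalys": None,
             "cost_usd": self.cost_pci, "incremental_cost_usd": None,
             "icer": None, "verdict": None, "acer": round(self.acer_pci),
             "nmb_at_wtp": self.nmb_pci},
            {"strategy": "CABG", "qalys": self.qaly_cabg,
             "incremental_qalys": self.delta_qaly, "cost_usd": self.cost_cabg,
             "incremental_cost_usd": self.delta_cost, "icer": ic.reported,
             "verdict": self.verdict.value, "acer": round(self.acer_cabg),
             "nmb_at_wtp": self.nmb_cabg},
        ])


def from_traces(cabg: CohortTrace, pci: CohortTrace, wtp: float,
                gdp_per_capita: float = GDP_PER_CAPITA_2012) -> CEAResult:
    """Build a :class:`CEAResult` from paired cohort traces (CABG, PCI)."""
    return CEAResult(cost_cabg=cabg.discounted_cost, qaly_cabg=cabg.discounted_qaly,
                     cost_pci=pci.discounted_cost, qaly_pci=pci.discounted_qaly,
                     wtp=wtp, gdp_per_capita=gdp_per_capita)


# ---------------------------------------------------------------------------
# sample size


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the net-monetary-benefit sample-size formula.

    Defaults are the study's design values: 5% one-sided alpha (z=1.64), 90%
    power (z=1.28), cost SD $10,972, QALY SD 0.00063, willingness to pay
    $40,000/QALY, cost-effect correlation 0.3 and a minimum detectable NMB
    of $3,200.
    """

    z_alpha: float = 1.64
    z_beta: float = 1.28
    sd_cost: float = 10972.0
    sd_qaly: float = 0.00063
    wtp: float = 40000.0
    rho: float = 0.3
    nmb_min: float = 3200.0

    def validate(self) -> None:
        if self.sd_cost <= 0 or self.sd_qaly <= 0:
            raise ValueError("standard deviations must be positive")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.nmb_min <= 0:
            raise ValueError("minimum detectable NMB must be positive")


def sample_size(inputs: SampleSizeInputs = SampleSizeInputs(),
                z_term: str = "squared") -> int:
    """Per-group sample size for detecting a net-monetary-benefit difference.

    ``z_term="squared"`` uses ``2 (z_a + z_b)^2 [...] / nmb_min^2`` (the
    conventional form, default); ``"linear"`` leaves the z-sum unsquared as
    the study's formula prints it.  Returns the ceiling integer.
    """
    inputs.validate()
    if z_term not in ("squared", "linear"):
        raise ValueError(f"z_term must be 'squared' or 'linear', got {z_term!r}")
    z = inputs.z_alpha + inputs.z_beta
    z_factor = z * z if z_term == "squared" else z
    bracket = (inputs.sd_cost ** 2 + (inputs.wtp * inputs.sd_qaly) ** 2
               - 2.0 * inputs.wtp * inputs.rho * inputs.sd_cost * inputs.sd_qaly)
    return math.ceil(2.0 * z_factor * bracket / inputs.nmb_min ** 2)
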