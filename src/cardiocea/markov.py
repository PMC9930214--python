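"""Six-state Markov cohort engine with discounted cost and QALY accrual.

States (canonical order): Stable, RepeatCABG, RepeatPCI, CVA, CADDeath,
OtherDeath.  Both death states are absorbing.  The cohort enters at age 59 in
the Stable state of its assigned arm and advances in six-month cycles.

Construction conventions (the parameter table prints marginal probabilities,
not full rows):

* The Stable row uses the arm's six printed probabilities, renormalized to
  sum to one (the printed rows sum to 0.9997 / 0.9996; renormalization
  preserves their ratios).
* Repeat-procedure states are one-cycle tunnels: the RepeatCABG row equals
  the CABG arm's Stable row and the RepeatPCI row equals the PCI arm's,
  whichever arm the matrix belongs to.
* CVA survivors return to Stable: the CVA row puts the printed CVA-specific
  coronary mortality and background mortality on the death states and the
  remainder on Stable.

Rewards: each living state accrues its per-cycle utility and cost on the
cohort fraction occupying it at cycle start (cycle 0 included, no half-cycle
correction by default); entering a death state charges that state's one-time
cost once, at the end of the transition cycle.  Both streams are discounted
at ``(1 + r)^(-k * cycle_length_years)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    Arm,
    Instrument,
    ModelParameters,
    STATE_INDEX,
    STATE_NAMES,
)

logger = logging.getLogger(__name__)

N_STATES = len(STATE_NAMES)
_I_STABLE = STATE_INDEX["stable"]
_I_CAD_DEATH = STATE_INDEX["cad_death"]
_I_OTHER_DEATH = STATE_INDEX["other_death"]
_DEATH_IDX = (_I_CAD_DEATH, _I_OTHER_DEATH)

_ROW_SUM_TOL = 1e-12


class MatrixConstructionError(ValueError):
    """A transition matrix could not be built or fails stochasticity."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 6x6 per-cycle transition matrix, tagged with its arm."""

    arm: Arm
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise MatrixConstructionError(f"matrix must be 6x6, got {m.shape}")
        if (m < -_ROW_SUM_TOL).any() or (m > 1 + 1e-9).any():
            raise MatrixConstructionError("matrix entries must lie in [0, 1]")
        row_sums = m.sum(axis=1)
        if not np.allclose(row_sums, 1.0, rtol=0, atol=1e-9):
            raise MatrixConstructionError(f"rows must sum to 1, got {row_sums}")
        for i in _DEATH_IDX:
            if m[i, i] != 1.0:
                raise MatrixConstructionError(f"state {STATE_NAMES[i]} must be absorbing")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class RewardSet:
    """Per-state rewards for one arm under one utility instrument."""

    arm: Arm
    instrument: Instrument
    utilities: np.ndarray          # per-cycle QALY weight by state
    recurring_costs: np.ndarray    # per-cycle USD by state
    death_costs: np.ndarray        # one-time USD on entry, death states only

    @classmethod
    def from_parameters(cls, params: ModelParameters, arm: Arm,
                        instrument: Instrument) -> "RewardSet":
        return cls(arm=arm, instrument=instrument,
                   utilities=params.utilities(instrument, arm),
                   recurring_costs=params.recurring_costs(arm),
                   death_costs=params.death_transition_costs(arm))


@dataclass
class AnalysisSettings:
    """Run settings shared by the base case and every sensitivity analysis."""

    horizon_cycles: int = 30
    discount_rate: float | None = None      # None -> take from the parameter set
    wtp: float = 24987.0                    # 3 x GDP per capita (2012 USD)
    gdp_per_capita: float = 8329.0
    half_cycle_correction: bool = False
    instrument: Instrument = Instrument.SAQ


def _renormalized_stable_row(params: ModelParameters, arm: Arm) -> np.ndarray:
    row = params.arm_stable_row(arm)
    if (row < 0).any():
        raise MatrixConstructionError(f"negative transition probability in {arm.value} row")
    total = row.sum()
    if total <= 0:
        raise MatrixConstructionError(f"{arm.value} stable row sums to {total}")
    if abs(total - 1.0) > 1e-12:
        logger.debug("renormalizing %s stable row (printed sum %.6f)", arm.value, total)
    return row / total


def build_matrix(params: ModelParameters, arm: Arm) -> TransitionMatrix:
    """Build the arm's per-cycle transition matrix from the parameter set."""
    m = np.zeros((N_STATES, N_STATES))
    m[_I_STABLE] = _renormalized_stable_row(params, arm)
    m[STATE_INDEX["repeat_cabg"]] = _renormalized_stable_row(params, Arm.CABG)
    m[STATE_INDEX["repeat_pci"]] = _renormalized_stable_row(params, Arm.PCI)

    p_cad = params.value("prob.shared.cad_death_after_cva")
    p_bg = params.value("prob.shared.death_other_causes")
    remainder = 1.0 - p_cad - p_bg
    if remainder < 0:
        raise MatrixConstructionError("CVA row death probabilities exceed 1")
    cva_row = np.zeros(N_STATES)
    cva_row[_I_STABLE] = remainder
    cva_row[_I_CAD_DEATH] = p_cad
    cva_row[_I_OTHER_DEATH] = p_bg
    m[STATE_INDEX["cva"]] = cva_row

    for i in _DEATH_IDX:
        m[i, i] = 1.0
    return TransitionMatrix(arm=arm, matrix=m)


@dataclass
class CohortTrace:
    """Cycle-by-cycle cohort trajectory with discounted accruals.

    ``occupancy`` has ``horizon_cycles + 1`` rows (cycle 0 = entry state);
    ``cycle_cost`` / ``cycle_qaly`` hold the *discounted* contribution of each
    cycle, so the totals are their sums.
    """

    arm: Arm
    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    horizon_cycles: int
    discount_rate: float
    cycle_length_years: float

    @property
    def discounted_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def discounted_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = np.arange(self.horizon_cycles + 1)
        df = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        df.insert(0, "cycle", rows)
        cost = np.append(self.cycle_cost, np.nan)
        qaly = np.append(self.cycle_qaly, np.nan)
        df["cycle_cost"] = cost
        df["cycle_qaly"] = qaly
        df["cum_discounted_cost"] = np.append(np.cumsum(self.cycle_cost), self.discounted_cost)
        df["cum_discounted_qaly"] = np.append(np.cumsum(self.cycle_qaly), self.discounted_qaly)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(matrix: TransitionMatrix, rewards: RewardSet, horizon_cycles: int,
               discount_rate: float, init: np.ndarray | None = None,
               cycle_length_years: float = 0.5,
               half_cycle_correction: bool = False) -> CohortTrace:
    """Propagate a cohort through the matrix, accruing discounted rewards.

    Parameters
    ----------
    horizon_cycles : number of cycles simulated (>= 1).
    discount_rate : annual discount rate applied as
        ``(1 + r)^(-k * cycle_length_years)`` at cycle ``k``.
    init : initial occupancy (defaults to all-Stable); must sum to 1.
    half_cycle_correction : when True, recurring rewards accrue on the
        average of the cycle's start and end occupancy.
    """
    if horizon_cycles < 1:
        raise ValueError(f"horizon_cycles must be >= 1, got {horizon_cycles}")
    if init is None:
        init = np.zeros(N_STATES)
        init[_I_STABLE] = 1.0
    init = np.asarray(init, dtype=float)
    if init.shape != (N_STATES,) or abs(init.sum() - 1.0) > 1e-9 or (init < 0).any():
        raise ValueError("init must be a nonnegative length-6 vector summing to 1")

    m = matrix.matrix
    occ = np.empty((horizon_cycles + 1, N_STATES))
    occ[0] = init
    for k in range(horizon_cycles):
        occ[k + 1] = occ[k] @ m

    k_idx = np.arange(horizon_cycles)
    disc_start = (1.0 + discount_rate) ** (-k_idx * cycle_length_years)
    disc_end = (1.0 + discount_rate) ** (-(k_idx + 1) * cycle_length_years)

    basis = 0.5 * (occ[:-1] + occ[1:]) if half_cycle_correction else occ[:-1]
    qaly_per_cycle = basis @ rewards.utilities
    cost_per_cycle = basis @ rewards.recurring_costs

    # one-time costs on the fraction newly absorbed during each cycle
    inflow = occ[1:, list(_DEATH_IDX)] - occ[:-1, list(_DEATH_IDX)]
    death_cost_per_cycle = inflow @ rewards.death_costs[list(_DEATH_IDX)]

    cycle_cost = cost_per_cycle * disc_start + death_cost_per_cycle * disc_end
    cycle_qaly = qaly_per_cycle * disc_start

    return CohortTrace(arm=matrix.arm, occupancy=occ, cycle_cost=cycle_cost,
                       cycle_qaly=cycle_qaly, horizon_cycles=horizon_cycles,
                       discount_rate=discount_rate,
                       cycle_length_years=cycle_length_years)


def run_arm(params: ModelParameters, arm: Arm, instrument: Instrument,
            settings: AnalysisSettings | None = None) -> CohortTrace:
    """Build the arm's matrix and rewards and run the cohort."""
    settings = settings or AnalysisSettings()
    rate = (params.annual_discount_rate if settings.discount_rate is None
            else settings.discount_rate)
    return run_cohort(build_matrix(params, arm),
                      RewardSet.from_parameters(params, arm, instrument),
                      horizon_cycles=settings.horizon_cycles,
                      discount_rate=rate,
                      cycle_length_years=params.cycle_length_years,
                      half_cycle_correction=settings.half_cycle_correction)


def compare_arms(params: ModelParameters, instrument: Instrument,
                 settings: AnalysisSettings | None = None
                 ) -> tuple[CohortTrace, CohortTrace]:
    """Run both strategies under identical settings; returns (CABG, PCI)."""
    settings = settings or AnalysisSettings()
    return (run_arm(params, Arm.CABG, instrument, settings),
            run_arm(params, Arm.PCI, instrument, settings))
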