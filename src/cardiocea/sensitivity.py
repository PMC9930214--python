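"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the paired cohort model with a single parameter at
its low and high bound (all else at base case, transition-row
renormalization reapplied) and records the incremental net monetary benefit
at the reference willingness-to-pay; the tornado diagram ranks parameters by
the resulting outcome swing.

Probabilistic sensitivity analysis jointly redraws every ranged parameter
from its fitted distribution (gamma for costs, beta for probabilities and
utilities) per Monte Carlo trial and records the incremental cost and QALY
pair.  Each trial owns an independent child of the root seed
(``SeedSequence.spawn``), so trial *i* is reproducible regardless of how many
trials are requested.  The cost-effectiveness acceptability curve (CEAC) is
the fraction of trials with positive incremental NMB as a function of WTP;
the CE-plane acceptance fraction is the same quantity at a single WTP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cea
from .markov import AnalysisSettings, compare_arms
from .parameters import (
    DistributionSpec,
    Instrument,
    ModelParameters,
    ParamKind,
    fit_distribution,
)


def _incremental_outcomes(params: ModelParameters, instrument: Instrument,
                          settings: AnalysisSettings) -> tuple[float, float]:
    cabg, pci = compare_arms(params, instrument, settings)
    return (cabg.discounted_cost - pci.discounted_cost,
            cabg.discounted_qaly - pci.discounted_qaly)


def _clamp_for_kind(value: float, kind: ParamKind) -> float:
    if kind is ParamKind.PROBABILITY:
        return min(max(value, 0.0), 1.0)
    return value


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome (incremental NMB) at a parameter's bounds, with the swing."""

    param_id: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def one_way(params: ModelParameters, param_id: str,
            low: float | None = None, high: float | None = None,
            settings: AnalysisSettings | None = None) -> TornadoEntry:
    """One-way deterministic sensitivity analysis of a single parameter.

    Bounds default to the entry's printed range (probabilities clamped to
    [0, 1]).  The outcome scale is incremental NMB at ``settings.wtp``.
    """
    settings = settings or AnalysisSettings()
    entry = params.entry(param_id)  # raises KeyError for unknown ids
    low = entry.low if low is None else low
    high = entry.high if high is None else high
    if low > high:
        raise ValueError(f"{param_id}: low bound exceeds high bound")
    low = _clamp_for_kind(low, entry.kind)
    high = _clamp_for_kind(high, entry.kind)

    outcomes = []
    for bound in (low, high):
        dc, dq = _incremental_outcomes(params.with_values({param_id: bound}),
                                       settings.instrument, settings)
        outcomes.append(settings.wtp * dq - dc)
    return TornadoEntry(param_id=param_id, low_value=low, high_value=high,
                        outcome_at_low=outcomes[0], outcome_at_high=outcomes[1])


def tornado(params: ModelParameters,
            settings: AnalysisSettings | None = None) -> list[TornadoEntry]:
    """One entry per ranged parameter, sorted by outcome swing, descending."""
    settings = settings or AnalysisSettings()
    entries = [one_way(params, pid, settings=settings)
               for pid in params.ranged_entries()]
    return sorted(entries, key=lambda e: e.swing, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "param": e.param_id, "low": e.low_value, "high": e.high_value,
        "outcome_at_low": e.outcome_at_low, "outcome_at_high": e.outcome_at_high,
        "swing": e.swing,
    } for e in entries])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Per-trial incremental (cost, QALY) pairs from Monte Carlo sampling."""

    n_trials: int
    seed: int
    instrument: Instrument
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    samples: pd.DataFrame | None = None   # per-trial sampled parameter values

    def incremental_nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_qaly - self.delta_cost

    def to_frame(self, wtp: float) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "nmb_at_wtp": self.incremental_nmb(wtp),
        })


def run_psa(params: ModelParameters, n_trials: int, seed: int,
            settings: AnalysisSettings | None = None,
            retain_samples: bool = True) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Every ranged parameter is redrawn per trial from its fitted distribution;
    transition rows are renormalized at matrix construction as in the base
    case.  Identical ``(params, n_trials, seed)`` give identical results, and
    trial *i*'s draw stream does not depend on ``n_trials``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    settings = settings or AnalysisSettings()
    ranged = params.ranged_entries()
    specs: dict[str, DistributionSpec] = {}
    for pid, entry in ranged.items():
        try:
            specs[pid] = fit_distribution(entry)
        except Exception as exc:
            raise ValueError(f"cannot fit sampling distribution for {pid}") from exc

    param_ids = list(specs)
    children = np.random.SeedSequence(seed).spawn(n_trials)
    delta_cost = np.empty(n_trials)
    delta_qaly = np.empty(n_trials)
    drawn = np.empty((n_trials, len(param_ids))) if retain_samples else None

    for i in range(n_trials):
        rng = np.random.default_rng(children[i])
        draws = {pid: float(specs[pid].sample(rng)) for pid in param_ids}
        if drawn is not None:
            drawn[i] = [draws[pid] for pid in param_ids]
        dc, dq = _incremental_outcomes(params.with_values(draws),
                                       settings.instrument, settings)
        delta_cost[i] = dc
        delta_qaly[i] = dq

    samples = (pd.DataFrame(drawn, columns=param_ids) if drawn is not None else None)
    return PSAResult(n_trials=n_trials, seed=seed, instrument=settings.instrument,
                     delta_cost=delta_cost, delta_qaly=delta_qaly, samples=samples)


@dataclass(frozen=True)
class CEACCurve:
    """Probability that CABG is cost-effective along a WTP grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def acceptance_fraction(psa: PSAResult, wtp: float) -> float:
    """Fraction of PSA trials with positive incremental NMB at ``wtp``.

    This is the CE-plane "acceptance area" operationalized as
    ``wtp * dQALY - dCost > 0``: the dominant (cheaper, more effective)
    quadrant plus the below-threshold part of the costlier-but-better one.
    """
    if psa.n_trials < 1:
        raise ValueError("PSA result is empty")
    return float(np.mean(psa.incremental_nmb(wtp) > 0))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve over a strictly increasing grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    if grid.size > 1 and not (np.diff(grid) > 0).all():
        raise ValueError("wtp grid must be strictly increasing")
    nmb = grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return CEACCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


DEFAULT_WTP_GRID = np.arange(0, 100_001, 1000, dtype=float)


def psa_summary(psa: PSAResult, settings: AnalysisSettings | None = None) -> dict:
    """Exploratory summary: acceptance fraction at the reference WTP plus
    quadrant shares of the CE plane."""
    settings = settings or AnalysisSettings()
    dominant = (psa.delta_cost < 0) & (psa.delta_qaly > 0)
    dominated = (psa.delta_cost > 0) & (psa.delta_qaly < 0)
    return {
        "n_trials": psa.n_trials,
        "seed": psa.seed,
        "wtp": settings.wtp,
        "acceptance_fraction": acceptance_fraction(psa, settings.wtp),
        "share_dominant": float(dominant.mean()),
        "share_dominated": float(dominated.mean()),
        "mean_delta_cost": float(psa.delta_cost.mean()),
        "mean_delta_qaly": float(psa.delta_qaly.mean()),
    }
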