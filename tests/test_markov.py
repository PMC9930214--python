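"""Transition-matrix construction and cohort simulation."""

import numpy as np
import pytest

from cardiocea import (
    AnalysisSettings,
    Arm,
    Instrument,
    build_matrix,
    compare_arms,
    run_cohort,
)
from cardiocea.markov import (
    MatrixConstructionError,
    RewardSet,
    TransitionMatrix,
    N_STATES,
)
from cardiocea.parameters import STATE_INDEX

from conftest import random_stochastic_matrix


def make_rewards(utilities=None, recurring=None, death=None,
                 arm=Arm.CABG, instrument=Instrument.SAQ):
    zeros = np.zeros(N_STATES)
    return RewardSet(arm=arm, instrument=instrument,
                     utilities=zeros if utilities is None else np.asarray(utilities, float),
                     recurring_costs=zeros if recurring is None else np.asarray(recurring, float),
                     death_costs=zeros if death is None else np.asarray(death, float))


def brute_force_totals(matrix, utilities, recurring, death_costs, horizon,
                       rate, cycle_len, init):
    """Independent per-cycle oracle: plain Python loops, no vectorization."""
    occ = list(init)
    total_cost, total_qaly = 0.0, 0.0
    for k in range(horizon):
        disc = (1 + rate) ** (-(k * cycle_len))
        total_qaly += disc * sum(occ[s] * utilities[s] for s in range(6))
        total_cost += disc * sum(occ[s] * recurring[s] for s in range(6))
        nxt = [sum(occ[i] * matrix[i][j] for i in range(6)) for j in range(6)]
        disc_end = (1 + rate) ** (-((k + 1) * cycle_len))
        for s in (4, 5):
            total_cost += disc_end * (nxt[s] - occ[s]) * death_costs[s]
        occ = nxt
    return total_cost, total_qaly


class TestBuildMatrix:
    def test_pci_stable_row_renormalized(self, params):
        m = build_matrix(params, Arm.PCI).matrix
        assert m[0, STATE_INDEX["repeat_cabg"]] == pytest.approx(0.1505 / 0.9996)
        assert m[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_cva_row_remainder(self, params):
        m = build_matrix(params, Arm.CABG).matrix
        i = STATE_INDEX["cva"]
        assert m[i, STATE_INDEX["stable"]] == pytest.approx(0.922)
        assert m[i, STATE_INDEX["cad_death"]] == 0.074
        assert m[i, STATE_INDEX["other_death"]] == 0.004

    def test_repeat_states_are_tunnels_to_their_procedure(self, params):
        cabg = build_matrix(params, Arm.CABG).matrix
        pci = build_matrix(params, Arm.PCI).matrix
        # RepeatCABG row equals the CABG stable row in both arms
        np.testing.assert_allclose(cabg[1], cabg[0])
        np.testing.assert_allclose(pci[1], cabg[0])
        # RepeatPCI row equals the PCI stable row in both arms
        np.testing.assert_allclose(cabg[2], pci[0])
        np.testing.assert_allclose(pci[2], pci[0])

    def test_death_rows_absorbing(self, params):
        for arm in Arm:
            m = build_matrix(params, arm).matrix
            for i in (4, 5):
                expected = np.zeros(6)
                expected[i] = 1.0
                np.testing.assert_array_equal(m[i], expected)

    def test_all_mass_on_stable_never_leaves(self, params):
        p = params.with_values({
            f"prob.cabg.{s}": 1.0 if s == "stable" else 0.0
            for s in ("stable", "repeat_cabg", "repeat_pci", "cva",
                      "cad_death", "other_death")})
        tm = build_matrix(p, Arm.CABG)
        trace = run_cohort(tm, make_rewards(), 20, 0.0)
        assert trace.occupancy[-1, 0] == pytest.approx(1.0)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.eye(6)
        bad[0, 0] = 0.5
        with pytest.raises(MatrixConstructionError):
            TransitionMatrix(arm=Arm.CABG, matrix=bad)


class TestRunCohort:
    def test_zero_rewards_zero_totals(self, params):
        tm = build_matrix(params, Arm.CABG)
        trace = run_cohort(tm, make_rewards(), 25, 0.03)
        assert trace.discounted_cost == 0.0
        assert trace.discounted_qaly == 0.0

    def test_identity_matrix_closed_form(self):
        tm = TransitionMatrix(arm=Arm.CABG, matrix=np.eye(6))
        u = np.zeros(6)
        u[0] = 0.7
        trace = run_cohort(tm, make_rewards(utilities=u), 12, 0.0)
        assert trace.discounted_qaly == pytest.approx(0.7 * 12)

    def test_horizon_zero_rejected(self, params):
        tm = build_matrix(params, Arm.CABG)
        with pytest.raises(ValueError):
            run_cohort(tm, make_rewards(), 0, 0.03)

    def test_matches_matrix_power_oracle(self, params, rng):
        tm = build_matrix(params, Arm.PCI)
        trace = run_cohort(tm, make_rewards(), 100, 0.03)
        for k in (1, 7, 42, 100):
            expected = trace.occupancy[0] @ np.linalg.matrix_power(tm.matrix, k)
            np.testing.assert_allclose(trace.occupancy[k], expected, atol=1e-10)

    def test_matches_brute_force_oracle_table1(self, params):
        """Discounted totals agree with a step-by-step plain-loop recomputation."""
        for arm in Arm:
            tm = build_matrix(params, arm)
            rewards = RewardSet.from_parameters(params, arm, Instrument.SAQ)
            trace = run_cohort(tm, rewards, 30, 0.03)
            init = [1, 0, 0, 0, 0, 0]
            cost, qaly = brute_force_totals(
                tm.matrix.tolist(), rewards.utilities.tolist(),
                rewards.recurring_costs.tolist(), rewards.death_costs.tolist(),
                30, 0.03, 0.5, init)
            assert trace.discounted_cost == pytest.approx(cost, rel=1e-12)
            assert trace.discounted_qaly == pytest.approx(qaly, rel=1e-12)

    def test_conservation_random_matrices(self, rng):
        for _ in range(10):
            tm = TransitionMatrix(arm=Arm.PCI, matrix=random_stochastic_matrix(rng))
            trace = run_cohort(tm, make_rewards(), 50, 0.03)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)

    def test_absorption_monotone(self, params):
        tm = build_matrix(params, Arm.CABG)
        trace = run_cohort(tm, make_rewards(), 60, 0.0)
        dead = trace.occupancy[:, 4:].sum(axis=1)
        assert (np.diff(dead) >= -1e-12).all()
        assert dead[-1] < 1.0

    def test_totals_monotone_in_horizon(self, params):
        tm = build_matrix(params, Arm.CABG)
        rewards = RewardSet.from_parameters(params, Arm.CABG, Instrument.SAQ)
        totals = [run_cohort(tm, rewards, h, 0.03) for h in (5, 10, 20, 40)]
        costs = [t.discounted_cost for t in totals]
        qalys = [t.discounted_qaly for t in totals]
        assert costs == sorted(costs)
        assert qalys == sorted(qalys)  # all CABG SAQ utilities are nonnegative

    def test_totals_antimonotone_in_discount_rate(self, params):
        tm = build_matrix(params, Arm.CABG)
        rewards = RewardSet.from_parameters(params, Arm.CABG, Instrument.SAQ)
        traces = [run_cohort(tm, rewards, 30, r) for r in (0.0, 0.03, 0.10)]
        costs = [t.discounted_cost for t in traces]
        qalys = [t.discounted_qaly for t in traces]
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)

    def test_half_cycle_correction_averages_endpoints(self, params):
        tm = build_matrix(params, Arm.CABG)
        rewards = RewardSet.from_parameters(params, Arm.CABG, Instrument.SAQ)
        plain = run_cohort(tm, rewards, 30, 0.0)
        hcc = run_cohort(tm, rewards, 30, 0.0, half_cycle_correction=True)
        expected = 0.5 * (plain.occupancy[:-1] + plain.occupancy[1:]) @ rewards.utilities
        assert hcc.discounted_qaly == pytest.approx(expected.sum())


class TestCompareArms:
    def test_identical_parameters_identical_traces(self, params):
        updates = {}
        for s in ("stable", "repeat_cabg", "repeat_pci", "cva", "cad_death",
                  "other_death"):
            updates[f"prob.pci.{s}"] = params.value(f"prob.cabg.{s}")
            updates[f"cost.pci.{s}"] = params.value(f"cost.cabg.{s}")
        for s in ("stable", "repeat_cabg", "repeat_pci", "cva"):
            updates[f"util.saq.pci.{s}"] = params.value(f"util.saq.cabg.{s}")
        p = params.with_values(updates)
        cabg, pci = compare_arms(p, Instrument.SAQ)
        np.testing.assert_allclose(cabg.occupancy, pci.occupancy)
        assert cabg.discounted_cost == pytest.approx(pci.discounted_cost)
        assert cabg.discounted_qaly == pytest.approx(pci.discounted_qaly)

    def test_one_cycle_hand_computation(self, params):
        settings = AnalysisSettings(horizon_cycles=1)
        cabg, pci = compare_arms(params, Instrument.SAQ, settings)
        # cycle 0: whole cohort in Stable, undiscounted (factor 1)
        assert cabg.cycle_qaly[0] == pytest.approx(0.135)
        m = build_matrix(params, Arm.CABG).matrix
        death_inflow_cost = (m[0, 4] * 3931 + m[0, 5] * 5700) * 1.03 ** -0.5
        assert cabg.discounted_cost == pytest.approx(2426 + death_inflow_cost)
        assert pci.cycle_qaly[0] == pytest.approx(0.063)

    def test_cabg_more_effective_at_default_settings(self, params):
        for inst in Instrument:
            cabg, pci = compare_arms(params, inst)
            assert cabg.discounted_qaly > pci.discounted_qaly

    def test_trace_csv_round_trip(self, params, tmp_path):
        cabg, _ = compare_arms(params, Instrument.SAQ)
        path = tmp_path / "trace.csv"
        cabg.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert len(df) == cabg.horizon_cycles + 1
        assert df["cum_discounted_cost"].iloc[-1] == pytest.approx(cabg.discounted_cost)
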