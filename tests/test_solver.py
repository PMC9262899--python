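"""Static optimization: closed forms, oracle equivalence, conservation."""

import numpy as np
import pytest

from coordsim.hill import MusculotendonParams
from coordsim.model import MusclePath, PlanarModel
from coordsim.solver import (
    ObjectiveSpec,
    brute_force_oracle,
    solve_timestep,
    solve_trial,
)
from coordsim.synth import GaitTrial


def toy_model(n_muscles=2, arm=0.05, f_o=1000.0, names=None,
              gastroc=()) -> PlanarModel:
    """Identical parallel muscles on a single (ankle) DOF."""
    names = names or [f"m{i}" for i in range(n_muscles)]
    muscles = []
    for name in names:
        p = MusculotendonParams(name, f_o, 0.10, 0.20, 0.0)
        path = MusclePath(
            muscle=name,
            dof_moment_arms={"ankle_plantarflexion": (arm, 0.0, 0.0)},
            l_mtu_ref=0.30,
        )
        muscles.append((p, path))
    return PlanarModel(
        muscles=muscles,
        groups={"gastrocnemius": tuple(gastroc)},
        dofs=("ankle_plantarflexion",),
    )


Q0 = {"ankle_plantarflexion": 0.0}


class TestClosedForms:
    def test_single_muscle_inversion(self):
        """One muscle, one DOF: a = (M/r - c0) / c1 exactly."""
        m = toy_model(1)
        M = np.array([20.0])
        a, res, fibers, forces, _, _ = solve_timestep(
            m, Q0, M, np.zeros(1), ObjectiveSpec("natural")
        )
        # at reference posture c0 = 0 and c1 = f_o (fiber at optimum, no penn)
        assert a[0] == pytest.approx(20.0 / (0.05 * 1000.0), rel=1e-8)
        assert res == pytest.approx(0.0, abs=1e-9)

    def test_identical_agonists_share_equally(self):
        m = toy_model(2)
        a, *_ = solve_timestep(
            m, Q0, np.array([30.0]), np.zeros(2), ObjectiveSpec("natural")
        )
        assert a[0] == pytest.approx(a[1], rel=1e-9)

    def test_avoidance_lagrange_ratio(self):
        """Two-muscle plantarflexor toy with weight 100 on one muscle:
        stationarity gives an exact 1:100 activation split."""
        m = toy_model(2, names=["gasmed", "soleus"], gastroc=("gasmed",))
        a, *_ = solve_timestep(
            m, Q0, np.array([25.0]), np.zeros(2),
            ObjectiveSpec("gastroc_avoidance", gastroc_weight=100.0),
        )
        assert a[0] / a[1] == pytest.approx(1.0 / 100.0, rel=1e-6)


class TestOracle:
    @pytest.mark.parametrize("objective", [
        ObjectiveSpec("natural"),
        ObjectiveSpec("gastroc_avoidance", gastroc_weight=100.0),
    ])
    def test_matches_grid_search(self, objective):
        m = toy_model(2, names=["gasmed", "soleus"], gastroc=("gasmed",))
        M = np.array([30.0])
        a, *_rest = solve_timestep(m, Q0, M, np.zeros(2), objective)
        grid = brute_force_oracle(m, Q0, M, np.zeros(2), objective,
                                  grid_step=1e-3)
        assert grid is not None
        assert np.all(np.abs(a - grid) <= 1e-3 + 1e-9)
        # the oracle never beats the QP
        w = objective.muscle_weights(m)
        assert np.sum(w * a**2) <= np.sum(w * grid**2) + 1e-12

    def test_infeasible_moment_flagged(self):
        m = toy_model(2)
        # total capacity is 2 * 1000 N * 0.05 m = 100 N*m
        grid = brute_force_oracle(
            m, Q0, np.array([150.0]), np.zeros(2), ObjectiveSpec("natural"),
            grid_step=0.05,
        )
        assert grid is None

    def test_three_muscle_objective_equivalence(self):
        m = toy_model(3)
        M = np.array([40.0])
        obj = ObjectiveSpec("natural")
        a, *_ = solve_timestep(m, Q0, M, np.zeros(3), obj)
        grid = brute_force_oracle(m, Q0, M, np.zeros(3), obj, grid_step=5e-3)
        assert np.sum(a**2) <= np.sum(grid**2) + 1e-4
        assert abs(np.sum(a**2) - np.sum(grid**2)) < 1e-3


class TestTrialSolve:
    def test_zero_moment_trial_rests(self):
        """No joint moments at the reference posture: every activation and
        reserve is zero."""
        m = toy_model(2)
        T = 4
        trial = GaitTrial(
            t=np.arange(T) * 0.01,
            q={"ankle_plantarflexion": np.zeros(T)},
            m_id={"ankle_plantarflexion": np.zeros(T)},
            stance_mask=np.ones(T, bool),
            interseg_axial=np.zeros(T),
            bodyweight=700.0,
        )
        sol = solve_trial(m, trial, ObjectiveSpec("natural"))
        assert np.all(np.abs(sol.activations) < 1e-9)
        assert np.all(np.abs(sol.reserve_torques) < 1e-9)

    def test_deterministic_resolve(self, model, trial_truth):
        trial, _ = trial_truth
        s1 = solve_trial(model, trial, ObjectiveSpec("natural"))
        s2 = solve_trial(model, trial, ObjectiveSpec("natural"))
        assert np.array_equal(s1.activations, s2.activations)
        assert np.array_equal(s1.mtu_forces, s2.mtu_forces)

    def test_moment_conservation(self, model, trial_truth, natural_solution):
        """Muscle moments plus reserves match inverse dynamics to 1e-6 N*m
        at every frame."""
        assert np.abs(natural_solution.moment_residuals).max() < 1e-6

    def test_synthetic_trial_needs_no_reserves(self, natural_solution):
        assert np.abs(natural_solution.reserve_torques).max() < 1e-6

    def test_avoidance_shifts_gastroc_to_soleus(
        self, model, trial_truth, natural_solution, avoidance_solution
    ):
        trial, _ = trial_truth
        st = trial.stance_mask
        names = natural_solution.muscle_names

        def stance_mean(sol, muscle):
            return sol.activations[st, names.index(muscle)].mean()

        gas_nat = stance_mean(natural_solution, "gasmed") + stance_mean(
            natural_solution, "gaslat"
        )
        gas_avd = stance_mean(avoidance_solution, "gasmed") + stance_mean(
            avoidance_solution, "gaslat"
        )
        assert gas_avd < gas_nat
        assert stance_mean(avoidance_solution, "soleus") > stance_mean(
            natural_solution, "soleus"
        )

    def test_gastroc_weight_monotone(self, model, trial_truth):
        """Raising the avoidance weight never raises gastrocnemius
        activation (checked frame-wise on an early-trial window)."""
        trial, _ = trial_truth
        names = model.muscle_names
        idx = [names.index("gasmed"), names.index("gaslat")]
        prev = None
        a_prev = np.zeros(len(names))
        k = 45  # a push-off frame where the gastrocnemius is active
        q = {d: float(trial.q[d][k]) for d in model.dofs}
        m_id = np.array([trial.m_id[d][k] for d in model.dofs])
        for wt in (2.0, 10.0, 100.0, 1000.0):
            a, *_ = solve_timestep(
                model, q, m_id, a_prev,
                ObjectiveSpec("gastroc_avoidance", gastroc_weight=wt),
            )
            tot = a[idx].sum()
            if prev is not None:
                assert tot <= prev + 1e-9
            prev = tot


class TestRatioConstraint:
    def test_enforced_frames_within_tolerance(self, emg_informed_report):
        summary = emg_informed_report["summary"]
        assert summary["n_enforced_frames"] > 0
        assert summary["max_ratio_residual"] <= 0.02

    def test_moments_still_conserved(self, emg_informed_report):
        sol = emg_informed_report["condition"].solution
        assert np.abs(sol.moment_residuals).max() < 1e-6
        assert np.abs(sol.reserve_torques).max() < 1e-6
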