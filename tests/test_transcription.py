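"""Time-grid transcription: structure, accuracy, conservation, optimality."""

import numpy as np
import pytest
import scipy.linalg as sla

from flexnets.fixtures import get_fixture
from flexnets.net import FlexibleNet, InitialConditions, bounds_block, conditions, relations_to_parameter_block
from flexnets.structure import build_structure_matrices
from flexnets.transcription import (
    ObjectiveExpr,
    TranscriptionSpec,
    avg_marking,
    build_transcription,
    intensity,
    marking,
    solve,
    steady_state_program,
)


def fig10a_fixed_control(u: float, m0: dict) -> tuple:
    """The controlled-cycle net with its input pinned to a constant."""
    fx = get_fixture("fig10a")
    init = fx.init.with_m0(m0)
    init.lambda0 = {"t1": 0.0, "t2": 0.0, "t3": 0.0, "t4": u}
    init.lambda0_block = bounds_block(fx.net.transitions, init.lambda0)
    return fx, init


def exact_linear_solution(m0: np.ndarray, u: float, t: float) -> np.ndarray:
    """Matrix-exponential oracle for dm/dt = A m + b u of the controlled cycle."""
    A = np.array([[-1, 0, 1], [1, -1, 0], [0, 1, -1]], float)
    b = np.array([-1, 3, -2], float)
    M = np.zeros((4, 4))
    M[:3, :3] = A
    M[:3, 3] = b * u
    return (sla.expm(M * t) @ np.r_[m0, 1.0])[:3]


class TestSpecValidation:
    def test_grid_must_increase_from_zero(self):
        with pytest.raises(ValueError):
            TranscriptionSpec(np.array([0.0, 1.0, 0.5]))
        with pytest.raises(ValueError):
            TranscriptionSpec(np.array([0.5, 1.0]))
        with pytest.raises(ValueError):
            TranscriptionSpec(np.array([0.0]))

    def test_unknown_forced_ids_raise(self, fig6):
        spec = TranscriptionSpec.uniform(1.0, 2, forced_exec={"zz"})
        with pytest.raises(KeyError):
            build_transcription(fig6.net, fig6.init, spec)


def test_constraint_row_tally_matches_closed_form(fig6):
    """Row count of the assembled system equals the per-interval closed form."""
    n = 7
    spec = TranscriptionSpec.uniform(1.0, n, forced_exec=fig6.forced_exec,
                                     forced_active=fig6.forced_active)
    problem = build_transcription(fig6.net, fig6.init, spec)
    net = fig6.net
    nP = len(net.places)
    nT = len(net.all_transitions)
    nEe, nEa = len(net.event_edges), len(net.event_arcs)
    nIa = len(net.intensity_arcs)
    rows_A = sum(net.blocks[h].nrows for h in net.ehandlers)
    rows_C = sum(net.blocks[h].nrows for h in net.shandlers)
    per_interval = (
        nP  # mbar definition
        + nP  # token allocation
        + rows_C
        + nT  # lam balance
        + nIa  # dsigma update
        + nT  # sigma from integral
        + nEe + nEa  # cumulative updates
        + rows_A
        + nT  # action balance
        + nP  # marking balance
    )
    rows_l0 = 0 if fig6.init.lambda0 is not None else fig6.init.lambda0_block.nrows
    expected_eq = nP + n * (per_interval - rows_A - rows_C)
    expected_le = n * (rows_A + rows_C) + rows_l0
    A_eq, b_eq, A_ub, b_ub, _lb, _ub = problem.system.matrices()
    assert A_eq.shape[0] == expected_eq
    assert A_ub.shape[0] == expected_le


class TestOdeLimit:
    def test_one_step_matches_trapezoidal_update(self):
        """A single interval reproduces the implicit-midpoint step of the
        linear ODE (hand-integrated oracle)."""
        dt, u = 0.1, 0.5
        m0 = np.array([1.0, 4.0, 4.0])
        fx, init = fig10a_fixed_control(u, dict(zip(["p1", "p2", "p3"], m0)))
        spec = TranscriptionSpec.uniform(dt, 1, forced_exec=fx.forced_exec,
                                         forced_active=fx.forced_active)
        traj = solve(build_transcription(fx.net, init, spec))
        assert traj.status == "optimal"
        A = np.array([[-1, 0, 1], [1, -1, 0], [0, 1, -1]], float)
        b = np.array([-1, 3, -2], float)
        lhs = np.eye(3) - dt / 2 * A
        rhs = (np.eye(3) + dt / 2 * A) @ m0 + dt * b * u
        m1_expected = np.linalg.solve(lhs, rhs)
        assert np.allclose(traj.m.iloc[1].to_numpy(), m1_expected, atol=1e-7)

    def test_convergence_to_matrix_exponential(self):
        """Error vs the closed-form solution is within 2% at dt=0.1 and
        shrinks when the grid is refined."""
        u = 0.5
        m0 = np.array([1.0, 4.0, 4.0])
        fx, init = fig10a_fixed_control(u, dict(zip(["p1", "p2", "p3"], m0)))
        errs = {}
        for n in (50, 100):
            spec = TranscriptionSpec.uniform(5.0, n, forced_exec=fx.forced_exec,
                                             forced_active=fx.forced_active)
            traj = solve(build_transcription(fx.net, init, spec))
            assert traj.status == "optimal"
            err = max(
                np.abs(
                    traj.m.iloc[k].to_numpy() - exact_linear_solution(m0, u, t)
                ).max()
                for k, t in enumerate(traj.times)
            )
            errs[n] = err / np.abs(m0).max()
        assert errs[50] < 0.02
        assert errs[100] < errs[50]


def test_conservation_rows_in_solution(fig8):
    fx = fig8
    spec = TranscriptionSpec.uniform(
        4.5,
        30,
        objective=ObjectiveExpr.maximize((1.0, avg_marking("p2")), (0.5, avg_marking("p4"))),
        forced_exec=fx.forced_exec,
    )
    problem = build_transcription(fx.net, fx.init, spec)
    traj = solve(problem)
    assert traj.status == "optimal"
    sol = traj._solution
    sm = build_structure_matrices(fx.net)
    n = spec.n_intervals
    m0 = sol["m0"].to_numpy()
    AB_ok = True
    for k in range(n + 1):
        m = sol[f"m@{k}"].to_numpy()
        assert np.abs(m - m0 - sm.Z_m @ sol[f"dm@{k}"].to_numpy()).max() < 1e-6
        assert (
            np.abs(
                sol[f"sigma@{k}"].to_numpy()
                - sol[f"aT@{k}"].to_numpy()
                - sm.Y_sigma @ sol[f"aE@{k}"].to_numpy()
            ).max()
            < 1e-6
        )
    for k in range(n):
        mbar = sol[f"mbar#{k}"].to_numpy()
        assert np.abs(
            mbar - sol[f"muP#{k}"].to_numpy() - sm.Y_m @ sol[f"muE#{k}"].to_numpy()
        ).max() < 1e-6
    # per-interval handler rows imply the cumulative inequality by summation
    from flexnets.net import assemble_global_blocks

    AB = assemble_global_blocks(fx.net, "event")
    dm_n = sol[f"dm@{n}"].to_numpy()
    aE_n = sol[f"aE@{n}"].to_numpy()
    assert np.all(AB.left @ dm_n <= AB.right @ aE_n + 1e-6), AB_ok


def test_refined_grids_converge_to_the_continuous_optimum():
    """Maximal final production on the small combined net.

    The interval-average coupling makes coarse grids *looser*, so the
    optimum decreases monotonically under refinement toward the continuous
    limit: consuming p1 at the maximal rate 3*m[p1] leaves 2*exp(-3) tokens
    at time 1, and doubling yields m[p3] = 4*(1 - exp(-3)).
    """
    fx = get_fixture("fig5")
    limit = 4.0 * (1.0 - np.exp(-3.0))
    values = []
    for n in (2, 4, 8, 16, 32):
        spec = TranscriptionSpec.uniform(
            1.0, n, objective=ObjectiveExpr.maximize((1.0, marking("p3"))),
            forced_exec={"t1"},
        )
        traj = solve(build_transcription(fx.net, fx.init, spec))
        assert traj.status == "optimal"
        values.append(traj.objective_value)
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
    assert all(v >= limit - 1e-7 for v in values)
    assert abs(values[-1] - limit) < abs(values[0] - limit)
    assert values[-1] == pytest.approx(limit, rel=0.02)


def test_constant_objective_is_a_feasibility_problem(fig6):
    spec = TranscriptionSpec.uniform(0.5, 5, forced_exec=fig6.forced_exec,
                                     forced_active=fig6.forced_active)
    traj = solve(build_transcription(fig6.net, fig6.init, spec))
    assert traj.status == "optimal"
    assert np.all(traj.m.to_numpy() >= -1e-9)


def test_impossible_forced_execution_is_infeasible():
    """A transition that produces actions nothing can execute cannot have
    its actions forced to zero."""
    net = FlexibleNet([], ["t1"], name="dangling")
    init = conditions([], ["t1"], {}, {"t1": 1.0})
    spec = TranscriptionSpec.uniform(1.0, 1, forced_exec={"t1"})
    traj = solve(build_transcription(net, init, spec))
    assert traj.status == "infeasible"


class TestSteadyState:
    @pytest.mark.parametrize("sense", ["min", "max"])
    def test_intensity_sum_invariant(self, sense):
        fx = get_fixture("fig4c")
        obj = ObjectiveExpr(sense, [(1.0, intensity(t, 0)) for t in ("t1", "t2", "t3")])
        traj = steady_state_program(fx.net, fx.init, obj)
        assert traj.status == "optimal"
        assert traj.objective_value == pytest.approx(6.0)

    @pytest.mark.parametrize("sense", ["min", "max"])
    def test_marking_sum_invariant(self, sense, fig10a):
        init = InitialConditions(
            m0_block=relations_to_parameter_block(["p1+p2+p3=9"], fig10a.net.places),
            lambda0_block=fig10a.init.lambda0_block,
        )
        obj = ObjectiveExpr(sense, [(1.0, marking(p)) for p in ("p1", "p2", "p3")])
        traj = steady_state_program(
            fig10a.net, init, obj, fig10a.forced_exec, fig10a.forced_active
        )
        assert traj.status == "optimal"
        assert traj.objective_value == pytest.approx(9.0)

    def test_empty_net_trivial_optimum(self):
        net = FlexibleNet([], [], name="empty")
        traj = steady_state_program(net, InitialConditions(), ObjectiveExpr("min"))
        assert traj.status == "optimal"
        assert traj.objective_value == pytest.approx(0.0)
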