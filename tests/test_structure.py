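"""Structure matrices and state-equation polytopes."""

import numpy as np
import pytest
from scipy.optimize import linprog

from flexnets.fixtures import get_fixture
from flexnets.linsys import AffineExpr, Term
from flexnets.net import FlexibleNet
from flexnets.structure import (
    build_structure_matrices,
    event_polytope,
    fn_polytope_at,
    intensity_polytope,
)


class TestStructureMatrices:
    def test_printed_incidence_matrices(self, fig2a):
        sm = build_structure_matrices(fig2a.net)
        assert sm.event_arcs == [("p1", "v1"), ("v1", "p2"), ("p1", "v2"), ("v2", "p3")]
        assert np.array_equal(
            sm.Z_m, [[-1, 0, -1, 0], [0, 1, 0, 0], [0, 0, 0, 1]]
        )
        # printed action-distribution matrix is the identity over the column
        # order ({t1,v2}, {t_fake,v1}); permute ours to that order
        perm = [sm.event_edges.index(e) for e in [("t1", "v2"), ("v1__fake", "v1")]]
        assert sm.transitions == ["t1", "v1__fake"]
        assert np.array_equal(sm.Y_sigma[:, perm], np.eye(2))

    def test_net_with_no_arcs_gives_zero_width_matrices(self):
        net = FlexibleNet(["p1", "p2"], ["t1"])
        sm = build_structure_matrices(net)
        assert sm.Z_m.shape == (2, 0)
        assert sm.Y_sigma.shape == (1, 0)
        assert sm.Y_m.shape == (2, 0)
        assert sm.Z_lambda.shape == (1, 0)

    def test_intensity_matrices_signs(self, fig10a):
        sm = build_structure_matrices(fig10a.net)
        j_in = sm.intensity_arcs.index(("t4", "s4"))  # consumes intensity
        j_out = sm.intensity_arcs.index(("s4", "t1"))  # produces intensity
        t4, t1 = sm.transitions.index("t4"), sm.transitions.index("t1")
        assert sm.Z_lambda[t4, j_in] == -1
        assert sm.Z_lambda[t1, j_out] == 1
        assert sm.Y_m[sm.places.index("p1"), sm.intensity_edges.index(("p1", "s1"))] == 1


class TestEventPolytope:
    def test_unique_observation_solution(self, fig3a):
        """With sigma=(2,1,1) and leftovers (1,0,0) the final marking is pinned."""
        sys = event_polytope(fig3a.net, {"t1": 2, "t2": 1, "t3": 1}, fig3a.init)
        sys.fix("a_T", {"t1": 1.0, "t2": 0.0, "t3": 0.0})
        for p, expected in [("p6", 1.0)]:
            lo = sys.solve_lp(AffineExpr([Term(1.0, "m", p)]), "min")
            hi = sys.solve_lp(AffineExpr([Term(1.0, "m", p)]), "max")
            assert lo.optimal and hi.optimal
            assert lo.value == pytest.approx(expected, abs=1e-7)
            assert hi.value == pytest.approx(expected, abs=1e-7)

    def test_no_actions_no_movement_through_action_handlers(self, fig2a):
        sys = event_polytope(fig2a.net, {"t1": 0}, fig2a.init)
        hi = sys.solve_lp(AffineExpr([Term(1.0, "dm", ("v2", "p3"))]), "max")
        assert hi.value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("amount,feasible", [(1.0, True), (2.0, True), (3.0, False)])
    def test_nondeterministic_production_range(self, fig2a, amount, feasible):
        """One executed action produces between 1 and 2 tokens; cross-checked
        against brute-force enumeration of the integer handler solutions."""
        sys = event_polytope(fig2a.net, {"t1": 1}, fig2a.init)
        sys.set_bounds("dm", ("v2", "p3"), lb=amount, ub=amount)
        sys.fix("a_T", {"t1": 0.0, "v1__fake": 0.0})
        assert sys.solve_lp().optimal is feasible
        # oracle: integer points of the printed block rows with one action
        ok = any(
            a == x and x <= b <= 2 * x and b == amount
            for a in range(3)
            for b in range(4)
            for x in [1]
        )
        assert ok is feasible

    def test_forced_execution_of_unknown_transition_raises(self, fig2a):
        with pytest.raises(KeyError):
            event_polytope(fig2a.net, None, fig2a.init, forced={"nope"})


class TestIntensityPolytope:
    def test_intensity_transfer_worked_example(self):
        """One active token moves one intensity unit from t1 (default 5) to t2."""
        fx = get_fixture("fig4b")
        sys = intensity_polytope(fx.net, init=fx.init)
        sys.fix("mu_E", {("p1", "s1"): 1.0})
        sol = sys.solve_lp()
        assert sol.optimal
        assert sol["lam"]["t1"] == pytest.approx(4.0)
        assert sol["lam"]["t2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("sense", ["min", "max"])
    def test_redistribution_preserves_total_intensity(self, sense):
        fx = get_fixture("fig4c")
        sys = intensity_polytope(fx.net, init=fx.init)
        obj = AffineExpr([Term(1.0, "lam", t) for t in ("t1", "t2", "t3")])
        sol = sys.solve_lp(obj, sense)
        assert sol.optimal
        assert sol.value == pytest.approx(6.0)

    def test_idle_everything_keeps_default_intensities(self):
        fx = get_fixture("fig4b")
        sys = intensity_polytope(fx.net, init=fx.init)
        sys.fix("mu_E", 0.0)
        sol = sys.solve_lp(AffineExpr([Term(1.0, "lam", "t2")]), "max")
        assert sol.optimal
        assert sol["lam"]["t1"] == pytest.approx(5.0)
        assert sol["lam"]["t2"] == pytest.approx(0.0)


class TestFullNetPolytope:
    def test_negative_time_rejected(self):
        fx = get_fixture("fig5")
        with pytest.raises(ValueError):
            fn_polytope_at(fx.net, -1.0, fx.init)

    def test_consuming_arc_pins_integral_at_time_zero(self):
        """The relaxation keeps dsigma free except where sigma >= 0 with a
        zero default intensity forces a consuming arc's integral to zero."""
        fx = get_fixture("fig10a")
        sys = fn_polytope_at(fx.net, 0.0, fx.init)
        sys.fix("lam0", {"t1": 0.0, "t2": 0.0, "t3": 0.0, "t4": 1.0})
        for var, key in [("dsigma", ("t4", "s4")), ("sigma", "t4")]:
            hi = sys.solve_lp(AffineExpr([Term(1.0, var, key)]), "max")
            assert hi.value == pytest.approx(0.0, abs=1e-9)

    def test_max_produced_actions_matches_hand_lp(self):
        """Independent LP over the printed matrices gives the same bound (2:
        executing actions consumes p1 tokens, of which there are two)."""
        fx = get_fixture("fig5")
        sys = fn_polytope_at(fx.net, 1.0, fx.init, forced_exec={"t1"})
        sol = sys.solve_lp(AffineExpr([Term(1.0, "sigma", "t1")]), "max")
        assert sol.optimal

        # oracle: variables (sigma, aE, dm_a, dm_b, m1, m3, dsig); hand-coded
        # rows of the state equations for this one-transition net
        # sigma = aE (forced execution), dm_a = aE (a=x), dm_b <= 2 aE,
        # aE <= dm... marking: m1 = 2 - dm_a - dm_v1 >= 0
        c = np.zeros(4)
        c[0] = -1.0  # maximize sigma
        # x = [sigma, aE, dm_a, dm_v1]
        A_eq = [[1, -1, 0, 0], [0, -1, 1, 0]]
        b_eq = [0, 0]
        A_ub = [[0, 0, 1, 1]]  # consumption <= m0[p1] = 2
        b_ub = [2]
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=(0, None))
        assert sol.value == pytest.approx(-res.fun)
        assert sol.value == pytest.approx(2.0)

    @pytest.mark.parametrize("name", ["fig5", "fig6"])
    def test_forcing_never_enlarges_the_feasible_set(self, name):
        """Random LP objectives: optimum with forced rows <= optimum without."""
        fx = get_fixture(name)
        rng = np.random.default_rng(12345)
        free = fn_polytope_at(fx.net, 1.0, fx.init)
        forced = fn_polytope_at(
            fx.net, 1.0, fx.init, forced_exec=set(fx.net.transitions),
            forced_active=fx.forced_active,
        )
        for _ in range(5):
            w = rng.uniform(-1, 1, size=len(fx.net.places) + len(fx.net.transitions))
            obj = AffineExpr(
                [Term(w[i], "m", p) for i, p in enumerate(fx.net.places)]
                + [
                    Term(w[len(fx.net.places) + j], "lam", t)
                    for j, t in enumerate(fx.net.transitions)
                ]
            )
            hi_free = free.solve_lp(obj, "max")
            hi_forced = forced.solve_lp(obj, "max")
            if hi_forced.optimal and hi_free.optimal:
                assert hi_forced.value <= hi_free.value + 1e-7
            elif hi_forced.status == "unbounded":
                assert hi_free.status == "unbounded"


def test_conservation_rows_hold_in_solutions(fig6):
    sm = build_structure_matrices(fig6.net)
    sys = fn_polytope_at(fig6.net, 2.0, fig6.init, forced_exec=fig6.forced_exec,
                         forced_active=fig6.forced_active)
    sol = sys.solve_lp(AffineExpr([Term(1.0, "m", "p3")]), "max")
    assert sol.optimal
    sigma = sol["sigma"].to_numpy()
    assert np.allclose(sigma, sol["a_T"].to_numpy() + sm.Y_sigma @ sol["a_E"].to_numpy(), atol=1e-7)
    assert np.allclose(
        sol["m"].to_numpy(), sol["m0"].to_numpy() + sm.Z_m @ sol["dm"].to_numpy(), atol=1e-7
    )
    assert np.allclose(
        sol["m"].to_numpy(), sol["mu_P"].to_numpy() + sm.Y_m @ sol["mu_E"].to_numpy(), atol=1e-7
    )
    assert np.allclose(
        sol["lam"].to_numpy(), sol["lam0"].to_numpy() + sm.Z_lambda @ sol["dlam"].to_numpy(), atol=1e-7
    )
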