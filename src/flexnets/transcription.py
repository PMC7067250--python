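"""Time-grid transcription of Flexible-Net dynamics into one LP/QP.

The continuous-time state equations couple the state across time only
through one integral (produced actions are the integral of intensity).  On
a grid ``tau_0 = 0 < tau_1 < ... < tau_n`` we assume piecewise-constant
intensity changes ``dlam_k`` on each interval, which makes that integral
exact::

    dsigma_{k+1} = dsigma_k + dlam_k * (tau_{k+1} - tau_k)
    sigma_{k+1}  = a_T0 + lambda0 * tau_{k+1} + Z_lambda dsigma_{k+1}

and closes the remaining rows per interval/boundary:

* intensity rows use the *interval-average* marking
  ``mbar_k = (m_k + m_{k+1}) / 2 = muP_k + Y_m muE_k`` and
  ``C dlam_k <= D muE_k``, ``lam_k = lambda0 + Z_lambda dlam_k >= 0``
  (midpoint coupling; second-order accurate, and for linear rate laws the
  scheme is the implicit midpoint rule);
* event rows add nonnegative per-interval increments
  ``A d(dm)_k <= B d(aE)_k`` together with the cumulative boundary balances
  ``sigma_k = a_T,k + Y_sigma aE_k`` and ``m_k = m0 + Z_m dm_k``; actions
  produced within an interval may be executed within it (no artificial
  one-step delay);
* uncertain parameters (``lambda0`` inside its block, handler slack inside
  the blocks) are decision variables resolved by the optimizer — the
  optimistic/control reading; robust (adversarial) resolution is out of
  scope.

This is a direct transcription with the same necessary-conditions caveat
as the state equations: every true trajectory satisfies the constraints
(up to the piecewise-constant-intensity approximation), but a solution need
not be realizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linsys import AffineExpr, LinearSystem, Solution, SolverError, Term
from .net import FlexibleNet, InitialConditions, assemble_global_blocks
from .structure import build_structure_matrices

__all__ = [
    "Quantity",
    "ObjectiveExpr",
    "marking",
    "avg_marking",
    "intensity",
    "default_intensity",
    "TranscriptionSpec",
    "TranscriptionProblem",
    "Trajectory",
    "build_transcription",
    "solve",
    "steady_state_program",
]


# ---------------------------------------------------------------------------
# objective language
@dataclass(frozen=True)
class Quantity:
    """An atomic trajectory quantity an objective may reference.

    kind:
      ``m``     marking of a place at a boundary (``at``: index or "final")
      ``mbar``  length-weighted horizon average marking of a place
      ``lam``   average intensity of a transition on an interval
                (``at``: interval index or "final" = last interval)
      ``lam0``  default intensity of a transition (a decision variable)
    """

    kind: str
    target: str
    at: int | str = "final"


def marking(p: str, at: int | str = "final") -> Quantity:
    return Quantity("m", p, at)


def avg_marking(p: str) -> Quantity:
    return Quantity("mbar", p)


def intensity(t: str, at: int | str = "final") -> Quantity:
    return Quantity("lam", t, at)


def default_intensity(t: str) -> Quantity:
    return Quantity("lam0", t)


@dataclass
class ObjectiveExpr:
    """``sense`` of ``sum(coeff * q) + sum((affine)^2) + const``.

    ``squares`` entries are ``(terms, const)`` with ``terms`` a list of
    ``(coeff, Quantity)``; the quadratic part is a sum of squared affine
    expressions, hence convex by construction (and only minimizable).
    """

    sense: str = "min"
    linear: list[tuple[float, Quantity]] = field(default_factory=list)
    squares: list[tuple[list[tuple[float, Quantity]], float]] = field(default_factory=list)
    const: float = 0.0

    @classmethod
    def minimize(cls, *terms, squares=(), const=0.0):
        return cls("min", [_as_term(t) for t in terms], list(squares), const)

    @classmethod
    def maximize(cls, *terms, squares=(), const=0.0):
        return cls("max", [_as_term(t) for t in terms], list(squares), const)


def _as_term(t) -> tuple[float, Quantity]:
    if isinstance(t, Quantity):
        return (1.0, t)
    coeff, q = t
    return (float(coeff), q)


# ---------------------------------------------------------------------------
@dataclass
class TranscriptionSpec:
    """Grid, forced sets and objective of one transcription."""

    boundaries: np.ndarray
    objective: ObjectiveExpr | None = None
    forced_exec: set[str] = field(default_factory=set)
    forced_active: set[str] = field(default_factory=set)
    integrality: bool = False

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size < 2:
            raise ValueError("need at least one interval")
        if self.boundaries[0] != 0.0 or np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be increasing and start at 0")

    @classmethod
    def uniform(cls, t_end: float, n_intervals: int, **kw) -> "TranscriptionSpec":
        return cls(np.linspace(0.0, t_end, n_intervals + 1), **kw)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1


@dataclass
class TranscriptionProblem:
    net: FlexibleNet
    spec: TranscriptionSpec
    system: LinearSystem
    sm: object
    init: InitialConditions

    def quantity_terms(self, coeff: float, q: Quantity) -> list[Term]:
        """Map a symbolic quantity to weighted system-variable terms."""
        n = self.spec.n_intervals
        tau = self.spec.boundaries
        if q.kind == "m":
            k = n if q.at == "final" else int(q.at)
            return [Term(coeff, f"m@{k}", q.target)]
        if q.kind == "mbar":
            total = tau[-1] - tau[0]
            return [
                Term(coeff * (tau[k + 1] - tau[k]) / total, f"mbar#{k}", q.target)
                for k in range(n)
            ]
        if q.kind == "lam":
            k = n - 1 if q.at == "final" else int(q.at)
            return [Term(coeff, f"lam#{k}", q.target)]
        if q.kind == "lam0":
            return [Term(coeff, "lam0", q.target)]
        raise ValueError(f"unknown quantity kind {q.kind!r}")

    def _affine(self, terms, const: float) -> AffineExpr:
        out = AffineExpr(const=const)
        for coeff, q in terms:
            out.terms.extend(self.quantity_terms(coeff, q))
        return out

    def objective_parts(self) -> tuple[AffineExpr, list[AffineExpr], str]:
        obj = self.spec.objective
        if obj is None:
            return AffineExpr(), [], "min"
        linear = self._affine(obj.linear, obj.const)
        squares = [self._affine(terms, c) for terms, c in obj.squares]
        return linear, squares, obj.sense


@dataclass
class Trajectory:
    """Solved trajectory: boundary states, interval averages, provenance."""

    times: np.ndarray
    m: pd.DataFrame  # boundaries x places
    a_T: pd.DataFrame  # boundaries x transitions (real)
    sigma: pd.DataFrame
    lam: pd.DataFrame  # intervals x transitions (average intensities)
    mbar: pd.DataFrame  # intervals x places
    mu_E: pd.DataFrame  # intervals x intensity edges
    lambda0: pd.Series
    objective_value: float | None
    status: str
    solver: str = "scipy/highs"
    controls: pd.DataFrame | None = None  # MPC: per-step applied lambda0

    def to_csv(self, path) -> None:
        """One row per boundary; interval averages sit on the row that ends them."""
        df = pd.DataFrame({"time": self.times})
        for p in self.m.columns:
            df[f"m[{p}]"] = self.m[p].to_numpy()
        for t in self.lam.columns:
            lam = np.concatenate([[np.nan], self.lam[t].to_numpy()])
            df[f"lambda_bar[{t}]"] = lam
        for t in self.a_T.columns:
            df[f"a_T[{t}]"] = self.a_T[t].to_numpy()
        df.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "objective_value": self.objective_value,
            "status": self.status,
            "solver": self.solver,
            "n_boundaries": int(self.times.size),
            "lambda0": {str(k): float(v) for k, v in self.lambda0.items()},
        }


def build_transcription(
    net: FlexibleNet,
    init: InitialConditions,
    spec: TranscriptionSpec,
    a_T0: dict[str, float] | None = None,
) -> TranscriptionProblem:
    """Assemble the full constraint system over the grid.

    ``a_T0`` are actions already available at the start (used when a
    receding-horizon driver rolls a solved state forward); they count as
    produced-at-time-0.
    """
    sm = build_structure_matrices(net)
    AB = assemble_global_blocks(net, "event")
    CD = assemble_global_blocks(net, "intensity")
    sys = LinearSystem()
    n = spec.n_intervals
    tau = spec.boundaries
    nT, nP = len(sm.transitions), len(sm.places)
    nEe, nEa = len(sm.event_edges), len(sm.event_arcs)
    nIa, nIe = len(sm.intensity_arcs), len(sm.intensity_edges)
    I_T, I_P = np.eye(nT), np.eye(nP)

    for t in spec.forced_exec:
        if t not in net.transitions:
            raise KeyError(f"forced transition {t!r} not in net")
    for p in spec.forced_active:
        if p not in net.places:
            raise KeyError(f"forced place {p!r} not in net")

    sys.add_var("m0", sm.places)
    sys.add_var("lam0", sm.transitions)
    a_T0_full = np.array([float((a_T0 or {}).get(t, 0.0)) for t in sm.transitions])

    # boundary blocks
    for k in range(n + 1):
        sys.add_var(f"m@{k}", sm.places)
        sys.add_var(f"sigma@{k}", sm.transitions)
        sys.add_var(f"aT@{k}", sm.transitions)
        sys.add_var(f"aE@{k}", sm.event_edges)
        sys.add_var(f"dm@{k}", sm.event_arcs)
        sys.add_var(f"dsig@{k}", sm.intensity_arcs)
    # interval blocks
    for k in range(n):
        sys.add_var(f"dlam#{k}", sm.intensity_arcs)
        sys.add_var(f"muE#{k}", sm.intensity_edges)
        sys.add_var(f"muP#{k}", sm.places)
        sys.add_var(f"lam#{k}", sm.transitions)
        sys.add_var(f"mbar#{k}", sm.places)
        sys.add_var(f"daE#{k}", sm.event_edges)
        sys.add_var(f"ddm#{k}", sm.event_arcs)

    # initial conditions
    if init.m0 is not None:
        sys.fix("m0", {p: init.m0.get(p, 0.0) for p in sm.places})
    elif init.m0_block is not None and init.m0_block.nrows:
        sys.add_le({"m0": init.m0_block.left}, init.m0_block.right[:, 0])
    for t in net.fake_transitions:
        sys.set_bounds("lam0", t, ub=0.0)
    if init.lambda0 is not None:
        sys.fix("lam0", {t: init.lambda0.get(t, 0.0) for t in net.transitions})
    elif init.lambda0_block is not None and init.lambda0_block.nrows:
        sys.add_le({"lam0": init.lambda0_block.left}, init.lambda0_block.right[:, 0])

    # boundary 0: nothing produced/executed yet beyond carried-over actions
    sys.add_eq({"m@0": I_P, "m0": -I_P}, np.zeros(nP))
    sys.fix("sigma@0", a_T0_full)
    sys.fix("aT@0", a_T0_full)
    sys.fix("aE@0", 0.0)
    sys.fix("dm@0", 0.0)
    sys.fix("dsig@0", 0.0)

    for k in range(n):
        dt = tau[k + 1] - tau[k]
        # interval-average marking, trapezoidal
        sys.add_eq(
            {f"mbar#{k}": I_P, f"m@{k}": -0.5 * I_P, f"m@{k+1}": -0.5 * I_P}, np.zeros(nP)
        )
        # token allocation & intensity handler rows at the average marking
        sys.add_eq({f"mbar#{k}": I_P, f"muP#{k}": -I_P, f"muE#{k}": -sm.Y_m}, np.zeros(nP))
        if CD.nrows:
            sys.add_le({f"dlam#{k}": CD.left, f"muE#{k}": -CD.right}, np.zeros(CD.nrows))
        sys.add_eq(
            {f"lam#{k}": I_T, "lam0": -I_T, f"dlam#{k}": -sm.Z_lambda}, np.zeros(nT)
        )
        # integral of intensity changes and produced actions
        sys.add_eq(
            {f"dsig@{k+1}": np.eye(nIa), f"dsig@{k}": -np.eye(nIa), f"dlam#{k}": -dt * np.eye(nIa)},
            np.zeros(nIa),
        )
        sys.add_eq(
            {f"sigma@{k+1}": I_T, "lam0": -tau[k + 1] * I_T, f"dsig@{k+1}": -sm.Z_lambda},
            a_T0_full,
        )
        # event side: per-interval increments and cumulative balances
        sys.add_eq(
            {f"aE@{k+1}": np.eye(nEe), f"aE@{k}": -np.eye(nEe), f"daE#{k}": -np.eye(nEe)},
            np.zeros(nEe),
        )
        sys.add_eq(
            {f"dm@{k+1}": np.eye(nEa), f"dm@{k}": -np.eye(nEa), f"ddm#{k}": -np.eye(nEa)},
            np.zeros(nEa),
        )
        if AB.nrows:
            sys.add_le({f"ddm#{k}": AB.left, f"daE#{k}": -AB.right}, np.zeros(AB.nrows))
        sys.add_eq(
            {f"sigma@{k+1}": I_T, f"aT@{k+1}": -I_T, f"aE@{k+1}": -sm.Y_sigma}, np.zeros(nT)
        )
        sys.add_eq({f"m@{k+1}": I_P, "m0": -I_P, f"dm@{k+1}": -sm.Z_m}, np.zeros(nP))
        # forced sets
        for p in spec.forced_active:
            sys.set_bounds(f"muP#{k}", p, ub=0.0)
        for t in spec.forced_exec:
            sys.set_bounds(f"aT@{k+1}", t, ub=0.0)

    return TranscriptionProblem(net, spec, sys, sm, init)


def extract_trajectory(problem: TranscriptionProblem, sol: Solution) -> Trajectory:
    spec, sm = problem.spec, problem.sm
    n = spec.n_intervals
    real_T = problem.net.transitions

    def frame(prefix: str, count: int, index) -> pd.DataFrame:
        rows = [sol[f"{prefix}{k}"] for k in range(count)]
        df = pd.DataFrame(rows)
        df.index = range(count)
        return df

    m = frame("m@", n + 1, sm.places)
    a_T = frame("aT@", n + 1, sm.transitions)[real_T]
    sigma = frame("sigma@", n + 1, sm.transitions)[real_T]
    lam = frame("lam#", n, sm.transitions)[real_T]
    mbar = frame("mbar#", n, sm.places)
    mu_E = frame("muE#", n, sm.intensity_edges)
    return Trajectory(
        times=spec.boundaries.copy(),
        m=m,
        a_T=a_T,
        sigma=sigma,
        lam=lam,
        mbar=mbar,
        mu_E=mu_E,
        lambda0=sol["lam0"][real_T],
        objective_value=sol.value,
        status=sol.status,
    )


def solve(problem: TranscriptionProblem, x0: np.ndarray | None = None) -> Trajectory:
    """Solve the transcription; LP when the objective is linear, QP otherwise."""
    linear, squares, sense = problem.objective_parts()
    if problem.spec.integrality:
        raise NotImplementedError("integrality on transcriptions is not supported")
    if squares:
        if sense != "min":
            raise SolverError("quadratic objectives must be minimized (convexity)")
        sol = problem.system.solve_qp(squares, linear, x0=x0)
    else:
        sol = problem.system.solve_lp(linear, sense)
    if not sol.optimal:
        return Trajectory(
            times=problem.spec.boundaries.copy(),
            m=pd.DataFrame(),
            a_T=pd.DataFrame(),
            sigma=pd.DataFrame(),
            lam=pd.DataFrame(),
            mbar=pd.DataFrame(),
            mu_E=pd.DataFrame(),
            lambda0=pd.Series(dtype=float),
            objective_value=None,
            status=sol.status,
        )
    traj = extract_trajectory(problem, sol)
    traj._solution = sol  # keep raw access for diagnostics/tests
    return traj


def steady_state_program(
    net: FlexibleNet,
    init: InitialConditions,
    objective: ObjectiveExpr,
    forced_exec: set[str] = frozenset(),
    forced_active: set[str] = frozenset(),
) -> Trajectory:
    """One-interval transcription pinned to zero net change (``m_1 = m_0``).

    A convenience wrapper for analytic checks of stationary regimes.
    """
    spec = TranscriptionSpec(
        np.array([0.0, 1.0]),
        objective=objective,
        forced_exec=set(forced_exec),
        forced_active=set(forced_active),
    )
    problem = build_transcription(net, init, spec)
    nP = len(problem.sm.places)
    if nP:
        problem.system.add_eq({"m@1": np.eye(nP), "m@0": -np.eye(nP)}, np.zeros(nP))
    return solve(problem)
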