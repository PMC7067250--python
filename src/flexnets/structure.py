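"""Structure matrices and state-equation constraint systems.

The linear state equations are necessary conditions for reachability: every
state reachable by firing event handlers / letting intensity handlers work
satisfies them, but the converse can fail (spurious solutions), because the
equations track cumulative changes, not firing order.  Nothing here claims
sufficiency.

Event net (actions -> tokens)::

    sigma = a_T + Y_sigma a_E      # produced = available + executed
    A dm <= B a_E                  # handler blocks, cumulative
    m = m0 + Z_m dm                # token balance
    J_m m0 <= K_m                  # initial-marking block

Intensity net (tokens -> speeds)::

    m = mu_P + Y_m mu_E            # tokens = idle + active
    C dlam <= D mu_E               # handler blocks
    lam = lambda0 + Z_lam dlam     # speed balance
    J_l lambda0 <= K_l             # default-intensity block

A full Flexible Net at a single instant ``tau`` adds ``sigma = lambda0*tau
+ Z_lam dsigma`` with ``dsigma >= 0`` free: the time integral that defines
``dsigma`` is deliberately relaxed here (single-time relaxation); the
time-linked version lives in :mod:`flexnets.transcription`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linsys import LinearSystem
from .net import ConstraintBlock, FlexibleNet, InitialConditions, assemble_global_blocks

__all__ = [
    "StructureMatrices",
    "build_structure_matrices",
    "event_polytope",
    "intensity_polytope",
    "fn_polytope_at",
]


@dataclass
class StructureMatrices:
    """The four 0/±1 incidence matrices with explicit row/column orders.

    ``Y_sigma`` distributes transition actions over event edges; ``Z_m``
    collects marking changes from event arcs; ``Y_m`` distributes place
    tokens over intensity edges; ``Z_lambda`` collects intensity changes
    from intensity arcs.  Rows: ``Y_sigma``/``Z_lambda`` over transitions
    (real then fake), ``Z_m``/``Y_m`` over places.  Columns follow the
    global handler-grouped element orders of the net.
    """

    Y_sigma: np.ndarray
    Z_m: np.ndarray
    Y_m: np.ndarray
    Z_lambda: np.ndarray
    transitions: list[str]
    places: list[str]
    event_arcs: list[tuple[str, str]]
    event_edges: list[tuple[str, str]]
    intensity_arcs: list[tuple[str, str]]
    intensity_edges: list[tuple[str, str]]


def build_structure_matrices(net: FlexibleNet) -> StructureMatrices:
    """Assemble the incidence matrices from the net structure."""
    trans = net.all_transitions
    places = net.places
    tpos = {t: i for i, t in enumerate(trans)}
    ppos = {p: i for i, p in enumerate(places)}

    ev_arcs, ev_edges = net.event_arcs, net.event_edges
    in_arcs, in_edges = net.intensity_arcs, net.intensity_edges

    Y_sigma = np.zeros((len(trans), len(ev_edges)))
    for j, (t, _v) in enumerate(ev_edges):
        Y_sigma[tpos[t], j] = 1.0

    Z_m = np.zeros((len(places), len(ev_arcs)))
    for j, (u, v) in enumerate(ev_arcs):
        if u in ppos:  # (place, handler): consumption
            Z_m[ppos[u], j] = -1.0
        else:  # (handler, place): production
            Z_m[ppos[v], j] = 1.0

    Y_m = np.zeros((len(places), len(in_edges)))
    for j, (p, _s) in enumerate(in_edges):
        Y_m[ppos[p], j] = 1.0

    Z_lambda = np.zeros((len(trans), len(in_arcs)))
    for j, (u, v) in enumerate(in_arcs):
        if u in tpos:  # (transition, handler): intensity decrease
            Z_lambda[tpos[u], j] = -1.0
        else:  # (handler, transition): intensity increase
            Z_lambda[tpos[v], j] = 1.0

    return StructureMatrices(
        Y_sigma, Z_m, Y_m, Z_lambda, trans, places, ev_arcs, ev_edges, in_arcs, in_edges
    )


def _add_block_le(sys: LinearSystem, block: ConstraintBlock | None, left_var: str, right_var: str) -> None:
    """Rows ``left x_left - right x_right <= 0`` (or ``<= K`` for parameter blocks)."""
    if block is None or block.nrows == 0:
        return
    if block.right_index == ["1"]:
        sys.add_le({left_var: block.left}, block.right[:, 0])
    else:
        sys.add_le({left_var: block.left, right_var: -block.right}, np.zeros(block.nrows))


def _event_rows(
    sys: LinearSystem,
    net: FlexibleNet,
    sm: StructureMatrices,
    init: InitialConditions | None,
    forced: set[str],
) -> None:
    AB = assemble_global_blocks(net, "event")
    nT, nP = len(sm.transitions), len(sm.places)
    for name, idx in (
        ("sigma", sm.transitions),
        ("a_T", sm.transitions),
        ("a_E", sm.event_edges),
        ("dm", sm.event_arcs),
        ("m", sm.places),
        ("m0", sm.places),
    ):
        if not sys.has_var(name):
            sys.add_var(name, idx)
    # sigma = a_T + Y_sigma a_E
    sys.add_eq({"sigma": np.eye(nT), "a_T": -np.eye(nT), "a_E": -sm.Y_sigma}, np.zeros(nT))
    # A dm <= B a_E
    if AB.nrows:
        sys.add_le({"dm": AB.left, "a_E": -AB.right}, np.zeros(AB.nrows))
    # m = m0 + Z_m dm
    sys.add_eq({"m": np.eye(nP), "m0": -np.eye(nP), "dm": -sm.Z_m}, np.zeros(nP))
    init = init or InitialConditions()
    if init.m0 is not None:
        sys.fix("m0", init.m0)
    else:
        _add_block_le(sys, init.m0_block, "m0", "m0")
    for t in forced:
        if t not in sm.transitions:
            raise KeyError(f"forced transition {t!r} is not in the net")
        sys.set_bounds("a_T", t, ub=0.0)


def event_polytope(
    net: FlexibleNet,
    sigma: dict[str, float] | None = None,
    init: InitialConditions | None = None,
    forced: set[str] = frozenset(),
) -> LinearSystem:
    """State-equation system of the event net.

    ``sigma`` pins produced actions of *real* transitions (fake-transition
    components stay free: a silent handler may have fired any number of
    times); ``None`` leaves all of sigma free.  ``forced`` transitions get
    ``a_T = 0`` (all their actions must have been executed).
    """
    sm = build_structure_matrices(net)
    sys = LinearSystem()
    _event_rows(sys, net, sm, init, set(forced))
    if sigma is not None:
        for t, val in sigma.items():
            sys.set_bounds("sigma", t, lb=float(val), ub=float(val))
    return sys


def _intensity_rows(
    sys: LinearSystem,
    net: FlexibleNet,
    sm: StructureMatrices,
    init: InitialConditions | None,
    forced: set[str],
) -> None:
    CD = assemble_global_blocks(net, "intensity")
    nT, nP = len(sm.transitions), len(sm.places)
    for name, idx in (
        ("m", sm.places),
        ("mu_P", sm.places),
        ("mu_E", sm.intensity_edges),
        ("dlam", sm.intensity_arcs),
        ("lam", sm.transitions),
        ("lam0", sm.transitions),
    ):
        if not sys.has_var(name):
            sys.add_var(name, idx)
    # m = mu_P + Y_m mu_E
    sys.add_eq({"m": np.eye(nP), "mu_P": -np.eye(nP), "mu_E": -sm.Y_m}, np.zeros(nP))
    # C dlam <= D mu_E
    if CD.nrows:
        sys.add_le({"dlam": CD.left, "mu_E": -CD.right}, np.zeros(CD.nrows))
    # lam = lam0 + Z_lambda dlam
    sys.add_eq({"lam": np.eye(nT), "lam0": -np.eye(nT), "dlam": -sm.Z_lambda}, np.zeros(nT))
    init = init or InitialConditions()
    for t in net.fake_transitions:
        sys.set_bounds("lam0", t, lb=0.0, ub=0.0)
    if init.lambda0 is not None:
        sys.fix("lam0", {t: init.lambda0.get(t, 0.0) for t in net.transitions})
    else:
        _add_block_le(sys, init.lambda0_block, "lam0", "lam0")
    for p in forced:
        if p not in sm.places:
            raise KeyError(f"forced place {p!r} is not in the net")
        sys.set_bounds("mu_P", p, ub=0.0)


def intensity_polytope(
    net: FlexibleNet,
    m: dict[str, float] | None = None,
    init: InitialConditions | None = None,
    forced: set[str] = frozenset(),
) -> LinearSystem:
    """State-equation system of the intensity net.

    ``m`` pins the marking (``None`` leaves it free); ``forced`` places get
    ``mu_P = 0`` (all their tokens must be active).
    """
    sm = build_structure_matrices(net)
    sys = LinearSystem()
    _intensity_rows(sys, net, sm, init, set(forced))
    if m is not None:
        sys.fix("m", m)
    return sys


def fn_polytope_at(
    net: FlexibleNet,
    tau: float,
    init: InitialConditions | None = None,
    forced_exec: set[str] = frozenset(),
    forced_active: set[str] = frozenset(),
) -> LinearSystem:
    """Single-instant state equations of a full Flexible Net at time ``tau``.

    Combines both layers plus ``sigma = lambda0*tau + Z_lambda dsigma`` with
    ``dsigma >= 0`` otherwise free (the integral defining ``dsigma`` is
    relaxed at a single instant; interval-coupled versions are built by the
    transcription module).
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    sm = build_structure_matrices(net)
    sys = LinearSystem()
    _intensity_rows(sys, net, sm, init, set(forced_active))
    _event_rows(sys, net, sm, init, set(forced_exec))
    nT = len(sm.transitions)
    sys.add_var("dsigma", sm.intensity_arcs)
    # sigma = lambda0 * tau + Z_lambda dsigma
    sys.add_eq(
        {"sigma": np.eye(nT), "lam0": -tau * np.eye(nT), "dsigma": -sm.Z_lambda},
        np.zeros(nT),
    )
    return sys
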