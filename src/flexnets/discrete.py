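"""Discrete execution of event nets.

Event handlers fire in discrete amounts here: enabling witnesses, firings,
integer reachability graphs, and the sets of markings consistent with an
observation (the executed-action counts of a partially observed run).

Two independent routes compute consistent markings:

* :func:`consistent_markings` enumerates all integer solutions of the event
  state equations with produced/leftover actions pinned (LP-bounded
  branch-and-enumerate);
* :func:`markings_after_observations` walks the reachability graph,
  closing the current set under silent firings between observed events.

The state equations are only necessary for reachability, so the graph-based
set is contained in (and can be strictly smaller than) the state-equation
set.

Unit-amount generation: a firing of a handler with transition edges uses
``a_f`` components in {0, 1}, at least one equal to 1; a transition-free
(silent) handler fires with integer token changes of total consumption 1.
Token changes are enumerated over the integer solutions of the handler
block within the available-token bounds.  A silent handler with no input
arc (a pure producer) has no unit firing and never appears in graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .linsys import AffineExpr, LinearSystem, Term
from .net import FlexibleNet, InitialConditions
from .structure import build_structure_matrices, event_polytope

__all__ = [
    "EventState",
    "FiringWitness",
    "InvalidWitness",
    "initial_state",
    "is_enabled",
    "enumerate_unit_witnesses",
    "fire",
    "reachability_graph",
    "consistent_markings",
    "markings_after_observations",
]

# strictness margin standing in for the '> 0' of the enabling definition in
# continuous mode (an LP cannot express a strict inequality)
EPS = 1e-9
_INT_TOL = 1e-6


class InvalidWitness(ValueError):
    """A proposed firing witness violates one of the enabling inequalities."""


@dataclass
class FiringWitness:
    """Amounts of one firing: executed actions per edge, token changes per arc."""

    handler: str
    a_f: pd.Series  # indexed by the handler's transition edges
    dm_f: pd.Series  # indexed by the handler's place arcs


@dataclass
class EventState:
    """Full event-net state (produced, available, executed, changes, marking)."""

    net: FlexibleNet
    sigma: pd.Series  # over all transitions (incl. fakes)
    a_T: pd.Series
    a_E: pd.Series  # over event edges
    dm: pd.Series  # over event arcs
    m: pd.Series  # over places
    m0: pd.Series

    def check(self, atol: float = 1e-9) -> None:
        """Assert nonnegativity and both balance equations against m0."""
        sm = build_structure_matrices(self.net)
        for name in ("sigma", "a_T", "a_E", "dm", "m"):
            if (getattr(self, name) < -atol).any():
                raise ValueError(f"negative component in {name}")
        lhs = self.sigma.to_numpy() - self.a_T.to_numpy() - sm.Y_sigma @ self.a_E.to_numpy()
        if np.abs(lhs).max(initial=0.0) > atol:
            raise ValueError("action balance violated")
        lhs = self.m.to_numpy() - self.m0.to_numpy() - sm.Z_m @ self.dm.to_numpy()
        if np.abs(lhs).max(initial=0.0) > atol:
            raise ValueError("token balance violated")


def initial_state(net: FlexibleNet, sigma: dict[str, float], m0: dict[str, float]) -> EventState:
    """State with ``sigma`` actions produced and available and no firings yet."""
    sig = pd.Series({t: float(sigma.get(t, 0.0)) for t in net.all_transitions})
    mk = pd.Series({p: float(m0.get(p, 0.0)) for p in net.places})
    return EventState(
        net,
        sig,
        sig.copy(),
        pd.Series(0.0, index=pd.Index(net.event_edges, tupleize_cols=False), dtype=float),
        pd.Series(0.0, index=pd.Index(net.event_arcs, tupleize_cols=False), dtype=float),
        mk.copy(),
        mk.copy(),
    )


def _handler(net: FlexibleNet, handler: str):
    if handler not in net.ehandlers:
        raise KeyError(f"unknown event handler {handler!r}")
    h = net.ehandlers[handler]
    block = net.blocks[handler]
    arcs = list(h.arcs.values())
    edges = list(h.edges.values())
    return h, block, arcs, edges


def _dm_boxes(net, block, arcs, state, a_f_vec):
    """Integer ranges for each arc change given fixed executed amounts.

    Upper bounds come from token availability (input arcs) and from an LP
    over the handler block (output arcs); an unbounded LP raises, since the
    enumeration would be infinite.
    """
    ranges = []
    for j, arc in enumerate(arcs):
        if arc[0] in net.places:  # input arc: consumption limited by tokens
            hi = float(state.m[arc[0]])
        else:
            sys = LinearSystem()
            sys.add_var("dm_f", arcs)
            if block.nrows:
                sys.add_le({"dm_f": block.left}, block.right @ a_f_vec)
            for k, other in enumerate(arcs):
                if other[0] in net.places:
                    sys.set_bounds("dm_f", other, ub=float(state.m[other[0]]))
            sol = sys.solve_lp(AffineExpr([Term(1.0, "dm_f", arc)]), "max")
            if sol.status == "unbounded":
                raise ValueError(
                    f"handler {block!r} allows unbounded production on {arc}; "
                    "cannot enumerate integer firings"
                )
            hi = sol.value if sol.optimal else -1.0
        ranges.append(range(0, int(np.floor(hi + _INT_TOL)) + 1))
    return ranges


def enumerate_unit_witnesses(net: FlexibleNet, state: EventState, handler: str) -> list[FiringWitness]:
    """All unit-amount integer firings of ``handler`` at ``state``."""
    _h, block, arcs, edges = _handler(net, handler)
    real_edges = [e for e in edges if e[0] not in net.fake_transitions]
    out: list[FiringWitness] = []

    if real_edges:
        choices = [
            (0, 1) if state.a_T[t] >= 1 - _INT_TOL else (0,) for (t, _v) in real_edges
        ]
        a_f_options = [c for c in itertools.product(*choices) if any(c)]
    else:
        a_f_options = [()]  # silent handler: no actions

    epos = {e: i for i, e in enumerate(edges)}
    for a_f_real in a_f_options:
        a_f_vec = np.zeros(len(edges))
        for e, v in zip(real_edges, a_f_real):
            a_f_vec[epos[e]] = v
        for dm_vals in itertools.product(*_dm_boxes(net, block, arcs, state, a_f_vec)):
            dm_vec = np.array(dm_vals, dtype=float)
            if block.nrows and not np.all(block.left @ dm_vec <= block.right @ a_f_vec + _INT_TOL):
                continue
            if not real_edges:
                consumed = sum(v for arc, v in zip(arcs, dm_vals) if arc[0] in net.places)
                if consumed != 1:
                    continue
            elif a_f_vec.sum() + dm_vec.sum() <= 0:
                continue
            out.append(
                FiringWitness(
                    handler,
                    pd.Series(a_f_vec, index=pd.Index(edges, tupleize_cols=False)),
                    pd.Series(dm_vec, index=pd.Index(arcs, tupleize_cols=False)),
                )
            )
    return out


def is_enabled(state: EventState, handler: str, integrality: bool = True) -> FiringWitness | None:
    """An enabling witness (executed amounts and token changes), or ``None``.

    A witness must execute no more actions than available, satisfy the
    handler block, consume no more tokens than present, and change *some*
    amount (the strict total-change inequality; replaced by ``>= EPS`` in
    continuous mode).
    """
    net = state.net
    if integrality:
        witnesses = enumerate_unit_witnesses(net, state, handler)
        return witnesses[0] if witnesses else None

    _h, block, arcs, edges = _handler(net, handler)
    sys = LinearSystem()
    sys.add_var("a_f", edges)
    sys.add_var("dm_f", arcs)
    for (t, _v) in edges:
        sys.set_bounds("a_f", (t, _v), ub=float(state.a_T[t]))
    for arc in arcs:
        if arc[0] in net.places:
            sys.set_bounds("dm_f", arc, ub=float(state.m[arc[0]]))
    if block.nrows:
        sys.add_le({"dm_f": block.left, "a_f": -block.right}, np.zeros(block.nrows))
    # maximize the total change, capped at 1 so the LP stays bounded (any
    # positive witness can be scaled); enabled iff the optimum clears the
    # strictness margin EPS standing in for '> 0'
    sys.add_le(
        {"a_f": np.ones((1, len(edges))), "dm_f": np.ones((1, len(arcs)))}, np.array([1.0])
    )
    total = AffineExpr(
        [Term(1.0, "a_f", e) for e in edges] + [Term(1.0, "dm_f", a) for a in arcs]
    )
    sol = sys.solve_lp(total, "max")
    if not sol.optimal or sol.value < EPS:
        return None
    return FiringWitness(handler, sol["a_f"], sol["dm_f"])


def fire(state: EventState, handler: str, witness: FiringWitness) -> EventState:
    """Apply one firing; rejects invalid witnesses naming the violated rule."""
    net = state.net
    _h, block, arcs, edges = _handler(net, handler)
    a_f = witness.a_f.reindex(pd.Index(edges, tupleize_cols=False), fill_value=0.0)
    dm_f = witness.dm_f.reindex(pd.Index(arcs, tupleize_cols=False), fill_value=0.0)
    tol = _INT_TOL
    if (a_f < -tol).any() or (dm_f < -tol).any():
        raise InvalidWitness("negative firing amount")
    for (t, _v) in edges:
        if a_f[(t, _v)] > state.a_T[t] + tol:
            raise InvalidWitness(f"not enough available actions in {t}")
    if block.nrows and not np.all(
        block.left @ dm_f.to_numpy() <= block.right @ a_f.to_numpy() + tol
    ):
        raise InvalidWitness(f"handler block of {handler} violated")
    for arc in arcs:
        if arc[0] in net.places and dm_f[arc] > state.m[arc[0]] + tol:
            raise InvalidWitness(f"not enough tokens in {arc[0]}")

    a_T = state.a_T.copy()
    a_E = state.a_E.copy()
    dm = state.dm.copy()
    m = state.m.copy()
    for (t, v) in edges:
        a_T[t] -= a_f[(t, v)]
        a_E[(t, v)] += a_f[(t, v)]
    for arc in arcs:
        dm[arc] += dm_f[arc]
        if arc[0] in net.places:
            m[arc[0]] -= dm_f[arc]
        else:
            m[arc[1]] += dm_f[arc]
    new = EventState(net, state.sigma, a_T, a_E, dm, m, state.m0)
    new.check(atol=1e-7)
    return new


def _node_key(state: EventState) -> tuple:
    m = tuple(int(round(v)) for v in state.m)
    a_T = tuple(int(round(state.a_T[t])) for t in state.net.transitions)
    return (m, a_T)


def reachability_graph(
    net: FlexibleNet,
    sigma: dict[str, float],
    m0: dict[str, float],
    max_nodes: int = 10_000,
) -> nx.MultiDiGraph:
    """BFS closure of ``(m, a_T)`` states under unit-amount integer firings.

    Nodes are ``(marking tuple, available-actions tuple)`` over the net's
    place/transition orders; edges are labelled with the fired handler and
    its token changes.  ``graph.graph["truncated"]`` reports whether the
    ``max_nodes`` cap was hit.
    """
    for vals in (sigma.values(), m0.values()):
        if any(abs(v - round(v)) > _INT_TOL for v in vals):
            raise ValueError("reachability_graph needs integer sigma and m0")
    start = initial_state(net, sigma, m0)
    graph = nx.MultiDiGraph(truncated=False, places=list(net.places), transitions=list(net.transitions))
    key0 = _node_key(start)
    graph.add_node(key0)
    frontier = [(key0, start)]
    seen = {key0}
    while frontier:
        key, state = frontier.pop(0)
        for handler in net.ehandlers:
            for w in enumerate_unit_witnesses(net, state, handler):
                nxt = fire(state, handler, w)
                nkey = _node_key(nxt)
                if nkey not in seen:
                    if len(seen) >= max_nodes:
                        graph.graph["truncated"] = True
                        continue
                    seen.add(nkey)
                    graph.add_node(nkey)
                    frontier.append((nkey, nxt))
                edge_key = (handler, tuple(w.dm_f))
                if not graph.has_edge(key, nkey, key=edge_key):
                    graph.add_edge(key, nkey, key=edge_key, handler=handler)
    return graph


def _enumerate_integer_points(sys: LinearSystem, coords: list[tuple[str, object]]):
    """All integer assignments of the given coordinates over the polytope.

    Depth-first: bound each coordinate by a pair of LPs, branch on every
    integer value, prune infeasible subtrees.  Complete (the polytope must
    be bounded in the listed coordinates, else this raises).
    """
    out: list[dict] = []

    def rec(i: int, fixed: dict) -> None:
        if i == len(coords):
            out.append(dict(fixed))
            return
        name, key = coords[i]
        lo_sol = sys.solve_lp(AffineExpr([Term(1.0, name, key)]), "min")
        if not lo_sol.optimal:
            return
        hi_sol = sys.solve_lp(AffineExpr([Term(1.0, name, key)]), "max")
        if hi_sol.status == "unbounded":
            raise ValueError(f"{name}[{key}] is unbounded; cannot enumerate")
        lo = int(np.ceil(lo_sol.value - _INT_TOL))
        hi = int(np.floor(hi_sol.value + _INT_TOL))
        sl, index = sys._vars[name]
        pos = sl.start + index.index(key)
        old = (sys._lb[pos], sys._ub[pos])
        for val in range(lo, hi + 1):
            sys._lb[pos] = sys._ub[pos] = float(val)
            fixed[(name, key)] = val
            rec(i + 1, fixed)
            del fixed[(name, key)]
        sys._lb[pos], sys._ub[pos] = old
    rec(0, {})
    return out


def consistent_markings(
    net: FlexibleNet,
    sigma: dict[str, float],
    a_T_final: dict[str, float],
    init: InitialConditions,
    integrality: bool = True,
    forced: set[str] = frozenset(),
):
    """Markings admitted by the state equations for a given observation.

    ``sigma`` are the produced and ``a_T_final`` the leftover action counts
    of the real transitions.  Under ``integrality`` the full integer
    solution set is enumerated and the markings returned as a set of tuples
    (ordered like ``net.places``); otherwise the constraint system itself is
    returned as the polytope description.  An infeasible observation yields
    the empty set.
    """
    sys = event_polytope(net, sigma=sigma, init=init, forced=forced)
    for t, val in a_T_final.items():
        sys.set_bounds("a_T", t, lb=float(val), ub=float(val))
    if not integrality:
        return sys
    if init.m0 is None:
        raise ValueError("integer enumeration needs point-valued m0")
    sm = build_structure_matrices(net)
    markings: set[tuple] = set()
    # fake-transition edges never constrain anything (zero column in B and a
    # free sigma component): pin them so the enumeration stays bounded
    for e in net.event_edges:
        if e[0] in net.fake_transitions:
            sys.set_bounds("a_E", e, ub=0.0)
    coords = [("a_E", e) for e in net.event_edges if e[0] not in net.fake_transitions]
    coords += [("dm", a) for a in net.event_arcs]
    points = _enumerate_integer_points(sys, coords)
    m0_vec = np.array([init.m0.get(p, 0.0) for p in net.places])
    for point in points:
        dm_vec = np.array([point.get(("dm", a), 0.0) for a in sm.event_arcs])
        m = m0_vec + sm.Z_m @ dm_vec
        markings.add(tuple(int(round(v)) for v in m))
    return markings


def markings_after_observations(
    net: FlexibleNet,
    sigma: dict[str, float],
    observed: list[str],
    m0: dict[str, float],
) -> set[tuple]:
    """Graph-based consistent markings after an observed transition sequence.

    Each observation executes exactly one action of the named transition
    (through any of its handlers); between observations, and before the
    first, the marking set is closed under silent firings (handlers with no
    real transition edge).  Returns the set of marking tuples.
    """
    silent = [
        hid
        for hid, h in net.ehandlers.items()
        if all(t in net.fake_transitions for (t, _v) in h.edges.values())
    ]

    def closure(states: dict[tuple, EventState]) -> dict[tuple, EventState]:
        frontier = list(states.values())
        while frontier:
            st = frontier.pop()
            for hid in silent:
                for w in enumerate_unit_witnesses(net, st, hid):
                    nxt = fire(st, hid, w)
                    key = _node_key(nxt)
                    if key not in states:
                        states[key] = nxt
                        frontier.append(nxt)
        return states

    start = initial_state(net, sigma, m0)
    current = closure({_node_key(start): start})
    for t in observed:
        if t not in net.transitions:
            raise KeyError(f"observed unknown transition {t!r}")
        nxt_states: dict[tuple, EventState] = {}
        for st in current.values():
            for hid, h in net.ehandlers.items():
                t_edges = [e for e in h.edges.values() if e[0] == t]
                if not t_edges:
                    continue
                for w in enumerate_unit_witnesses(net, st, hid):
                    if any(w.a_f[e] >= 1 - _INT_TOL for e in t_edges) and w.a_f.sum() == 1:
                        nxt = fire(st, hid, w)
                        nxt_states.setdefault(_node_key(nxt), nxt)
        current = closure(nxt_states)
    return {key[0] for key in current}
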