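"""Flexible Net structure: places, transitions, handlers, and constraint blocks.

A Flexible Net is a tripartite graph.  Places (state variables, holding
tokens) and transitions (processes, holding actions) are never connected
directly; instead *event handlers* map executed actions to token changes and
*intensity handlers* map active tokens to speed changes.  Each handler
carries a block of linear inequalities over the labels of its incident arcs
and edges, which is where parameter uncertainty lives: any solution of the
block is an admissible behaviour.

Conventions
-----------
* Event-handler blocks are ``A_k dm_f <= B_k a_f`` with ``A_k`` columns
  indexed by the handler's place arcs and ``B_k`` columns by its transition
  edges.  Intensity-handler blocks are ``C_l dlam_w <= D_l mu_w`` with
  ``C_l`` columns over transition arcs and ``D_l`` columns over place edges.
* An event handler with no transition edge is given a *fake transition*
  (id ``"<handler>__fake"``) whose edge has an all-zero column in ``B``; the
  fake transition has default intensity 0 and no other connections, so it
  changes no semantics but keeps every handler action-indexed.
* An intensity handler with no place edge simply has a zero-width ``D_l``.
* Global matrices stack handler blocks diagonally; columns are ordered by
  handler declaration order, then label declaration order within a handler.
* Arcs are directed pairs ``(src, dst)``; edges are stored as ``(other
  vertex, handler)`` pairs.  Within one net an element pair is unambiguous,
  so matrix indices are these plain tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relations import relation_rows

__all__ = [
    "Handler",
    "ConstraintBlock",
    "InitialConditions",
    "FlexibleNet",
    "NetStructureError",
    "parse_handler_constraints",
    "validate_net",
    "assemble_global_blocks",
    "bounds_block",
]

FAKE_SUFFIX = "__fake"


class NetStructureError(ValueError):
    """The net description violates the tripartite structure rules."""


@dataclass
class Handler:
    """One event or intensity handler with its labelled connections.

    ``arcs`` maps label -> directed pair (event: place<->handler, intensity:
    transition<->handler); ``edges`` maps label -> undirected pair stored as
    ``(partner, handler)``.  Declaration order of the dicts fixes the column
    order of the handler's block.  Empty ``relations`` means the omission
    convention: all labels of the handler are equal.
    """

    id: str
    kind: str  # "event" | "intensity"
    arcs: dict[str, tuple[str, str]] = field(default_factory=dict)
    edges: dict[str, tuple[str, str]] = field(default_factory=dict)
    relations: list[str] = field(default_factory=list)


@dataclass
class ConstraintBlock:
    """A matrix pair ``left x_left <= right x_right`` with explicit column orders."""

    left: np.ndarray
    right: np.ndarray
    left_index: list
    right_index: list

    def __post_init__(self) -> None:
        def coerce(mat, ncols, nrows):
            arr = np.asarray(mat, dtype=float)
            if ncols == 0:
                return np.zeros((arr.shape[0] if arr.ndim == 2 else nrows, 0))
            return arr.reshape(-1, ncols)

        left = np.asarray(self.left, dtype=float)
        nrows = left.shape[0] if left.ndim == 2 else left.size // max(len(self.left_index), 1)
        self.left = coerce(self.left, len(self.left_index), nrows)
        self.right = coerce(self.right, len(self.right_index), self.left.shape[0])
        if self.left.shape[0] != self.right.shape[0]:
            raise ValueError("left/right row counts differ")

    @property
    def nrows(self) -> int:
        return self.left.shape[0]


def bounds_block(index: list[str], bounds: dict[str, tuple[float, float] | float]) -> ConstraintBlock:
    """Interval/point bounds as a parameter block ``J x <= K``.

    ``right_index`` is the single constant column ``["1"]``: parameter blocks
    compare against constants rather than against other variables.
    """
    rows: list[np.ndarray] = []
    k: list[float] = []
    pos = {name: i for i, name in enumerate(index)}
    for name, b in bounds.items():
        lo, hi = (b, b) if np.isscalar(b) else b
        row = np.zeros(len(index))
        row[pos[name]] = 1.0
        rows.append(row)
        k.append(float(hi))
        rows.append(-row)
        k.append(-float(lo))
    J = np.array(rows) if rows else np.zeros((0, len(index)))
    return ConstraintBlock(J, np.array(k).reshape(-1, 1), list(index), ["1"])


def relations_to_parameter_block(relations: list[str], index: list[str]) -> ConstraintBlock:
    """Extra linear constraints over places/transitions, e.g. ``"p1+p2=5"``."""
    J, _R, K = relation_rows(relations, list(index), [], allow_constant=True)
    return ConstraintBlock(J, K.reshape(-1, 1), list(index), ["1"])


@dataclass
class InitialConditions:
    """Initial-marking and default-intensity constraint blocks.

    ``m0_block`` encodes ``J_m m0 <= K_m`` over places; ``lambda0_block``
    encodes ``J_l lambda0 <= K_l`` over (real) transitions.  When the values
    are exact, ``m0``/``lambda0`` hold the point vectors as well.
    """

    m0_block: ConstraintBlock | None = None
    lambda0_block: ConstraintBlock | None = None
    m0: dict[str, float] | None = None
    lambda0: dict[str, float] | None = None
    # raw per-vertex values/intervals and relation strings as declared, kept
    # for lossless serialization (None when built directly from matrices)
    raw: dict | None = None

    def with_m0(self, m0: dict[str, float]) -> "InitialConditions":
        """A copy with the marking pinned to the point vector ``m0``."""
        return InitialConditions(
            m0_block=bounds_block(list(m0), {p: float(v) for p, v in m0.items()}),
            lambda0_block=self.lambda0_block,
            m0={p: float(v) for p, v in m0.items()},
            lambda0=self.lambda0,
        )


def conditions(
    places: list[str],
    transitions: list[str],
    m0: dict[str, tuple[float, float] | float],
    lambda0: dict[str, tuple[float, float] | float],
    m0_relations: list[str] | None = None,
    lambda0_relations: list[str] | None = None,
) -> InitialConditions:
    """Build :class:`InitialConditions` from per-vertex values/intervals.

    Unmentioned places/transitions default to 0 exactly.  Extra cross-vertex
    relations (strings over the vertex ids) are appended to the blocks.
    """
    m0_full = {p: m0.get(p, 0.0) for p in places}
    l0_full = {t: lambda0.get(t, 0.0) for t in transitions}
    mb = bounds_block(places, m0_full)
    lb = bounds_block(transitions, l0_full)
    if m0_relations:
        extra = relations_to_parameter_block(m0_relations, places)
        mb = ConstraintBlock(
            np.vstack([mb.left, extra.left]), np.vstack([mb.right, extra.right]), places, ["1"]
        )
    if lambda0_relations:
        extra = relations_to_parameter_block(lambda0_relations, transitions)
        lb = ConstraintBlock(
            np.vstack([lb.left, extra.left]), np.vstack([lb.right, extra.right]), transitions, ["1"]
        )
    point_m0 = {p: float(v) for p, v in m0_full.items() if np.isscalar(v)} if all(
        np.isscalar(v) for v in m0_full.values()
    ) and not m0_relations else None
    point_l0 = {t: float(v) for t, v in l0_full.items() if np.isscalar(v)} if all(
        np.isscalar(v) for v in l0_full.values()
    ) and not lambda0_relations else None
    raw = {
        "m0": {k: (list(v) if not np.isscalar(v) else float(v)) for k, v in m0.items()},
        "lambda0": {k: (list(v) if not np.isscalar(v) else float(v)) for k, v in lambda0.items()},
        "m0cons": list(m0_relations or []),
        "l0cons": list(lambda0_relations or []),
    }
    return InitialConditions(mb, lb, point_m0, point_l0, raw)


class FlexibleNet:
    """Tripartite net structure plus parsed handler constraint blocks.

    A pure event net has no intensity handlers and vice versa; the combined
    net shares places and transitions between both layers.
    """

    def __init__(
        self,
        places: list[str],
        transitions: list[str],
        ehandlers: list[Handler] = (),
        shandlers: list[Handler] = (),
        name: str = "net",
    ):
        self.name = name
        self.places = list(places)
        self.transitions = list(transitions)
        self.ehandlers: dict[str, Handler] = {h.id: h for h in ehandlers}
        self.shandlers: dict[str, Handler] = {h.id: h for h in shandlers}

        # fake transitions for event handlers with no transition edge
        self.fake_transitions: list[str] = []
        for h in self.ehandlers.values():
            if h.kind != "event":
                raise NetStructureError(f"{h.id} declared in ehandlers but kind={h.kind!r}")
            # drop any fake edge injected by a previous net construction
            for lab in [lab for lab in h.edges if lab.startswith("__")]:
                del h.edges[lab]
            if not h.edges:
                tfake = h.id + FAKE_SUFFIX
                self.fake_transitions.append(tfake)
                h.edges["__" + tfake] = (tfake, h.id)
        for h in self.shandlers.values():
            if h.kind != "intensity":
                raise NetStructureError(f"{h.id} declared in shandlers but kind={h.kind!r}")

        self.blocks: dict[str, ConstraintBlock] = {}
        for h in list(self.ehandlers.values()) + list(self.shandlers.values()):
            self.blocks[h.id] = parse_handler_constraints(h.relations, h.arcs, h.edges, handler=h.id)

    # -- global element orders (handler declaration order, labels within) ----
    @property
    def all_transitions(self) -> list[str]:
        """Real transitions followed by fake ones (row order of Y_sigma and sigma)."""
        return self.transitions + self.fake_transitions

    @property
    def event_arcs(self) -> list[tuple[str, str]]:
        return [a for h in self.ehandlers.values() for a in h.arcs.values()]

    @property
    def event_edges(self) -> list[tuple[str, str]]:
        return [e for h in self.ehandlers.values() for e in h.edges.values()]

    @property
    def intensity_arcs(self) -> list[tuple[str, str]]:
        return [a for h in self.shandlers.values() for a in h.arcs.values()]

    @property
    def intensity_edges(self) -> list[tuple[str, str]]:
        return [e for h in self.shandlers.values() for e in h.edges.values()]

    def handler_of(self, element: tuple[str, str]) -> Handler:
        u, v = element
        hid = v if (v in self.ehandlers or v in self.shandlers) else u
        return self.ehandlers.get(hid) or self.shandlers[hid]


def parse_handler_constraints(
    relations: list[str],
    arcs: dict[str, tuple[str, str]],
    edges: dict[str, tuple[str, str]],
    *,
    handler: str | None = None,
) -> ConstraintBlock:
    """Parse a handler's relation strings into its ``(A_k,B_k)``/``(C_l,D_l)`` block.

    Arc labels form the left columns (token / intensity changes), edge labels
    the right columns (executed actions / active tokens).  ``edges`` may
    include a fake-transition edge under a label starting with ``"__"``;
    such labels are excluded from the omission convention and cannot appear
    in relations, so their column is identically zero.  An empty
    ``relations`` list yields the all-labels-equal block.
    """
    real = [lab for lab in list(arcs) + list(edges) if not lab.startswith("__")]
    specs = list(relations) if relations else [f"{a}={b}" for a, b in zip(real, real[1:])]
    L, R, _k = relation_rows(specs, list(arcs), list(edges), allow_constant=False, handler=handler)
    return ConstraintBlock(L, R, list(arcs.values()), list(edges.values()))


def validate_net(net: FlexibleNet) -> list[str]:
    """Check the tripartite-structure invariants; returns human-readable violations."""
    violations: list[str] = []
    places = set(net.places)
    transitions = set(net.all_transitions)
    handler_ids = set(net.ehandlers) | set(net.shandlers)
    if places & transitions:
        violations.append(f"places and transitions share ids: {sorted(places & transitions)}")
    if handler_ids & (places | transitions):
        violations.append(
            f"handler ids collide with places/transitions: {sorted(handler_ids & (places | transitions))}"
        )
    if len(net.ehandlers) + len(net.shandlers) < len(handler_ids):
        violations.append("an id is used for both an event and an intensity handler")

    seen_pairs: set[frozenset[str]] = set()

    def check(h: Handler, lab: str, pair: tuple[str, str], expect_place: bool, directed: bool) -> None:
        u, v = pair
        if h.id not in (u, v):
            violations.append(f"handler {h.id}: element {lab}={pair} does not touch the handler")
            return
        other = v if u == h.id else u
        if other in places and other in transitions:
            pass
        if expect_place and other not in places:
            kindname = "arc" if directed else "edge"
            violations.append(f"handler {h.id}: {kindname} {lab}={pair} must touch a place, got {other!r}")
        if not expect_place and other not in transitions:
            kindname = "arc" if directed else "edge"
            violations.append(
                f"handler {h.id}: {kindname} {lab}={pair} must touch a transition, got {other!r}"
            )
        fp = frozenset(pair)
        if fp in seen_pairs:
            violations.append(f"duplicate connection between {sorted(fp)}")
        seen_pairs.add(fp)

    for h in net.ehandlers.values():
        for lab, pair in h.arcs.items():
            check(h, lab, pair, expect_place=True, directed=True)
        for lab, pair in h.edges.items():
            check(h, lab, pair, expect_place=False, directed=False)
    for h in net.shandlers.values():
        for lab, pair in h.arcs.items():
            check(h, lab, pair, expect_place=False, directed=True)
        for lab, pair in h.edges.items():
            check(h, lab, pair, expect_place=True, directed=False)
    # direct place-transition connections cannot be expressed in this data
    # model (every element touches its handler); io.load_net rejects such
    # declarations when reading files.
    return violations


def assemble_global_blocks(net: FlexibleNet, kind: str = "event") -> ConstraintBlock:
    """Block-diagonal global ``(A, B)`` (event) or ``(C, D)`` (intensity) matrices."""
    handlers = net.ehandlers if kind == "event" else net.shandlers
    blocks = [net.blocks[hid] for hid in handlers]
    left_index = [e for b in blocks for e in b.left_index]
    right_index = [e for b in blocks for e in b.right_index]
    rows = sum(b.nrows for b in blocks)
    L = np.zeros((rows, len(left_index)))
    R = np.zeros((rows, len(right_index)))
    r0 = c0 = d0 = 0
    for b in blocks:
        L[r0 : r0 + b.nrows, c0 : c0 + len(b.left_index)] = b.left
        R[r0 : r0 + b.nrows, d0 : d0 + len(b.right_index)] = b.right
        r0 += b.nrows
        c0 += len(b.left_index)
        d0 += len(b.right_index)
    return ConstraintBlock(L, R, left_index, right_index)
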