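"""Programmatic constructors for the worked example nets.

Each constructor returns a :class:`Fixture` bundling the net, its initial
conditions and the forced-execution / forced-activity sets under which the
worked analyses run.  These nets are first-class test subjects (and CLI
inputs by name), not ad-hoc test data.

Forced sets follow each example's stated regime: where every action must be
executed, ``forced_exec`` is the whole transition set (including transitions
with no event edge — for those, forcing ``a_T = 0`` pins the produced
actions to zero, which is what turns an edge-less transition into a pure
intensity source); where every token must be active, ``forced_active`` is
the set of places that have at least one intensity edge (a place with no
edge cannot hold active tokens, so forcing it would just empty it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .net import FlexibleNet, Handler, InitialConditions, conditions

__all__ = ["Fixture", "FIXTURES", "get_fixture"]


@dataclass
class Fixture:
    name: str
    net: FlexibleNet
    init: InitialConditions
    forced_exec: set[str] = field(default_factory=set)
    forced_active: set[str] = field(default_factory=set)
    description: str = ""


def _ev(hid: str, arcs: dict, edges: dict, relations: list[str] = ()) -> Handler:
    return Handler(hid, "event", dict(arcs), dict(edges), list(relations))


def _in(hid: str, arcs: dict, edges: dict, relations: list[str] = ()) -> Handler:
    return Handler(hid, "intensity", dict(arcs), dict(edges), list(relations))


def fig1(m0_reading: str = "corrected") -> Fixture:
    """Two-reaction chemical network: R1 produces A, R2 splits A into n B + 4n C.

    The stoichiometric factor n is uncertain in [20, 22]; the R1 rate is in
    [4.5, 5.5] and the R2 rate is proportional to [A] within 10%.  The
    printed initial interval for [A] is internally inconsistent
    ("[9.9,1.1]"); ``m0_reading="corrected"`` uses [0.9, 1.1],
    ``"printed"`` keeps the literal (empty) interval.
    """
    net = FlexibleNet(
        places=["A", "B", "C"],
        transitions=["R1", "R2"],
        ehandlers=[
            _ev("v1", {"a": ("v1", "A")}, {"x": ("R1", "v1")}),
            _ev(
                "v2",
                {"a": ("A", "v2"), "b": ("v2", "B"), "c": ("v2", "C")},
                {"v": ("R2", "v2")},
                ["a=v", "20v<=b<=22v", "c=4b"],
            ),
        ],
        shandlers=[_in("s1", {"r": ("s1", "R2")}, {"a": ("A", "s1")}, ["0.9a<=r<=1.1a"])],
        name="fig1",
    )
    interval = (0.9, 1.1) if m0_reading == "corrected" else (9.9, 1.1)
    init = conditions(net.places, net.transitions, {"A": interval}, {"R1": (4.5, 5.5)})
    return Fixture("fig1", net, init, description="uncertain chemical reaction network")


def fig2a() -> Fixture:
    """Three places, one transition, one silent handler (v1) and one uncertain one (v2)."""
    net = FlexibleNet(
        places=["p1", "p2", "p3"],
        transitions=["t1"],
        ehandlers=[
            _ev("v1", {"a": ("p1", "v1"), "b": ("v1", "p2")}, {}, ["a=b"]),
            _ev(
                "v2",
                {"a": ("p1", "v2"), "b": ("v2", "p3")},
                {"x": ("t1", "v2")},
                ["a=x", "x<=b<=2x"],
            ),
        ],
        name="fig2a",
    )
    init = conditions(net.places, net.transitions, {"p1": 2.0}, {})
    return Fixture("fig2a", net, init, description="basic event net")


def fig3a() -> Fixture:
    """Partially observable event net: observing t2 cannot distinguish v3 from v4."""
    net = FlexibleNet(
        places=["p1", "p2", "p3", "p4", "p5", "p6"],
        transitions=["t1", "t2", "t3"],
        ehandlers=[
            _ev("v1", {"a": ("p1", "v1"), "b": ("v1", "p2")}, {"x": ("t1", "v1")}),
            _ev("v2", {"a": ("p2", "v2"), "b": ("v2", "p3")}, {}),  # silent
            _ev("v3", {"a": ("p3", "v3"), "b": ("v3", "p4")}, {"x": ("t2", "v3")}),
            _ev(
                "v4",
                {"a": ("p2", "v4"), "b": ("v4", "p5")},
                {"x": ("t2", "v4")},
                ["a=x", "x<=b<=2x"],
            ),
            _ev(
                "v5",
                {"a": ("p5", "v5"), "b": ("v5", "p6")},
                {"x": ("t3", "v5")},
                ["a=2x", "b=x"],
            ),
        ],
        name="fig3a",
    )
    init = conditions(net.places, net.transitions, {"p1": 1.0}, {})
    return Fixture("fig3a", net, init, description="partially observable event net")


def fig4a() -> Fixture:
    """One intensity handler producing an uncertain speed of 2-3 per active token."""
    net = FlexibleNet(
        places=["p1"],
        transitions=["t1"],
        shandlers=[_in("s1", {"y": ("s1", "t1")}, {"x": ("p1", "s1")}, ["2x<=y<=3x"])],
        name="fig4a",
    )
    init = conditions(net.places, net.transitions, {"p1": 2.0}, {})
    return Fixture("fig4a", net, init, description="uncertain speed per active token")


def fig4b() -> Fixture:
    """Intensity transfer: active tokens of p1 shift speed from t1 (default 5) to t2."""
    net = FlexibleNet(
        places=["p1"],
        transitions=["t1", "t2"],
        shandlers=[_in("s1", {"y": ("t1", "s1"), "z": ("s1", "t2")}, {"x": ("p1", "s1")})],
        name="fig4b",
    )
    init = conditions(net.places, net.transitions, {"p1": 2.0}, {"t1": 5.0})
    return Fixture("fig4b", net, init, description="intensity transfer")


def fig4c() -> Fixture:
    """Speed of t1 (default 6) redistributed to t2/t3; the total speed is invariant."""
    net = FlexibleNet(
        places=[],
        transitions=["t1", "t2", "t3"],
        shandlers=[
            _in("s1", {"x": ("t1", "s1"), "y": ("s1", "t2")}, {}),
            _in("s2", {"x": ("t1", "s2"), "y": ("s2", "t3")}, {}),
        ],
        name="fig4c",
    )
    init = conditions(net.places, net.transitions, {}, {"t1": 6.0})
    return Fixture("fig4c", net, init, description="intensity redistribution, sum invariant")


def fig4d() -> Fixture:
    """Choice: a p1 token feeds t1 alone or synchronizes with a p2 token for t2."""
    net = FlexibleNet(
        places=["p1", "p2"],
        transitions=["t1", "t2"],
        shandlers=[
            _in("s1", {"y": ("s1", "t1")}, {"x": ("p1", "s1")}, ["x<=y<=2x"]),
            _in(
                "s2",
                {"y": ("s2", "t2")},
                {"x1": ("p1", "s2"), "x2": ("p2", "s2")},
                ["x1=x2", "3x1<=y<=5x1"],
            ),
        ],
        name="fig4d",
    )
    init = conditions(net.places, net.transitions, {"p1": 1.0, "p2": 1.0}, {})
    return Fixture("fig4d", net, init, description="token choice and synchronization")


def fig5() -> Fixture:
    """Full FN: the fig2a event net driven by the fig4a intensity handler."""
    ev = fig2a().net
    net = FlexibleNet(
        places=["p1", "p2", "p3"],
        transitions=["t1"],
        ehandlers=list(ev.ehandlers.values()),
        shandlers=[_in("s1", {"y": ("s1", "t1")}, {"x": ("p1", "s1")}, ["2x<=y<=3x"])],
        name="fig5",
    )
    init = conditions(net.places, net.transitions, {"p1": 2.0}, {})
    return Fixture("fig5", net, init, description="combined event + intensity net")


def fig6() -> Fixture:
    """Linear system with uncertain dynamics.

    dm1/dt = -q - h*m1 + m2 + 2, dm2/dt = q - m2, dm3/dt = h*m1 - 2 with
    q in [1.0, 1.5] (default intensity of t1) and h in [0.9, 1.1] (slope of
    the s3 block).
    """
    net = FlexibleNet(
        places=["p1", "p2", "p3"],
        transitions=["t1", "t2", "t3", "t4"],
        ehandlers=[
            _ev("v1", {"a": ("p1", "v1"), "b": ("v1", "p2")}, {"x": ("t1", "v1")}),
            _ev("v2", {"a": ("p2", "v2"), "b": ("v2", "p1")}, {"x": ("t2", "v2")}),
            _ev("v3", {"a": ("p1", "v3"), "b": ("v3", "p3")}, {"x": ("t3", "v3")}),
            _ev("v4", {"a": ("p3", "v4"), "b": ("v4", "p1")}, {"x": ("t4", "v4")}),
        ],
        shandlers=[
            _in("s2", {"r": ("s2", "t2")}, {"a": ("p2", "s2")}),
            _in("s3", {"r": ("s3", "t3")}, {"a": ("p1", "s3")}, ["0.9a<=r<=1.1a"]),
        ],
        name="fig6",
    )
    init = conditions(
        net.places,
        net.transitions,
        {"p1": 4.0},
        {"t1": (1.0, 1.5), "t4": 2.0},
    )
    return Fixture(
        "fig6",
        net,
        init,
        forced_exec={"t1", "t2", "t3", "t4"},
        forced_active={"p1", "p2"},
        description="linear system with uncertain q, h",
    )


def fig8() -> Fixture:
    """Resource allocation: two pa tokens and one pb token drive three lines.

    t1 turns p1 into p2 at the speed of the pa tokens allocated to s1; t2
    turns p3 into p4 at the speed of pa+pb pairs synchronized by s2; t3
    produces p5 from nothing at the speed of the pb tokens on s3.
    """
    net = FlexibleNet(
        places=["p1", "p2", "p3", "p4", "p5", "pa", "pb"],
        transitions=["t1", "t2", "t3"],
        ehandlers=[
            _ev("v1", {"a": ("p1", "v1"), "b": ("v1", "p2")}, {"x": ("t1", "v1")}),
            _ev("v2", {"a": ("p3", "v2"), "b": ("v2", "p4")}, {"x": ("t2", "v2")}),
            _ev("v3", {"b": ("v3", "p5")}, {"x": ("t3", "v3")}),
        ],
        shandlers=[
            _in("s1", {"y": ("s1", "t1")}, {"a": ("pa", "s1")}),
            _in("s2", {"y": ("s2", "t2")}, {"a": ("pa", "s2"), "b": ("pb", "s2")}),
            _in("s3", {"y": ("s3", "t3")}, {"b": ("pb", "s3")}),
        ],
        name="fig8",
    )
    init = conditions(
        net.places, net.transitions, {"p1": 3.0, "p3": 2.0, "pa": 2.0, "pb": 1.0}, {}
    )
    return Fixture(
        "fig8",
        net,
        init,
        forced_exec={"t1", "t2", "t3"},
        forced_active=set(),
        description="resource allocation with shared pa/pb",
    )


def fig10a() -> Fixture:
    """Controlled cycle p1 -> p2 -> p3 -> p1 with a single input lambda0[t4].

    s4 (y=x, z=2x) converts each unit of intensity taken from t4 into +1 on
    t1 and -2 on t2, so lam[t1] = m1 + u and lam[t2] = m2 - 2u with
    u = lambda0[t4] in [0, 1.5]; lam[t3] = m3.  Forcing t4's (inexecutable)
    actions to zero pins the transfer to consume all of u.
    """
    net = FlexibleNet(
        places=["p1", "p2", "p3"],
        transitions=["t1", "t2", "t3", "t4"],
        ehandlers=[
            _ev("v1", {"a": ("p1", "v1"), "b": ("v1", "p2")}, {"x": ("t1", "v1")}),
            _ev("v2", {"a": ("p2", "v2"), "b": ("v2", "p3")}, {"x": ("t2", "v2")}),
            _ev("v3", {"a": ("p3", "v3"), "b": ("v3", "p1")}, {"x": ("t3", "v3")}),
        ],
        shandlers=[
            _in("s1", {"r": ("s1", "t1")}, {"a": ("p1", "s1")}),
            _in("s2", {"r": ("s2", "t2")}, {"a": ("p2", "s2")}),
            _in("s3", {"r": ("s3", "t3")}, {"a": ("p3", "s3")}),
            _in(
                "s4",
                {"x": ("t4", "s4"), "y": ("s4", "t1"), "z": ("t2", "s4")},
                {},
                ["y=x", "z=2x"],
            ),
        ],
        name="fig10a",
    )
    init = conditions(net.places, net.transitions, {"p3": 9.0}, {"t4": (0.0, 1.5)})
    return Fixture(
        "fig10a",
        net,
        init,
        forced_exec={"t1", "t2", "t3", "t4"},
        forced_active={"p1", "p2", "p3"},
        description="dynamically constrained control action",
    )


FIXTURES = {
    f.__name__: f
    for f in (fig1, fig2a, fig3a, fig4a, fig4b, fig4c, fig4d, fig5, fig6, fig8, fig10a)
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None
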