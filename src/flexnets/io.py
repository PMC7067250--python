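"""Reading and writing nets, analysis specs and results.

Net files are YAML documents (schema in ``docs/net.schema.json``)::

    name: fig2a
    places:
      - {id: p1, m0: 2}          # m0: value, [lo, hi], or omitted (= 0)
      - {id: p2}
    transitions:
      - {id: t1}                 # l0: value or [lo, hi]; omitted = 0
    ehandlers:
      - id: v2
        connect: {a: [p1, v2], b: [v2, p3], x: [t1, v2]}
        relations: ["a=x", "x<=b<=2x"]
    shandlers: []
    m0cons: []                   # extra relations over place ids
    l0cons: []                   # extra relations over transition ids

Each ``connect`` pair touches the handler and one place or transition;
place pairs keep their written direction (arcs), transition pairs of event
handlers and place pairs of intensity handlers are undirected edges.
Objective strings (``"max mbar[p2] + 0.5 mbar[p4]"``,
``"min (m[p1]-1)^2 + (m[p2]-4)^2"``) are parsed into
:class:`~flexnets.transcription.ObjectiveExpr`.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import yaml

from .net import FlexibleNet, Handler, InitialConditions, conditions, validate_net
from .transcription import ObjectiveExpr, Quantity, TranscriptionSpec

__all__ = [
    "NetFileError",
    "load_net",
    "save_net",
    "parse_objective",
    "load_analysis_spec",
    "load_mpc_config",
    "graph_to_dot",
    "markings_to_csv",
    "write_metadata",
]


class NetFileError(ValueError):
    """A net description file violates the schema; message carries context."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise NetFileError(msg)


def load_net(path) -> tuple[FlexibleNet, InitialConditions]:
    """Read a net + initial conditions from a YAML file (or file object)."""
    if hasattr(path, "read"):
        doc = yaml.safe_load(path.read())
        name = "net"
    else:
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        name = Path(path).stem
    _require(isinstance(doc, dict), "file is empty or not a YAML mapping")
    for key in ("places", "transitions"):
        _require(key in doc, f"missing required section {key!r}")

    def ids(section, kind):
        out = []
        for item in doc.get(section) or []:
            _require(isinstance(item, dict) and "id" in item, f"every {kind} needs an 'id'")
            out.append(str(item["id"]))
        return out

    places = ids("places", "place")
    transitions = ids("transitions", "transition")
    pset, tset = set(places), set(transitions)

    def build_handler(item, kind: str) -> Handler:
        _require(isinstance(item, dict) and "id" in item, f"every {kind} handler needs an 'id'")
        hid = str(item["id"])
        connect = item.get("connect") or {}
        _require(isinstance(connect, dict), f"handler {hid}: 'connect' must be a mapping")
        arcs: dict[str, tuple[str, str]] = {}
        edges: dict[str, tuple[str, str]] = {}
        for lab, pair in connect.items():
            _require(
                isinstance(pair, (list, tuple)) and len(pair) == 2,
                f"handler {hid}: label {lab!r} must map to a pair",
            )
            u, v = str(pair[0]), str(pair[1])
            _require(hid in (u, v), f"handler {hid}: element {lab!r}={pair} does not touch the handler")
            other = v if u == hid else u
            _require(
                not (u in pset | tset and v in pset | tset),
                f"direct place-transition connection {pair} is not allowed",
            )
            if other in pset:
                (arcs if kind == "event" else edges)[str(lab)] = (u, v) if kind == "event" else (other, hid)
            elif other in tset:
                (edges if kind == "event" else arcs)[str(lab)] = (other, hid) if kind == "event" else (u, v)
            else:
                raise NetFileError(f"handler {hid}: label {lab!r} touches unknown vertex {other!r}")
        relations = [str(r) for r in item.get("relations") or []]
        return Handler(hid, kind, arcs, edges, relations)

    ehandlers = [build_handler(item, "event") for item in doc.get("ehandlers") or []]
    shandlers = [build_handler(item, "intensity") for item in doc.get("shandlers") or []]
    net = FlexibleNet(places, transitions, ehandlers, shandlers, name=str(doc.get("name", name)))
    problems = validate_net(net)
    if problems:
        raise NetFileError("; ".join(problems))

    def vals(section, key):
        out = {}
        for item in doc.get(section) or []:
            if key in item and item[key] is not None:
                v = item[key]
                out[str(item["id"])] = tuple(float(x) for x in v) if isinstance(v, (list, tuple)) else float(v)
        return out

    init = conditions(
        places,
        transitions,
        vals("places", "m0"),
        vals("transitions", "l0"),
        [str(r) for r in doc.get("m0cons") or []],
        [str(r) for r in doc.get("l0cons") or []],
    )
    return net, init


def save_net(net: FlexibleNet, init: InitialConditions, path) -> None:
    """Serialize back to the YAML schema (lossless for nets built via the API)."""
    raw = init.raw or {"m0": init.m0 or {}, "lambda0": init.lambda0 or {}, "m0cons": [], "l0cons": []}

    def vertex(vid, key, store):
        item = {"id": vid}
        if vid in store and store[vid] != 0.0 and store[vid] != [0.0, 0.0]:
            item[key] = store[vid]
        return item

    def handlers(hs):
        out = []
        for h in hs.values():
            connect = {}
            for lab, (u, v) in list(h.arcs.items()) + list(h.edges.items()):
                if lab.startswith("__"):
                    continue  # fake-transition edge is an internal artifact
                connect[lab] = [u, v]
            out.append({"id": h.id, "connect": connect, "relations": list(h.relations)})
        return out

    doc = {
        "name": net.name,
        "places": [vertex(p, "m0", raw["m0"]) for p in net.places],
        "transitions": [vertex(t, "l0", raw["lambda0"]) for t in net.transitions],
        "ehandlers": handlers(net.ehandlers),
        "shandlers": handlers(net.shandlers),
        "m0cons": raw.get("m0cons", []),
        "l0cons": raw.get("l0cons", []),
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# objective strings
_OBJ_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>\^2|[+\-*()\[\]]))"
)

_KINDS = {"m": "m", "mbar": "mbar", "lam": "lam", "lambar": "lam", "lam0": "lam0", "lambda0": "lam0"}


def _obj_tokens(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        match = _OBJ_TOKEN.match(text, pos)
        if match is None:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"objective: unexpected character {text[pos]!r}")
        pos = match.end()
        for kind in ("num", "name", "op"):
            if match.group(kind) is not None:
                tokens.append((kind, match.group(kind)))
    return tokens


def parse_objective(text: str) -> ObjectiveExpr:
    """Parse ``min/max <affine and squared-affine sum>`` into an ObjectiveExpr."""
    tokens = _obj_tokens(text)
    if not tokens or tokens[0][0] != "name" or tokens[0][1] not in ("min", "max"):
        raise ValueError("objective must start with 'min' or 'max'")
    sense = tokens[0][1]
    toks = tokens[1:]
    i = 0

    def peek():
        return toks[i] if i < len(toks) else (None, None)

    def eat(kind=None, value=None):
        nonlocal i
        k, v = peek()
        if k is None or (kind and k != kind) or (value and v != value):
            raise ValueError(f"objective: expected {value or kind}, got {v!r}")
        i += 1
        return v

    def atom():
        """quantity | number | parenthesised affine group (possibly ^2)."""
        k, v = peek()
        if k == "num":
            return {"const": float(eat("num")), "linear": [], "square": None}
        if k == "name":
            name = eat("name")
            if name not in _KINDS:
                raise ValueError(f"objective: unknown quantity {name!r}")
            eat("op", "[")
            target = eat("name")
            eat("op", "]")
            return {"const": 0.0, "linear": [(1.0, Quantity(_KINDS[name], target))], "square": None}
        if (k, v) == ("op", "("):
            eat("op", "(")
            inner = affine_sum()
            eat("op", ")")
            k2, v2 = peek()
            if (k2, v2) == ("op", "^2"):
                eat("op", "^2")
                return {"const": 0.0, "linear": [], "square": (inner["linear"], inner["const"])}
            return {"const": inner["const"], "linear": inner["linear"], "square": None}
        raise ValueError(f"objective: unexpected token {v!r}")

    def product():
        coeff = 1.0
        k, v = peek()
        if k == "num":
            nxt = toks[i + 1] if i + 1 < len(toks) else (None, None)
            if nxt == ("op", "*") or nxt[0] == "name" or nxt == ("op", "("):
                coeff = float(eat("num"))
                if peek() == ("op", "*"):
                    eat("op", "*")
            else:
                return {"const": float(eat("num")), "linear": [], "square": None}
        a = atom()
        if a["square"] is not None:
            if coeff < 0:
                raise ValueError("negative coefficient on a squared term is nonconvex")
            s = np.sqrt(coeff)
            terms, const = a["square"]
            return {
                "const": 0.0,
                "linear": [],
                "square": ([(s * c, q) for c, q in terms], s * const),
            }
        return {
            "const": coeff * a["const"],
            "linear": [(coeff * c, q) for c, q in a["linear"]],
            "square": None,
        }

    def affine_sum():
        out = {"const": 0.0, "linear": []}
        sign = 1.0
        first = True
        while True:
            k, v = peek()
            if (k, v) == ("op", "-"):
                eat()
                sign = -1.0
            elif (k, v) == ("op", "+"):
                eat()
                sign = 1.0
            elif not first:
                return out
            p = product()
            if p["square"] is not None:
                raise ValueError("nested squared terms are not affine")
            out["const"] += sign * p["const"]
            out["linear"].extend([(sign * c, q) for c, q in p["linear"]])
            sign, first = 1.0, False
            k, v = peek()
            if k is None or (k, v) == ("op", ")"):
                return out

    expr = ObjectiveExpr(sense)
    sign = 1.0
    while i < len(toks):
        k, v = peek()
        if (k, v) == ("op", "+"):
            eat()
            sign = 1.0
            continue
        if (k, v) == ("op", "-"):
            eat()
            sign = -1.0
            continue
        p = product()
        if p["square"] is not None:
            if sign < 0:
                raise ValueError("subtracting a squared term is nonconvex")
            expr.squares.append(p["square"])
        else:
            expr.const += sign * p["const"]
            expr.linear.extend([(sign * c, q) for c, q in p["linear"]])
        sign = 1.0
    return expr


def _forced_sets(doc: dict, net: FlexibleNet) -> tuple[set[str], set[str]]:
    fe = doc.get("forced_exec", [])
    fa = doc.get("forced_active", [])
    if fe == "all":
        fe = list(net.transitions)
    if fa == "all":
        fa = list(net.places)
    if fa == "connected":
        fa = sorted({p for (p, _s) in net.intensity_edges})
    return set(fe or []), set(fa or [])


def load_analysis_spec(path, net: FlexibleNet) -> TranscriptionSpec:
    """Read a single-program analysis spec (grid + objective + forced sets)."""
    doc = yaml.safe_load(Path(path).read_text())
    _require(isinstance(doc, dict), "analysis spec must be a YAML mapping")
    if "boundaries" in doc:
        boundaries = np.asarray(doc["boundaries"], dtype=float)
    else:
        boundaries = np.linspace(0.0, float(doc["t_end"]), int(doc["n_intervals"]) + 1)
    fe, fa = _forced_sets(doc, net)
    objective = parse_objective(doc["objective"]) if doc.get("objective") else None
    return TranscriptionSpec(boundaries, objective=objective, forced_exec=fe, forced_active=fa)


def load_mpc_config(path, net: FlexibleNet):
    """Read an MPC config; returns an :class:`flexnets.mpc.MPCConfig`."""
    from .mpc import MPCConfig

    doc = yaml.safe_load(Path(path).read_text())
    _require(isinstance(doc, dict), "MPC config must be a YAML mapping")
    fe, fa = _forced_sets(doc, net)
    return MPCConfig(
        dt=float(doc["dt"]),
        n_steps=int(doc["n_steps"]),
        horizon=int(doc.get("horizon", 1)),
        objective=parse_objective(doc["objective"]),
        forced_exec=fe,
        forced_active=fa,
        tol=float(doc.get("tol", 1e-4)),
        window=int(doc.get("window", 10)),
        stop_on_convergence=bool(doc.get("stop_on_convergence", True)),
    )


# ---------------------------------------------------------------------------
# result exports
def graph_to_dot(graph) -> str:
    """Reachability graph in DOT; nodes show the (marking, available) pair."""
    lines = ["digraph reachability {"]

    def label(node):
        m, a_T = node
        return f"m={','.join(map(str, m))}|aT={','.join(map(str, a_T))}"

    index = {node: f"n{i}" for i, node in enumerate(graph.nodes)}
    for node, nid in index.items():
        lines.append(f'  {nid} [label="{label(node)}"];')
    for u, v, data in graph.edges(data=True):
        lines.append(f'  {index[u]} -> {index[v]} [label="{data.get("handler", "")}"];')
    lines.append("}")
    return "\n".join(lines)


def markings_to_csv(markings, places: list[str]) -> str:
    """One CSV row per marking, columns in place order."""
    lines = [",".join(places)]
    for m in sorted(markings):
        lines.append(",".join(str(v) for v in m))
    return "\n".join(lines) + "\n"


def write_metadata(path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, default=float) + "\n")
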