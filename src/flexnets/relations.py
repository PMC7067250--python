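"""Parsing of linear relation strings.

Handler behaviour and parameter uncertainty are declared as human-readable
chains of linear relations over labels, e.g. ``"a=b"``, ``"x<=b<=2x"``,
``"0.9a<=r<=1.1a"`` or ``"m0_A + m0_B = 5"``.  A chain of ``n`` expressions
joined by ``=``/``<=``/``>=`` is split into ``n-1`` pairwise relations; every
equality contributes two inequality rows (lhs<=rhs, then rhs<=lhs) so that
all blocks are pure ``<=`` systems.

Grammar: expressions are sums of terms; a term is a decimal coefficient, a
label, or a coefficient times a label with implicit (``2x``) or explicit
(``2*x``) multiplication.  Anything non-linear is rejected.
"""

from __future__ import annotations

import re
from typing import Iterable

import numpy as np

__all__ = ["RelationError", "parse_expression", "parse_chain", "relation_rows"]


class RelationError(ValueError):
    """A relation string could not be interpreted.

    Carries the offending string and, when known, the handler it belongs to.
    """

    def __init__(self, message: str, relation: str | None = None, handler: str | None = None):
        self.relation = relation
        self.handler = handler
        where = ""
        if handler is not None:
            where += f" [handler {handler!r}]"
        if relation is not None:
            where += f" in {relation!r}"
        super().__init__(message + where)


_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|=|\+|-|\*))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None:
            if text[pos:].strip() == "":
                break
            raise RelationError(f"unexpected character {text[pos]!r}", text)
        pos = match.end()
        for kind in ("num", "name", "op"):
            if match.group(kind) is not None:
                tokens.append((kind, match.group(kind)))
                break
    return tokens


def parse_expression(tokens: list[tuple[str, str]], relation: str | None = None) -> dict[str | None, float]:
    """Parse a token stream into ``{label: coeff}``; the ``None`` key is the constant."""
    coeffs: dict[str | None, float] = {}
    sign = 1.0
    expect_term = True
    i = 0
    n = len(tokens)
    while i < n:
        kind, value = tokens[i]
        if kind == "op" and value in "+-":
            if expect_term and value == "-":
                sign = -sign
            elif expect_term:
                pass
            else:
                sign = 1.0 if value == "+" else -1.0
            expect_term = True
            i += 1
            continue
        if not expect_term:
            raise RelationError("missing operator between terms", relation)
        if kind == "num":
            coeff = sign * float(value)
            # optional "*" and/or adjacent label -> linear term
            j = i + 1
            if j < n and tokens[j] == ("op", "*"):
                j += 1
                if j >= n or tokens[j][0] != "name":
                    raise RelationError("dangling '*'", relation)
            if j < n and tokens[j][0] == "name":
                label = tokens[j][1]
                coeffs[label] = coeffs.get(label, 0.0) + coeff
                i = j + 1
            else:
                coeffs[None] = coeffs.get(None, 0.0) + coeff
                i += 1
        elif kind == "name":
            # a bare label; reject label*label (nonlinear)
            if i + 1 < n and tokens[i + 1][0] == "name":
                raise RelationError("nonlinear term (two adjacent labels)", relation)
            if i + 1 < n and tokens[i + 1] == ("op", "*"):
                raise RelationError("nonlinear term (label * ...)", relation)
            coeffs[value] = coeffs.get(value, 0.0) + sign
            i += 1
        else:
            raise RelationError(f"unexpected token {value!r}", relation)
        sign = 1.0
        expect_term = False
    if expect_term:
        raise RelationError("empty expression", relation)
    return coeffs


def parse_chain(relation: str) -> list[tuple[dict[str | None, float], str, dict[str | None, float]]]:
    """Split ``e1 <= e2 = e3 ...`` into pairwise ``(lhs, op, rhs)`` triples."""
    tokens = _tokenize(relation)
    parts: list[list[tuple[str, str]]] = [[]]
    ops: list[str] = []
    for kind, value in tokens:
        if kind == "op" and value in ("<=", ">=", "="):
            ops.append(value)
            parts.append([])
        else:
            parts[-1].append((kind, value))
    if not ops:
        raise RelationError("no relational operator", relation)
    exprs = [parse_expression(p, relation) for p in parts]
    return [(exprs[i], ops[i], exprs[i + 1]) for i in range(len(ops))]


def relation_rows(
    relations: Iterable[str],
    left_index: list[str],
    right_index: list[str],
    *,
    allow_constant: bool = False,
    handler: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn relation strings into inequality rows ``L x_left <= R x_right + k``.

    ``left_index`` and ``right_index`` fix the column orders.  Labels found on
    the "wrong" side of a relation are simply moved across with flipped sign
    (relations may freely mix both kinds of labels); unknown labels raise.
    Equalities produce the ``<=`` row first, then the ``>=`` row, and chains
    are split pairwise, matching the printed handler matrices.

    Returns ``(L, R, k)``; when ``allow_constant`` is false a nonzero ``k``
    raises (handler blocks are homogeneous).
    """
    left_pos = {lab: i for i, lab in enumerate(left_index)}
    right_pos = {lab: i for i, lab in enumerate(right_index)}
    L_rows: list[np.ndarray] = []
    R_rows: list[np.ndarray] = []
    k_rows: list[float] = []

    def add_ineq(lhs: dict[str | None, float], rhs: dict[str | None, float], relation: str) -> None:
        lrow = np.zeros(len(left_index))
        rrow = np.zeros(len(right_index))
        const = 0.0
        for expr, sgn in ((lhs, 1.0), (rhs, -1.0)):
            for label, coeff in expr.items():
                if label is None:
                    const -= sgn * coeff
                elif label in left_pos:
                    lrow[left_pos[label]] += sgn * coeff
                elif label in right_pos:
                    rrow[right_pos[label]] -= sgn * coeff
                else:
                    raise RelationError(f"unknown label {label!r}", relation, handler)
        if const != 0.0 and not allow_constant:
            raise RelationError("constant term not allowed here", relation, handler)
        L_rows.append(lrow)
        R_rows.append(rrow)
        k_rows.append(const)

    for relation in relations:
        for lhs, op, rhs in parse_chain(relation):
            if op == "=":
                add_ineq(lhs, rhs, relation)
                add_ineq(rhs, lhs, relation)
            elif op == "<=":
                add_ineq(lhs, rhs, relation)
            else:  # ">="
                add_ineq(rhs, lhs, relation)

    if L_rows:
        return np.array(L_rows), np.array(R_rows), np.array(k_rows)
    return (
        np.zeros((0, len(left_index))),
        np.zeros((0, len(right_index))),
        np.zeros(0),
    )
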