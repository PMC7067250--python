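"""Named-variable linear systems and LP/QP solving.

:class:`LinearSystem` collects blocks of nonnegative (by default) variables,
each indexed by net elements, plus equality/inequality rows over them.  It
is the in-memory form of every constraint system in the package (state
equations, transcriptions).  Solving goes through SciPy: linear programs use
``linprog`` with the HiGHS backend; convex quadratic programs (objectives
that are sums of squared affine terms plus a linear part) use
``trust-constr`` with analytic derivatives, warm-started from an LP point.
Both are deterministic for fixed inputs and options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

__all__ = ["LinearSystem", "Solution", "Term", "AffineExpr", "SolverError"]

FEAS_TOL = 1e-8


class SolverError(RuntimeError):
    """A solver failed or returned a status the caller cannot use."""


@dataclass
class Term:
    """``coeff * var[key]`` inside an affine expression."""

    coeff: float
    var: str
    key: object


@dataclass
class AffineExpr:
    """``sum(terms) + const`` over system variables."""

    terms: list[Term] = field(default_factory=list)
    const: float = 0.0


@dataclass
class Solution:
    status: str  # optimal | infeasible | unbounded | error
    value: float | None
    _system: "LinearSystem | None" = None
    _x: np.ndarray | None = None
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def get(self, name: str) -> pd.Series:
        if self._x is None:
            raise SolverError(f"no solution available (status={self.status}): {self.message}")
        sl, index = self._system._vars[name]
        return pd.Series(
            self._x[sl], index=pd.Index(index, tupleize_cols=False, dtype=object), name=name
        )

    def __getitem__(self, name: str) -> pd.Series:
        return self.get(name)


class LinearSystem:
    """A block-structured system ``{x >= lb, A_eq x = b_eq, A_ub x <= b_ub}``."""

    def __init__(self) -> None:
        self._vars: dict[str, tuple[slice, list]] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._eq_rows: list[tuple[dict[str, np.ndarray], np.ndarray]] = []
        self._ub_rows: list[tuple[dict[str, np.ndarray], np.ndarray]] = []

    # -- variables -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._lb)

    def add_var(self, name: str, index: Sequence, lb: float = 0.0, ub: float = np.inf) -> str:
        if name in self._vars:
            raise ValueError(f"variable {name!r} already declared")
        index = list(index)
        start = self.n
        self._vars[name] = (slice(start, start + len(index)), index)
        self._lb.extend([lb] * len(index))
        self._ub.extend([ub] * len(index))
        return name

    def has_var(self, name: str) -> bool:
        return name in self._vars

    def index(self, name: str) -> list:
        return self._vars[name][1]

    def dim(self, name: str) -> int:
        return len(self._vars[name][1])

    def fix(self, name: str, values) -> None:
        """Pin a variable block (or selected keys) to point values via bounds."""
        sl, index = self._vars[name]
        if np.isscalar(values):
            values = {k: values for k in index}
        if isinstance(values, (pd.Series, dict)):
            items = dict(values).items()
        else:
            items = zip(index, np.asarray(values, dtype=float))
        pos = {k: i for i, k in enumerate(index)}
        for key, val in items:
            i = sl.start + pos[key]
            self._lb[i] = float(val)
            self._ub[i] = float(val)

    def set_bounds(self, name: str, key, lb: float | None = None, ub: float | None = None) -> None:
        sl, index = self._vars[name]
        i = sl.start + index.index(key)
        if lb is not None:
            self._lb[i] = lb
        if ub is not None:
            self._ub[i] = ub

    # -- rows ----------------------------------------------------------------
    def _coerce(self, terms: dict[str, object], nrows: int) -> dict[str, np.ndarray]:
        out = {}
        for name, mat in terms.items():
            arr = np.asarray(mat, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(nrows, -1)
            if arr.shape != (nrows, self.dim(name)):
                raise ValueError(
                    f"matrix for {name!r} has shape {arr.shape}, expected {(nrows, self.dim(name))}"
                )
            out[name] = arr
        return out

    def add_eq(self, terms: dict[str, object], rhs) -> None:
        """Rows ``sum_name M_name x_name = rhs``."""
        rhs = np.atleast_1d(np.asarray(rhs, dtype=float))
        self._eq_rows.append((self._coerce(terms, rhs.size), rhs))

    def add_le(self, terms: dict[str, object], rhs) -> None:
        """Rows ``sum_name M_name x_name <= rhs``."""
        rhs = np.atleast_1d(np.asarray(rhs, dtype=float))
        self._ub_rows.append((self._coerce(terms, rhs.size), rhs))

    def _stack(self, rows: list[tuple[dict[str, np.ndarray], np.ndarray]]):
        if not rows:
            return sp.csr_matrix((0, self.n)), np.zeros(0)
        data, ri, ci, rhs_all = [], [], [], []
        r0 = 0
        for terms, rhs in rows:
            for name, mat in terms.items():
                sl = self._vars[name][0]
                rr, cc = np.nonzero(mat)
                data.extend(mat[rr, cc])
                ri.extend(rr + r0)
                ci.extend(cc + sl.start)
            rhs_all.append(rhs)
            r0 += rhs.size
        A = sp.coo_matrix((data, (ri, ci)), shape=(r0, self.n)).tocsr()
        return A, np.concatenate(rhs_all)

    def matrices(self):
        """Assembled ``(A_eq, b_eq, A_ub, b_ub, lb, ub)``."""
        A_eq, b_eq = self._stack(self._eq_rows)
        A_ub, b_ub = self._stack(self._ub_rows)
        return A_eq, b_eq, A_ub, b_ub, np.array(self._lb), np.array(self._ub)

    def write_lp(self, path, objective: "AffineExpr | None" = None, sense: str = "min") -> None:
        """Dump the system in CPLEX LP text format (debugging aid)."""
        A_eq, b_eq, A_ub, b_ub, lb, ub = self.matrices()
        names = np.empty(self.n, dtype=object)
        for vname, (sl, index) in self._vars.items():
            for i, key in enumerate(index):
                clean = "".join(ch if ch.isalnum() else "_" for ch in f"{vname}_{key}")
                names[sl.start + i] = f"x{sl.start + i}_{clean}"

        def row(A, r):
            Ar = A.getrow(r)
            return " + ".join(
                f"{Ar.data[i]:g} {names[Ar.indices[i]]}" for i in range(Ar.nnz)
            ) or "0 " + names[0]

        lines = ["Minimize" if sense == "min" else "Maximize"]
        c = self.cost_vector(objective or AffineExpr())
        obj = " + ".join(f"{c[i]:g} {names[i]}" for i in np.flatnonzero(c)) or "0"
        lines += [f" obj: {obj}", "Subject To"]
        for r in range(A_ub.shape[0]):
            lines.append(f" le{r}: {row(A_ub, r)} <= {b_ub[r]:g}")
        for r in range(A_eq.shape[0]):
            lines.append(f" eq{r}: {row(A_eq, r)} = {b_eq[r]:g}")
        lines.append("Bounds")
        for i in range(self.n):
            lo = "-inf" if np.isneginf(lb[i]) else f"{lb[i]:g}"
            hi = "+inf" if np.isposinf(ub[i]) else f"{ub[i]:g}"
            lines.append(f" {lo} <= {names[i]} <= {hi}")
        lines.append("End")
        from pathlib import Path

        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            Path(path).write_text(text)

    # -- objectives ----------------------------------------------------------
    def cost_vector(self, expr: AffineExpr) -> np.ndarray:
        c = np.zeros(self.n)
        for t in expr.terms:
            sl, index = self._vars[t.var]
            c[sl.start + index.index(t.key)] += t.coeff
        return c

    # -- solving -------------------------------------------------------------
    def solve_lp(self, objective: AffineExpr | None = None, sense: str = "min") -> Solution:
        """Solve as an LP; ``objective=None`` solves feasibility (zero cost)."""
        objective = objective or AffineExpr()
        if self.n == 0:
            return Solution("optimal", objective.const, self, np.zeros(0))
        c = self.cost_vector(objective)
        sgn = 1.0 if sense == "min" else -1.0
        A_eq, b_eq, A_ub, b_ub, lb, ub = self.matrices()
        res = linprog(
            sgn * c,
            A_ub=A_ub if A_ub.shape[0] else None,
            b_ub=b_ub if A_ub.shape[0] else None,
            A_eq=A_eq if A_eq.shape[0] else None,
            b_eq=b_eq if A_eq.shape[0] else None,
            bounds=[
                (None if np.isneginf(lo) else lo, None if np.isposinf(hi) else hi)
                for lo, hi in zip(lb, ub)
            ],
            method="highs",
        )
        if res.status == 0:
            return Solution("optimal", sgn * res.fun + objective.const, self, res.x, res.message)
        status = {2: "infeasible", 3: "unbounded"}.get(res.status, "error")
        return Solution(status, None, self, None, res.message)

    def solve_qp(
        self,
        squares: list[AffineExpr],
        linear: AffineExpr | None = None,
        sense: str = "min",
        x0: np.ndarray | None = None,
    ) -> Solution:
        """Minimize ``sum_i (a_i'x + b_i)^2 + c'x + d`` over the system.

        Convex by construction.  ``sense`` must be ``"min"`` (a maximization
        of a concave quadratic is not representable here and is rejected).
        """
        if sense != "min":
            raise SolverError("quadratic objectives support only minimization")
        linear = linear or AffineExpr()
        F = np.array([self.cost_vector(e) for e in squares]) if squares else np.zeros((0, self.n))
        g = np.array([e.const for e in squares]) if squares else np.zeros(0)
        c = self.cost_vector(linear)
        Q = 2.0 * F.T @ F  # hessian

        A_eq, b_eq, A_ub, b_ub, lb, ub = self.matrices()
        if x0 is None:
            feas = self.solve_lp()
            if not feas.optimal:
                return Solution(feas.status, None, self, None, feas.message)
            x0 = feas._x
        x0 = np.clip(x0, lb, ub)

        def fun(x):
            r = F @ x + g
            return float(r @ r + c @ x)

        def grad(x):
            return 2.0 * F.T @ (F @ x + g) + c

        constraints = []
        if A_eq.shape[0]:
            constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
        if A_ub.shape[0]:
            constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))
        import warnings

        with warnings.catch_warnings():
            # trust-constr warns about the (expected) rank-deficient equality
            # rows of transcriptions; it falls back to an SVD projection
            warnings.filterwarnings("ignore", message="Singular Jacobian matrix")
            warnings.filterwarnings("ignore", message="delta_grad == 0.0")
            # large intermediate iterates can overflow inside the subproblem
            # solver without affecting the converged solution
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                fun,
                x0,
                jac=grad,
                hess=lambda x: Q,
                bounds=Bounds(lb, ub),
                constraints=constraints,
                method="trust-constr",
                options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 500, "verbose": 0},
            )
        if res.status in (1, 2) or res.constr_violation < 1e-6:
            return Solution("optimal", float(res.fun) + linear.const, self, res.x, res.message)
        return Solution("error", None, self, None, res.message)
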