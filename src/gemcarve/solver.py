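"""Thin LP/MILP layer over scipy's HiGHS interface.

Problems are built with named variables and ranged linear constraints and
solved with :func:`scipy.optimize.milp`, which handles both continuous and
mixed-integer problems deterministically. This keeps the optimization
modules readable and makes the backend swappable behind one contract:
load problem, set integrality, optimize, report status/solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["LinearProblem", "Solution", "SolverError"]

_STATUS = {
    0: "optimal",
    1: "iteration_limit",
    2: "infeasible",
    3: "unbounded",
    4: "other",
}


class SolverError(RuntimeError):
    pass


@dataclass
class Solution:
    status: str
    objective: float | None = None
    values: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class LinearProblem:
    """Incrementally-built linear or mixed-integer program."""

    def __init__(self, name: str = "") -> None:
        self.name = name
        self._vars: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._objective: dict[int, float] = {}
        self._sense = 1.0  # scipy minimizes; -1 encodes maximization

    # -- model building ----------------------------------------------

    def add_variable(
        self,
        name: str,
        lb: float = -np.inf,
        ub: float = np.inf,
        *,
        integer: bool = False,
    ) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self._vars)
        self._vars.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        return name

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i] = lb
        self._ub[i] = ub

    def add_constraint(
        self,
        coeffs: Mapping[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        row = {self._index[v]: c for v, c in coeffs.items() if c != 0}
        self._rows.append(row)
        self._row_lb.append(lb)
        self._row_ub.append(ub)

    def set_objective(
        self, coeffs: Mapping[str, float], sense: str = "min"
    ) -> None:
        if sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        self._sense = 1.0 if sense == "min" else -1.0
        self._objective = {self._index[v]: c for v, c in coeffs.items()}

    # -- solving ------------------------------------------------------

    def solve(self, mip_gap: float = 1e-9) -> Solution:
        n = len(self._vars)
        if n == 0:
            return Solution("optimal", 0.0, {})
        c = np.zeros(n)
        for i, coeff in self._objective.items():
            c[i] = self._sense * coeff

        constraints = []
        if self._rows:
            rows, cols, data = [], [], []
            for r, row in enumerate(self._rows):
                for i, coeff in row.items():
                    rows.append(r)
                    cols.append(i)
                    data.append(coeff)
            a_mat = sparse.csr_matrix(
                (data, (rows, cols)), shape=(len(self._rows), n)
            )
            constraints.append(
                LinearConstraint(a_mat, np.array(self._row_lb), np.array(self._row_ub))
            )

        integrality = np.array(self._integer, dtype=int)
        res = milp(
            c=c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(np.asarray(self._lb), np.asarray(self._ub)),
            options={"mip_rel_gap": mip_gap, "presolve": True},
        )
        status = _STATUS.get(res.status, "other")
        if res.x is None:
            return Solution(status)
        values = {v: float(res.x[i]) for v, i in self._index.items()}
        objective = float(self._sense * res.fun)
        return Solution(status, objective, values)
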