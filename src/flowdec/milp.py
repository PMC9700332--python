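"""Minimal mixed-integer linear program container with a HiGHS backend.

The decomposition models are assembled into this container and handed to
``scipy.optimize.milp`` (which wraps the open-source HiGHS solver).  The
container keeps named variables and row-wise constraints so that models can
be built incrementally by the variant installers and exported as LP text for
debugging.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

__all__ = ["LinearProgram", "LpSolution", "BackendError"]

_STATUS_MAP = {
    0: "optimal",
    1: "time_limit",   # iteration/time limit reached
    2: "infeasible",
    3: "unbounded",
    4: "error",
}


class BackendError(RuntimeError):
    """The requested solver backend is unavailable or failed."""


@dataclass
class LpSolution:
    status: str
    x: Optional[np.ndarray]
    objective: Optional[float]
    wall_time: float


@dataclass
class LinearProgram:
    names: list[str] = field(default_factory=list)
    lb: list[float] = field(default_factory=list)
    ub: list[float] = field(default_factory=list)
    integer: list[bool] = field(default_factory=list)
    # each row: (coeff map var-index -> value, row lb, row ub)
    rows: list[tuple[dict[int, float], float, float]] = field(default_factory=list)
    objective: dict[int, float] = field(default_factory=dict)
    maximize: bool = False

    @property
    def n_vars(self) -> int:
        return len(self.names)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf,
                integer: bool = False) -> int:
        self.names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(integer)
        return len(self.names) - 1

    def add_binary(self, name: str) -> int:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def add_row(self, coeffs: dict[int, float], lb: float, ub: float) -> int:
        self.rows.append((dict(coeffs), lb, ub))
        return len(self.rows) - 1

    def add_eq(self, coeffs: dict[int, float], rhs: float) -> int:
        return self.add_row(coeffs, rhs, rhs)

    def set_objective(self, coeffs: dict[int, float], maximize: bool = False) -> None:
        self.objective = dict(coeffs)
        self.maximize = maximize

    # -- solving ---------------------------------------------------------------

    def solve(self, time_limit: Optional[float] = None,
              mip_rel_gap: Optional[float] = None) -> LpSolution:
        c = np.zeros(self.n_vars)
        sign = -1.0 if self.maximize else 1.0
        for j, v in self.objective.items():
            c[j] = sign * v
        constraints = []
        if self.rows:
            data, indices, indptr = [], [], [0]
            row_lb, row_ub = [], []
            for coeffs, lo, hi in self.rows:
                for j, v in coeffs.items():
                    indices.append(j)
                    data.append(v)
                indptr.append(len(indices))
                row_lb.append(lo)
                row_ub.append(hi)
            a = csr_matrix((data, indices, indptr), shape=(self.n_rows, self.n_vars))
            constraints.append(LinearConstraint(a, row_lb, row_ub))
        options: dict = {"presolve": True}
        if time_limit is not None:
            options["time_limit"] = max(float(time_limit), 0.01)
        if mip_rel_gap is not None:
            options["mip_rel_gap"] = mip_rel_gap
        t0 = time.perf_counter()
        try:
            res = milp(
                c,
                constraints=constraints,
                integrality=np.array(self.integer, dtype=float),
                bounds=Bounds(np.array(self.lb), np.array(self.ub)),
                options=options,
            )
        except Exception as exc:  # pragma: no cover - backend failure path
            raise BackendError(f"HiGHS backend failed: {exc}") from exc
        wall = time.perf_counter() - t0
        status = _STATUS_MAP.get(res.status, "error")
        if status == "time_limit" and res.x is not None:
            # best incumbent available within the limit
            pass
        obj = None
        if res.x is not None and self.objective:
            obj = float(sum(v * res.x[j] for j, v in self.objective.items()))
        return LpSolution(status=status,
                          x=None if res.x is None else np.asarray(res.x),
                          objective=obj, wall_time=wall)

    # -- debugging -------------------------------------------------------------

    def to_lp_text(self) -> str:
        """Render the model in (CPLEX-style) LP text format."""
        def term(j, v):
            s = "+" if v >= 0 else "-"
            return f"{s} {abs(v):g} {self.names[j]}"

        lines = ["Maximize" if self.maximize else "Minimize"]
        obj = " ".join(term(j, v) for j, v in self.objective.items()) or "0"
        lines.append(" obj: " + obj)
        lines.append("Subject To")
        for i, (coeffs, lo, hi) in enumerate(self.rows):
            body = " ".join(term(j, v) for j, v in coeffs.items())
            if lo == hi:
                lines.append(f" c{i}: {body} = {lo:g}")
            else:
                if np.isfinite(lo):
                    lines.append(f" c{i}lo: {body} >= {lo:g}")
                if np.isfinite(hi):
                    lines.append(f" c{i}hi: {body} <= {hi:g}")
        lines.append("Bounds")
        for j, name in enumerate(self.names):
            lines.append(f" {self.lb[j]:g} <= {name} <= {self.ub[j]:g}")
        ints = [self.names[j] for j in range(self.n_vars) if self.integer[j]]
        if ints:
            lines.append("Generals")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        return "\n".join(lines) + "\n"
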