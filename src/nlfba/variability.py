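"""Quasi-optimal variability bounds (modified FVA).

Given a solved program with optimal objective f*, each selected variable is
minimized and maximized subject to the original constraints plus an
objective-degradation budget — by default an objective no more than 0.1%
worse than f* — warm-started from the incumbent optimum.  The resulting
intervals are the dotted prediction bands drawn around point estimates.

For f* of magnitude ~0 a relative budget degenerates, so the budget is
f* ± (fraction·|f*| + ε_abs) with a small absolute floor ε_abs = 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import sympy as sp

from .nlp_core import NonlinearProgram, Solution, solve, solve_lp, sym

__all__ = ["FVAResult", "quasi_optimal_bounds"]

EPS_ABS = 1e-6


@dataclass
class FVAResult:
    bounds: pd.DataFrame  # index: variable; columns: lower, upper, status_*

    def interval(self, name: str) -> tuple[float, float]:
        row = self.bounds.loc[name]
        return float(row["lower"]), float(row["upper"])


def quasi_optimal_bounds(prog: NonlinearProgram, f_star: float,
                         variables: list[str],
                         fraction: float = 0.001,
                         tolerance: float = 1e-4,
                         incumbent: Solution | None = None) -> FVAResult:
    """Min/max each variable under F within ``fraction`` of ``f_star``.

    ``f_star`` must be a solved objective value of ``prog`` (its sense is
    taken from the program).  Per-variable solver failures are recorded in
    the status columns, not raised.  The incumbent solution, when given,
    warm-starts every solve and guarantees the budget set is nonempty.
    """
    for name in variables:
        if not prog.has_variable(name):
            raise KeyError(f"unknown variable {name!r}")
    budget = fraction * abs(f_star) + EPS_ABS
    sense = prog.objective_sense
    saved_obj, saved_sense = prog.objective, sense
    n_lin = len(prog.linear_constraints)
    n_nl = len(prog.nonlinear_constraints)

    obj = prog.objective
    try:
        try:
            coeffs, const = _linear_objective(obj)
            rel = "<=" if sense == "min" else ">="
            bound = (f_star + budget - const) if sense == "min" \
                else (f_star - budget - const)
            prog.add_linear_constraint(coeffs, rel, bound)
        except ValueError:
            rel = "<=" if sense == "min" else ">="
            bound = f_star + budget if sense == "min" else f_star - budget
            prog.add_nonlinear_constraint(obj, rel, bound)

        linear = _is_linear_body(prog)
        rows = []
        start = incumbent.values if incumbent is not None else None
        for name in variables:
            rec = {"variable": name}
            for direction, key in (("min", "lower"), ("max", "upper")):
                prog.set_objective(sym(name), direction)
                if linear:
                    s = solve_lp(prog)
                else:
                    s = solve(prog, start=start,
                              options={"tolerance": tolerance})
                rec[key] = s.values.get(name, float("nan"))
                rec[f"status_{key}"] = s.status
            rows.append(rec)
        return FVAResult(pd.DataFrame(rows).set_index("variable"))
    finally:
        del prog.linear_constraints[n_lin:]
        del prog.nonlinear_constraints[n_nl:]
        prog.objective = saved_obj
        prog.objective_sense = saved_sense
        prog._compiled = None


def _linear_objective(expr: sp.Expr) -> tuple[dict[str, float], float]:
    from .nlp_core import _linear_coeffs
    return _linear_coeffs(expr)


def _is_linear_body(prog: NonlinearProgram) -> bool:
    return not prog.nonlinear_constraints
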