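"""Flux-balance problems with arbitrary symbolic nonlinear constraints.

A :class:`NonlinearProgram` couples the linear steady-state structure of a
metabolic network (``S·v = 0`` plus general linear rows) with symbolic
nonlinear constraints and a symbolic objective, written as sympy expressions
over named variables.  Analytic first and second derivatives of every
expression are generated automatically (term-by-term, so large separable
objectives stay cheap to differentiate) and passed, with their sparsity
patterns, to the solver.

The solver is an adapter contract, not a fixed dependency: general problems
are handed to scipy's interior-point ``trust-constr`` method (``SLSQP``
available as an option for small dense problems), and purely linear problems
take a dedicated LP path through ``scipy.optimize.linprog`` (HiGHS), which
yields global optima and is used for cross-checking the NLP path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy import sparse
from scipy.optimize import (Bounds, LinearConstraint, NonlinearConstraint,
                            linprog, minimize)

__all__ = [
    "sym",
    "NonlinearProgram",
    "Solution",
    "solve",
    "solve_lp",
    "derivative_evaluators",
    "epigraph_min",
]

INF = float("inf")

#: expression heads that break differentiability; rejected with guidance
_NON_SMOOTH = (sp.Abs, sp.sign, sp.Min, sp.Max, sp.ceiling, sp.floor,
               sp.Heaviside, sp.Piecewise)


def sym(name: str) -> sp.Symbol:
    """Shorthand for a (real) sympy symbol used as a program variable."""
    return sp.Symbol(name, real=True)


@dataclass
class Solution:
    values: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | iteration-limit | failed
    residuals: float  # max constraint violation at the returned point
    message: str = ""
    n_iterations: int = 0

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class _NLRow:
    expr: sp.Expr
    relation: str  # '=', '<=', '>='
    rhs: float


class NonlinearProgram:
    """Variables with bounds, linear rows, symbolic nonlinear rows, objective."""

    def __init__(self):
        self._bounds: dict[str, tuple[float, float]] = {}
        self._scales: dict[str, float] = {}
        self.parameters: dict[str, float] = {}
        self.linear_constraints: list[tuple[dict[str, float], str, float]] = []
        self.nonlinear_constraints: list[_NLRow] = []
        self.objective: sp.Expr = sp.Integer(0)
        self.objective_sense: str = "min"
        self._compiled = None

    # -- construction -----------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return list(self._bounds)

    def has_variable(self, name: str) -> bool:
        return name in self._bounds

    def add_variable(self, name: str, lower: float = -INF,
                     upper: float = INF) -> sp.Symbol:
        if name in self._bounds:
            raise ValueError(f"variable {name!r} already declared")
        if lower > upper:
            raise ValueError(f"variable {name!r}: lower bound above upper")
        self._bounds[name] = (float(lower), float(upper))
        self._compiled = None
        return sym(name)

    def bounds_of(self, name: str) -> tuple[float, float]:
        return self._bounds[name]

    def set_bounds(self, name: str, lower: float, upper: float) -> None:
        if name not in self._bounds:
            raise KeyError(f"unknown variable {name!r}")
        self._bounds[name] = (float(lower), float(upper))
        self._compiled = None

    def set_parameter(self, name: str, value: float) -> None:
        self.parameters[name] = float(value)
        self._compiled = None

    def set_scale(self, name: str, scale: float) -> None:
        """Characteristic magnitude of a variable, used to equilibrate the
        solver's internal scaling (e.g. gas levels in μbar vs fluxes)."""
        if name not in self._bounds:
            raise KeyError(f"unknown variable {name!r}")
        if scale <= 0:
            raise ValueError("scale must be positive")
        self._scales[name] = float(scale)
        self._compiled = None

    def _check_symbols(self, expr: sp.Expr) -> None:
        for s in expr.free_symbols:
            if s.name not in self._bounds and s.name not in self.parameters:
                raise ValueError(
                    f"expression uses undeclared symbol {s.name!r}; declare it "
                    "as a variable or register it as a parameter first"
                )

    def add_linear_constraint(self, coeffs: dict[str, float], relation: str,
                              rhs: float) -> None:
        if relation not in ("=", "<=", ">="):
            raise ValueError(f"bad relation {relation!r}")
        for name in coeffs:
            if name not in self._bounds:
                raise ValueError(f"linear row uses undeclared variable {name!r}")
        self.linear_constraints.append((dict(coeffs), relation, float(rhs)))
        self._compiled = None

    def add_nonlinear_constraint(self, expr, relation: str, rhs: float) -> None:
        """Add ``expr <relation> rhs``; expr may reference registered parameters.

        Expressions that are actually linear in the variables (e.g. a kinetic
        law whose capacity parameter is zero) are routed to the linear block,
        so purely linear programs stay recognizable to the LP path.
        """
        if relation not in ("=", "<=", ">="):
            raise ValueError(f"bad relation {relation!r}")
        expr = sp.sympify(expr)
        self._check_symbols(expr)
        if all(s.name in self._bounds for s in expr.free_symbols):
            try:
                coeffs, const = _linear_coeffs(expr)
            except ValueError:
                pass
            else:
                self.add_linear_constraint(coeffs, relation, float(rhs) - const)
                return
        self.nonlinear_constraints.append(_NLRow(expr, relation, float(rhs)))
        self._compiled = None

    def set_objective(self, expr, sense: str = "min") -> None:
        if sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        expr = sp.sympify(expr)
        self._check_symbols(expr)
        self.objective = expr
        self.objective_sense = sense
        self._compiled = None

    # -- model import -----------------------------------------------------

    @classmethod
    def from_model(cls, model) -> "NonlinearProgram":
        """One flux variable per reaction; one S·v = 0 row per non-boundary species."""
        np_ = cls()
        for r in model.reactions:
            np_.add_variable(r.id, r.lower_bound, r.upper_bound)
        boundary = {s.id for s in model.species if s.boundary}
        rows: dict[str, dict[str, float]] = {}
        for r in model.reactions:
            for sid, coef in r.stoichiometry.items():
                if sid in boundary:
                    continue
                rows.setdefault(sid, {})[r.id] = rows.setdefault(sid, {}).get(r.id, 0.0) + coef
        for sid in (s.id for s in model.species):
            if sid in rows:
                np_.add_linear_constraint(rows[sid], "=", 0.0)
        return np_

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "variables": {k: list(v) for k, v in self._bounds.items()},
            "parameters": self.parameters,
            "linear_constraints": [
                {"coeffs": c, "relation": rel, "rhs": rhs}
                for c, rel, rhs in self.linear_constraints
            ],
            "nonlinear_constraints": [
                {"expr": str(row.expr), "relation": row.relation, "rhs": row.rhs}
                for row in self.nonlinear_constraints
            ],
            "objective": {"expr": str(self.objective),
                          "sense": self.objective_sense},
        }

        def _clean(o):
            if isinstance(o, float) and not np.isfinite(o):
                return "inf" if o > 0 else "-inf"
            return o

        text = json.dumps(payload, default=_clean, indent=1)
        text = text.replace('"inf"', '"Infinity"')  # keep explicit marker
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "NonlinearProgram":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)

        def _num(v):
            if v in ("Infinity", "inf"):
                return INF
            if v in ("-Infinity", "-inf"):
                return -INF
            return float(v)

        np_ = cls()
        for name, (lo, hi) in payload["variables"].items():
            np_.add_variable(name, _num(lo), _num(hi))
        np_.parameters = {k: float(v) for k, v in payload["parameters"].items()}
        for row in payload["linear_constraints"]:
            np_.add_linear_constraint(row["coeffs"], row["relation"], row["rhs"])
        local = {name: sym(name) for name in np_.variables}
        local.update({k: sym(k) for k in np_.parameters})
        for row in payload["nonlinear_constraints"]:
            np_.add_nonlinear_constraint(
                sp.sympify(row["expr"], locals=local), row["relation"], row["rhs"])
        np_.set_objective(sp.sympify(payload["objective"]["expr"], locals=local),
                          payload["objective"]["sense"])
        return np_


# ---------------------------------------------------------------------------
# Symbolic differentiation (term-wise, sparse)
# ---------------------------------------------------------------------------

def _reject_non_smooth(expr: sp.Expr) -> None:
    if expr.has(*_NON_SMOOTH):
        raise ValueError(
            "expression contains a non-differentiable function (Abs/min/max "
            "or similar); use the direction-assignment path for absolute "
            "values, or the epigraph_min reformulation for min()"
        )


def _substituted(expr: sp.Expr, params: dict[str, float]) -> sp.Expr:
    if not params:
        return expr
    subs = {sym(k): sp.Float(v) for k, v in params.items()
            if sym(k) in expr.free_symbols}
    return expr.xreplace(subs) if subs else expr


def _sparse_gradient(expr: sp.Expr) -> dict[sp.Symbol, sp.Expr]:
    """Gradient of expr wrt its own free symbols, computed term by term."""
    grad: dict[sp.Symbol, sp.Expr] = {}
    for term in sp.Add.make_args(expr):
        for s in term.free_symbols:
            d = sp.diff(term, s)
            if d != 0:
                grad[s] = grad.get(s, sp.Integer(0)) + d
    return grad


def _sparse_hessian(expr: sp.Expr) -> dict[tuple[sp.Symbol, sp.Symbol], sp.Expr]:
    """Lower-triangle-free dict {(si, sj): d2f/dsi dsj} (si ordered by name)."""
    hess: dict[tuple[sp.Symbol, sp.Symbol], sp.Expr] = {}
    for term in sp.Add.make_args(expr):
        syms = sorted(term.free_symbols, key=lambda s: s.name)
        for i, si in enumerate(syms):
            di = sp.diff(term, si)
            if di == 0:
                continue
            for sj in syms[i:]:
                dij = sp.diff(di, sj)
                if dij != 0:
                    key = (si, sj)
                    hess[key] = hess.get(key, sp.Integer(0)) + dij
    return hess


class _Lambdified:
    """Vector-valued lambdified expressions over a fixed symbol tuple."""

    def __init__(self, symbols: list[sp.Symbol], exprs: list[sp.Expr]):
        self.symbols = symbols
        self.idx: np.ndarray | None = None  # set by compiler
        if exprs:
            self._fun = sp.lambdify(symbols, exprs, modules="numpy")
        else:
            self._fun = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self._fun is None:
            return np.zeros(0)
        return np.asarray(self._fun(*x[self.idx]), dtype=float)


class _Compiled:
    """Index maps, sparse linear blocks and callable derivative evaluators."""

    def __init__(self, prog: NonlinearProgram):
        self.prog = prog
        self.names = list(prog._bounds)
        self.index = {n: i for i, n in enumerate(self.names)}
        n = len(self.names)
        self.lb = np.array([prog._bounds[k][0] for k in self.names])
        self.ub = np.array([prog._bounds[k][1] for k in self.names])

        # linear rows -> A_eq x = b_eq ; A_ub x <= b_ub
        eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
        for coeffs, rel, rhs in prog.linear_constraints:
            row = {self.index[k]: v for k, v in coeffs.items()}
            if rel == "=":
                eq_rows.append(row), eq_rhs.append(rhs)
            elif rel == "<=":
                ub_rows.append(row), ub_rhs.append(rhs)
            else:  # >=  ->  -lhs <= -rhs
                ub_rows.append({k: -v for k, v in row.items()})
                ub_rhs.append(-rhs)

        def build(rows):
            m = sparse.lil_matrix((len(rows), n))
            for i, row in enumerate(rows):
                for j, v in row.items():
                    m[i, j] = v
            return m.tocsr()

        self.A_eq, self.b_eq = build(eq_rows), np.array(eq_rhs, dtype=float)
        self.A_ub, self.b_ub = build(ub_rows), np.array(ub_rhs, dtype=float)
        # Conserved moieties make stoichiometric rows linearly dependent;
        # solvers that factor the equality Jacobian need a full-rank subset.
        # Feasibility is still checked against the full row set, so an
        # inconsistent rhs on a dropped row is reported as infeasible.
        self.A_eq_full, self.b_eq_full = self.A_eq, self.b_eq
        if self.A_eq.shape[0] > 0:
            from scipy.linalg import qr
            _, R, piv = qr(self.A_eq.toarray().T, mode="economic",
                           pivoting=True)
            diag = np.abs(np.diag(R))
            tol = max(self.A_eq.shape) * np.finfo(float).eps * \
                (diag[0] if diag.size else 1.0)
            rank = int(np.sum(diag > tol)) if diag.size else 0
            keep = np.sort(piv[:rank])
            if rank < self.A_eq.shape[0]:
                self.A_eq = self.A_eq[keep]
                self.b_eq = self.b_eq[keep]
        self.scales = np.array([prog._scales.get(k, 1.0) for k in self.names])

        # nonlinear rows
        self.nl_rows = []
        for row in prog.nonlinear_constraints:
            expr = _substituted(row.expr, prog.parameters)
            _reject_non_smooth(expr)
            syms = sorted((s for s in expr.free_symbols), key=lambda s: s.name)
            grad = _sparse_gradient(expr)
            hess = _sparse_hessian(expr)
            val = _Lambdified(syms, [expr])
            val.idx = np.array([self.index[s.name] for s in syms], dtype=int)
            gsyms = sorted(grad, key=lambda s: s.name)
            gfun = _Lambdified(syms, [grad[s] for s in gsyms])
            gfun.idx = val.idx
            hkeys = sorted(hess, key=lambda p: (p[0].name, p[1].name))
            hfun = _Lambdified(syms, [hess[k] for k in hkeys])
            hfun.idx = val.idx
            self.nl_rows.append({
                "relation": row.relation,
                "rhs": row.rhs,
                "val": val,
                "grad_vars": np.array([self.index[s.name] for s in gsyms], dtype=int),
                "grad": gfun,
                "hess_keys": [(self.index[a.name], self.index[b.name])
                              for a, b in hkeys],
                "hess": hfun,
            })

        # objective
        obj = _substituted(prog.objective, prog.parameters)
        _reject_non_smooth(obj)
        self.obj_sign = 1.0 if prog.objective_sense == "min" else -1.0
        osyms = sorted(obj.free_symbols, key=lambda s: s.name)
        self.obj_val = _Lambdified(osyms, [obj])
        self.obj_val.idx = np.array([self.index[s.name] for s in osyms], dtype=int)
        ograd = _sparse_gradient(obj)
        gsyms = sorted(ograd, key=lambda s: s.name)
        self.obj_grad_vars = np.array([self.index[s.name] for s in gsyms], dtype=int)
        self.obj_grad = _Lambdified(osyms, [ograd[s] for s in gsyms])
        self.obj_grad.idx = self.obj_val.idx
        ohess = _sparse_hessian(obj)
        hkeys = sorted(ohess, key=lambda p: (p[0].name, p[1].name))
        self.obj_hess_keys = [(self.index[a.name], self.index[b.name])
                              for a, b in hkeys]
        self.obj_hess = _Lambdified(osyms, [ohess[k] for k in hkeys])
        self.obj_hess.idx = self.obj_val.idx

    # -- callable evaluators ---------------------------------------------

    def objective_value(self, x: np.ndarray) -> float:
        v = self.obj_val(x)
        return float(v[0]) if v.size else 0.0

    def objective_gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros(len(self.names))
        if self.obj_grad_vars.size:
            g[self.obj_grad_vars] = self.obj_grad(x)
        return g

    def objective_hessian(self, x: np.ndarray) -> sparse.csr_matrix:
        n = len(self.names)
        if not self.obj_hess_keys:
            return sparse.csr_matrix((n, n))
        vals = self.obj_hess(x)
        rows, cols, data = [], [], []
        for (i, j), v in zip(self.obj_hess_keys, vals):
            rows.append(i), cols.append(j), data.append(v)
            if i != j:
                rows.append(j), cols.append(i), data.append(v)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def nl_values(self, x: np.ndarray) -> np.ndarray:
        return np.array([row["val"](x)[0] for row in self.nl_rows])

    def nl_jacobian(self, x: np.ndarray) -> sparse.csr_matrix:
        m, n = len(self.nl_rows), len(self.names)
        jac = sparse.lil_matrix((m, n))
        for i, row in enumerate(self.nl_rows):
            if row["grad_vars"].size:
                jac[i, row["grad_vars"]] = row["grad"](x)
        return jac.tocsr()

    def nl_hessian_combination(self, x: np.ndarray,
                               weights: np.ndarray) -> sparse.csr_matrix:
        n = len(self.names)
        rows, cols, data = [], [], []
        for w, row in zip(weights, self.nl_rows):
            if w == 0 or not row["hess_keys"]:
                continue
            vals = row["hess"](x)
            for (i, j), v in zip(row["hess_keys"], vals):
                rows.append(i), cols.append(j), data.append(w * v)
                if i != j:
                    rows.append(j), cols.append(i), data.append(w * v)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def violation(self, x: np.ndarray) -> float:
        worst = 0.0
        if self.A_eq_full.shape[0]:
            worst = max(worst, float(np.max(np.abs(
                self.A_eq_full @ x - self.b_eq_full))))
        if self.A_ub.shape[0]:
            worst = max(worst, float(np.max(np.maximum(
                self.A_ub @ x - self.b_ub, 0.0))))
        for row in self.nl_rows:
            v = row["val"](x)[0] - row["rhs"]
            if row["relation"] == "=":
                worst = max(worst, abs(v))
            elif row["relation"] == "<=":
                worst = max(worst, max(v, 0.0))
            else:
                worst = max(worst, max(-v, 0.0))
        worst = max(worst, float(np.max(np.maximum(self.lb - x, 0.0), initial=0.0)))
        worst = max(worst, float(np.max(np.maximum(x - self.ub, 0.0), initial=0.0)))
        return worst


def _compiled(prog: NonlinearProgram) -> _Compiled:
    if prog._compiled is None:
        prog._compiled = _Compiled(prog)
    return prog._compiled


def derivative_evaluators(prog: NonlinearProgram):
    """Analytic objective gradient, constraint Jacobian, Lagrangian Hessian.

    Returns ``(grad_f, (jac, jac_sparsity), (hess_lag, hess_sparsity))`` where
    ``grad_f(x)`` is the dense objective gradient, ``jac(x)`` the sparse
    Jacobian of the nonlinear constraint bodies, and
    ``hess_lag(x, obj_weight, lam)`` the Hessian of
    ``obj_weight·f + Σ lam_k·c_k``.  Sparsity patterns are index-pair lists,
    supersets of the true nonzeros, and stable across evaluations.
    """
    comp = _compiled(prog)

    def grad_f(x):
        return comp.objective_gradient(np.asarray(x, dtype=float))

    jac_sparsity = [(i, j) for i, row in enumerate(comp.nl_rows)
                    for j in row["grad_vars"]]

    def jac(x):
        return comp.nl_jacobian(np.asarray(x, dtype=float))

    hess_sparsity = sorted(set(comp.obj_hess_keys)
                           | {k for row in comp.nl_rows for k in row["hess_keys"]})

    def hess_lag(x, obj_weight=1.0, lam=None):
        x = np.asarray(x, dtype=float)
        H = obj_weight * comp.objective_hessian(x)
        if lam is not None and len(comp.nl_rows):
            H = H + comp.nl_hessian_combination(x, np.asarray(lam, dtype=float))
        return H

    return grad_f, (jac, jac_sparsity), (hess_lag, hess_sparsity)


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

def _project_start(comp: _Compiled, start) -> np.ndarray:
    x0 = np.zeros(len(comp.names))
    if start:
        for name, v in start.items():
            if name in comp.index:
                x0[comp.index[name]] = v
    lo = np.where(np.isfinite(comp.lb), comp.lb, -1e6)
    hi = np.where(np.isfinite(comp.ub), comp.ub, 1e6)
    x0 = np.clip(x0, lo, hi)
    return x0


_DEFAULTS = {"tolerance": 1e-5, "max_iterations": 3000, "restarts": 0,
             "seed": 0, "method": "auto", "feasibility_tolerance": None,
             "perturbation_scale": 1.0, "retries_on_failure": 2,
             # 'auto': active-set SQP (SLSQP) for problems up to this many
             # variables — it converges sharply on dense mid-size programs —
             # with the sparse interior-point method as fallback and for
             # larger problems
             "auto_slsqp_max": 1200,
             # interior-point iterates stop short of active constraints by the
             # barrier slack; a cheap active-set (SLSQP) polish from the
             # converged point sharpens small problems to ~1e-8
             "polish": True, "polish_max_size": 300}


def solve(prog: NonlinearProgram, start: dict[str, float] | None = None,
          options: dict | None = None) -> Solution:
    """Solve the program from ``start`` (projected into bounds if outside).

    Options: ``tolerance`` (KKT/convergence, default 1e-5),
    ``max_iterations``, ``restarts`` (seeded multistart; the best feasible
    local optimum is returned), ``seed``, ``method``
    (``trust-constr``/``slsqp``).  Statuses are reported faithfully:
    infeasible, iteration-limit and numeric failure are distinct and never
    silent.
    """
    opts = dict(_DEFAULTS)
    opts.update(options or {})
    comp = _compiled(prog)
    x0 = _project_start(comp, start)

    if opts["method"] == "auto":
        small = len(comp.names) <= int(opts["auto_slsqp_max"])
        if small and not prog.nonlinear_constraints:
            try:  # purely linear: the convex interior-point path (plus its
                  # active-set polish) is reliable where SLSQP can stall
                _linear_coeffs(_substituted(prog.objective, prog.parameters))
                small = False
            except ValueError:
                pass
        first = dict(opts, method="slsqp" if small else "trust-constr")
        sol = solve(prog, start, first)
        # SLSQP occasionally reports success without leaving the start
        # point; a no-progress "optimum" is cross-checked against the
        # interior-point method
        f_start = comp.objective_value(x0)
        no_progress = (sol.status == "optimal"
                       and abs(sol.objective_value - f_start)
                       <= opts["tolerance"] * (1 + abs(f_start)))
        if first["method"] == "slsqp" and \
                (sol.status in ("failed", "infeasible") or no_progress):
            fallback = solve(prog, start, dict(opts, method="trust-constr"))
            rank = {"optimal": 0, "iteration-limit": 1, "failed": 2,
                    "infeasible": 3}
            sign = comp.obj_sign

            def key(s):
                obj = sign * s.objective_value
                return (rank[s.status], obj if np.isfinite(obj) else np.inf)

            if key(fallback) < key(sol):
                sol = fallback
        return sol

    best: Solution | None = None
    rng = np.random.default_rng(opts["seed"])
    planned = int(opts["restarts"]) + 1
    max_attempts = planned + int(opts["retries_on_failure"])
    rank = {"optimal": 0, "iteration-limit": 1, "failed": 2, "infeasible": 3}
    attempt = 0
    while True:
        xi = x0
        if attempt > 0:
            step = opts["perturbation_scale"] * comp.scales
            lo = np.maximum(np.where(np.isfinite(comp.lb), comp.lb, -1e6),
                            x0 - step)
            hi = np.minimum(np.where(np.isfinite(comp.ub), comp.ub, 1e6),
                            x0 + step)
            xi = rng.uniform(lo, np.maximum(lo, hi))
        sol = _solve_once(comp, xi, opts)
        if best is None:
            best = sol
        else:
            sign = comp.obj_sign
            key = lambda s: (rank[s.status],
                             sign * s.objective_value
                             if np.isfinite(s.objective_value) else np.inf)
            if key(sol) < key(best):
                best = sol
        attempt += 1
        if attempt < planned:
            continue  # seeded multistart: run all planned attempts
        if best.status == "optimal" or attempt >= max_attempts:
            break

    if (opts["polish"] and opts["method"] == "trust-constr"
            and best.status == "optimal"
            and len(comp.names) <= int(opts["polish_max_size"])):
        popts = dict(opts)
        popts["method"] = "slsqp"
        popts["max_iterations"] = 100
        popts["tolerance"] = min(opts["tolerance"], 1e-9)
        x_best = np.array([best.values[n] for n in comp.names])
        polished = _solve_once(comp, x_best, popts)
        sign = comp.obj_sign
        if polished.status == "optimal" and \
                sign * polished.objective_value <= \
                sign * best.objective_value + opts["tolerance"]:
            best = polished

    if opts["polish"] and best.status == "optimal" and \
            not comp.nl_rows and not comp.obj_hess_keys:
        # purely linear program: crossover, then an exact primal
        # active-set refinement to the optimal vertex/face
        for eps in (1e-7, 1e-5, 1e-3):
            polished = _vertex_polish(comp, best, eps)
            if polished is not None and \
                    comp.obj_sign * polished.objective_value <= \
                    comp.obj_sign * best.objective_value:
                best = polished
        refined = _active_set_lp_refine(comp, best)
        if refined is not None:
            best = refined
    return best


def _solve_once(comp: _Compiled, x0: np.ndarray, opts: dict) -> Solution:
    """Solve in the scaled coordinates y = x / scales."""
    S = comp.scales
    D = sparse.diags(S)

    constraints = []
    if comp.A_eq.shape[0]:
        constraints.append(LinearConstraint(comp.A_eq @ D, comp.b_eq,
                                            comp.b_eq))
    if comp.A_ub.shape[0]:
        constraints.append(LinearConstraint(
            comp.A_ub @ D, -np.inf * np.ones(len(comp.b_ub)), comp.b_ub))
    if comp.nl_rows:
        lbs, ubs = [], []
        for row in comp.nl_rows:
            if row["relation"] == "=":
                lbs.append(row["rhs"]), ubs.append(row["rhs"])
            elif row["relation"] == "<=":
                lbs.append(-np.inf), ubs.append(row["rhs"])
            else:
                lbs.append(row["rhs"]), ubs.append(np.inf)
        constraints.append(NonlinearConstraint(
            lambda y: comp.nl_values(S * y), np.array(lbs), np.array(ubs),
            jac=lambda y: comp.nl_jacobian(S * y) @ D,
            hess=lambda y, v: D @ comp.nl_hessian_combination(S * y, v) @ D))

    sign = comp.obj_sign
    fun = lambda y: sign * comp.objective_value(S * y)
    grad = lambda y: sign * (S * comp.objective_gradient(S * y))
    hess = lambda y: (sign * (D @ comp.objective_hessian(S * y) @ D)).toarray() \
        if opts["method"] == "slsqp" else \
        sign * (D @ comp.objective_hessian(S * y) @ D)

    tol = float(opts["tolerance"])
    feas_tol = opts["feasibility_tolerance"]
    if feas_tol is None:
        feas_tol = max(1e-6, tol)

    y0 = x0 / S
    ylb, yub = comp.lb / S, comp.ub / S
    try:
        if opts["method"] == "slsqp":
            # SLSQP's ftol is absolute; scale it with the objective magnitude
            # at the start so convergence means the same thing at F ~ 1e2 as
            # at F ~ 1e-6
            f0 = abs(fun(y0))
            ftol = tol * 1e-2 * max(1.0, f0)
            res = minimize(fun, y0, jac=grad, method="SLSQP",
                           bounds=list(zip(ylb, yub)),
                           constraints=_slsqp_constraints(comp, S),
                           options={"maxiter": int(opts["max_iterations"]),
                                    "ftol": ftol})
            niter = res.get("nit", 0)
            hit_limit = res.status == 9
        else:
            res = minimize(fun, y0, jac=grad, hess=hess,
                           method="trust-constr",
                           bounds=Bounds(ylb, yub),
                           constraints=constraints,
                           options={"gtol": tol, "xtol": 1e-10,
                                    "maxiter": int(opts["max_iterations"]),
                                    "verbose": 0})
            niter = res.niter
            hit_limit = res.status == 0
    except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
        return Solution(values={n: float(x0[i]) for i, n in enumerate(comp.names)},
                        objective_value=np.nan, status="failed",
                        residuals=comp.violation(x0), message=str(exc))

    x = S * np.asarray(res.x, dtype=float)
    viol = comp.violation(x)
    if hit_limit and viol <= feas_tol:
        status = "iteration-limit"
    elif viol > max(feas_tol, 1e-4):
        status = "infeasible"
    elif viol > feas_tol:
        status = "failed"
    elif hit_limit:
        status = "iteration-limit"
    else:
        status = "optimal"
    return Solution(
        values={n: float(x[i]) for i, n in enumerate(comp.names)},
        objective_value=comp.objective_value(x),
        status=status, residuals=viol,
        message=getattr(res, "message", ""), n_iterations=int(niter))


def _vertex_polish(comp: _Compiled, sol: Solution,
                   eps_scale: float = 1e-5) -> Solution | None:
    """Crossover for purely linear programs: from a near-optimal interior
    point, fix the apparently-active bounds, treat apparently-active
    inequality rows as equalities, and solve the resulting linear system.
    Accepted only if the refined point is feasible and not worse."""
    x = np.array([sol.values[n] for n in comp.names])
    n = len(x)
    eps = eps_scale * np.maximum(1.0, np.abs(x))
    fixed = np.full(n, np.nan)
    at_lb = np.isfinite(comp.lb) & (x - comp.lb <= eps)
    at_ub = np.isfinite(comp.ub) & (comp.ub - x <= eps)
    fixed[at_lb] = comp.lb[at_lb]
    fixed[at_ub] = comp.ub[at_ub]
    free = np.isnan(fixed)
    if not free.any():
        return None

    rows, rhs = [], []
    if comp.A_eq_full.shape[0]:
        A = comp.A_eq_full.toarray()
        rows.append(A)
        rhs.append(comp.b_eq_full)
    if comp.A_ub.shape[0]:
        A_ub = comp.A_ub.toarray()
        resid = comp.b_ub - A_ub @ x
        active = resid <= eps_scale * np.maximum(1.0, np.abs(comp.b_ub))
        if active.any():
            rows.append(A_ub[active])
            rhs.append(comp.b_ub[active])
    if not rows:
        return None
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    x_fix = np.where(free, x, fixed)
    # minimal-norm correction of the free block onto the active face
    resid = b - A @ x_fix
    d, *_ = np.linalg.lstsq(A[:, free], resid, rcond=None)
    x_new = x_fix.copy()
    x_new[free] = x_fix[free] + d
    if np.any(x_new < comp.lb - 1e-8) or np.any(x_new > comp.ub + 1e-8):
        return None
    if comp.violation(x_new) > 1e-8:
        return None
    obj_new = comp.objective_value(x_new)
    if comp.obj_sign * obj_new > comp.obj_sign * sol.objective_value + 1e-9:
        return None
    return Solution(
        values={name: float(x_new[i]) for i, name in enumerate(comp.names)},
        objective_value=obj_new, status="optimal",
        residuals=comp.violation(x_new), message="vertex crossover",
        n_iterations=sol.n_iterations)


def _active_set_lp_refine(comp: _Compiled, sol: Solution,
                          tol: float = 1e-9) -> Solution | None:
    """Primal active-set refinement for LPs with equality rows and bounds.

    From a feasible near-optimal point, walks along faces of the polytope
    (projected-gradient direction, exact ratio test, multiplier-based bound
    release) to the exact optimum.  Returns None when it cannot certify an
    improvement (e.g. general inequality rows present, or the iteration cap
    is reached mid-walk).
    """
    if comp.A_ub.shape[0] or comp.nl_rows or comp.obj_hess_keys:
        return None
    n = len(comp.names)
    c = comp.objective_gradient(np.zeros(n))
    w = -comp.obj_sign * c        # ascend w·x
    wnorm = np.max(np.abs(w)) if n else 0.0
    if wnorm == 0:
        return None
    A = comp.A_eq.toarray() if comp.A_eq.shape[0] else np.zeros((0, n))
    x = np.array([sol.values[k] for k in comp.names])

    working: dict[int, str] = {}
    scale = np.maximum(1.0, np.abs(x))
    for i in range(n):
        if np.isfinite(comp.lb[i]) and x[i] - comp.lb[i] <= 1e-7 * scale[i]:
            working[i] = "lb"
            x[i] = comp.lb[i]
        elif np.isfinite(comp.ub[i]) and comp.ub[i] - x[i] <= 1e-7 * scale[i]:
            working[i] = "ub"
            x[i] = comp.ub[i]

    for _ in range(5 * (n + 1)):
        free = np.array([i for i in range(n) if i not in working], dtype=int)
        if free.size:
            Af = A[:, free]
            wf = w[free]
            if Af.shape[0]:
                lam, *_ = np.linalg.lstsq(Af.T, wf, rcond=None)
                d_f = wf - Af.T @ lam
            else:
                lam = np.zeros(0)
                d_f = wf.copy()
        else:
            lam, d_f = None, np.zeros(0)

        if d_f.size and np.max(np.abs(d_f)) > tol * (1 + wnorm):
            d = np.zeros(n)
            d[free] = d_f
            alpha, blocker, kind = np.inf, None, None
            for i in free:
                if d[i] > 1e-12 and np.isfinite(comp.ub[i]):
                    a = (comp.ub[i] - x[i]) / d[i]
                    if a < alpha:
                        alpha, blocker, kind = a, i, "ub"
                elif d[i] < -1e-12 and np.isfinite(comp.lb[i]):
                    a = (comp.lb[i] - x[i]) / d[i]
                    if a < alpha:
                        alpha, blocker, kind = a, i, "lb"
            if blocker is None:
                return None  # unbounded ray; leave the incumbent alone
            x = x + max(alpha, 0.0) * d
            x[blocker] = comp.lb[blocker] if kind == "lb" else comp.ub[blocker]
            working[blocker] = kind
            continue

        # stationary on the current face: check bound multipliers
        if lam is None:
            break
        mu = w - (A.T @ lam if A.shape[0] else 0.0)
        release, worst = None, tol * (1 + wnorm)
        for i, kind in working.items():
            if kind == "ub" and -mu[i] > worst:
                release, worst = i, -mu[i]
            elif kind == "lb" and mu[i] > worst:
                release, worst = i, mu[i]
        if release is None:
            break  # optimality certified on this face
        x[release] = np.clip(x[release], comp.lb[release], comp.ub[release])
        del working[release]
    else:
        return None  # iteration cap: do not trust the partial walk

    if np.any(x < comp.lb - 1e-8) or np.any(x > comp.ub + 1e-8) or \
            comp.violation(x) > 1e-7:
        return None
    obj = comp.objective_value(x)
    if comp.obj_sign * obj > comp.obj_sign * sol.objective_value + 1e-12:
        return None
    return Solution(
        values={k: float(x[i]) for i, k in enumerate(comp.names)},
        objective_value=obj, status="optimal",
        residuals=comp.violation(x), message="active-set crossover",
        n_iterations=sol.n_iterations)


def _slsqp_constraints(comp: _Compiled, S: np.ndarray):
    cons = []
    if comp.A_eq.shape[0]:
        A, b = (comp.A_eq @ sparse.diags(S)).toarray(), comp.b_eq
        cons.append({"type": "eq", "fun": lambda y, A=A, b=b: A @ y - b,
                     "jac": lambda y, A=A: A})
    if comp.A_ub.shape[0]:
        A, b = (comp.A_ub @ sparse.diags(S)).toarray(), comp.b_ub
        cons.append({"type": "ineq", "fun": lambda y, A=A, b=b: b - A @ y,
                     "jac": lambda y, A=A: -A})
    for row in comp.nl_rows:
        val, gvars, gfun, rhs = row["val"], row["grad_vars"], row["grad"], row["rhs"]

        def make(valf, gvars, gfun, rhs, flip):
            def f(y):
                return flip * (valf(S * y)[0] - rhs)

            def j(y):
                g = np.zeros(len(comp.names))
                if gvars.size:
                    g[gvars] = flip * gfun(S * y)
                return g * S
            return f, j

        if row["relation"] == "=":
            f, j = make(val, gvars, gfun, rhs, 1.0)
            cons.append({"type": "eq", "fun": f, "jac": j})
        elif row["relation"] == "<=":
            f, j = make(val, gvars, gfun, rhs, -1.0)
            cons.append({"type": "ineq", "fun": f, "jac": j})
        else:
            f, j = make(val, gvars, gfun, rhs, 1.0)
            cons.append({"type": "ineq", "fun": f, "jac": j})
    return cons


def _linear_coeffs(expr: sp.Expr) -> tuple[dict[str, float], float]:
    """Coefficients of a linear expression; raises if nonlinear content found."""
    expr = sp.expand(expr)
    coeffs: dict[str, float] = {}
    const = 0.0
    for term, coef in expr.as_coefficients_dict().items():
        if term == 1:
            const += float(coef)
        elif isinstance(term, sp.Symbol):
            coeffs[term.name] = coeffs.get(term.name, 0.0) + float(coef)
        else:
            raise ValueError(f"nonlinear term {term} in supposedly linear expression")
    return coeffs, const


def solve_lp(prog: NonlinearProgram) -> Solution:
    """Global optimum of a purely linear program via the LP path (HiGHS).

    Rejects programs containing nonlinear constraints or a nonlinear
    objective.
    """
    if prog.nonlinear_constraints:
        raise ValueError("program has nonlinear constraints; use solve()")
    obj = _substituted(prog.objective, prog.parameters)
    coeffs, const = _linear_coeffs(obj)  # raises if nonlinear

    comp = _compiled(prog)
    n = len(comp.names)
    c = np.zeros(n)
    for name, v in coeffs.items():
        c[comp.index[name]] = v
    sign = comp.obj_sign
    res = linprog(sign * c,
                  A_eq=comp.A_eq if comp.A_eq.shape[0] else None,
                  b_eq=comp.b_eq if comp.A_eq.shape[0] else None,
                  A_ub=comp.A_ub if comp.A_ub.shape[0] else None,
                  b_ub=comp.b_ub if comp.A_ub.shape[0] else None,
                  bounds=list(zip(comp.lb, comp.ub)), method="highs")
    status = {0: "optimal", 1: "iteration-limit", 2: "infeasible",
              3: "failed", 4: "failed"}.get(res.status, "failed")
    if res.x is None:
        values = {name: 0.0 for name in comp.names}
        objv = np.nan
        resid = np.inf
    else:
        x = np.asarray(res.x, dtype=float)
        values = {name: float(x[i]) for i, name in enumerate(comp.names)}
        objv = float(c @ x + const)
        resid = comp.violation(x)
    return Solution(values=values, objective_value=objv, status=status,
                    residuals=resid, message=res.message)


def epigraph_min(prog: NonlinearProgram, name: str, *exprs,
                 lower: float = -INF, upper: float = INF) -> sp.Symbol:
    """Auxiliary variable t with t <= e for each expression (epigraph form).

    Under an objective that (directly or indirectly) pushes ``t`` upward,
    ``t`` attains min(exprs) at the optimum, keeping the program smooth.
    """
    t = prog.add_variable(name, lower, upper)
    for e in exprs:
        prog.add_nonlinear_constraint(t - sp.sympify(e), "<=", 0.0)
    return t
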