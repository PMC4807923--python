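"""Program construction, analytic derivatives, LP/NLP agreement, statuses."""

import numpy as np
import pytest
import sympy as sp

from nlfba.model_io import MetabolicModel, Reaction, Species
from nlfba.nlp_core import (NonlinearProgram, derivative_evaluators,
                            epigraph_min, solve, solve_lp, sym)


def _linear_chain_model():
    """A -> B with exchanges for both."""
    m = MetabolicModel(id="chain", compartments=["c"])
    m.species = [Species(id=s, compartment="c") for s in ("A", "B")]
    m.reactions = [
        Reaction(id="conv", stoichiometry={"A": -1, "B": 1},
                 reversible=False, lower_bound=0, upper_bound=10),
        Reaction(id="EX_A", stoichiometry={"A": -1}, reversible=True,
                 lower_bound=-10, upper_bound=10),
        Reaction(id="EX_B", stoichiometry={"B": -1}, reversible=True,
                 lower_bound=-10, upper_bound=10),
    ]
    return m


class TestFromModel:
    def test_one_reaction_with_exchanges(self):
        prog = NonlinearProgram.from_model(_linear_chain_model())
        assert len(prog.variables) == 3
        eq_rows = [c for c in prog.linear_constraints if c[1] == "="]
        assert len(eq_rows) == 2

    def test_steady_state_carbon_balance_on_toy(self, toy_two_cell):
        """Net CO2 uptake must equal the carbon leaving through exports."""
        from nlfba.synthetic_data import CARBON
        prog = NonlinearProgram.from_model(toy_two_cell)
        # drive the network: fix some assimilation through the carboxylases
        prog.set_bounds("ms_pepc", 5.0, 5.0)
        prog.set_objective(-sym("ms_EX_co2"), "max")
        sol = solve_lp(prog)
        assert sol.status == "optimal"
        carbon_out = 0.0
        for r in toy_two_cell.reactions:
            if not r.is_exchange:
                continue
            sid = next(iter(r.stoichiometry))
            base = sid.split("_", 1)[1]
            carbon_out += sol.values[r.id] * CARBON.get(base, 0)
        # exports are positive; net carbon export must vanish at steady state
        assert abs(carbon_out) < 1e-6

    def test_boundary_species_excluded_from_rows(self):
        m = _linear_chain_model()
        m.species[0].boundary = True
        prog = NonlinearProgram.from_model(m)
        assert len([c for c in prog.linear_constraints if c[1] == "="]) == 1


class TestNonlinearConstraints:
    def test_hyperbola_constraint(self):
        prog = NonlinearProgram()
        v1 = prog.add_variable("v1", 0.1, 10)
        v2 = prog.add_variable("v2", 0.1, 10)
        prog.add_nonlinear_constraint(v1 * v2, "=", 1.0)
        prog.set_objective(v1 + v2, "min")
        sol = solve(prog, start={"v1": 2.0, "v2": 2.0})
        assert sol.status == "optimal"
        assert sol["v1"] * sol["v2"] == pytest.approx(1.0, abs=1e-5)
        assert sol["v1"] == pytest.approx(1.0, abs=1e-3)

    def test_trivial_constraint_keeps_feasibility(self):
        prog = NonlinearProgram()
        prog.add_variable("x", 0, 5)
        prog.add_nonlinear_constraint(sp.Integer(0), "=", 0.0)
        prog.set_objective(sym("x"), "max")
        sol = solve(prog)
        assert sol.status == "optimal"
        assert sol["x"] == pytest.approx(5.0, abs=1e-5)

    def test_quadratic_bound(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", -10, 10)
        prog.add_nonlinear_constraint(x ** 2, "<=", 4.0)
        prog.set_objective(x, "max")
        sol = solve(prog, start={"x": 0.5})
        assert sol["x"] == pytest.approx(2.0, abs=1e-4)

    def test_unknown_symbol_rejected(self):
        prog = NonlinearProgram()
        prog.add_variable("x")
        with pytest.raises(ValueError, match="undeclared"):
            prog.add_nonlinear_constraint(sym("x") * sym("ghost"), "=", 1.0)

    def test_non_differentiable_rejected_with_guidance(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", -1, 1)
        prog.add_nonlinear_constraint(sp.Abs(x), "<=", 1.0)
        prog.set_objective(x, "max")
        with pytest.raises(ValueError, match="direction-assignment"):
            solve(prog)


def _finite_difference_gradient(f, x, h=1e-6):
    h = np.broadcast_to(np.asarray(h, dtype=float), x.shape)
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        g[i] = (f(xp) - f(xm)) / (2 * h[i])
    return g


class TestDerivatives:
    def test_linear_program_has_zero_hessian(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", 0, 1)
        y = prog.add_variable("y", 0, 1)
        prog.set_objective(2 * x + 3 * y, "min")
        _, _, (hess, sparsity) = derivative_evaluators(prog)
        assert sparsity == []
        H = hess(np.array([0.5, 0.5]))
        assert np.count_nonzero(H.toarray() if hasattr(H, "toarray") else H) == 0

    def test_quadratic_objective_hessian_is_two_identity(self):
        prog = NonlinearProgram()
        xs = [prog.add_variable(f"v{i}", -10, 10) for i in range(4)]
        d = [1.0, 2.0, 3.0, 4.0]
        prog.set_objective(sum((x - di) ** 2 for x, di in zip(xs, d)), "min")
        _, _, (hess, _) = derivative_evaluators(prog)
        H = hess(np.zeros(4)).toarray()
        assert np.allclose(H, 2 * np.eye(4))

    def test_rubisco_constraint_jacobian_vs_finite_differences(self, rng):
        """Analytic gradient of the kinetic law matches central differences."""
        from nlfba.c4_kinetics import C4Params, rubisco_carboxylation_expr
        params = C4Params()
        prog = NonlinearProgram()
        vc = prog.add_variable("vc", 0, 100)
        C = prog.add_variable("C", 1, 1e6)
        O = prog.add_variable("O", 1, 1e6)
        vmax = prog.add_variable("vmax", 0, 100)
        prog.add_nonlinear_constraint(
            vc - rubisco_carboxylation_expr(vmax, C, O, params), "=", 0.0)
        prog.set_objective(vc, "max")
        _, (jac, sparsity), _ = derivative_evaluators(prog)
        assert len(sparsity) > 0
        comp_fun = lambda x: _constraint_value(prog, x)
        for _ in range(20):
            x = np.array([rng.uniform(0, 50), rng.uniform(100, 5000),
                          rng.uniform(1e4, 3e5), rng.uniform(1, 80)])
            J = np.asarray(jac(x).todense()).ravel()
            fd = _finite_difference_gradient(comp_fun, x,
                                             h=1e-4 * np.maximum(np.abs(x), 1))
            scale = np.maximum(np.abs(fd), 1.0)
            assert np.all(np.abs(J - fd) / scale < 1e-5)


def _constraint_value(prog, x):
    from nlfba.nlp_core import _compiled
    return _compiled(prog).nl_values(np.asarray(x, float))[0]


class TestSolvePaths:
    def test_lp_simple_bound(self):
        prog = NonlinearProgram()
        v1 = prog.add_variable("v1", -100, 100)
        prog.add_linear_constraint({"v1": 1.0}, "<=", 5.0)
        prog.set_objective(v1, "max")
        sol = solve_lp(prog)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(5.0)

    def test_lp_rejects_nonlinear(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", 0, 1)
        prog.set_objective(x ** 2, "min")
        with pytest.raises(ValueError, match="nonlinear"):
            solve_lp(prog)

    def test_infeasible_lp_status(self):
        prog = NonlinearProgram()
        prog.add_variable("x", 0, 1)
        prog.add_linear_constraint({"x": 1.0}, ">=", 2.0)
        prog.set_objective(sym("x"), "min")
        assert solve_lp(prog).status == "infeasible"

    def test_nlp_max_with_quadratic_constraint(self):
        prog = NonlinearProgram()
        v = prog.add_variable("v", -10, 10)
        prog.add_nonlinear_constraint(v ** 2, "<=", 9.0)
        prog.set_objective(v, "max")
        sol = solve(prog, start={"v": 1.0})
        assert sol["v"] == pytest.approx(3.0, abs=1e-4)

    def test_cross_solver_agreement_on_toy_fba(self, toy_two_cell):
        prog = NonlinearProgram.from_model(toy_two_cell)
        prog.set_bounds("ms_EX_co2", -8.0, 8.0)
        prog.set_objective(-sym("ms_EX_co2"), "max")
        lp = solve_lp(prog)
        nlp = solve(prog)
        assert lp.status == nlp.status == "optimal"
        assert abs(lp.objective_value - nlp.objective_value) <= \
            1e-6 * (1 + abs(lp.objective_value))

    def test_deterministic_for_fixed_seed(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", -5, 5)
        y = prog.add_variable("y", -5, 5)
        prog.add_nonlinear_constraint(x * y, "=", 2.0)
        prog.set_objective(x ** 2 + y ** 2, "min")
        sols = [solve(prog, start={"x": 1, "y": 1},
                      options={"restarts": 2, "seed": 7}) for _ in range(2)]
        assert sols[0].values == sols[1].values


class TestEpigraphMin:
    def test_min_realized_under_maximization(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", 0, 10)
        t = epigraph_min(prog, "t", x, 4.0, lower=0, upper=100)
        prog.set_objective(t, "max")
        sol = solve(prog, start={"x": 1.0})
        # t = min(x, 4) maximized over x in [0, 10] -> 4
        assert sol["t"] == pytest.approx(4.0, abs=1e-4)


class TestSerialization:
    def test_json_round_trip(self):
        prog = NonlinearProgram()
        x = prog.add_variable("x", 0, 5)
        y = prog.add_variable("y", -1, 1)
        prog.add_linear_constraint({"x": 1, "y": 2}, "<=", 4.0)
        prog.add_nonlinear_constraint(x * y + y ** 2, "=", 0.5)
        prog.set_objective(x - y, "max")
        again = NonlinearProgram.from_json(prog.to_json())
        assert again.variables == prog.variables
        assert again.linear_constraints == prog.linear_constraints
        s1 = solve(prog, start={"x": 1, "y": 0.5})
        s2 = solve(again, start={"x": 1, "y": 0.5})
        assert s1.objective_value == pytest.approx(s2.objective_value,
                                                   abs=1e-6)
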