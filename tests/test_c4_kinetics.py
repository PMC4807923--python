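"""Kinetic-law constraints: half saturation, capacity ratio, diffusion."""

import numpy as np
import pytest

from nlfba.c4_kinetics import (C4Params, C4ReactionIds, assimilation_summary,
                               attach_c4_constraints, diffusive_flux,
                               maximize_assimilation, pepc_rate_expr,
                               rubisco_carboxylation_expr,
                               rubisco_oxygenation_expr)
from nlfba.nlp_core import NonlinearProgram, solve, sym


@pytest.fixture(scope="module")
def params():
    return C4Params()


class TestParams:
    def test_oxygen_conductance_tracks_g_s(self):
        for g in (0.5, 1.03, 3.0):
            p = C4Params(g_s=g)
            assert p.g_sO == pytest.approx(0.047 * g)

    def test_capacity_ratio_formula(self, params):
        # v_o,max / v_c,max = k_O / (k_C · S_R), with k_O on the same scale
        assert params.vo_vc_capacity_ratio == pytest.approx(
            450e3 / (650 * 2590))

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            C4Params(k_C=-1)
        with pytest.raises(ValueError):
            C4Params(r_d=-0.1)

    def test_conversion_function(self):
        # 1.03 mmol m-2 s-1 bar-1 across 1000 μbar -> 1.03 μmol m-2 s-1
        assert diffusive_flux(1.03, 1000.0) == pytest.approx(1.03)


class TestKineticLaws:
    def test_half_saturation_without_oxygen(self, params):
        # O2 = 0: v_c = v_cmax·C/(C + k_C); at C = k_C exactly half
        v = rubisco_carboxylation_expr(50.0, params.k_C, 0.0, params)
        assert v == pytest.approx(25.0)

    def test_oxygenation_carboxylation_ratio_identity(self, params, rng):
        """v_o/v_c = (1/S_R)(O/C) whenever capacities obey the imposed ratio."""
        for _ in range(100):
            C = rng.uniform(10, 1e4)
            O = rng.uniform(1e3, 5e5)
            vc = rubisco_carboxylation_expr(50.0, C, O, params)
            vo = rubisco_oxygenation_expr(
                params.vo_vc_capacity_ratio * 50.0, C, O, params)
            assert vo / vc == pytest.approx(O / (params.S_R * C), rel=1e-10)

    def test_pepc_half_saturation_and_limits(self, params):
        assert pepc_rate_expr(100.0, params.k_C_p, params) == pytest.approx(50.0)
        assert pepc_rate_expr(100.0, 0.0, params) == 0.0
        levels = [pepc_rate_expr(100.0, c, params)
                  for c in (10, 100, 1e3, 1e5, 1e7)]
        assert all(a < b for a, b in zip(levels, levels[1:]))
        assert levels[-1] < 100.0  # saturates below v_pmax


class TestConstraintAttachment:
    def _two_cell_prog(self, toy_two_cell, params, caps):
        prog = NonlinearProgram.from_model(toy_two_cell)
        attach_c4_constraints(prog, params, C4ReactionIds(), caps)
        return prog

    def test_missing_reactions_raise(self, params):
        prog = NonlinearProgram()
        from nlfba.c4_kinetics import add_rubisco_constraints
        with pytest.raises(ValueError, match="not in program"):
            add_rubisco_constraints(prog, params)

    def test_constraint_matches_direct_formula_on_grid(self, toy_two_cell,
                                                       params, rng):
        """Constraint residual vanishes exactly where the law holds."""
        from nlfba.nlp_core import _compiled
        prog = self._two_cell_prog(toy_two_cell, params,
                                   {"v_cmax": 50.0, "v_pmax": 110.0})
        comp = _compiled(prog)
        idx = comp.index
        for _ in range(100):
            x = np.zeros(len(comp.names))
            C, O = rng.uniform(10, 1e4), rng.uniform(1e3, 5e5)
            vmax = rng.uniform(0, 50)
            x[idx["CO2_BS"]], x[idx["O2_BS"]] = C, O
            x[idx["vcmax_bs"]] = vmax
            x[idx["bs_rbc_c"]] = rubisco_carboxylation_expr(vmax, C, O, params)
            x[idx["bs_rbc_o"]] = rubisco_oxygenation_expr(
                params.vo_vc_capacity_ratio * vmax, C, O, params)
            vals = comp.nl_values(x)
            assert np.all(np.abs(vals) < 1e-10)

    def test_diffusion_rows_linear_and_proportional(self, toy_two_cell,
                                                    params):
        prog = self._two_cell_prog(toy_two_cell, params,
                                   {"v_cmax": 50.0, "v_pmax": 110.0})
        # find the leak rows among the linear constraints
        rows = [c for c in prog.linear_constraints
                if "CO2_BS" in c[0] or "O2_BS" in c[0]]
        assert len(rows) == 2
        for coeffs, rel, rhs in rows:
            assert rel == "="
            if "leak_co2" in coeffs:
                # leak = g_s·1e-3·(C_BS − C_ME): doubling ΔC doubles L
                g = -coeffs["CO2_BS"]
                assert g == pytest.approx(diffusive_flux(params.g_s, 1.0))
                assert rhs == pytest.approx(-g * params.CO2_ME)
            else:
                g = -coeffs["O2_BS"]
                assert g == pytest.approx(diffusive_flux(params.g_sO, 1.0))


class TestMaximizeAssimilation:
    def test_no_pump_limited_by_diffusion(self, toy_two_cell, params):
        sol = maximize_assimilation(toy_two_cell, params,
                                    {"v_cmax": 50.0, "v_pmax": 0.0})
        s = assimilation_summary(sol)
        assert s["status"] == "optimal"
        # without the pump, CO2 reaches the bundle sheath by diffusion only:
        # A is small, positive, and far below the Rubisco capacity
        assert 0 < s["A"] < 50.0
        assert s["C_BS"] < params.CO2_ME  # drawn down, not concentrated
        assert s["A"] == pytest.approx(-s["L"], rel=1e-2)

    def test_ratio_identity_at_optimum(self, toy_two_cell, params):
        sol = maximize_assimilation(toy_two_cell, params,
                                    {"v_cmax": 50.0, "v_pmax": 70.0})
        s = assimilation_summary(sol)
        lhs = s["v_o"] * params.S_R * s["C_BS"]
        rhs = s["v_c"] * s["O_BS"]
        assert lhs == pytest.approx(rhs, rel=1e-3)

    def test_assimilation_nondecreasing_in_capacities(self, toy_two_cell,
                                                      params):
        grid = [(30.0, 30.0), (30.0, 70.0), (50.0, 70.0), (50.0, 110.0)]
        A = [assimilation_summary(maximize_assimilation(
            toy_two_cell, params, {"v_cmax": vc, "v_pmax": vp}))["A"]
            for vc, vp in grid]
        for lo, hi in zip(A, A[1:]):
            assert hi >= lo - 1e-3

    def test_nonzero_respiration_rejected(self, toy_two_cell):
        with pytest.raises(ValueError, match="r_d = r_m = 0"):
            maximize_assimilation(toy_two_cell, C4Params(r_d=0.5), {})

    def test_carbon_bookkeeping_at_optimum(self, toy_two_cell, params):
        """A = v_c − 0.5·v_o holds through the network stoichiometry."""
        sol = maximize_assimilation(toy_two_cell, params,
                                    {"v_cmax": 40.0, "v_pmax": 90.0})
        s = assimilation_summary(sol)
        assert s["A"] == pytest.approx(s["v_c"] - 0.5 * s["v_o"], rel=1e-3)
        assert s["A"] == pytest.approx(s["v_p"] - s["L"], rel=1e-3)
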