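"""C4 physiological constraints for nonlinear FBA programs.

Attaches Michaelis-Menten kinetic laws with competitive CO2/O2 inhibition for
Rubisco, a saturating PEPC law, and linear bundle-sheath ⇄ mesophyll gas
diffusion rows to a :class:`~nlfba.nlp_core.NonlinearProgram`, introducing
bundle-sheath gas-level variables.

Units
-----
Gas levels are "equivalent partial pressures" in μbar (≡ μmol mol⁻¹ at 1 bar),
one scalar per cell, shared across subcellular compartments.  The mesophyll
level equals the intercellular level (mesophyll-wall resistance neglected).
Conductances are stored on the mmol m⁻² s⁻¹ bar⁻¹ scale, so that
``conductance × Δ(μbar)`` needs a single 10⁻³ factor to yield flux in
μmol m⁻² s⁻¹; that conversion is centralized in :func:`diffusive_flux`.
The literature prints the PEPC half-saturation constant and the bundle-sheath
conductance with inconsistent unit strings; both interpretations are exposed
(``k_C_p_unit``, ``g_s_unit`` metadata) and the defaults here are the ones
consistent with the enzyme-limited physiology oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp

from .nlp_core import NonlinearProgram, Solution, solve, sym

__all__ = [
    "C4Params",
    "C4ReactionIds",
    "GasState",
    "RubiscoVars",
    "diffusive_flux",
    "rubisco_carboxylation_expr",
    "rubisco_oxygenation_expr",
    "pepc_rate_expr",
    "add_rubisco_constraints",
    "add_pepc_constraint",
    "add_diffusion_constraints",
    "maximize_assimilation",
]

#: mmol m⁻² s⁻¹ bar⁻¹ × μbar → μmol m⁻² s⁻¹
_CONDUCTANCE_FLUX_SCALE = 1e-3


def diffusive_flux(conductance_mmol, delta_ubar):
    """Flux (μmol m⁻² s⁻¹) through a conductance (mmol m⁻² s⁻¹ bar⁻¹)
    driven by a partial-pressure difference (μbar)."""
    return _CONDUCTANCE_FLUX_SCALE * conductance_mmol * delta_ubar


@dataclass
class C4Params:
    """Kinetic constants, conductances and mesophyll gas levels.

    Defaults are values typical of C4 species: k_C 650 μmol mol⁻¹, k_O
    450 mmol mol⁻¹, S_R 2590, k_C,p 80 (μmol mol⁻¹ scale), g_s 1.03
    mmol m⁻² s⁻¹ bar⁻¹ with g_s,O = 0.047·g_s.  Respiration defaults to
    zero, the condition under which the nonlinear-FBA and physiology-oracle
    assimilation surfaces are compared.
    """

    k_C: float = 650.0          # μmol mol⁻¹ (≡ μbar)
    k_O: float = 450.0          # mmol mol⁻¹
    S_R: float = 2590.0         # dimensionless
    k_C_p: float = 80.0         # μmol mol⁻¹ scale (printed unit preserved below)
    g_s: float = 1.03           # mmol m⁻² s⁻¹ bar⁻¹
    g_sO_ratio: float = 0.047   # g_s,O / g_s
    CO2_ME: float = 150.0       # μbar, mesophyll = intercellular level
    O2_ME: float = 210000.0     # μbar (21% O2 at 1 bar)
    r_d: float = 0.0            # bundle-sheath (day) respiration, μmol m⁻² s⁻¹
    r_m: float = 0.0            # mesophyll respiration, μmol m⁻² s⁻¹
    k_C_p_unit: str = "umol/mol (printed source says 'mmol mol-1')"
    g_s_unit: str = "mmol m-2 s-1 bar-1 (printed source says 'umol m-2 s-1')"

    def __post_init__(self):
        for name in ("k_C", "k_O", "S_R", "k_C_p", "g_s", "g_sO_ratio",
                     "CO2_ME", "O2_ME"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_d < 0 or self.r_m < 0:
            raise ValueError("respiration rates must be nonnegative")

    @property
    def k_O_ubar(self) -> float:
        """k_O converted from mmol mol⁻¹ to the μbar scale."""
        return self.k_O * 1e3

    @property
    def g_sO(self) -> float:
        """Bundle-sheath O2 conductance; always 0.047·g_s."""
        return self.g_sO_ratio * self.g_s

    @property
    def vo_vc_capacity_ratio(self) -> float:
        """v_o,max / v_c,max = k_O / (k_C · S_R)."""
        return self.k_O_ubar / (self.k_C * self.S_R)


@dataclass
class C4ReactionIds:
    """Which model reactions carry the kinetically constrained fluxes."""

    rubisco_c: str = "bs_rbc_c"
    rubisco_o: str = "bs_rbc_o"
    pepc: str = "ms_pepc"
    leak_co2: str = "leak_co2"   # positive = bundle sheath → mesophyll
    leak_o2: str = "leak_o2"
    decarboxylases: tuple[str, ...] = ("bs_nadp_me", "bs_pepck")
    co2_exchange: str = "ms_EX_co2"  # positive = export to atmosphere


@dataclass
class GasState:
    CO2_BS: str
    O2_BS: str
    leak_co2: str
    leak_o2: str


@dataclass
class RubiscoVars:
    v_c: str
    v_o: str
    v_cmax: "str | float"
    capacity_mode: str
    v_p: str | None = None
    v_pmax: "str | float | None" = None


# -- kinetic-law expressions (shared with the physiology oracle) -----------

def rubisco_carboxylation_expr(v_cmax, C, O, params: C4Params):
    """v_c,max · C / (C + k_C·(1 + O/k_O)); C, O in μbar."""
    return v_cmax * C / (C + params.k_C * (1 + O / params.k_O_ubar))


def rubisco_oxygenation_expr(v_omax, C, O, params: C4Params):
    """v_o,max · O / (O + k_O·(1 + C/k_C)); C, O in μbar."""
    return v_omax * O / (O + params.k_O_ubar * (1 + C / params.k_C))


def pepc_rate_expr(v_pmax, C, params: C4Params):
    """v_p,max · C / (k_C,p + C); C in μbar."""
    return v_pmax * C / (params.k_C_p + C)


# -- constraint attachment -------------------------------------------------

def _gas_var(prog: NonlinearProgram, name: str) -> sp.Symbol:
    if prog.has_variable(name):
        return sym(name)
    v = prog.add_variable(name, 0.0, 1e7)
    # gas levels live on the 1e3–1e5 μbar scale, fluxes on ~1e1
    prog.set_scale(name, 1e4 if "O2_BS" in name and not name.endswith("CO2_BS")
                   else 1e3)
    return v


def _capacity(prog, name, capacity_mode, cap):
    """Fixed capacity → numeric; optimizable → variable in [0, cap].

    A zero optimizable capacity is degenerate (an interval of width zero),
    so it collapses to the fixed numeric 0 and the kinetic law becomes a
    plain zero-flux row.
    """
    if capacity_mode == "fixed" or (capacity_mode == "optimizable" and cap == 0):
        return float(cap)
    if capacity_mode == "optimizable":
        if prog.has_variable(name):
            return sym(name)
        return prog.add_variable(name, 0.0, float(cap))
    raise ValueError(f"capacity_mode must be 'fixed' or 'optimizable', got {capacity_mode!r}")


def add_rubisco_constraints(prog: NonlinearProgram, params: C4Params,
                            ids: C4ReactionIds | None = None,
                            capacity_mode: str = "optimizable",
                            v_cmax: float = 100.0,
                            prefix: str = "") -> RubiscoVars:
    """Tie the carboxylase and oxygenase fluxes to bundle-sheath gas levels.

    Adds (creating them if needed) the gas-level variables
    ``<prefix>CO2_BS``/``<prefix>O2_BS`` and two equality constraints imposing
    the competitive Michaelis-Menten laws, with the capacity relation
    v_o,max = v_c,max·k_O/(k_C·S_R) built in — from which
    v_o/v_c = (1/S_R)·(P_O2/P_CO2) follows identically.

    In ``optimizable`` mode the carboxylation capacity is a variable bounded
    by ``v_cmax``; this is the epigraph-style encoding of an enzyme pool that
    need not be saturated, and lets an assimilation-maximizing solve realize
    the physiological min() between competing capacity limits smoothly.
    """
    ids = ids or C4ReactionIds()
    for rid in (prefix + ids.rubisco_c, prefix + ids.rubisco_o):
        if not prog.has_variable(rid):
            raise ValueError(f"rubisco reaction {rid!r} not in program")
    C = _gas_var(prog, prefix + "CO2_BS")
    O = _gas_var(prog, prefix + "O2_BS")
    vc = sym(prefix + ids.rubisco_c)
    vo = sym(prefix + ids.rubisco_o)
    vcmax = _capacity(prog, prefix + "vcmax_bs", capacity_mode, v_cmax)
    vomax = params.vo_vc_capacity_ratio * vcmax
    prog.add_nonlinear_constraint(
        vc - rubisco_carboxylation_expr(vcmax, C, O, params), "=", 0.0)
    prog.add_nonlinear_constraint(
        vo - rubisco_oxygenation_expr(vomax, C, O, params), "=", 0.0)
    return RubiscoVars(v_c=prefix + ids.rubisco_c, v_o=prefix + ids.rubisco_o,
                       v_cmax=(prefix + "vcmax_bs"
                               if capacity_mode == "optimizable" else v_cmax),
                       capacity_mode=capacity_mode)


def add_pepc_constraint(prog: NonlinearProgram, params: C4Params,
                        ids: C4ReactionIds | None = None,
                        capacity_mode: str = "optimizable",
                        v_pmax: float = 120.0,
                        prefix: str = "",
                        rubisco_vars: RubiscoVars | None = None) -> RubiscoVars:
    """v_p = v_p,max·C/(k_C,p + C) at the mesophyll CO2 level.

    The mesophyll level is a parameter (μbar), so the law reduces to a linear
    row tying the PEPC flux to its capacity; with an optimizable capacity in
    [0, v_pmax] the PEPC flux can realize any value up to the
    Michaelis-Menten rate, saturating there when pushed by the objective.
    """
    ids = ids or C4ReactionIds()
    rid = prefix + ids.pepc
    if not prog.has_variable(rid):
        raise ValueError(f"PEPC reaction {rid!r} not in program")
    vpmax = _capacity(prog, prefix + "vpmax_ms", capacity_mode, v_pmax)
    frac = params.CO2_ME / (params.k_C_p + params.CO2_ME)
    if isinstance(vpmax, float):
        prog.add_linear_constraint({rid: 1.0}, "=", vpmax * frac)
    else:
        prog.add_linear_constraint({rid: 1.0, str(vpmax): -frac}, "=", 0.0)
    out = rubisco_vars or RubiscoVars(v_c="", v_o="", v_cmax=0.0,
                                      capacity_mode=capacity_mode)
    out.v_p = rid
    out.v_pmax = str(vpmax) if not isinstance(vpmax, float) else vpmax
    return out


def add_diffusion_constraints(prog: NonlinearProgram, params: C4Params,
                              ids: C4ReactionIds | None = None,
                              prefix: str = "") -> GasState:
    """L = g_s·(CO2_BS − CO2_ME) and L_O = g_s,O·(O2_BS − O2_ME).

    The leak reaction fluxes (reversible; positive = bundle sheath →
    mesophyll) are identified with L and L_O through linear rows; g_s,O is
    always 0.047·g_s.
    """
    ids = ids or C4ReactionIds()
    for rid in (prefix + ids.leak_co2, prefix + ids.leak_o2):
        if not prog.has_variable(rid):
            raise ValueError(f"leak reaction {rid!r} not in program")
    C = _gas_var(prog, prefix + "CO2_BS")
    O = _gas_var(prog, prefix + "O2_BS")
    gc = diffusive_flux(params.g_s, 1.0)     # μmol per μbar of ΔC
    go = diffusive_flux(params.g_sO, 1.0)
    prog.add_linear_constraint(
        {prefix + ids.leak_co2: 1.0, str(C): -gc}, "=", -gc * params.CO2_ME)
    prog.add_linear_constraint(
        {prefix + ids.leak_o2: 1.0, str(O): -go}, "=", -go * params.O2_ME)
    return GasState(CO2_BS=str(C), O2_BS=str(O),
                    leak_co2=prefix + ids.leak_co2,
                    leak_o2=prefix + ids.leak_o2)


def attach_c4_constraints(prog: NonlinearProgram, params: C4Params,
                          ids: C4ReactionIds | None = None,
                          capacities: dict | None = None,
                          prefix: str = "") -> tuple[RubiscoVars, GasState]:
    """Rubisco + PEPC + diffusion in one call; returns the variable handles.

    ``capacities``: ``v_cmax``, ``v_pmax`` (upper bounds on the optimizable
    capacities) and optionally ``decarboxylase`` (a linear cap on the summed
    bundle-sheath decarboxylase fluxes, the effective PEP-regeneration
    limit).
    """
    ids = ids or C4ReactionIds()
    caps = {"v_cmax": 100.0, "v_pmax": 120.0}
    caps.update(capacities or {})
    rv = add_rubisco_constraints(prog, params, ids, "optimizable",
                                 caps["v_cmax"], prefix)
    rv = add_pepc_constraint(prog, params, ids, "optimizable",
                             caps["v_pmax"], prefix, rubisco_vars=rv)
    gs = add_diffusion_constraints(prog, params, ids, prefix)
    if caps.get("decarboxylase") is not None:
        row = {prefix + d: 1.0 for d in ids.decarboxylases
               if prog.has_variable(prefix + d)}
        if not row:
            raise ValueError("no decarboxylase reactions found for cap")
        prog.add_linear_constraint(row, "<=", float(caps["decarboxylase"]))
    return rv, gs


def maximize_assimilation(model, params: C4Params,
                          capacities: dict | None = None,
                          ids: C4ReactionIds | None = None,
                          options: dict | None = None,
                          export_only: tuple[str, ...] = ("bs_EX_suc",
                                                          "bs_EX_gly"),
                          regularization: float = 1e-8) -> Solution:
    """Maximize net CO2 uptake of a two-cell model under the C4 constraints.

    The objective is the negated atmospheric CO2 exchange flux (exchanges are
    written export-positive, so −flux is assimilation A).  Gas-level
    variables start at mesophyll ambient values, fluxes at zero.  Vascular
    exchanges listed in ``export_only`` are restricted to export — the
    source-tissue condition under which assimilation is compared to the
    enzyme-limited physiology model.

    A tiny quadratic flux penalty (``regularization``, default 1e-8) breaks
    the degeneracy of cost-free futile cycles, selecting the minimal-norm
    optimum; its effect on A is orders of magnitude below the comparison
    tolerance.
    """
    if params.r_d != 0.0 or params.r_m != 0.0:
        raise ValueError(
            "maximize_assimilation implements the r_d = r_m = 0 comparison "
            "condition; encode nonzero respiration in the model instead")
    ids = ids or C4ReactionIds()
    prog = NonlinearProgram.from_model(model)
    attach_c4_constraints(prog, params, ids, capacities)
    for rid in export_only:
        if prog.has_variable(rid):
            lb, ub = prog.bounds_of(rid)
            prog.set_bounds(rid, max(0.0, lb), ub)
    objective = -sym(ids.co2_exchange)
    if regularization:
        objective = objective - regularization * sum(
            sym(r.id) ** 2 for r in model.reactions)
    prog.set_objective(objective, "max")
    start = {"CO2_BS": params.CO2_ME, "O2_BS": params.O2_ME}
    return solve(prog, start=start, options=options)


def assimilation_summary(sol: Solution, ids: C4ReactionIds | None = None) -> dict:
    ids = ids or C4ReactionIds()
    return {
        "A": -sol[ids.co2_exchange],
        "C_BS": sol["CO2_BS"],
        "O_BS": sol["O2_BS"],
        "v_c": sol[ids.rubisco_c],
        "v_o": sol[ids.rubisco_o],
        "v_p": sol[ids.pepc],
        "L": sol[ids.leak_co2],
        "L_O": sol[ids.leak_o2],
        "status": sol.status,
    }
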