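"""Enzyme-limited C4 physiology model (closed form / low dimensional).

An independent implementation of the steady-state, enzyme-limited C4
assimilation model used to validate the nonlinear-FBA machinery: the same
kinetic laws and diffusion relations, but solved as a two-unknown root
problem in the bundle-sheath gas levels instead of a network optimization.

Steady-state system (all rates μmol m⁻² s⁻¹, gas levels μbar):

    v_p  = min(v_p,max·C_m/(C_m + k_C,p), V_pr)
    L    = g_s·(C_BS − C_m)                       (CO2 leak, BS → mesophyll)
    A    = v_p − L − r_m                          (mesophyll CO2 balance)
    A    = v_c − 0.5·v_o − r_d                    (bundle-sheath carbon balance)
    v_c, v_o : competitive Michaelis-Menten laws at (C_BS, O_BS)
    O2 balance: g_s,O·(O_m − O_BS) + α_O·v_c = v_o

with v_o,max/v_c,max = k_O/(k_C·S_R).  The O2-evolution fraction α_O
defaults to 0 (NADP-ME-like bundle sheath with reduced photosystem II
activity, matching the toy network where bundle-sheath light reactions are
ATP-only).

Root finding uses nested bracketing (brentq in O_BS inside brentq in C_BS);
both residuals are monotone in their unknowns, so the bracketed search is
robust including near the min() kink, and converges to |residual| ≤ 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .c4_kinetics import (C4Params, diffusive_flux, pepc_rate_expr,
                          rubisco_carboxylation_expr,
                          rubisco_oxygenation_expr)

__all__ = ["PhysioParams", "OracleResult", "enzyme_limited_A", "fig2_sweep"]

INF = float("inf")


@dataclass
class PhysioParams:
    """Capacities plus the shared kinetic constants of :class:`C4Params`."""

    v_cmax: float = 50.0      # μmol m⁻² s⁻¹
    v_pmax: float = 110.0     # μmol m⁻² s⁻¹
    V_pr: float = INF         # max PEP regeneration (decarboxylase cap)
    alpha_O: float = 0.0      # bundle-sheath O2-evolution fraction (of v_c)
    kinetics: C4Params = field(default_factory=C4Params)

    def __post_init__(self):
        if self.v_cmax < 0 or self.v_pmax < 0 or self.V_pr < 0:
            raise ValueError("capacities must be nonnegative")
        if not (0.0 <= self.alpha_O <= 1.0):
            raise ValueError("alpha_O must be in [0, 1]")


@dataclass
class OracleResult:
    A: float
    C_BS: float
    O_BS: float
    v_c: float
    v_o: float
    v_p: float
    L: float
    L_O: float
    feasible: bool = True


_C_LO, _C_HI = 1e-9, 1e7
_O_TOL = 1e-12


def _gas_rates(C_BS: float, p: PhysioParams) -> tuple[float, float, float]:
    """(v_c, v_o, O_BS) at a given bundle-sheath CO2 level."""
    k = p.kinetics
    v_omax = k.vo_vc_capacity_ratio * p.v_cmax
    gO = diffusive_flux(k.g_sO, 1.0)  # μmol per μbar

    def o_residual(O_BS: float) -> float:
        v_c = rubisco_carboxylation_expr(p.v_cmax, C_BS, O_BS, k)
        v_o = rubisco_oxygenation_expr(v_omax, C_BS, O_BS, k)
        return gO * (k.O2_ME - O_BS) + p.alpha_O * v_c - v_o

    # o_residual is strictly decreasing in O_BS; bracket [0, high]
    hi = k.O2_ME
    while o_residual(hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for physical params
            raise RuntimeError("no oxygen balance root found")
    if o_residual(0.0) <= 0:
        O_BS = 0.0
    else:
        O_BS = brentq(o_residual, 0.0, hi, xtol=_O_TOL, rtol=8.9e-16)
    v_c = rubisco_carboxylation_expr(p.v_cmax, C_BS, O_BS, k)
    v_o = rubisco_oxygenation_expr(v_omax, C_BS, O_BS, k)
    return v_c, v_o, O_BS


def enzyme_limited_A(params: PhysioParams) -> OracleResult:
    """Solve the enzyme-limited steady state; |carbon residual| ≤ 1e-9."""
    p = params
    k = p.kinetics
    v_p = min(pepc_rate_expr(p.v_pmax, k.CO2_ME, k), p.V_pr)
    g = diffusive_flux(k.g_s, 1.0)

    def residual(C_BS: float) -> float:
        v_c, v_o, _ = _gas_rates(C_BS, p)
        L = g * (C_BS - k.CO2_ME)
        # (BS fixation net of photorespiration and r_d) − (pump supply net)
        return (v_c - 0.5 * v_o - k.r_d) - (v_p - L - k.r_m)

    lo, hi = _C_LO, _C_HI
    if residual(lo) > 0 or residual(hi) < 0:
        return OracleResult(A=np.nan, C_BS=np.nan, O_BS=np.nan, v_c=np.nan,
                            v_o=np.nan, v_p=v_p, L=np.nan, L_O=np.nan,
                            feasible=False)
    C_BS = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    v_c, v_o, O_BS = _gas_rates(C_BS, p)
    L = g * (C_BS - k.CO2_ME)
    L_O = diffusive_flux(k.g_sO, O_BS - k.O2_ME)
    A = v_p - L - k.r_m
    return OracleResult(A=A, C_BS=C_BS, O_BS=O_BS, v_c=v_c, v_o=v_o,
                        v_p=v_p, L=L, L_O=L_O)


def fig2_sweep(grid: dict, kinetics: C4Params | None = None) -> pd.DataFrame:
    """Tabulate A over a parameter grid (outer product of the listed axes).

    ``grid`` maps any of ``v_pmax``, ``v_cmax``, ``V_pr``, ``CO2_ME`` to a
    list of values; unlisted parameters stay at their defaults.  Returns a
    DataFrame with one row per grid point: the parameter values plus
    A, C_BS, O_BS, v_c, v_o, v_p and L.
    """
    kinetics = kinetics or C4Params()
    axes = {key: list(np.atleast_1d(vals)) for key, vals in grid.items()}
    for key in axes:
        if key not in ("v_pmax", "v_cmax", "V_pr", "CO2_ME"):
            raise ValueError(f"unknown sweep axis {key!r}")
    names = list(axes)
    rows = []
    mesh = np.meshgrid(*[axes[k] for k in names], indexing="ij") if names else []
    points = (np.stack([m.ravel() for m in mesh], axis=-1)
              if names else np.zeros((1, 0)))
    for point in points:
        spec = dict(zip(names, point))
        kin = C4Params(**{**_kin_kwargs(kinetics),
                          **({"CO2_ME": spec["CO2_ME"]} if "CO2_ME" in spec else {})})
        p = PhysioParams(
            v_cmax=spec.get("v_cmax", 50.0),
            v_pmax=spec.get("v_pmax", 110.0),
            V_pr=spec.get("V_pr", INF),
            kinetics=kin,
        )
        res = enzyme_limited_A(p)
        row = dict(spec)
        row.update({"A": res.A, "C_BS": res.C_BS, "O_BS": res.O_BS,
                    "v_c": res.v_c, "v_o": res.v_o, "v_p": res.v_p,
                    "L": res.L, "feasible": res.feasible})
        rows.append(row)
    return pd.DataFrame(rows)


def _kin_kwargs(k: C4Params) -> dict:
    return {f: getattr(k, f) for f in
            ("k_C", "k_O", "S_R", "k_C_p", "g_s", "g_sO_ratio",
             "CO2_ME", "O2_ME", "r_d", "r_m")}
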