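"""Toy C4 network fixture and synthetic leaf-gradient datasets.

The toy network is a deliberately small (≈25-reaction single-cell base,
≈55-reaction two-cell) but mass-leak-free C4 model carrying the motifs the
full-scale analysis depends on: PEPC and the NADP-ME (optionally PEPCK)
decarboxylation route, Rubisco carboxylase/oxygenase with a photorespiratory
pathway releasing 0.5 CO2 per oxygenation, the 3-PGA/triose-phosphate
shuttle, PPDK, sucrose synthesis/breakdown, respiration, light-driven
ATP/NADPH with O2 evolution confined to the mesophyll, glycine synthesis (a
second phloem-mobile metabolite), and biomass sinks in fixed-ratio or
flexible form.

The gradient generator produces, per segment of a leaf model, a feasible
flux state satisfying all steady-state and kinetic constraints: segments
below the transition are heterotrophic sinks (import sucrose from the
phloem, produce biomass, net-release CO2), segments at and above it are
photoautotrophic sources (run the C4 cycle, export sucrose and glycine).
Expression data are then generated by inverting the fitting model:
d_ij = e^{−s_i*}·v*_ij·(1 + noise), distributed equally over each reaction's
genes, with multiplicative Gaussian noise (cv = noise_cv, truncated so data
stay nonnegative) and activity caps set a margin above the true demands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .c4_kinetics import C4Params, C4ReactionIds, attach_c4_constraints
from .expression_fit import CELLS, ActivityData, ExpressionDataset
from .leaf_assembly import LeafModel, TwoCellSpec, build_leaf, build_two_cell, seg_prefix
from .model_io import MetabolicModel, Reaction, Species
from .nlp_core import NonlinearProgram, solve, solve_lp, sym

__all__ = [
    "ToyC4Options",
    "GradientSpec",
    "GradientTruth",
    "CARBON",
    "make_toy_c4_model",
    "toy_two_cell_spec",
    "make_toy_two_cell",
    "make_toy_leaf",
    "make_gradient_truth",
    "make_expression_data",
]

#: carbon atoms per toy species (for atom-count bookkeeping)
CARBON = {
    "co2": 1, "pep": 3, "oaa": 4, "mal": 4, "pyr": 3, "pga": 3, "tp": 3,
    "rubp": 5, "glyc": 2, "gly": 2, "suc": 12, "biomass": 10,
    "bm_carb": 9, "bm_aa": 5,
    "o2": 0, "h2o": 0, "hv": 0, "atp": 0, "adp": 0, "nadph": 0, "nadp": 0,
}


@dataclass
class ToyC4Options:
    include_pepck: bool = True
    biomass_mode: str = "fixed-ratio"  # or "flexible-sinks"
    n_light_reactions: int = 2


@dataclass
class GradientSpec:
    n_segments: int = 15
    transition_segment: int = 6     # first source (carbon-exporting) segment
    noise_cv: float = 0.2
    scale_spread: float = 0.4       # sd of the true log scale factors s_i*
    seed: int = 0
    v_cmax_tip: float = 50.0        # μmol m⁻² s⁻¹ at the mature tip
    v_pmax_tip: float = 110.0
    gly_export_frac: float = 0.02   # glycine export as a fraction of v_cmax
    sink_light: float = 2.0         # light cap (μmol m⁻² s⁻¹) in sink segments
    activity_margin: float = 0.15
    activity_enzymes: tuple[str, ...] = ("rubisco", "pepc", "decarboxylase")

    def __post_init__(self):
        if not (1 <= self.transition_segment <= self.n_segments):
            raise ValueError("transition_segment must lie within 1..n_segments")
        if self.noise_cv < 0 or self.scale_spread < 0:
            raise ValueError("noise_cv and scale_spread must be nonnegative")


@dataclass
class GradientTruth:
    values: dict[str, np.ndarray]   # two-cell variable -> per-segment values
    spec: GradientSpec
    caps: pd.DataFrame              # per-segment v_cmax / v_pmax used
    report: pd.DataFrame            # per-segment A, biomass, suc/gly export

    def leaf_values(self, leaf: LeafModel) -> dict[str, float]:
        """Truth as a flat {leaf variable: value} map (phloem loads included)."""
        out: dict[str, float] = {}
        for j in range(1, self.spec.n_segments + 1):
            pre = seg_prefix(j)
            for name, arr in self.values.items():
                v = float(arr[j - 1])
                if name.startswith("bs_EX_") and \
                        name[len("bs_EX_"):] in leaf.phloem_metabolites:
                    out[f"{pre}phloem_{name[len('bs_EX_'):]}"] = v
                else:
                    out[pre + name] = v
        return out

    def flux_table(self, reactions: list[str]) -> pd.DataFrame:
        segs = list(range(1, self.spec.n_segments + 1))
        return pd.DataFrame(
            {j: [self.values.get(r, np.zeros(len(segs)))[j - 1]
                 for r in reactions] for j in segs}, index=reactions)


# ---------------------------------------------------------------------------
# Toy network
# ---------------------------------------------------------------------------

def _rxn(id, stoich, rev=False, lb=None, ub=1000.0, genes=""):
    if lb is None:
        lb = -1000.0 if rev else 0.0
    return Reaction(id=id, stoichiometry=stoich, reversible=rev,
                    lower_bound=lb, upper_bound=ub, gene_rule=genes)


def make_toy_c4_model(opts: ToyC4Options | None = None) -> MetabolicModel:
    """Single-cell base model, ready for two-cell assembly.

    Carbon is conserved by every reaction (see :data:`CARBON`); ATP/ADP and
    NADPH/NADP are explicit conserved pairs; light (``hv``) is an exempt
    species consumed by the light reactions, which split water so that O2
    evolution requires H2O input.  Photorespiration releases 0.5 CO2 per
    oxygenation.  Rubisco oxygenase carries no gene rule of its own — its
    transcript signal is inseparable from the carboxylase — so expression
    data attach to the carboxylase flux only.
    """
    opts = opts or ToyC4Options()
    m = MetabolicModel(id="toy_c4")
    m.compartments = ["cyt"]
    sids = ["co2", "o2", "h2o", "hv", "pep", "oaa", "mal", "pyr", "pga", "tp",
            "rubp", "glyc", "gly", "suc", "atp", "adp", "nadph", "nadp"]
    if opts.biomass_mode == "fixed-ratio":
        sids.append("biomass")
    elif opts.biomass_mode == "flexible-sinks":
        sids.extend(["bm_carb", "bm_aa"])
    else:
        raise ValueError("biomass_mode must be 'fixed-ratio' or 'flexible-sinks'")
    m.species = [Species(id=s, compartment="cyt") for s in sids]
    m.exempt_species = {"hv"}

    R = m.reactions
    R.append(_rxn("pepc", {"pep": -1, "co2": -1, "oaa": 1}, genes="g_pepc"))
    R.append(_rxn("mdh", {"oaa": -1, "nadph": -1, "mal": 1, "nadp": 1},
                  rev=True, genes="g_mdh1 or g_mdh2"))
    R.append(_rxn("nadp_me", {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1,
                              "nadph": 1}, genes="g_me"))
    if opts.include_pepck:
        R.append(_rxn("pepck", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1,
                                "adp": 1}, genes="g_pepck"))
    R.append(_rxn("ppdk", {"pyr": -1, "atp": -2, "pep": 1, "adp": 2},
                  genes="g_ppdk"))
    R.append(_rxn("rbc_c", {"rubp": -1, "co2": -1, "pga": 2},
                  genes="g_rbcL and g_rbcS"))
    R.append(_rxn("rbc_o", {"rubp": -1, "o2": -1, "pga": 1, "glyc": 1}))
    R.append(_rxn("photoresp", {"glyc": -2, "atp": -1, "nadp": -1, "pga": 1,
                                "co2": 1, "adp": 1, "nadph": 1, "h2o": 2},
                  genes="g_pr"))
    R.append(_rxn("pga_red", {"pga": -1, "atp": -1, "nadph": -1, "tp": 1,
                              "adp": 1, "nadp": 1}, genes="g_gapdh"))
    # glycolytic counterpart (cytosolic GAPDH/PGK): the downhill direction
    # heterotrophic tissue uses to reach PGA from imported sugar
    R.append(_rxn("glycolysis", {"tp": -1, "adp": -1, "nadp": -1, "pga": 1,
                                 "atp": 1, "nadph": 1}, genes="g_gapC"))
    R.append(_rxn("rubp_regen", {"tp": -5, "atp": -3, "rubp": 3, "adp": 3,
                                "h2o": 2}, genes="g_prk"))
    R.append(_rxn("suc_synth", {"tp": -4, "atp": -1, "suc": 1, "adp": 1,
                               "h2o": 2}, genes="g_sps"))
    R.append(_rxn("suc_breakdown", {"suc": -1, "h2o": -2, "tp": 4},
                  genes="g_inv"))
    R.append(_rxn("resp", {"tp": -1, "o2": -2.5, "adp": -1, "nadp": -1,
                           "co2": 3, "atp": 1, "nadph": 1, "h2o": 3},
                  genes="g_resp"))
    # Glycine is made from triose phosphate; glycolate's only fate is the
    # photorespiratory pathway, so every oxygenation costs 0.5 CO2 — the
    # same carbon accounting the enzyme-limited physiology model assumes.
    R.append(_rxn("gly_synth", {"tp": -2, "atp": -2, "nadp": -3, "gly": 3,
                                "nadph": 3, "adp": 2, "h2o": 2},
                  genes="g_glysyn"))
    R.append(_rxn("gly_decarb", {"gly": -1, "nadp": -3, "h2o": -2, "co2": 2,
                                "nadph": 3}, genes="g_gdc"))
    if opts.n_light_reactions >= 1:
        R.append(_rxn("light_atp", {"hv": -1, "adp": -1, "atp": 1},
                      genes="g_atpsyn"))
    if opts.n_light_reactions >= 2:
        R.append(_rxn("light_nadph", {"hv": -2, "h2o": -1, "nadp": -1,
                                      "nadph": 1, "o2": 0.5}, genes="g_psii"))
    for k in range(3, opts.n_light_reactions + 1):
        R.append(_rxn(f"light_cyc{k}", {"hv": -2, "adp": -1, "atp": 1},
                      genes=f"g_cyc{k}"))
    # alternative-oxidase-style valve re-oxidizing surplus NADPH; without it
    # heterotrophic (respiring) states cannot balance the NADP pool
    R.append(_rxn("nadph_ox", {"nadph": -1, "o2": -0.5, "nadp": 1, "h2o": 1},
                  genes="g_aox"))
    R.append(_rxn("atpase", {"atp": -1, "adp": 1}))
    if opts.biomass_mode == "fixed-ratio":
        R.append(_rxn("biomass_rxn",
                      {"tp": -2, "pga": -1, "gly": -0.5, "atp": -4,
                       "nadph": -1, "biomass": 1, "adp": 4, "nadp": 1},
                      genes="g_grow"))
        sinks = ["biomass"]
    else:
        R.append(_rxn("bm_carb_rxn", {"tp": -3, "atp": -3, "bm_carb": 1,
                                      "adp": 3}, genes="g_grow_c"))
        R.append(_rxn("bm_aa_rxn", {"pga": -1, "gly": -1, "atp": -2,
                                    "nadph": -1, "bm_aa": 1, "adp": 2,
                                    "nadp": 1}, genes="g_grow_a"))
        sinks = ["bm_carb", "bm_aa"]

    R.append(_rxn("EX_co2", {"co2": -1}, rev=True))
    R.append(_rxn("EX_o2", {"o2": -1}, rev=True))
    R.append(_rxn("EX_h2o", {"h2o": -1}, rev=True))
    R.append(_rxn("EX_hv", {"hv": -1}, lb=-10000.0, ub=0.0, rev=True))
    R.append(_rxn("EX_suc", {"suc": -1}, rev=True))
    R.append(_rxn("EX_gly", {"gly": -1}, rev=True))
    for s in sinks:
        R.append(_rxn(f"EX_{s}", {s: -1}, lb=0.0))

    m.validate()
    return m


def toy_two_cell_spec(opts: ToyC4Options | None = None) -> TwoCellSpec:
    opts = opts or ToyC4Options()
    sinks = (["biomass"] if opts.biomass_mode == "fixed-ratio"
             else ["bm_carb", "bm_aa"])
    return TwoCellSpec(
        plasmodesmata_metabolites=["pga", "tp", "mal", "pyr", "pep", "suc",
                                   "gly"],
        bs_exchange_whitelist=["suc", "gly", "hv", "h2o"],
        me_gas_exchange=["co2", "o2", "h2o", "hv"],
        shared_sinks=sinks,
        # Strict NADP-ME-type cell separation: Rubisco and photorespiration
        # confined to the bundle sheath, PEPC and photosystem II (the
        # O2-evolving light reaction) to the mesophyll.  An unconstrained
        # bundle-sheath carboxylase would bypass the diffusive leak that the
        # kinetic comparison is about.
        # the NADPH valve stays out of the bundle sheath: there it would
        # scrub O2 with shuttle-delivered reducing power and sidestep the
        # oxygen balance the diffusion constraint encodes
        # glycine decarboxylase likewise: in the bundle sheath it would act
        # as a second, kinetics-free CO2 pump
        ms_disabled=["rbc_c", "rbc_o", "photoresp"],
        bs_disabled=["light_nadph", "pepc", "nadph_ox", "gly_decarb"],
    )


def make_toy_two_cell(opts: ToyC4Options | None = None) -> MetabolicModel:
    opts = opts or ToyC4Options()
    return build_two_cell(make_toy_c4_model(opts), toy_two_cell_spec(opts))


def make_toy_leaf(n_segments: int = 15,
                  opts: ToyC4Options | None = None) -> LeafModel:
    return build_leaf(make_toy_two_cell(opts), n_segments, ["suc", "gly"])


# ---------------------------------------------------------------------------
# Gradient ground truth
# ---------------------------------------------------------------------------

def _segment_program(two_cell: MetabolicModel, kinetics: C4Params,
                     caps: dict) -> NonlinearProgram:
    prog = NonlinearProgram.from_model(two_cell)
    attach_c4_constraints(prog, kinetics, C4ReactionIds(), caps)
    return prog


def _biomass_vars(two_cell: MetabolicModel) -> list[str]:
    return [r.id for r in two_cell.reactions
            if r.id.endswith("EX_biomass") or "_EX_bm_" in r.id]


def make_gradient_truth(leaf: LeafModel, spec: GradientSpec | None = None,
                        kinetics: C4Params | None = None) -> GradientTruth:
    """A feasible, kinetics-respecting flux state per segment.

    Source segments (j ≥ transition) maximize CO2 assimilation with enzyme
    capacities ramping linearly to their tip values and a small forced
    glycine export; sink segments (j < transition) have zero C4 capacity and
    dim light, import an equal-share quota of the sources' total sucrose
    export, and maximize biomass production.  Phloem loads therefore sum to
    zero per metabolite (closed phloem), and the per-segment net CO2
    exchange changes sign exactly at the transition.
    """
    spec = spec or GradientSpec()
    kinetics = kinetics or C4Params()
    if leaf.n_segments != spec.n_segments:
        raise ValueError("leaf and spec disagree on the number of segments")
    two_cell = leaf.base
    t, n = spec.transition_segment, spec.n_segments
    biomass_vars = _biomass_vars(two_cell)

    values: dict[str, np.ndarray] = {}

    def record(j: int, sol_values: dict):
        for name, v in sol_values.items():
            values.setdefault(name, np.zeros(n))[j - 1] = v

    caps_rows = []
    # --- source segments -------------------------------------------------
    suc_total = 0.0
    gly_total = 0.0
    n_src = n - t + 1
    for j in range(t, n + 1):
        ramp = (j - t + 1) / n_src
        vcmax = spec.v_cmax_tip * ramp
        vpmax = spec.v_pmax_tip * ramp
        gly_export = spec.gly_export_frac * vcmax
        prog = _segment_program(two_cell, kinetics,
                                {"v_cmax": vcmax, "v_pmax": vpmax})
        prog.set_bounds("bs_EX_suc", 0.0, 1000.0)       # export only
        prog.set_bounds("bs_EX_gly", gly_export, gly_export)
        for b in biomass_vars:
            prog.set_bounds(b, 0.0, 0.0)
        # tiny flux penalty: unique minimal-norm optimum among the
        # cost-free futile cycles of the toy network
        prog.set_objective(
            -sym("ms_EX_co2")
            - 1e-8 * sum(sym(r.id) ** 2 for r in two_cell.reactions), "max")
        sol = solve(prog, start={"CO2_BS": kinetics.CO2_ME,
                                 "O2_BS": kinetics.O2_ME})
        if sol.status in ("infeasible", "failed"):
            raise RuntimeError(
                f"source segment {j} infeasible under the gradient spec "
                f"({sol.message})")
        record(j, sol.values)
        suc_total += sol.values["bs_EX_suc"]
        gly_total += sol.values["bs_EX_gly"]
        caps_rows.append({"segment": j, "v_cmax": vcmax, "v_pmax": vpmax})

    # --- sink segments ----------------------------------------------------
    if t > 1:
        weights = np.array([t - j for j in range(1, t)], dtype=float)
        weights /= weights.sum()
        for j in range(1, t):
            w = weights[j - 1]
            suc_in = suc_total * w
            gly_in = gly_total * w
            prog = _segment_program(two_cell, kinetics,
                                    {"v_cmax": 0.0, "v_pmax": 0.0})
            prog.set_bounds("bs_EX_suc", -suc_in, -suc_in)   # import quota
            prog.set_bounds("bs_EX_gly", -gly_in, -gly_in)
            prog.set_bounds("ms_EX_hv", -spec.sink_light, 0.0)
            prog.set_bounds("bs_EX_hv", -spec.sink_light, 0.0)
            prog.set_objective(sum(sym(b) for b in biomass_vars), "max")
            # with zero capacities the kinetic rows are linear: global LP
            if not prog.nonlinear_constraints:
                sol = solve_lp(prog)
            else:  # pragma: no cover - nonzero sink capacities
                sol = solve(prog, start={"CO2_BS": kinetics.CO2_ME,
                                         "O2_BS": kinetics.O2_ME})
            if sol.status in ("infeasible", "failed"):
                raise RuntimeError(
                    f"sink segment {j} infeasible under the gradient spec "
                    f"({sol.message})")
            record(j, sol.values)
            caps_rows.append({"segment": j, "v_cmax": 0.0, "v_pmax": 0.0})

    caps = pd.DataFrame(caps_rows).set_index("segment").sort_index()
    report = pd.DataFrame({
        "co2_uptake": -values["ms_EX_co2"],
        "suc_export": values["bs_EX_suc"],
        "gly_export": values["bs_EX_gly"],
        "biomass": sum(values.get(b, np.zeros(n)) for b in biomass_vars),
    }, index=pd.RangeIndex(1, n + 1, name="segment"))
    return GradientTruth(values=values, spec=spec, caps=caps, report=report)


# ---------------------------------------------------------------------------
# Expression + activity data generation
# ---------------------------------------------------------------------------

def make_expression_data(truth: GradientTruth, two_cell: MetabolicModel,
                         spec: GradientSpec | None = None,
                         ) -> tuple[ExpressionDataset, ActivityData, pd.Series]:
    """Invert the fitting model: d_ij = e^{−s_i*}·|v*_ij|·(1 + noise).

    Reaction-level values are distributed equally over each reaction's genes
    (any split summing correctly is consistent with sum-aggregation); gene
    sds are noise_cv·mean.  Activity caps are set to (1 + margin)·the true
    per-segment requirement for Rubisco, PEPC and the decarboxylases.
    Returns (expression, activity, true scale factors by scale group).
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed)
    n = spec.n_segments
    segs = list(range(1, n + 1))

    data_rxns = [r for r in two_cell.reactions if r.genes()
                 and (r.id.startswith("ms_") or r.id.startswith("bs_"))]
    groups = sorted({_strip_cell(r.id) for r in data_rxns})
    s_true = pd.Series({g: rng.normal(0.0, spec.scale_spread) for g in groups},
                       name="s_true")

    gene_means: dict[tuple[str, str], np.ndarray] = {}
    gene_sds: dict[tuple[str, str], np.ndarray] = {}
    for r in data_rxns:
        cell = r.id[:2]
        v = np.abs(truth.values.get(r.id, np.zeros(n)))
        s_star = s_true[_strip_cell(r.id)]
        noise = rng.normal(0.0, spec.noise_cv, size=n) if spec.noise_cv else \
            np.zeros(n)
        noise = np.clip(noise, -0.9, None)
        d = np.exp(-s_star) * v * (1.0 + noise)
        genes = sorted(r.genes())
        for g in genes:
            share = d / len(genes)
            gene_means[(g, cell)] = gene_means.get((g, cell), 0.0) + share
            gene_sds[(g, cell)] = spec.noise_cv * np.abs(
                gene_means[(g, cell)])

    all_genes = sorted({g for g, _ in gene_means})
    cols = pd.MultiIndex.from_tuples([(c, j) for c in CELLS for j in segs])
    means = pd.DataFrame(0.0, index=all_genes, columns=cols)
    sds = pd.DataFrame(0.0, index=all_genes, columns=cols)
    for (g, cell), arr in gene_means.items():
        for j in segs:
            means.loc[g, (cell, j)] = arr[j - 1]
            sds.loc[g, (cell, j)] = gene_sds[(g, cell)][j - 1]
    expr = ExpressionDataset(means, sds)

    margin = 1.0 + spec.activity_margin
    E_rows, groups_map = [], {}
    if "rubisco" in spec.activity_enzymes:
        E_rows.append(("rubisco",
                       margin * truth.caps["v_cmax"].to_numpy()))
        groups_map["rubisco"] = ["vcmax_bs"]
    if "pepc" in spec.activity_enzymes:
        E_rows.append(("pepc", margin * truth.caps["v_pmax"].to_numpy()))
        groups_map["pepc"] = ["vpmax_ms"]
    if "decarboxylase" in spec.activity_enzymes:
        dec = sum(np.abs(truth.values.get(rid, np.zeros(n)))
                  for rid in ("bs_nadp_me", "bs_pepck"))
        E_rows.append(("decarboxylase", margin * dec + 1e-3))
        groups_map["decarboxylase"] = ["bs_nadp_me", "bs_pepck"]
    E = pd.DataFrame({j: [row[1][j - 1] for row in E_rows] for j in segs},
                     index=[row[0] for row in E_rows])
    activity = ActivityData(E=E, groups=groups_map)
    return expr, activity, s_true


def _strip_cell(rid: str) -> str:
    for cell in CELLS:
        if rid.startswith(cell + "_"):
            return rid[len(cell) + 1:]
    return rid
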