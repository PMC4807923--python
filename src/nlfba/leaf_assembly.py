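"""Assemble two-cell (mesophyll + bundle sheath) and multi-segment leaf models.

A two-cell model is built from two prefixed copies (``ms_``, ``bs_``) of a
base model, joined by reversible plasmodesmata transport reactions and CO2/O2
leak reactions, with exchanges restricted: gas exchange with the
intercellular airspace belongs to the mesophyll, vascular nutrient uptake to
the bundle sheath.

A leaf model is n identical segment copies (``seg01_`` … ``segNN_``) of the
two-cell model sharing a single phloem compartment: each segment gets one
reversible load/unload reaction per phloem metabolite, and the phloem pool is
mass-balanced across segments with no imposed transport direction.  By
default the phloem is closed (no external exchange), so segment loads must
sum to zero for every transported metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model_io import MetabolicModel, Reaction, Species

__all__ = ["TwoCellSpec", "LeafModel", "build_two_cell", "build_leaf",
           "segment_report", "seg_prefix"]

CELLS = ("ms", "bs")


@dataclass
class TwoCellSpec:
    """Wiring lists for the two-cell assembly (all ids refer to the base model)."""

    plasmodesmata_metabolites: list[str] = field(default_factory=list)
    bs_exchange_whitelist: list[str] = field(default_factory=list)
    me_gas_exchange: list[str] = field(default_factory=list)
    #: species whose export sinks stay available in both cells (e.g. biomass)
    shared_sinks: list[str] = field(default_factory=list)
    #: base reactions omitted from one cell (e.g. PSII absent in bundle sheath)
    ms_disabled: list[str] = field(default_factory=list)
    bs_disabled: list[str] = field(default_factory=list)
    gas_leak_species: tuple[str, str] = ("co2", "o2")


@dataclass
class LeafModel:
    base: MetabolicModel              # the two-cell model
    model: MetabolicModel             # the assembled n-segment model
    n_segments: int
    phloem_metabolites: list[str]
    segment_of: dict[str, int]        # reaction id -> 1-based segment index
    pairing: dict[str, str]           # ms reaction id <-> bs counterpart

    def segment_ids(self, j: int) -> list[str]:
        pre = seg_prefix(j)
        return [r.id for r in self.model.reactions if r.id.startswith(pre)]


def seg_prefix(j: int) -> str:
    return f"seg{j:02d}_"


def _check_species(model: MetabolicModel, ids, what: str) -> None:
    known = {s.id for s in model.species}
    missing = [x for x in ids if x not in known]
    if missing:
        raise ValueError(f"{what} lists unknown species: {missing}")


def build_two_cell(base: MetabolicModel, spec: TwoCellSpec) -> MetabolicModel:
    """Duplicate the base model into mesophyll and bundle sheath copies.

    Base exchange reactions (single-species) are not duplicated wholesale;
    they are re-created per the spec lists: ``me_gas_exchange`` species keep
    their exchange in the mesophyll, ``bs_exchange_whitelist`` species in the
    bundle sheath, ``shared_sinks`` in both.  Reversible CO2 and O2 leak
    reactions (positive flux = bundle sheath → mesophyll) connect the two
    cells, and each plasmodesmata metabolite gets a reversible ``pd_``
    transport reaction between the cytosols.
    """
    base.validate()
    for lst, what in ((spec.plasmodesmata_metabolites, "plasmodesmata"),
                      (spec.bs_exchange_whitelist, "bs whitelist"),
                      (spec.me_gas_exchange, "mesophyll gas exchange"),
                      (spec.shared_sinks, "shared sinks")):
        _check_species(base, lst, what)
    leak_set = set(spec.gas_leak_species)
    if leak_set & (set(spec.plasmodesmata_metabolites)
                   | set(spec.bs_exchange_whitelist)):
        raise ValueError("gas leak species may not appear in transport lists")

    out = MetabolicModel(id=base.id + "_x2")
    out.compartments = [f"{cell}_{c}" for cell in CELLS for c in base.compartments]
    for cell in CELLS:
        for s in base.species:
            out.species.append(Species(
                id=f"{cell}_{s.id}", name=s.name,
                compartment=f"{cell}_{s.compartment}", boundary=s.boundary))
    out.exempt_species = {f"{cell}_{sid}" for cell in CELLS
                          for sid in base.exempt_species}

    exchange_bounds = {next(iter(r.stoichiometry)): (r.lower_bound, r.upper_bound,
                                                     r.reversible)
                       for r in base.reactions if r.is_exchange}
    disabled = {"ms": set(spec.ms_disabled), "bs": set(spec.bs_disabled)}

    for cell in CELLS:
        for r in base.reactions:
            if r.is_exchange or r.id in disabled[cell]:
                continue
            out.reactions.append(Reaction(
                id=f"{cell}_{r.id}", name=r.name,
                stoichiometry={f"{cell}_{sid}": c
                               for sid, c in r.stoichiometry.items()},
                reversible=r.reversible, lower_bound=r.lower_bound,
                upper_bound=r.upper_bound, gene_rule=r.gene_rule,
                pathway_tags=set(r.pathway_tags)))

    def add_exchange(cell: str, sid: str):
        lb, ub, rev = exchange_bounds.get(sid, (-1000.0, 1000.0, True))
        out.reactions.append(Reaction(
            id=f"{cell}_EX_{sid}", stoichiometry={f"{cell}_{sid}": -1.0},
            reversible=rev, lower_bound=lb, upper_bound=ub))

    for sid in spec.me_gas_exchange:
        add_exchange("ms", sid)
    for sid in spec.bs_exchange_whitelist:
        add_exchange("bs", sid)
    for sid in spec.shared_sinks:
        for cell in CELLS:
            add_exchange(cell, sid)

    for sid in spec.gas_leak_species:
        out.reactions.append(Reaction(
            id=f"leak_{sid}",
            stoichiometry={f"bs_{sid}": -1.0, f"ms_{sid}": 1.0},
            reversible=True, lower_bound=-1000.0, upper_bound=1000.0))
    for sid in spec.plasmodesmata_metabolites:
        out.reactions.append(Reaction(
            id=f"pd_{sid}",
            stoichiometry={f"ms_{sid}": -1.0, f"bs_{sid}": 1.0},
            reversible=True, lower_bound=-1000.0, upper_bound=1000.0))

    out.validate()
    return out


def build_leaf(two_cell: MetabolicModel, n_segments: int,
               phloem_metabolites: list[str],
               phloem_cell: str = "bs",
               open_phloem: bool = False) -> LeafModel:
    """n prefixed copies of the two-cell model sharing one phloem compartment.

    Per segment and phloem metabolite a reversible load/unload reaction is
    added (positive flux = segment → phloem) and the segment's own vascular
    exchange for that metabolite, if any, is removed — phloem transport
    replaces it.  With ``open_phloem`` the pool additionally gets an external
    exchange; the default leaves the phloem closed so that segment loads sum
    to zero, with no directionality imposed on any load.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    two_cell.validate()
    cyt_ids = {f"{phloem_cell}_{m}" for m in phloem_metabolites}
    _check_species(two_cell, cyt_ids, "phloem metabolites (in source cell)")

    out = MetabolicModel(id=f"{two_cell.id}x{n_segments}")
    out.compartments = [f"{seg_prefix(j)}{c}"
                        for j in range(1, n_segments + 1)
                        for c in two_cell.compartments] + ["phloem"]
    segment_of: dict[str, int] = {}
    pairing: dict[str, str] = {}
    replaced_exchanges = {f"{phloem_cell}_EX_{m}" for m in phloem_metabolites}

    for j in range(1, n_segments + 1):
        pre = seg_prefix(j)
        for s in two_cell.species:
            out.species.append(Species(
                id=pre + s.id, name=s.name,
                compartment=pre + s.compartment, boundary=s.boundary))
        for r in two_cell.reactions:
            if r.id in replaced_exchanges:
                continue
            rid = pre + r.id
            out.reactions.append(Reaction(
                id=rid,
                stoichiometry={pre + sid: c for sid, c in r.stoichiometry.items()},
                reversible=r.reversible, lower_bound=r.lower_bound,
                upper_bound=r.upper_bound, gene_rule=r.gene_rule,
                pathway_tags=set(r.pathway_tags), name=r.name))
            segment_of[rid] = j
            if r.id.startswith("ms_"):
                mate = pre + "bs_" + r.id[3:]
                pairing[rid] = mate
            elif r.id.startswith("bs_"):
                mate = pre + "ms_" + r.id[3:]
                pairing[rid] = mate
        out.exempt_species |= {pre + sid for sid in two_cell.exempt_species}

    pairing = {a: b for a, b in pairing.items()
               if b in {r.id for r in out.reactions}}

    for m in phloem_metabolites:
        out.species.append(Species(id=f"phloem_{m}", compartment="phloem"))
        for j in range(1, n_segments + 1):
            pre = seg_prefix(j)
            rid = f"{pre}phloem_{m}"
            out.reactions.append(Reaction(
                id=rid,
                stoichiometry={f"{pre}{phloem_cell}_{m}": -1.0,
                               f"phloem_{m}": 1.0},
                reversible=True, lower_bound=-1000.0, upper_bound=1000.0))
            segment_of[rid] = j
        if open_phloem:
            out.reactions.append(Reaction(
                id=f"EX_phloem_{m}", stoichiometry={f"phloem_{m}": -1.0},
                reversible=True, lower_bound=-1000.0, upper_bound=1000.0))

    out.validate()
    return LeafModel(base=two_cell, model=out, n_segments=n_segments,
                     phloem_metabolites=list(phloem_metabolites),
                     segment_of=segment_of, pairing=pairing)


def segment_report(leaf: LeafModel, solution, co2_exchange: str = "ms_EX_co2",
                   biomass_prefixes: tuple[str, ...] = ("ms_EX_biomass",
                                                        "bs_EX_biomass",
                                                        "ms_EX_bm_", "bs_EX_bm_"),
                   ) -> pd.DataFrame:
    """Per-segment net CO2 exchange, phloem fluxes and biomass production.

    Sign convention: uptake positive.  ``solution`` maps variable names to
    values (a Solution or plain dict).
    """
    values = solution.values if hasattr(solution, "values") and not isinstance(
        solution, dict) else dict(solution)
    get = values.get
    rows = []
    for j in range(1, leaf.n_segments + 1):
        pre = seg_prefix(j)
        row = {"segment": j,
               "co2_uptake": -get(pre + co2_exchange, 0.0)}
        for m in leaf.phloem_metabolites:
            # load is written segment → phloem positive; report uptake positive
            row[f"phloem_{m}_uptake"] = -get(f"{pre}phloem_{m}", 0.0)
        biomass = 0.0
        for r in leaf.model.reactions:
            if leaf.segment_of.get(r.id) != j:
                continue
            stripped = r.id[len(pre):]
            if any(stripped.startswith(p) for p in biomass_prefixes):
                biomass += get(r.id, 0.0)
        row["biomass"] = biomass
        rows.append(row)
    return pd.DataFrame(rows).set_index("segment")
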