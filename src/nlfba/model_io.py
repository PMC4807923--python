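"""Read, write and validate SBML metabolic models.

Models are held in lightweight dataclasses (:class:`Species`, :class:`Reaction`,
:class:`MetabolicModel`) carrying exactly what constraint-based analysis needs:
stoichiometry, reversibility, flux bounds and gene-association (GPR) rules.
Both the legacy COBRA dialect (kinetic-law ``LOWER_BOUND``/``UPPER_BOUND``
parameters, ``GENE_ASSOCIATION`` notes) and the modern SBML-FBC extension are
read; when both are present FBC takes precedence.  Files are written in the
legacy COBRA dialect (SBML L2v4), which round-trips through this reader and is
accepted by mainstream COBRA tooling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import libsbml
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

DEFAULT_BOUND = 1000.0

__all__ = [
    "Species",
    "Reaction",
    "MetabolicModel",
    "GeneRule",
    "parse_gene_rule",
    "read_sbml",
    "write_sbml",
    "check_mass_leaks",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "c"
    boundary: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = True
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    name: str = ""
    pathway_tags: set[str] = field(default_factory=set)

    @property
    def is_exchange(self) -> bool:
        """Single-species reactions are treated as exchanges."""
        return len(self.stoichiometry) == 1

    def genes(self) -> set[str]:
        return parse_gene_rule(self.gene_rule).genes()

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            pathway_tags=set(self.pathway_tags),
        )


@dataclass
class MetabolicModel:
    id: str = "model"
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: list[str] = field(default_factory=list)
    exempt_species: set[str] = field(default_factory=set)

    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            species=[replace(s) for s in self.species],
            reactions=[r.copy() for r in self.reactions],
            compartments=list(self.compartments),
            exempt_species=set(self.exempt_species),
        )

    def validate(self) -> None:
        """Raise ValueError on any structural invariant violation."""
        sids = set()
        for s in self.species:
            if s.id in sids:
                raise ValueError(f"duplicate species id {s.id!r}")
            sids.add(s.id)
            if s.compartment not in self.compartments:
                raise ValueError(
                    f"species {s.id!r} references unknown compartment "
                    f"{s.compartment!r}"
                )
        rids = set()
        for r in self.reactions:
            if r.id in rids:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            rids.add(r.id)
            if not r.stoichiometry:
                raise ValueError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ValueError(f"reaction {r.id!r} has lower_bound > upper_bound")
            if not r.reversible and r.lower_bound < 0:
                raise ValueError(
                    f"irreversible reaction {r.id!r} has negative lower bound"
                )
            for sid in r.stoichiometry:
                if sid not in sids:
                    raise ValueError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
            parse_gene_rule(r.gene_rule)  # raises on malformed rules

    def summary(self) -> dict:
        return {
            "id": self.id,
            "n_species": len(self.species),
            "n_reactions": len(self.reactions),
            "n_compartments": len(self.compartments),
            "n_reversible": sum(r.reversible for r in self.reactions),
            "n_exchanges": sum(r.is_exchange for r in self.reactions),
            "n_with_genes": sum(bool(r.genes()) for r in self.reactions),
        }


# ---------------------------------------------------------------------------
# Gene-association rules (COBRA conventions: AND/OR over gene ids)
# ---------------------------------------------------------------------------

class GeneRule:
    """Boolean expression tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``.
    """

    __slots__ = ("op", "gene", "children")

    def __init__(self, op: str, gene: str | None = None,
                 children: list["GeneRule"] | None = None):
        self.op = op
        self.gene = gene
        self.children = children or []

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, present: dict[str, bool] | set) -> bool:
        if isinstance(present, set):
            present = {g: True for g in present}
        if self.op == "empty":
            return False
        if self.op == "gene":
            return bool(present.get(self.gene, False))
        vals = [c.evaluate(present) for c in self.children]
        return all(vals) if self.op == "and" else any(vals)

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene
        joiner = " and " if self.op == "and" else " or "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"GeneRule({self.to_string()!r})"


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gene_rule(rule_text: str) -> GeneRule:
    """Parse a COBRA-convention gene rule ("(g1 and g2) or g3") into a tree.

    An empty or whitespace-only rule yields an empty tree with gene set ∅.
    Raises ValueError on unbalanced parentheses or dangling operators.
    """
    tokens = _TOKEN_RE.findall(rule_text or "")
    if not tokens:
        return GeneRule("empty")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GeneRule:
        node = parse_and()
        kids = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            kids.append(parse_and())
        return kids[0] if len(kids) == 1 else GeneRule("or", children=kids)

    def parse_and() -> GeneRule:
        node = parse_atom()
        kids = [node]
        while peek() is not None and peek().lower() == "and":
            take()
            kids.append(parse_atom())
        return kids[0] if len(kids) == 1 else GeneRule("and", children=kids)

    def parse_atom() -> GeneRule:
        tok = peek()
        if tok is None:
            raise ValueError(f"gene rule ended unexpectedly: {rule_text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in gene rule {rule_text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token {tok!r} in gene rule {rule_text!r}")
        return GeneRule("gene", gene=take())

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in gene rule {rule_text!r}")
    return tree


# ---------------------------------------------------------------------------
# SBML reading
# ---------------------------------------------------------------------------

_GA_NOTE_RE = re.compile(
    r"GENE[_ ]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
)


def _notes_gene_rule(sbml_reaction) -> str:
    notes = sbml_reaction.getNotesString() if sbml_reaction.isSetNotes() else ""
    m = _GA_NOTE_RE.search(notes)
    return m.group(1).strip() if m else ""


def _fbc_gene_rule(sbml_reaction) -> str | None:
    rplug = sbml_reaction.getPlugin("fbc")
    if rplug is None:
        return None
    gpa = rplug.getGeneProductAssociation()
    if gpa is None:
        return None

    model = sbml_reaction.getModel()
    mplug = model.getPlugin("fbc")

    def assoc_to_str(assoc) -> str:
        if assoc is None:
            return ""
        if assoc.isGeneProductRef():
            gp = mplug.getGeneProduct(assoc.getGeneProduct())
            return gp.getLabel() or gp.getId() if gp else assoc.getGeneProduct()
        kids = [assoc_to_str(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())]
        op = " and " if assoc.isFbcAnd() else " or "
        return "(" + op.join(kids) + ")"

    return assoc_to_str(gpa.getAssociation())


def _kinetic_bounds(sbml_reaction) -> tuple[float | None, float | None]:
    kl = sbml_reaction.getKineticLaw()
    if kl is None:
        return None, None
    lb = ub = None
    for i in range(kl.getNumParameters()):
        p = kl.getParameter(i)
        if p.getId() == "LOWER_BOUND":
            lb = p.getValue()
        elif p.getId() == "UPPER_BOUND":
            ub = p.getValue()
    return lb, ub


def _fbc_bounds(sbml_reaction, sbml_model) -> tuple[float | None, float | None]:
    rplug = sbml_reaction.getPlugin("fbc")
    if rplug is None:
        return None, None

    def param_value(pid):
        if not pid:
            return None
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    return (param_value(rplug.getLowerFluxBound()),
            param_value(rplug.getUpperFluxBound()))


def read_sbml(path: str) -> MetabolicModel:
    """Load an SBML Level 2 or 3 model into a :class:`MetabolicModel`.

    Flux bounds are taken from FBC attributes when present, else from
    COBRA-style kinetic-law parameters, else defaulted to ±1000 (0/1000 for
    irreversible reactions).  Gene rules likewise prefer FBC over
    ``GENE_ASSOCIATION`` notes.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ValueError(
                    f"SBML parse error in {path}: {err.getMessage().strip()} "
                    f"(line {err.getLine()})"
                )
    sm = doc.getModel()
    if sm is None:
        raise ValueError(f"no model element found in {path}")

    model = MetabolicModel(id=sm.getId() or "model")
    model.compartments = [sm.getCompartment(i).getId()
                          for i in range(sm.getNumCompartments())]

    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        model.species.append(Species(
            id=s.getId(),
            name=s.getName() or "",
            compartment=s.getCompartment(),
            boundary=bool(s.getBoundaryCondition()),
        ))
    sids = {s.id for s in model.species}

    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            sid = sr.getSpecies()
            if sid not in sids:
                raise ValueError(
                    f"reaction {r.getId()!r} references unknown species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            sid = sr.getSpecies()
            if sid not in sids:
                raise ValueError(
                    f"reaction {r.getId()!r} references unknown species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + sr.getStoichiometry()

        reversible = bool(r.getReversible()) if r.isSetReversible() else True
        lb, ub = _fbc_bounds(r, sm)
        if lb is None and ub is None:
            lb, ub = _kinetic_bounds(r)
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        if lb < 0:
            reversible = True

        rule = _fbc_gene_rule(r)
        if rule is None:
            rule = _notes_gene_rule(r)
        rule = _normalize_rule(rule)

        model.reactions.append(Reaction(
            id=r.getId(),
            name=r.getName() or "",
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=lb,
            upper_bound=ub,
            gene_rule=rule,
        ))

    model.exempt_species = {s.id for s in model.species
                            if re.search(r"photon|light|(?:^|_)hv(?:_|$)",
                                         s.id, re.I)
                            or re.search(r"photon|light", s.name, re.I)}
    model.validate()
    return model


def _normalize_rule(rule: str) -> str:
    """Canonical string form of a gene rule (parses then re-serializes)."""
    return parse_gene_rule(rule).to_string()


# ---------------------------------------------------------------------------
# SBML writing
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write a model as SBML L2v4 in the legacy COBRA dialect."""
    model.validate()
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(model.id)

    for cid in model.compartments:
        c = sm.createCompartment()
        c.setId(cid)
        c.setSize(1.0)

    for sp in model.species:
        s = sm.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        s.setCompartment(sp.compartment)
        s.setBoundaryCondition(bool(sp.boundary))
        s.setInitialConcentration(0.0)

    for rx in model.reactions:
        r = sm.createReaction()
        r.setId(rx.id)
        if rx.name:
            r.setName(rx.name)
        r.setReversible(bool(rx.reversible))
        for sid, coef in sorted(rx.stoichiometry.items()):
            if coef < 0:
                sr = r.createReactant()
                sr.setSpecies(sid)
                sr.setStoichiometry(-coef)
            elif coef > 0:
                sr = r.createProduct()
                sr.setSpecies(sid)
                sr.setStoichiometry(coef)
        kl = r.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pid, val in (("LOWER_BOUND", rx.lower_bound),
                         ("UPPER_BOUND", rx.upper_bound),
                         ("FLUX_VALUE", 0.0)):
            p = kl.createParameter()
            p.setId(pid)
            p.setValue(float(val))
            p.setUnits("dimensionless")
        if rx.gene_rule:
            r.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>GENE_ASSOCIATION: {rx.gene_rule}</p></body>"
            )

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Conservation (mass-leak) testing
# ---------------------------------------------------------------------------

def check_mass_leaks(model: MetabolicModel, tol: float = 1e-6,
                     exempt: set[str] | None = None) -> list[tuple[str, str]]:
    """Find species that can be created or destroyed with all exchanges closed.

    For every non-exempt species, all exchange routes (single-species
    reactions; boundary flags) are closed and a probe sink (or source) is
    added; if the probe can carry flux above ``tol`` at steady state the
    species is reported as ``(species_id, "produced")`` or
    ``(species_id, "consumed")``.  Species representing light are exempt —
    they may legitimately be consumed to drive futile cycles — and their
    balance rows are dropped so light-driven cycles do not implicate other
    species.  One LP is solved per species and direction.
    """
    if exempt is None:
        exempt = set(model.exempt_species)

    test_species = [s.id for s in model.species if s.id not in exempt]
    row_of = {sid: k for k, sid in enumerate(test_species)}

    n_rxn = len(model.reactions)
    S = lil_matrix((len(test_species), n_rxn))
    lb = np.zeros(n_rxn)
    ub = np.zeros(n_rxn)
    for j, r in enumerate(model.reactions):
        if r.is_exchange:
            continue  # exchanges closed: bounds stay 0
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for sid, coef in r.stoichiometry.items():
            if sid in row_of:
                S[row_of[sid], j] += coef
    S = S.tocsc()

    leaks: list[tuple[str, str]] = []
    from scipy.sparse import hstack, csc_matrix

    for sid in test_species:
        k = row_of[sid]
        for direction, sign in (("produced", -1.0), ("consumed", +1.0)):
            # probe column: sink (consumes sid) for production test,
            # source (creates sid) for consumption test
            probe = csc_matrix(
                ([sign], ([k], [0])), shape=(len(test_species), 1)
            )
            A = hstack([S, probe], format="csc")
            c = np.zeros(n_rxn + 1)
            c[-1] = -1.0  # maximize probe flux
            bounds = list(zip(lb, ub)) + [(0.0, DEFAULT_BOUND)]
            res = linprog(c, A_eq=A, b_eq=np.zeros(len(test_species)),
                          bounds=bounds, method="highs")
            if res.status not in (0, 2):
                raise RuntimeError(
                    f"LP solver failure during leak check for {sid!r}: "
                    f"{res.message}"
                )
            if res.status == 0 and -res.fun > tol:
                leaks.append((sid, direction))
                break  # one direction is enough to flag the species
    return leaks


def leak_report_tsv(model: MetabolicModel, path: str, tol: float = 1e-6) -> list:
    """Write the leak report as TSV (species, direction)."""
    leaks = check_mass_leaks(model, tol=tol)
    with open(path, "w") as fh:
        fh.write("species\tdirection\n")
        for sid, direction in leaks:
            fh.write(f"{sid}\t{direction}\n")
    return leaks
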