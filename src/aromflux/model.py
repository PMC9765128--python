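"""Data model, I/O and validation for stoichiometric metabolic models.

A :class:`MetabolicModel` is the in-memory form of a genome-scale
reconstruction: metabolites with elemental formulas, reactions with signed
stoichiometries and flux bounds, and a biomass reaction acting as the growth
objective.  Reactions are categorised (enzymatic, transport, boundary,
biomass, maintenance, definition) so that bookkeeping such as "how many
reactions are enzyme-catalyzed" is explicit and testable.

Supported formats: a native JSON dialect (lossless round-trip), a TSV table
with human-readable equation strings, and read-only SBML import.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from scipy import sparse

COMPARTMENTS = ("cytoplasm", "periplasm", "external")
CATEGORIES = ("enzymatic", "transport", "boundary", "biomass", "maintenance", "definition")

#: Element symbols the balance checker knows how to count.
CHECKED_ELEMENTS = ("C", "H", "N", "O", "P", "S", "Fe", "Mg", "Co")

DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)


class ModelValidationError(ValueError):
    """Raised when a model or model file violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytoplasm"
    formula: dict[str, float] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )

    def n_atoms(self, element: str) -> float:
        """Atom count of *element*; 0 if the formula is present but lacks it."""
        if self.formula is None:
            raise ModelValidationError(f"metabolite {self.id!r} has no formula")
        return float(self.formula.get(element, 0.0))


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[1]
    name: str = ""
    gene_association: tuple[str, ...] = ()
    category: str = "enzymatic"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.category not in CATEGORIES:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown category {self.category!r}"
            )
        self.gene_association = tuple(self.gene_association)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound


@dataclass
class CategoryCounts:
    n_reactions_total: int
    n_metabolites: int
    per_category: dict[str, int]
    n_enzyme_catalyzed: int


@dataclass
class BalanceReport:
    """Outcome of an elemental balance check.

    ``imbalances`` maps reaction id -> element -> net atoms produced minus
    consumed; only non-zero entries appear.  ``unchecked`` lists reactions
    that could not be checked because a participating metabolite lacks a
    formula (those are *not* counted as balanced).
    """

    imbalances: dict[str, dict[str, float]]
    unchecked: list[str]

    @property
    def balanced(self) -> bool:
        return not self.imbalances


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        by_id = {m.id: m for m in self.metabolites}
        for rxn in self.reactions:
            missing = [m for m in rxn.stoichiometry if m not in by_id]
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites: {missing}"
                )
            if rxn.category == "boundary":
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"boundary reaction {rxn.id!r} must touch exactly one metabolite"
                    )
                (mid,) = rxn.stoichiometry
                if by_id[mid].compartment != "external":
                    raise ModelValidationError(
                        f"boundary reaction {rxn.id!r} touches non-external "
                        f"metabolite {mid!r}"
                    )
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(f"objective {self.objective_id!r} not in model")
        if self.reaction(self.objective_id).category != "biomass":
            raise ModelValidationError(
                f"objective {self.objective_id!r} must have category 'biomass'"
            )

    # -- access helpers ----------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[
                Metabolite(m.id, m.name, m.compartment,
                           dict(m.formula) if m.formula is not None else None, m.charge)
                for m in self.metabolites
            ],
            reactions=[
                Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                         r.name, r.gene_association, r.category)
                for r in self.reactions
            ],
            objective_id=self.objective_id,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """Sparse S: one row per metabolite, one column per reaction (declared order)."""
    row_of = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(row_of[mid])
            cols.append(j)
            data.append(float(coeff))
    return sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def model_summary(model: MetabolicModel) -> CategoryCounts:
    """Per-category reaction counts plus the enzyme-catalyzed tally.

    A reaction counts as enzyme-catalyzed iff its category is ``enzymatic``,
    or it is a ``transport`` reaction with a non-empty gene association
    (carrier-mediated transport).  Boundary, biomass, maintenance and
    definition pseudo-reactions never count.
    """
    per_category = {c: 0 for c in CATEGORIES}
    n_enzyme = 0
    for r in model.reactions:
        per_category[r.category] += 1
        if r.category == "enzymatic" or (r.category == "transport" and r.gene_association):
            n_enzyme += 1
    per_category = {c: n for c, n in per_category.items() if n}
    return CategoryCounts(
        n_reactions_total=len(model.reactions),
        n_metabolites=len(model.metabolites),
        per_category=per_category,
        n_enzyme_catalyzed=n_enzyme,
    )


#: Reaction categories exempt from elemental balancing: they intentionally
#: create or destroy matter (exchange with the environment, lumped biomass,
#: definition pseudo-reactions) or are pure energy drains (maintenance).
_BALANCE_EXEMPT = {"boundary", "biomass", "definition", "maintenance"}


def check_mass_balance(
    model: MetabolicModel,
    elements: Sequence[str] = ("C",),
    tol: float = 1e-9,
) -> BalanceReport:
    """Net atom balance of every non-exempt reaction for the given elements.

    Unrecognised element symbols are skipped with a warning.  A reaction in
    which any participant lacks a formula is reported as unchecked.
    """
    elements = list(elements)
    for el in list(elements):
        if el not in CHECKED_ELEMENTS:
            warnings.warn(f"element {el!r} is not checked; skipping", stacklevel=2)
            elements.remove(el)
    by_id = {m.id: m for m in model.metabolites}
    imbalances: dict[str, dict[str, float]] = {}
    unchecked: list[str] = []
    for rxn in model.reactions:
        if rxn.category in _BALANCE_EXEMPT:
            continue
        if any(by_id[mid].formula is None for mid in rxn.stoichiometry):
            unchecked.append(rxn.id)
            continue
        bad = {}
        for el in elements:
            net = sum(
                coeff * by_id[mid].n_atoms(el) for mid, coeff in rxn.stoichiometry.items()
            )
            if abs(net) > tol:
                bad[el] = net
        if bad:
            imbalances[rxn.id] = bad
    return BalanceReport(imbalances=imbalances, unchecked=unchecked)


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def _metabolite_to_dict(m: Metabolite) -> dict:
    d: dict = {"id": m.id, "name": m.name, "compartment": m.compartment}
    if m.formula is not None:
        d["formula"] = m.formula
    if m.charge is not None:
        d["charge"] = m.charge
    return d


def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "name": r.name,
        "stoichiometry": r.stoichiometry,
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "gene_association": list(r.gene_association),
        "category": r.category,
    }


def save_model(model: MetabolicModel, path) -> None:
    doc = {
        "metadata": model.metadata,
        "objective_id": model.objective_id,
        "metabolites": [_metabolite_to_dict(m) for m in model.metabolites],
        "reactions": [_reaction_to_dict(r) for r in model.reactions],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _load_json(path) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("metabolites", "reactions", "objective_id"):
        if key not in doc:
            raise ModelParseError(f"{path}: missing top-level key {key!r}")
    mets = [
        Metabolite(
            id=d["id"],
            name=d.get("name", ""),
            compartment=d.get("compartment", "cytoplasm"),
            formula={k: float(v) for k, v in d["formula"].items()} if "formula" in d else None,
            charge=d.get("charge"),
        )
        for d in doc["metabolites"]
    ]
    rxns = [
        Reaction(
            id=d["id"],
            stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
            lower_bound=float(d.get("lower_bound", DEFAULT_IRREVERSIBLE_BOUNDS[0])),
            upper_bound=float(d.get("upper_bound", DEFAULT_IRREVERSIBLE_BOUNDS[1])),
            name=d.get("name", ""),
            gene_association=tuple(d.get("gene_association", ())),
            category=d.get("category", "enzymatic"),
        )
        for d in doc["reactions"]
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=doc["objective_id"],
        metadata=dict(doc.get("metadata", {})),
    )


# ---------------------------------------------------------------------------
# TSV (one reaction per row, equation strings like "2 A + B -> C")
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into a signed stoichiometry map.

    ``<->``/``<=>`` mark reversible reactions.  A missing side denotes an
    exchange/drain (e.g. ``"A ->"``).  Returns (stoichiometry, reversible).
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelParseError(f"no reaction arrow in equation {equation!r}")
    reversible = arrow in ("<->", "<=>")
    lhs, rhs = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def _add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelParseError(f"empty term in equation {equation!r}")
            m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
            if not m:
                raise ModelParseError(f"cannot parse term {term!r} in {equation!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            mid = m.group(2)
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    _add(lhs, -1.0)
    _add(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelParseError(f"equation {equation!r} cancels to nothing")
    return stoich, reversible


def _load_tsv(path) -> MetabolicModel:
    """TSV dialect: columns id, equation and optionally name, lower_bound,
    upper_bound, genes (comma-separated), category.  Metabolites are declared
    implicitly by the equations; ids ending in ``_e`` are external."""
    import csv

    rxns: list[Reaction] = []
    met_ids: dict[str, None] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or "id" not in reader.fieldnames or "equation" not in reader.fieldnames:
            raise ModelParseError(f"{path}: TSV needs at least 'id' and 'equation' columns")
        for lineno, row in enumerate(reader, start=2):
            try:
                stoich, reversible = parse_equation(row["equation"])
            except ModelParseError as exc:
                raise ModelParseError(f"{path}:{lineno}: {exc}") from exc
            default = DEFAULT_REVERSIBLE_BOUNDS if reversible else DEFAULT_IRREVERSIBLE_BOUNDS
            lb = float(row["lower_bound"]) if row.get("lower_bound") else default[0]
            ub = float(row["upper_bound"]) if row.get("upper_bound") else default[1]
            genes = tuple(g for g in (row.get("genes") or "").split(",") if g)
            category = row.get("category") or ("boundary" if len(stoich) == 1 else "enzymatic")
            rxns.append(
                Reaction(row["id"], stoich, lb, ub, row.get("name", "") or "",
                         genes, category)
            )
            for mid in stoich:
                met_ids.setdefault(mid, None)
    mets = [
        Metabolite(mid, compartment="external" if mid.endswith("_e") else "cytoplasm")
        for mid in met_ids
    ]
    objective = next((r.id for r in rxns if r.category == "biomass"), None)
    if objective is None:
        raise ModelValidationError(f"{path}: no reaction with category 'biomass'")
    return MetabolicModel(mets, rxns, objective, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# SBML import (read-only)
# ---------------------------------------------------------------------------

def _load_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML error at line {err.getLine()}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path}: no model element")

    def _clip(sid: str, prefix: str) -> str:
        # SBML convention writes reaction/species ids as R_*/M_*
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    boundary_species = set()
    mets = []
    for sp in sm.getListOfSpecies():
        sid = _clip(sp.getId(), "M_")
        if sp.getBoundaryCondition():
            boundary_species.add(sid)
        comp = "external" if sp.getBoundaryCondition() else "cytoplasm"
        mets.append(Metabolite(sid, sp.getName() or "", comp))

    fbc = sm.getPlugin("fbc")
    objective_rid = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rid = _clip(obj.getFluxObjective(0).getReaction(), "R_")

    def _param(model, ref):
        p = model.getParameter(ref)
        return p.getValue() if p is not None else None

    rxns = []
    for rx in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rx.getNumReactants()):
            sr = rx.getReactant(i)
            mid = _clip(sr.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for i in range(rx.getNumProducts()):
            sr = rx.getProduct(i)
            mid = _clip(sr.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        rev = rx.getReversible()
        lb, ub = DEFAULT_REVERSIBLE_BOUNDS if rev else DEFAULT_IRREVERSIBLE_BOUNDS
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                v = _param(sm, rfbc.getLowerFluxBound())
                if v is not None:
                    lb = v
            if rfbc.isSetUpperFluxBound():
                v = _param(sm, rfbc.getUpperFluxBound())
                if v is not None:
                    ub = v
        if not stoich:
            continue
        rid = _clip(rx.getId(), "R_")
        category = "enzymatic"
        if len(stoich) == 1 and next(iter(stoich)) in boundary_species:
            category = "boundary"
        elif rid == objective_rid or "biomass" in rid.lower():
            category = "biomass"
        rxns.append(Reaction(rid, stoich, lb, ub, rx.getName() or "", (), category))

    if objective_rid is None:
        objective_rid = next((r.id for r in rxns if r.category == "biomass"), None)
    if objective_rid is None:
        raise ModelValidationError(f"{path}: no objective (fbc) and no biomass reaction")
    return MetabolicModel(mets, rxns, objective_rid, metadata={"source": str(path)})


def load_model(path, format: str = "native-json") -> MetabolicModel:
    """Read a model file.  ``format`` is one of native-json, tsv, sbml."""
    loaders = {"native-json": _load_json, "tsv": _load_tsv, "sbml": _load_sbml}
    if format not in loaders:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(loaders)}")
    return loaders[format](path)
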