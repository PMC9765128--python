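"""Biomass reaction assembly from sequence-derived monomer compositions.

The biomass reaction consumes monomer precursors in mmol per gram dry weight.
Nucleotide fractions come from genome GC content under the double-stranded
convention; amino-acid fractions are pooled, length-weighted residue
frequencies over all predicted proteins.  Macromolecular class masses
(g per gDW) are configuration — the shipped defaults are the textbook
E. coli composition — and monomer molar masses are polymerized-residue
masses (free monomer minus water) so that the assembled reaction closes to
1 g of biomass per unit flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import Reaction

MONOMER_BASES = ("dna", "rna", "protein", "lipid")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Water mass removed on polymerization, g/mol.
WATER_MASS = 18.0153


class CompositionError(ValueError):
    pass


@dataclass
class MonomerComposition:
    """Mole fractions of the monomers of one macromolecule class."""

    basis: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.basis not in MONOMER_BASES:
            raise CompositionError(f"unknown basis {self.basis!r}")
        if any(v < 0 for v in self.fractions.values()):
            raise CompositionError("mole fractions must be >= 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"{self.basis} fractions sum to {total}, not 1")


@dataclass
class MacroComposition:
    """Macromolecule class -> g per gDW, plus trace soluble-pool entries.

    Class masses must sum to 1 g/gDW within 2%; :meth:`normalized` rescales
    them to exactly 1.
    """

    class_masses: dict[str, float]
    soluble_pool: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.class_masses.values()) + sum(self.soluble_pool.values())
        if abs(total - 1.0) > 0.02:
            raise CompositionError(f"macromolecular masses sum to {total:.4f} g/gDW, "
                                   "outside 1 ± 2%")

    def normalized(self) -> "MacroComposition":
        total = sum(self.class_masses.values()) + sum(self.soluble_pool.values())
        return MacroComposition(
            {k: v / total for k, v in self.class_masses.items()},
            {k: v / total for k, v in self.soluble_pool.items()},
        )


def nucleotide_composition(sequences: Iterable[str] | str) -> MonomerComposition:
    """dNMP mole fractions from genome sequence(s), double-stranded convention.

    GC is computed from the given strand ignoring N; then
    f(dAMP) = f(dTMP) = (1-GC)/2 and f(dGMP) = f(dCMP) = GC/2, which makes the
    result strand-symmetric.  More than 5% N is an error.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = {b: 0 for b in "ACGTN"}
    total = 0
    for seq in sequences:
        for ch in seq.upper():
            if ch not in counts:
                raise CompositionError(f"unexpected nucleotide {ch!r}")
            counts[ch] += 1
            total += 1
    if total == 0:
        raise CompositionError("empty genome sequence")
    if counts["N"] / total >= 0.05:
        raise CompositionError(f"N fraction {counts['N'] / total:.3f} exceeds 5%")
    acgt = total - counts["N"]
    if acgt == 0:
        raise CompositionError("sequence contains only N")
    gc = (counts["G"] + counts["C"]) / acgt
    return MonomerComposition(
        basis="dna",
        fractions={
            "dAMP": (1 - gc) / 2,
            "dTMP": (1 - gc) / 2,
            "dGMP": gc / 2,
            "dCMP": gc / 2,
        },
    )


def rna_composition(gene_sequences: Iterable[str] | str) -> MonomerComposition:
    """NMP mole fractions from predicted gene sequences (transcribed strand).

    Unlike DNA, RNA is single-stranded, so the fractions follow the base
    frequencies of the coding sequences directly (T read as U).
    """
    if isinstance(gene_sequences, str):
        gene_sequences = [gene_sequences]
    counts = {b: 0 for b in "ACGU"}
    n_skipped = 0
    for seq in gene_sequences:
        for ch in seq.upper().replace("T", "U"):
            if ch in counts:
                counts[ch] += 1
            elif ch == "N":
                n_skipped += 1
            else:
                raise CompositionError(f"unexpected nucleotide {ch!r}")
    total = sum(counts.values())
    if total == 0:
        raise CompositionError("empty gene sequences")
    return MonomerComposition(
        basis="rna",
        fractions={base + "MP": counts[base] / total for base in "ACGU"},
    )


def amino_acid_composition(sequences: Iterable[str] | str) -> MonomerComposition:
    """Pooled, length-weighted residue frequencies over all protein sequences.

    ``X`` (unknown residue) is skipped with a warning; ``*`` (stop) is ignored.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = {aa: 0 for aa in AMINO_ACIDS}
    n_x = 0
    for seq in sequences:
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
            elif ch == "X":
                n_x += 1
            elif ch == "*":
                continue
            else:
                raise CompositionError(f"unexpected amino acid {ch!r}")
    total = sum(counts.values())
    if total == 0:
        raise CompositionError("empty proteome")
    if n_x:
        warnings.warn(f"skipped {n_x} 'X' residues", stacklevel=2)
    return MonomerComposition(
        basis="protein",
        fractions={aa: c / total for aa, c in counts.items()},
    )


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id (thin Biopython wrapper)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def assemble_biomass(
    macro: MacroComposition,
    monomers: Mapping[str, MonomerComposition],
    monomer_masses: Mapping[str, float],
    gam: float = 0.0,
    *,
    reaction_id: str = "BIOMASS",
    atp_id: str = "atp_c",
    adp_id: str = "adp_c",
    pi_id: str = "pi_c",
    normalize: bool = True,
    mass_tol: float = 0.01,
) -> Reaction:
    """Build the biomass reaction (category ``biomass``) in mmol/gDW units.

    For every macromolecule class, the coefficient of monomer m is
    class g/gDW × mole fraction / polymerized molar mass, in mmol/gDW
    (negative: consumed).  Soluble-pool entries are charged at their own
    molar masses.  ``gam`` adds the growth-associated ATP hydrolysis
    (mmol ATP/gDW).  The consumed precursor mass must close to 1 g per unit
    biomass flux within ``mass_tol``.
    """
    if normalize:
        macro = macro.normalized()
    stoich: dict[str, float] = {}

    def _charge(monomer: str, grams: float) -> None:
        if monomer not in monomer_masses:
            raise CompositionError(f"no molar mass for monomer {monomer!r}")
        mmol = 1000.0 * grams / monomer_masses[monomer]
        stoich[monomer] = stoich.get(monomer, 0.0) - mmol

    for cls, grams in macro.class_masses.items():
        if cls not in monomers:
            raise CompositionError(f"no monomer composition for class {cls!r}")
        # coefficient of monomer m: class g/gDW × fraction / M_m (mmol/gDW);
        # summing coeff × M_m over the class returns exactly the class grams.
        for mono, frac in monomers[cls].fractions.items():
            if frac > 0:
                _charge(mono, grams * frac)
    for mono, grams in macro.soluble_pool.items():
        _charge(mono, grams)

    mass = sum(-coeff * monomer_masses[mono] / 1000.0 for mono, coeff in stoich.items())
    if abs(mass - 1.0) > mass_tol:
        raise CompositionError(f"biomass mass closure failed: {mass:.4f} g/gDW")

    if gam > 0:
        stoich[atp_id] = stoich.get(atp_id, 0.0) - gam
        stoich[adp_id] = stoich.get(adp_id, 0.0) + gam
        stoich[pi_id] = stoich.get(pi_id, 0.0) + gam

    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="biomass assembly",
        category="biomass",
    )


def biomass_mass(reaction: Reaction, monomer_masses: Mapping[str, float],
                 skip: Iterable[str] = ()) -> float:
    """Grams of precursors consumed per unit biomass flux (mass-ledger check)."""
    skip = set(skip)
    return sum(
        -coeff * monomer_masses[mono] / 1000.0
        for mono, coeff in reaction.stoichiometry.items()
        if coeff < 0 and mono not in skip
    )


#: Textbook E. coli macromolecular composition (g per gDW), shipped as
#: configuration — never hard-coded inside assembly logic.
ECOLI_MACRO_DEFAULT = {
    "protein": 0.55,
    "rna": 0.20,
    "dna": 0.031,
    "lipid": 0.091,
    "murein_lps_glycogen": 0.088,
    "soluble_pool": 0.04,
}
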