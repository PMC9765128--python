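"""Biomass reaction assembly from (synthetic) genome and proteome sequences.

Draws a small random genome with 65% GC and a proteome with a planted
residue distribution, estimates the DNA and protein monomer compositions,
and assembles a mass-closed biomass reaction from textbook macromolecular
fractions.
"""

import numpy as np

import aromflux as af
from aromflux.biomass import ECOLI_MACRO_DEFAULT, MacroComposition, biomass_mass

rng = np.random.default_rng(12)
gc = 0.65
genome = "".join(rng.choice(list("ACGT"), size=50_000,
                            p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))
letters = list("ACDEFGHIKLMNPQRSTVWY")
probs = rng.dirichlet(np.full(20, 5.0))
proteome = ["".join(rng.choice(letters, p=probs, size=300)) for _ in range(200)]

dna = af.nucleotide_composition(genome)
protein = af.amino_acid_composition(proteome)
print("dNMP mole fractions:", {k: round(v, 3) for k, v in dna.fractions.items()})
print("top-5 residues:",
      sorted(protein.fractions.items(), key=lambda kv: -kv[1])[:5])

# polymerized residue masses (g/mol); one simple mass per class suffices here
residue_masses = {aa: 110.0 for aa in letters}  # mean protein residue
residue_masses.update({"dAMP": 313.21, "dTMP": 304.20, "dGMP": 329.21,
                       "dCMP": 289.18, "lipid_unit": 700.0, "pool": 400.0})

macro = MacroComposition(
    {"protein": ECOLI_MACRO_DEFAULT["protein"],
     "dna": ECOLI_MACRO_DEFAULT["dna"]},
    soluble_pool={"lipid_unit": 0.30, "pool": 0.119},
)
reaction = af.assemble_biomass(
    macro, {"protein": protein, "dna": dna}, residue_masses, gam=59.81
)
print(f"\nbiomass reaction consumes {len(reaction.stoichiometry)} species")
print(f"precursor mass per unit biomass flux: "
      f"{biomass_mass(reaction, residue_masses, skip=('atp_c',)):.4f} g/gDW")
print("growth-associated maintenance: "
      f"{-reaction.stoichiometry['atp_c']:.2f} mmol ATP/gDW")
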