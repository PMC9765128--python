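"""Synthetic data emulating a facultative anaerobic aromatic degrader.

Three generators make every analysis module testable without external data:

* :func:`make_toy_model` — a carbon- and electron-balanced reaction network
  with the qualitative structure of a facultative anaerobe: substrate
  activation shared between respiratory modes, an O₂-independent
  (ring-reducing) and an O₂-dependent (oxygenase) aromatic branch, a
  TCA-like oxidation to CO₂, NADH dehydrogenase feeding a quinone pool, a
  lumped denitrification chain (NO₃⁻ + 5 e⁻ → ½N₂) and an O₂ reductase
  (4 e⁻), proton-gradient-driven ATP synthase, maintenance, and a biomass
  drain.  Electron bookkeeping rides on the metabolite formulas, so the
  generic balance checker verifies the construction independently.

* :func:`make_transcript_counts` — gene × condition count matrices with
  lognormal per-condition marginals and a planted low-rank metagene
  structure (disjoint gene modules, condition-specific activity) so
  factorization-rank recovery has a known ground truth.

* :func:`make_growth_curve` — exponential growth curves with known rate and
  yield whose substrate and acceptor series are drawn down consistently with
  the same electron ledger the stoichiometry module closes.

All generators are bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import DEFAULT_GAM, DEFAULT_NGAM, Condition
from .model import MetabolicModel, Metabolite, Reaction
from .nmf import TranscriptMatrix
from .stoichiometry import ACCEPTOR_ELECTRONS, CARBON_MASS, GrowthCurve, degree_of_reduction


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# toy metabolic network
# ---------------------------------------------------------------------------

@dataclass
class ToyNetworkSpec:
    include_phb: bool = True
    include_glyoxylate_shunt: bool = True
    substrates: tuple[str, ...] = ("acetate", "aromatic")
    #: ATP gained per electron pair (NADH) for each terminal acceptor;
    #: O₂ respiration must beat denitrification for the aerobic growth
    #: advantage to be a planted truth.
    p_to_o_ratio: dict[str, float] = field(
        default_factory=lambda: {"oxygen": 2.0, "nitrate": 5.0 / 3.0}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.substrates) - {"acetate", "aromatic"}
        if unknown:
            raise SpecError(f"unknown substrates {sorted(unknown)}")
        if not self.substrates:
            raise SpecError("need at least one substrate")
        if set(self.p_to_o_ratio) != {"oxygen", "nitrate"}:
            raise SpecError("p_to_o_ratio must name exactly oxygen and nitrate")
        if min(self.p_to_o_ratio.values()) <= 0:
            raise SpecError("p_to_o ratios must be positive")


#: Biomass drain: per unit flux, 20 mmol acetyl units (40 mmol C, ~1 g dry
#: mass at ~48 wt% C), ATP covering polymerization plus growth-associated
#: maintenance, and 2 mmol NADH for reductive biosynthesis steps.
_BIOMASS_ACCOA = 20.0
_BIOMASS_ATP = 80.0
_BIOMASS_NADH = 2.0


def make_toy_model(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Build the facultative-anaerobe toy network (~25–30 reactions).

    Every non-exempt reaction conserves carbon atoms and degree-of-reduction
    electrons by construction; formulas carry the ledger (reduced carriers
    are written as H₂ so γ = 2 per pair).
    """
    spec = spec or ToyNetworkSpec()
    h_ox = 3.0 * spec.p_to_o_ratio["oxygen"]  # protons per QH₂ at the O₂ reductase
    h_den = 3.0 * spec.p_to_o_ratio["nitrate"]  # … at the denitrification lump

    mets = [
        Metabolite("ac_e", "acetate (external)", "external", {"C": 2, "H": 4, "O": 2}),
        Metabolite("bz_e", "aromatic acid (external)", "external", {"C": 7, "H": 6, "O": 2}),
        Metabolite("o2_e", "dioxygen (external)", "external", {"O": 2}),
        Metabolite("no3_e", "nitrate (external)", "external", {"N": 1, "O": 3}, charge=-1),
        Metabolite("co2_e", "CO2 (external)", "external", {"C": 1, "O": 2}),
        Metabolite("n2_e", "dinitrogen (external)", "external", {"N": 2}),
        Metabolite("h2o_e", "water (external)", "external", {"H": 2, "O": 1}),
        Metabolite("ac_c", "acetate", "cytoplasm", {"C": 2, "H": 4, "O": 2}),
        Metabolite("bz_c", "aromatic acid", "cytoplasm", {"C": 7, "H": 6, "O": 2}),
        Metabolite("o2_c", "dioxygen", "cytoplasm", {"O": 2}),
        Metabolite("no3_c", "nitrate", "cytoplasm", {"N": 1, "O": 3}, charge=-1),
        Metabolite("co2_c", "CO2", "cytoplasm", {"C": 1, "O": 2}),
        Metabolite("n2_c", "dinitrogen", "cytoplasm", {"N": 2}),
        Metabolite("h2o_c", "water", "cytoplasm", {"H": 2, "O": 1}),
        Metabolite("accoa_c", "acetyl unit", "cytoplasm", {"C": 2, "H": 4, "O": 2}),
        Metabolite("bzcoa_c", "aroyl unit", "cytoplasm", {"C": 7, "H": 6, "O": 2}),
        Metabolite("redring_c", "reduced-ring diene unit", "cytoplasm",
                    {"C": 7, "H": 10, "O": 2}),
        Metabolite("oxring_c", "ring-epoxide unit", "cytoplasm", {"C": 7, "H": 8, "O": 4}),
        Metabolite("atp_c", "ATP (energy unit)", "cytoplasm", {}),
        Metabolite("nadh_c", "NADH (electron pair)", "cytoplasm", {"H": 2}),
        Metabolite("q_c", "quinone", "cytoplasm", {}),
        Metabolite("qh2_c", "quinol (electron pair)", "cytoplasm", {"H": 2}),
        Metabolite("hp_p", "translocated proton", "periplasm", {}),
    ]

    def rxn(rid, stoich, lb=0.0, ub=1000.0, name="", genes=(), category="enzymatic"):
        return Reaction(rid, stoich, lb, ub, name, tuple(genes), category)

    rxns = [
        # exchanges: positive flux exports, negative imports
        rxn("EX_o2", {"o2_e": -1}, name="O2 exchange", category="boundary"),
        rxn("EX_no3", {"no3_e": -1}, name="nitrate exchange", category="boundary"),
        rxn("EX_co2", {"co2_e": -1}, name="CO2 exchange", category="boundary"),
        rxn("EX_n2", {"n2_e": -1}, name="N2 exchange", category="boundary"),
        rxn("EX_h2o", {"h2o_e": -1}, name="water exchange", category="boundary"),
        rxn("T_o2", {"o2_e": -1, "o2_c": 1}, name="O2 diffusion", category="transport"),
        rxn("T_no3", {"no3_e": -1, "no3_c": 1}, genes=("narK",),
            name="nitrate transport", category="transport"),
        rxn("T_co2", {"co2_c": -1, "co2_e": 1}, name="CO2 export", category="transport"),
        rxn("T_n2", {"n2_c": -1, "n2_e": 1}, name="N2 export", category="transport"),
        rxn("T_h2o", {"h2o_c": -1, "h2o_e": 1}, name="water export", category="transport"),
        # respiration
        rxn("NDH", {"nadh_c": -1, "q_c": -1, "qh2_c": 1}, genes=("nuoA",),
            name="NADH dehydrogenase"),
        rxn("NAR", {"qh2_c": -1, "no3_c": -0.4, "q_c": 1, "n2_c": 0.2,
                    "h2o_c": 1.2, "hp_p": h_den},
            genes=("narG", "nirS", "norB", "nosZ"), name="denitrification chain (lumped)"),
        rxn("CCO", {"qh2_c": -1, "o2_c": -0.5, "q_c": 1, "h2o_c": 1, "hp_p": h_ox},
            genes=("ccoN",), name="O2 reductase"),
        rxn("ATPS", {"hp_p": -3, "atp_c": 1}, genes=("atpA",), name="ATP synthase"),
        rxn("NGAM", {"atp_c": -1}, lb=0.0, ub=1000.0,
            name="non-growth maintenance", category="maintenance"),
        rxn("BIOMASS", {"accoa_c": -_BIOMASS_ACCOA, "atp_c": -_BIOMASS_ATP,
                        "nadh_c": -_BIOMASS_NADH},
            name="biomass drain", category="biomass"),
        # TCA-like core
        rxn("TCA", {"accoa_c": -1, "co2_c": 2, "nadh_c": 4}, genes=("gltA", "icd"),
            name="acetyl oxidation to CO2 (TCA-like)"),
    ]

    if "acetate" in spec.substrates:
        rxns += [
            rxn("EX_ac", {"ac_e": -1}, name="acetate exchange", category="boundary"),
            rxn("T_ac", {"ac_e": -1, "ac_c": 1}, genes=("actP",),
                name="acetate uptake", category="transport"),
            rxn("ACS", {"ac_c": -1, "atp_c": -1, "accoa_c": 1}, genes=("acsA",),
                name="acetate activation"),
        ]
    if "aromatic" in spec.substrates:
        rxns += [
            rxn("EX_bz", {"bz_e": -1}, name="aromatic exchange", category="boundary"),
            rxn("T_bz", {"bz_e": -1, "bz_c": 1}, genes=("bzdT",),
                name="aromatic uptake", category="transport"),
            rxn("BCL", {"bz_c": -1, "atp_c": -2, "bzcoa_c": 1}, genes=("bcl",),
                name="aromatic activation (shared)"),
            rxn("BCR", {"bzcoa_c": -1, "nadh_c": -2, "redring_c": 1}, genes=("bcrA",),
                name="O2-independent ring reduction"),
            rxn("BOX_OXY", {"bzcoa_c": -1, "o2_c": -1, "nadh_c": -1,
                            "oxring_c": 1, "h2o_c": 1}, genes=("boxB",),
                name="O2-dependent ring epoxidation"),
            rxn("BETAOX", {"redring_c": -1, "accoa_c": 3.5, "nadh_c": 3},
                genes=("fadB",), name="modified beta-oxidation"),
            rxn("BOX_CLEAVE", {"oxring_c": -1, "accoa_c": 3.5}, genes=("boxC",),
                name="epoxide ring cleavage"),
        ]
    if spec.include_glyoxylate_shunt:
        rxns += [
            rxn("GLX", {"accoa_c": -2, "suc_c": 1, "nadh_c": 1}, genes=("aceA", "aceB"),
                name="glyoxylate shunt (lumped)"),
            rxn("SUCOX", {"suc_c": -1, "co2_c": 4, "nadh_c": 7}, genes=("sdhA",),
                name="C4 oxidation to CO2"),
        ]
        mets.append(Metabolite("suc_c", "C4 dicarboxylate unit", "cytoplasm",
                               {"C": 4, "H": 6, "O": 4}))
    if spec.include_phb:
        rxns += [
            rxn("PHB_SYN", {"accoa_c": -2, "nadh_c": -1, "phb_c": 1},
                genes=("phaC",), name="PHB monomer synthesis"),
            rxn("PHB_STORE", {"phb_c": -1}, name="PHB storage drain",
                category="definition"),
        ]
        mets.append(Metabolite("phb_c", "PHB monomer", "cytoplasm",
                               {"C": 4, "H": 6, "O": 2}))

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS",
        metadata={"name": "facultative-anaerobe toy network"},
    )


#: Default uptake maxima, mmol·gDW⁻¹·h⁻¹ — roughly carbon-equivalent for the
#: C2 and C7 substrates, with the acceptor generously but finitely supplied.
TOY_UPTAKE = {"acetate": 10.0, "aromatic": 3.0}
TOY_ACCEPTOR_MAX = {"oxygen": 25.0, "nitrate": 30.0}

_SUBSTRATE_EXCHANGE = {"acetate": "EX_ac", "aromatic": "EX_bz"}
_ACCEPTOR_EXCHANGE = {"oxygen": "EX_o2", "nitrate": "EX_no3"}


def toy_conditions(
    substrates: tuple[str, ...] = ("acetate", "aromatic"),
    acceptors: tuple[str, ...] = ("oxygen", "nitrate"),
    ngam: float = DEFAULT_NGAM,
) -> list[Condition]:
    """The shipped substrate × acceptor condition presets for the toy network."""
    conditions = []
    for sub in substrates:
        for acc in acceptors:
            rival = "nitrate" if acc == "oxygen" else "oxygen"
            conditions.append(
                Condition(
                    label=f"{sub}-{'aerobic' if acc == 'oxygen' else 'anaerobic'}",
                    substrate_exchange=_SUBSTRATE_EXCHANGE[sub],
                    substrate_uptake_max=TOY_UPTAKE[sub],
                    acceptor=acc,
                    acceptor_exchange=_ACCEPTOR_EXCHANGE[acc],
                    acceptor_uptake_max=TOY_ACCEPTOR_MAX[acc],
                    ngam=ngam,
                    gam=DEFAULT_GAM,
                    closed_exchanges=(_ACCEPTOR_EXCHANGE[rival],),
                )
            )
    return conditions


# ---------------------------------------------------------------------------
# transcript counts with planted metagene structure
# ---------------------------------------------------------------------------

@dataclass
class TranscriptSimSpec:
    n_genes: int = 500
    n_conditions: int = 10
    m_true: int = 3
    #: condition score when the module owns / does not own the condition.
    #: The zero default plants strict substrate-specific regulation — a
    #: module's genes are simply not detected off-condition — which makes
    #: the factorization identifiable (anchor structure); s_off > 0 gives
    #: relaxed regulation but a non-unique factorization.
    s_on: float = 1.0
    s_off: float = 0.0
    meanlog: float = 5.0  # baseline expression, log copy numbers
    sdlog: float = 1.5
    w_sdlog: float = 0.3  # spread of per-gene module weights
    noise_sd: float = 0.01  # fractional sd of the additive truncated-Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_true < 1 or self.m_true > min(self.n_genes, self.n_conditions):
            raise SpecError("m_true must be in [1, min(n_genes, n_conditions)]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


def make_transcript_counts(
    spec: TranscriptSimSpec,
) -> tuple[TranscriptMatrix, dict]:
    """Raw counts with planted rank-m structure plus the ground truth.

    counts_ij = baseline_i · W_true[i, k(i)] · S_true[k(i), j] (+ noise),
    with genes partitioned into m disjoint modules and conditions assigned
    round-robin to modules.  At zero noise the matrix has exact rank m_true.
    Ground truth contains W (with the baseline folded in, i.e. on the count
    scale), S, the baseline, and the module/condition assignments.
    """
    rng = np.random.default_rng(spec.seed)
    n, M, m = spec.n_genes, spec.n_conditions, spec.m_true
    gene_module = np.repeat(np.arange(m), int(np.ceil(n / m)))[:n]
    condition_module = np.arange(M) % m
    W = np.zeros((n, m))
    W[np.arange(n), gene_module] = rng.lognormal(0.0, spec.w_sdlog, size=n)
    S = np.where(
        condition_module[None, :] == np.arange(m)[:, None], spec.s_on, spec.s_off
    )
    baseline = rng.lognormal(spec.meanlog, spec.sdlog, size=n)
    counts = (baseline[:, None] * W) @ S
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=counts.shape) * counts
        counts = np.clip(counts + noise, 0.0, None)
    genes = [f"gene_{i:04d}" for i in range(n)]
    conditions = [f"cond_{j:02d}" for j in range(M)]
    truth = {
        "W": baseline[:, None] * W,  # count-scale gene loadings
        "S": S,
        "baseline": baseline,
        "gene_module": gene_module,
        "condition_module": condition_module,
    }
    return TranscriptMatrix(genes, conditions, counts, scale="raw"), truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimSpec:
    mu_true: float = 0.25  # h⁻¹
    od0: float = 0.02
    yield_true: float = 0.42  # C/C fraction in (0, 1)
    substrate0_mM: float = 8.0  # acetate-like batch concentration
    substrate_formula: dict[str, float] = field(
        default_factory=lambda: {"C": 2, "H": 4, "O": 2}
    )
    substrate_charge: float = 0.0
    acceptor: str = "nitrate"
    acceptor0_mM: float = 7.0
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 10.5, 0.5))
    noise_sd: float = 0.0  # fractional, applied to OD and concentration series
    od_to_cdw: float = 0.45  # g CDW per L per OD unit
    biomass_c_wt_pct: float = 48.0
    biomass_gamma_per_c: float = 4.2  # e⁻ per biomass C (CH1.8O0.5N0.2-like)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_true <= 0:
            raise SpecError("mu_true must be > 0")
        if not 0 < self.yield_true <= 1:
            raise SpecError("yield_true must be in (0, 1]")
        if self.acceptor not in ACCEPTOR_ELECTRONS:
            raise SpecError(f"unknown acceptor {self.acceptor!r}")


def make_growth_curve(spec: GrowthSimSpec) -> tuple[GrowthCurve, dict]:
    """Exponential growth with substrate/acceptor draw-down and known truth.

    The noiseless OD obeys od0·e^{μt}; substrate consumption follows from the
    carbon balance at the true C/C yield, and acceptor consumption from the
    electron ledger (substrate electrons minus electrons kept in biomass).
    Sampling is truncated (and flagged) where substrate or acceptor would be
    exhausted.  Noise is multiplicative on every measured series.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    od = spec.od0 * np.exp(spec.mu_true * t)
    cdw = od * spec.od_to_cdw  # g/L
    n_c = spec.substrate_formula.get("C", 0.0)
    gamma_s = degree_of_reduction(spec.substrate_formula, spec.substrate_charge)
    bio_c = 1000.0 * (cdw - cdw[0]) * (spec.biomass_c_wt_pct / 100.0) / CARBON_MASS
    substrate = spec.substrate0_mM - bio_c / spec.yield_true / n_c
    consumed = spec.substrate0_mM - substrate  # mM
    electrons = consumed * gamma_s - bio_c * spec.biomass_gamma_per_c
    acceptor = spec.acceptor0_mM - electrons / ACCEPTOR_ELECTRONS[spec.acceptor]
    ok = (substrate >= 0) & (acceptor >= 0)
    truncated = not bool(ok.all())
    keep = int(np.sum(np.cumprod(ok)))
    if keep < 3:
        raise SpecError("substrate/acceptor exhausted too early; shorten times")
    t, od, substrate, acceptor = t[:keep], od[:keep], substrate[:keep], acceptor[:keep]
    if spec.noise_sd > 0:
        od = od * (1.0 + rng.normal(0.0, spec.noise_sd, size=od.shape))
        substrate = substrate * (1.0 + rng.normal(0.0, spec.noise_sd, size=od.shape))
        acceptor = acceptor * (1.0 + rng.normal(0.0, spec.noise_sd, size=od.shape))
    curve = GrowthCurve(
        time=t,
        od=od,
        substrate_mM=substrate,
        nitrate_mM=acceptor if spec.acceptor == "nitrate" else None,
        od_to_cdw=spec.od_to_cdw,
    )
    truth = {
        "mu": spec.mu_true,
        "t_d": float(np.log(2) / spec.mu_true),
        "yield_cc_pct": 100.0 * spec.yield_true,
        "substrate_gamma": gamma_s,
        "truncated": truncated,
        "acceptor": spec.acceptor,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# random small networks for LP ground-truthing
# ---------------------------------------------------------------------------

def make_random_network(
    seed: int,
    n_reactions: int = 9,
    n_metabolites: int = 5,
) -> MetabolicModel:
    """A small random flux network with finite bounds for oracle comparisons.

    A linear backbone (uptake → chain of conversions → biomass drain)
    guarantees a non-trivial optimum; extra random reactions add parallel
    routes and degeneracy.  All bounds are finite so the flux polytope is
    bounded and exhaustively enumerable.
    """
    if n_reactions < n_metabolites + 2:
        raise SpecError("need at least n_metabolites + 2 reactions")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"m{i}", compartment="cytoplasm") for i in range(n_metabolites)]
    mets.append(Metabolite("sub_e", compartment="external"))
    rxns = [
        Reaction("UPT", {"sub_e": -1}, -float(rng.integers(2, 10)), 0.0,
                 category="boundary"),
        Reaction("T0", {"sub_e": -1, "m0": 1}, 0.0, 1000.0, category="transport"),
    ]
    for i in range(n_metabolites - 1):
        coeff = float(rng.integers(1, 3))
        rxns.append(
            Reaction(f"C{i}", {f"m{i}": -1, f"m{i + 1}": coeff}, 0.0,
                     float(rng.integers(5, 20)))
        )
    rxns.append(
        Reaction("BIO", {f"m{n_metabolites - 1}": -float(rng.integers(1, 4))},
                 0.0, float(rng.integers(5, 20)), category="biomass")
    )
    n_extra = n_reactions - len(rxns)
    for k in range(n_extra):
        a, b = rng.choice(n_metabolites, size=2, replace=False)
        stoich = {f"m{a}": -float(rng.integers(1, 3)), f"m{b}": float(rng.integers(1, 3))}
        reversible = bool(rng.random() < 0.5)
        ub = float(rng.integers(3, 15))
        rxns.append(Reaction(f"R{k}", stoich, -ub if reversible else 0.0, ub))
    return MetabolicModel(mets, rxns, "BIO", metadata={"seed": str(seed)})
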