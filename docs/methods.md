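# Methods

This note documents the models, conventions and numerical choices behind
aromflux, and what the synthetic-data tests do and do not demonstrate.

## Stoichiometric models

A model is a list of metabolites (id, compartment ∈ {cytoplasm, periplasm,
external}, optional elemental formula and charge) and reactions (signed
stoichiometry, flux bounds in mmol·gDW⁻¹·h⁻¹, gene associations, category).
Categories separate chemistry from bookkeeping: `enzymatic`, `transport`,
`boundary` (exchange pseudo-reactions touching exactly one external
metabolite), `biomass`, `maintenance` (ATP drain) and `definition`
(pool/storage pseudo-reactions). A reaction is counted as *enzyme-catalyzed*
iff it is `enzymatic`, or `transport` with a non-empty gene association;
diffusion and pseudo-reactions never count. This rule is a package
convention — reconstructions differ in where they draw this line, so the
per-category counts are always reported alongside.

Default bounds when a file omits them: (0, 1000) irreversible,
(−1000, 1000) reversible. The native JSON dialect round-trips losslessly;
the TSV dialect carries one reaction per row as an equation string
(`"2 A + B -> C"`, `<->` reversible); SBML import (read-only, via libsbml)
takes fbc bounds and objective where present, maps `boundaryCondition`
species to exchanges, and strips the conventional `R_`/`M_` id prefixes.

The balance checker verifies conservation of requested elements
({C, H, N, O, P, S, Fe, Mg, Co}; others warn and are skipped) for every
non-exempt reaction; exempt are boundary, biomass, definition and
maintenance categories, which intentionally exchange or lump matter. A
reaction with any formula-less participant is reported *unchecked*, never
silently balanced.

## FBA engine

`solve_fba` maximizes the biomass flux subject to S·v = 0 and bounds
(scipy HiGHS, feasibility tolerances 10⁻⁹). With substrate uptake bounded at
its measured maximum, rate and yield maximization coincide, which is the
intended reading of a "maximum biomass yield" objective. Infeasibility and
unboundedness are reported as statuses; other solver failures raise.

LP optima are degenerate, so the single returned flux vector is never used
for activity claims; `flux_variability` (per-reaction min/max at
`objective_fraction` of the optimum, default 1.0 with a 10⁻⁹ slack) is.
Fluxes below 10⁻⁶ mmol·gDW⁻¹·h⁻¹ count as zero.

A growth `Condition` names the substrate and acceptor exchanges with their
uptake maxima, closes the rival acceptor, and fixes the non-growth
maintenance reaction at NGAM. Defaults NGAM = 8.39 mmol ATP·gDW⁻¹·h⁻¹ and
GAM = 59.81 mmol ATP·gDW⁻¹ are the conventional E. coli K-12 values, shipped
as explicit configuration and surfaced in every report rather than being
baked into logic.

**Verification oracle.** `aromflux.vertices` enumerates every basic feasible
solution of the flux polytope {S·v = 0, lb ≤ v ≤ ub} (finite bounds): choose
n − rank(S) variables, pin each to a bound, solve for the rest. The LP
optimum is the best vertex and the FVA ranges are coordinate extrema over
the optimal face's vertices. Cost is exponential, so the oracle runs on
networks of ~10–20 reactions; it shares no code with the engine.

## Post-FBA analytics

*Split ratios.* At a metabolite node, reaction r produces
max(coeff·v_r, 0) and consumes max(−coeff·v_r, 0); reversible reactions are
classified by flux sign, not declared direction. Fractions are percentages
of the node turnover; zero turnover yields an empty table. Steady state
guarantees production = consumption at every internal node of an optimal
solution, which the tests assert to 10⁻⁶.

*Activity.* A reaction is active under a condition when its FVA range is not
identically zero beyond the 10⁻⁶ threshold; "always active" means active in
every condition considered.

*Variation shares.* A reaction's variation is its max-minus-min flux across
conditions; a group's share is its summed variation over the total. Groups
must be disjoint; an all-constant matrix is flagged (NaN shares, zero total).

*Clustering.* Conditions are clustered on their flux vectors with Euclidean
distance and Ward linkage (both overridable). Fluxes are first divided by
the condition's substrate **carbon** uptake (`carbon_uptake_scale`), not by
substrate molecules — a C7 substrate at a third of the molar uptake carries
the same carbon, and without carbon normalization uptake magnitude rather
than network state dominates the distances. The two-group cut of the toy
network separates oxic from anoxic conditions, which is a planted truth of
the generator.

## Biomass assembly

DNA monomer fractions follow the double-stranded convention
f(dAMP)=f(dTMP)=(1−GC)/2, f(dGMP)=f(dCMP)=GC/2 with GC computed from one
strand ignoring N (error above 5% N); this makes the estimate
strand-symmetric. RNA composition is estimated from predicted gene
(transcribed-strand) sequences rather than the whole genome — transcript
base usage, not chromosomal, is what RNA is polymerized from; the choice is
a documented function (`rna_composition`), not a hidden default. Protein
composition pools length-weighted residue frequencies over all predicted
proteins (X skipped with a warning).

The biomass reaction charges, for each macromolecule class (g/gDW), monomer
m at class·fraction_m/M_m mmol/gDW, using polymerized (water-free) residue
masses so the assembled precursor mass closes to 1 g per unit biomass flux;
closure is enforced to ±1% and class masses are normalized to 1 g/gDW
(guarded at ±2% before normalization). GAM adds an ATP→ADP+Pi term. The
macromolecular fractions ship as a configuration table (`ECOLI_MACRO_DEFAULT`,
the textbook E. coli composition); lipid/LPS/murein structural detail is out
of scope and enters as configured pool species.

## Growth stoichiometry

μ is the least-squares slope of ln(OD) vs. time, either over a user window
or over the longest stretch (≥3 points) with R² ≥ 0.98 *and* positive slope
— without the positivity requirement a stationary plateau fits a flat line
"perfectly" and would win on length. t_D = ln2/μ, undefined (NaN) when
μ ≤ 10⁻¹².

Oxygen by difference: O = 100 − C − H − N − 12.03 (wt%), the ash constant
including S. Degrees of reduction use the CO₂/H₂O/NH₃ reference
(C=4, H=1, O=−2, N=−3, S=6, minus charge): acetate 8, benzoate 30, nitrate
−8. Acceptor demand closes the electron ledger — dissimilated electrons =
substrate electrons − electrons retained in biomass carbon — at 5 e⁻ per
NO₃⁻ (full denitrification to N₂, matching a NarGHI→NirS→NorBC→NosZ chain),
4 per O₂, with a 3 e⁻ nitrite option for transient NO₂⁻ accounting.

C/C yield from endpoint deltas is
(ΔCDW·C%/12.011)/(ΔS·n_C)·100. The curve-level estimator
(`yield_from_curve`) instead regresses remaining substrate carbon on biomass
carbon across all sampling points and returns −100/slope: the intercept
absorbs the noisy initial readings, so no single measurement anchors the
estimate. On 2%-noise simulations this keeps every recovered yield within
2 points of truth where endpoint deltas scatter by ±5.

## Metagene expression types

Normalization follows the order log-transform first, column-normalize
second: T_ij = log(1+c_ij), then each condition column scaled to sum 1 —
the only order under which both the log definition and the unit column sums
hold simultaneously. Linear mode skips the log. A raw-count floor (e.g. 50
for RNA-seq pipelines that cut low counts upstream) is exposed but off by
default.

The factorization minimizes ‖T − WS‖²_F by Lee–Seung multiplicative updates:
deterministic per (seed, restarts), best of 10 restarts by default,
max_iter 2000, relative-loss tolerance 10⁻⁶, non-convergence flagged. The
loss trace is non-increasing by construction and asserted in tests.

Explained variance is **uncentered** (EV_j = 1 − ‖T_·j − (WS)_·j‖²/‖T_·j‖²):
an NMF has no intercept, so centered variance would credit/blame the fit
for the column mean it cannot represent. Values are clipped at 0 and
flagged if clipping occurred. Cumulative EV by rank comes from nested
refits at ranks 1..m with the same seed. `select_components` returns the
smallest m whose fit reaches the threshold (default 0.90) in *every*
condition.

Component recovery in tests matches fitted to planted components by the
Hungarian assignment on gene-side cosine similarity.

## Synthetic generators

All generators are bit-reproducible per seed (numpy `default_rng`).

*Toy network* (~25–31 reactions): substrate uptake and activation shared
between respiratory modes; an O₂-independent branch (ATP-consuming
activation + NADH-consuming ring reduction + β-oxidation) and an
O₂-dependent branch (oxygenase) for the C7 substrate; a TCA-like lumped
oxidation of acetyl units; NADH dehydrogenase feeding a quinone pool; a
lumped denitrification chain (QH₂ + 0.4 NO₃⁻ → 0.2 N₂, i.e. 5 e⁻ per N) and
an O₂ reductase (4 e⁻ per O₂); proton-translocating ATP synthase (3 H⁺ per
ATP); optional glyoxylate-shunt and PHB modules. Carbon and
degree-of-reduction electrons are conserved by construction in every
non-exempt reaction — reduced carriers carry formula H₂ so γ = 2 per pair —
and the generic balance checker verifies this independently. The
`p_to_o_ratio` (ATP per electron pair; defaults 2.0 for O₂, 5/3 for nitrate)
sets the proton yield of the terminal reductases, planting the aerobic
growth advantage as a testable truth. The biomass drain consumes 20 mmol
acetyl units (40 mmol C ≈ 1 g at ~48 wt% C), 80 mmol ATP and 2 mmol NADH
per gDW, which puts the preset C/C yields in the 45–59% range expected of a
heterotroph. Uptake presets: acetate 10, aromatic 3 mmol·gDW⁻¹·h⁻¹ (nearly
carbon-equivalent), O₂ 25, NO₃⁻ 30.

*Transcript matrices*: counts_ij = baseline_i · w_i · S_{k(i),j} (+
truncated multiplicative Gaussian noise, clipped at 0), with genes
partitioned into m disjoint modules, per-gene weights lognormal(0, 0.3),
baseline lognormal(meanlog 5, sdlog 1.5), and conditions assigned
round-robin to modules. Off-condition scores default to **zero** — strict
substrate-specific regulation in which a module's transcripts are simply
not detected off-condition. This choice is what makes the planted
factorization unique: with strictly positive off-scores the on/off score
matrix is itself a positive combination of sharper indicator scores, so
alternative mixed factorizations fit as well or better and component
recovery is impossible in principle. Per condition, the log of detected
(positive) counts is a sum of two normals and passes a KS normality test;
zero counts correspond to transcripts below the detection cutoff, which
real RNA-seq pipelines also exclude before distributional statements. At
zero noise the prepared matrix has exact rank m. What these tests show:
the selection rule and factorization recover clean planted structure. What
they do not show: behaviour under relaxed regulation (constitutive
expression, overlapping modules), library-size artefacts, or count
overdispersion.

*Growth curves*: OD = od0·e^{μt} with multiplicative noise on every measured
series; substrate draw-down follows the carbon balance at the true C/C
yield and acceptor draw-down follows the same electron ledger the analysis
closes, so noiseless recovery is exact by construction. Defaults emulate an
acetate/nitrate batch (8 mM acetate, 7 mM nitrate, μ = 0.25 h⁻¹, OD→CDW
0.45 g/L per OD, biomass 48 wt% C with γ = 4.2 per C, 21 samples over 10 h);
sampling truncates (flagged) at substrate or acceptor exhaustion.

*Random LP networks* (for the oracle comparisons): a linear uptake→chain→
biomass backbone guaranteeing a non-trivial optimum, plus random reversible
side reactions for degeneracy; all bounds finite so the polytope is bounded.
Networks are kept at ~9 reactions because the oracle's basis enumeration is
exponential; the LP structure exercised (equalities + box bounds + optimal
face) is the same at any size.

## Numerical conventions

LP feasibility 10⁻⁹; flux-activity threshold 10⁻⁶ mmol·gDW⁻¹·h⁻¹; FVA
optimum slack 10⁻⁹; vertex-oracle feasibility 10⁻⁸ and optimal-face
membership 10⁻⁷; NMF update guard ε = 10⁻¹²; composition sums enforced to
10⁻⁹ (monomer fractions) and 2% (macro masses before normalization);
biomass mass closure ±1%. Clustering ties are broken by input column order
(scipy linkage is deterministic given the distance matrix).

## Known limitations

- The FBA objective is biomass only; ATP/redox parsimony or regulatory
  constraints from omics data are out of scope.
- The vertex oracle cannot certify genome-scale models; at that scale the
  engine is cross-checked against cobrapy instead (test suite).
- Electron bookkeeping via metabolite formulas requires the γ-convention
  encoding used by the generators; arbitrary imported models need formulas
  before the ledger applies.
- The NMF is the plain Frobenius multiplicative-update variant; sparse or
  regularized factorizations are not implemented.
- Table-driven biomass assembly treats lipids, murein and the soluble pool
  as configured lump species; no structural lipid chemistry.
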