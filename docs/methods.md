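# Methods

Models, assumptions, parameter defaults, generator scope and numerical
choices for `aaflux`.  Notation: S is the m×n stoichiometric matrix, v the
flux vector, lb/ub flux bounds, μ the growth rate.

## 1. Metabolic model and linear programming

A model is a list of metabolites, a list of reactions (sparse stoichiometry,
bounds), and a designated biomass reaction.  Flux states satisfy steady-state
mass balance S·v = 0 with lb ≤ v ≤ ub.  `solve_lp` maximizes a single
reaction's flux with `scipy.optimize.linprog` (HiGHS); statuses map to
`optimal` / `infeasible` / `unbounded`.  Solutions are verified post hoc
(`check_solution`): |S·v| ≤ 1e-6 per metabolite, bounds respected within
1e-9.  The LP contract is the *optimum*, not the algorithm; tests cross-check
it against a brute-force vertex-enumeration oracle and against cobrapy+GLPK.

Model I/O: COBRA-style JSON (read and write, stdlib `json`) and SBML L3 with
the FBC extension (read, via `python-libsbml`).  SBML `R_`/`M_` identifier
prefixes are stripped so that JSON and SBML renderings of the same model load
identically.  The biomass reaction is taken from the FBC objective (or the
JSON `objective_coefficient`), with an explicit `biomass_id` override.

## 2. Two-step amino-acid supply

**Step 1 (growth).**  Maximize biomass flux with the substrate exchange lower
bound set to −uptake (default uptake 10 mmol·gDW⁻¹·h⁻¹, the conventional
glucose cap).  The optimum is μ.

**Step 2 (supply).**  Three modifications, applied to a copy of the model:

1. *Partial biomass*: every coefficient of a mapped amino-acid metabolite in
   the biomass reaction is multiplied by the basal level β ∈ (0, 1]
   (default 0.3); all other coefficients are untouched.  Mapped amino acids
   absent from the biomass raise a warning, not an error.
2. The partial-biomass flux is fixed (lb = ub = μ).  If fixing at exactly μ
   is numerically infeasible, the solve is retried once at μ·(1 − 1e-6).
3. A *protein sink* reaction is added consuming amino acid a at its residue
   frequency f_a (frequencies must sum to 1 within 1e-9; bounds [0, ∞)).
   The sink carries no ATP or water terms — the score isolates amino-acid
   availability, not polymerization energetics.

The protein's **supply** is the maximal sink flux.  Since the polytope is
linear in β (releasing amino-acid demand frees substrate proportionally),
changing β rescales supplies without reordering them; the package therefore
only ever interprets supply *ranks*, and the rank invariance is asserted in
tests over β ∈ {0.1, 0.3, 0.5, 0.7}.

Sink coefficients are *frequencies*, not residue counts: supply is a
per-residue rate, comparable across proteins of different lengths.  (Counts
would simply divide each supply by protein length, confounding composition
with length.)

`supply_table` computes μ once, builds the fixed partial-biomass model once,
and solves one LP per protein; per-protein failures (e.g. a residue missing
from the amino-acid map) yield `supply = None` rather than aborting the
batch.

**Amino-acid maps.**  An `AminoAcidMap` sends one-letter residue codes to
metabolite ids.  Shipped defaults: iJO1366 cytosolic BiGG ids
(e.g. `ala__L_c`, glycine `gly_c`); for models with opaque ids (Yeast-6
style) the map is inferred by chemical-name matching.  Toy models use the
`aa_<code>` convention.  Full 20-code coverage is enforced only for the
genome-scale defaults — toy alphabets are smaller by design.

## 3. Sequence features

* **Residue frequencies**: counts over the sequence, trailing stop `*`
  stripped; `strict` mode rejects unknown letters, lenient mode drops and
  renormalizes.
* **CAI**: relative adaptiveness w = (codon count)/(max synonymous count)
  from a highly-expressed reference set; unseen codons in a seen family get
  w = 0.01, wholly unseen families w = 1.0.  CAI is the geometric mean of w
  over the CDS.  Default dialect `sharp-li` excludes Met, Trp and stops
  (the original definition); `emboss` keeps Met/Trp.  The standard genetic
  code comes from `Bio.Data.CodonTable`.
* **Gene-start window**: nucleotides −4..+38 relative to the start codon
  (42 nt, no position 0), requiring ≥ 4 nt of upstream context and ≥ 38 nt of
  CDS; otherwise the window — and its folding energy — is missing (`None`),
  never padded.  Folding energy is the minimum free energy of the window,
  via a precomputed table or a pluggable engine (`vienna_mfe` wraps the
  ViennaRNA `RNA.fold` bindings when installed).

## 4. Expression metrics and filters

TE = protein abundance / mRNA level (molecules per cell); RD =
mean footprint RPKM / mean mRNA-fragment RPKM (replicates averaged before the
ratio).  Zero or missing denominators give missing metrics.

Reliability filters, all *strict* inequalities:

* mRNA level > 0.5 molecules/cell (TE analyses);
* each replicate RPKM series needs mean > 1 **and** max/min < 1.5, applied to
  **both** the footprint and mRNA-fragment series (RD analyses).  A
  single-replicate series passes the fold criterion vacuously; a zero in a
  multi-replicate series fails it.

The per-series rule (rather than a pooled one) is chosen because replicate
disagreement in either assay invalidates the RD ratio.  Gene tables join
supply and metrics on gene id (inner join; duplicate or disjoint id sets are
errors naming the offender), with optional protein→gene id mapping.

## 5. Robust statistics

* **Spearman correlation** delegates to `scipy.stats.spearmanr`
  (average ranks for ties, t-approximation p-value); NaN pairs are dropped,
  constant inputs are flagged rather than returning NaN silently.
* **Wilcoxon rank-sum (one-sided)**: for pooled n ≤ 12 the p-value is exact —
  full enumeration of rank assignments, correct under ties; above that, the
  normal approximation with tie and continuity corrections.
  `scipy.stats.mannwhitneyu` appears only as an independent oracle in tests.
* **Rank-based regression** (Jaeckel dispersion, Wilcoxon scores
  a(i) = √12(i/(n+1) − ½)).  The dispersion of residuals e equals
  √12/(2(n+1)) Σ_{i<j} |e_i − e_j|, a convex piecewise-linear function of the
  coefficients.  For one covariate the exact minimizer is the weighted median
  of pairwise slopes; for several, coordinate-wise weighted-median descent
  from the least-squares start, polished by Nelder-Mead.  (An exact linear
  programming formulation of the same L1 problem was implemented first and
  gives identical answers, but is orders of magnitude slower at n ≥ 500; the
  weighted-median route minimizes the same convex objective and is used
  instead.  Local optimality of fits is asserted against grid perturbations
  in tests.)  The intercept is the median residual.
  The scale parameter τ uses a Koul–Sievers–McKean-style window estimator
  (pairwise-difference density at zero, Silverman bandwidth,
  √(n/(n−p−1)) degrees-of-freedom correction); coefficient p-values come from
  drop-in-dispersion F-tests, F = (D_reduced − D_full)/(τ/2) ~ F(1, n−p−1).
  The reported `total_r = √(1 − D_full/D_null)` is a *dispersion-based*
  robust analogue of multiple R — explicitly labelled as such in the output
  (`total_r_definition`) because it is not an R² and not comparable across
  definitions.

## 6. Starvation analysis

Fold change = RD(starved)/RD(normal); genes are sorted by supply
(descending, stable) and split at the median into WAAS (well-supplied) and
PAAS (poorly supplied); with an odd count WAAS is the larger half, and tied
supplies go to WAAS — a deterministic convention asserted in tests
(2801 genes → 1401/1400).  The buffering hypothesis is one-sided:
WAAS fold change < PAAS fold change, tested by the rank-sum test above.  A
second comparison tests whether genes whose RD more than doubles under
starvation (fold change > 2, strict) have lower *normal-condition* mRNA
levels than the rest — normal-condition, because the hypothesis concerns
which genes were lowly expressed to begin with.  Empty groups yield a
flagged NaN p-value rather than an exception.

## 7. Synthetic data: what the generators emulate, and what they don't

Generator defaults are the study conditions; they were fixed before the
analyses were run and are not tuned to outcomes.

* **Toy metabolic models** (`ToyModelSpec`): substrate → amino acids →
  biomass, 2–6 amino acids, optional non-amino-acid biomass precursor.
  Supply optima are hand-computable; random specs draw yields U(0.5, 3),
  biomass coefficients U(0.2, 2), uptake U(5, 20).  These probe the LP
  machinery, not realistic network topology (no cofactors, no alternate
  routes, no reversibility).
* **Proteomes**: fixed length 300, per-protein Dirichlet(1) compositions
  interpolated toward the cheapest (highest-yield) residue by a bias knob
  (default 0.2) — emulating the enrichment of highly expressed proteins in
  cheap residues; no real sequence structure.
* **Expression tables** (`gen_expression`): a Gaussian copula couples the
  normal scores of the supply ranks to TE (target Spearman 0.30), RD (0.3)
  and mRNA level (0.2); the Pearson parameter is 2·sin(πρ_s/6), so the
  *population* Spearman equals the target exactly.  Marginals are lognormal
  (TE = 25·e^{0.8z}, mRNA = 10·e^{0.7z}, RD = 1.1·e^{0.35z}); protein
  abundance = TE·mRNA, mRNA RPKM = 8·mRNA, footprint RPKM = RD·mRNA RPKM —
  so the computed metrics reproduce the planted values exactly at zero noise.
  Replicates get unit-mean lognormal noise with coefficient of variation
  `replicate_cv` (default 0.1, two replicates).  The supply–RD and
  supply–mRNA targets are generator defaults beyond the single named TE
  target: the downstream RD and RD-increased analyses need planted structure
  to have power against.  Not emulated: count noise, mappability, batch
  effects, length-dependent RPKM artifacts.
* **Starvation tables** (`gen_starvation`): fold change
  (1 + δ(1 − pct))·e^{0.25ε} with pct the supply percentile and δ the planted
  buffering effect (default 0.2); δ = 0 makes fold change independent of
  supply, which is what calibrates the null rejection rate.  Seeded at
  `params.seed + 1` so expression and starvation noise are independent.

## 8. Pipeline

`run_all` executes load → supply → metrics → gene table → correlations →
regressions → starvation, writing one TSV per stage and a versioned
`summary.json` (schema_version 1) that echoes the governing parameters
(β, uptake, filter definitions, split convention, CAI dialect).  Failures
raise with the stage name; earlier outputs are kept for inspection.  Outputs
are byte-identical across runs for a fixed config (asserted in tests).
Configs are TOML with unknown-key rejection; missing input files fail
validation before any computation.

## 9. Numerical choices and limitations

* Steady-state tolerance 1e-6, bound tolerance 1e-9, default reaction upper
  bound 1000 (keeps toy polytopes bounded, enabling the vertex oracle).
* Fixing the step-2 biomass at exactly μ sits on the LP's feasibility
  boundary; a single retry at μ(1 − 1e-6) absorbs solver round-off.
* Exact rank-sum enumeration is limited to pooled n ≤ 12
  (C(12,6) = 924 assignments); beyond that the corrected normal
  approximation is used (agrees with enumeration within 0.01 at 6 vs 6).
* τ's bandwidth constant follows Silverman; published implementations differ
  slightly here, so regression p-values are approximation-level reproducible,
  not bit-identical across packages.
* The package does not model isoenzymes/GPR rules, flux variability, or
  alternate optima in step 1 (μ is unique but the flux distribution need not
  be; only μ is used, so this does not affect supplies).
* Headline numbers of the motivating analysis depend on external resources
  (genome-scale models, proteomics/profiling datasets) that are not bundled;
  all shipped validation is property-based on synthetic data.
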