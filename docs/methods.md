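# Methods

## Scope and data model

`spatialgem` couples two data kinds: a spot-level spatial expression matrix
(genes × spots, non-negative counts, with spot coordinates in μm and
per-spot region labels among tumor / PIN / normal / stroma) and a
constraint-based metabolic network (stoichiometric matrix `S`, flux bounds
in mmol·gDW⁻¹·h⁻¹, boolean gene–protein–reaction rules, subsystem
annotations, biomass objective). Models round-trip through a JSON dialect
(the canonical format, chosen so tests can assert field-for-field identity)
and import from SBML Level 3 + fbc, mapping `fbc` gene-product associations
to GPR trees and cobra-style `M_`/`R_`/`G_` id prefixes back to bare ids.
Region outlines are taken as *inputs*: inferring them from histology or
factor analysis is out of scope.

## Spatially variable gene detection

Counts are normalized per spot to total read counts and log-transformed:
`value[g,s] = log2(1 + counts[g,s]/total_s · median(total))`. The scale
factor is the median spot total (any constant works; the median keeps
values in a familiar count-like range). Genes detected in fewer than
`min_expressed_spots` (default 10) spots are dropped. When the counts
matrix covers only a subset of the transcriptome (e.g. metabolic genes),
totals should be whole-transcriptome totals — normalizing to the subset's
own totals would leak the spatially variable genes' structure into every
other gene.

Per gene, two Gaussian models are compared. The alternative places a
squared-exponential Gaussian-process prior on expression,
`y ~ MVN(μ1, σ²(K_ℓ + δI))` with `K_ℓ[i,j] = exp(−‖xᵢ−xⱼ‖²/2ℓ²)`; the null
is `y ~ MVN(μ1, σ²I)`. For each lengthscale ℓ on the grid
{0.5, 1, 2, 4, 8} × pitch (the pitch is the median nearest-neighbor
distance), `K_ℓ` is eigendecomposed once and shared across all genes; μ and
σ² are then profiled in closed form and the noise-to-signal ratio δ is
optimized by bounded scalar search on log δ ∈ [−10, 10]. Because the null
is the δ → ∞ boundary of the alternative, the maximized alternative
likelihood is floored at the null likelihood analytically rather than
relying on the finite search bound. The statistic `2(ll_alt − ll_null)`,
clipped at 0, is referred to χ²(1). This reference is conservative at the
boundary (roughly half the null mass sits at LR = 0); empirically the null
rejection rate at α = 0.05 is ~0.03 on a 200-spot grid, which the
lengthscale-grid maximization does not overcome. Benjamini–Hochberg
q-values are computed over all tested genes and `is_sv ⇔ q ≤ α`
(default α = 0.05).

The Welch t-test screen (tumor vs all non-tumor spots, BH-adjusted) is the
deliberately naive baseline: it needs the region dichotomy a priori and
ignores spatial continuity. Degenerate genes (zero variance in both groups,
equal means) report t = 0, p = 1.

## Pathway enrichment

Pathways are the model's reaction subsystems mapped to their GPR genes. The
universe is the set of model genes that survived the low-expression filter,
so the background matches the tested set. Enrichment of the SV set is the
one-sided hypergeometric upper tail `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`;
raw p (and its −log10) is the primary output, BH-adjusted p is also
emitted since reasonable workflows differ on adjusting here.

## Region-specific extraction (modified mCADRE)

Gene-level evidence is the **mean** normalized expression of the gene
across the region's spots — not the fraction of spots expressing it.
Reaction evidence follows the GPR with **AND → mean** of the children and
**OR → sum**. The mean (rather than the conventional min) for complexes is
deliberate: with ~3000 detected genes per spot, dropout would drive min
scores of most complexes to zero. Genes missing from the expression data
score 0 (the conservative reading of sparse data). Reactions with no GPR —
exchanges, spontaneous reactions, biomass — carry a +∞ sentinel score:
they are never evidence-pruned, which matches extraction practice (an
exchange should disappear only when its metabolite's consumers do, via the
cascade).

A reaction is **core** when its score is strictly above 0.2 (on the
normalized log2 expression scale; configurable). Non-core reactions are
ranked worst-supported first: ascending expression score, then ascending
connectivity evidence, then reaction id. Connectivity evidence is the mean
expression score of the reactions sharing at least one non-currency
metabolite; the currency list (ATP, ADP, H₂O, Pi, NAD(H), NADP(H), CoA,
H⁺, CO₂ by convention) lives on the model and is configurable per model.
Neighbors carrying the +∞ sentinel are skipped in the mean — a sentinel is
not expression evidence.

Pruning iterates that order. A tentative removal is accepted iff (a) every
core reaction still attains |flux| ≥ ε_flux (1e-6) in FVA and (b) biomass
flux stays ≥ ε_growth (1e-6). Accepted removals also sweep away any
reactions they newly blocked (cascade); condition (a) already forbids
cascading a core reaction. The final submodel is re-verified by an
independent FVA pass. The original mCADRE's expression-frequency ubiquity
score and salvage checks are superseded by these modifications; no
metabolic-task list is enforced beyond core consistency plus growth. The
pseudo-bulk model uses the identical procedure with "region = all spots",
which is exactly how section-averaging hides regional gene loss: a gene at
0.6 in half the section and 0 in the tumor averages to 0.3 and stays core.

## Flux balance analysis

FBA maximizes the objective flux over `{v : S·v = 0, lb ≤ v ≤ ub}` via
HiGHS (`scipy.optimize.linprog`); FVA solves the per-reaction min/max pair.
Only objective values are contracts — flux vectors at degenerate optima are
not unique, and no test asserts individual fluxes unless the LP solution is
unique by construction. COBRApy/GLPK serves as an independent oracle in the
test suite only, never at runtime. Gene knockouts disable every reaction
whose GPR evaluates false without the gene (AND = complex broken by any
member, OR = any isozyme suffices), set those bounds to [0, 0] and
re-solve; a knockout is lethal when growth falls below 1% of wild type
(configurable — no principled universal cutoff exists, and all fixture
knockouts are far from the boundary).

## Differential lethality and rescue genes

Hits are genes lethal in screen A but not B (genes absent from B's model
are viable there by the knockout contract). Rescue candidates are genes of
reactions present in the viable model but pruned from the lethal one; a
candidate is a rescue gene iff re-adding its reactions with the viable
model's bounds makes the hit's knockout non-lethal, decided by direct LP.
Only single-gene rescues are searched — multi-gene combinations are out of
scope — and an empty rescue set is a reported result, not an error.

## Flux dependency, robustness, compensation

`dependency_scan` re-targets the LP objective to a chosen reaction and
classifies a gene as essential for it when the knockout drops the
attainable maximum below ε_flux. `robustness_curve` forces the reaction's
flux upward by setting its **lower** bound to f·v_max for f on a [0, 1]
grid; the lower-bound formulation makes feasible sets nested, hence the
curve provably non-increasing (an equality-constraint mode exists behind a
flag for sensitivity checks). Infeasible grid points record 0% growth.
`compensation_scan` pins the forced reaction at its maximum, scales a
supply reaction's uptake bound by each multiplier in
{1, 2, 3, 4, 5, 6, 8, 10} (configurable) and reports growth as % of the
unconstrained optimum plus the smallest multiplier reaching 99% of it
("restored"; the 99% criterion is a pragmatic reading of full restoration).

## Synthetic data

The simulator emulates an array-based section: a square spot grid at
200 μm pitch (default 15 × 15 = 225 spots), a central circular tumor of
radius 800 μm with an annular normal rim (outer radius 1.5×) inside
stroma. Per gene, log-intensity is (i) a zero-mean GP draw (squared-
exponential, lengthscale 400 μm = 2 × pitch, variance 1) plus iid Gaussian
noise (variance 0.2, i.e. signal-to-noise 5) for `sv_spatial` genes,
(ii) iid noise with intensity *exactly zero inside the tumor* for
`sv_regional` genes (the CBS/FH/ACAT2 absence pattern), or (iii) iid noise
alone for flat genes. 20% of genes are SV, a quarter of those regional.
GP draws use a jittered Cholesky (jitter 1e-8·trace/n). Counts are Poisson
with per-spot library sizes lognormal around 5000 reads (σ = 0.3, mean
preserved); the simulated genes carry 20% of each spot's reads and the
dataset also reports whole-transcriptome spot totals (simulated genes plus
a flat Poisson background), which is what normalization divides by.
Poisson (rather than negative-binomial) counts are intentional: the GP
test operates on log-normalized values where Poisson noise already yields
realistic heteroscedasticity, and overdispersion would add a parameter the
tested methods never estimate. The simulator does not attempt histology,
factor-analysis region inference, hexagonal geometry, or cell-type
deconvolution — so passing tests certify statistical calibration and
mechanism recovery under the stated generative model, not performance on
real tissue artifacts (segmentation errors, spatial library-size gradients,
overdispersion).

Fixture networks are ≤ 10-reaction hand-built models, each with tumor and
non-tumor expression vectors: `cysteine` (transporter complex vs CBS
synthesis), `succinate` (heme-path analog vs FH), `acetoacetate`
(ATP-dependent AACS vs ACAT2 condensation, with an ATP/ADP currency pair),
`urea` (arginine uptake ub 0.4, de novo arginine synthesis ub 1.0,
arginase → ornithine + urea, urea export, ornithine from OAT, biomass
consuming 1 arg + 0.5 orn), and `linear_chain` (every gene essential). The
urea stoichiometry fixes the compensation arithmetic exactly: maximal urea
export flux 1.4 consumes all arginine, and restoring growth v = 1.4
requires uptake 0.4·m ≥ 0.4 + 1.4 − 1.0, i.e. m = 4.5 — verified by LP at
run time, never asserted from external numbers. Region expression vectors
are given per region (extraction consumes region means); a spot-expansion
helper adds iid noise for end-to-end tests.

## Numerical choices and degenerate inputs

* LP tolerances: solver defaults (HiGHS, ~1e-9); ε_flux = ε_growth = 1e-6
  in model flux units for consistency/lethality decisions.
* Ties in the pruning order break by reaction id — extraction is fully
  deterministic, and reruns of the pipeline with the same config and seed
  are byte-identical (asserted on manifest hashes).
* Zero-variance genes short-circuit the GP test to LR = 0, p = 1; zero
  spot totals are an error naming the spot.
* The GPR grammar is case-insensitive `and`/`or` with parentheses, `and`
  binding tighter; gene ids match `[A-Za-z0-9_.-]+`.

## Problem sizes

Validation workloads were sized to make their statistical claims testable
at interactive speed: 500 null genes and 100 alternative genes on a
200-spot grid for calibration/power, 20 replicates of the 225-spot default
section for screen-level FDR, 50 random network/reaction pairs for
robustness monotonicity. All fixture-network computations are exact LPs
and run in seconds.

## Known limitations

* χ²(1) reference is conservative under the boundary null; no permutation
  or mixture-χ² option is provided.
* Extraction enforces core consistency + growth only — no metabolic-task
  lists, no alternative extractors (iMAT, INIT, FASTCORE).
* Rescue search is single-gene; synthetic-lethal pair discovery is out of
  scope, as are double knockouts, MOMA/ROOM and parsimonious FBA.
* The connectivity graph is binary (shared non-currency metabolite), not
  stoichiometry-weighted.
* SBML import covers Level 3 + fbc as written by standard tools; exotic
  `notes`-only encodings beyond a `SUBSYSTEM:` tag are not parsed.
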