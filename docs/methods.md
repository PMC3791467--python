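# Methods

This note records the statistical models, the generator's assumptions,
the numerical choices, and the limits of what the synthetic tests can
show about real data.

## Synthetic reciprocal RIL populations

**Genotypes.** Each chromosome of each line is a Markov chain over the
ordered markers: a fair allele draw at the first marker, then a switch
between parental alleles with probability `R = 2r/(1+2r)`, where
`r = ½(1 − e^(−2d))` is the Haldane recombination fraction for the
inter-marker distance `d` (Morgans). The `2r/(1+2r)` adjustment is the
standard expansion of the recombinant fraction between fully inbred
selfed lines. No interference beyond Haldane, no segregation distortion,
no residual heterozygosity and no missing genotypes are simulated (a
real RIL panel has small amounts of all four). The cytoplasm is assigned
deterministically: the first `cyto_counts[0]` lines carry the Kas
cytoplasm (+1), the remainder Tsu (−1); the default desk-scale split is
100/140 over 240 lines, and the full-size 136/180 over 316 lines is one
configuration away (`paper_scale_config`).

**Phenotypes.** Metabolite abundances are generated multiplicatively:
on the log scale

```
y = μ + Σ aₗ·gₗ + Σ e_{ab}·g_a·g_b + Σ t_{ab}·g_a·g_b·c + E_e + B_b(E_e) + (C×E)_e·c + ε
```

with `gₗ, c ∈ {+1, −1}`, `ε ~ N(0, σ)`, then exponentiated. This keeps
values strictly positive (ion-count-like), makes per-sample median
normalization meaningful, and gives the replicated structure of a
2-experiment × 2-block randomized complete block design. Defaults:
`μ = 5`, `σ = 0.3` (≈ 30% CV, typical of GC-TOF ion counts), additive
hotspot effects 0.25, cytoplasm main effects 0.15, interaction effects
0.15 — moderate effects giving per-term variance shares in the 2–20%
range a metabolomics QTL study reports.

The default scenario is desk-scale — 5 chromosomes × 100 cM, 200
markers, 240 lines, 100 metabolites, 4 replicates — chosen so that every
stage, including permutation nulls, runs in seconds to minutes on one
core.

**Planted interaction loci are spread loci.** `cytonuclear_scenario`
places its nuclear interaction partners at evenly spaced map positions.
They stand in for QTL hotspot markers, which are well-separated loci;
two tightly linked planted loci would make their interaction regressors
collinear and split their Type III sums of squares between them, which
is a property of partial SS, not of the design being emulated.

**What passing tests do not show.** The generator has no peak-calling
noise, no metabolite-metabolite correlation beyond shared loci, no
heavy-tailed or zero-inflated abundances, no batch drift within a block,
and its mapping function matches the analyser's exactly. Results on real
data will be noisier in all of these directions; the tests establish
correctness of the estimators under their stated model, plus calibration
(type-I error, bias) at the stated scale.

## Median normalization and line means

Each sample (one line × experiment × block extraction) is rescaled by a
single factor bringing its within-sample median over metabolites to the
grand median of all sample medians. The reference (grand median of
sample medians) is a documented choice; scaling to 1 instead only
changes the global unit. Normalization is global rather than
per-experiment (the alternative is one groupby away). Zeros are treated
as missing for ion counts. Metabolites detected in ≤ 25% of lines are
dropped. Downstream analysis uses plain per-line arithmetic means over
available replicates; with a complete balanced design these coincide
with least-squares means up to rounding, so LS-means are not
implemented.

## Heritability (variance components)

The per-metabolite model `y = μ + C + G(C) + E + B(E) + C×E + ε` is
solved by equating observed to expected mean squares on the balanced
complete-block layout; analysis is on the log scale (`log_scale=False`
is available). The reciprocal subpopulations have unequal line counts,
so the C stratum uses the effective class size
`n₀ = (L − Σn_c²/L)/(a−1)`; with two classes of effects ±a this makes
the estimated σ²_C equal 2a² in expectation — the ddof = 1 variance of
the two class effects, the standard variance-component convention for a
two-level factor. Negative solutions truncate to zero, `σ²_p` is the
sum of the (truncated) components, and `H = σ²/σ²_p` is reported per
genome. F-tests: G(C) against the residual mean square; C against the
C×E mean square by default (experiment and block are random, so C×E is
the appropriate error stratum; `cyto_denominator="residual"` is
available). With two experiments the C test has 1 numerator and 1
denominator df and is intentionally conservative. Unbalanced tables
fall back to the same moment equations with a logged warning; REML is
out of scope.

## Composite interval mapping

Haley–Knott regression on the expected Kas dosage `2·P(Kas) − 1`.
`P(Kas)` at a pseudomarker conditions on the nearest flanking observed
markers through the same RIL Markov chain the simulator uses (exact for
that chain; at observed markers the probability is 0/1). Cofactors:
greedy forward selection of k = 3 markers by RSS reduction, ties to the
lowest (chromosome, cM). At each grid position (default step 1 cM)
cofactors within 10 cM on the same chromosome are excluded from both
the null and full models. Permutation thresholds shuffle phenotypes
across lines with genotype rows fixed and re-select cofactors per
permutation, recording genome-wide max LOD; the threshold is the
(1 − α) quantile. Both the fixed LOD > 2 rule and the permutation
threshold are computed; LOD > 2 is the pipeline's default filter, and
the two are reported side by side because they answer different
questions (a fixed conventional bar vs a genome-wide error rate). Peak
calling: local maxima above threshold; the one-LOD interval is the
contiguous run with LOD ≥ peak − 1; lower peaks whose intervals overlap
an accepted peak merge into it. Effects are estimated at the nearest
observed marker; the percent effect `(x̄_Tsu − x̄_Kas)/x̄_RIL` is positive
when the Tsu allele raises the metabolite.

## Hotspots

Each metabolite contributes a 1 at each QTL peak; a centered closed
window (5 cM, i.e. ±2.5 cM) counts distinct metabolites per grid
position. The permutation null redraws every peak uniformly on the cM
map (chromosome proportional to length), preserving per-metabolite QTL
counts — a positional null chosen because the phenotype-level null is
already handled by the scan permutations. Thresholds use the `higher`
quantile so they are attained counts. Contiguous above-threshold runs
collapse to their maximum-count position (plateaus resolve to their
middle), named `M.<roman>.<rounded cM>` with the nearest observed
marker as representative.

## ANOVA model families, Type III SS and FDR

All models regress line means on ±1-coded loci (cytoplasm included as
one more biallelic locus) and products of those codes; every term is a
single df, so the Type III SS of term j is `β̂ⱼ²/[(XᵀX)⁻¹]ⱼⱼ`, exactly
the full-vs-reduced RSS difference (verified against refits to 1e-8).
Variance fractions divide by the total SS (model + residual); the
fractions-plus-residual-sum-to-one identity holds exactly only in
orthogonal designs, since partial SS of correlated terms need not sum
to the model SS. Aliased terms are flagged with SS = 0. Allele
substitution effects are 2× the coefficient. FDR is Benjamini–Hochberg
pooled over all terms × metabolites of one model family (pooling keeps
q-values stable across thousands of metabolites; a per-metabolite
family is one groupby away). Model df accounting: each term costs 1 df
and the available budget is `n_lines − 2`, reproducing the 314-for-316
convention used when judging over-fitting in RIL panels.

**Partial-SS deflation at aggressive panel sizes.** With p model terms
on n lines, the in-sample collinearity between any true regressor and
the other p − 1 columns removes about `p/(n − 1)` of its partial SS in
expectation. At 240 lines a full 15-locus/105-pair panel (120 df)
deflates each true term's Type III fraction by roughly half, so
significant-terms r² under-states the planted variance share even when
every planted term is detected. The packaged recovery scenario
therefore analyses a df-disciplined panel (11 loci, 66 df ≈ 28% of
lines), the same discipline the 316-line design applies at 120/314 df.
This deflation is a property of partial sums of squares, worth keeping
in mind whenever significant-terms r² from dense marker panels is
interpreted as "variance explained".

With/without-cytoplasm comparisons refit each family after removing
every cytoplasm-containing term. With significance filtering on, r²
sums FDR-significant fractions (the headline comparison); with it off,
r² is the full-model `1 − RSS/TSS`, which is monotone under nesting.

## Epistatic network and three-way terms

Edge weights are interaction prevalences — the fraction of metabolites
with a q < 0.05 interaction — and edges below 10% prevalence are
dropped (a deliberate conservative filter on top of the FDR). Degree
statistics (mean ± SE) are over connected nodes only; isolated loci are
excluded because degree is reported for the displayed network (the
convention is configurable by reading isolates from the graph). Nodes
order cytoplasm-first then map order, so outputs are deterministic.
Cytonuclear triangles — nuclear pairs where (cyto,A), (cyto,B) and
(A,B) all survive — become the three-way model terms.

## Center of phenotype

The four homozygous classes of a locus pair sit at (±1, ±1) with
Kas = +1; class means of raw (un-scaled, positive) line means act as
masses and the center of mass is reported per metabolite. Raw class
means (marginalizing all other loci) are used rather than model-fitted
means, for transparency; positivity guarantees the center lies in
[−1, 1]². A class with no lines is an error at the single-pair level
and a logged skip in batch mode. Hexagonal binning for the summary
plots uses a 30-bin grid over [−1, 1]². For three-way analyses the
pairwise center pools cytoplasm classes, stratified centers are
computed within each class, the three-way center is their midpoint, and
each metabolite's change in distance from the (1, 1) corner between the
pairwise and three-way estimates is classified as increase or decrease.
A pure interaction places all class means symmetrically and therefore
centers at the origin in every stratum; stratified centers separate
only when the strata differ in their marginal (main-effect) structure,
which is exactly the cytonuclear signature the masked-epistasis
demonstration plants.

## Numerical details

- Degenerate regressions: a constant phenotype gives LOD 0; a test
  regressor collinear with the active cofactors gives LOD 0; RSS is
  floored at 1e-12 of its null value before taking logs.
- Noiseless fits: when RSS < 1e-12·TSS, terms with positive SS get
  p = 0 and null terms p = 1 (the F statistic is degenerate).
- Quantiles: LOD thresholds use linear interpolation; count thresholds
  use the `higher` method so they are integers; α = 1 returns the
  minimum of the null maxima in both cases.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  the CLI derives per-stage seeds from the master seed via
  `SeedSequence((seed, stage))`, so runs are byte-reproducible and
  stable under stage re-ordering.

## Problem sizes used by the packaged checks

Calibration and recovery checks run at desk scale, chosen to make the
suite a few minutes on one core: 240-line populations for estimator
calibration and recovery; a 100-line, 2×60 cM map with 200-permutation
thresholds and 200 replicate scans for the genome-wide type-I-error
check; 50 simulations for CIM localization; 50 random 240-line designs
for the Type III oracle; 20 simulations for hotspot recovery. The
full-size population (316 lines, 1069 markers, 1000 permutations) is
reachable through `SimulationConfig`/`PipelineConfig` alone.

## Known limitations

- REML/mixed-model estimation is not provided; unbalanced designs use
  approximate moment equations.
- The scan models a single QTL per position against cofactors;
  multiple-QTL model search (MQM) and dominance are out of scope
  (inbred lines carry none).
- Full-genome pairwise interaction surveys are not implemented; the
  epistasis models operate on hotspot panels.
- Center-of-phenotype coordinates compress a 2×2 table to two numbers;
  different interaction patterns can share a center (the origin in
  particular), so centers complement rather than replace the ANOVA
  terms.
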