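# Methods

`rrgskit` simulates and analyses one cycle of reciprocal recurrent genomic
selection (RRGS) in a two-pool hybrid wheat program, focusing on the female
pool. This note records the models, the generator's assumptions, the
numerical choices, and what the package's tests do and do not establish
about real data.

## Genomes and meiosis

Founders are fully inbred lines carrying biallelic markers on a configurable
genetic map (default 21 chromosomes x 150 cM, uniformly spaced markers —
wheat-like, since map positions are rarely published with trial data).
Per-marker allele frequencies are drawn uniformly inside a minor-allele-
frequency band (default 0.05–0.5) and randomly reflected so reference and
alternative alleles are exchangeable. Founders are in linkage equilibrium;
no population structure or ascertainment bias is simulated.

Simulated plants are carried as phased haplotype pairs, because linkage
disequilibrium created by crossing is what the downstream selfing
generations transmit. Meiosis follows the Haldane model: crossover counts
per chromosome are Poisson with mean equal to the map length in Morgans,
crossover positions uniform, no interference. Single-seed descent (SSD)
draws two independent gametes per generation; expected heterozygosity
halves per selfing generation, and the recombination fraction between two
markers at distance d cM converges to (1 − e^(−2d/100))/2 — both are
verified by Monte-Carlo tests.

## Trait architecture

A trait is an intercept plus per-marker additive effects `a` (coded on
dosage − 1 ∈ {−1, 0, 1}) and dominance effects `d` applied to
heterozygotes. The heterozygote-centered coding makes the dominance column
an orthogonal heterozygosity indicator, the standard parameterization for
ridge-BLUP with two effect classes. The degree of dominance at a locus is
k = d/a. Architectures are sparse (default 300 QTL of 4,031 markers);
additive effects are scaled so their squared sum hits a target genic
variance, dominance effects are centered at zero with spread
`dominance_ratio` times the additive scale. No epistasis.

## Phenotypes and the stress regime

Trial records decompose as genetic value + location-year effect +
block-in-environment effect + a genotype-by-environment deviation shared by
blocks + residual, all independent normals with user-set variances
(defaults: location 4, block 1, G x E 2, residual 5.7 squared dt/ha, in
line with the magnitudes reported for intensive winter-wheat yield trials).
Drought-stressed locations do not merely add noise: the genotype effect
expressed there is an independent draw correlated only `stress_rho`
(default 0.1) with the genotype's value elsewhere, which reproduces the
near-zero and negative cross-location ranking correlations that stressed
trials show. Alpha-lattice incomplete blocking is simplified to
location + block random effects; spatial field trend is not modelled.

Environmental profiles are seasonal EVI curves (baseline 0.2, green-up to
~0.7) plus noise; stressed sites sit on a lowered baseline with reduced
amplitude, so they stay below the other sites throughout the season in
expectation. The vegetation condition index rescales EVI by reference-
period extremes and clamps to [0, 1]. A plant-available-water series with
the same stress structure is attached. Real EVI series have autocorrelated
cloud-gap noise and year-to-year drift that the generator does not emulate;
tests passing on these profiles show the diagnostics recover a planted
stress contrast, not that they would detect every real drought.

## Genomic prediction

Hybrid and line performance is predicted by ridge-regression BLUP with
additive and dominance marker-effect classes. For a cross of a candidate
with an inbred tester the expected-hybrid design rows are
z_A = (x_c + x_t)/2 − 1 and z_D = |x_t − x_c|/2; this reduces to the exact
F1 rows for inbred candidates and gives the gametic expectation (0, 1/2, 1)
for heterozygous F2 candidates, whose contribution to a hybrid is
stochastic. Line records enter as self-crosses (zero dominance row).

Variance components are estimated by EM-REML on the kernel representation
V = σ²_a Z_A Z_A' + σ²_d Z_D Z_D' + σ²_e I with updates
σ² ← σ² + σ⁴ (y'PKPy − tr(PK))/n, which converge monotonically to the REML
optimum; marker effects are recovered as â = σ²_a Z_A' P y. Convergence is
declared at a relative log-likelihood change below 1e−8 (at most 500
iterations; non-convergence raises, never passes silently). Components are
floored at 1e−10 times the phenotypic variance. EM was chosen over
average-information REML for robustness on the small fixtures the test
suite uses; it is slower but cannot step outside the parameter space.

GBLUP with the VanRaden relationship matrix
G = WW'/(2Σp(1−p)) (W frequency-centered dosages, frequencies from the
supplied panel) is the dual formulation; on additive traits with matched
kernels the two give identical predictions to numerical tolerance, which
the suite uses as its cornerstone correctness oracle. A diagonal jitter of
1e−8 is added when G is numerically singular. Missing dosages are
mean-imputed per marker; markers with more than 5% missingness, and
duplicate or monomorphic columns, are removed by the marker filter with a
reasoned log entry. GCA of a candidate is the mean predicted hybrid value
over the tester panel minus the grand mean; both the full male panel and a
reduced production-tester panel are supported, since published programs use
either.

## Phenotypic analysis

BLUEs across environments come from a mixed model with fixed genotype and
random location-year and block effects, solved by dense mixed-model
equations; on balanced data with homogeneous variance they equal raw means.
An environment is a location x year cell throughout. Outlier control
("M4r") standardizes conditional residuals by median and scaled MAD
(x1.4826), computes two-sided normal p-values, and applies the
Bonferroni–Holm step-down at family-wise alpha = 0.05; flagged records are
removed before downstream analysis.

The combining-ability model decomposes the genetic signal into line,
female-GCA, male-GCA and SCA terms plus their environment interactions,
sharing one model across checks, lines and hybrids through role dummies
(fixed) and role-masked random design columns. Checks contribute to the
line variance unless excluded by flag (off by default). SCA x environment
is separable from the residual only when environments contain replicated
blocks. All terms are estimated by the MME-based EM-REML with the classical
updates σ²_i ← (û_i'û_i + σ²_e tr(C^ii))/q_i; EM keeps estimates
nonnegative by construction. Convergence uses the maximum absolute
component change scaled by the phenotypic variance (tolerance 1e−5 for the
full model, 1e−6 for the BLUE model) — a relative criterion never settles
for components near zero. On balanced two-way designs the estimates agree
with the Henderson expected-mean-squares estimator within 1%, the module's
main correctness test.

Entry-mean heritability is h² = σ²_G / (σ²_G + (σ²_GxE + σ²_e)/l) with l
the average number of environments per genotype, exposed explicitly
because published tables are not always reproducible from their printed
components without knowing the effective l. Midparent and better-parent
heterosis are percentages of the midparent and better parent respectively
and are undefined (raise) when those are not positive.

## Cross-validation

Repeated k-fold cross-validation partitions by seeded permutation with fold
sizes differing by at most one; prediction ability is the Pearson
correlation of observed and predicted values per fold, repeatability the
grand mean. Folds with undefined correlations are recorded as missing and
logged; leave-one-out pools held-out predictions per repeat. The chessboard
scheme partitions females and males separately (defaults 5 x 3, echoing
the asymmetric parent panels); for each held-out cell, T2 training drops
only the tested hybrids, T1 additionally drops every hybrid whose female
parent is in the tested female group (test hybrids then share male lines
only — the relevant scenario when testers are fixed across cycles), and T0
drops both parent groups. Abilities order T2 ≥ T1 ≥ T0 on simulated
additive traits.

## Selection theory

The standardized selection differential is computed from the closed-form
truncated-normal mean i(α) = φ(z)/p rather than printed tables; published
table-based values can differ by ~0.01 in the second decimal, so checks
against them use a ±0.01 band. The finite-population intensity is
i(N, G) = i(α) − (G − N)/(2N(G + 1) i(α)), with i(G, G) defined as 0. A
Monte-Carlo order-statistics oracle (mean of the top N of G normal draws)
brackets both quantities in the tests.

The usable GCA standard deviation deflates across generations: selection
within an F2 family exploits half the GCA variance of the random-mating
base population, and SSD to F5 releases 1/2 + 1/4 + 1/8 = 7/8 of the
F2-stage variance among descendant lines. Both factors are verified by
direct simulation. One subtlety the simulation makes explicit: a panel of
fully inbred founders carries (1 + F) = 2 times the additive variance of
the random-mating population with the same allele frequencies, so the
within-family variance is 1/2 of the HWE-base GCA variance but 1/4 of the
GCA variance measured among the inbred lines themselves. The 1/2 factor is
stated, and tested, against the HWE base.

Expected response is R_exp = Σ i·h·σ_A over steps, with h a selection
accuracy (the mean of T1/T2 chessboard abilities in the program's own
calculation); observed response is the realized differential
μ_sel − μ_pop, with the C0-hybrid mean as the default stand-in for the
unobservable candidate-population mean. Under negative overdominance
(k < −1) selection fixes the favourable allele only above the frequency
threshold (k + 1)/(2k), verified by a deterministic single-locus
recurrence.

## G x E diagnostics

Female-GCA-by-environment BLUPs are arranged as a genotypes x environments
matrix; environments are compared by Euclidean distance, clustered by
complete linkage (deterministic scipy implementation; dendrograms exported
as Newick with merge-height branch lengths), and summarized by PCA via SVD
(centered, unscaled for interaction effects, which share units;
centered and scaled for environmental profiles, which do not). The sign
convention makes the largest-magnitude loading of each component positive.
Progenies can be projected onto founder-derived axes using the reference
centering. The Mantel test correlates off-diagonal distances with a
one-sided upper permutation p-value, p = (1 + #{r* ≥ r})/(1 + n_perm),
9,999 permutations by default, exhaustive enumeration available for tiny
matrices; null p-values are uniform by calibration test.

## The end-to-end experiment

`run_rrgs_experiment` chains the stages: founder simulation → training
factorial (default 90% of a 120 x 15 factorial plus the parents) → RRBLUP
fit → select 20 females on predicted GCA → round robin → ~629 F2 plants,
genomic selection of 3 per family (plus a random 3-per-family control
branch) → SSD to F5 → visual preselection, modelled as truncation on an
auxiliary trait correlated 0.2 with yield (an explicit stand-in for
selection on height, flowering and disease, which the package does not
model) → second genomic selection (50, C1S) and a 30-line random control
(C1R) → testcrosses with 3 testers → six-location evaluation with two
stressed sites → BLUEs, bootstrap group contrasts, heterosis, response
accounting, realized prediction ability, and the G x E diagnostics.
Every stage draws from its own generator spawned from one experiment seed;
identical configurations reproduce byte-identical tables. Group-contrast
significance uses a genotype-level bootstrap (percentile intervals,
two-sided p), which is assumption-light where a field study's exact test
machinery is unknown.

Expected response inside the report is computed from realized quantities
the simulation can observe directly: the correlation of predicted and true
GCA at each selection stage, and the realized GCA dispersions (root mean
within-family variance at the F2 step, candidate standard deviation at the
F5 step). Across 50 replicate cycles the mean observed gain under matched
evaluation environments tracks this expected response within about 10–15%;
the agreement degrades when stressed environments enter the evaluation,
which is the program-level phenomenon the package exists to study. The
intensity formula assumes unrelated candidates, while F5 candidates are
clustered in families; at the default geometry this bias is modest but it
grows if selected fractions within families become extreme.

## Problem sizes in the test suite

The default configuration mirrors the reference program's counts
(120 x 15 founders, 4,031 markers, 629 F2, 382 preselected F5:6, 50 + 30
selections, 3 testers, 6 environments of which 2 stressed). The test suite
exercises a structurally identical configuration scaled to run a full
cycle in ~0.4 s (36 x 6 founders, 180 markers, 120 F2, 72 preselected,
20 + 12 selections), with 50 replicate cycles for the distributional
claims; Monte-Carlo checks of meiosis and the deflation factors use 10³–10⁴
gametes and 50–150 families. Sampling tolerances in the tests are set to
three Monte-Carlo standard errors of these sizes, so a pass establishes
the property at the simulated scale, not numerical identity with any
field study.

## Known limitations

- No epistasis, no marker-by-environment effects inside the predictor, no
  multi-trait index selection, and no multi-cycle recursion in the default
  pipeline (the machinery loops, but one cycle is the documented scope).
- The visual-selection stand-in is a single correlated auxiliary trait; it
  is not a model of breeder judgement.
- EM-REML is robust but slow near boundaries; large combining-ability
  models (thousands of levels) take minutes, and average-information
  updates would be the next step if that mattered.
- The generator's stress regime is a two-regime correlation model; real
  G x E is a continuum, so clustering "recovering" the stress group in
  simulation is a best-case benchmark.
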