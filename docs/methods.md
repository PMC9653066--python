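# Methods

`paircomm` implements the complete post-OTU statistical workflow for a paired
two-treatment soil-microbiome study: alpha diversity with gated group tests,
multivariate composition tests, a differential-taxon screen, predicted-function
comparisons, Pearson co-occurrence networks with stability and robustness
analysis, niche metrics with a permutation null, a dispersal-vs-niche
assembly test, and a Bayesian mediation model linking treatment to network
change through niche metrics. A synthetic community generator with planted
ground truth stands in for raw sequencing data, which studies of this design
frequently do not deposit. This note records the models, the defaults and why
they were chosen, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic paired communities

Counts follow a lognormal-compositional model. Per taxon *i*, a baseline
log-abundance `mu_i ~ Normal(0, sigma_A)` (default `sigma_A = 2`, giving the
heavy-tailed rank-abundance curves typical of OTU tables); per pair *p*, a
shared random intercept `u_ip ~ Normal(0, 0.4)` so that the two samples of a
site pair share their baseline community, mirroring a paired sampling design;
per sample, residual noise `Normal(0, 0.6)`. Sample proportions are the
softmax of these log-abundances and reads are drawn
`Multinomial(Poisson(depth), proportions)`. The default dimensions mirror the
emulated study (3 site pairs x 2 treatments, mean depth 10,432 reads); most
benchmarks raise `n_pairs`, because six samples cannot identify pairwise
correlations at r > 0.8 — a limitation of the design, not of the generator.

*Differential taxa* are planted by adding `log2FC * ln 2` to a taxon's
log-abundance in one treatment group. *Correlation blocks* replace a member's
entire non-baseline variation with
`sigma_r * (L*z_s + sqrt(1 - L^2) * eps_is)` where `z_s` is a latent factor
shared by the block, `L` the loading, and `sigma_r` the pooled pair+noise
scale; pairwise log-abundance correlation within a block is therefore `L^2`
before compositional closure and count noise, so `L = 1` plants edges
detectable at the r > 0.8 threshold. A negative block sign flips the loading
of every member after the first. The block construction deliberately
overrides the pair intercept for its members: a planted edge's strength is
then controlled by `L` alone rather than diluted by pair-level variance.

*Assembly scenarios* are presence/absence metacommunities in two groups of
sites. In niche mode the habitat filters: sites of one group are broadly
suitable (per-site occurrence probability drawn from 0.85–0.98), the other
group hostile (0.05–0.25), so composition and richness are determined by the
sample margin. In dispersal mode every species has its own prevalence
(uniform on 0.1–0.9) applied identically at all sites, so the species margin
carries the structure. These two margins are exactly what the
dispersal–niche test's null models constrain, which is what makes regime
recovery a meaningful benchmark (see below). Occupied cells receive
`1 + Poisson(50)` individuals.

## Diversity

Rarefaction subsamples without replacement (multivariate hypergeometric);
samples below the target depth are dropped, never upsampled. Index variants,
chosen to match the most common defaults where the emulated analysis names
only the index: classic Chao1 `S + F1^2 / (2 F2)` with the bias-corrected
form only when `F2 = 0` (keeps the estimate finite); ACE with the
rare/abundant cutoff at 10 reads; Shannon in nats so Pielou `J = H / ln S`;
inverse Simpson `1 / sum p^2`; Fisher's alpha as the root of
`S = a ln(1 + N/a)`; Good's coverage `1 - F1/N`; Faith's PD on a rooted tree
including the path to the root. Pielou is undefined (NaN) for single-taxon
samples. scikit-bio provides ACE, Fisher's alpha and Faith's PD; Chao1 is
computed in-package to get the exact fallback rule and cross-checked against
scikit-bio in the tests.

## Group inference

The gated test selection runs Shapiro–Wilk per group and Levene across
groups, both at alpha = 0.05 (the convention; the emulated workflow states
the gates but not the level): both pass → t test (2 groups) or one-way ANOVA;
otherwise Wilcoxon rank-sum (exact for groups of ≤ 10 without ties) or
Kruskal–Wallis. Groups of fewer than three observations cannot be
normality-tested and conservatively fall to the rank branch.

PERMANOVA uses Anderson's pseudo-F on squared distances with
`p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)` under free label shuffles
(9,999 permutations by default) and exhaustive enumeration whenever the
number of distinct label arrangements does not exceed the requested
permutations; `R^2 = SS_among / SS_total` is reported alongside. Pair
structure is not constrained in the default permutation scheme, matching the
plain test the workflow reports; restricted permutations can be layered on by
the caller. The implementation is cross-checked against scikit-bio's
PERMANOVA in the tests.

The random-forest screen trains a classifier (default 10,000 trees; tests and
the acceptance harness use 500–2,000 trees at 30 samples, a problem size at
which rankings are already stable) on relative abundances and ranks taxa by
mean decrease in Gini impurity with deterministic index tie-breaking;
scikit-learn's forest uses a plain bootstrap, so balanced class weights stand
in for the stratification that tiny paired designs would otherwise want. A
per-taxon Kruskal–Wallis p accompanies the ranking; the discriminating set is
conventionally `kw_p < 0.05`, with both reported because the combination rule
is a user decision. Venn read-share fractions are reported relative to each
group's own total reads; an alternative grand-total denominator is a
one-line change in the caller.

## Co-occurrence networks

Taxa are filtered to those present in at least 2 samples with grand-total
read share ≥ 0.1% (the filter is configurable to a mean-per-sample share).
Pearson r is computed between all pairs of within-sample relative-abundance
profiles, two-sided p-values from the t transform, BH adjustment over all
pairs, and an edge kept iff `|r| > 0.8` and adjusted `p < 0.001`. The
absolute-value criterion admits negative edges, which signed thresholding
would silently discard. Pearson on proportions is compositionally biased —
the heavy-tailed benchmark below quantifies the consequence — and is used
deliberately because it is the method being reproduced; SparCC-style
corrections are out of scope.

Property suite: clusters are connected components; modularity is Newman's Q
of the greedy agglomerative partition (deterministic); degree centralization
is Freeman's `sum(d_max - d_i) / ((N-1)(N-2))`; "central eigen" is the
maximum eigenvector-centrality score, computed from a dense
eigendecomposition of the adjacency matrix because co-occurrence networks
routinely have isolated nodes that break iterative solvers; vulnerability is
the largest relative drop in global efficiency over single-node deletions;
natural connectivity is `ln(mean(exp(lambda_i)))` over adjacency eigenvalues,
evaluated with a log-sum-exp to avoid overflow.

Bootstrap node-attribute distributions resample N nodes with replacement from
the intact graph's attribute vectors (degree, harmonic closeness normalised
by N−1, local clustering, eigenvector centrality); attributes are not
recomputed per resample. The package default is 10,000 bootstraps — at the
10^5 used in the emulated analysis the distributions are visually identical
and the KS comparisons unchanged. Stability draws replicate node (or edge)
removals at a fixed fraction (default 50%, 1,000 replicates) and returns the
replicate distributions of average degree and natural connectivity for KS and
Kruskal–Wallis comparison; robustness sweeps repeat this along a fraction
grid and attach an OLS line to each mean curve. High/low-degree classes use
the 0.75/0.25 quantiles of positive degrees (the emulated study does not
define its cutoffs; observed degrees there cluster bimodally, so any interior
quantile reproduces the partition); classes that overlap under degenerate
degree distributions raise rather than silently merging, and the pipeline
records that stage as skipped.

## Niche metrics and assembly

Resource states are individual samples. Levins breadth is
`B_i = 1 / sum_j P_ij^2` on the taxon's across-sample usage profile, reported
unstandardised (a standardised variant is a trivial transformation and the
emulated figures do not indicate one). Pianka overlap is the cosine-like
similarity of two usage profiles. Generalists/specialists are called against
a fixed–fixed null preserving both sample totals and taxon totals via
Patefield draws (`scipy.stats.random_table`): generalist above the
`1 - alpha/2` null quantile of B, specialist below `alpha/2`.

The dispersal–niche continuum test works on presence/absence. The observed
per-taxon SIMPER contribution profile (mean `|x_i - y_i| / sum(x + y)` over
between-group sample pairs, ranked and normalised) is compared with profiles
from three constrained permutation ensembles: species rows shuffled
(occurrence totals preserved — the dispersal-controlled null), sample columns
shuffled (richness preserved — the niche-controlled null), and a curveball
fixed–fixed shuffle. The fit statistic is
`E = sum_ranks (log10 obs - log10 perm)^2` with additive smoothing
`1/(10 S)` on the normalised profiles so that a permutation that zeroes a
taxon contributes a bounded penalty instead of dominating E; the regime whose
null reproduces the profile best (lowest mean E) is selected. This is a
reconstruction of the published PER-SIMPER/DNCI idea from its description —
the full effect-size and confidence-interval machinery of the published
index is intentionally out of scope, and regime selection by mean E is the
supported conclusion. Note the structural asymmetry: the row-fixed null
conditions on species occupancies, the dominant driver of a taxon's
contribution, so it fits well unless the sample margin genuinely carries the
signal; the niche scenario the generator produces is correspondingly
sample-margin-driven, and the benchmark shows direction recovery under those
conditions, not for every conceivable niche process.

## Regressions and the path model

Degree is regressed on niche width, and the absolute between-network degree
change (Δdegree; a signed option exists) on niche overlap, by OLS with
two-sided slope tests. The mediation model is

    M = a0 + a T + e1,   Y = b0 + b M + c T + e2

with Normal(0, 10^2) priors on coefficients and Inverse-Gamma(0.001, 0.001)
on the variances; both blocks are conjugate, so a plain Gibbs sampler (4
chains x 5,000 iterations, 1,000 burn-in by default) draws the posterior.
Variables are z-scored by default so estimates are comparable across
pathways. A pathway is accepted when its 95% credible interval excludes zero;
the indirect effect is the posterior of `a*b`. Split-R-hat above 1.1 on any
pathway flags the fit as non-converged; the result is still returned, with
the flag, never silently. Observations are per-OTU records (OTU x group cells
with that group's niche metric and degree); the emulated analysis does not
state its observational unit, and this choice is recorded here as the
package's own.

## Pipeline determinism and problem sizes

A single seed spawns independent substreams per stage
(`numpy.random.SeedSequence`), so re-running a configuration reproduces every
output byte-for-byte; the run log records the per-stage seeds. The packaged
benchmark fixture uses 150 taxa, 15 pairs, depth 20,000, two planted
differential taxa and three overlapping correlation blocks — sizes at which
every stage is exercised end-to-end in seconds while networks, degree
classes and the path model all remain identifiable. Calibration benchmarks
use 500 null simulations per test family; recovery benchmarks 50–100
replicates; these sizes give Monte-Carlo standard errors comfortably inside
the tolerance bands being checked.

## What the benchmarks do not show

The generator reproduces the shape of OTU tables (heavy tails, compositional
closure, paired structure, plantable signal) but not amplification or
clustering artefacts, taxon-specific dispersion, or phylogenetic signal in
abundances; passing recovery benchmarks demonstrates correctness of the
implementations under the stated generative model, not field performance on
real sequencing data. Pearson-on-proportions inflates false edges as
abundance distributions grow heavier-tailed (precision at the default
threshold drops visibly at `sigma_A = 2` versus `sigma_A = 1` in the planted
benchmark), a known compositional caveat reproduced here by design. The
DNCI reconstruction selects between margin-constrained regimes and should
not be read as the published index's effect size.
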