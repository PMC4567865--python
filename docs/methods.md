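# Methods

This note documents the statistical models and numerical choices behind
`isopop`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and where the design was genuinely
open.

## Dominant-marker data model

Genotypes are strictly binary band-presence calls (individuals × loci).
Missing codes are rejected by design: in AFLP practice, samples without
a clear banding pattern are re-run or excluded before analysis, and a
"missing" band is indistinguishable from a scoring failure. The
container enforces the sampling design the analyses assume — every
population has at least two individuals and every region at least two
populations.

The replicate-based genotyping error rate is defined per pair-locus:
discordant calls across all original/replicate pairs divided by
(pairs × loci). Normalising instead by the number of reproducible bands
would give a slightly different (typically larger) figure; the
pair-locus definition was chosen because it needs no band-frequency
bookkeeping and is invariant to locus and pair order.

## Diversity statistics

For a dominant marker, allele frequencies are not observable. The
default estimator assumes Hardy–Weinberg proportions: with band
frequency `f`, the null-allele frequency is `q = sqrt(1 − f)` and
`p = 1 − q`. This square-root rule is the convention of the classic
dominant-marker software; a band-as-allele estimator (`p = f`) is
available for sensitivity analysis, and the two agree at fixed loci.
Nei's gene diversity `He = 1 − p² − q²` and Shannon's index
`I = −(p ln p + q ln q)` (with `0 ln 0 = 0`) are averaged over all
loci; %PL counts loci with `0 < f < 1`, with no rare-allele cutoff.
The Shannon index is reported in its standard non-negative form; the
form without the minus sign is negative-valued and inconsistent with
any tabled diversity value. Because the allele-frequency estimator used
by legacy software is rarely reported, absolute He/I values are only
comparable within an estimator; %PL is estimator-free.

## AMOVA

Distances between individuals are squared Euclidean on the 0/1 band
vectors, i.e. the count of differing loci — the standard AMOVA input
for binary data. Sums of squares are computed from pairwise distances
(`SS = Σ_{i<j} d_ij / n` within each grouping); this is algebraically
identical to a per-locus ANOVA decomposition, which the test suite uses
as an independent oracle.

Variance components use the classical unequal-sample-size coefficients.
One level: `n₀ = (N − Σnᵢ²/N)/(k − 1)`,
`σ²_among = (MS_among − MS_within)/n₀`. Nested (regions g, populations
i): `n = (N − Σ_g Σ_{i∈g} nᵢ²/N_g)/(P − G)`,
`n′ = (Σ_g Σ_{i∈g} nᵢ²/N_g − Σnᵢ²/N)/(G − 1)`,
`n″ = (N − ΣN_g²/N)/(G − 1)`, with
`σ²_b = (MS_pop − σ²_c)/n` and
`σ²_a = (MS_region − σ²_c − n′σ²_b)/n″`. Φ statistics are the usual
ratios (Φ_RT = σ²_a/total, Φ_PR = σ²_b/(σ²_b + σ²_c),
Φ_PT = (σ²_a + σ²_b)/total, or σ²_a/total at one level).

Negative component estimates are retained in the result object for
diagnostics but truncated to zero when percentages and Φ are formed —
the convention of the widely used AMOVA programs. `components_from_summary`
applies exactly the same algebra to published (df, SS) rows plus sample
sizes, which makes tabled AMOVA results checkable without raw data.
Note that rebuilt Φ values can disagree with a printed Φ in the last
digit when the printed value was itself derived from rounded
percentages (the bundled survey's three-level Φ_PT rebuilds to 0.427,
while the printed 0.42 equals the sum of the truncated integer
percentages 14% + 28%).

Permutation tests permute individuals among populations (Φ_PT), among
populations within their region (Φ_PR), or whole populations among
regions (Φ_RT), with 999 permutations by default and the
`(b+1)/(m+1)` p-value estimator so p is never exactly zero. With few
populations per region the Φ_RT scheme has a coarse permutation space
(its attainable p-values are limited by the number of distinct
region assignments). All permutation streams are seeded; results are
bit-reproducible given a seed.

Pairwise Φ_PT runs a one-level AMOVA per population pair; a genetically
uniform pair (zero total variance) is reported as Φ = 0. Raw
(untruncated) pairwise estimates are kept alongside the truncated
matrix used downstream.

## Mantel tests

The genetic input is the population-level pairwise Φ_PT matrix (not
individual distances); the geographic input is great-circle km
(haversine, R = 6371 km) for real coordinates or planar Euclidean km
for synthetic grids. The statistic is the Pearson correlation of the
upper triangles; the alternative is one-tailed positive, matching the
directional isolation-by-distance hypothesis. For n ≤ 6 labels all n!
simultaneous row/column permutations are enumerated and the p-value is
exact; otherwise random permutations with the `(b+1)/(m+1)` estimator
are used.

## Bayesian two-group comparisons

Traits are compared between regions with the robust two-group model:
each group Student-t with its own location μ and scale σ and a shared
degrees-of-freedom ν. Priors follow the established robust-estimation
defaults, chosen because the original analyses state only that priors
were vague: μ_g ~ Normal(pooled mean, 1000 × pooled sd),
σ_g ~ Uniform(pooled sd/1000, pooled sd × 1000),
ν − 1 ~ Exponential(mean 29). Habitat-area-like traits (strictly
positive, strongly skewed) use a gamma likelihood with vague
Gamma(10⁻³, 10⁻³) hyperpriors on shape and rate; the reported
difference is then the difference of group means shape/rate on the
original scale. A normal likelihood is available for
robustness comparisons.

Sampling is component-wise random-walk Metropolis with per-chain,
per-parameter step sizes adapted during warmup toward 44% acceptance
(Robbins–Monro schedule, frozen afterwards), several chains advanced in
lockstep. Defaults (4 chains × 20,000 kept draws after 1,000 warmup)
give bulk ESS above 10,000 and split R-hat below 1.01 on the survey's
cushion-density comparison; fits falling short attach an explicit
diagnostics warning rather than failing.

Decisions use the 95% highest density interval of the difference of
group locations: *credible* iff the HDI excludes zero. The point
estimate ("most credible difference") is the posterior mode from a
Gaussian KDE of the pooled difference draws. Effect size is
`d = (μ₁ − μ₂)/sqrt((σ₁² + σ₂²)/2)` converted to `r = d/sqrt(d² + 4)`;
this definition is stated explicitly because "effect size r" is
ambiguous in parts of the literature. For square-root-transformed
traits both the transformed-scale difference and a back-transformed
difference of squared locations are reported, since the scale of a
published difference is often ambiguous; neither is privileged.

The HDI routine is the shortest-contiguous-window rule on sorted draws
(cross-checked against arviz); ESS and split R-hat come from arviz.

## Germination model

Dish counts follow a Bayesian two-way logistic ANOVA analogue with
overdispersion: count ~ Binomial(sown, π_dish); π_dish ~ Beta with cell
mode ω and shared concentration κ (`a = ω(κ−2)+1`,
`b = (1−ω)(κ−2)+1` — the mode/concentration form keeps "equal
concentration between cells" literal, and κ > 2 keeps the density
unimodal); logit(ω) = grand mean + treatment + region + interaction
deflections with Normal(0, σ_family) shrinkage, vague Gamma(0.01, 0.01)
priors on the deflection precisions and on κ − 2, and a Normal(0, 5)
prior on the grand mean (5 logit units spans probabilities from
~0.007 to ~0.993, i.e. effectively flat over the plausible range).

The dish probabilities are marginalised analytically — given ω and κ
the counts are beta-binomial — so the sampler works directly on the
~16 structural parameters. This matters: sampling the dish
probabilities explicitly creates a strong random-walk coupling between
π and ω that inflates autocorrelation times by orders of magnitude (the
historical remedy was running hundreds of thousands of steps with heavy
thinning). With the marginalised likelihood, adaptive scalar Metropolis
updates (plus conjugate Gibbs for the deflection precisions) reach ESS
in the thousands within seconds; the default 4 × 20,000 kept draws
target ESS ≥ 10,000 on the cell probabilities, with warnings attached
otherwise. Deflections are sampled unconstrained (the hierarchical
priors keep the posterior proper) and recentred to sum-to-zero form in
every retained draw, so the reported deflection families satisfy the
constraint exactly.

Marginal treatment/region probabilities are balanced averages of the
cell modes on the probability scale; contrasts are draw-wise
differences judged by 95% HDIs, and the compact letter display uses the
standard insert-and-absorb construction (levels sharing a letter have
no credible pairwise difference). Day-level census detail is out of
scope: the model sees one count per dish (the day-7 snapshot, where
overall germination is near one half and the design is most
informative).

## Correlation screen

Spearman's ρ with mid-ranks for ties; two-sided p from the t
approximation on n − 2 df (scipy's convention), with an exact
permutation p available for n ≤ 10. **No multiple-testing correction
is applied anywhere in the screen** — the original analysis style
reports raw coefficients with 0.05/0.01 stars, and the package mirrors
that; users scanning the full matrix should expect ~5% false stars
under the null (the suite verifies this calibration).

Fruit set is capsules per flower. At the region level two
non-equivalent definitions exist: the ratio of regional means and the
mean of per-population ratios. Both are implemented;
`ratio_of_means` is the default because it reproduces tabled regional
summaries (e.g. 0.36 for the Swiss region) and is defined even when
individual populations flowered but set no fruit.

## Synthetic data generator

The generator emulates the survey's design: 2 regions × 10 populations
× 15 individuals × 308 loci, within-region differentiation targets
0.29/0.37 (the survey's regional Φ_PT estimates), a between-region
parameter of 0.14 (its among-region variance share), isolation by
distance in the second region, trait tables at the survey's regional
means and spreads, and germination cells of 8 dishes × 10 seeds with
probabilities near 0.5 and a region offset of ~0.07.

Differentiation uses a Balding–Nichols beta step,
Beta(f(1−F)/F, (1−f)(1−F)/F), applied on the **band-frequency scale**.
This choice makes the parameter mean what it says: a beta step with
parameter F yields an among-group variance fraction of exactly F at
every locus (Var = F·f(1−f) among groups against (1−F)·f(1−f) expected
within), so AMOVA Φ_PT estimates centre on the configured target —
verified unbiased by simulation. Applying the step on the allele scale
and coding dominance afterwards inflates band-level differentiation at
low-frequency loci (realised Φ_PT ≈ 0.37 for a nominal 0.3), which
would make the parameter a misnomer. Dominance remains explicit:
individuals are Bernoulli draws of the dominant phenotype, and the
implied band-allele frequency is `1 − sqrt(1 − band freq)`, exactly the
assumption the `sqrt_hwe` estimator inverts.

Isolation by distance places the populations of one region on a 15-km
line and accumulates drift stepwise along it with per-step
`F_step = 1 − (1 − F_within)^(1/mean pairwise step count)`, so the mean
pairwise differentiation matches the region's target while increasing
with distance. Traits are Student-t (df 10) or moment-matched gamma
draws at region-specific location/scale, with lower truncation for
counts; population density is derived as NI/HA rather than drawn, so
the screen's strong HA–PD dependence arises mechanically, as in real
tables.

What the generator does **not** emulate: linkage between loci,
coalescent genealogical noise, mutation models, spatial structure
within populations, and trait–genotype correlations beyond those
induced by shared region membership. Passing recovery tests therefore
show that the estimators invert the generator's assumptions at survey
scale, not that those assumptions hold for any particular real
dataset.

## Numerical and testing choices

Problem sizes in the test suite are chosen for desk-scale runtimes:
permutation calibrations use 500 null replicates at 199 permutations
(the attainable p-values make the nominal 0.05 level exact),
island-model recovery uses 50 replicates of 10 × 15 × 150 loci, and the
germination calibration uses 20 replicates with 2 × 1,500 kept draws,
where HDI coverage of the generating cell modes is required to reach
85% and mean absolute recovery error 0.07 (single cells in a single
replicate can miss by more — with 8 dishes the data's own sampling
noise is ~0.04 per cell). MCMC-based tests fix seeds; permutation
p-value ties are broken conservatively (`>= observed − 1e-12`).
Degenerate inputs fail loudly: zero total molecular variance, constant
distance matrices, constant variables in the screen, non-positive data
under a gamma likelihood, and all-boundary germination data (which fits
but carries a warning).
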