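# Methods

## The split model

`ibdkit` estimates how recently two groups of individuals, sampled
centuries apart, belonged to one population, using only the spectrum of
IBD segment lengths shared between them.

The demographic model is a two-island split: an ancestral population of
constant diploid effective size N₀ splits T₀ generations before the
*younger* sample into the two sampled populations, with no gene flow
afterwards. Between-group coalescence can therefore happen only in the
ancestral population. The groups are heterochronous with offset Δ
generations; counting generations back from the younger sample, a lineage
pair sampled one from each group has passed through m(t) = 2t − Δ meioses
by the time its common ancestor lived (the older lineage stops
accumulating meioses Δ generations early), and coalescence is possible
from t_min = max(T₀, Δ) at rate 1/(2N₀) per generation.

Conditional on m meioses, the expected number density of IBD segments of
length l Morgans per haplotype pair is the classical crossover-survival
result, summed over chromosomes of genetic length L_c:

    φ(l | m) = Σ_{c: L_c > l} [ (L_c − l) m² + 2m ] e^{−ml}

(interior segments require a crossover at each end, segments abutting a
telomere only one). The marginal density integrates m(t) over the
exponential coalescence time,

    λ(l) = ∫_{t_min}^∞ (1/2N₀) e^{−(t−t_min)/2N₀} φ(l | 2t − Δ) dt ,

and because m is linear in t this reduces exactly to first and second
moments of an exponential: with β = 1/(2N₀), m₀ = 2t_min − Δ and
a = β + 2l,

    λ_c(l) = β e^{−m₀ l} [ (L_c − l)(8/a³ + 4m₀/a² + m₀²/a) + 4/a² + 2m₀/a ].

Expected bin counts are μ_b = 4 · n_pairs · ∫_bin λ(l) dl — the factor 4
is our explicit convention that each diploid pair contributes four
haplotype pairs — and the composite log-likelihood is
ℓ = Σ_b O_b ln μ_b − μ_b, treating bins (and pairs) as independent
Poisson counts. Composite independence is an approximation: segments of
one pair share one coalescence history, so the likelihood is valid for
point estimation and approximate for uncertainty.

### Assumptions and known limitations

- No post-split gene flow. Real cohorts with continued contact inflate
  the long-segment bins; the Pearson-residual diagnostic
  (`SplitTimeResults.predict_vs_observed`) makes this visible, and a
  residual excess of long segments biases T̂₀ downward.
- Constant ancestral size, no population structure before the split.
- The whole-chromosome sharing term (a point mass e^{−mL_c} at l = L_c)
  is omitted; at m ≥ 17 meioses it is below 10⁻²⁰ per chromosome and
  irrelevant at the ≥ 8 cM lengths fitted here.
- N₀ is a *diploid* effective size with pairwise coalescence rate
  1/(2N₀). This is the standard convention and matches the magnitude of
  the estimates the model produces; halving/doubling conventions would
  rescale N̂₀ accordingly.
- Dates enter only through Δ = round(|date₁ − date₂| / g) with
  g = 29 years per generation by default; per-individual date
  uncertainty and generation-time uncertainty are not propagated.

## Fitting and uncertainty

`SplitTimeModel.fit()` evaluates ℓ on a dense rectangular grid, by
default T₀ ∈ {Δ, Δ+1, …, Δ+150} (step 1 generation; the split cannot
postdate the older sample, hence the lower limit) and N₀ log-spaced with
201 points over [10², 10⁶]. Ties at the maximum are broken toward smaller
T₀, then smaller N₀. The 95% confidence region is
{ℓ ≥ ℓ_max − 1.92}, 1.92 being half the 95% χ² quantile with 1 df, and
the reported per-parameter intervals are the min/max projections of that
region onto each axis.

Two caveats are deliberate and documented rather than "fixed":

- A 1-df threshold applied to a two-parameter joint region is
  anticonservative as a *joint* statement (nominal 85.4%); the
  *projections* over-cover correspondingly. Simulation at the default
  design (36×17 diploid pairs, truth N₀ = 34,245, T₀ = 18, Δ = 17)
  measures ≈ 90% joint coverage (the T₀ ≥ Δ boundary truncates the
  region) and 96–99% per-parameter projection coverage. The package
  reports the projections, which is also how interval estimates from
  this procedure are conventionally quoted. A profile-likelihood
  alternative can be obtained by fitting with `confidence`/`df` choices
  via `chi2_half_threshold`.
- The region may legitimately touch T₀ = Δ (direct-ancestry-compatible
  data); `fit()` warns only when the region touches a *truncation*
  boundary (the upper T₀ edge or either N₀ edge), where the reported
  intervals would be clipped.

Numerical choices: the closed form above is the default density (exact to
machine precision; the adaptive-quadrature route is retained and tested
against it to 10⁻⁹ relative). Bin integrals over l use Gauss–Legendre
quadrature split at every chromosome length inside the bin, because λ is
smooth between but kinked at the lengths where a chromosome stops hosting
segments; without the splits the open bin cannot reach 10⁻⁹ additivity.
The open last bin truncates at the longest chromosome (λ = 0 beyond). A
bin with μ_b = 0 and a positive observed count yields ℓ = −∞; an all-−∞
surface raises a fit failure rather than returning an arbitrary argmax.
Expected-count grids factor out of the likelihood and can be precomputed
once (`SplitTimeModel.mu_grid`) and reused across spectra that share
binning, pair count, offset and map — replicate refits are then a single
array contraction each, with bit-identical results.

Default length bins are [8,12), [12,16), [16,20), [20,∞) cM, aligned
with the 8/12/20 cM thresholds used throughout the segment filters;
binning is configurable everywhere.

## Synthetic data

The generators produce data with exactly the statistical structure the
estimators assume, which makes simulator↔likelihood agreement a sharp
test of both sides rather than a tautology on either.

**Between-group simulator** (`simulate_split_ibd`). Draws the total
segment count over all n₁ × n₂ diploid pairs as Poisson with mean
4 n₁ n₂ Λ, Λ = ∫_{l_min}^∞ λ, then segment lengths i.i.d. from λ/Λ by
inverse CDF on a 4096-point grid, a hosting chromosome with probability
∝ λ_c(l), a uniform admissible start position, and a uniformly chosen
pair. Defaults are the study design the model is fitted under: n₁ = 36,
n₂ = 17, Δ = 17 generations, 8 cM emission floor. Sampling from the
marginal density (coalescence time integrated out) is intentional — it
matches the composite likelihood exactly; a per-pair coalescence-time
variant (`per_pair_times=True`) adds the between-pair overdispersion of
a shared coalescent history for robustness experiments.

**Pedigree gene-dropper** (`simulate_pedigree_ibd`). Founder haplotypes
get globally unique labels; each meiosis places crossovers as a Poisson
process of rate 1 per Morgan per chromosome with uniform positions, no
interference, and a fair-coin starting haplotype. Emitted segments are
the maximal intervals where the two focal diploids carry at least one
haplotype pair descending from the same founder haplotype (IBD ≥ 1).
Degree is the number of meioses on the connecting path through a single
common ancestor; parent–child and full siblings are the two degree-1
relationships (siblings have two common ancestors), and chains of
degree d ≥ 2 come in lineal and half-collateral variants. This yields the
textbook expectations used as invariants: a child shares one full
haplotype genome-wide with each parent (22 segments, 3545.51 cM on the
bundled map), siblings cover 3/4 of the genome IBD ≥ 1 in expectation,
and single-ancestor chains cover 2^{−(d−1)}.

**Reference cloud** (`build_reference_cloud`). Stacks per-replicate
(sum_cM, n_segments, max_cM) summaries at the 8 cM floor for degrees 1–8,
each degree split evenly over its two relationship variants. Replicates
that share nothing at the floor are kept as zero rows — at degrees 7–8
these are common and they calibrate the "unrelated" call.

What the generators do *not* emulate: phasing and imputation error, false
positive/negative IBD calls, SNP-density variation along the genome
(synthetic n_snps is a flat 250 per cM, chosen to clear the 220/cM filter
so that filter plumbing is exercised without modelling call quality),
crossover interference, sex-specific maps, and inbreeding loops. Passing
tests therefore validate the estimators under their own model;
robustness to caller artifacts on real data is out of scope, and
empirical pedigree reference sets may spread wider than the idealized
cloud.

## Filters, networks, degree calls

Segment-level filter: length strictly greater than 8 cM and SNP density
strictly greater than 220/cM (the caller's published false-positive
guidance); individual-level filter: strictly more than 450k genome-wide
SNPs. The network floor, by contrast, is non-strict (≥ 8 cM / ≥ 20 cM),
following the wording of each threshold's source context; every
threshold is a parameter.

The strict trans-regional pair rule — at least three shared tracts of
8–12 cM *or* any tract over 12 cM — is implemented disjunctively; the
source phrasing is grammatically ambiguous and the conjunctive reading is
available behind a flag. "Interconnected individuals" are nodes with at
least one passing edge; isolated individuals are excluded from the graph,
components are reported in decreasing size order, and edge tallies by
unordered macroregion pair ({C.Basin, C.Asia, E.E.Steppe, other}) sum to
the edge count by construction.

Degree classification fits, per degree, a bivariate Gaussian to the
reference cloud in (log1p(sum_cM), log1p(n_segments)) — the log1p keeps
zero-sharing replicates finite and roughly symmetrizes the spread — with
a small ridge (10⁻⁴) on the covariance for degenerate clouds. A pair is
called as the inclusive range of degrees whose density is within e⁻³ of
the best degree, mirroring interval-style reporting ("5th- to
7th-degree"); pairs sharing nothing, or totalling less than the 1st
percentile of the degree-8 cloud, are "unrelated". This statistical rule
is an explicit stand-in for assignment against published empirical
pedigree distributions and is labelled as synthetic in all exports. On
its own training conditions it recovers the generating degree within the
range in ≥ 96% of replicates for degrees 1–5 (500 cloud replicates per
degree, seed-fixed); beyond degree 6 ranges widen and unrelated calls
appear, as they should.

## Problem sizes

The test suite and `scripts/acceptance.py` use the study-design scale
throughout: 100 seeds for simulator↔likelihood consistency, 100 replicate
grid fits (medians over the first 25) for recovery and coverage, 2,000
gene-dropping replicates for the sibling and half-sibling coverage
fractions, 500 cloud replicates per degree for the classifier. The full
suite runs in under a minute on one CPU thanks to the precomputed
expected-count grid; these sizes are the package's documented reference
conditions, not a ceiling.
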