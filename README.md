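# ibdkit

Identity-by-descent (IBD) segment analysis for heterochronous ancient-DNA
cohorts: quality filtering of IBD caller output, trans-regional sharing
networks, pedigree-based degree-of-relatedness classification, and
maximum-likelihood estimation of a population split time from the IBD
length spectrum.

The package is aimed at population geneticists who already have IBD
segment calls (e.g. from an HMM caller run on imputed ancient genotypes)
for individuals sampled centuries apart, and who want to ask how recently
two groups of individuals were part of one population.

## The model

Two populations descend from a single ancestral population of diploid
effective size N₀ and exchange no migrants after splitting T₀ generations
before the younger sample. The samples are heterochronous: the older group
antedates the younger by Δ generations, so two lineages sampled one from
each group accumulate m(t) = 2t − Δ meioses when their common ancestor
lived t generations before the younger sample, and between-group
coalescence is possible only for t ≥ t_min = max(T₀, Δ), at rate 1/(2N₀).

Given m meioses, the expected density of IBD segments of length l
(Morgans) per haplotype pair, summed over chromosomes of map length L_c, is

    φ(l | m) = Σ_{c : L_c > l} [ (L_c − l) m² + 2m ] e^{−ml}

and the marginal density integrates the exponential coalescence time:

    λ(l) = ∫_{t_min}^∞ (1/2N₀) e^{−(t − t_min)/2N₀} φ(l | 2t − Δ) dt

which reduces in closed form to moments of x^k e^{−ax} with
a = 1/(2N₀) + 2l. Expected counts per length bin are
μ_b = 4 · n_pairs · ∫_bin λ (four haplotype pairs per diploid pair), the
composite likelihood treats bins as independent Poisson counts, and the
fit is a dense 2D grid search over (T₀, N₀). The 95% confidence region is
the set of grid points within 1.92 log-likelihood units of the maximum
(half the 95% χ²₁ quantile), reported through its per-parameter
projections.

The bundled synthetic-data generators close the loop: a between-group
simulator draws segments from exactly this inhomogeneous Poisson model,
and a pedigree gene-dropper (Poisson crossovers, no interference) produces
the realized IBD of relatives of degree 1–8 used as the reference cloud
for degree classification.

## Worked example

Simulate a cohort at the model's point estimates — 36 diploids in the
older group and 17 in the younger, sampled 17 generations apart — and fit
the split model back:

```python
from ibdkit import (
    BinnedSpectrum, GenomeMap, SimConfig, SplitModelParams, SplitTimeModel,
    simulate_split_ibd,
)

gmap = GenomeMap.default()                # 22 autosomes, 3545.51 cM
truth = SplitModelParams(n0=34245, t0=18, delta_gens=17, gmap=gmap)
segments = simulate_split_ibd(truth, SimConfig(seed=7))   # 56 segments >= 8 cM
spectrum = BinnedSpectrum.from_segments(segments, n_pairs=36 * 17)
result = SplitTimeModel(spectrum, delta_gens=17, gmap=gmap).fit()
print(result.summary())
```

```
Two-island split model: grid maximum likelihood
=======================================================
Bins (cM):        (8.0, 12.0, 16.0, 20.0, inf)
Observed counts:  (42, 11, 1, 2)  (n_pairs=612)
Sampling offset:  17 generations
-------------------------------------------------------
T0 (split time):  19 generations (95% CI: 17 to 24)
N0 (ancestral):   28,840 diploids (95% CI: 15,849 to 45,709)
log-likelihood:   127.7615  (region drop 1.921)
-------------------------------------------------------
  bin_cM  observed  expected  pearson_resid
 [8, 12)        42 42.874878      -0.133612
[12, 16)        11  9.897310       0.350505
[16, 20)         1  2.790481      -1.071841
    >=20         2  1.319603       0.592299
```

The split time is read against the sampling offset: T̂₀ = 19 generations
with a CI reaching down to Δ = 17 means the data are consistent with the
older group lying on the direct ancestral line of the younger one. The
Pearson residuals per bin diagnose model misfit (systematic positive
residuals in the long-segment bins would indicate recent gene flow the
pure-split model cannot absorb).

The same analysis runs from the shell:

```sh
ibdkit simulate-split --n0 34245 --t0 18 --delta 17 --seed 7 -o sim/
ibdkit fit-split --ibd sim/ibd_segments.tsv --meta meta.tsv \
    --group1 old --group2 young -o fit/
ibdkit network --summaries filt/pair_summaries.tsv --meta meta.tsv -o net/
```

`fit-split` derives Δ from the groups' median dates at 29 years per
generation unless `--delta` is given, and every command writes a
`manifest.json` recording seed, parameters and package version.

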