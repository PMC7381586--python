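# Methods

## Model and estimators

The population is closed (no birth, death or migration within the sampling
occasion) and consists of three classes: adult males (`N_M`), adult females
(`N_F`) and juveniles (`N_J`). Each juvenile has exactly one mother and one
father among the adults. A single subsample of size `n` is taken; within it,
`m_FC` counts the sampled juveniles whose father is also sampled and `m_MC`
the sampled juveniles whose mother is also sampled. Because each juvenile has
exactly one parent of each sex, "pairs" and "juveniles with that parent
present" coincide and `m_FC, m_MC ≤ n_J`.

Conditional on the subsample composition, exchangeability gives
`P(father sampled) = n_M / N_M` for every sampled juvenile, hence
`E(m_FC / n_J) = E(n_M) / N_M`. Inverting yields

    N̂_M = n_M n_J / m_FC,   N̂_F = n_F n_J / m_MC,
    N̂_A = N̂_M + N̂_F,        Ĵ = n_J / (n_M + n_F),   N̂ = N̂_A (1 + Ĵ).

The conditional form of the identity is exact: the test suite verifies it by
exhaustive enumeration of all 252 size-5 subsamples of a 10-animal
population, where the two conditional means agree to machine precision.

Design choices at the estimator surface:

- `m_FC = 0` or `m_MC = 0` raises a typed `ZeroPairsError` naming the
  offending count; infinity is never propagated. The validation harness
  treats this signal as "replicate not estimable" and reports the
  estimability rate separately.
- Estimates are real numbers, never rounded; rounding is presentation.
- `N̂_A` is valid under class-wise random sampling even if the class
  proportions are distorted; `Ĵ` (and therefore `N̂`) additionally assumes a
  representative composition. The CLI prints this caveat; it is not
  enforced, since representativeness is not checkable from one subsample.

## Bootstrap intervals

Intervals are percentile bootstrap: `n_boot` (default 200) resamples of size
`n` drawn with replacement from the subsample, the estimator recomputed on
each, and the empirical `α/2` and `1 − α/2` quantiles (linear interpolation,
`α = 0.05` default) taken over the valid resamples. One master seed expands
into per-resample streams via `SeedSequence.spawn`, so enlarging `n_boot`
extends rather than reshuffles the sequence.

The one genuinely open design point is how to recount pairs inside a
resample, and it matters:

- Recounting by joint presence within the resample is badly off-centre: a
  with-replacement resample contains on average only `1 − (1−1/n)^n ≈ 63%`
  of the distinct individuals, so `m/n_J` deflates by that factor and every
  resampled estimate inflates by ≈1.6×. Measured at `n/N = 0.3` this puts
  the interval entirely above the point estimate and collapses coverage of
  the true `N` to ≈0.26.
- Weighting pairs by parent copy multiplicity over-disperses (bootstrap sd
  ≈200 against a true sampling sd of ≈75 at `n = 120`) and pushes coverage
  to ≈1.0.
- The adopted rule: each resampled juvenile **row carries its pair status**
  (father sampled / mother sampled) from the original subsample. This keeps
  `m ≤ n_J` in every resample, centres the bootstrap distribution on the
  point estimate, and matches the true sampling distribution best
  (bootstrap sd ≈58 vs true ≈75 at `n = 120`).

Resamples whose pair count falls to zero are degenerate: dropped, counted
and reported (`n_valid + n_degenerate = n_boot`). If fewer than
`min_valid_fraction` (default 50%) of resamples are valid the interval is
refused with `DegenerateBootstrapError` — the subsample is too sparse for
interval estimation.

Known limitation: the residual gap between bootstrap and true sd comes from
sibling clustering (juveniles sharing a parent make the pair indicators
positively correlated), which an iid row bootstrap cannot see, partly offset
by its ignoring the finite-population correction. Together with the
estimator's positive skew this leaves the 95% percentile interval mildly
anti-conservative: measured coverage at `n/N = 0.3` is ≈0.89 (1,000
replicates), with misses dominated by intervals lying entirely above `N`.
BCa or studentized corrections would address the skew but are deliberately
out of scope; the package ships the plain percentile interval.

## Synthetic populations

`generate_population` builds a single-generation pedigree: `N_M` founder
males and `N_F` founder females; each mother's litter size is
Poisson(`offspring_rate`, default λ = 2); each offspring's father is uniform
over the adult males, independently; offspring sex is uniform (carried for
realism; the estimators treat juveniles as one class). The standard
validation scenario uses 100 males, 100 females and a juvenile total fixed
at 200 (N = 400).

"200 juveniles" and "Poisson litters" cannot both hold exactly, so both
readings are available: the default `N_J=None` mode keeps honest Poisson
totals, while `N_J=200` conditions the litter vector on its sum by rejection
sampling, reproducing the fixed N = 400 setup used throughout validation.

Subsampling is without replacement (a harvested animal is harvested once);
replacement exists only inside the bootstrap. The "shot together" scheme
models family groups harvested jointly: individuals are visited in uniform
random order, and whenever a juvenile enters the sample its mother and
father each join with probability `b` (independently; an alternative
`single` mode instead pulls one uniformly chosen parent with probability
`b`). The draw stops at exactly `n`, truncating pending parent additions.
`b = 0` reduces to uniform sampling; at `b = 1` every non-truncated juvenile
has both parents sampled. The `b = 0.5` semantics of co-harvest are
ambiguous between the two modes; `independent` is the default and the two
should be compared, not assumed identical.

What the simulator does **not** emulate: spatial structure and spatially
correlated harvest, multi-year dynamics and overlapping generations, age
structure beyond adult/juvenile, non-Poisson litter overdispersion, and
migration. Passing tests therefore demonstrate the estimator's properties
under idealized random (or parametrically biased) harvest of a closed
population, not robustness to real hunting-bag selectivity.

## Monte Carlo validation

The headline statistic is the relative bias `N̂/N`, summarized as the mean
over estimable replicates; estimability itself is reported, never silently
conditioned away. Experiments (all reproducible from one seed):

- `sweep_subsample_size`: one subsample per `n` on a fixed population over
  `n = 20…360` (`n/N` from 0.05 to 0.9), with intervals — the scatter view.
- `replicate_estimates`: many subsamples at fixed `n` — used for replicate
  means, since a single draw per grid point cannot pin down a bias curve.
- `coverage_experiment`: fresh population per replicate, interval from 200
  resamples, coverage = fraction of estimable replicates whose interval
  contains `N`.
- `nonrandom_bias_experiment`: fixed `n = 50`, grid over `b`.
- `pairs_vs_bias_summary`: relative bias against the total number of pairs
  per sample, with binned means.

Problem sizes used by the shipped validation runs — 300–1,000 replicates per
condition, 200 bootstrap resamples — keep every experiment in the seconds
range while leaving Monte Carlo standard errors well below the widths of the
bands being checked.

Measured behaviour on the standard population: the estimator converges to
unbiasedness from above as `n/N` grows (mean `N̂/N` ≈ 1.01 at `n/N = 0.5`,
≈1.3 at `n/N` = 0.125), and under certain co-harvest (`b = 1`, `n = 50`) it
collapses to ≈0.13 — co-harvested families make pairs vastly over-frequent,
so the population is drastically underestimated. A caution at the other
extreme: at very small subsample fractions the conditioning on `m ≥ 1` caps
the estimate — at `n = 20` the algebraic maximum of `N̂` is
`n_J(n_M+n_F) + n_J² ≤ 380 < 400` — so conditional on being estimable the
estimator is strongly **negatively** biased there (mean ≈0.44 at
`n/N = 0.05`), and only ≈14% of such draws are estimable at all. Smoothed
single-draw scatters can mask this edge effect; the replicate-mean summaries
here expose it. Practical reading: with so few expected pairs
(`E(m_FC) ≈ 0.5` at `n = 20`) the method should simply not be applied at
such fractions.

## Parentage from genotypes

`simulate_genotypes` draws founder genotypes from locus allele frequencies
(Hardy–Weinberg) and transmits one uniformly chosen allele per parent per
locus; optional uniform-replacement genotyping error and per-call
missingness. `assign_parent_offspring` recovers pairs by Mendelian
exclusion only: a sampled adult is a candidate parent of a sampled juvenile
if they share at least one allele at all but at most `max_mismatch_loci`
(default 0) of the compared loci; loci missing in either member are skipped,
and fewer than `min_compared_loci` (default 5) compared loci blocks
assignment entirely. Per juvenile and parental sex at most one pair is
counted: fewest mismatches wins, ties assign none and emit an
`AmbiguityWarning`. The conservative tie rule is deliberate — false pairs
bias `N̂` downward, so refusing ambiguous assignments preserves the
estimator's documented bias direction.

With error-free genotypes and `max_mismatch_loci = 0` there are no false
negatives; the residual failure mode is a non-parent matching at every
compared locus by chance. For the demonstration panel of 12 loci × 8
equifrequent alleles that probability is `0.412^12 ≈ 2.4 × 10⁻⁵` per
comparison — about one affected trial in seventy for a 50-animal subsample
of the standard population — and it vanishes rapidly with more loci (the
suite's 16 × 10 panel is error-free in practice). These defaults are chosen
for demonstrable near-perfect assignment in simulation; they are not field
recommendations, and likelihood-based assignment software should be used on
real microsatellite data with realistic error rates.
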