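# Methods

This note documents the statistical procedures implemented in `cnatree`,
the choices made where the design was genuinely open, and what the
simulation-based tests do and do not demonstrate.

## Signal model and simulator

A tumor sample is modelled as a mixture of a tumor fraction *p* (purity) and
normal cells.  At a marker with *c* total tumor copies, *b* of them carrying
the B allele, and germline B count *g* ∈ {0, 1, 2}:

* expected LRR = log2((p·c + 2(1−p))/2) — 0 at two copies, diluted toward 0
  as p → 0;
* expected BAF = (p·b + (1−p)·g)/(p·c + 2(1−p)) — 0.5 at balanced
  heterozygotes, diluted toward g/2.

The simulator draws germline genotypes i.i.d. (heterozygous with probability
`genome_het_rate`, default 0.3), adds Gaussian noise on both channels
(`lrr_noise_sd` 0.15 log2 units; `baf_noise_sd` 0.04, homozygotes at a
quarter of that to mimic the tight 0/1 bands), clips BAF to [0, 1], and at
heterozygous loci inside an aberrant segment affects either parental
haplotype with probability ½, producing the mirrored BAF bands seen in real
arrays.  Defaults describe a desk-scale genome — 22 autosomes × 1000 evenly
spaced markers — standing in for a ~240k-marker exome array; purities of
interest span 0.2–0.6, and purity ≤ 0.05 emulates samples with essentially
no tumor cells.  The noise magnitudes are implementer choices (typical of
Illumina arrays); no published marker-level noise model was available.

Features of real data deliberately *not* emulated: GC waves and
probe-specific bias, clustered exome marker spacing (calling operates on
marker indices), genotyping error, and subclonal mixtures of more than one
tumor population.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to array
artefacts.

## Segmentation

Per chromosome, the cost of interval [s, e) is the residual sum of squares
of LRR about its mean plus the RSS of folded BAF (|BAF − 0.5|, heterozygous
markers only) about its mean.  Folding makes the BAF channel sensitive to
allelic imbalance while ignoring which haplotype is affected; restricting it
to the heterozygous range (estimated genome-wide first) stops the 0/1
homozygote bands from swamping the cost.

Candidate breakpoints come from recursive binary splitting (split at the cut
maximizing the cost reduction; recurse to `max_depth` = 6, minimum segment
size 10 markers).  The final set is chosen by exact dynamic programming over
the candidates, minimizing total cost + penalty × (number of breakpoints).
The default penalty is 2σ̂²·log n per breakpoint — BIC-like — with σ̂ the
robust noise scale from the median absolute successive LRR difference
(1.4826·MAD/√2), which is insensitive to the few true level shifts.  Ties
in the DP are broken toward more breakpoints so that a zero penalty retains
every candidate.  The DP is verified against exhaustive subset search in the
tests; on noise-free piecewise-constant input recovery is exact, and the
segmentation is invariant to adding a constant to all LRR values.

## Calling tree

Heterozygous markers are delimited by the two interior local minima of a
Gaussian kernel density (Silverman bandwidth, 512-point grid) of the
genome-wide BAF closest to 0 and to 1; degenerate densities (fewer than two
interior minima, or minima closer than 0.1) fall back to (0.15, 0.85) with a
warning.  Five test nodes then classify each segment:

1. **LOH** — one-sided lower binomial tail of the segment heterozygote count
   at the genome-wide rate.
2. **Parity** (non-LOH) — odd total copy number splits the heterozygous BAF
   band; the node combines a dip test of unimodality with a one-sided
   rank-sum test that the segment's folded BAF exceeds the sample-wide
   heterozygous background, each at half the segment's level.  Either
   significant ⇒ odd.
3. **Even segments** — iterative one-sided Grubbs outlier test on the
   segment LRR medians flags gains (≥ 2 extra copies); survivors pool into
   the copy-neutral LRR reference.  Medians are standardized by their
   sampling scale 1.2533·σ̂/√n_i before testing: raw medians of small and
   large segments have very different variances, and Grubbs' equal-variance
   normality assumption holds only after standardization (without it, null
   genomes showed a several-fold inflated family-wise error through spurious
   small segments).
4. **Odd segments** — a two-one-sided-tests equivalence check (rank-sum
   components, margin δ = 0.1 log2 units, configurable) against the neutral
   reference declares CNLOH; otherwise the median above/below the neutral
   median gives Gain/Loss.  An exactly tied median resolves to CNLOH.
5. **LOH segments** — one-sided rank-sum tests against the reference
   resolve Loss vs Gain; neither significant ⇒ CNLOH.

The per-node forms of the parity rank-sum and the equivalence test are
documented implementation choices; only the test families (dip, Wilcoxon,
Grubbs, binomial, equivalence) are fixed by the procedure's design.

**Multiplicity.**  Segment *i* of size n_i is tested at
α_i = (n_i/Σn_j)·α/M with M = 5, the number of decision nodes (so at most
five tests can touch one segment).  The weights sum to one, hence
M·Σα_i = α and the probability of any false non-Neutral call on a fully
neutral genome is at most α (Bonferroni), conservatively.  Weighting by
segment size spends the budget where the markers are.

**Degenerate inputs.**  Segments under 10 markers are called Neutral with a
low-confidence flag; segments with fewer than 10 heterozygous markers skip
the parity node (treated as even, flagged).  If no copy-neutral reference
segment survives, calling aborts with an error rather than guessing.
Identical track and parameters always yield identical calls — internal
subsampling (density estimation thinning, background caps of 2000 values,
dip subsampling to 500 order statistics) uses deterministic evenly spaced
order statistics.

## The dip statistic and its calibration

No dip implementation was available as a dependency, so the statistic is
implemented here as a *split-unimodality* variant: the smallest sup-norm
distance between the empirical cdf and a function that is a convex
distribution branch left of a mode and a concave branch right of it, with
the mode placed between distinct data values and no slope coupling across
the mode.  Each side reduces to a convex-hull feasibility condition on the
ecdf bands, and the optimal mode is found by bisection (the convex-side gap
grows and the concave-side gap shrinks in the split position), giving
O(n log n) total.  The variant is a lower bound of the classical dip and
coincides with it up to O(1/n) on continuous data; it equals its defining
linear program exactly, which the tests verify case by case, including tied
data.

Because the null distribution depends only on the sample size, critical
values are simulated once per size on a fixed grid (uniform null — the
asymptotically least favourable unimodal distribution; 500 replicates per
grid point, fixed internal seed) and interpolated on the √n-scaled quantile
scale.  The very small weighted-Bonferroni levels are reached by an
exponential fit to the upper tail (exceedances over the 90th percentile),
which is heavier-tailed than the empirical null and therefore conservative.
Since observed and null samples use the same statistic, the resulting test
is correctly (if conservatively) calibrated regardless of the variant's
difference from the classical dip.

## Cytoband summarization

Each marker inherits its segment's state; each cytoband takes the state of
the plurality of its markers.  Votes are weighted by marker count, not
physical span, because the signal lives at the markers and exome arrays are
physically uneven.  Exact ties resolve to Neutral (conservative, matching
the procedure's specificity emphasis); bands without markers are Missing.
The vote provably equals a per-marker tally and is invariant to splitting a
segment into same-state parts.

## Nine-class recurrence model

Cohort counts x_band = (x_L, x_N, x_G) (CNLOH counted as Neutral — the
recurrence model describes loss/neutral/gain only, and recurrent CNLOH is
rare) are modelled as a mixture of nine trinomials, treating the samples as
conditionally independent given the band's class.  EM with 20 random starts
(Dirichlet-initialized component probabilities), relative log-likelihood
tolerance 1e-8, at most 2000 iterations; the log-likelihood is monotone and
non-convergence returns the best iterate with a flag.

Components are fitted unconstrained and then assigned to the 3×3
loss-by-gain grid.  The grid structure implies per-component propensities
a = λ/(1−γ) and c = γ/(1−λ) taking one of three values each (a per loss
level, c per gain level) — the reference parameterization satisfies this
product structure to printed precision.  Assignment alternates between
estimating the three row and three column propensities from the current
labels and re-solving the 9×9 linear assignment of components to cells under
a squared propensity distance; this is robust where a plain tercile split of
the loss probabilities misorders overlapping components (which demonstrably
happens for some count realizations).

Bands are allocated to components by maximum posterior probability (ties to
the lowest index).  The (loss = high, gain = low) component defines the
exclusively deleted bands; (loss = low, gain = high) the exclusively
amplified ones.  For downstream analyses, contradictory rare states on
exclusive bands are collapsed to Neutral (losses on exclusively amplified
bands, gains on exclusively deleted bands).

## Latent-class clustering with variable selection

Samples are clustered on the collapsed three-state matrix over candidate
bands.  In the model, *relevant* bands have cluster-specific multinomials
and *irrelevant* bands one shared multinomial, which factors out of the
mixture likelihood.  BIC = 2·log L − ν·log S (larger is better) with
ν = (K−1) + 2(K·|relevant| + |irrelevant|).

Model search, for each K in 1..6: start with all bands relevant; repeatedly
move the band whose removal most improves the expected BIC (computed from
the current posteriors) to the irrelevant set, accepting a move only if the
exactly refitted BIC improves; at each sweep's fixed point, refit the pruned
model from fresh multi-starts and resume if that improves BIC.  EM starts
seed the clusters with K random samples and soft-assign the rest by Hamming
distance, which locates good optima far more reliably than unstructured
random responsibilities; warm-started refits alone can lock in a poor
partition, which is why the fresh-restart refresh is part of the loop.
Empty clusters trigger a restart; if every start degenerates the best fit is
returned flagged.  The selected (K, relevant set) maximizes BIC over
everything visited, which the tests assert, along with K = 1 on
structureless data, exclusion of pure-noise bands, and local optimality
against single-band swaps.

## Verification scale and determinism

The acceptance-style checks run at desk scale: 400 null genomes of
22 × 1000 markers for the family-wise error rate (bound
0.05 + 2·√(0.05·0.95/400) ≈ 0.072); 768 bands × 42 samples for nine-class
parameter recovery (±5 percentage points on the exclusively-deleted
component's loss probability); three-state cohorts of 42 samples × 140 bands
(clusters of 10/20/12; cluster-defining state probability 0.8, background
aberration rate 0.05 per state) for clustering recovery.  These sizes keep
the full suite within a few minutes while leaving the statistical margins
comfortable.  Every stochastic step is seeded; the acceptance script derives
all seeds from its `--seed` argument.

## Known limitations

* Absolute copy number, ploidy and purity are not estimated (no ASCAT-style
  fitting); states are relative to the sample's dominant copy-neutral level.
  A genome aberrant in its majority would mislead the neutral reference.
* The binomial LOH test treats markers as independent; linkage
  disequilibrium on real arrays makes the effective marker count smaller
  than the nominal one.
* The dip calibration assumes continuous BAF values; heavy ties (e.g.
  quantized BAF) would make the uniform-null calibration conservative.
* Cytoband majority voting can hide focal events far smaller than a band.
* The latent-class model treats bands as conditionally independent within a
  cluster; chromosome-scale events violate this, which BIC partially absorbs
  into extra clusters.
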