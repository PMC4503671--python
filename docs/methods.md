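# Methods

## The three-category hitchhiking clock

The analytic core classifies mutations as adaptive, harmful or neutral and
tracks two bookkeeping levels. Per genome, neutral mutations accumulate at
`μL(1−α−β)` per generation. Per population, adaptive mutations arise at
`μLαN` per generation; each successful one fixes the neutral mutations that
accumulated on its genome since the previous sweep, `(1−α−β)/(αN)` of them
in expectation. Multiplying supply by passengers gives back `μL(1−α−β)`
exactly — the identity is algebraic, so `neutral_population_rate` is
implemented *as* `neutral_genome_rate` and the equality is bit-for-bit, not
approximate.

Assumptions inherited from the model: α is the fraction of mutations that
actually come to dominate (post-interference), not the raw beneficial
fraction; adaptive mutations strike non-synonymous sites only, so the
category-resolved adaptive supply uses `Ln`; synonymous mutations are
treated as strictly neutral; epistasis is collapsed into the averaged
"neutral" category. Two printed quantities are mutually inconsistent in the
source material: the adaptive fixation rate `μ·Ln·α·N = 0.006` and the
observed interval 4419 generations / 20 events ≈ 221 (whose inverse is
0.0045). The package computes the model rate as 0.006 and reports the
empirical 221-generation interval separately, without reconciling them.

Estimation inverts the passenger counts: `α = (Ls/Ln)/(N·k_s)` from the
synonymous passengers per sweep `k_s`, then
`β = 1 − α − k_n·αN` from the non-synonymous passengers `k_n`. β outside
[0, 1] signals counts inconsistent with the model; the value is clamped and
a warning raised. Reported estimates carry both the unrounded value and a
rendering at the conventional printed precision (one significant figure for
rates and α, two decimals for β), rounded half-away-from-zero.

The drift boundary uses the escape probability `(1−μLNα)^N` (clamped to
[0, 1]; defined as 0 once `μLNα ≥ 1`). The largest N meeting a target
escape probability is found by integer bisection on [1, 10¹²] — the
function is monotone in N, so the answer is exact; a power-of-ten rendering
`10^⌊log₁₀N*⌋` is attached.

The fluctuation test uses the p0 method: with mutational events per culture
Poisson distributed, the empty-plate fraction estimates `P0 = e^{−m}`, and
the rate is `m/(n_final − n_initial)` per cell per generation. No
per-division correction factor is applied; the estimator is exactly the
fraction-of-empty-plates statistic.

## The simulator

`simulate_wright_fisher` is a forward-time haploid Wright–Fisher model with
constant population size: each generation, genotype counts are multinomially
resampled with probabilities proportional to `count × fitness`, then
`Poisson(μ(ls+ln)·N)` new mutations are placed on randomly chosen genomes.
A genotype is a set of mutation identifiers plus a log-fitness — genome
strings are never stored, because only frequencies and co-residence matter
for hitchhiking. Fitness is multiplicative: `×(1+s_adaptive)` per adaptive,
`×(1+s_harmful)` per harmful mutation. New mutations are synonymous with
probability `ls/(ls+ln)` (always neutral) and otherwise non-synonymous
(adaptive with probability α, harmful with probability β, else neutral).
There is no recombination, no bottleneck/serial-transfer structure, no
explicitly evolving mutator modifier and no epistasis; the elevated μ is a
fixed input.

Truth bookkeeping: fixation is recorded when every genome carries the
mutation (checked on the sampling grid, so fixation generations are
quantized to `sample_every`; this shifts intercepts, never slopes). When an
adaptive mutation arises, the identities of all mutations resident on its
genome are stored; after the run, sweeps that reached majority (>50%) claim
— in chronological order — the not-yet-claimed residents as their cluster
and passenger set, and failed sweeps then label whatever unclaimed residents
died with them. Claiming at arise time instead (the obvious alternative)
lets doomed adaptive mutations steal passengers from the real sweep arising
later on the same background and biases passengers-per-sweep several-fold
low. The realized α (sweeps reaching majority / adaptive arisings) is
reported per run, since input α is a pre-interference quantity.

The observation layer mimics Sanger peak-ratio measurement. Detection
follows the **true** minor-peak height: a true frequency below the 5%
detection floor produces no reading (censored, never zero), because an
absent peak cannot yield a quantification; the 6.2% SD is quantification
noise added to detected values and clipped to [0, 1], and measured values
falling below the floor are likewise censored. Values above the 95%
saturation ceiling are reported as exactly 100%, reflecting the assay's
inability to resolve residual wild type. Frequencies are fractions
internally and percent only in the TSV dialect.

Default configuration (popsize 5000, μ = 10⁻⁵/bp, 300 synonymous + 700
non-synonymous sites, α = 0.005, β = 0.4, s_adaptive = 0.05, 20000
generations, sampling every 200): a desk-scale stand-in for ~10⁻⁸/bp
mutagenesis of an Mbp genome at N ≈ 10⁷, chosen so that `μ(ls+ln) = 0.01`
per genome and sweeps recur on a few-hundred-generation timescale. The
model's predictions depend on the products μL and αN, so conclusions
transfer across scale; what does *not* transfer is discussed under
limitations.

## Trajectory analysis

The S2-dialect TSV carries one row per mutation (`mutation_id`, `gene`,
`category`, optional `cluster`) and one percent-valued column per sampled
generation, with `<5`-style cells for censored observations. Loading
validates monotone generations, unique ids, categories and the [0, 100]%
range; censored cells stay flagged rather than zeroed, but are treated as 0
for distances and plotting.

Clustering is agglomerative single linkage under the Chebyshev distance
`d(i,j) = max_t |f_i(t) − f_j(t)|`, merging while `d ≤ tolerance`; the
default tolerance 0.124 is two Sanger SDs. Rows are sorted lexicographically
by mutation id before linkage, making the partition a pure function of the
(table, tolerance) pair, invariant to row order, and single linkage makes
partitions nest as the tolerance grows. Cluster means average members with
censored cells as 0; the standard error falls back to the Sanger SD 0.062
for singletons, which have no between-member spread.

Lineage reconstruction exploits the asexual containment property: a
descendant genome's frequency can never exceed its ancestor's, so a
descendant cluster's mean trajectory is bounded by its ancestor's. Clusters
are ordered by onset (first mean above the detection floor; ties broken by
higher total frequency, i.e. the earlier sweeper first) and each attaches
to the latest preceding cluster that bounds it everywhere within twice the
combined standard errors — the 2×SE margin absorbs clipped observation
noise over long post-fixation plateaus. Root-to-leaf paths are lineages.
Fate classification uses the absorbing nature of fixation: a trajectory is
`fixed-in-line` if it ever reached 0.95 and averages ≥ 0.7 from that point
on (a genuine fixer only dips by measurement noise; a cluster declining at
the series end fails the average); `extinct` if its last two points average
at or below the floor; otherwise `interfered`. Clone-count checks ask
whether the carrier count lies in the central 95% region of
`Binomial(n_clones, sanger_frequency)`, with the exact two-sided binomial
p-value attached — a sharper criterion than eyeballing "within one SD".

## The clock regression

Each lineage path is walked in onset order, stopping at the first cluster
that did not fix in the line (its descendants die with it). Every fixed
cluster contributes one point at the generation its mean first exceeds 10%
(sampled time points only, no interpolation), carrying the cumulative
category counts along the path; points shared through common ancestry are
emitted once, and a zero-count anchor at the baseline generation (default
5212) is always included. Ordinary least squares with an intercept gives
slope, two-sided p for slope ≠ 0 and the per-site rate `slope / site count`
(defaults `Ls = 0.96×10⁶`, `Ln = 3.2×10⁶`; non-coding counts are reported
without per-site normalization). A through-origin variant on
`generation − baseline` is available behind a flag for sensitivity; the
default keeps the intercept since the baseline zero point is counted as an
ordinary observation. `compare_to_spontaneous` reports `per_site_rate/μ`
and flags ratios within one order of magnitude.

## Problem sizes used by the tests

All statistical checks run at desk scale, sized to keep the suite fast
while leaving the tested property scale-free:

- **Clock parameter recovery** (cumulative fixed synonymous count slope =
  `μ·ls` within 2 SE): 20 replicates of popsize 1000, `μ(ls+ln) = 0.02`,
  α = 0.005, s = 0.05, 4000 generations — the clonal-interference regime,
  where the identity is least obvious and still holds.
- **Clustering truth recovery** (≥ 95% of hitchhiked mutations pooled over
  20 noise-free replicates): popsize 20000, `μ = 2.5×10⁻⁶`, α = 10⁻⁴,
  s = 0.15, 8000 generations, sampling every 100. This regime is chosen to
  be the one the motivating experiment occupies: the detection floor (5% of
  N = 1000 copies) sits far above typical neutral drift excursions, and
  sweeps are resolved by the sampling grid.
- **p0 calibration**: 10⁴ simulated cultures at m = 1 expected event.
- The noisy end-to-end pipeline check uses sparse sampling (every 400
  generations over 6000) with the full 6.2% observation noise and asserts
  same-order recovery of μ.

## What the generator does and does not emulate

It reproduces the statistical structure that the analysis depends on —
rare sweeps carrying co-resident neutral passengers, clonal interference,
censored/saturated noisy frequency observations on a sparse grid. It does
not emulate daily serial-transfer bottlenecks, environmental (temperature)
dynamics, epistatic fitness compensation, recombination or an evolving
mutator allele. Passing tests therefore demonstrate the method's internal
correctness and the clock property under the stated model, not robustness
to those omitted features.

Desk scale introduces two artifacts absent at experimental scale, both
documented by the test regimes above: neutral pre-sweep drift can rise
above the detection floor in small populations, giving same-cluster members
visibly different early trajectories, and consecutive sweeps can cross the
detection threshold within one sampling gap and merge. Both artifacts
shrink as N grows at fixed μN.

## Numerical choices

- Rounding of rendered estimates is half-away-from-zero (with a 10⁻¹²
  guard against binary-representation edge cases).
- The threshold solver brackets [1, 10¹²] and raises when no population
  size meets the target.
- Clustering tie-breaks: lexicographic mutation-id order; cluster ids are
  assigned in onset order.
- Cluster onset is the first sampled generation with mean above the floor;
  clusters never detected sort last and become single-cluster extinct
  lineages.
- Degenerate inputs raise: empty tables, fewer than 3 clock points, all
  points at one generation, α·N = 0 passenger counts, p0 with no empty
  plates.

## Known limitations

- The noisy end-to-end reconstruction mildly *under*estimates the clock
  rate (observed ratios ~0.7–1.0 of μ across seeds): observation noise
  occasionally fragments clusters or truncates lineage chains, dropping
  late counts. The motivating experiment's own reconstruction sits at a
  ratio of 0.7, so this behavior is realistic rather than surprising.
- The clustering criterion (Chebyshev + single linkage at 2 SD) is one
  defensible reading of "concurrent frequency changes"; the tolerance is
  exposed everywhere and the partition should be treated as
  tolerance-conditional.
- `estimate_beta` propagates no uncertainty; counts are treated as exact.
- The simulator's fixation log is quantized to the sampling interval.
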