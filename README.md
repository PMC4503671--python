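# hitchclock

**The molecular clock of neutral mutations in adaptive, fitness-increasing
evolution — run by genetic hitchhiking rather than drift.**

In a large asexual population under strong selection (the motivating system
is a mutator *E. coli* population adapting to near-lethal temperature over
thousands of generations), neutral mutations cannot drift to fixation: any
drifting allele is swept out — or dragged along — by the next adaptive
mutation that rises to dominance. Yet sequencing time courses of such
populations show mutations fixing at a steady, clock-like rate equal to the
spontaneous mutation accumulation rate. `hitchclock` implements the analytic
model, the simulation machinery and the data analysis that together explain
and test this: every genome accumulates neutral mutations at rate μL, only
one genome occasionally gains the adaptive mutation that sweeps, and the
neutral passengers resident on that genome hitchhike to fixation — so the
*population-level* neutral fixation rate collapses back to the *genome-level*
spontaneous rate.

The package is for evolutionary biologists and population geneticists working
with allele-frequency time courses from evolution experiments (and for anyone
who wants a compact, tested forward simulator of sweeps with clonal
interference).

## The model

Mutations are classified adaptive (fraction α, defined as triggering a
sweep), harmful (fraction β, purged) or neutral (the rest). With spontaneous
rate μ per bp per generation, genome target L, and population size N:

- per-genome neutral accumulation: `R_Neutral_Genome = μL(1−α−β)`
- population adaptive supply: `R_Adaptive_Population = μLαN`
  (with non-synonymous targeting, `μ Ln α N`)
- neutral passengers fixed per sweep: `N_Neutral_Hitchhike = (1−α−β)/(αN)`
- population neutral fixation rate:
  `R_Neutral_Population = μLαN · (1−α−β)/(αN) = μL(1−α−β) = R_Neutral_Genome`

The last identity is the hitchhiking molecular clock. Resolved by site
category (`Ls` synonymous, `Ln` non-synonymous sites), the passenger counts
`Ls/(Ln·αN)` and `(1−α−β)/(αN)` can be inverted to estimate α and β from
observed fixation counts. A companion drift analysis gives the probability
`(1−μLNα)^N` that a drifting neutral mutation escapes hitchhiking for the ~N
generations drift fixation takes, and the population-size threshold below
which drift, not hitchhiking, runs the clock.

## Modules

- `hitchclock.core_model` — the rates, estimators, drift threshold, and a
  p0-method (Luria–Delbrück) fluctuation-test estimator of μ.
- `hitchclock.simulator` — forward Wright–Fisher simulation of an asexual
  population (genotypes = mutation sets, multiplicative fitness, Poisson
  mutation, multinomial resampling) with a Sanger-like observation layer
  (6.2% noise SD, 5% detection floor, ≥95% reported as fixed).
- `hitchclock.trajectories` — S2-dialect TSV I/O for frequency time courses,
  single-linkage co-fixation clustering (Chebyshev distance, default
  tolerance two Sanger SDs), genome-lineage reconstruction by frequency-
  envelope nesting, and exact-binomial clone-count consistency checks.
- `hitchclock.clock` — cumulative fixed-mutation counts at lineage
  10%-crossing generations and the least-squares molecular-clock fit with
  per-site rates.
- `hitchclock.cli_io` — configuration, run manifests, and the `hitchclock`
  command-line interface (`simulate`, `cluster`, `lineages`, `clock`,
  `estimate`, `threshold`, `pipeline`).

## Worked example

Estimating the model parameters from the experiment's pooled counts — 32
synonymous and 62 non-synonymous mutations fixed through 20 sweeps, N = 10⁷,
Ls = 0.96 Mbp, Ln = 3.2 Mbp, μ = 10⁻⁸:

```sh
hitchclock estimate --syn 32 --nonsyn 62 --hitchhikes 20 \
    --N 1e7 --ls 0.96e6 --ln 3.2e6 --mu 1e-8
```

prints (abridged):

```json
{
  "alpha_rendered": "2e-08",
  "beta_rendered": "0.42",
  "syn_per_hitchhike": 1.6,
  "nonsyn_per_hitchhike": 3.1,
  "r_neutral_synonymous_rendered": "0.01",
  "r_neutral_nonsynonymous_rendered": "0.02",
  "r_adaptive_population_rendered": "0.006",
  "mean_sweep_interval": 220.95,
  "drift_threshold_popsize": 32909,
  "drift_threshold_power_of_ten": 10000.0
}
```

Read: each sweep fixed on average 1.6 synonymous and 3.1 non-synonymous
neutral passengers; inverting those counts says only α ≈ 2×10⁻⁸ of mutations
trigger sweeps while β ≈ 0.42 of non-synonymous mutations are purged as
harmful; genomes accumulate neutral mutations (0.01 + 0.02 per generation)
faster than the population fixes adaptive ones (0.006 per generation,
one sweep every ~221 generations observed); and drift could only run the
clock in populations of order 10⁴ or smaller.

The full synthetic pipeline — simulate a mutator population, observe it
through Sanger-like noise, recluster, rebuild lineages and refit the clock:

```sh
hitchclock pipeline --config examples/demo.yaml --seed 1 --out demo_run/
```

logs `rows=399 … clusters=41 … points=31` and writes `clockfit.json`, whose
synonymous fit recovers a per-site rate of 2.39×10⁻⁵ against the configured
spontaneous rate 2×10⁻⁵ (ratio 1.19, same order) — the clock property
reproduced from noisy frequency data alone.

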