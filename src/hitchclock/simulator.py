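"""Forward-time Wright-Fisher simulation of hitchhiking sweeps.

Generates synthetic data with the statistical structure of a mutator-driven
asexual evolution experiment: an haploid population of constant size under
multinomial resampling, Poisson mutation pressure split into synonymous
(always neutral) and non-synonymous sites (adaptive with probability
``alpha``, harmful with probability ``beta``, else neutral), multiplicative
fitness, no recombination.  Rare adaptive mutations sweep and drag their
genome's resident neutral mutations to fixation; concurrent sweeps produce
clonal interference.  A Sanger-like observation layer (additive noise,
detection floor, saturation ceiling, sparse sampling) turns the true
frequencies into the kind of trajectory table the experiment reports.

Genotypes are represented as sets of mutation ids with a log-fitness, not as
genome strings: only frequencies and co-residence matter for hitchhiking.
Parameters are desk-scale by default — a much smaller population and a
correspondingly inflated per-genome mutation rate — which preserves the
model's predictions because they depend only on the products mu*L and
alpha*N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trajectories import TrajectoryTable

__all__ = [
    "SimulationConfig",
    "MutationRecord",
    "HitchhikeEvent",
    "SimulationResult",
    "simulate_wright_fisher",
    "observe_sanger",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale study conditions for one simulated evolution run.

    Defaults give a per-genome mutation rate ``mu*(ls+ln) = 0.01`` in a
    population of 5000 over 20000 generations — the scaled stand-in for
    ~1e-8/bp mutagenesis of an Mbp genome at N ~ 1e7.  ``alpha`` and
    ``beta`` apply to non-synonymous mutations only; synonymous mutations
    are always neutral.  Observation constants mirror Sanger peak-ratio
    measurement: noise SD 6.2%, 5% detection floor, >95% reported as fixed.
    """

    popsize: int = 5000
    mu: float = 1e-5
    ls: int = 300
    ln: int = 700
    alpha: float = 0.005
    beta: float = 0.4
    s_adaptive: float = 0.05
    s_harmful: float = -0.02
    generations: int = 20000
    sample_every: int = 200
    detection_floor: float = 0.05
    saturation_ceiling: float = 0.95
    obs_sd: float = 0.062
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.popsize < 10:
            raise ValueError("popsize must be >= 10")
        if self.mu < 0 or self.ls <= 0 or self.ln <= 0:
            raise ValueError("mu must be >= 0 and ls, ln > 0")
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta > 1:
            raise ValueError("need alpha, beta >= 0 and alpha + beta <= 1")
        if not self.s_adaptive > 0 >= self.s_harmful:
            raise ValueError("need s_adaptive > 0 >= s_harmful")
        if not 0 < self.detection_floor < self.saturation_ceiling < 1:
            raise ValueError("need 0 < detection_floor < saturation_ceiling < 1")
        if self.generations < 1 or self.sample_every < 1:
            raise ValueError("generations and sample_every must be >= 1")

    @property
    def genome_rate(self) -> float:
        """Total mutations per genome per generation, mu*(ls+ln)."""
        return self.mu * (self.ls + self.ln)


@dataclass
class MutationRecord:
    """Truth bookkeeping for one mutation."""

    category: str  # 'synonymous' | 'non-synonymous'
    effect: str  # 'neutral' | 'adaptive' | 'harmful'
    origin_generation: int
    cluster: Optional[int] = None
    fixed_generation: Optional[int] = None


@dataclass
class HitchhikeEvent:
    """An adaptive mutation arising with its resident neutral passengers.

    ``passengers`` counts the neutral mutations co-resident on the genome at
    onset that no earlier successful sweep had already claimed — the set
    that will hitchhike if this sweep wins.  ``swept`` is True if the
    adaptive mutation ever reached majority (> 50%).
    """

    generation: int
    adaptive_id: str
    passengers: int
    cluster: int
    swept: bool = False


@dataclass
class SimulationResult:
    """Simulated truth plus the noisy observed trajectory table."""

    observed: TrajectoryTable
    truth_clusters: dict[str, Optional[int]]
    hitchhike_events: list[HitchhikeEvent]
    true_frequencies: pd.DataFrame
    mutations: dict[str, MutationRecord]
    config: SimulationConfig

    def __post_init__(self) -> None:
        missing = set(self.observed.mutation_ids) - set(self.mutations)
        if missing:
            raise ValueError(f"observed mutations absent from truth: {missing}")
        vals = self.true_frequencies.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("true frequencies must lie in [0, 1]")

    @property
    def n_sweeps(self) -> int:
        """Adaptive mutations that actually reached majority."""
        return sum(e.swept for e in self.hitchhike_events)

    @property
    def realized_alpha(self) -> float:
        """Fraction of arising adaptive mutations that swept to majority.

        The model's alpha counts only sweeps that dominate; clonal
        interference makes this smaller than the input beneficial fraction.
        """
        if not self.hitchhike_events:
            return float("nan")
        return self.n_sweeps / len(self.hitchhike_events)

    def fixed_counts_by_generation(self) -> pd.DataFrame:
        """Cumulative fixed-mutation counts per category at each sample point."""
        gens = [int(g) for g in self.true_frequencies.columns]
        cats = ("synonymous", "non-synonymous")
        out = {c: [] for c in cats}
        for g in gens:
            for c in cats:
                out[c].append(
                    sum(
                        1
                        for r in self.mutations.values()
                        if r.category == c
                        and r.fixed_generation is not None
                        and r.fixed_generation <= g
                    )
                )
        return pd.DataFrame(out, index=pd.Index(gens, name="generation"))


def _mutation_id(i: int) -> str:
    return f"m{i:05d}"


def simulate_wright_fisher(config: SimulationConfig) -> SimulationResult:
    """Run one seeded Wright-Fisher hitchhiking simulation.

    Per generation: multinomial resampling of genotype counts weighted by
    multiplicative fitness, then Poisson(mu*(ls+ln)*N) new mutations, each
    placed on a random surviving genome.  An adaptive mutation opens a new
    truth cluster that also claims every not-yet-claimed, not-yet-fixed
    mutation resident on its genome (they will hitchhike if it sweeps).
    Mutation frequencies are recorded every ``sample_every`` generations;
    a mutation enters the reported tables once its true frequency exceeds
    the detection floor at some sample point, or it fixes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    N = cfg.popsize
    u_total = cfg.genome_rate
    p_syn = cfg.ls / (cfg.ls + cfg.ln)

    expected_arising = u_total * (cfg.ln / (cfg.ls + cfg.ln)) * cfg.alpha * N
    expected_sweeps = expected_arising * min(1.0, 2 * cfg.s_adaptive) * cfg.generations
    if expected_sweeps > cfg.generations / 10:
        warnings.warn(
            "interference-saturated regime: expected sweep count "
            f"{expected_sweeps:.0f} exceeds generations/10",
            stacklevel=2,
        )

    gsets: list[frozenset[str]] = [frozenset()]
    logw = np.zeros(1)
    counts = np.array([N], dtype=np.int64)

    records: dict[str, MutationRecord] = {}
    events: list[HitchhikeEvent] = []
    resident_sets: list[frozenset[str]] = []  # parallel to events
    samples: dict[int, dict[str, float]] = {0: {}}
    next_mid = 0
    next_cluster = 0
    log_adaptive = np.log1p(cfg.s_adaptive)
    log_harmful = np.log1p(cfg.s_harmful)

    def bookkeep(gen: int, sample: bool) -> None:
        nonlocal gsets
        carrier: dict[str, int] = {}
        for g, c in zip(gsets, counts):
            for m in g:
                carrier[m] = carrier.get(m, 0) + int(c)
        newly_fixed = frozenset(m for m, c in carrier.items() if c == N)
        if newly_fixed:
            for m in newly_fixed:
                records[m].fixed_generation = gen
            gsets = [g - newly_fixed for g in gsets]
        if sample:
            samples[gen] = {m: c / N for m, c in carrier.items() if c < N}

    for gen in range(1, cfg.generations + 1):
        # selection + multinomial resampling
        if len(counts) > 1:
            w = np.exp(logw - logw.max())
            prob = counts * w
            counts = rng.multinomial(N, prob / prob.sum())
            alive = counts > 0
            if not alive.all():
                counts = counts[alive]
                logw = logw[alive]
                gsets = [g for g, a in zip(gsets, alive) if a]

        # mutation
        n_new = rng.poisson(u_total * N)
        if n_new:
            k = len(counts)
            parents = rng.choice(k, size=n_new, p=counts / N)
            u_cat = rng.random(n_new)
            u_eff = rng.random(n_new)
            new_sets: list[frozenset[str]] = []
            new_logw: list[float] = []
            for pi, uc, ue in zip(parents, u_cat, u_eff):
                if counts[pi] == 0:
                    continue  # parent genotype exhausted by an earlier mutation
                mid = _mutation_id(next_mid)
                next_mid += 1
                if uc < p_syn:
                    category, effect, dlw = "synonymous", "neutral", 0.0
                elif ue < cfg.alpha:
                    category, effect, dlw = "non-synonymous", "adaptive", log_adaptive
                elif ue < cfg.alpha + cfg.beta:
                    category, effect, dlw = "non-synonymous", "harmful", log_harmful
                else:
                    category, effect, dlw = "non-synonymous", "neutral", 0.0
                parent_set = gsets[pi]
                cluster = None
                if effect == "adaptive":
                    cluster = next_cluster
                    next_cluster += 1
                    events.append(
                        HitchhikeEvent(
                            generation=gen,
                            adaptive_id=mid,
                            passengers=0,  # resolved after the run
                            cluster=cluster,
                        )
                    )
                    resident_sets.append(parent_set)
                records[mid] = MutationRecord(
                    category=category,
                    effect=effect,
                    origin_generation=gen,
                    cluster=cluster,
                )
                counts[pi] -= 1
                new_sets.append(parent_set | {mid})
                new_logw.append(logw[pi] + dlw)
            if new_sets:
                gsets.extend(new_sets)
                logw = np.concatenate([logw, np.array(new_logw)])
                counts = np.concatenate(
                    [counts, np.ones(len(new_sets), dtype=np.int64)]
                )
                alive = counts > 0
                if not alive.all():
                    counts = counts[alive]
                    logw = logw[alive]
                    gsets = [g for g, a in zip(gsets, alive) if a]

        if gen % cfg.sample_every == 0 or gen == cfg.generations:
            bookkeep(gen, sample=True)

    # assemble truth frequency matrix over the sample grid
    sample_gens = sorted(samples)
    tracked = sorted(
        {
            m
            for gen in sample_gens
            for m, f in samples[gen].items()
            if f >= cfg.detection_floor
        }
        | {m for m, r in records.items() if r.fixed_generation is not None}
    )
    true_freq = np.zeros((len(tracked), len(sample_gens)))
    for j, gen in enumerate(sample_gens):
        snap = samples[gen]
        for i, m in enumerate(tracked):
            fg = records[m].fixed_generation
            if fg is not None and fg <= gen:
                true_freq[i, j] = 1.0
            else:
                true_freq[i, j] = snap.get(m, 0.0)
    true_frequencies = pd.DataFrame(
        true_freq,
        index=pd.Index(tracked, name="mutation_id"),
        columns=sample_gens,
    )

    # a sweep "succeeded" if its adaptive mutation ever reached majority
    for ev in events:
        row = (
            true_frequencies.loc[ev.adaptive_id]
            if ev.adaptive_id in true_frequencies.index
            else None
        )
        ev.swept = row is not None and bool((row > 0.5).any())

    # Passenger/cluster resolution.  Successful sweeps claim, in
    # chronological order, the not-yet-claimed mutations resident on their
    # genome at onset: those are the mutations that hitchhike with them.
    # Failed sweeps then label whatever unclaimed residents died with them.
    for ev, resident in zip(events, resident_sets):
        if not ev.swept:
            continue
        ev.passengers = 0
        for m in resident:
            rec = records[m]
            if rec.cluster is None:
                rec.cluster = ev.cluster
                if rec.effect == "neutral":
                    ev.passengers += 1
    for ev, resident in zip(events, resident_sets):
        if ev.swept:
            continue
        ev.passengers = 0
        for m in resident:
            rec = records[m]
            if rec.cluster is None:
                rec.cluster = ev.cluster
                if rec.effect == "neutral":
                    ev.passengers += 1

    observed = observe_sanger(true_frequencies, cfg, rng=rng, records=records)
    return SimulationResult(
        observed=observed,
        truth_clusters={m: records[m].cluster for m in tracked},
        hitchhike_events=events,
        true_frequencies=true_frequencies,
        mutations=records,
        config=cfg,
    )


def observe_sanger(
    true_frequencies: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    records: Optional[dict[str, MutationRecord]] = None,
) -> TrajectoryTable:
    """Apply the Sanger-like observation model to true frequency series.

    Additive Gaussian noise (SD ``obs_sd``) clipped to [0, 1]; values above
    ``saturation_ceiling`` report as exactly 1.0 (the peak ratio can no
    longer resolve residual wild type); censored — flagged below-limit, not
    zeroed — wherever the mutant allele is undetectable.  Detection follows
    the true minor-peak height: a true frequency below ``detection_floor``
    produces no measurable peak at all (the noise SD describes
    quantification error of a detected peak, not spurious signal), and a
    measured value that lands below the floor is likewise not reportable.
    With ``obs_sd = 0`` the output equals the input wherever it is above
    the floor.
    """
    vals = true_frequencies.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("true frequencies must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noisy = vals.copy()
    if config.obs_sd > 0:
        noisy = np.clip(noisy + rng.normal(0.0, config.obs_sd, vals.shape), 0.0, 1.0)
    censored = (vals < config.detection_floor) | (noisy < config.detection_floor)
    noisy[noisy > config.saturation_ceiling] = 1.0
    noisy[censored] = np.nan

    ids = list(true_frequencies.index)
    if records is None:
        categories = ["non-coding"] * len(ids)
        clusters = [None] * len(ids)
    else:
        categories = [records[m].category for m in ids]
        clusters = [
            None if records[m].cluster is None else f"T{records[m].cluster}"
            for m in ids
        ]
    meta = pd.DataFrame(
        {
            "gene": [f"locus_{m}" for m in ids],
            "category": categories,
            "cluster": clusters,
        },
        index=pd.Index(ids, name="mutation_id"),
    )
    gens = [int(g) for g in true_frequencies.columns]
    return TrajectoryTable(
        meta=meta,
        freq=pd.DataFrame(noisy, index=meta.index, columns=gens),
        censored=pd.DataFrame(censored, index=meta.index, columns=gens),
    )
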