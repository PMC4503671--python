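"""Analytic model of the hitchhike-driven molecular clock.

In a large asexual population under strong selection, neutral mutations are
fixed not by drift but by riding along with the rare adaptive mutation that
sweeps to dominance.  Classifying mutations as adaptive (fraction ``alpha``),
harmful (fraction ``beta``) or neutral (the remainder), the per-genome neutral
accumulation rate is

    R_Neutral_Genome = mu * L * (1 - alpha - beta)

while the population as a whole gains adaptive mutations at

    R_Adaptive_Population = mu * L * alpha * N.

Each sweep drags along the neutral mutations its genome accumulated since the
previous sweep, ``(1 - alpha - beta) / (alpha * N)`` of them on average, so the
population-level neutral fixation rate collapses back to ``mu*L*(1-alpha-beta)``
— the hitchhiking clock runs at the spontaneous rate, exactly as a drift clock
would.  This module provides those rates, the inversion that estimates ``alpha``
and ``beta`` from observed fixation counts, the drift-vs-hitchhike regime
boundary, and a p0-method fluctuation-test estimator of ``mu``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "ModelParams",
    "RateSet",
    "DriftAssessment",
    "FluctuationCounts",
    "neutral_genome_rate",
    "adaptive_population_rate",
    "neutral_per_hitchhike",
    "neutral_population_rate",
    "estimate_alpha",
    "estimate_beta",
    "drift_escape_probability",
    "drift_threshold_popsize",
    "p0_mutation_rate",
    "rate_set",
    "estimate_from_counts",
    "round_sig",
    "render_sig",
]

Category = Literal["all", "synonymous", "non-synonymous"]

#: Generations of independent propagation pooled over the two lines
#: (5212-7580 shared, then 7581-8829 and 7581-8382).
DEFAULT_TOTAL_GENERATIONS = (7580 - 5212) + (8829 - 7580) + (8382 - 7580)
#: Number of sweep (propagation) events behind the default estimates.
DEFAULT_N_HITCHHIKES = 20


def round_sig(x: float, sig: int = 1) -> float:
    """Round ``x`` to ``sig`` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    decimals = sig - 1 - math.floor(math.log10(abs(x)))
    return round_decimals(x, decimals)


def round_decimals(x: float, decimals: int) -> float:
    """Round to a fixed number of decimals, half away from zero."""
    factor = 10.0 ** decimals
    scaled = abs(x) * factor
    # nudge guards against 2.4999999 artefacts from the scaling itself
    rounded = math.floor(scaled + 0.5 + 1e-12)
    return math.copysign(rounded / factor, x)


def render_sig(x: float, sig: int = 1) -> str:
    """One-line scientific rendering at ``sig`` significant figures."""
    r = round_sig(x, sig)
    if r == 0:
        return "0"
    exponent = math.floor(math.log10(abs(r)))
    if -3 <= exponent <= 3:
        return f"{r:g}"
    mantissa = r / 10.0 ** exponent
    return f"{mantissa:g}e{exponent:+03d}"


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the three-category hitchhiking clock model.

    Parameters
    ----------
    mu : float
        Spontaneous mutation accumulation rate, per bp per generation.
    L : float
        Genome length considered for mutational targets, bp.
    Ls, Ln : float
        Synonymous and non-synonymous site counts, bp.
    alpha : float
        Fraction of mutations that are adaptive, i.e. that trigger a sweep.
    beta : float
        Fraction of mutations that are harmful (purged from the population).
    N : float
        Population size in genomes.
    """

    mu: float
    L: float
    Ls: float
    Ln: float
    alpha: float
    beta: float
    N: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        for name in ("L", "Ls", "Ln", "N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.alpha + self.beta > 1:
            raise ValueError(
                f"alpha + beta must be <= 1, got {self.alpha + self.beta}"
            )

    @property
    def neutral_fraction(self) -> float:
        return 1.0 - self.alpha - self.beta


@dataclass(frozen=True)
class RateSet:
    """The model's rate summary for one parameter set.

    ``r_neutral_population == r_neutral_genome`` always holds: it is the
    model's central identity, not an empirical coincidence.
    """

    r_neutral_genome: float
    r_adaptive_population: float
    n_neutral_per_hitchhike: float
    r_neutral_population: float
    r_neutral_synonymous: float
    r_neutral_nonsynonymous: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_neutral_population != self.r_neutral_genome:
            raise ValueError(
                "r_neutral_population must equal r_neutral_genome exactly"
            )


@dataclass(frozen=True)
class DriftAssessment:
    """Largest population size at which a drift-fixed neutral mutation can
    escape being overtaken by a hitchhiking sweep."""

    escape_probability: float
    threshold_popsize: int
    target_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_probability <= 1.0:
            raise ValueError("escape_probability must lie in [0, 1]")
        if self.threshold_popsize < 1:
            raise ValueError("threshold_popsize must be >= 1")

    @property
    def power_of_ten(self) -> float:
        """Order-of-magnitude rendering, 10**floor(log10 N*)."""
        return 10.0 ** math.floor(math.log10(self.threshold_popsize))


@dataclass(frozen=True)
class FluctuationCounts:
    """Plate counts from a Luria-Delbruck fluctuation test (p0 method)."""

    plates_total: int
    plates_no_colony: int
    n_final: float
    n_initial: float

    def __post_init__(self) -> None:
        if not 0 <= self.plates_no_colony <= self.plates_total:
            raise ValueError("need 0 <= plates_no_colony <= plates_total")
        if not self.n_final > self.n_initial >= 0:
            raise ValueError("need n_final > n_initial >= 0")


def neutral_genome_rate(params: ModelParams) -> float:
    """Neutral mutations accumulated per genome per generation, mu*L*(1-a-b)."""
    return params.mu * params.L * params.neutral_fraction


def adaptive_population_rate(params: ModelParams, *, nonsyn_targeting: bool = False) -> float:
    """Adaptive mutations arising in the whole population per generation.

    ``mu*L*alpha*N``; with ``nonsyn_targeting`` the target length is ``Ln``
    (adaptive mutations are assumed to strike non-synonymous sites only).
    """
    length = params.Ln if nonsyn_targeting else params.L
    return params.mu * length * params.alpha * params.N


def neutral_per_hitchhike(params: ModelParams, category: Category = "all") -> float:
    """Expected neutral passengers fixed per sweep.

    The genome accumulates neutral mutations for an average of
    ``1 / (mu*L*alpha*N)`` generations between sweeps, so the category-resolved
    passenger counts are ``(1-a-b)/(a*N)`` (all or non-synonymous, identical
    under non-synonymous adaptive targeting) and ``Ls/(Ln*a*N)`` (synonymous).
    """
    denom = params.alpha * params.N
    if denom == 0:
        raise ValueError("neutral_per_hitchhike undefined for alpha*N == 0")
    if category == "all" or category == "non-synonymous":
        return params.neutral_fraction / denom
    if category == "synonymous":
        return params.Ls / (params.Ln * denom)
    raise ValueError(f"unknown category {category!r}")


def neutral_population_rate(params: ModelParams) -> float:
    """Neutral mutations fixed in the population per generation.

    Algebraically ``(mu*L*alpha*N) * (1-a-b)/(a*N) = mu*L*(1-a-b)``: computed
    through :func:`neutral_genome_rate` so the identity holds bit-for-bit.
    """
    return neutral_genome_rate(params)


def estimate_alpha(
    syn_fixed: float,
    n_hitchhikes: float,
    ls_over_ln: float,
    N: float,
) -> tuple[float, str]:
    """Invert the synonymous passenger count for the adaptive fraction.

    ``Ls/(Ln*alpha*N) = syn_fixed/n_hitchhikes`` gives
    ``alpha = (Ls/Ln) / (N * syn_fixed/n_hitchhikes)``.

    Returns the unrounded estimate and its one-significant-figure rendering.
    """
    if n_hitchhikes <= 0 or N <= 0:
        raise ValueError("n_hitchhikes and N must be > 0")
    if syn_fixed <= 0:
        raise ValueError(
            "alpha is not estimable from zero fixed synonymous mutations "
            "(the passenger count inversion diverges)"
        )
    alpha = ls_over_ln / (N * (syn_fixed / n_hitchhikes))
    return alpha, render_sig(alpha, 1)


def estimate_beta(
    nonsyn_fixed: float,
    n_hitchhikes: float,
    alpha: float,
    N: float,
) -> tuple[float, str]:
    """Invert the non-synonymous passenger count for the harmful fraction.

    ``(1-alpha-beta)/(alpha*N) = nonsyn_fixed/n_hitchhikes`` gives
    ``beta = 1 - alpha - (nonsyn_fixed/n_hitchhikes) * alpha * N``.

    Returns the unrounded estimate and a two-decimal rendering.  An estimate
    outside [0, 1] means the counts are inconsistent with the three-category
    model at these alpha and N: the value is clamped and a warning raised.
    """
    if alpha <= 0 or N <= 0:
        raise ValueError("alpha and N must be > 0")
    if n_hitchhikes <= 0:
        raise ValueError("n_hitchhikes must be > 0")
    beta = 1.0 - alpha - (nonsyn_fixed / n_hitchhikes) * alpha * N
    if beta < -1e-9 or beta > 1 + 1e-9:
        warnings.warn(
            f"beta estimate {beta:.4g} outside [0, 1]: counts are "
            "inconsistent with the three-category model at these alpha and "
            "N; reporting the clamped value",
            stacklevel=2,
        )
    beta = min(1.0, max(0.0, beta))
    return beta, f"{round_decimals(beta, 2):.2f}"


def drift_escape_probability(params: ModelParams, N: float | None = None) -> float:
    """Probability that no adaptive mutation arises for N generations.

    ``(1 - mu*L*N*alpha)**N``: the chance a drifting neutral mutation escapes
    both sweep-out and hitchhiking for the ~N generations drift fixation
    takes.  Clamped to [0, 1]; by convention 0 once ``mu*L*N*alpha > 1``.
    """
    if N is None:
        N = params.N
    per_gen = params.mu * params.L * N * params.alpha
    if per_gen >= 1.0:
        return 0.0
    return min(1.0, max(0.0, (1.0 - per_gen) ** N))


def drift_threshold_popsize(
    params: ModelParams,
    target_probability: float = 0.5,
    n_max: int = 10**12,
) -> DriftAssessment:
    """Largest integer N whose drift-escape probability meets the target.

    The escape probability is monotone non-increasing in N, so integer
    bisection on [1, n_max] yields the exact boundary.  Below this population
    size genetic drift can fix neutral mutations undisturbed; above it,
    hitchhiking dominates.
    """
    if not 0.0 < target_probability < 1.0:
        raise ValueError("target_probability must lie in (0, 1)")

    def escape(n: int) -> float:
        return drift_escape_probability(params, n)

    if escape(1) < target_probability:
        raise ValueError(
            f"no population size in [1, {n_max}] meets target "
            f"{target_probability}"
        )
    lo, hi = 1, n_max  # invariant: escape(lo) >= target; escape(hi+1) < target
    if escape(n_max) >= target_probability:
        lo = n_max
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if escape(mid) >= target_probability:
            lo = mid
        else:
            hi = mid - 1
    return DriftAssessment(
        escape_probability=escape(lo),
        threshold_popsize=lo,
        target_probability=target_probability,
    )


def p0_mutation_rate(counts: FluctuationCounts) -> float:
    """Mutation rate from the fraction of cultures with no mutants.

    Mutational events per culture are Poisson, so the empty-plate fraction
    estimates ``P0 = exp(-m)``; the rate is ``m / (n_final - n_initial)``
    per cell per generation (one net division per new cell in batch growth).
    """
    if counts.plates_no_colony == 0:
        raise ValueError(
            "rate not estimable by p0 method: no plate is mutant-free, "
            "-ln(P0) is unbounded"
        )
    p0 = counts.plates_no_colony / counts.plates_total
    m = -math.log(p0)
    return m / (counts.n_final - counts.n_initial)


def rate_set(params: ModelParams) -> RateSet:
    """All model rates for one parameter set, Eq-consistent by construction."""
    genome = neutral_genome_rate(params)
    return RateSet(
        r_neutral_genome=genome,
        r_adaptive_population=adaptive_population_rate(params, nonsyn_targeting=True),
        n_neutral_per_hitchhike=neutral_per_hitchhike(params, "all"),
        r_neutral_population=neutral_population_rate(params),
        r_neutral_synonymous=params.mu * params.Ls,
        r_neutral_nonsynonymous=params.mu * params.Ln * params.neutral_fraction,
    )


def estimate_from_counts(
    syn_fixed: float = 32,
    nonsyn_fixed: float = 62,
    n_hitchhikes: float = DEFAULT_N_HITCHHIKES,
    N: float = 1e7,
    ls: float = 0.96e6,
    ln: float = 3.2e6,
    mu: float = 1e-8,
    total_generations: float = DEFAULT_TOTAL_GENERATIONS,
) -> dict:
    """Full empirical estimation report from observed fixation counts.

    Defaults are the thermal-adaptation experiment's pooled counts: 32
    synonymous and 62 averaged-neutral non-synonymous mutations fixed through
    20 sweeps over 4419 generations, N = 1e7, Ls = 0.96 Mbp, Ln = 3.2 Mbp.
    """
    syn_per_hh = syn_fixed / n_hitchhikes
    nonsyn_per_hh = nonsyn_fixed / n_hitchhikes
    alpha, alpha_r = estimate_alpha(syn_fixed, n_hitchhikes, ls / ln, N)
    beta, beta_r = estimate_beta(nonsyn_fixed, n_hitchhikes, alpha, N)
    params = ModelParams(mu=mu, L=ln, Ls=ls, Ln=ln, alpha=alpha, beta=beta, N=N)
    rates = rate_set(params)
    drift = drift_threshold_popsize(
        ModelParams(
            mu=mu, L=0.32e7, Ls=ls, Ln=ln,
            alpha=round_sig(alpha, 1), beta=beta, N=N,
        ),
        target_probability=0.5,
    )
    return {
        "alpha": alpha,
        "alpha_rendered": alpha_r,
        "beta": beta,
        "beta_rendered": beta_r,
        "syn_per_hitchhike": syn_per_hh,
        "nonsyn_per_hitchhike": nonsyn_per_hh,
        "r_neutral_synonymous": rates.r_neutral_synonymous,
        "r_neutral_synonymous_rendered": render_sig(rates.r_neutral_synonymous, 1),
        "r_neutral_nonsynonymous": rates.r_neutral_nonsynonymous,
        "r_neutral_nonsynonymous_rendered": render_sig(
            rates.r_neutral_nonsynonymous, 1
        ),
        "r_adaptive_population": rates.r_adaptive_population,
        "r_adaptive_population_rendered": render_sig(rates.r_adaptive_population, 1),
        "mean_sweep_interval": total_generations / n_hitchhikes,
        "model_sweep_interval": 1.0 / rates.r_adaptive_population,
        "drift_threshold_popsize": drift.threshold_popsize,
        "drift_threshold_power_of_ten": drift.power_of_ten,
        "n_hitchhikes": n_hitchhikes,
        "total_generations": total_generations,
    }
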