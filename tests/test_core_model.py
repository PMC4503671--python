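"""Unit and property tests for the analytic hitchhiking-clock model."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hitchclock.core_model import (
    DriftAssessment,
    FluctuationCounts,
    ModelParams,
    adaptive_population_rate,
    drift_escape_probability,
    drift_threshold_popsize,
    estimate_alpha,
    estimate_beta,
    estimate_from_counts,
    neutral_genome_rate,
    neutral_per_hitchhike,
    neutral_population_rate,
    p0_mutation_rate,
    rate_set,
    render_sig,
    round_sig,
)

# the experiment-scale parameter set: mu 1e-8/bp, non-synonymous targeting,
# alpha and beta as estimated from the 32/62/20 fixation counts
EXP = ModelParams(
    mu=1e-8, L=3.2e6, Ls=0.96e6, Ln=3.2e6,
    alpha=1.875e-8, beta=0.41874998125, N=1e7,
)

params_strategy = st.builds(
    ModelParams,
    mu=st.floats(1e-12, 1e-6),
    L=st.floats(1e3, 1e8),
    Ls=st.floats(1e2, 1e7),
    Ln=st.floats(1e2, 1e7),
    alpha=st.floats(1e-10, 0.4),
    beta=st.floats(0.0, 0.5),
    N=st.floats(10, 1e9),
)


class TestRates:
    def test_neutral_genome_rate_experiment_scale(self):
        # mu*Ln*(1-a-b) = 0.0186, printed as 0.02 at one significant figure
        rate = neutral_genome_rate(EXP)
        assert rate == pytest.approx(0.0186, rel=1e-3)
        assert render_sig(rate, 1) == "0.02"

    @pytest.mark.parametrize(
        "mu,alpha,beta,expected",
        [(1e-8, 0.5, 0.5, 0.0), (0.0, 0.1, 0.2, 0.0)],
    )
    def test_neutral_genome_rate_degenerate(self, mu, alpha, beta, expected):
        p = ModelParams(mu=mu, L=1e6, Ls=3e5, Ln=7e5, alpha=alpha, beta=beta, N=100)
        assert neutral_genome_rate(p) == expected

    def test_adaptive_population_rate(self):
        # mu*Ln*alpha*N = 0.006 adaptive mutations per generation
        assert adaptive_population_rate(EXP, nonsyn_targeting=True) == pytest.approx(
            0.006, rel=1e-9
        )

    def test_adaptive_rate_linear_in_popsize(self):
        doubled = ModelParams(
            mu=EXP.mu, L=EXP.L, Ls=EXP.Ls, Ln=EXP.Ln,
            alpha=EXP.alpha, beta=EXP.beta, N=2 * EXP.N,
        )
        assert adaptive_population_rate(doubled) == pytest.approx(
            2 * adaptive_population_rate(EXP)
        )
        zero_alpha = ModelParams(
            mu=EXP.mu, L=EXP.L, Ls=EXP.Ls, Ln=EXP.Ln, alpha=0, beta=EXP.beta, N=EXP.N
        )
        assert adaptive_population_rate(zero_alpha) == 0.0

    def test_passengers_per_hitchhike(self):
        # 1.6 synonymous and 3.1 non-synonymous neutral passengers per sweep
        assert neutral_per_hitchhike(EXP, "synonymous") == pytest.approx(1.6, rel=1e-6)
        assert neutral_per_hitchhike(EXP, "non-synonymous") == pytest.approx(
            3.1, rel=1e-6
        )

    def test_passengers_all_neutral_fraction_zero(self):
        p = ModelParams(mu=1e-8, L=1e6, Ls=3e5, Ln=7e5, alpha=0.5, beta=0.5, N=1e4)
        assert neutral_per_hitchhike(p, "all") == 0.0

    def test_passengers_undefined_without_sweeps(self):
        p = ModelParams(mu=1e-8, L=1e6, Ls=3e5, Ln=7e5, alpha=0.0, beta=0.2, N=1e4)
        with pytest.raises(ValueError):
            neutral_per_hitchhike(p, "all")

    def test_synonymous_population_rate(self):
        # mu*Ls = 0.0096 per genome per generation, printed 0.01
        assert EXP.mu * EXP.Ls == pytest.approx(0.0096)
        assert render_sig(EXP.mu * EXP.Ls, 1) == "0.01"

    def test_all_neutral_params_give_mu_L(self):
        p = ModelParams(mu=1e-8, L=1e6, Ls=3e5, Ln=7e5, alpha=0, beta=0, N=1e4)
        assert neutral_population_rate(p) == p.mu * p.L


class TestIdentities:
    @given(params_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_population_rate_equals_genome_rate_exactly(self, p):
        """The model's central identity: hitchhiking fixes neutral mutations
        at exactly the per-genome spontaneous neutral rate."""
        assert neutral_population_rate(p) == neutral_genome_rate(p)

    @given(params_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_sweep_rate_times_passengers_closes_the_loop(self, p):
        """(adaptive mutations/generation) x (neutral passengers/sweep)
        recovers the neutral genome rate."""
        loop = adaptive_population_rate(p) * neutral_per_hitchhike(p, "all")
        assert loop == pytest.approx(neutral_genome_rate(p), rel=1e-12)

    @given(params_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_alpha_beta_estimators_invert_passenger_counts(self, p):
        syn_per_hh = neutral_per_hitchhike(p, "synonymous")
        nonsyn_per_hh = neutral_per_hitchhike(p, "non-synonymous")
        alpha_hat, _ = estimate_alpha(syn_per_hh * 10, 10, p.Ls / p.Ln, p.N)
        assert alpha_hat == pytest.approx(p.alpha, rel=1e-12)
        beta_hat, _ = estimate_beta(nonsyn_per_hh * 10, 10, alpha_hat, p.N)
        assert beta_hat == pytest.approx(p.beta, rel=1e-9, abs=1e-9)

    def test_rate_set_is_consistent(self):
        rates = rate_set(EXP)
        assert rates.r_neutral_population == rates.r_neutral_genome
        assert rates.r_neutral_synonymous == pytest.approx(0.0096)
        assert rates.r_neutral_nonsynonymous == pytest.approx(0.0186, rel=1e-3)


class TestEstimators:
    def test_alpha_from_experiment_counts(self):
        alpha, rendered = estimate_alpha(32, 20, 0.3, 1e7)
        assert alpha == pytest.approx(1.875e-8)
        assert rendered == "2e-08"

    def test_alpha_ratio_invariance(self):
        a1, _ = estimate_alpha(32, 20, 0.3, 1e7)
        a2, _ = estimate_alpha(16, 10, 0.3, 1e7)
        assert a1 == a2

    def test_alpha_degenerate_unit_case(self):
        alpha, _ = estimate_alpha(1, 1, 1.0, 1)
        assert alpha == 1.0

    def test_alpha_requires_synonymous_fixations(self):
        with pytest.raises(ValueError, match="not estimable"):
            estimate_alpha(0, 20, 0.3, 1e7)

    def test_beta_from_experiment_counts(self):
        beta, rendered = estimate_beta(62, 20, 1.875e-8, 1e7)
        assert beta == pytest.approx(0.41875, rel=1e-4)
        assert rendered == "0.42"

    def test_beta_zero_when_all_nonsyn_neutral(self):
        alpha, N = 1e-6, 1e5
        nonsyn_per_hh = (1 - alpha) / (alpha * N)
        beta, _ = estimate_beta(nonsyn_per_hh, 1, alpha, N)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_beta_flags_inconsistent_counts(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            beta, _ = estimate_beta(1000, 1, 1e-6, 1e7)
        assert beta == 0.0  # clamped

    def test_estimate_from_counts_full_report(self):
        report = estimate_from_counts()
        assert report["alpha_rendered"] == "2e-08"
        assert report["beta_rendered"] == "0.42"
        assert report["r_neutral_synonymous_rendered"] == "0.01"
        assert report["r_neutral_nonsynonymous_rendered"] == "0.02"
        assert report["r_adaptive_population_rendered"] == "0.006"
        assert report["mean_sweep_interval"] == pytest.approx(220.95)


class TestDrift:
    DRIFT = ModelParams(mu=1e-8, L=0.32e7, Ls=1, Ln=1, alpha=2e-8, beta=0, N=1)

    def test_escape_probability_virtually_zero_at_1e5(self):
        # direct evaluation of (1 - mu*L*N*alpha)^N at N = 1e5
        p = drift_escape_probability(self.DRIFT, 1e5)
        assert p == pytest.approx(1.66e-3, rel=0.02)

    def test_escape_certain_without_adaptive_mutations(self):
        p = ModelParams(mu=1e-8, L=1e6, Ls=1, Ln=1, alpha=0, beta=0, N=1)
        assert drift_escape_probability(p, 1e6) == 1.0

    def test_escape_near_one_for_single_genome(self):
        assert drift_escape_probability(self.DRIFT, 1) == pytest.approx(1.0, abs=1e-8)

    @given(st.floats(10, 1e8), st.floats(1.1, 100.0))
    @settings(max_examples=60, derandomize=True)
    def test_escape_probability_non_increasing_in_popsize(self, n, factor):
        assert drift_escape_probability(self.DRIFT, n * factor) <= (
            drift_escape_probability(self.DRIFT, n) + 1e-15
        )

    def test_threshold_matches_exhaustive_scan(self):
        """Bisection agrees with a brute-force integer scan (the oracle)."""
        result = drift_threshold_popsize(self.DRIFT, 0.5)
        ns = np.arange(1, 100001, dtype=float)
        escape = (1.0 - self.DRIFT.mu * self.DRIFT.L * ns * self.DRIFT.alpha) ** ns
        brute = int(ns[escape >= 0.5][-1])
        assert result.threshold_popsize == brute
        assert result.power_of_ten == 1e4

    def test_threshold_grows_when_sweeps_rarer(self):
        halved = ModelParams(
            mu=1e-8, L=0.32e7, Ls=1, Ln=1, alpha=1e-8, beta=0, N=1
        )
        assert (
            drift_threshold_popsize(halved, 0.5).threshold_popsize
            > drift_threshold_popsize(self.DRIFT, 0.5).threshold_popsize
        )

    def test_threshold_small_for_stringent_target(self):
        result = drift_threshold_popsize(self.DRIFT, 1 - 1e-8)
        assert result.threshold_popsize <= 5

    def test_escape_assessment_validates(self):
        with pytest.raises(ValueError):
            DriftAssessment(escape_probability=1.5, threshold_popsize=10,
                            target_probability=0.5)


class TestFluctuationTest:
    def test_all_plates_empty_gives_zero_rate(self):
        counts = FluctuationCounts(35, 35, n_final=1e8, n_initial=1e3)
        assert p0_mutation_rate(counts) == 0.0

    def test_unit_mean_construction(self):
        # P0 = 1/e means exactly one expected mutation per culture
        empties = round(35 / math.e)
        counts = FluctuationCounts(35, empties, n_final=1e8, n_initial=0)
        rate = p0_mutation_rate(counts)
        assert rate == pytest.approx(-math.log(empties / 35) / 1e8)

    def test_experiment_style_counts(self):
        # 35 tubes, 12 without colonies, 5e7 net cells per culture
        counts = FluctuationCounts(35, 12, n_final=5e7, n_initial=0)
        assert p0_mutation_rate(counts) == pytest.approx(-math.log(12 / 35) / 5e7)

    def test_no_empty_plates_not_estimable(self):
        counts = FluctuationCounts(35, 0, n_final=1e8, n_initial=1e3)
        with pytest.raises(ValueError, match="p0"):
            p0_mutation_rate(counts)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            FluctuationCounts(35, 36, n_final=1e8, n_initial=1e3)
        with pytest.raises(ValueError):
            FluctuationCounts(35, 10, n_final=1e3, n_initial=1e8)

    def test_poisson_inversion_recovers_m(self):
        """Simulating Poisson(m) mutational events over many cultures and
        re-estimating through the empty fraction recovers m within
        binomial sampling error."""
        rng = np.random.default_rng(2024)
        m_true, cultures, cells = 0.8, 10_000, 1e8
        mutants = rng.poisson(m_true, size=cultures)
        empties = int((mutants == 0).sum())
        rate = p0_mutation_rate(
            FluctuationCounts(cultures, empties, n_final=cells, n_initial=0)
        )
        m_hat = rate * cells
        p0 = math.exp(-m_true)
        se_m = math.sqrt(p0 * (1 - p0) / cultures) / p0  # delta method
        assert abs(m_hat - m_true) < 3 * se_m


class TestValidationAndRendering:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu=-1e-9),
            dict(L=0),
            dict(N=-5),
            dict(alpha=0.7, beta=0.7),
            dict(alpha=-0.1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(mu=1e-8, L=1e6, Ls=3e5, Ln=7e5, alpha=0.1, beta=0.1, N=100)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ModelParams(**base)

    @pytest.mark.parametrize(
        "value,sig,expected",
        [
            (0.0186, 1, 0.02),
            (0.0096, 1, 0.01),
            (1.875e-8, 1, 2e-8),
            (0.006, 1, 0.006),
            (0.25, 1, 0.3),  # half away from zero
            (-0.25, 1, -0.3),
            (0.0, 2, 0.0),
        ],
    )
    def test_round_sig(self, value, sig, expected):
        assert round_sig(value, sig) == pytest.approx(expected, rel=1e-12)

    def test_render_sig_scientific(self):
        assert render_sig(1.875e-8, 1) == "2e-08"
        assert render_sig(0.0186, 1) == "0.02"
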