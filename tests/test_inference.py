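"""Pooled-assay likelihood, MLE, credible intervals and the frequency test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from phagecommons import (
    Outcome,
    PooledAssayData,
    Reaction,
    chi_square_frequency_test,
    credible_interval,
    estimate_frequency,
    log_likelihood,
    mle_frequency,
    reaction_class_probs,
    unanimous_bound,
)
from phagecommons.inference import _posterior


def brute_force_mle(data: PooledAssayData, points: int = 100_001) -> float:
    """Independent grid maximizer built directly from the class formulas."""
    grid = np.linspace(0.0, 1.0, points)
    total = np.zeros_like(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        for reaction in data.reactions:
            u = 1.0 - grid
            if reaction.outcome is Outcome.ALL_NEG:
                term = reaction.n * np.log(u)
            elif reaction.outcome is Outcome.ALL_POS:
                term = reaction.n * np.log(grid)
            else:
                term = np.log(1.0 - u ** reaction.n - grid ** reaction.n)
            total += np.nan_to_num(term, nan=-np.inf, neginf=-np.inf)
    return float(grid[np.argmax(total)])


def random_dataset(rng: np.random.Generator) -> PooledAssayData:
    reactions = []
    for _ in range(int(rng.integers(1, 11))):
        n = int(rng.integers(1, 11))
        choices = [Outcome.ALL_NEG, Outcome.ALL_POS]
        if n > 1:
            choices.append(Outcome.MIXED)
        reactions.append(Reaction(n, choices[int(rng.integers(len(choices)))]))
    return PooledAssayData(reactions)


class TestReactionClassProbs:
    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_boundary_frequencies(self, n):
        assert reaction_class_probs(0.0, n) == (1.0, 0.0, 0.0)
        assert reaction_class_probs(1.0, n) == (0.0, 1.0, 0.0)

    def test_no_mixed_class_for_singleton_pools(self):
        a, b, c = reaction_class_probs(0.5, 1)
        assert (a, b, c) == (0.5, 0.5, 0.0)

    def test_closed_form_at_half(self):
        a, b, c = reaction_class_probs(0.5, 10)
        assert a == pytest.approx(2.0 ** -10, rel=1e-12)
        assert b == pytest.approx(2.0 ** -10, rel=1e-12)
        assert c == pytest.approx(1.0 - 2.0 ** -9, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        t=st.floats(min_value=0.0, max_value=1.0),
        n=st.integers(min_value=1, max_value=15),
    )
    def test_simplex_property(self, t, n):
        a, b, c = reaction_class_probs(t, n)
        assert 0.0 <= a <= 1.0 and 0.0 <= b <= 1.0 and 0.0 <= c <= 1.0
        assert a + b + c == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reaction_class_probs(1.5, 10)
        with pytest.raises(ValueError):
            reaction_class_probs(0.5, 0)


class TestAssayData:
    def test_mixed_singleton_rejected(self):
        with pytest.raises(ValueError, match="cannot be MIXED"):
            Reaction(1, Outcome.MIXED)

    def test_counts_and_aggregates(self):
        data = PooledAssayData.from_counts(10, all_neg=3, all_pos=2, mixed=1)
        assert (data.n_all_neg, data.n_all_pos, data.n_mixed) == (3, 2, 1)
        assert data.n_reactions == 6
        assert data.common_pool_size == 10
        assert data.total_plaques == 60

    def test_heterogeneous_pool_sizes(self):
        data = PooledAssayData([Reaction(10, "ALL_NEG"), Reaction(1, "all_pos")])
        assert data.common_pool_size is None
        assert data.total_plaques == 11

    def test_tsv_round_trip(self, tmp_path):
        data = PooledAssayData.from_counts(10, all_neg=4, mixed=2)
        path = tmp_path / "assays.tsv"
        data.to_tsv(path)
        assert PooledAssayData.from_tsv(path) == data

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PooledAssayData.from_counts(10, all_neg=-1)


class TestLogLikelihood:
    def test_empty_data_is_flat_zero(self):
        data = PooledAssayData([])
        grid = np.linspace(0, 1, 11)
        assert np.array_equal(log_likelihood(grid, data), np.zeros(11))

    def test_single_all_negative_closed_form(self):
        data = PooledAssayData.from_counts(10, all_neg=1)
        assert log_likelihood(0.1, data) == pytest.approx(10 * math.log(0.9), rel=1e-12)

    def test_additivity_across_heterogeneous_pools(self):
        data = PooledAssayData([Reaction(10, Outcome.ALL_NEG), Reaction(1, Outcome.ALL_POS)])
        expected = 10 * math.log(0.7) + math.log(0.3)
        assert log_likelihood(0.3, data) == pytest.approx(expected, rel=1e-12)

    def test_impossible_class_gives_neg_inf(self):
        data = PooledAssayData.from_counts(10, all_pos=1)
        assert log_likelihood(0.0, data) == -math.inf

    def test_domain_checked(self):
        data = PooledAssayData.from_counts(10, all_neg=1)
        with pytest.raises(ValueError):
            log_likelihood(-0.1, data)


class TestMLE:
    def test_unanimous_boundaries(self):
        assert mle_frequency(PooledAssayData.from_counts(10, all_neg=6)) == 0.0
        assert mle_frequency(PooledAssayData.from_counts(10, all_pos=6)) == 1.0

    def test_singleton_pools_reduce_to_binomial(self):
        data = PooledAssayData.from_counts(1, all_neg=5, all_pos=5)
        assert mle_frequency(data) == pytest.approx(0.5, abs=1e-9)

    def test_mostly_mixed_pools(self):
        # X=1, Z=5 at n=10: T^n negligible, so T_hat ~ 1 - (X/(X+Z))^(1/n)
        data = PooledAssayData.from_counts(10, all_neg=1, mixed=5)
        t_hat = mle_frequency(data)
        assert t_hat == pytest.approx(brute_force_mle(data), abs=1e-4)
        assert t_hat == pytest.approx(1 - (1 / 6) ** 0.1, abs=1e-3)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            mle_frequency(PooledAssayData([]))

    def test_agrees_with_grid_oracle_on_random_datasets(self):
        rng = np.random.default_rng(20140801)
        for _ in range(50):
            data = random_dataset(rng)
            assert mle_frequency(data) == pytest.approx(
                brute_force_mle(data), abs=1e-4
            ), repr(data)

    @pytest.mark.parametrize(
        "base",
        [
            PooledAssayData.from_counts(10, all_neg=2, mixed=3),
            PooledAssayData.from_counts(5, all_neg=1, all_pos=1, mixed=2),
            PooledAssayData.from_counts(1, all_neg=4, all_pos=2),
        ],
    )
    def test_monotone_in_added_evidence(self, base):
        t_base = mle_frequency(base)
        n = base.common_pool_size
        plus = PooledAssayData(list(base.reactions) + [Reaction(n, Outcome.ALL_POS)])
        minus = PooledAssayData(list(base.reactions) + [Reaction(n, Outcome.ALL_NEG)])
        assert mle_frequency(plus) >= t_base - 1e-9
        assert mle_frequency(minus) <= t_base + 1e-9


class TestCredibleInterval:
    def test_unanimous_negative_matches_beta_closed_form(self):
        data = PooledAssayData.from_counts(10, all_neg=6)  # 60 negative plaques
        lo, hi = credible_interval(data)
        assert hi == pytest.approx(1 - 0.025 ** (1 / 61), abs=1e-4)
        assert round(hi, 2) == 0.06
        assert lo == pytest.approx(stats.beta.ppf(0.025, 1, 61), abs=1e-4)

    def test_unanimous_positive_matches_beta_closed_form(self):
        data = PooledAssayData.from_counts(10, all_pos=6)  # 60 positive plaques
        lo, hi = credible_interval(data)
        assert lo == pytest.approx(0.025 ** (1 / 61), abs=1e-4)
        assert round(lo, 2) == 0.94
        assert hi == pytest.approx(stats.beta.ppf(0.975, 61, 1), abs=1e-4)

    @pytest.mark.parametrize("x,y", [(60, 0), (0, 60), (40, 20), (7, 3), (1, 1)])
    def test_singleton_pools_match_conjugate_beta(self, x, y):
        data = PooledAssayData.from_counts(1, all_neg=x, all_pos=y)
        lo, hi = credible_interval(data)
        assert lo == pytest.approx(stats.beta.ppf(0.025, y + 1, x + 1), abs=1e-4)
        assert hi == pytest.approx(stats.beta.ppf(0.975, y + 1, x + 1), abs=1e-4)

    @pytest.mark.parametrize(
        "data",
        [
            PooledAssayData.from_counts(10, all_neg=6),
            PooledAssayData.from_counts(10, all_neg=1, mixed=5),
            PooledAssayData.from_counts(1, all_neg=40, all_pos=20),
            PooledAssayData([Reaction(10, "ALL_NEG"), Reaction(3, "MIXED")]),
        ],
    )
    def test_posterior_normalizes_to_one(self, data):
        grid, density = _posterior(data)
        assert integrate.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-6)

    def test_width_shrinks_with_more_reactions(self):
        # same observed class proportions, growing replication
        widths = []
        for scale in (1, 4, 16):
            data = PooledAssayData.from_counts(
                10, all_neg=1 * scale, mixed=5 * scale
            )
            lo, hi = credible_interval(data)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_level_validated(self):
        data = PooledAssayData.from_counts(10, all_neg=6)
        with pytest.raises(ValueError):
            credible_interval(data, level=1.0)


class TestUnanimousBound:
    def test_closed_forms(self):
        assert unanimous_bound(60, 0.95, "all_negative") == pytest.approx(
            1 - 0.025 ** (1 / 61), rel=1e-12
        )
        assert unanimous_bound(1, 0.95, "all_negative") == pytest.approx(
            1 - 0.025 ** 0.5, rel=1e-12
        )
        assert unanimous_bound(60, 0.95, "all_positive") == pytest.approx(
            0.025 ** (1 / 61), rel=1e-12
        )

    @pytest.mark.parametrize("n_plaques", [1, 10, 60, 200])
    def test_agrees_with_quadrature(self, n_plaques):
        data = PooledAssayData.from_counts(1, all_neg=n_plaques)
        _, hi = credible_interval(data)
        assert hi == pytest.approx(unanimous_bound(n_plaques), abs=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            unanimous_bound(0)
        with pytest.raises(ValueError):
            unanimous_bound(10, direction="sideways")


class TestEstimateFrequency:
    def test_bundles_mle_and_interval(self):
        data = PooledAssayData.from_counts(10, all_neg=1, mixed=5)
        est = estimate_frequency(data)
        assert est.lower <= est.t_hat <= est.upper
        assert est.level == 0.95
        assert integrate.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-6)

    def test_boundary_mle_may_sit_on_interval_edge(self):
        est = estimate_frequency(PooledAssayData.from_counts(10, all_neg=6))
        assert est.t_hat == 0.0
        assert est.lower > 0.0  # equal-tail interval excludes a 2.5% lower tail


class TestChiSquareFrequencyTest:
    def test_exact_expectation_gives_zero(self):
        result = chi_square_frequency_test(15, 60, 0.25)
        assert result.statistic == 0.0
        assert result.pvalue == 1.0
        assert result.df == 1

    def test_hand_computed_example(self):
        # 36/60 observed against expected frequency 0.26:
        # (36-15.6)^2/15.6 + (24-44.4)^2/44.4
        result = chi_square_frequency_test(36, 60, 0.26)
        assert result.statistic == pytest.approx(36.0499, abs=1e-3)
        assert result.pvalue < 1e-4

    def test_matches_scipy_chisquare(self):
        result = chi_square_frequency_test(36, 60, 0.26)
        ref = stats.chisquare([36, 24], f_exp=[15.6, 44.4])
        assert result.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert result.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_doubling_counts_doubles_statistic(self):
        base = chi_square_frequency_test(36, 60, 0.26)
        doubled = chi_square_frequency_test(72, 120, 0.26)
        assert doubled.statistic == pytest.approx(2 * base.statistic, rel=1e-12)

    def test_continuity_correction_shrinks_statistic(self):
        plain = chi_square_frequency_test(36, 60, 0.26)
        corrected = chi_square_frequency_test(36, 60, 0.26, continuity_correction=True)
        assert corrected.statistic < plain.statistic

    @pytest.mark.parametrize(
        "args", [(5, 0, 0.5), (-1, 10, 0.5), (11, 10, 0.5), (5, 10, 0.0), (5, 10, 1.0)]
    )
    def test_validation(self, args):
        with pytest.raises(ValueError):
            chi_square_frequency_test(*args)
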