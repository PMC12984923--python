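"""Entropy measures vs. independent brute-force oracles and analytic values."""

import math

import numpy as np
import pytest

import oracles
from entrosel.entropy import (
    approximate_entropy,
    composite_multiscale_entropy,
    cosine_similarity_entropy,
    default_tolerance,
    dispersion_entropy,
    diversity_entropy,
    fuzzy_entropy,
    permutation_entropy,
    sample_entropy,
    shannon_entropy,
    spectral_entropy,
)
from entrosel.errors import InsufficientLengthError, InvalidInputError

from conftest import random_signal

# (callable on (x[, y]) -> value, oracle on python lists) covering all measure
# families at registry-default parameters; r fixed per signal as 0.2*SD.
def _r(x):
    return default_tolerance(x)


def _single_cases():
    import entrosel.entropy as E

    return {
        "apen_m0": (lambda x: E.approximate_entropy(x, 0, _r(x)),
                    lambda x: oracles.apen_oracle(x, 0, _r(x))),
        "apen_m1": (lambda x: E.approximate_entropy(x, 1, _r(x)),
                    lambda x: oracles.apen_oracle(x, 1, _r(x))),
        "apen_m2": (lambda x: E.approximate_entropy(x, 2, _r(x)),
                    lambda x: oracles.apen_oracle(x, 2, _r(x))),
        "attention": (E.attention_entropy, oracles.attention_oracle),
        "bubble": (lambda x: E.bubble_entropy(x, 10),
                   lambda x: oracles.bubble_oracle(x, 10)),
        "cmse_s1": (lambda x: E.composite_multiscale_entropy(x, 1, 2, _r(x)),
                    lambda x: oracles.cmse_oracle(x, 1, 2, _r(x))),
        "cmse_s2": (lambda x: E.composite_multiscale_entropy(x, 2, 2, _r(x)),
                    lambda x: oracles.cmse_oracle(x, 2, 2, _r(x))),
        "cmse_s3": (lambda x: E.composite_multiscale_entropy(x, 3, 2, _r(x)),
                    lambda x: oracles.cmse_oracle(x, 3, 2, _r(x))),
        "shannon": (lambda x: E.shannon_entropy(x, 256),
                    lambda x: oracles.shannon_oracle(x, 256)),
        "cce": (lambda x: E.corrected_conditional_entropy(x, 2, 6),
                lambda x: oracles.cce_oracle(x, 2, 6)),
        "cse": (lambda x: E.cosine_similarity_entropy(x, 2, 0.1),
                lambda x: oracles.cse_oracle(x, 2, 0.1)),
        "dispersion": (lambda x: E.dispersion_entropy(x, 2, 6),
                       lambda x: oracles.dispen_oracle(x, 2, 6)),
        "distribution": (lambda x: E.distribution_entropy(x, 2, 512),
                         lambda x: oracles.disten_oracle(x, 2, 512)),
        "diversity": (lambda x: E.diversity_entropy(x, 2, 5),
                      lambda x: oracles.diven_oracle(x, 2, 5)),
        "entropy_of_entropy": (E.entropy_of_entropy, oracles.eoe_oracle),
        "fuzzy_m1": (lambda x: E.fuzzy_entropy(x, 1, _r(x)),
                     lambda x: oracles.fuzzy_oracle(x, 1, _r(x))),
        "fuzzy_m2": (lambda x: E.fuzzy_entropy(x, 2, _r(x)),
                     lambda x: oracles.fuzzy_oracle(x, 2, _r(x))),
        "gridded": (E.gridded_distribution_entropy, oracles.gde_oracle),
        "permutation": (lambda x: E.permutation_entropy(x, 3),
                        lambda x: oracles.permen_oracle(x, 3)),
        "phase": (E.phase_entropy, oracles.phase_oracle),
        "range": (lambda x: E.range_entropy(x, 2, 0.2),
                  lambda x: oracles.rangeen_oracle(x, 2, 0.2)),
        "sampen_m0": (lambda x: E.sample_entropy(x, 0, _r(x)),
                      lambda x: oracles.sampen_oracle(x, 0, _r(x))),
        "sampen_m1": (lambda x: E.sample_entropy(x, 1, _r(x)),
                      lambda x: oracles.sampen_oracle(x, 1, _r(x))),
        "sampen_m2": (lambda x: E.sample_entropy(x, 2, _r(x)),
                      lambda x: oracles.sampen_oracle(x, 2, _r(x))),
        "slope": (E.slope_entropy, oracles.slopen_oracle),
        "spectral": (E.spectral_entropy, oracles.spectral_oracle),
    }


def _cross_cases():
    import entrosel.entropy as E

    return {
        "xapen_m1": (lambda u, v: E.cross_approximate_entropy(u, v, 1, _r(u)),
                     lambda u, v: oracles.xapen_oracle(u, v, 1, _r(u))),
        "xapen_m2": (lambda u, v: E.cross_approximate_entropy(u, v, 2, _r(u)),
                     lambda u, v: oracles.xapen_oracle(u, v, 2, _r(u))),
        "xcce": (lambda u, v: E.corrected_cross_conditional_entropy(u, v, 2, 6),
                 lambda u, v: oracles.xcce_oracle(u, v, 2, 6)),
        "xdisten": (lambda u, v: E.cross_distribution_entropy(u, v, 2, 512),
                    lambda u, v: oracles.xdisten_oracle(u, v, 2, 512)),
        "xfuzzy_m1": (lambda u, v: E.cross_fuzzy_entropy(u, v, 1, _r(u)),
                      lambda u, v: oracles.xfuzzy_oracle(u, v, 1, _r(u))),
        "xfuzzy_m2": (lambda u, v: E.cross_fuzzy_entropy(u, v, 2, _r(u)),
                      lambda u, v: oracles.xfuzzy_oracle(u, v, 2, _r(u))),
        "xk2_m1": (lambda u, v: E.cross_kolmogorov_entropy(u, v, 1, _r(u)),
                   lambda u, v: oracles.xk2_oracle(u, v, 1, _r(u))),
        "xk2_m2": (lambda u, v: E.cross_kolmogorov_entropy(u, v, 2, _r(u)),
                   lambda u, v: oracles.xk2_oracle(u, v, 2, _r(u))),
        "xsampen_m0": (lambda u, v: E.cross_sample_entropy(u, v, 0, _r(u)),
                       lambda u, v: oracles.xsampen_oracle(u, v, 0, _r(u))),
        "xsampen_m1": (lambda u, v: E.cross_sample_entropy(u, v, 1, _r(u)),
                       lambda u, v: oracles.xsampen_oracle(u, v, 1, _r(u))),
        "xsampen_m2": (lambda u, v: E.cross_sample_entropy(u, v, 2, _r(u)),
                       lambda u, v: oracles.xsampen_oracle(u, v, 2, _r(u))),
        "xspectral": (E.cross_spectral_entropy, oracles.xspectral_oracle),
    }


@pytest.mark.parametrize("name", sorted(_single_cases()))
@pytest.mark.parametrize("seed", [1, 2, 3])
def test_single_measures_match_brute_force(name, seed):
    fn, oracle = _single_cases()[name]
    x = random_signal(seed, n=30)
    expected = oracle(list(x))
    got = fn(x)
    assert math.isclose(got, expected, rel_tol=0, abs_tol=1e-9), (got, expected)


@pytest.mark.parametrize("name", sorted(_cross_cases()))
@pytest.mark.parametrize("seed", [11, 12, 13])
def test_cross_measures_match_brute_force(name, seed):
    fn, oracle = _cross_cases()[name]
    u = random_signal(seed, n=30)
    v = random_signal(seed + 100, n=30)
    expected = oracle(list(u), list(v))
    got = fn(u, v)
    if not math.isfinite(expected):
        assert not math.isfinite(got)
    else:
        assert math.isclose(got, expected, rel_tol=0, abs_tol=1e-9), (got, expected)


class TestAnalyticValues:
    def test_shannon_uniform_8_bins(self):
        # values centered in 8 distinct bins, equal counts -> exactly 3 bits
        centers = (np.arange(8) + 0.5) * (255.0 / 8)
        x = np.repeat(centers, 4)
        assert math.isclose(shannon_entropy(x, 8, (0.0, 255.0)), 3.0, abs_tol=1e-12)

    def test_shannon_two_bins_3_to_1(self):
        x = np.array([10.0, 10.0, 10.0, 200.0])
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert math.isclose(shannon_entropy(x, 2, (0.0, 255.0)), expected, abs_tol=1e-12)

    def test_shannon_constant_is_zero(self):
        assert shannon_entropy(np.full(50, 5.0)) == 0.0

    def test_apen_constant_signal_is_zero(self):
        x = np.full(40, 3.0)
        assert math.isclose(approximate_entropy(x, 1, default_tolerance(x)), 0.0, abs_tol=1e-12)

    def test_apen_m0_nonnegative(self):
        for seed in range(5):
            x = random_signal(seed, 25)
            assert approximate_entropy(x, 0, default_tolerance(x)) >= -1e-12

    def test_sampen_constant_is_zero(self):
        x = np.full(40, 1.5)
        assert sample_entropy(x, 1, 1e-9) == 0.0

    def test_sampen_alternating_matches_oracle(self):
        x = [1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        assert math.isclose(
            sample_entropy(x, 1, 0.5), oracles.sampen_oracle(x, 1, 0.5), abs_tol=1e-12
        )

    def test_sampen_pi_digit_fixture_matches_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        assert math.isclose(
            sample_entropy(x, 1, 1.0), oracles.sampen_oracle(x, 1, 1.0), abs_tol=1e-12
        )

    def test_sampen_periodic_below_shuffled(self):
        """Regular structure scores below its random permutation in >=95/100 shuffles."""
        x = np.sin(np.linspace(0, 12 * np.pi, 120))
        r = default_tolerance(x)
        base = sample_entropy(x, 1, r)
        rng = np.random.default_rng(0)
        wins = sum(base <= sample_entropy(rng.permutation(x), 1, r) for _ in range(100))
        assert wins >= 95

    def test_permutation_monotone_is_zero(self):
        assert permutation_entropy(np.arange(20.0), 3) == 0.0

    def test_permutation_all_patterns_equal_is_one(self):
        # m=2: patterns up/down alternate equally in a zigzag of even pairs
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        assert math.isclose(permutation_entropy(x, 2), 1.0, abs_tol=1e-12)

    def test_permutation_worked_example(self):
        # six ordinal pairs: 4 ascents, 2 descents
        x = [4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0]
        expected = -(4 / 6 * math.log2(4 / 6) + 2 / 6 * math.log2(2 / 6))
        assert math.isclose(permutation_entropy(x, 2), expected, abs_tol=1e-12)

    def test_spectral_pure_tone_is_zero(self):
        n = 64
        x = np.sin(2 * np.pi * 5 * np.arange(n) / n)
        assert math.isclose(spectral_entropy(x), 0.0, abs_tol=1e-9)

    def test_spectral_impulse_is_one(self):
        x = np.zeros(64)
        x[0] = 1.0
        assert math.isclose(spectral_entropy(x), 1.0, abs_tol=1e-12)

    def test_spectral_two_equal_tones(self):
        n = 64
        t = np.arange(n)
        x = np.sin(2 * np.pi * 5 * t / n) + np.sin(2 * np.pi * 11 * t / n)
        expected = math.log(2) / math.log(n // 2)
        assert math.isclose(spectral_entropy(x), expected, abs_tol=1e-9)

    def test_spectral_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            spectral_entropy(np.zeros(32))

    def test_dispersion_constant_is_zero(self):
        assert dispersion_entropy(np.full(40, 2.0), 2, 6) == 0.0

    def test_dispersion_hand_enumerated_12_point_fixture(self):
        x = [1.0, 9.0, 2.0, 8.0, 3.0, 7.0, 1.0, 9.0, 2.0, 8.0, 3.0, 7.0]
        assert math.isclose(
            dispersion_entropy(x, 2, 3), oracles.dispen_oracle(x, 2, 3), abs_tol=1e-12
        )

    def test_fuzzy_constant_is_zero(self):
        assert math.isclose(fuzzy_entropy(np.full(30, 4.0), 1, 0.5), 0.0, abs_tol=1e-12)

    def test_fuzzy_translation_invariance_exact(self):
        x = random_signal(3, 25)
        assert fuzzy_entropy(x, 1, 2.0) == fuzzy_entropy(x + 10.0, 1, 2.0)

    def test_cmse_scale1_equals_sampen(self):
        x = random_signal(9, 40)
        r = default_tolerance(x)
        assert composite_multiscale_entropy(x, 1, 2, r) == sample_entropy(x, 2, r)

    def test_cmse_decreases_with_scale_for_white_noise(self):
        deltas = []
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=256)
            r = default_tolerance(x)
            deltas.append(
                composite_multiscale_entropy(x, 1, 2, r)
                - composite_multiscale_entropy(x, 3, 2, r)
            )
        assert np.mean(deltas) > 0

    def test_cse_constant_signal_is_zero(self):
        assert cosine_similarity_entropy(np.full(30, 2.0)) == 0.0

    def test_diversity_in_unit_interval(self):
        for seed in range(5):
            assert 0.0 <= diversity_entropy(random_signal(seed, 40)) <= 1.0


class TestDomainContracts:
    def test_normalized_measures_in_unit_interval(self):
        import entrosel.entropy as E

        for seed in range(5):
            x = random_signal(seed, 60)
            for fn in (
                lambda s: E.permutation_entropy(s, 3),
                lambda s: E.dispersion_entropy(s, 2, 6),
                E.spectral_entropy,
                lambda s: E.diversity_entropy(s, 2, 5),
                lambda s: E.distribution_entropy(s, 2, 512),
                E.gridded_distribution_entropy,
                E.phase_entropy,
                E.slope_entropy,
            ):
                v = fn(x)
                assert -1e-12 <= v <= 1.0 + 1e-12

    def test_conditional_ratio_measures_nonnegative(self):
        import entrosel.entropy as E

        for seed in range(5):
            x = random_signal(seed, 40)
            r = default_tolerance(x)
            assert E.approximate_entropy(x, 1, r) >= -1e-9
            assert E.sample_entropy(x, 1, r) >= -1e-9
            assert E.fuzzy_entropy(x, 1, r) >= -1e-9
            assert E.range_entropy(x, 2, 0.2) >= -1e-9

    def test_too_short_signal_raises(self):
        with pytest.raises(InsufficientLengthError):
            sample_entropy(np.array([1.0, 2.0]), 2, 0.5)
        with pytest.raises(InsufficientLengthError):
            permutation_entropy(np.array([1.0, 2.0]), 3)

    def test_measures_are_deterministic(self):
        x = random_signal(5, 50)
        import entrosel.entropy as E

        assert E.sample_entropy(x, 2, 1.0) == E.sample_entropy(x.copy(), 2, 1.0)
        assert E.attention_entropy(x) == E.attention_entropy(x.copy())
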