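import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from togglekit import (
    ParameterDomainError,
    evolve,
    generation_kernel,
    generations_to_steady,
    monte_carlo_population,
    stationary_composition,
    total_variation,
)
from togglekit.population import mean_fraction_recursion


def enumerate_kernel(y_prev: int, n_prev: int, py: float, pz: float) -> np.ndarray:
    """Brute-force oracle: enumerate every switch pattern of the population."""
    probs = np.zeros(n_prev + 1)
    cells = [1] * y_prev + [0] * (n_prev - y_prev)
    for pattern in itertools.product([0, 1], repeat=n_prev):
        prob = 1.0
        y_after = 0
        for state, flips in zip(cells, pattern):
            if state == 1:
                prob *= py if flips else (1 - py)
                y_after += 0 if flips else 1
            else:
                prob *= pz if flips else (1 - pz)
                y_after += 1 if flips else 0
        probs[y_after] += prob
    return probs


class TestGenerationKernel:
    def test_frozen_switching_is_point_mass(self):
        k = generation_kernel(3, 3, 0.0, 0.0)
        assert k[3] == 1.0 and k.sum() == pytest.approx(1.0)

    def test_single_cell_enumeration(self):
        k = generation_kernel(1, 1, 0.3, 0.9)
        assert k[1] == pytest.approx(0.7)
        assert k[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("y_prev, i, py, pz", [
        (0, 2, 0.1, 0.2), (2, 2, 0.02, 0.2), (4, 3, 0.5, 0.5),
        (3, 3, 0.9, 0.05), (4, 4, 0.33, 0.77), (7, 4, 0.6, 0.01),
    ])
    def test_matches_exhaustive_enumeration(self, y_prev, i, py, pz):
        exact = generation_kernel(y_prev, i, py, pz)
        brute = enumerate_kernel(y_prev, 2 ** (i - 1), py, pz)
        np.testing.assert_allclose(exact, brute, atol=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterDomainError):
            generation_kernel(1, 1, 1.5, 0.0)


class TestEvolve:
    def test_frozen_population_doubles_deterministically(self):
        for i, d in enumerate(evolve(0.0, 0.0, 5, seed_state=1)):
            assert d.probs[2 ** i] == pytest.approx(1.0)

    @pytest.mark.parametrize("py, pz", [(0.02, 0.2), (0.1, 0.05), (0.1, 0.15)])
    def test_distributions_normalized_with_exact_support(self, py, pz):
        for d in evolve(py, pz, 6, seed_state=0):
            assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(d.probs >= 0)
            assert len(d.probs) == 2 ** d.generation + 1

    def test_mean_matches_closed_form_recursion(self):
        py, pz = 0.07, 0.21
        for seed in (0, 1):
            means = [d.mean_fraction for d in evolve(py, pz, 8, seed)]
            np.testing.assert_allclose(
                means, mean_fraction_recursion(py, pz, 8, seed), atol=1e-10)

    def test_mean_fraction_converges_to_stationary_from_both_seeds(self):
        # the mean approaches the stationary fraction geometrically with
        # ratio 1 - py - pz, from either seed state (sharp analytic bound)
        py, pz = 0.02, 0.2
        target = pz / (py + pz)
        ratio = 1 - py - pz
        for seed in (0, 1):
            final = evolve(py, pz, 12, seed)[-1].mean_fraction
            bound = abs(seed - target) * ratio ** 12
            assert abs(final - target) <= bound + 1e-9

    def test_complement_symmetry_is_exact(self):
        d = evolve(0.1, 0.3, 5, seed_state=1)[-1]
        np.testing.assert_array_equal(d.z_probs(), d.probs[::-1])

    def test_swapping_rates_and_seed_mirrors_distribution(self):
        q = evolve(0.12, 0.31, 5, seed_state=0)[-1]
        r = evolve(0.31, 0.12, 5, seed_state=1)[-1]
        np.testing.assert_allclose(q.probs, r.probs[::-1], atol=1e-14)

    def test_generation_cap_enforced(self):
        with pytest.raises(ParameterDomainError):
            evolve(0.1, 0.1, 21, seed_state=0)


class TestSwitchCounts:
    def test_bookkeeping_identities(self):
        from togglekit import SwitchCounts

        c = SwitchCounts(n_y=3, n_z=2, m_y=1, m_z=2)
        assert c.y_prev == c.n_y + c.m_y
        assert c.z_prev == c.n_z + c.m_z
        assert c.y_prime == c.n_y + c.m_z
        assert c.y_prev + c.z_prev == c.n_y + c.n_z + c.m_y + c.m_z


class TestStationary:
    def test_symmetric_rates_give_even_composition(self):
        assert stationary_composition(0.3, 0.3) == 0.5

    def test_closed_form_fraction(self):
        assert stationary_composition(0.1, 0.05) == pytest.approx(1 / 3)

    def test_frozen_switching_has_no_stationary_composition(self):
        with pytest.raises(ParameterDomainError):
            stationary_composition(0.0, 0.0)

    def test_memoryless_mixing_reaches_steady_state_in_one_generation(self):
        assert generations_to_steady(0.5, 0.5, seed_state=0) == 1
        assert generations_to_steady(0.5, 0.5, seed_state=1) == 1

    def test_speed_depends_on_seed_state_for_asymmetric_rates(self):
        g0 = generations_to_steady(0.02, 0.2, seed_state=0)
        g1 = generations_to_steady(0.02, 0.2, seed_state=1)
        assert g0 != g1

    def test_matches_direct_scan_of_mean_recursion(self):
        py, pz, seed = 0.03, 0.11, 1
        target = stationary_composition(py, pz)
        track = mean_fraction_recursion(py, pz, 200, seed)
        first = next(i for i, f in enumerate(track)
                     if abs(f - target) <= 0.001 * target)
        assert generations_to_steady(py, pz, seed) == first


class TestMonteCarloOracle:
    def test_frozen_replicates_are_deterministic(self):
        d = monte_carlo_population(0.0, 0.0, 4, seed_state=1, replicates=500,
                                   rng_seed=0)
        assert d.probs[16] == 1.0

    def test_empirical_mean_within_binomial_error(self):
        py, pz, gens = 0.1, 0.15, 5
        exact = evolve(py, pz, gens, seed_state=1)[-1]
        mc = monte_carlo_population(py, pz, gens, seed_state=1,
                                    replicates=20_000, rng_seed=11)
        se = math.sqrt(float(np.dot(exact.support ** 2, exact.probs))
                       - exact.mean ** 2) / math.sqrt(20_000)
        assert abs(mc.mean - exact.mean) < 3 * se

    def test_distribution_error_shrinks_with_replicates(self):
        py, pz, gens = 0.1, 0.15, 5
        exact = evolve(py, pz, gens, seed_state=0)[-1]
        tv_small = total_variation(
            monte_carlo_population(py, pz, gens, 0, 1_000, rng_seed=5).probs,
            exact.probs)
        tv_large = total_variation(
            monte_carlo_population(py, pz, gens, 0, 100_000, rng_seed=5).probs,
            exact.probs)
        assert tv_large < tv_small

    @given(py=st.floats(0, 1), pz=st.floats(0, 1),
           seed=st.sampled_from([0, 1]))
    @settings(max_examples=30, deadline=None)
    def test_distributions_stay_normalized(self, py, pz, seed):
        d = evolve(py, pz, 4, seed)[-1]
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
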