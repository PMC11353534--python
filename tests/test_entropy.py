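"""Entropy estimators: discrete Shannon, continuous KDE-variance, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import incoherence as inc
from incoherence.entropy import (
    point_mass_profile_variance,
    uniform_profile_variance,
)


class TestDiscreteDistribution:
    def test_rejects_negative_probabilities(self):
        with pytest.raises(ValueError, match="negative"):
            inc.DiscreteDistribution(np.array([1.2, -0.2]))

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum"):
            inc.DiscreteDistribution(np.array([0.5, 0.4]))

    def test_from_counts_normalizes(self):
        d = inc.DiscreteDistribution.from_counts([3, 1])
        assert np.allclose(d.probs, [0.75, 0.25])

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            inc.DiscreteDistribution.from_counts([0, 0, 0])


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "probs, expected, places",
        [
            ([1, 0], 0.0, 12),  # certainty
            ([0.5, 0.5], 1.0, 12),  # one fair bit
            ([0.85, 0.15, 0, 0, 0], 0.6, 1),  # pooled low-entropy pair
            ([0.3, 0.1, 0.2, 0.2, 0.2], 2.2, 1),  # pooled high-entropy pair
        ],
    )
    def test_known_values(self, probs, expected, places):
        assert inc.shannon_entropy(probs) == pytest.approx(expected, abs=10**-places / 2)

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_max_entropy(self, n_states, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(n_states))
        h = inc.shannon_entropy(p)
        assert -1e-12 <= h <= inc.max_entropy_discrete(n_states) + 1e-12

    @given(st.integers(3, 8), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant(self, n_states, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n_states))
        assert inc.shannon_entropy(p) == pytest.approx(
            inc.shannon_entropy(rng.permutation(p)), abs=1e-12
        )


class TestMaxEntropy:
    @pytest.mark.parametrize("n, expected", [(1, 0.0), (2, 1.0), (5, math.log2(5))])
    def test_closed_form(self, n, expected):
        assert inc.max_entropy_discrete(n) == pytest.approx(expected)

    def test_rejects_empty_space(self):
        with pytest.raises(ValueError):
            inc.max_entropy_discrete(0)


class TestPooledDistribution:
    def test_elementwise_mean(self):
        e = inc.DiscreteEnsemble.from_rows([[0.9, 0.1, 0, 0, 0], [0.8, 0.2, 0, 0, 0]])
        assert np.allclose(inc.pooled_distribution(e).probs, [0.85, 0.15, 0, 0, 0])

    def test_identity_pair_pools_to_uniform(self):
        e = inc.DiscreteEnsemble.from_rows(np.eye(2))
        assert np.allclose(inc.pooled_distribution(e).probs, [0.5, 0.5])

    @given(st.integers(2, 6), st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_identical_members_pool_to_member(self, n_states, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(n_states))
        e = inc.DiscreteEnsemble.from_rows([p, p, p])
        assert np.allclose(inc.pooled_distribution(e).probs, p, atol=1e-12)

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError, match="state space"):
            inc.DiscreteEnsemble.from_rows([[1, 0], [1, 0, 0]])


class TestGFComplexity:
    @pytest.mark.parametrize(
        "h, hmax, expected", [(0, 2, 0.0), (2, 2, 0.0), (1, 2, 1.0), (0, 0, 0.0)]
    )
    def test_parabola(self, h, hmax, expected):
        assert inc.gf_complexity(h, hmax) == pytest.approx(expected)


class TestNormalizeObservations:
    def test_affine_endpoints(self):
        e = inc.ContinuousEnsemble.from_rows([[0, 5, 10]])
        assert np.allclose(inc.normalize_observations(e).members[0].values, [0, 0.5, 1])

    def test_degenerate_range_maps_to_half(self):
        e = inc.ContinuousEnsemble.from_rows([[2, 2], [2, 2]])
        out = inc.normalize_observations(e)
        assert all(np.allclose(m.values, 0.5) for m in out.members)

    def test_shared_range_across_members(self):
        e = inc.ContinuousEnsemble.from_rows([[0, 1], [1, 2]])
        out = inc.normalize_observations(e)
        assert np.allclose(out.members[0].values, [0, 0.5])
        assert np.allclose(out.members[1].values, [0.5, 1])


class TestDensityProfile:
    def test_single_observation_on_reference_point(self, entropy_cfg):
        r = entropy_cfg.ref_points
        g = inc.density_profile(inc.ObservationSet(np.array([r[40]])), entropy_cfg)
        assert g.densities[40] == pytest.approx(1.0)

    def test_identical_observations_follow_kernel(self, entropy_cfg):
        c = 0.3
        g = inc.density_profile(inc.ObservationSet(np.full(7, c)), entropy_cfg)
        expected = np.exp(-entropy_cfg.kernel_constant * np.abs(entropy_cfg.ref_points - c))
        assert np.allclose(g.densities, expected)

    def test_matches_brute_force_double_loop(self, rng):
        cfg = inc.ContinuousEntropyConfig(n_ref_points=17, kernel_constant=30.0)
        for _ in range(5):
            obs = rng.random(rng.integers(1, 50))
            g = inc.density_profile(inc.ObservationSet(obs), cfg).densities
            brute = np.array(
                [
                    sum(math.exp(-cfg.kernel_constant * abs(r - o)) for o in obs) / obs.size
                    for r in cfg.ref_points
                ]
            )
            assert np.allclose(g, brute, atol=1e-14)

    def test_large_uniform_sample_matches_quadrature(self, rng, entropy_cfg):
        obs = inc.ObservationSet(rng.random(200_000))
        g = inc.density_profile(obs, entropy_cfg).densities
        k = entropy_cfg.kernel_constant
        r = entropy_cfg.ref_points
        analytic = (2 - np.exp(-k * r) - np.exp(-k * (1 - r))) / k
        assert np.allclose(g, analytic, atol=5e-3)

    def test_out_of_range_rejected(self, entropy_cfg):
        with pytest.raises(ValueError, match="range"):
            inc.density_profile(inc.ObservationSet(np.array([1.5])), entropy_cfg)


class TestContinuousEntropy:
    def test_calibration_identities(self):
        cfg = inc.ContinuousEntropyConfig()
        # the analytic uniform profile sits exactly at the maximum-entropy anchor
        assert uniform_profile_variance(cfg) == pytest.approx(cfg.v0_effective)
        assert point_mass_profile_variance(cfg) == pytest.approx(cfg.v1_effective)
        assert cfg.v1_effective > cfg.v0_effective > 0

    def test_uniform_sample_near_max_entropy(self, rng, entropy_cfg):
        h = inc.continuous_entropy(inc.ObservationSet(rng.random(100_000)), entropy_cfg)
        assert h == pytest.approx(1.0, abs=0.05)

    def test_point_mass_below_uniform(self, rng, entropy_cfg):
        h_point = inc.continuous_entropy(inc.ObservationSet(np.full(500, 0.5)), entropy_cfg)
        h_unif = inc.continuous_entropy(inc.ObservationSet(rng.random(500)), entropy_cfg)
        assert h_point <= h_unif
        assert h_point == pytest.approx(0.0, abs=1e-9)

    def test_explicit_constants_accepted(self):
        cfg = inc.ContinuousEntropyConfig(v0=0.001, v1=0.01)
        assert cfg.v0_effective == 0.001 and cfg.v1_effective == 0.01
        with pytest.raises(ValueError):
            inc.ContinuousEntropyConfig(v0=0.01, v1=0.001)


class TestPooledObservations:
    def test_concatenation(self):
        e = inc.ContinuousEnsemble.from_rows([[1, 2], [3]])
        assert np.allclose(inc.pooled_observations(e).values, [1, 2, 3])

    def test_duplicating_members_preserves_density(self, rng, entropy_cfg):
        obs = rng.random(300)
        once = inc.ContinuousEnsemble.from_rows([obs])
        thrice = inc.ContinuousEnsemble.from_rows([obs, obs, obs])
        g1 = inc.density_profile(inc.pooled_observations(once), entropy_cfg).densities
        g3 = inc.density_profile(inc.pooled_observations(thrice), entropy_cfg).densities
        assert np.allclose(g1, g3, atol=1e-12)
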