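"""Incoherence, its variants, and the comparator divergences."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon as scipy_js_distance

import incoherence as inc
from incoherence.measures import report_from_summary


def summary_of(rows):
    return inc.summarize_discrete(inc.DiscreteEnsemble.from_rows(rows))


def random_ensemble(seed, n_members=None, n_states=None):
    rng = np.random.default_rng(seed)
    k = n_members or rng.integers(2, 6)
    n = n_states or rng.integers(2, 7)
    return inc.DiscreteEnsemble.from_rows(rng.dirichlet(np.ones(n), size=k))


class TestWorkedTable:
    """The low- vs high-entropy two-member comparison, to printed precision."""

    @pytest.mark.parametrize(
        "rows, h_pool, djs, ratio, incoh",
        [
            ([[0.9, 0.1, 0, 0, 0], [0.8, 0.2, 0, 0, 0]], 0.6, 0.014, 0.024, 0.107),
            ([[0.2] * 5, [0.4, 0, 0.2, 0.2, 0.2]], 2.2, 0.125, 0.055, 0.103),
        ],
    )
    def test_values(self, rows, h_pool, djs, ratio, incoh):
        s = summary_of(rows)
        d = inc.jensen_shannon(s)
        assert round(s.pooled_entropy, 1) == h_pool
        assert round(d, 3) == djs
        assert round(d / s.pooled_entropy, 3) == ratio
        assert round(inc.incoherence(s), 3) == incoh


class TestBounds:
    @pytest.mark.parametrize("size", range(2, 11))
    def test_identity_matrix_is_maximal(self, size):
        s = summary_of(np.eye(size))
        assert inc.incoherence(s) == pytest.approx(1.0, abs=1e-12)
        assert inc.t_variant(s) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 5000), st.integers(2, 8), st.integers(2, 6))
    @settings(max_examples=30, deadline=None)
    def test_identical_members_are_coherent(self, seed, n_states, k):
        p = np.random.default_rng(seed).dirichlet(np.ones(n_states))
        s = summary_of([p] * k)
        assert inc.incoherence(s) == pytest.approx(0.0, abs=1e-9)
        assert inc.jensen_shannon(s) == pytest.approx(0.0, abs=1e-9)

    def test_max_min_entropy_pair(self):
        assert inc.incoherence(summary_of([[0.5, 0.5], [1, 0]])) == pytest.approx(
            0.654, abs=5e-4
        )

    def test_zero_pooled_entropy_is_coherent(self):
        s = summary_of([[1, 0], [1, 0]])
        assert s.pooled_entropy == 0.0
        assert inc.incoherence(s) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_incoherence_within_unit_interval(self, seed):
        assert 0.0 <= inc.incoherence(inc.summarize_discrete(random_ensemble(seed))) <= 1.0


class TestJensenShannon:
    def test_identity_pair_is_one_bit(self):
        assert inc.jensen_shannon(summary_of(np.eye(2))) == pytest.approx(1.0)

    @given(st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_two_member_divergence(self, seed):
        """Entropy-difference route equals the classic pairwise definition."""
        rng = np.random.default_rng(seed)
        p, q = rng.dirichlet(np.ones(4), size=2)
        s = summary_of([p, q])
        expected = scipy_js_distance(p, q, base=2) ** 2
        assert inc.jensen_shannon(s) == pytest.approx(expected, abs=1e-10)


class TestVariants:
    def test_identity_l_variant_scaling(self):
        s2, s4 = summary_of(np.eye(2)), summary_of(np.eye(4))
        assert inc.l_variant(s2) == pytest.approx(inc.incoherence(s2))
        assert inc.l_variant(s4) == pytest.approx(inc.incoherence(s4) * math.sqrt(2))

    def test_t_closed_form_for_max_min_pair(self):
        s = summary_of([[0.5, 0.5], [1, 0]])
        assert inc.t_variant(s) == pytest.approx(
            inc.incoherence(s) * math.sqrt(s.pooled_entropy), abs=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_i_t_algebraic_identity(self, seed):
        """I^2 * H~ * Hmax == T^2 * Hmax^2 for any ensemble."""
        s = inc.summarize_discrete(random_ensemble(seed))
        lhs = inc.incoherence(s) ** 2 * s.pooled_entropy * s.h_max
        rhs = inc.t_variant(s) ** 2 * s.h_max**2
        assert lhs == pytest.approx(rhs, abs=1e-9)

    @pytest.mark.parametrize("n_low", [2, 5, 20, 100])
    def test_outlier_emphasis_i_exceeds_t(self, n_low):
        """One uniform among point masses: I decays slower than T."""
        s = summary_of([[0.5, 0.5]] + [[1, 0]] * n_low)
        assert inc.incoherence(s) > inc.t_variant(s)


class TestPairwiseDivergences:
    def test_kl_examples(self):
        assert inc.kl_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0)
        assert inc.kl_divergence([1, 0], [0.5, 0.5]) == pytest.approx(1.0)
        assert inc.kl_divergence([1, 0], [0, 1]) == math.inf

    def test_hellinger_examples(self, rng):
        assert inc.hellinger([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0)
        assert inc.hellinger([1, 0], [0, 1]) == pytest.approx(1.0)
        for _ in range(10):
            p, q = rng.dirichlet(np.ones(5), size=2)
            brute = math.sqrt(0.5 * sum((math.sqrt(a) - math.sqrt(b)) ** 2 for a, b in zip(p, q)))
            assert inc.hellinger(p, q) == pytest.approx(brute, abs=1e-12)

    def test_total_variation_and_earth_mover(self):
        assert inc.total_variation([0.9, 0.1], [0.8, 0.2]) == pytest.approx(0.1)
        assert inc.earth_mover([1, 0], [0, 1]) == pytest.approx(1.0)
        assert inc.earth_mover([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0)

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError):
            inc.kl_divergence([1, 0], [1, 0, 0])


class TestComparatorTests:
    def test_identical_gaussians_anova_accepts_null(self, rng):
        e = inc.ContinuousEnsemble.from_rows(rng.normal(0, 1, size=(3, 2000)))
        out = inc.comparator_tests(e)
        assert out["anova_p"] > 0.05

    def test_disjoint_samples_kruskal_rejects_null(self, rng):
        e = inc.ContinuousEnsemble.from_rows(
            [rng.normal(0, 0.01, 200), rng.normal(5, 0.01, 200)]
        )
        assert inc.comparator_tests(e)["kruskal_p"] < 1e-6

    def test_chi2_on_identity_matrix(self):
        out = inc.comparator_tests(inc.DiscreteEnsemble.from_rows(np.eye(4)))
        assert out["chi2_p"] is not None and 0 <= out["chi2_p"] <= 1

    def test_constant_continuous_input_flagged_absent(self):
        e = inc.ContinuousEnsemble.from_rows([[1.0, 1.0], [1.0, 1.0]])
        out = inc.comparator_tests(e)
        assert out["anova_p"] is None and out["kruskal_p"] is None


class TestReports:
    def test_identity_three_report(self):
        r = inc.measure_discrete(inc.DiscreteEnsemble.from_rows(np.eye(3)))
        assert r.incoherence == pytest.approx(1.0)
        assert r.js_normalized == pytest.approx(1.0)

    def test_single_member_is_coherent(self):
        r = inc.measure_discrete(inc.DiscreteEnsemble.from_rows([[0.4, 0.6]]))
        assert r.incoherence == 0.0 and r.js_divergence == pytest.approx(0.0)

    def test_continuous_minmax_matches_discrete_analogue(self, rng, entropy_cfg):
        members = [np.ones(1000) for _ in range(3)] + [rng.random(1000) for _ in range(3)]
        e = inc.normalize_observations(inc.ContinuousEnsemble.from_rows(members))
        r = inc.measure_continuous(e, entropy_cfg)
        assert r.incoherence == pytest.approx(0.654, abs=0.05)

    @given(st.integers(0, 5000), st.integers(2, 4))
    @settings(max_examples=25, deadline=None)
    def test_duplication_invariance(self, seed, copies):
        e = random_ensemble(seed, n_members=2)
        s1 = inc.summarize_discrete(e)
        s2 = inc.summarize_discrete(
            inc.DiscreteEnsemble(tuple(list(e.members) * copies))
        )
        for f in (inc.incoherence, inc.t_variant, inc.l_variant, inc.jensen_shannon):
            assert f(s1) == pytest.approx(f(s2), abs=1e-9)

    def test_report_serialization_field_order(self):
        r = inc.measure_discrete(inc.DiscreteEnsemble.from_rows(np.eye(2)))
        d = r.to_dict()
        assert list(d)[:5] == [
            "incoherence",
            "t_variant",
            "l_variant",
            "js_divergence",
            "js_normalized",
        ]

    def test_report_from_summary_cgf_max(self):
        # the [0.5,0.5,0,0] member has H = 1 = Hmax/2, maximizing the balance
        s = summary_of([[1, 0, 0, 0], [0.5, 0.5, 0, 0]])
        r = report_from_summary(s)
        assert r.cgf_max == pytest.approx(1.0)
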