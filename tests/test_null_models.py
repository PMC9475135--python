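"""Unit and property tests for the additive/multiplicative effect-size core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressorpower import (
    FactorialExperiment,
    NonPositiveMeanError,
    TreatmentSummary,
    ZeroPooledSDError,
    additive_effect_size,
    j_correction,
    multiplicative_effect_size,
    pooled_sd,
    single_stressor_effect_size,
)


def make_exp(means, sds, ns, id=None):
    arms = [TreatmentSummary(m, s, n) for m, s, n in zip(means, sds, ns)]
    return FactorialExperiment(*arms, id=id)


class TestTreatmentSummary:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean=0.5, sd=-0.1, n=4),
            dict(mean=0.5, sd=float("nan"), n=4),
            dict(mean=float("inf"), sd=0.1, n=4),
            dict(mean=0.5, sd=0.1, n=1),
        ],
    )
    def test_invalid_arms_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TreatmentSummary(**kwargs)


class TestPooledSD:
    @pytest.mark.parametrize("sd,ns", [(0.05, (4, 4, 4, 4)), (0.1, (3, 5, 7, 9))])
    def test_equal_sds_pool_to_themselves(self, sd, ns):
        exp = make_exp((1, 1, 1, 1), (sd,) * 4, ns)
        assert pooled_sd(exp) == pytest.approx(sd)

    def test_weighted_formula(self):
        # independent evaluation: sqrt(sum (n-1) sd^2 / (sum n - 4))
        exp = make_exp((1, 1, 1, 1), (0.02, 0.04, 0.06, 0.08), (3, 4, 5, 6))
        assert pooled_sd(exp) == pytest.approx(0.06094494002200441, rel=1e-12)

    def test_zero_only_when_all_zero(self):
        exp = make_exp((1, 1, 1, 1), (0.0, 0.0, 0.0, 0.0), (4, 4, 4, 4))
        assert pooled_sd(exp) == 0.0


class TestJCorrection:
    @pytest.mark.parametrize("df,expected", [(12, 1 - 3 / 47), (8, 1 - 3 / 31)])
    def test_values(self, df, expected):
        assert j_correction(df) == pytest.approx(expected, rel=1e-15)

    def test_monotone_to_one(self):
        js = [j_correction(df) for df in (2, 5, 20, 100, 10_000)]
        assert all(a < b for a, b in zip(js, js[1:]))
        assert 0 < js[0] < 1
        assert js[-1] == pytest.approx(1.0, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            j_correction(0)


class TestAdditiveEffectSize:
    def test_exactly_additive_means_give_zero(self):
        exp = make_exp((0.8, 0.65, 0.65, 0.5), (0.07, 0.03, 0.05, 0.04), (4, 6, 3, 5))
        assert additive_effect_size(exp).effect_size == pytest.approx(0.0, abs=1e-14)

    def test_worked_example(self):
        # contrast 0.15, s = 0.05, J(12) = 44/47
        exp = make_exp((0.8, 0.65, 0.65, 0.65), (0.05,) * 4, (4, 4, 4, 4))
        r = additive_effect_size(exp)
        assert r.effect_size == pytest.approx(3 * (1 - 3 / 47), rel=1e-12)
        assert r.effect_size == pytest.approx(2.80851, abs=1e-5)
        assert r.df == 12
        assert r.se == pytest.approx(math.sqrt(r.variance), rel=1e-15)
        # CI is symmetric with z(0.025) half-width
        assert (r.ci_high - r.ci_low) / 2 == pytest.approx(1.9599639845 * r.se, rel=1e-9)

    def test_zero_pooled_sd_error(self):
        exp = make_exp((0.8, 0.65, 0.65, 0.6), (0.0,) * 4, (4, 4, 4, 4))
        with pytest.raises(ZeroPooledSDError):
            additive_effect_size(exp)

    def test_brute_force_reevaluation(self):
        # the formulas, re-evaluated from scratch without any package code
        rng = np.random.default_rng(0)
        for _ in range(100):
            means = rng.uniform(-2, 2, size=4)
            sds = rng.uniform(0.01, 1.0, size=4)
            ns = rng.integers(2, 40, size=4)
            exp = make_exp(means, sds, ns)
            r = additive_effect_size(exp, alpha=0.05)

            mc, ma, mb, mi = means
            total = int(ns.sum())
            s = math.sqrt(sum((n - 1) * sd**2 for n, sd in zip(ns, sds)) / (total - 4))
            j = 1 - 3 / (4 * (total - 4) - 1)
            es = j * (mi - ma - mb + mc) / s
            v = j**2 * (sum(1 / n for n in ns) + es**2 / (2 * total))
            assert r.effect_size == pytest.approx(es, rel=1e-12)
            assert r.variance == pytest.approx(v, rel=1e-12)

    @given(
        c=st.floats(0.5, 5),
        shift=st.floats(-10, 10),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_and_location_invariance(self, c, shift, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        means = rng.uniform(-1, 1, size=4)
        sds = rng.uniform(0.05, 0.5, size=4)
        ns = rng.integers(2, 20, size=4)
        base = additive_effect_size(make_exp(means, sds, ns)).effect_size
        scaled = additive_effect_size(make_exp(means * c, sds * c, ns)).effect_size
        shifted = additive_effect_size(make_exp(means + shift, sds, ns)).effect_size
        assert scaled == pytest.approx(base, rel=1e-9)
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_contrast_antisymmetry(self):
        # relabelling arms so the contrast negates flips the sign exactly
        means, sds, ns = (0.8, 0.6, 0.7, 0.4), (0.1, 0.2, 0.15, 0.12), (3, 5, 4, 6)
        fwd = additive_effect_size(make_exp(means, sds, ns)).effect_size
        # swap C<->A and B<->I: new contrast = -(old contrast), same pooled SD/J
        means2 = (means[1], means[0], means[3], means[2])
        sds2 = (sds[1], sds[0], sds[3], sds[2])
        ns2 = (ns[1], ns[0], ns[3], ns[2])
        rev = additive_effect_size(make_exp(means2, sds2, ns2)).effect_size
        assert rev == pytest.approx(-fwd, rel=1e-12)

    def test_ci_halfwidth_shrinks_with_n(self):
        widths = []
        for n in (3, 6, 12, 24, 48):
            r = additive_effect_size(make_exp((0.8, 0.65, 0.65, 0.6), (0.05,) * 4, (n,) * 4))
            widths.append(r.ci_high - r.ci_low)
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestMultiplicativeEffectSize:
    def test_multiplicative_means_give_zero(self):
        exp = make_exp((1.0, 0.5, 0.5, 0.25), (0.05,) * 4, (4, 4, 4, 4))
        assert multiplicative_effect_size(exp).effect_size == pytest.approx(0.0, abs=1e-14)

    def test_worked_example(self):
        exp = make_exp((0.8, 0.65, 0.65, 0.55), (0.05,) * 4, (4, 4, 4, 4))
        r = multiplicative_effect_size(exp)
        assert r.effect_size == pytest.approx(math.log(0.55 * 0.8 / (0.65 * 0.65)), rel=1e-12)
        assert r.effect_size == pytest.approx(0.04058528, abs=1e-8)
        assert r.variance == pytest.approx(0.006001258084136144, rel=1e-12)
        assert r.j_correction == 1.0
        assert r.pooled_sd is None

    @pytest.mark.parametrize("bad_mean", [0.0, -0.3])
    def test_non_positive_mean_error(self, bad_mean):
        exp = make_exp((0.8, bad_mean, 0.65, 0.55), (0.05,) * 4, (4, 4, 4, 4))
        with pytest.raises(NonPositiveMeanError):
            multiplicative_effect_size(exp)

    @given(c=st.floats(0.1, 50), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_ratio_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        means = rng.uniform(0.2, 3.0, size=4)
        sds = rng.uniform(0.01, 0.3, size=4)
        base = multiplicative_effect_size(make_exp(means, sds, (5, 5, 5, 5)))
        scaled = multiplicative_effect_size(make_exp(means * c, sds * c, (5, 5, 5, 5)))
        assert scaled.effect_size == pytest.approx(base.effect_size, rel=1e-9, abs=1e-12)
        assert scaled.variance == pytest.approx(base.variance, rel=1e-9)


class TestSingleStressor:
    def test_identical_means_give_zero(self):
        r = single_stressor_effect_size(
            TreatmentSummary(0.7, 0.1, 8), TreatmentSummary(0.7, 0.2, 8)
        )
        assert r.effect_size == 0.0

    def test_worked_example(self):
        r = single_stressor_effect_size(
            TreatmentSummary(0.8, 0.05, 10), TreatmentSummary(0.65, 0.05, 10)
        )
        assert r.effect_size == pytest.approx(-3 * (1 - 3 / 71), rel=1e-12)
        assert r.effect_size == pytest.approx(-2.87324, abs=1e-5)
        assert r.df == 18

    def test_agrees_with_metafor_smd(self):
        # frozen from R: metafor::escalc(measure="SMD", m1i=.65, sd1i=.05,
        # n1i=10, m2i=.8, sd2i=.05, n2i=10) -> yi=-2.8729392811, vi=0.4063445028
        # (metafor uses the exact gamma-function bias correction; ours is the
        # standard 1 - 3/(4df-1) approximation, so agreement is ~1e-4)
        r = single_stressor_effect_size(
            TreatmentSummary(0.8, 0.05, 10), TreatmentSummary(0.65, 0.05, 10)
        )
        assert r.effect_size == pytest.approx(-2.8729392811, abs=1e-3)
        assert r.variance == pytest.approx(0.4063445028, abs=1e-3)

    def test_variance_collapses_at_zero_effect(self):
        r = single_stressor_effect_size(
            TreatmentSummary(0.5, 0.1, 10), TreatmentSummary(0.5, 0.1, 10)
        )
        assert r.variance == pytest.approx(0.2, rel=1e-12)
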