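"""Tests of the four causal estimators, heterogeneity and OR scaling.

Printed-value comparisons use the published serum-mineral analysis; the
independent routes (statsmodels regression, brute-force weight scans) never
reuse the implementation's code path.
"""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit import (
    BootstrapSpec,
    ExposureSpec,
    InstrumentSet,
    InsufficientInstrumentsError,
    SnpAssociation,
    ValidationError,
    cochran_q,
    egger_estimate,
    ivw_estimate,
    scale_to_or,
    wald_ratio,
    weighted_median,
    weighted_median_estimate,
    weighted_mode,
    weighted_mode_estimate,
)

UNIT = ExposureSpec("unit", 1.0, "unit", 0.01)


def make_set(bx, by, sy, sx=None, sd=1.0):
    sx = sx if sx is not None else [0.01] * len(bx)
    exposure = ExposureSpec("x", sd, "unit", 0.01)
    snps = tuple(
        SnpAssociation(rsid=f"rs{i}", effect_allele="A", beta_exposure=float(b),
                       se_exposure=float(s), beta_outcome=float(o), se_outcome=float(t))
        for i, (b, s, o, t) in enumerate(zip(bx, sx, by, sy))
    )
    return InstrumentSet(exposure, snps, "made")


def random_sets(seed, n_sets=20, max_n=8):
    rng = np.random.default_rng(seed)
    for _ in range(n_sets):
        n = int(rng.integers(2, max_n + 1))
        yield make_set(
            bx=rng.uniform(0.01, 0.1, n) * rng.choice([-1, 1], n),
            by=rng.normal(0, 0.05, n),
            sy=rng.uniform(0.005, 0.05, n),
        )


class TestIvw:
    def test_calcium_reproduces_printed_or(self, calcium):
        r = ivw_estimate(calcium)
        assert round(r.or_per_sd, 2) == 0.89
        assert r.ci_low == pytest.approx(0.67, abs=0.01)
        assert r.ci_high == pytest.approx(1.17, abs=0.01)

    def test_magnesium_reproduces_printed_or(self, magnesium):
        r = ivw_estimate(magnesium)
        assert round(r.or_per_sd, 2) == 0.89
        assert round(r.ci_low, 2) == 0.72
        assert round(r.ci_high, 2) == 1.10

    def test_single_snp_equals_wald_ratio(self, calcium):
        single = InstrumentSet(calcium.exposure, calcium.snps[:1], "one")
        r = ivw_estimate(single)
        w = wald_ratio(calcium.snps[0])
        assert r.beta_per_unit == pytest.approx(w.ratio, rel=1e-12)
        assert r.se_per_unit == pytest.approx(w.se, rel=1e-12)

    def test_single_snp_random_effects_falls_back(self, calcium):
        single = InstrumentSet(calcium.exposure, calcium.snps[:1], "one")
        r = ivw_estimate(single, model="multiplicative_random")
        assert r.se_per_unit == pytest.approx(ivw_estimate(single).se_per_unit)
        assert "fell back" in r.note

    def test_multiplicative_random_floors_at_fixed(self, calcium, magnesium):
        # calcium is under-dispersed (Q < df): the floor leaves the SE untouched
        ca_fixed, ca_rand = ivw_estimate(calcium), ivw_estimate(calcium, "multiplicative_random")
        assert ca_rand.se_per_unit == pytest.approx(ca_fixed.se_per_unit)
        # magnesium is over-dispersed: the SE inflates by sqrt(Q/df)
        mg_fixed, mg_rand = ivw_estimate(magnesium), ivw_estimate(magnesium, "multiplicative_random")
        expected = mg_fixed.se_per_unit * np.sqrt(mg_fixed.q_statistic / mg_fixed.q_df)
        assert mg_rand.se_per_unit == pytest.approx(expected)

    def test_equals_origin_constrained_wls(self, calcium, magnesium):
        """Dual route: IVW must agree exactly with weighted regression through the origin."""
        for instruments in (calcium, magnesium):
            fit = sm.WLS(
                instruments.beta_outcome,
                instruments.beta_exposure[:, None],
                weights=1.0 / instruments.se_outcome**2,
            ).fit()
            r = ivw_estimate(instruments)
            assert r.beta_per_unit == pytest.approx(float(fit.params[0]), rel=1e-12)
            plain_se = float(fit.bse[0]) / np.sqrt(float(fit.scale))
            assert r.se_per_unit == pytest.approx(plain_se, rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_invariant_to_snp_reorientation(self, seed):
        for instruments in random_sets(seed, n_sets=5):
            base = ivw_estimate(instruments)
            rng = np.random.default_rng(seed)
            flip = rng.choice([-1.0, 1.0], len(instruments))
            flipped = make_set(
                instruments.beta_exposure * flip,
                instruments.beta_outcome * flip,
                instruments.se_outcome,
            )
            r = ivw_estimate(flipped)
            assert r.beta_per_unit == pytest.approx(base.beta_per_unit, rel=1e-12)
            assert r.se_per_unit == pytest.approx(base.se_per_unit, rel=1e-12)

    def test_or_is_exp_of_beta_per_sd(self, calcium):
        r = ivw_estimate(calcium)
        assert r.or_per_sd == pytest.approx(np.exp(r.beta_per_sd), rel=1e-12)
        assert r.ci_low <= r.or_per_sd <= r.ci_high
        assert r.q_df == r.n_snps - 1


class TestCochranQ:
    def test_calcium_homogeneous(self, calcium):
        r = ivw_estimate(calcium)
        q = cochran_q(calcium, r.beta_per_unit)
        assert q.p_value == pytest.approx(0.83, abs=0.02)

    def test_magnesium_suggestive_heterogeneity(self, magnesium):
        r = ivw_estimate(magnesium)
        assert cochran_q(magnesium, r.beta_per_unit).p_value == pytest.approx(0.09, abs=0.02)

    def test_post_exclusion_homogeneous(self, magnesium, exclusions):
        from mrkit import apply_exclusion

        reduced = apply_exclusion(magnesium, exclusions["shroom3"])
        r = ivw_estimate(reduced)
        assert cochran_q(reduced, r.beta_per_unit).p_value == pytest.approx(0.73, abs=0.02)

    def test_identical_ratios_give_zero(self):
        s = make_set(bx=[0.1, 0.2, 0.4], by=[0.05, 0.10, 0.20], sy=[0.01, 0.02, 0.01])
        q = cochran_q(s, 0.5)
        assert q.q == pytest.approx(0.0, abs=1e-20)
        assert q.p_value == 1.0

    def test_needs_two_snps(self, calcium):
        single = InstrumentSet(calcium.exposure, calcium.snps[:1], "one")
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(single, 0.0)

    def test_shift_invariance_against_ivw_reference(self):
        """Q around the IVW estimate is invariant to adding a constant to all outcome slopes."""
        s = make_set(bx=[0.1, 0.2, 0.3], by=[0.02, 0.08, 0.01], sy=[0.01, 0.02, 0.015])
        shifted = make_set(
            s.beta_exposure, s.beta_outcome + 0.7 * s.beta_exposure, s.se_outcome
        )
        q0 = cochran_q(s, ivw_estimate(s).beta_per_unit)
        q1 = cochran_q(shifted, ivw_estimate(shifted).beta_per_unit)
        assert q1.q == pytest.approx(q0.q, rel=1e-9)


class TestEgger:
    def test_calcium_intercept(self, calcium):
        r = egger_estimate(calcium)
        i = r.egger_intercept
        assert i.value == pytest.approx(0.017, abs=0.002)
        assert i.p_value == pytest.approx(0.24, abs=0.05)
        assert i.ci_low == pytest.approx(-0.012, abs=0.002)
        assert i.ci_high == pytest.approx(0.046, abs=0.002)

    def test_magnesium_intercept(self, magnesium):
        r = egger_estimate(magnesium)
        i = r.egger_intercept
        assert i.value == pytest.approx(-0.023, abs=0.002)
        assert i.p_value == pytest.approx(0.50, abs=0.05)
        assert i.ci_low == pytest.approx(-0.088, abs=0.002)
        assert i.ci_high == pytest.approx(0.043, abs=0.002)

    def test_closed_form_weighted_regression(self, calcium, magnesium):
        """Independent route: the textbook weighted simple-regression formulas."""
        for instruments in (calcium, magnesium):
            bx, by = instruments.beta_exposure, instruments.beta_outcome
            w = 1.0 / instruments.se_outcome**2
            xbar = np.sum(w * bx) / np.sum(w)
            ybar = np.sum(w * by) / np.sum(w)
            slope = np.sum(w * (bx - xbar) * (by - ybar)) / np.sum(w * (bx - xbar) ** 2)
            intercept = ybar - slope * xbar
            r = egger_estimate(instruments)
            assert r.beta_per_unit == pytest.approx(slope, rel=1e-10)
            assert r.egger_intercept.value == pytest.approx(intercept, rel=1e-10)

    def test_exact_linear_law(self):
        s = make_set(bx=[0.1, 0.2, 0.3, 0.4], by=[0.05, 0.10, 0.15, 0.20],
                     sy=[0.01, 0.02, 0.015, 0.01])
        r = egger_estimate(s)
        assert r.egger_intercept.value == pytest.approx(0.0, abs=1e-12)
        assert r.beta_per_unit == pytest.approx(0.5, rel=1e-10)

    def test_negative_exposure_betas_reoriented(self):
        s = make_set(bx=[0.1, 0.2, 0.3, 0.4], by=[0.05, 0.10, 0.15, 0.20],
                     sy=[0.01, 0.02, 0.015, 0.01])
        flipped = make_set(bx=[-0.1, 0.2, -0.3, 0.4], by=[-0.05, 0.10, -0.15, 0.20],
                           sy=[0.01, 0.02, 0.015, 0.01])
        assert egger_estimate(flipped).beta_per_unit == pytest.approx(
            egger_estimate(s).beta_per_unit, rel=1e-10
        )

    def test_plain_se_convention_smaller_when_overdispersed(self, magnesium):
        plain = egger_estimate(magnesium, se_method="plain")
        disp = egger_estimate(magnesium)
        assert plain.egger_intercept.se < disp.egger_intercept.se

    def test_needs_three_snps(self, calcium):
        with pytest.raises(InsufficientInstrumentsError):
            egger_estimate(InstrumentSet(calcium.exposure, calcium.snps[:2], "two"))

    def test_degenerate_design_rejected(self):
        s = make_set(bx=[0.1, 0.1, 0.1], by=[0.05, 0.02, 0.01], sy=[0.01, 0.01, 0.01])
        with pytest.raises(ValidationError, match="degenerate"):
            egger_estimate(s)


def brute_force_weighted_median(values, weights):
    """Direct cumulative-weight scan with linear interpolation at weight 0.5."""
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    positions = np.cumsum(w) - w / 2
    if 0.5 <= positions[0]:
        return v[0]
    for j in range(1, len(v)):
        if positions[j] >= 0.5:
            frac = (0.5 - positions[j - 1]) / (positions[j] - positions[j - 1])
            return v[j - 1] + frac * (v[j] - v[j - 1])
    return v[-1]


class TestWeightedMedian:
    def test_calcium_reproduces_printed_or(self, calcium):
        r = weighted_median_estimate(calcium, BootstrapSpec(200, 7))
        assert r.or_per_sd == pytest.approx(0.87, abs=0.01)

    def test_magnesium_reproduces_printed_or(self, magnesium):
        r = weighted_median_estimate(magnesium, BootstrapSpec(200, 7))
        assert r.or_per_sd == pytest.approx(0.98, abs=0.01)

    def test_equal_weights_match_plain_median(self):
        rng = np.random.default_rng(0)
        for n in (3, 4, 5, 9):
            v = rng.normal(size=n)
            # interpolated (Hazen) definition of the sample median
            q = np.quantile(v, 0.5, method="hazen")
            assert weighted_median(v, np.ones(n)) == pytest.approx(q, rel=1e-10)

    def test_all_equal_ratios_return_constant(self):
        assert weighted_median([1.7] * 5, [1, 2, 3, 4, 5]) == pytest.approx(1.7)

    @given(
        n=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_matches_brute_force_scan(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=n)
        w = rng.uniform(0.1, 5.0, size=n)
        assert weighted_median(v, w) == pytest.approx(
            brute_force_weighted_median(v, w), rel=1e-10, abs=1e-12
        )

    def test_bootstrap_se_is_seed_deterministic(self, calcium):
        a = weighted_median_estimate(calcium, BootstrapSpec(100, 3))
        b = weighted_median_estimate(calcium, BootstrapSpec(100, 3))
        c = weighted_median_estimate(calcium, BootstrapSpec(100, 4))
        assert a.se_per_unit == b.se_per_unit
        assert a.se_per_unit != c.se_per_unit

    def test_needs_three_snps(self, calcium):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median_estimate(InstrumentSet(calcium.exposure, calcium.snps[:2], "two"))


class TestWeightedMode:
    def test_calcium_reproduces_printed_or(self, calcium):
        r = weighted_mode_estimate(calcium, bootstrap=BootstrapSpec(200, 7))
        assert r.or_per_sd == pytest.approx(0.81, abs=0.02)

    def test_magnesium_reproduces_printed_or(self, magnesium):
        r = weighted_mode_estimate(magnesium, bootstrap=BootstrapSpec(200, 7))
        assert r.or_per_sd == pytest.approx(1.05, abs=0.02)

    def test_all_equal_ratios_return_constant(self):
        assert weighted_mode([0.3] * 4, [1, 1, 2, 2]) == pytest.approx(0.3)

    def test_mode_tracks_the_heavier_cluster(self):
        # two clusters: the one with more total weight should win
        v = [0.0, 0.01, -0.005, 1.0, 1.01]
        w = [3.0, 3.0, 3.0, 1.0, 1.0]
        assert abs(weighted_mode(v, w)) < 0.2
        w_flipped = [1.0, 1.0, 1.0, 5.0, 5.0]
        assert abs(weighted_mode(v, w_flipped) - 1.0) < 0.2

    def test_non_positive_phi_rejected(self, calcium):
        with pytest.raises(ValidationError):
            weighted_mode_estimate(calcium, phi=0.0)

    def test_needs_three_snps(self, calcium):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode_estimate(InstrumentSet(calcium.exposure, calcium.snps[:2], "two"))


class TestScaleToOr:
    def test_null_effect(self):
        scaled = scale_to_or(0.0, 0.3, 0.5)
        assert scaled.odds_ratio == 1.0
        assert scaled.ci_low * scaled.ci_high == pytest.approx(1.0, rel=1e-12)
        assert scaled.p_value == pytest.approx(1.0)

    def test_hand_computed_calcium_ivw(self):
        scaled = scale_to_or(-0.2252, 0.2827, 0.5)
        assert scaled.odds_ratio == pytest.approx(0.89, abs=0.005)
        assert scaled.ci_low == pytest.approx(0.68, abs=0.01)
        assert scaled.ci_high == pytest.approx(1.18, abs=0.01)

    @given(
        beta=st.floats(-2, 2, allow_nan=False),
        se=st.floats(0.01, 2),
        sd1=st.floats(0.05, 3),
        sd2=st.floats(0.05, 3),
    )
    @settings(deadline=None, derandomize=True)
    def test_p_value_invariant_to_sd(self, beta, se, sd1, sd2):
        assert scale_to_or(beta, se, sd1).p_value == pytest.approx(
            scale_to_or(beta, se, sd2).p_value, rel=1e-9
        )
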