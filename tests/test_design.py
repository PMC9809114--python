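"""Alpha spending, boundary computation, futility calibration, domain types."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from gatedgsd.design import (
    AlphaAllocation,
    AnalysisSchedule,
    CombinationWeights,
    FutilityRule,
    compute_boundaries,
    futility_threshold,
    implied_futility_events,
    spend_alpha,
)
from gatedgsd.presets import load_setting, make_design


def mvn_no_cross(bounds, fractions):
    """Oracle: P(Z_1 < c_1, ..., Z_k < c_k) under the canonical joint normal."""
    t = np.asarray(fractions)
    k = t.size
    if k == 0:
        return 1.0
    cov = np.sqrt(np.minimum.outer(t, t) / np.maximum.outer(t, t))
    return float(
        multivariate_normal(mean=np.zeros(k), cov=cov, allow_singular=True).cdf(
            np.asarray(bounds)
        )
    )


class TestSpendAlpha:
    def test_exhausts_alpha_at_full_information(self):
        assert spend_alpha(1.0, 0.025) == pytest.approx(0.025, abs=1e-12)

    @pytest.mark.parametrize(
        "t, alpha, expected",
        [(0.5, 0.025, 0.0015253), (0.9, 0.01, 0.0066243)],
    )
    def test_closed_form_values(self, t, alpha, expected):
        # frozen from direct evaluation of 2*(1 - Phi(Phi^-1(1-a/2)/sqrt(t)))
        assert spend_alpha(t, alpha) == pytest.approx(expected, rel=1e-4)

    def test_nondecreasing_in_t(self):
        grid = np.linspace(0.05, 1.0, 40)
        vals = [spend_alpha(t, 0.025) for t in grid]
        assert np.all(np.diff(vals) >= 0)

    @pytest.mark.parametrize("t", [0.0, -0.2, 1.2])
    def test_domain_errors(self, t):
        with pytest.raises(ValueError):
            spend_alpha(t, 0.025)


class TestComputeBoundaries:
    def test_single_look_is_fixed_test(self):
        b = compute_boundaries([1.0], 0.025)
        assert b.z_bounds[0] == pytest.approx(norm.isf(0.025), abs=1e-9)

    def test_two_look_obf_values(self):
        # standard Lan-DeMets O'Brien-Fleming boundaries at t = (0.5, 1)
        b = compute_boundaries([0.5, 1.0], 0.025)
        assert b.z_bounds[0] == pytest.approx(2.963, abs=2e-3)
        assert b.z_bounds[1] == pytest.approx(1.969, abs=2e-3)

    @pytest.mark.parametrize(
        "fractions, alpha",
        [
            ((0.5, 1.0), 0.025),
            ((0.9, 1.0), 0.01),
            ((0.66, 0.91, 1.0), 0.025),
            ((0.69, 0.92, 1.0), 0.0128),
        ],
    )
    def test_crossing_matches_mvn_oracle(self, fractions, alpha):
        b = compute_boundaries(fractions, alpha)
        cum_spend = [spend_alpha(t, alpha) for t in fractions]
        incr = np.diff([0.0] + cum_spend)
        for k in range(len(fractions)):
            oracle = mvn_no_cross(b.z_bounds[:k], fractions[:k]) - mvn_no_cross(
                b.z_bounds[: k + 1], fractions[: k + 1]
            )
            assert oracle == pytest.approx(incr[k], abs=1e-4)

    def test_alpha_conservation(self):
        b = compute_boundaries((0.66, 0.91, 1.0), 0.025)
        assert b.total_crossing == pytest.approx(0.025, abs=1e-6)

    def test_partial_spend_when_final_look_early(self):
        # a hypothesis whose last look is before full information spends
        # only f(t_last) < alpha
        b = compute_boundaries((0.45, 0.9), 0.025)
        assert b.total_crossing == pytest.approx(spend_alpha(0.9, 0.025), abs=1e-6)

    def test_monotone_in_alpha(self):
        lo = compute_boundaries((0.5, 1.0), 0.01)
        hi = compute_boundaries((0.5, 1.0), 0.05)
        assert all(h < l for h, l in zip(hi.z_bounds, lo.z_bounds))

    def test_interim_look_raises_final_boundary(self):
        single = compute_boundaries([1.0], 0.025)
        two = compute_boundaries([0.5, 1.0], 0.025)
        assert two.z_bounds[-1] > single.z_bounds[0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_boundaries((0.8, 0.5), 0.025)
        with pytest.raises(ValueError):
            compute_boundaries((0.5, 1.0), -0.01)


class TestFutilityCalibration:
    def test_median_case(self):
        assert futility_threshold(0.7, 0.5, 200) == pytest.approx(0.7, abs=1e-12)

    def test_monte_carlo_oracle(self):
        # P(observed HR > theta | true HR) should equal gamma under the
        # log-normal sampling approximation
        theta = futility_threshold(0.7, 0.05, 171)
        rng = np.random.default_rng(7)
        draws = np.exp(rng.normal(math.log(0.7), 2 / math.sqrt(171), size=400_000))
        assert np.mean(draws > theta) == pytest.approx(0.05, abs=0.002)

    def test_monotone_in_events(self):
        thetas = [futility_threshold(0.7, 0.05, d) for d in (50, 100, 200, 400)]
        assert np.all(np.diff(thetas) < 0)  # more events -> tighter threshold

    def test_round_trip_with_implied_events(self):
        for theta in (0.9, 0.85, 0.83):
            d = implied_futility_events(0.7, 0.05, theta)
            assert futility_threshold(0.7, 0.05, d) <= theta
            if d > 1:
                assert futility_threshold(0.7, 0.05, d - 1) > theta

    def test_degenerate_gamma_half(self):
        assert implied_futility_events(0.7, 0.5, 0.9) == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            futility_threshold(0.7, 0.05, 0)
        with pytest.raises(ValueError):
            implied_futility_events(0.7, 0.05, 0.6)


class TestDomainTypes:
    def test_alpha_allocation_sums(self):
        a = AlphaAllocation(0.025, 0.0022, 0.00165, 0.0128, 0.00835)
        a.validate("GSD")
        with pytest.raises(ValueError):
            a.validate("gGSD")
        g = AlphaAllocation(0.025, 0.01429, 0.01071, 0.01513, 0.00987)
        g.validate("gGSD")
        with pytest.raises(ValueError):
            g.validate("AD")

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnalysisSchedule({("F", "PFS"): (0.9, 0.8)})
        with pytest.raises(ValueError):
            AnalysisSchedule({("F", "PFS"): (0.5, 0.9)})
        sched = AnalysisSchedule({("F", "PFS"): (0.9, 1.0), ("F", "OS"): (0.69, 0.92, 1.0)})
        assert sched.tested_at("F", "PFS", 2)
        assert not sched.tested_at("F", "PFS", 3)
        assert sched.final_look("F", "OS") == 3

    def test_weights_validation_and_immutability(self):
        with pytest.raises(ValueError):
            CombinationWeights((0.5, 0.5), (0.7, 0.3))
        w = CombinationWeights((math.sqrt(0.5),) * 2, (math.sqrt(0.5),) * 2)
        with pytest.raises(Exception):
            w.pfs = (1.0, 0.0)

    def test_futility_rule_from_thresholds(self):
        rule = FutilityRule.from_thresholds(0.85, 0.9)
        assert (rule.d_F, rule.d_S) == (288, 172)


class TestPresets:
    @pytest.mark.parametrize("setting", [1, 2, 3])
    def test_presets_load_and_validate(self, setting):
        for variant in ("gGSD", "GSD", "AD"):
            d = make_design(setting, variant)
            assert d.setting == setting
            total = (
                d.alphas.alpha1 + d.alphas.alpha2 + d.alphas.alpha3 + d.alphas.alpha4
            )
            if variant == "gGSD":
                assert total == pytest.approx(0.05, abs=1e-9)  # alpha per population
            else:
                assert total == pytest.approx(0.025, abs=1e-9)

    def test_setting_parameters(self):
        raw = load_setting(1)
        assert raw["n_total"] == 554 and raw["subgroup_prevalence"] == 0.75
        assert raw["futility"]["theta"] == {"F": 0.85, "S": 0.90}
        raw2 = load_setting(2)
        assert raw2["n_total"] == 924 and raw2["enroll_duration"] == 33.0
        raw3 = load_setting(3)
        assert raw3["hazard_ratio"]["OS"]["complement"] == 1.0

    def test_global_null_override(self):
        d = make_design(1, "gGSD", global_null=True)
        assert all(h == 1.0 for h in d.hazard_ratio.values())

    def test_boundary_export_rows(self):
        d = make_design(1, "GSD")
        rows = d.boundary_set("S", "OS").to_rows("S-OS")
        assert len(rows) == 3
        assert rows[0]["z_bound"] > rows[-1]["z_bound"]  # OBF-type decrease
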