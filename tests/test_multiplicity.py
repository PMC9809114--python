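"""Combination tests, Hochberg intersections, closed testing, alpha graph."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from gatedgsd.multiplicity import (
    HypothesisGraph,
    StagewisePValues,
    closed_test_step,
    graphical_update,
    hochberg_intersection,
    intersection_boundary,
    inverse_normal_combine,
)

SQ5 = math.sqrt(0.5)
probs = st.floats(1e-6, 1 - 1e-6)


class TestInverseNormalCombine:
    def test_degenerate_weight_passes_through(self):
        z, p = inverse_normal_combine(0.1, 0.7, 1.0, 0.0)
        assert z == pytest.approx(norm.isf(0.1), abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_equal_small_pvalues(self):
        z, p = inverse_normal_combine(0.025, 0.025, SQ5, SQ5)
        assert z == pytest.approx(2.772, abs=1e-3)
        assert p == pytest.approx(0.00279, abs=5e-5)

    def test_neutral_pvalues_give_zero(self):
        z, p = inverse_normal_combine(0.5, 0.5, SQ5, SQ5)
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(0.5)

    def test_boundary_pvalue_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            z, _ = inverse_normal_combine(0.0, 0.5, SQ5, SQ5)
        assert np.isfinite(z)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            inverse_normal_combine(0.1, 0.1, 0.9, 0.9)


class TestHochberg:
    @pytest.mark.parametrize(
        "pF, pS, expected", [(0.01, 0.04, 0.02), (0.3, 0.3, 0.3), (0.03, 0.001, 0.002)]
    )
    def test_formula(self, pF, pS, expected):
        assert hochberg_intersection(pF, pS) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(probs, probs)
    def test_symmetric_and_bounded_below(self, pF, pS):
        h = hochberg_intersection(pF, pS)
        assert h == hochberg_intersection(pS, pF)
        assert h >= min(pF, pS) - 1e-15
        assert h <= 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(probs, probs, st.floats(1e-6, 0.5))
    def test_monotone_in_each_argument(self, pF, pS, eps):
        h = hochberg_intersection(pF, pS)
        assert hochberg_intersection(min(pF + eps, 1.0), pS) >= h - 1e-15


class TestIntersectionBoundary:
    def test_minimum_and_single(self):
        assert intersection_boundary([2.96, 2.49]) == pytest.approx(2.49)
        assert intersection_boundary([2.1]) == pytest.approx(2.1)
        assert intersection_boundary([2.3, 2.3]) == pytest.approx(2.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            intersection_boundary([])


def closure_oracle(scenario, p1, p2, w1, w2, bounds):
    """Brute-force closed testing over the two-population closure for one
    endpoint: an elementary hypothesis is rejected iff its own test and every
    intersection containing it (here only {F,S}) cross their boundaries."""
    def comb(a, b):
        return w1 * norm.isf(a) + w2 * norm.isf(b)

    def hoch(a, b):
        return min(2 * min(a, b), max(a, b))

    p1fs = hoch(p1["F"], p1["S"])
    if scenario == "S_only":
        p2c = p2["S"]
    elif scenario == "F_only":
        p2c = p2["F"]
    else:
        p2c = hoch(p2["F"], p2["S"])
    active = {"S_only": ["S"], "F_only": ["F"], "F_and_S": ["F", "S"]}[scenario]
    fs_rejected = comb(p1fs, p2c) >= min(bounds[pop] for pop in active)
    return {
        pop: fs_rejected and comb(p1[pop], p2[pop]) >= bounds[pop] for pop in active
    }


class TestClosedTestStep:
    def test_neutral_pvalues_never_reject(self):
        pv = StagewisePValues(p1={"F": 0.5, "S": 0.5}, p2={"F": 0.5, "S": 0.5})
        d = closed_test_step("S", "F_and_S", pv, SQ5, SQ5, 2.0, 2.0)
        assert not d.reject_elementary and not d.reject_intersection

    def test_closure_blocks_elementary_without_intersection(self):
        # intersection clearly above boundary, elementary clearly below
        pv = StagewisePValues(p1={"F": 0.5, "S": 0.0001}, p2={"F": 0.5, "S": 0.0001})
        d = closed_test_step("F", "F_and_S", pv, SQ5, SQ5,
                             elementary_bound=2.5, intersection_bound=2.0)
        assert d.reject_intersection and not d.reject_elementary

    def test_intersection_persistence(self):
        pv = StagewisePValues(p1={"F": 0.4, "S": 0.3}, p2={"F": 0.4, "S": 0.35})
        d = closed_test_step("S", "F_and_S", pv, SQ5, SQ5, 0.0, 99.0,
                             intersection_rejected=True)
        assert d.reject_elementary  # earlier intersection rejection carries over

    def test_missing_component_raises(self):
        pv = StagewisePValues(p1={"S": 0.1}, p2={"S": 0.1})
        with pytest.raises(KeyError):
            closed_test_step("F", "F_and_S", pv, SQ5, SQ5, 2.0, 2.0)

    @pytest.mark.parametrize("scenario", ["S_only", "F_only", "F_and_S"])
    def test_matches_exhaustive_closure_oracle(self, scenario):
        rng = np.random.default_rng(42)
        for _ in range(300):
            p1 = {"F": rng.uniform(1e-4, 1), "S": rng.uniform(1e-4, 1)}
            p2 = {"F": rng.uniform(1e-4, 1), "S": rng.uniform(1e-4, 1)}
            w1 = math.sqrt(rng.uniform(0.1, 0.9))
            w2 = math.sqrt(1 - w1**2)
            bounds = {"F": rng.uniform(1.5, 3.0), "S": rng.uniform(1.5, 3.0)}
            active = {"S_only": ["S"], "F_only": ["F"], "F_and_S": ["F", "S"]}[scenario]
            pv = StagewisePValues(
                p1=p1, p2={k: v for k, v in p2.items() if scenario == "F_and_S" or k in active}
            )
            expected = closure_oracle(scenario, p1, pv.p2, w1, w2, bounds)
            int_bound = min(bounds[p] for p in active)
            for pop in active:
                d = closed_test_step(pop, scenario, pv, w1, w2, bounds[pop], int_bound)
                assert d.reject_elementary == expected[pop], (scenario, pop)


class TestHypothesisGraph:
    def nodes(self, **alphas):
        key = {"F_OS": ("F", "OS"), "F_PFS": ("F", "PFS"),
               "S_OS": ("S", "OS"), "S_PFS": ("S", "PFS")}
        return {key[k]: v for k, v in alphas.items()}

    def test_within_population_transfer(self):
        g = HypothesisGraph(self.nodes(S_OS=0.01513, S_PFS=0.00987))
        graphical_update(g, ("S", "PFS"), analysis=1)
        assert g.alpha(("S", "OS")) == pytest.approx(0.025)

    def test_alpha_conservation_two_rejections(self):
        g = HypothesisGraph(self.nodes(S_OS=0.0128, S_PFS=0.00835,
                                       F_OS=0.0022, F_PFS=0.00165),
                            cross_population=True)
        g.reject(("S", "PFS"), 1)
        g.reject(("S", "OS"), 1)
        assert g.total_alpha() == pytest.approx(0.025)
        assert g.alpha(("F", "PFS")) == pytest.approx(0.00165 + 0.0128 + 0.00835)

    def test_transfer_skips_rejected_and_respects_receivable(self):
        g = HypothesisGraph(self.nodes(S_OS=0.01, S_PFS=0.01,
                                       F_OS=0.0025, F_PFS=0.0025),
                            cross_population=True)
        g.reject(("S", "PFS"), 1)
        # PFS past its final look cannot receive alpha at the last analysis
        g.reject(("S", "OS"), 3, receivable={("F", "OS")})
        assert g.alpha(("F", "OS")) == pytest.approx(0.0025 + 0.02)
        assert g.alpha(("F", "PFS")) == pytest.approx(0.0025)

    def test_all_rejected_terminal(self):
        g = HypothesisGraph(self.nodes(S_OS=0.02, S_PFS=0.005))
        g.reject(("S", "OS"), 1)
        g.reject(("S", "PFS"), 2)
        assert g.all_rejected and g.total_alpha() == 0.0

    def test_double_rejection_errors(self):
        g = HypothesisGraph(self.nodes(S_OS=0.025))
        g.reject(("S", "OS"), 1)
        with pytest.raises(ValueError):
            g.reject(("S", "OS"), 2)
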