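"""Stagewise combination tests, closed testing, and alpha reallocation.

The adaptive designs analyze stage-1 and stage-2 cohorts separately (the
adaptation at the futility analysis breaks the independent-increments
structure of a pooled statistic) and combine the two one-sided p-values with
pre-specified inverse-normal weights.  Closed testing across the two
populations uses the Hochberg intersection p-value with equal weighting, and
alpha moves between the PFS and OS hypotheses of a population via a
graphical reallocation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.stats import norm

from .design import Endpoint, Population

Scenario = Literal["S_only", "F_only", "F_and_S"]

_P_EPS = 1e-16


def _clamp_p(p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.0 or p >= 1.0:
        warnings.warn(
            "p-value at the boundary of (0, 1); clamped before normal inversion",
            RuntimeWarning,
            stacklevel=3,
        )
    return min(max(p, _P_EPS), 1.0 - _P_EPS)


def inverse_normal_combine(
    p1: float, p2: float, w1: float, w2: float
) -> tuple[float, float]:
    """Inverse-normal combination of stagewise one-sided p-values.

    ``z = w1 * Phi^-1(1 - p1) + w2 * Phi^-1(1 - p2)`` with pre-specified
    weights satisfying ``w1**2 + w2**2 = 1``; returns ``(z, 1 - Phi(z))``.
    """
    if abs(w1 * w1 + w2 * w2 - 1.0) > 1e-9:
        raise ValueError("combination weights must satisfy w1^2 + w2^2 = 1")
    z = w1 * norm.isf(_clamp_p(p1)) + w2 * norm.isf(_clamp_p(p2))
    return float(z), float(norm.sf(z))


def hochberg_intersection(pF: float, pS: float) -> float:
    """Hochberg p-value (equal weighting) for the two-population
    intersection hypothesis: ``min(2 min(pF, pS), max(pF, pS))``."""
    if not (0.0 < pF <= 1.0 and 0.0 < pS <= 1.0):
        raise ValueError("component p-values must lie in (0, 1]")
    return min(2.0 * min(pF, pS), max(pF, pS))


def intersection_boundary(component_bounds) -> float:
    """Intersection-test z boundary at one analysis: the minimum z boundary
    among the component hypotheses that carry allocated alpha."""
    bounds = list(component_bounds)
    if not bounds:
        raise ValueError("intersection requires at least one active component")
    return float(min(bounds))


# ---------------------------------------------------------------------------
# stagewise p-value container and closed testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StagewisePValues:
    """Cohort-wise one-sided p-values for one endpoint at one analysis.

    ``p1[pop]`` is from the stage-1 cohort (including its follow-up accrued
    during stage 2; stage-1 complement patients always contribute, so the
    "FS" value exists even under S-only continuation), ``p2[pop]`` from the
    stage-2 cohort of populations still enrolling.
    """

    p1: Mapping[str, float]
    p2: Mapping[str, float]

    def p1_fs(self) -> float:
        return hochberg_intersection(self.p1["F"], self.p1["S"])

    def p2_component(self, scenario: Scenario) -> float:
        if scenario == "S_only":
            return self.p2["S"]
        if scenario == "F_only":
            return self.p2["F"]
        return hochberg_intersection(self.p2["F"], self.p2["S"])


@dataclass(frozen=True)
class ClosedTestDecision:
    elementary_z: float
    intersection_z: float | None
    reject_elementary: bool
    reject_intersection: bool


def closed_test_step(
    population: Population,
    scenario: Scenario,
    pvals: StagewisePValues,
    w1: float,
    w2: float,
    elementary_bound: float,
    intersection_bound: float,
    intersection_rejected: bool = False,
) -> ClosedTestDecision:
    """One closed-testing step for one elementary hypothesis at one analysis.

    The elementary hypothesis (``population`` x the endpoint carried by
    ``pvals``) is rejected iff its own combined z meets its boundary AND the
    two-population intersection is rejected — now, at this analysis, or at an
    earlier one (``intersection_rejected``; rejections are permanent).  The
    intersection combination uses the scenario-specific stage-2 component:
    the continued population's p-value under single-population continuation,
    or the Hochberg combination of both stage-2 p-values when both continue.
    """
    if population not in pvals.p1:
        raise KeyError(
            f"missing stage-1 p-value for population {population!r} "
            f"(scenario {scenario})"
        )
    z_int = None
    if not intersection_rejected:
        z_int, _ = inverse_normal_combine(
            pvals.p1_fs(), pvals.p2_component(scenario), w1, w2
        )
        intersection_rejected = z_int >= intersection_bound
    z_elem, _ = inverse_normal_combine(
        pvals.p1[population], pvals.p2[population], w1, w2
    )
    reject = intersection_rejected and z_elem >= elementary_bound
    return ClosedTestDecision(
        elementary_z=float(z_elem),
        intersection_z=z_int,
        reject_elementary=bool(reject),
        reject_intersection=bool(intersection_rejected),
    )


# ---------------------------------------------------------------------------
# graphical alpha reallocation
# ---------------------------------------------------------------------------

@dataclass
class HypothesisGraph:
    """Alpha bookkeeping across the four elementary hypotheses.

    ``alphas`` maps (population, endpoint) to the hypothesis's current alpha.
    On rejection the node's alpha transfers to the other endpoint of the same
    population if that node is still receivable; with ``cross_population``
    enabled (the GSD/AD default) an exhausted population passes its alpha to
    the other population's PFS node, else OS.  Within gGSD, reallocation
    never crosses populations (each population already holds a full alpha
    budget behind the gate).
    """

    alphas: dict[tuple[Population, Endpoint], float]
    cross_population: bool = False
    rejected_at: dict[tuple[Population, Endpoint], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._budget = sum(self.alphas.values())

    def alpha(self, key: tuple[Population, Endpoint]) -> float:
        return self.alphas.get(key, 0.0)

    def is_rejected(self, key: tuple[Population, Endpoint]) -> bool:
        return key in self.rejected_at

    @property
    def all_rejected(self) -> bool:
        return all(self.is_rejected(k) for k in self.alphas)

    def total_alpha(self) -> float:
        """Unspent alpha currently allocated to unrejected nodes."""
        return sum(a for k, a in self.alphas.items() if not self.is_rejected(k))

    def reject(
        self,
        key: tuple[Population, Endpoint],
        analysis: int,
        receivable=None,
    ) -> None:
        """Mark ``key`` rejected at ``analysis`` and reallocate its alpha.

        ``receivable`` optionally restricts transfer targets to hypotheses
        that can still be tested (e.g. PFS past its final look cannot absorb
        alpha usefully); unplaceable alpha is dropped, which is conservative.
        """
        if self.is_rejected(key):
            raise ValueError(f"hypothesis {key} already rejected")
        self.rejected_at[key] = analysis
        freed = self.alphas.get(key, 0.0)
        self.alphas[key] = 0.0
        pop, ep = key
        other_ep: Endpoint = "OS" if ep == "PFS" else "PFS"
        candidates: list[tuple[Population, Endpoint]] = [(pop, other_ep)]
        if self.cross_population:
            other_pop: Population = "S" if pop == "F" else "F"
            candidates += [(other_pop, "PFS"), (other_pop, "OS")]
        for cand in candidates:
            if cand not in self.alphas or self.is_rejected(cand):
                continue
            if receivable is not None and cand not in receivable:
                continue
            self.alphas[cand] += freed
            return
        # no receivable node: alpha is dropped (never exceeds the budget)


def graphical_update(
    graph: HypothesisGraph,
    node: tuple[Population, Endpoint],
    analysis: int,
    receivable=None,
) -> HypothesisGraph:
    """Apply one rejection to the graph (in place) and return it."""
    graph.reject(node, analysis, receivable=receivable)
    return graph
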