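"""End-to-end execution of one trial replication.

Orchestrates the seamless two-stage flow: the stage-1 PFS futility analysis
selects the continuing population(s) (or stops the trial), stage 2 runs
event-driven group-sequential analyses, and each analysis applies the
variant-specific testing machinery — stagewise inverse-normal combination
tests with closed testing across populations for the adaptive designs (AD,
gGSD), the population gate for gGSD, pooled-cohort tests for the GSD
comparator, and graphical alpha reallocation throughout.

A replication is split into a data phase (:func:`prepare_adaptive` /
:func:`prepare_gsd`, which simulate nothing but consume a
:class:`~gatedgsd.simulate.PatientDataset` and compute every cohort-wise
p-value once) and a cheap decision phase (:func:`evaluate_adaptive` /
:func:`evaluate_gsd`), so a simulation study can reuse one dataset across
many weight configurations exactly as a single study would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import HYPOTHESES, Endpoint, Population, TrialDesign, cached_boundaries
from .inference import NoInformationError, estimate_hr, logrank_p
from .multiplicity import (
    HypothesisGraph,
    Scenario,
    StagewisePValues,
    closed_test_step,
    graphical_update,
    intersection_boundary,
)
from .simulate import PatientDataset, apply_cutoff, cutoff_for_events

STOP_POINTS = ("futility", "IA1", "IA2", "FA")

FutilityOutcome = str  # one of the four values below
CONTINUE_F_AND_S = "continue_F_and_S"
CONTINUE_S_ONLY = "continue_S_only"
CONTINUE_F_ONLY = "continue_F_only"
STOP_FUTILITY = "stop_futility"


@dataclass(frozen=True)
class FutilityDecision:
    """Population-selection decision at the end of stage 1 (PFS based)."""

    hr_F: float
    hr_S: float
    outcome: FutilityOutcome

    @property
    def scenario(self) -> Scenario | None:
        return {
            CONTINUE_F_AND_S: "F_and_S",
            CONTINUE_S_ONLY: "S_only",
            CONTINUE_F_ONLY: "F_only",
            STOP_FUTILITY: None,
        }[self.outcome]


def futility_decision(hr_F: float, hr_S: float, rule) -> FutilityDecision:
    """Apply the population-selection rule to observed stage-1 PFS HRs.

    An estimate passes its gate only with a strict inequality ``HR < theta``
    (a missing or non-finite estimate fails).  Both pass -> continue F and S;
    only S -> S only; only F -> F only; neither -> stop for futility.
    """
    def passes(hr: float | None, theta: float) -> bool:
        return hr is not None and math.isfinite(hr) and hr < theta

    pass_F = passes(hr_F, rule.theta_F)
    pass_S = passes(hr_S, rule.theta_S)
    if pass_F and pass_S:
        outcome = CONTINUE_F_AND_S
    elif pass_S:
        outcome = CONTINUE_S_ONLY
    elif pass_F:
        outcome = CONTINUE_F_ONLY
    else:
        outcome = STOP_FUTILITY
    return FutilityDecision(
        hr_F=float("nan") if hr_F is None else float(hr_F),
        hr_S=float("nan") if hr_S is None else float(hr_S),
        outcome=outcome,
    )


@dataclass(frozen=True)
class TrialOutcome:
    """Decisions of one replication."""

    variant: str
    futility: FutilityDecision | None
    scenario: Scenario | None
    rejected_at: dict[tuple[Population, Endpoint], int]
    stop_point: str
    gate_open_at: int | None = None
    under_accrual: bool = False

    def rejected_any(self, population: Population | None = None) -> bool:
        if population is None:
            return bool(self.rejected_at)
        return any(pop == population for pop, _ in self.rejected_at)


# ---------------------------------------------------------------------------
# data phase
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveReplication:
    """Everything weight-independent about one adaptive-path replication."""

    futility: FutilityDecision
    futility_time: float
    scenario: Scenario | None
    cutoffs: list[float] = field(default_factory=list)
    stagewise: dict[tuple[int, Endpoint], StagewisePValues] = field(default_factory=dict)
    stage_events: dict[tuple[int, Endpoint], tuple[int, int]] = field(default_factory=dict)
    under_accrual: bool = False


@dataclass
class GsdReplication:
    """Pooled-cohort p-values for the GSD comparator path."""

    cutoffs: list[float] = field(default_factory=list)
    pooled_p: dict[tuple[int, Endpoint, Population], float] = field(default_factory=dict)
    under_accrual: bool = False


def _stage1_hr(dataset: PatientDataset, population: str, cutoff: float) -> float:
    snap = apply_cutoff(dataset, cutoff, "PFS", population, "pooled")
    try:
        return estimate_hr(snap).hr
    except NoInformationError:
        return float("nan")


def prepare_adaptive(design: TrialDesign, dataset: PatientDataset) -> AdaptiveReplication:
    """Futility decision, analysis cutoffs, and stagewise p-values for one
    AD/gGSD replication (shared by both variants of a setting)."""
    rule = design.futility
    if rule is None:
        raise ValueError("adaptive path requires a futility rule")

    t_F, _ = cutoff_for_events(dataset, "PFS", "F", rule.d_F)
    t_S, _ = cutoff_for_events(dataset, "PFS", "S", rule.d_S)
    t_fut = max(t_F, t_S)
    dataset.stage1_cutoff = t_fut

    decision = futility_decision(
        _stage1_hr(dataset, "F", t_fut), _stage1_hr(dataset, "S", t_fut), rule
    )
    rep = AdaptiveReplication(futility=decision, futility_time=t_fut,
                             scenario=decision.scenario)
    if rep.scenario is None:
        return rep

    # under S-only continuation, complement patients are never enrolled in
    # stage 2; stage-1 complement patients stay on follow-up
    if rep.scenario == "S_only":
        eff = dataset.select(dataset.subgroup | (dataset.enroll <= t_fut))
        driving: Population = "S"
    else:
        eff = dataset
        driving = "F"

    targets = design.event_targets("OS", driving)
    K = design.schedule.n_analyses
    prev = t_fut
    for k in range(1, K + 1):
        t_k, reached = cutoff_for_events(eff, "OS", driving, targets[k - 1])
        rep.under_accrual |= not reached
        t_k = max(t_k, prev + 1e-9)
        prev = t_k
        rep.cutoffs.append(t_k)

        endpoints: list[Endpoint] = ["OS"]
        if design.schedule.tested_at(driving, "PFS", k):
            endpoints.append("PFS")
        for ep in endpoints:
            p1 = {
                pop: logrank_p(apply_cutoff(eff, t_k, ep, pop, "stage1"))
                for pop in ("F", "S")
            }
            stage2_pops = ("S",) if rep.scenario == "S_only" else ("F", "S")
            p2 = {
                pop: logrank_p(apply_cutoff(eff, t_k, ep, pop, "stage2"))
                for pop in stage2_pops
            }
            rep.stagewise[(k, ep)] = StagewisePValues(p1=p1, p2=p2)
            n1 = apply_cutoff(eff, t_k, ep, driving, "stage1").n_events
            n2 = apply_cutoff(eff, t_k, ep, driving, "stage2").n_events
            rep.stage_events[(k, ep)] = (n1, n2)
    return rep


def prepare_gsd(design: TrialDesign, dataset: PatientDataset) -> GsdReplication:
    """Analysis cutoffs and pooled-cohort p-values for the GSD path."""
    rep = GsdReplication()
    targets = design.event_targets("OS", "F")
    K = design.schedule.n_analyses
    prev = 0.0
    for k in range(1, K + 1):
        t_k, reached = cutoff_for_events(dataset, "OS", "F", targets[k - 1])
        rep.under_accrual |= not reached
        t_k = max(t_k, prev + 1e-9)
        prev = t_k
        rep.cutoffs.append(t_k)
        for pop in ("F", "S"):
            for ep in ("PFS", "OS"):
                if design.schedule.tested_at(pop, ep, k):
                    rep.pooled_p[(k, ep, pop)] = logrank_p(
                        apply_cutoff(dataset, t_k, ep, pop, "pooled")
                    )
    return rep


# ---------------------------------------------------------------------------
# decision phase
# ---------------------------------------------------------------------------

def _initial_graph(design: TrialDesign, scenario: Scenario) -> HypothesisGraph:
    a = design.alphas
    if design.variant == "gGSD":
        if scenario == "S_only":
            nodes = {("S", "OS"): a.alpha3, ("S", "PFS"): a.alpha4}
        elif scenario == "F_only":
            nodes = {("F", "OS"): a.alpha1, ("F", "PFS"): a.alpha2}
        else:
            nodes = {
                ("F", "OS"): a.alpha1, ("F", "PFS"): a.alpha2,
                ("S", "OS"): a.alpha3, ("S", "PFS"): a.alpha4,
            }
        return HypothesisGraph(alphas=nodes, cross_population=False)
    # AD: single-alpha budget split over four hypotheses; a dropped
    # population's alpha moves endpoint-wise to the continued one
    if scenario == "S_only":
        nodes = {("S", "OS"): a.alpha3 + a.alpha1, ("S", "PFS"): a.alpha4 + a.alpha2}
        return HypothesisGraph(alphas=nodes, cross_population=False)
    if scenario == "F_only":
        nodes = {("F", "OS"): a.alpha1 + a.alpha3, ("F", "PFS"): a.alpha2 + a.alpha4}
        return HypothesisGraph(alphas=nodes, cross_population=False)
    nodes = {
        ("F", "OS"): a.alpha1, ("F", "PFS"): a.alpha2,
        ("S", "OS"): a.alpha3, ("S", "PFS"): a.alpha4,
    }
    return HypothesisGraph(alphas=nodes, cross_population=True)


def _weights_at(weights, rep: AdaptiveReplication, k: int, ep: Endpoint):
    w = weights.for_endpoint(ep)
    if w == "event_driven":
        n1, n2 = rep.stage_events[(k, ep)]
        if n1 + n2 == 0:
            return math.sqrt(0.5), math.sqrt(0.5)
        return math.sqrt(n1 / (n1 + n2)), math.sqrt(n2 / (n1 + n2))
    return w


def _bound(design: TrialDesign, pop: Population, ep: Endpoint, alpha: float, k: int) -> float:
    return cached_boundaries(design.schedule.fractions[(pop, ep)], alpha).z_bounds[k - 1]


def evaluate_adaptive(
    design: TrialDesign, rep: AdaptiveReplication, weights=None
) -> TrialOutcome:
    """Run the AD or gGSD testing logic over a prepared replication.

    ``weights`` overrides the design's combination weights (used by the
    harness to sweep weight configurations over shared replications); the
    weight object is immutable, enforcing pre-specification, and its
    fingerprint is checked at every analysis.
    """
    if design.variant not in ("AD", "gGSD"):
        raise ValueError("evaluate_adaptive handles AD and gGSD only")
    weights = weights if weights is not None else design.weights
    fingerprint = weights.fingerprint()

    if rep.scenario is None:
        return TrialOutcome(
            variant=design.variant, futility=rep.futility, scenario=None,
            rejected_at={}, stop_point="futility",
        )

    graph = _initial_graph(design, rep.scenario)
    gated = design.variant == "gGSD" and rep.scenario == "F_and_S"
    gate_open = not gated
    gate_open_at: int | None = None
    intersection_rejected: dict[Endpoint, bool] = {"PFS": False, "OS": False}
    tested_ever: set[tuple[Population, Endpoint]] = set()
    K = design.schedule.n_analyses
    stop_point = "FA"

    for k in range(1, K + 1):
        if weights.fingerprint() != fingerprint:
            raise AssertionError("combination weights mutated after the first analysis")
        changed = True
        while changed:
            changed = False
            for ep in ("OS", "PFS"):
                if (k, ep) not in rep.stagewise:
                    continue
                pv = rep.stagewise[(k, ep)]
                w1, w2 = _weights_at(weights, rep, k, ep)

                receivable = {
                    key for key in graph.alphas
                    if not graph.is_rejected(key)
                    and design.schedule.final_look(*key) >= k
                }
                components = [
                    _bound(design, pop, e, graph.alpha((pop, e)), k)
                    for (pop, e) in graph.alphas
                    if e == ep and graph.alpha((pop, e)) > 0.0
                    and not graph.is_rejected((pop, e))
                    and design.schedule.tested_at(pop, e, k)
                ]
                if not components:
                    continue
                int_bound = intersection_boundary(components)

                for pop in ("S", "F"):
                    key = (pop, ep)
                    if key not in graph.alphas or graph.is_rejected(key):
                        continue
                    if not design.schedule.tested_at(pop, ep, k):
                        continue
                    if pop == "F" and not gate_open:
                        continue  # gGSD hierarchy: F waits for an S rejection
                    if graph.alpha(key) <= 0.0:
                        continue
                    tested_ever.add(key)
                    decision = closed_test_step(
                        pop, rep.scenario, pv, w1, w2,
                        elementary_bound=_bound(design, pop, ep, graph.alpha(key), k),
                        intersection_bound=int_bound,
                        intersection_rejected=intersection_rejected[ep],
                    )
                    intersection_rejected[ep] = decision.reject_intersection
                    if decision.reject_elementary:
                        graphical_update(graph, key, k, receivable=receivable)
                        changed = True
                        if gated and pop == "S" and not gate_open:
                            gate_open = True
                            gate_open_at = k
        if tested_ever and all(graph.is_rejected(h) for h in tested_ever) and k < K:
            stop_point = STOP_POINTS[k]
            break

    return TrialOutcome(
        variant=design.variant,
        futility=rep.futility,
        scenario=rep.scenario,
        rejected_at=dict(graph.rejected_at),
        stop_point=stop_point,
        gate_open_at=gate_open_at,
        under_accrual=rep.under_accrual,
    )


def evaluate_gsd(design: TrialDesign, rep: GsdReplication) -> TrialOutcome:
    """Run the GSD comparator: pooled-cohort z tests, graphical reallocation,
    no futility, no combination, no closed testing across populations."""
    if design.variant != "GSD":
        raise ValueError("evaluate_gsd handles the GSD variant only")
    graph = _initial_graph(design, "F_and_S")
    tested_ever: set[tuple[Population, Endpoint]] = set()
    K = design.schedule.n_analyses
    stop_point = "FA"

    for k in range(1, K + 1):
        changed = True
        while changed:
            changed = False
            for key in HYPOTHESES:
                pop, ep = key
                if graph.is_rejected(key) or graph.alpha(key) <= 0.0:
                    continue
                if not design.schedule.tested_at(pop, ep, k):
                    continue
                tested_ever.add(key)
                z = float(norm.isf(min(max(rep.pooled_p[(k, ep, pop)], 1e-16), 1 - 1e-16)))
                if z >= _bound(design, pop, ep, graph.alpha(key), k):
                    receivable = {
                        kk for kk in graph.alphas
                        if not graph.is_rejected(kk)
                        and design.schedule.final_look(*kk) >= k
                    }
                    graphical_update(graph, key, k, receivable=receivable)
                    changed = True
        if len(graph.rejected_at) == len(HYPOTHESES) and k < K:
            stop_point = STOP_POINTS[k]
            break

    return TrialOutcome(
        variant="GSD", futility=None, scenario=None,
        rejected_at=dict(graph.rejected_at), stop_point=stop_point,
        under_accrual=rep.under_accrual,
    )


def run_trial(design: TrialDesign, dataset: PatientDataset) -> TrialOutcome:
    """Execute one full replication of ``design`` on a simulated dataset."""
    if design.variant == "GSD":
        return evaluate_gsd(design, prepare_gsd(design, dataset))
    return evaluate_adaptive(design, prepare_adaptive(design, dataset))


# ---------------------------------------------------------------------------
# worked-example replay
# ---------------------------------------------------------------------------

def replay_decision_table(table: pd.DataFrame) -> dict[str, dict]:
    """Replay printed boundary/p-value pairs through the decision logic.

    ``table`` columns: variant, analysis (IA1/IA2/FA), population (F/S),
    endpoint (PFS/OS), boundary, p_value (empty when the hypothesis is not
    tested at that analysis).  A hypothesis is rejected when its p-value is
    at or below its printed boundary; rejections are permanent.  Adaptive
    variants stop early once every hypothesis tested so far is rejected;
    GSD stops early only when all four hypotheses are rejected.

    Returns per variant: ``{"rejections": {(pop, ep): analysis},
    "stop_point": str}``.
    """
    results: dict[str, dict] = {}
    analyses = [a for a in ("IA1", "IA2", "FA") if a in set(table["analysis"])]
    for variant, sub in table.groupby("variant"):
        rejected: dict[tuple[str, str], str] = {}
        tested: set[tuple[str, str]] = set()
        stop_point = analyses[-1]
        for a in analyses:
            rows = sub[sub["analysis"] == a]
            for _, row in rows.iterrows():
                key = (row["population"], row["endpoint"])
                if key in rejected or pd.isna(row["p_value"]):
                    continue
                tested.add(key)
                if row["p_value"] <= row["boundary"]:
                    rejected[key] = a
            all_done = (
                len(rejected) == 4
                if variant == "GSD"
                else bool(tested) and tested <= set(rejected)
            )
            if all_done and a != analyses[-1]:
                stop_point = a
                break
        results[variant] = {"rejections": rejected, "stop_point": stop_point}
    return results


def load_illustrative_example() -> pd.DataFrame:
    """Packaged decision table of the illustrative Phase III example (printed
    nominal boundaries and data-generated p-values for GSD and gGSD)."""
    from importlib import resources

    ref = resources.files("gatedgsd.data").joinpath("illustrative_example.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)
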