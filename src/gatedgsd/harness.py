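"""Replication harness and summary statistics.

Runs many simulated replications of a design, under the setting's
alternative or under the global null (every hazard ratio forced to 1), and
aggregates familywise error, power, and the stopping-time distribution.

Two power conventions are reported side by side.  ``power_S``/``power_SF``
are the probabilities of rejecting the OS hypothesis in S (and, for SF, in
both populations) — the definition consistent with the published design
comparisons, where OS is the confirmatory endpoint.  ``power_S_any`` /
``power_SF_any`` count a rejection of at least one hypothesis per
population.  Subgroup power is computed among the replications in which S
passes the futility gate (the published denominator); S & F power among
those where both populations pass; unconditional variants divide by all
replications.  For the GSD comparator there is no futility, so the
denominators coincide.

:func:`sweep_study` evaluates several (variant, weight) configurations on
shared simulated datasets — the decision phase is re-run per configuration
while each replication is simulated, and its cohort-wise p-values computed,
only once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import TrialDesign
from .engine import (
    TrialOutcome,
    evaluate_adaptive,
    evaluate_gsd,
    prepare_adaptive,
    prepare_gsd,
    run_trial,
)
from .presets import WEIGHT_PRESETS, make_design
from .simulate import simulate_trial

STOP_ORDER = ("futility", "IA1", "IA2", "FA")


def event_driven_weights(n1: int, n2: int) -> tuple[float, float]:
    """Stagewise combination weights proportional to the square root of the
    number of events in each stage: ``(sqrt(n1/(n1+n2)), sqrt(n2/(n1+n2)))``.

    Reference-only: such weights depend on observed data and cannot be
    pre-specified in a real trial.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("event counts must be nonnegative")
    total = n1 + n2
    if total == 0:
        raise ValueError("event-driven weights need at least one event")
    return math.sqrt(n1 / total), math.sqrt(n2 / total)


def summarize_stopping(outcomes: list[TrialOutcome]) -> dict[str, float]:
    """Empirical distribution of the trial stopping point."""
    if not outcomes:
        raise ValueError("need at least one outcome")
    n = len(outcomes)
    return {sp: sum(o.stop_point == sp for o in outcomes) / n for sp in STOP_ORDER}


@dataclass(frozen=True)
class SimSummary:
    """Aggregated results of one (design variant, weight set) study."""

    variant: str
    setting: int | None
    weight_name: str
    truth: str
    n_reps: int
    fwer: float
    power_S: float
    power_S_unconditional: float
    power_SF: float
    power_SF_unconditional: float
    power_S_any: float
    power_SF_any: float
    n_pass_S: int
    n_pass_SF: int
    stopping: dict[str, float]

    @property
    def fwer_se(self) -> float:
        return math.sqrt(self.fwer * (1 - self.fwer) / self.n_reps)

    @property
    def power_S_se(self) -> float:
        d = max(self.n_pass_S, 1)
        return math.sqrt(self.power_S * (1 - self.power_S) / d)

    @property
    def power_SF_se(self) -> float:
        d = max(self.n_pass_SF, 1)
        return math.sqrt(self.power_SF * (1 - self.power_SF) / d)

    def to_row(self) -> dict:
        row = {
            "variant": self.variant,
            "setting": self.setting,
            "weights": self.weight_name,
            "truth": self.truth,
            "n_reps": self.n_reps,
            "fwer": self.fwer,
            "fwer_se": self.fwer_se,
            "power_S": self.power_S,
            "power_S_unconditional": self.power_S_unconditional,
            "power_SF": self.power_SF,
            "power_SF_unconditional": self.power_SF_unconditional,
            "power_S_any": self.power_S_any,
            "power_SF_any": self.power_SF_any,
            "n_pass_S": self.n_pass_S,
            "n_pass_SF": self.n_pass_SF,
        }
        row.update({f"stop_{k}": v for k, v in self.stopping.items()})
        return row


def _passes_S(o: TrialOutcome) -> bool:
    if o.futility is None:  # GSD: no futility gate
        return True
    return o.futility.outcome in ("continue_F_and_S", "continue_S_only")


def _passes_both(o: TrialOutcome) -> bool:
    if o.futility is None:
        return True
    return o.futility.outcome == "continue_F_and_S"


def summarize_outcomes(
    outcomes: list[TrialOutcome],
    variant: str,
    setting: int | None,
    weight_name: str,
    truth: str,
) -> SimSummary:
    n = len(outcomes)
    fwer = sum(bool(o.rejected_at) for o in outcomes) / n

    pass_S = [o for o in outcomes if _passes_S(o)]
    pass_both = [o for o in outcomes if _passes_both(o)]
    hit_S = sum(("S", "OS") in o.rejected_at for o in pass_S)
    hit_SF = sum(
        ("S", "OS") in o.rejected_at and ("F", "OS") in o.rejected_at
        for o in pass_both
    )
    hit_S_any = sum(o.rejected_any("S") for o in pass_S)
    hit_SF_any = sum(
        o.rejected_any("S") and o.rejected_any("F") for o in pass_both
    )

    return SimSummary(
        variant=variant,
        setting=setting,
        weight_name=weight_name,
        truth=truth,
        n_reps=n,
        fwer=fwer,
        power_S=hit_S / len(pass_S) if pass_S else 0.0,
        power_S_unconditional=hit_S / n,
        power_SF=hit_SF / len(pass_both) if pass_both else 0.0,
        power_SF_unconditional=hit_SF / n,
        power_S_any=hit_S_any / len(pass_S) if pass_S else 0.0,
        power_SF_any=hit_SF_any / len(pass_both) if pass_both else 0.0,
        n_pass_S=len(pass_S),
        n_pass_SF=len(pass_both),
        stopping=summarize_stopping(outcomes),
    )


def _under_truth(design: TrialDesign, truth: str) -> TrialDesign:
    if truth == "global_null":
        return replace(design, hazard_ratio={k: 1.0 for k in design.hazard_ratio})
    if truth == "setting_alternative":
        return design
    raise ValueError(f"unknown hypothesis truth {truth!r}")


def run_study(
    design: TrialDesign,
    hypothesis_truth: str,
    n_reps: int,
    master_seed: int,
) -> SimSummary:
    """Simulate ``n_reps`` independent replications of one design and
    summarize.  Per-replication seeds are deterministic spawns of
    ``master_seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    d = _under_truth(design, hypothesis_truth)
    seeds = np.random.SeedSequence(master_seed).spawn(n_reps)
    outcomes = [run_trial(d, simulate_trial(d, s)) for s in seeds]
    return summarize_outcomes(
        outcomes, d.variant, d.setting, d.weights.name or "custom", hypothesis_truth
    )


def sweep_study(
    setting: int,
    hypothesis_truth: str,
    n_reps: int,
    master_seed: int,
    variants: tuple[str, ...] = ("GSD", "AD", "gGSD"),
    weight_names: tuple[str, ...] | None = None,
    collect_outcomes: bool = False,
):
    """Evaluate many (variant, weight set) configurations on shared
    replications of one setting.

    Every configuration sees the same simulated datasets, futility decisions
    and cohort-wise p-values (the generative model and the futility rule do
    not depend on the variant's alpha allocation or weights), exactly as in
    a simulation study that feeds one dataset stream to all methods.

    Returns ``{(variant, weight_name): SimSummary}``; GSD is weight-free and
    keyed as ``("GSD", "-")``.  With ``collect_outcomes`` the per-replication
    :class:`TrialOutcome` lists are returned alongside.
    """
    if weight_names is None:
        weight_names = tuple(WEIGHT_PRESETS)
    null = hypothesis_truth == "global_null"
    gsd_design = make_design(setting, "GSD", global_null=null)
    adaptive_designs = {
        v: make_design(setting, v, global_null=null)
        for v in ("AD", "gGSD")
        if v in variants
    }

    keys: list[tuple[str, str]] = []
    if "GSD" in variants:
        keys.append(("GSD", "-"))
    for v in adaptive_designs:
        keys += [(v, w) for w in weight_names]
    outcomes: dict[tuple[str, str], list[TrialOutcome]] = {k: [] for k in keys}

    seeds = np.random.SeedSequence(master_seed).spawn(n_reps)
    for seed in seeds:
        dataset = simulate_trial(gsd_design, seed)
        arep = None
        if adaptive_designs:
            any_adaptive = next(iter(adaptive_designs.values()))
            arep = prepare_adaptive(any_adaptive, dataset)
        if "GSD" in variants:
            grep = prepare_gsd(gsd_design, dataset)
            outcomes[("GSD", "-")].append(evaluate_gsd(gsd_design, grep))
        for v, d in adaptive_designs.items():
            for w in weight_names:
                outcomes[(v, w)].append(
                    evaluate_adaptive(d, arep, weights=WEIGHT_PRESETS[w])
                )

    summaries = {
        (v, w): summarize_outcomes(outs, v, setting, w, hypothesis_truth)
        for (v, w), outs in outcomes.items()
    }
    if collect_outcomes:
        return summaries, outcomes
    return summaries


def summaries_frame(summaries: dict) -> pd.DataFrame:
    """Flat table of sweep results, one row per (variant, weight set)."""
    return pd.DataFrame([s.to_row() for s in summaries.values()])


def outcomes_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    """Per-replication decision log."""
    rows = []
    for i, o in enumerate(outcomes):
        row = {
            "replicate": i,
            "variant": o.variant,
            "futility": o.futility.outcome if o.futility else "",
            "scenario": o.scenario or "",
            "stop_point": o.stop_point,
            "gate_open_at": o.gate_open_at if o.gate_open_at is not None else "",
            "under_accrual": o.under_accrual,
        }
        for pop, ep in (("F", "OS"), ("F", "PFS"), ("S", "OS"), ("S", "PFS")):
            row[f"reject_{pop}_{ep}"] = o.rejected_at.get((pop, ep), "")
        rows.append(row)
    return pd.DataFrame(rows)
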