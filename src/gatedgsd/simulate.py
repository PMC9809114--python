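"""Patient-level trial simulation with subgroup structure.

Generates two-arm time-to-event data matching the packaged design settings:
uniform accrual over the enrollment window, exponential event times with the
hazard scaled by the endpoint x stratum hazard ratio in the experimental
arm, and exponential dropout matching the stated annual dropout
probabilities.  PFS and OS event streams are generated independently per
patient (orderings such as PFS <= OS are not enforced).

All times are in months.  Calendar time of an event is ``enroll_time +
latent time``; snapshots at an analysis cutoff censor each patient at
``cutoff - enroll_time``.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import Endpoint, TrialDesign


class SurvivalRecords(NamedTuple):
    """Observed (censored) records for one analysis: time on study, event
    indicator, and arm flag (True = experimental)."""

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


class PatientDataset:
    """Latent patient-level data for one simulated trial replication.

    Stage labels (1 = enrolled before the futility cutoff) are derived from
    ``stage1_cutoff``, which the trial engine sets once the futility analysis
    time is known.
    """

    def __init__(
        self,
        enroll: np.ndarray,
        arm: np.ndarray,
        subgroup: np.ndarray,
        event_time: dict[Endpoint, np.ndarray],
        dropout_time: dict[Endpoint, np.ndarray],
        design: TrialDesign | None = None,
        seed: int | None = None,
    ) -> None:
        self.enroll = np.asarray(enroll, dtype=float)
        self.arm = np.asarray(arm, dtype=bool)
        self.subgroup = np.asarray(subgroup, dtype=bool)
        self.event_time = {k: np.asarray(v, dtype=float) for k, v in event_time.items()}
        self.dropout_time = {
            k: np.asarray(v, dtype=float) for k, v in dropout_time.items()
        }
        self.design = design
        self.seed = seed
        self.stage1_cutoff: float | None = None
        if np.any(self.enroll < 0):
            raise ValueError("enrollment times must be nonnegative")
        for arrs in (self.event_time, self.dropout_time):
            for v in arrs.values():
                if np.any(v <= 0):
                    raise ValueError("latent times must be positive")

    @property
    def n(self) -> int:
        return self.enroll.size

    def population_mask(self, population: str) -> np.ndarray:
        if population == "F":
            return np.ones(self.n, dtype=bool)
        if population == "S":
            return self.subgroup
        if population in ("F\\S", "complement"):
            return ~self.subgroup
        raise ValueError(f"unknown population {population!r}")

    def stage_mask(self, cohort: str) -> np.ndarray:
        if cohort == "pooled":
            return np.ones(self.n, dtype=bool)
        if self.stage1_cutoff is None:
            raise ValueError("stage cohorts undefined before the futility cutoff is set")
        stage1 = self.enroll <= self.stage1_cutoff
        if cohort == "stage1":
            return stage1
        if cohort == "stage2":
            return ~stage1
        raise ValueError(f"unknown cohort {cohort!r}")

    def select(self, mask: np.ndarray) -> "PatientDataset":
        """Sub-dataset of the patients where ``mask`` is True (used e.g. to
        drop never-enrolled complement patients under S-only continuation)."""
        out = PatientDataset(
            enroll=self.enroll[mask],
            arm=self.arm[mask],
            subgroup=self.subgroup[mask],
            event_time={k: v[mask] for k, v in self.event_time.items()},
            dropout_time={k: v[mask] for k, v in self.dropout_time.items()},
            design=self.design,
            seed=self.seed,
        )
        out.stage1_cutoff = self.stage1_cutoff
        return out

    # -- export ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Flat patient table; per endpoint the observed time is the earlier
        of event and dropout with an event indicator (times rounded to two
        decimals on export only)."""
        stage = np.ones(self.n, dtype=int)
        if self.stage1_cutoff is not None:
            stage[self.enroll > self.stage1_cutoff] = 2
        cols = {
            "id": np.arange(self.n),
            "arm": np.where(self.arm, "experimental", "control"),
            "subgroup": self.subgroup.astype(int),
            "enroll_time": np.round(self.enroll, 2),
            "stage": stage,
        }
        for ep in ("PFS", "OS"):
            ev = self.event_time[ep]
            dr = self.dropout_time[ep]
            cols[f"{ep.lower()}_time"] = np.round(np.minimum(ev, dr), 2)
            cols[f"{ep.lower()}_event"] = (ev <= dr).astype(int)
        return pd.DataFrame(cols)


def simulate_trial(design: TrialDesign, seed) -> PatientDataset:
    """Simulate one trial replication under a design's generative model.

    Enrollment is uniform over ``enroll_duration`` with 1:1 block-balanced
    randomization; subgroup membership is Bernoulli(prevalence); event and
    dropout times are exponential per endpoint.  Reproducible given ``seed``
    (an int or :class:`numpy.random.SeedSequence`).
    """
    rng = np.random.default_rng(seed)
    n = design.n_total

    arm = np.zeros(n, dtype=bool)
    arm[: n // 2] = True
    arm = rng.permutation(arm)
    subgroup = rng.random(n) < design.subgroup_prevalence
    enroll = rng.uniform(0.0, design.enroll_duration, size=n)

    event_time: dict[Endpoint, np.ndarray] = {}
    dropout_time: dict[Endpoint, np.ndarray] = {}
    for ep in ("PFS", "OS"):
        lam = np.where(
            subgroup,
            math.log(2.0) / design.control_median[(ep, "subgroup")],
            math.log(2.0) / design.control_median[(ep, "complement")],
        )
        hr = np.where(
            subgroup,
            design.hazard_ratio[(ep, "subgroup")],
            design.hazard_ratio[(ep, "complement")],
        )
        lam = lam * np.where(arm, hr, 1.0)
        event_time[ep] = rng.exponential(1.0 / lam)
        mu = design.dropout_rate(ep)
        dropout_time[ep] = (
            rng.exponential(1.0 / mu, size=n)
            if mu > 0
            else np.full(n, np.inf)
        )

    return PatientDataset(
        enroll, arm, subgroup, event_time, dropout_time, design=design, seed=None
    )


def apply_cutoff(
    dataset: PatientDataset,
    cutoff_time: float,
    endpoint: Endpoint,
    population: str = "F",
    cohort: str = "pooled",
) -> SurvivalRecords:
    """Censored snapshot of one (endpoint, population, cohort) cell.

    Patients enrolled after the cutoff are excluded; for the rest the
    observed time is ``min(event, dropout, cutoff - enroll)`` with the event
    indicator set when the event comes first.
    """
    if cutoff_time < 0:
        raise ValueError("cutoff_time must be nonnegative")
    mask = dataset.population_mask(population) & dataset.stage_mask(cohort)
    mask &= dataset.enroll <= cutoff_time

    ev = dataset.event_time[endpoint][mask]
    dr = dataset.dropout_time[endpoint][mask]
    admin = cutoff_time - dataset.enroll[mask]
    time = np.minimum(np.minimum(ev, dr), admin)
    event = (ev <= dr) & (ev <= admin)
    return SurvivalRecords(time=time, event=event, arm=dataset.arm[mask])


def cutoff_for_events(
    dataset: PatientDataset,
    endpoint: Endpoint,
    population: str,
    target_events: int,
) -> tuple[float, bool]:
    """Smallest calendar time at which the pooled observed event count for
    (endpoint, population) reaches ``target_events``.

    Returns ``(time, reached)``.  When the target can never be reached
    (dropout removes too many patients) the sentinel is the end of
    follow-up — the time at which every patient's endpoint is resolved —
    and ``reached`` is False.
    """
    if target_events < 1:
        raise ValueError("target_events must be >= 1")
    mask = dataset.population_mask(population)
    ev = dataset.event_time[endpoint][mask]
    dr = dataset.dropout_time[endpoint][mask]
    enroll = dataset.enroll[mask]

    is_event = ev <= dr
    event_times = np.sort(enroll[is_event] + ev[is_event])
    if event_times.size >= target_events:
        return float(event_times[target_events - 1]), True
    resolved = enroll + np.minimum(ev, dr)
    sentinel = float(resolved.max()) if resolved.size else 0.0
    return sentinel, False
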