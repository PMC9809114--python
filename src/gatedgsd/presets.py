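"""Packaged design presets and combination-weight configurations.

The three simulation settings ship as YAML files mirroring the design
parameter table field-for-field; :func:`make_design` turns one of them into
a concrete :class:`~gatedgsd.design.TrialDesign` for a chosen variant
(gGSD, GSD or AD) and weight configuration.
"""

from __future__ import annotations

import math
from importlib import resources

import yaml

from .design import (
    AlphaAllocation,
    AnalysisSchedule,
    CombinationWeights,
    FutilityRule,
    TrialDesign,
    Variant,
)

_SQ = math.sqrt

#: the eight weight configurations evaluated in the simulation study; the
#: event-driven set is a reference only (it cannot be pre-specified).
WEIGHT_PRESETS: dict[str, CombinationWeights] = {
    "event_driven": CombinationWeights("event_driven", "event_driven", name="event_driven"),
    "w20_80": CombinationWeights((_SQ(0.2), _SQ(0.8)), (_SQ(0.2), _SQ(0.8)), name="w20_80"),
    "w30_70": CombinationWeights((_SQ(0.3), _SQ(0.7)), (_SQ(0.3), _SQ(0.7)), name="w30_70"),
    "w50_50": CombinationWeights((_SQ(0.5), _SQ(0.5)), (_SQ(0.5), _SQ(0.5)), name="w50_50"),
    "w50_pfs_w70_os": CombinationWeights(
        (_SQ(0.5), _SQ(0.5)), (_SQ(0.7), _SQ(0.3)), name="w50_pfs_w70_os"
    ),
    "w70_30": CombinationWeights((_SQ(0.7), _SQ(0.3)), (_SQ(0.7), _SQ(0.3)), name="w70_30"),
    "w80_20": CombinationWeights((_SQ(0.8), _SQ(0.2)), (_SQ(0.8), _SQ(0.2)), name="w80_20"),
    "w60_40": CombinationWeights((_SQ(0.6), _SQ(0.4)), (_SQ(0.6), _SQ(0.4)), name="w60_40"),
}

SETTINGS = (1, 2, 3)


def load_setting(setting: int) -> dict:
    """Raw preset dictionary for one simulation setting."""
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting}; choose from {SETTINGS}")
    ref = resources.files("gatedgsd.data").joinpath(f"setting{setting}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def make_design(
    setting: int,
    variant: Variant,
    weights: CombinationWeights | str = "w50_50",
    global_null: bool = False,
    **overrides,
) -> TrialDesign:
    """Build a :class:`TrialDesign` from a packaged setting preset.

    ``global_null=True`` forces every hazard ratio to 1 (the configuration
    under which familywise error is measured); settings 2 and 3 then
    coincide.  ``overrides`` replace top-level preset fields (e.g.
    ``followup_duration``).
    """
    raw = load_setting(setting)
    raw.update(overrides)
    if isinstance(weights, str):
        weights = WEIGHT_PRESETS[weights]

    key = "ggsd" if variant == "gGSD" else "gsd_ad"
    alloc = raw["alpha_allocation"][key]
    alphas = AlphaAllocation(
        alpha_total=raw["alpha_total"],
        alpha1=alloc["F_OS"],
        alpha2=alloc["F_PFS"],
        alpha3=alloc["S_OS"],
        alpha4=alloc["S_PFS"],
    )

    fractions = {
        (pop, ep): tuple(raw["information_fractions"][pop][ep])
        for pop in ("F", "S")
        for ep in ("PFS", "OS")
    }
    schedule = AnalysisSchedule(fractions=fractions)

    futility = None
    if variant in ("gGSD", "AD"):
        fut = raw["futility"]
        futility = FutilityRule.from_thresholds(
            theta_F=fut["theta"]["F"],
            theta_S=fut["theta"]["S"],
            gamma=fut["gamma"],
            hr_alt=fut["hr_alt"],
        )

    hr = {
        (ep, st): (1.0 if global_null else raw["hazard_ratio"][ep][st])
        for ep in ("PFS", "OS")
        for st in ("subgroup", "complement")
    }
    medians = {
        (ep, st): raw["control_median"][ep][st]
        for ep in ("PFS", "OS")
        for st in ("subgroup", "complement")
    }

    return TrialDesign(
        variant=variant,
        n_total=raw["n_total"],
        subgroup_prevalence=raw["subgroup_prevalence"],
        enroll_duration=raw["enroll_duration"],
        followup_duration=raw["followup_duration"],
        control_median=medians,
        hazard_ratio=hr,
        annual_dropout={ep: raw["annual_dropout"][ep] for ep in ("PFS", "OS")},
        alphas=alphas,
        schedule=schedule,
        futility=futility,
        weights=weights,
        setting=raw["setting"],
    )
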