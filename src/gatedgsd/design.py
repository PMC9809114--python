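"""Design primitives for gated group sequential (gGSD) trials.

Domain types describing a two-arm seamless Phase II/III trial with a
pre-specified subgroup ``S`` inside the full population ``F`` and dual
time-to-event endpoints (PFS and OS), together with the numerical machinery
the design rests on:

* Lan-DeMets alpha spending approximating O'Brien-Fleming bounds,
* group-sequential z boundaries obtained by recursive numerical integration
  over the canonical joint normal (correlation ``sqrt(t_i/t_j)``),
* calibration of the stage-1 futility hazard-ratio threshold ``theta`` from
  the normal approximation ``log(HR) ~ N(log(true HR), 4/d)`` under equal
  randomization.

Four elementary one-sided null hypotheses are tracked throughout the
package, keyed by ``(population, endpoint)`` with population in ``{"F",
"S"}`` and endpoint in ``{"PFS", "OS"}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.stats import norm

Population = Literal["F", "S"]
Endpoint = Literal["PFS", "OS"]
Variant = Literal["gGSD", "GSD", "AD"]

POPULATIONS: tuple[Population, ...] = ("F", "S")
ENDPOINTS: tuple[Endpoint, ...] = ("PFS", "OS")
#: the four elementary hypotheses, in the paper-facing alpha order
#: alpha1=(F,OS), alpha2=(F,PFS), alpha3=(S,OS), alpha4=(S,PFS)
HYPOTHESES: tuple[tuple[Population, Endpoint], ...] = (
    ("F", "OS"),
    ("F", "PFS"),
    ("S", "OS"),
    ("S", "PFS"),
)

_ATOL = 1e-9


# ---------------------------------------------------------------------------
# alpha spending and group-sequential boundaries
# ---------------------------------------------------------------------------

def spend_alpha(t: float, alpha: float) -> float:
    """Cumulative one-sided alpha spent at information fraction ``t``.

    Lan-DeMets spending function approximating O'Brien-Fleming bounds,

    .. math:: f(t) = 2\\,(1 - \\Phi(\\Phi^{-1}(1 - \\alpha/2) / \\sqrt{t})),

    which is nondecreasing in ``t`` with ``f(1) = alpha``.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"information fraction must lie in (0, 1], got {t}")
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    return 2.0 * norm.sf(norm.isf(alpha / 2.0) / math.sqrt(t))


@dataclass(frozen=True)
class BoundarySet:
    """Efficacy boundaries for one hypothesis across its planned looks.

    ``z_bounds[k]`` is the z-scale boundary at the (k+1)-th look; the test
    statistic must satisfy ``z >= z_bounds[k]`` to reject.  ``nominal_p`` is
    the equivalent one-sided nominal p-value boundary ``1 - Phi(c_k)``.
    """

    info_fractions: tuple[float, ...]
    alpha: float
    z_bounds: tuple[float, ...]
    crossing_probs: tuple[float, ...]

    @property
    def nominal_p(self) -> tuple[float, ...]:
        return tuple(float(norm.sf(z)) for z in self.z_bounds)

    @property
    def total_crossing(self) -> float:
        return float(sum(self.crossing_probs))

    def to_rows(self, hypothesis: str = "") -> list[dict]:
        return [
            {
                "hypothesis": hypothesis,
                "analysis": k + 1,
                "info_fraction": t,
                "z_bound": z,
                "nominal_p": p,
            }
            for k, (t, z, p) in enumerate(
                zip(self.info_fractions, self.z_bounds, self.nominal_p)
            )
        ]


_Z_CAP = 8.5  # beyond ~8.5 SD the crossing probability is below 1e-16

# numerical-integration controls: grid over +-8 SD, >=500 nodes per look
_GRID_SD = 8.0
_GRID_N = 801


def compute_boundaries(
    info_fractions,
    alpha: float,
    spending=spend_alpha,
) -> BoundarySet:
    """Group-sequential z boundaries for one hypothesis.

    Boundaries ``c_1, ..., c_K`` are chosen so the sequential crossing
    probabilities under the canonical joint normal (score increments are
    independent; ``corr(Z_i, Z_j) = sqrt(t_i/t_j)``) equal the incremental
    spend ``f(t_k) - f(t_{k-1})`` at each look.  The recursion integrates
    the sub-density of the non-crossing sample paths on the score scale
    ``S_k = Z_k * sqrt(t_k)``.

    The last fraction may be below 1 when the hypothesis's final look is
    earlier than the trial's final analysis; the total crossing probability
    then equals ``f(t_K) < alpha``.
    """
    t = np.asarray(info_fractions, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("info_fractions must be a non-empty 1-D sequence")
    if np.any(t <= 0.0) or np.any(t > 1.0):
        raise ValueError("information fractions must lie in (0, 1]")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("information fractions must be strictly increasing")
    if alpha <= 0.0 or alpha >= 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")

    cum = np.array([spending(tk, alpha) for tk in t])
    incr = np.diff(np.concatenate([[0.0], cum]))

    z_bounds: list[float] = []
    crossing: list[float] = []

    # first look is exact
    pi1 = max(incr[0], 0.0)
    c1 = float(norm.isf(pi1)) if pi1 > 1e-16 else _Z_CAP
    c1 = min(c1, _Z_CAP)
    z_bounds.append(c1)
    crossing.append(float(norm.sf(c1)))

    # sub-density of the score S_1 on the continuation region
    grid = np.linspace(-_GRID_SD * math.sqrt(t[0]), c1 * math.sqrt(t[0]), _GRID_N)
    dens = norm.pdf(grid, scale=math.sqrt(t[0]))

    for k in range(1, t.size):
        sigma = math.sqrt(t[k] - t[k - 1])
        w = _trapezoid_weights(grid)
        mass = dens * w  # sub-probability mass of non-crossed paths

        def tail(c: float) -> float:
            # P(no crossing before look k, S_k >= c * sqrt(t_k))
            return float(np.sum(mass * norm.sf((c * math.sqrt(t[k]) - grid) / sigma)))

        pik = max(float(incr[k]), 0.0)
        if pik <= 1e-16 or tail(_Z_CAP) >= pik:
            ck = _Z_CAP
        else:
            ck = _bisect_decreasing(tail, pik, lo=-2.0, hi=_Z_CAP)
        z_bounds.append(ck)
        crossing.append(tail(ck))

        if k < t.size - 1:
            new_grid = np.linspace(
                -_GRID_SD * math.sqrt(t[k]), ck * math.sqrt(t[k]), _GRID_N
            )
            kernel = norm.pdf((new_grid[:, None] - grid[None, :]) / sigma) / sigma
            dens = kernel @ mass
            grid = new_grid

    return BoundarySet(
        info_fractions=tuple(float(x) for x in t),
        alpha=float(alpha),
        z_bounds=tuple(z_bounds),
        crossing_probs=tuple(crossing),
    )


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    h = grid[1] - grid[0]
    w = np.full(grid.size, h)
    w[0] = w[-1] = h / 2.0
    return w


def _bisect_decreasing(f, target: float, lo: float, hi: float, tol: float = 1e-10):
    """Solve f(c) = target for strictly decreasing f by bisection."""
    flo, fhi = f(lo), f(hi)
    if not (fhi <= target <= flo):
        # target outside the bracket; clamp to the nearer end
        return hi if target < fhi else lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm - target) < tol * max(target, 1e-12) or hi - lo < 1e-12:
            return mid
        if fm > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@lru_cache(maxsize=4096)
def cached_boundaries(info_fractions: tuple, alpha: float) -> BoundarySet:
    """Memoized :func:`compute_boundaries` (alpha rounded to 1e-12)."""
    return compute_boundaries(info_fractions, round(alpha, 12))


# ---------------------------------------------------------------------------
# futility threshold calibration
# ---------------------------------------------------------------------------

def futility_threshold(hr_alt: float, gamma: float, d: int) -> float:
    """Hazard-ratio futility threshold ``theta``.

    Calibrated so that ``P(observed HR > theta | true HR = hr_alt) = gamma``
    under the normal approximation ``log(HR) ~ N(log(hr_alt), 4/d)`` (equal
    randomization, ``d`` events):

    .. math:: \\theta = \\exp(\\log(hr_{alt}) + z_{1-\\gamma} \\cdot 2/\\sqrt{d}).
    """
    if hr_alt <= 0.0:
        raise ValueError("hr_alt must be positive")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if d < 1:
        raise ValueError("event count d must be >= 1")
    return math.exp(math.log(hr_alt) + norm.ppf(1.0 - gamma) * 2.0 / math.sqrt(d))


def implied_futility_events(hr_alt: float, gamma: float, theta: float) -> int:
    """Smallest event count whose calibrated threshold does not exceed ``theta``.

    Inverts :func:`futility_threshold`:
    ``d = ceil((2 z_{1-gamma} / log(theta/hr_alt))^2)``, so that
    ``futility_threshold(hr_alt, gamma, d) <= theta``.
    """
    if theta <= hr_alt:
        raise ValueError("theta must exceed hr_alt (no finite event count otherwise)")
    if not 0.0 < gamma <= 0.5:
        raise ValueError("gamma must lie in (0, 0.5]")
    z = norm.ppf(1.0 - gamma)
    d = math.ceil((2.0 * z / math.log(theta / hr_alt)) ** 2)
    return max(int(d), 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaAllocation:
    """One-sided alpha split across the four elementary hypotheses.

    ``alpha1``..``alpha4`` fund (F,OS), (F,PFS), (S,OS), (S,PFS).  GSD/AD
    allocations sum to ``alpha_total`` across all four; gGSD allocations sum
    to ``alpha_total`` within each population (the gate makes the F budget a
    full alpha of its own).
    """

    alpha_total: float
    alpha1: float  # (F, OS)
    alpha2: float  # (F, PFS)
    alpha3: float  # (S, OS)
    alpha4: float  # (S, PFS)

    def __post_init__(self) -> None:
        for a in (self.alpha1, self.alpha2, self.alpha3, self.alpha4):
            if not 0.0 <= a <= self.alpha_total + _ATOL:
                raise ValueError("each alpha component must lie in [0, alpha_total]")

    def for_hypothesis(self, population: Population, endpoint: Endpoint) -> float:
        return {
            ("F", "OS"): self.alpha1,
            ("F", "PFS"): self.alpha2,
            ("S", "OS"): self.alpha3,
            ("S", "PFS"): self.alpha4,
        }[(population, endpoint)]

    def validate(self, variant: Variant) -> None:
        if variant in ("GSD", "AD"):
            total = self.alpha1 + self.alpha2 + self.alpha3 + self.alpha4
            if abs(total - self.alpha_total) > _ATOL:
                raise ValueError(
                    f"{variant} allocation must sum to alpha_total: {total}"
                )
        elif variant == "gGSD":
            for pair in ((self.alpha1, self.alpha2), (self.alpha3, self.alpha4)):
                if abs(sum(pair) - self.alpha_total) > _ATOL:
                    raise ValueError(
                        "gGSD allocation must sum to alpha_total per population"
                    )
        else:  # pragma: no cover - guarded by typing
            raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class AnalysisSchedule:
    """Planned stage-2 analyses as information fractions per hypothesis.

    ``fractions[(population, endpoint)]`` is the strictly increasing tuple of
    design information fractions, ending at 1 on the endpoint's own
    information scale.  An endpoint is tested at analyses ``1..len(...)``;
    PFS (two looks) is final at IA2 and never tested at FA.
    """

    fractions: dict[tuple[Population, Endpoint], tuple[float, ...]]

    def __post_init__(self) -> None:
        for key, fr in self.fractions.items():
            arr = np.asarray(fr, dtype=float)
            if np.any(np.diff(arr) <= 0.0):
                raise ValueError(f"fractions for {key} must be strictly increasing")
            if abs(arr[-1] - 1.0) > _ATOL:
                raise ValueError(f"final fraction for {key} must equal 1")
            if np.any(arr <= 0.0):
                raise ValueError(f"fractions for {key} must be positive")

    @property
    def n_analyses(self) -> int:
        return max(len(fr) for fr in self.fractions.values())

    def tested_at(self, population: Population, endpoint: Endpoint, k: int) -> bool:
        """Whether hypothesis (population, endpoint) is tested at analysis ``k`` (1-based)."""
        return 1 <= k <= len(self.fractions[(population, endpoint)])

    def final_look(self, population: Population, endpoint: Endpoint) -> int:
        return len(self.fractions[(population, endpoint)])


@dataclass(frozen=True)
class FutilityRule:
    """Stage-1 non-binding futility rule on PFS hazard-ratio estimates.

    ``theta_F``/``theta_S`` are the pass thresholds (observed HR must be
    strictly below theta to pass), calibrated so a treatment with true HR
    ``hr_alt`` fails the gate with probability ``gamma`` at ``d`` events.
    ``d_F``/``d_S`` are the stage-1 PFS event counts at which the futility
    analysis is performed.
    """

    gamma_F: float
    gamma_S: float
    theta_F: float
    theta_S: float
    hr_alt_F: float
    hr_alt_S: float
    d_F: int
    d_S: int

    @classmethod
    def from_thresholds(
        cls,
        theta_F: float,
        theta_S: float,
        gamma: float = 0.05,
        hr_alt: float = 0.7,
    ) -> "FutilityRule":
        """Build a rule from printed thresholds, back-solving the stage-1
        event counts that calibrate them."""
        return cls(
            gamma_F=gamma,
            gamma_S=gamma,
            theta_F=theta_F,
            theta_S=theta_S,
            hr_alt_F=hr_alt,
            hr_alt_S=hr_alt,
            d_F=implied_futility_events(hr_alt, gamma, theta_F),
            d_S=implied_futility_events(hr_alt, gamma, theta_S),
        )


@dataclass(frozen=True)
class CombinationWeights:
    """Pre-specified inverse-normal combination weights per endpoint.

    Each endpoint maps to a ``(w1, w2)`` pair applied at every stage-2
    analysis (``w1`` weights the stage-1 cohort, ``w2`` the stage-2 cohort;
    ``w1**2 + w2**2 == 1``), or to the string ``"event_driven"`` meaning the
    weights are recomputed per analysis from observed stage event counts.
    Event-driven weights are a reference configuration only: they cannot be
    pre-specified in a real trial.
    """

    pfs: tuple[float, float] | str
    os: tuple[float, float] | str
    name: str = ""

    def __post_init__(self) -> None:
        for ep, w in (("pfs", self.pfs), ("os", self.os)):
            if isinstance(w, str):
                if w != "event_driven":
                    raise ValueError(f"unknown weight spec {w!r} for {ep}")
            else:
                if len(w) != 2 or w[0] < 0 or w[1] < 0:
                    raise ValueError("weights must be a nonnegative pair")
                if abs(w[0] ** 2 + w[1] ** 2 - 1.0) > _ATOL:
                    raise ValueError("weights must satisfy w1^2 + w2^2 = 1")

    def for_endpoint(self, endpoint: Endpoint):
        return self.pfs if endpoint == "PFS" else self.os

    @property
    def is_event_driven(self) -> bool:
        return self.pfs == "event_driven" or self.os == "event_driven"

    def fingerprint(self) -> tuple:
        return (self.pfs, self.os)


Stratum = Literal["subgroup", "complement"]


@dataclass(frozen=True)
class TrialDesign:
    """Complete parameterization of one design variant for one setting."""

    variant: Variant
    n_total: int
    subgroup_prevalence: float
    enroll_duration: float  # months
    followup_duration: float  # months of additional follow-up to planned FA
    control_median: dict[tuple[Endpoint, Stratum], float]  # months
    hazard_ratio: dict[tuple[Endpoint, Stratum], float]  # experimental / control
    annual_dropout: dict[Endpoint, float]
    alphas: AlphaAllocation
    schedule: AnalysisSchedule
    futility: FutilityRule | None
    weights: CombinationWeights
    spending: str = "lan_demets_of"
    setting: int | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.subgroup_prevalence < 1.0:
            raise ValueError("subgroup_prevalence must lie in (0, 1)")
        if any(m <= 0 for m in self.control_median.values()):
            raise ValueError("control medians must be positive")
        if any(h <= 0 for h in self.hazard_ratio.values()):
            raise ValueError("hazard ratios must be positive")
        self.alphas.validate(self.variant)
        if self.variant in ("gGSD", "AD") and self.futility is None:
            raise ValueError(f"{self.variant} requires a futility rule")

    # -- event-rate model -------------------------------------------------

    def hazard(self, endpoint: Endpoint, stratum: Stratum, experimental: bool) -> float:
        """Monthly exponential event hazard for one stratum/arm."""
        lam = math.log(2.0) / self.control_median[(endpoint, stratum)]
        if experimental:
            lam *= self.hazard_ratio[(endpoint, stratum)]
        return lam

    def dropout_rate(self, endpoint: Endpoint) -> float:
        """Monthly exponential dropout rate matching the annual probability."""
        return -math.log(1.0 - self.annual_dropout[endpoint]) / 12.0

    @property
    def planned_fa_time(self) -> float:
        return self.enroll_duration + self.followup_duration

    def expected_events(
        self, endpoint: Endpoint, population: Population, calendar_time: float
    ) -> float:
        """Expected observed event count at a calendar time under the design
        model (exponential events and dropout, uniform accrual)."""
        total = 0.0
        strata: list[tuple[Stratum, float]] = [
            ("subgroup", self.subgroup_prevalence)
        ]
        if population == "F":
            strata.append(("complement", 1.0 - self.subgroup_prevalence))
        mu = self.dropout_rate(endpoint)
        for stratum, prev in strata:
            for experimental in (False, True):
                lam = self.hazard(endpoint, stratum, experimental)
                n = self.n_total * prev * 0.5
                total += n * _event_fraction(
                    lam, mu, calendar_time, self.enroll_duration
                )
        return total

    def event_targets(self, endpoint: Endpoint, population: Population) -> tuple[int, ...]:
        """Per-analysis target event counts: design final events at the
        planned FA time scaled by the hypothesis's information fractions."""
        final = self.expected_events(endpoint, population, self.planned_fa_time)
        fr = self.schedule.fractions[(population, endpoint)]
        return tuple(int(round(final * f)) for f in fr)

    def boundary_set(
        self, population: Population, endpoint: Endpoint, alpha: float | None = None
    ) -> BoundarySet:
        """Boundaries for one hypothesis at its design fractions; ``alpha``
        defaults to the initial allocation (pass the current alpha after a
        graphical reallocation)."""
        if alpha is None:
            alpha = self.alphas.for_hypothesis(population, endpoint)
        return cached_boundaries(
            self.schedule.fractions[(population, endpoint)], alpha
        )


def _event_fraction(lam: float, mu: float, T: float, accrual: float) -> float:
    """P(event observed by calendar time T) for one patient with exponential
    event rate ``lam``, dropout rate ``mu``, enrollment ~ U(0, accrual)."""
    if T <= 0.0:
        return 0.0
    c = lam + mu
    m = min(T, accrual)
    integral = (math.exp(-c * (T - m)) - math.exp(-c * T)) / c
    return (lam / c) * (m - integral) / accrual
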