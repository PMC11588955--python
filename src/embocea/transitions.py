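"""Per-cycle transition probabilities and the expanded transition matrix.

The five clinical states are: local (tumour controlled), TAE-eligible
progressive (progressed but still a candidate for embolization),
TAE-refractory progressive (on systemic therapy), decompensated
cirrhosis, and death. Per-cycle probabilities are derived from median
time-to-event data under an exponential (constant-hazard) approximation,

    p = 1 - 0.5**(cycle / median),

and from annual event rates via ``p = 1 - (1 - annual)**(cycle/12)``.
Transitions out of the treatment-eligible states form a competing-risk
cascade: death first, then decompensation among survivors, then
progression among non-decompensated survivors. By model assumption the
same quadruple applies to the local and TAE-eligible states (the primed
probabilities equal the unprimed ones).

The cohort engine needs more than five states because treatment costs
are capped at a maximum number of embolization sessions per arm; the
expanded state space crosses the two treatable states with a
sessions-delivered counter. Session counters gate cost accrual only --
they never alter the clinical transition probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters, _normalize_arm

__all__ = [
    "CycleProbabilities",
    "RefractoryProbabilities",
    "DecompProbabilities",
    "TransitionSet",
    "StateDef",
    "TransitionMatrix",
    "median_to_cycle_prob",
    "annual_prob_to_cycle_prob",
    "progression_cycle_prob",
    "compose_treatment_state_probs",
    "compose_refractory_probs",
    "compose_decomp_probs",
    "derive_transition_set",
    "build_matrix",
]

_PROB_TOL = 1e-9


def median_to_cycle_prob(median: float, cycle: float) -> float:
    """Probability of the event within one cycle given the median time to event."""
    if median <= 0 or cycle <= 0:
        raise ValueError("median and cycle must be > 0")
    return 1.0 - 0.5 ** (cycle / median)


def annual_prob_to_cycle_prob(annual: float, cycle: float) -> float:
    """Rescale an annual event probability to the cycle length."""
    if not 0.0 <= annual < 1.0:
        raise ValueError("annual probability must be in [0, 1)")
    if cycle <= 0:
        raise ValueError("cycle must be > 0")
    return 1.0 - (1.0 - annual) ** (cycle / 12.0)


def progression_cycle_prob(median_pfs: float, median_os: float, cycle: float) -> float:
    """Per-cycle progression probability from PFS and OS medians.

    Under the exponential approximation the progression-specific hazard is
    the PFS hazard minus the OS hazard; a negative difference (PFS median
    above OS median) is clinically impossible and is clamped to zero with
    a warning.
    """
    if median_pfs <= 0 or median_os <= 0:
        raise ValueError("medians must be > 0")
    if cycle <= 0:
        raise ValueError("cycle must be > 0")
    hazard = math.log(2.0) / median_pfs - math.log(2.0) / median_os
    if hazard < 0:
        warnings.warn(
            "median_pfs exceeds median_os; progression hazard clamped to 0",
            stacklevel=2,
        )
        hazard = 0.0
    return 1.0 - math.exp(-hazard * cycle)


@dataclass(frozen=True)
class CycleProbabilities:
    """Per-cycle four-way split out of the local / TAE-eligible states.

    ``p1`` stay, ``p2`` progress (to TAE-eligible from local, to
    TAE-refractory from TAE-eligible), ``p3`` decompensate, ``p4`` die.
    """

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        probs = (self.p1, self.p2, self.p3, self.p4)
        if any(p < -_PROB_TOL or p > 1 + _PROB_TOL for p in probs):
            raise ValueError(f"probabilities out of [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass(frozen=True)
class RefractoryProbabilities:
    """Per-cycle split out of the TAE-refractory (systemic therapy) state."""

    p5: float
    p6: float
    p7: float

    def __post_init__(self) -> None:
        probs = (self.p5, self.p6, self.p7)
        if any(p < -_PROB_TOL or p > 1 + _PROB_TOL for p in probs):
            raise ValueError(f"probabilities out of [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")


@dataclass(frozen=True)
class DecompProbabilities:
    """Per-cycle split out of the decompensated-cirrhosis state."""

    p8: float
    p9: float

    def __post_init__(self) -> None:
        if not (0 <= self.p8 <= 1 and 0 <= self.p9 <= 1):
            raise ValueError("probabilities out of [0, 1]")
        if abs(self.p8 + self.p9 - 1.0) > 1e-6:
            raise ValueError("p8 + p9 must equal 1")


def compose_treatment_state_probs(
    p_death: float, p_decomp_cycle: float, p_prog_cycle: float
) -> CycleProbabilities:
    """Competing-risk cascade for the local / TAE-eligible states.

    Death is applied first, decompensation among survivors, progression
    among non-decompensated survivors; staying is the complement.
    """
    for name, p in (("p_death", p_death), ("p_decomp_cycle", p_decomp_cycle),
                    ("p_prog_cycle", p_prog_cycle)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    p4 = p_death
    p3 = (1.0 - p4) * p_decomp_cycle
    p2 = (1.0 - p4) * (1.0 - p_decomp_cycle) * p_prog_cycle
    p1 = 1.0 - p2 - p3 - p4
    if p1 < -_PROB_TOL:
        raise ValueError(f"stay probability is negative: {p1}")
    return CycleProbabilities(max(p1, 0.0), p2, p3, p4)


def compose_refractory_probs(
    median_os_systemic: float, annual_decomp_systemic: float, cycle: float
) -> RefractoryProbabilities:
    """Cascade for the systemic-therapy state: death, then decompensation."""
    p7 = median_to_cycle_prob(median_os_systemic, cycle)
    p6 = (1.0 - p7) * annual_prob_to_cycle_prob(annual_decomp_systemic, cycle)
    p5 = 1.0 - p6 - p7
    if p5 < -_PROB_TOL:
        raise ValueError(f"stay probability is negative: {p5}")
    return RefractoryProbabilities(max(p5, 0.0), p6, p7)


def compose_decomp_probs(annual_survival: float, cycle: float) -> DecompProbabilities:
    """Per-cycle survival in decompensated cirrhosis from the 1-year survival rate."""
    if not 0.0 < annual_survival <= 1.0:
        raise ValueError("annual_survival must be in (0, 1]")
    if cycle <= 0:
        raise ValueError("cycle must be > 0")
    p8 = annual_survival ** (cycle / 12.0)
    return DecompProbabilities(p8, 1.0 - p8)


@dataclass(frozen=True)
class TransitionSet:
    """All per-cycle probabilities for one arm (P1-P9 in the reports)."""

    arm: str
    population: str
    treatment: CycleProbabilities
    refractory: RefractoryProbabilities
    decomp: DecompProbabilities

    def to_series(self) -> pd.Series:
        t, r, d = self.treatment, self.refractory, self.decomp
        return pd.Series(
            {"p1": t.p1, "p2": t.p2, "p3": t.p3, "p4": t.p4,
             "p5": r.p5, "p6": r.p6, "p7": r.p7, "p8": d.p8, "p9": d.p9},
            name=f"{self.arm}_{self.population}",
        )


def derive_transition_set(arm: str, params: ModelParameters) -> TransitionSet:
    """Derive every per-cycle probability for one arm from the model inputs."""
    arm = _normalize_arm(arm)
    cycle = params.settings.cycle_months
    sv, rates = params.survival, params.rates
    median_os = sv.median_os_tare if arm == "tare" else sv.median_os_deb
    median_pfs = sv.median_pfs_tare if arm == "tare" else sv.median_pfs_deb
    treatment = compose_treatment_state_probs(
        median_to_cycle_prob(median_os, cycle),
        annual_prob_to_cycle_prob(rates.annual_decomp_tae_eligible, cycle),
        progression_cycle_prob(median_pfs, median_os, cycle),
    )
    refractory = compose_refractory_probs(
        sv.median_os_systemic, rates.annual_decomp_systemic, cycle)
    decomp = compose_decomp_probs(rates.annual_survival_decomp, cycle)
    return TransitionSet(arm, sv.population, treatment, refractory, decomp)


@dataclass(frozen=True)
class StateDef:
    """One expanded Markov state.

    ``kind`` is the clinical state; ``sessions`` counts embolization
    sessions delivered up to and including the current cycle; ``treated``
    marks states in which a session is delivered during the cycle.
    """

    kind: str  # local | eligible | refractory | decomp | dead
    sessions: int = 0
    treated: bool = False

    @property
    def label(self) -> str:
        if self.kind in ("local", "eligible"):
            suffix = "tx" if self.treated else "fu"
            return f"{self.kind}_s{self.sessions}_{suffix}"
        return self.kind


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix over the expanded state space for one arm."""

    arm: str
    states: tuple[StateDef, ...]
    matrix: np.ndarray  # (n, n), rows sum to 1
    transition_set: TransitionSet

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match state list")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.matrix < -1e-15).any():
            raise ValueError("transition probabilities must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def index_of(self, kind: str) -> list[int]:
        return [i for i, s in enumerate(self.states) if s.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="state")

    def collapse_occupancy(self, occupancy: np.ndarray) -> pd.Series:
        """Collapse an expanded occupancy vector to the five clinical states."""
        out = {}
        for kind in ("local", "eligible", "refractory", "decomp", "dead"):
            idx = self.index_of(kind)
            out[kind] = float(occupancy[..., idx].sum(axis=-1))
        return pd.Series(out)


def build_matrix(
    arm: str,
    params: ModelParameters,
    transition_set: TransitionSet | None = None,
) -> TransitionMatrix:
    """Assemble the expanded transition matrix for one arm.

    The expansion depends on the session policy:

    - ``per_cycle_while_eligible`` (default): a session is delivered in
      every cycle spent in the local or TAE-eligible state until the
      arm's cap is reached.
    - ``on_entry``: a session is delivered in the first cycle and on
      entry into the TAE-eligible state only.

    The clinical four-way split is identical in every expanded
    local/eligible state; only the cost-relevant session bookkeeping
    differs between columns.
    """
    arm = _normalize_arm(arm)
    ts = transition_set or derive_transition_set(arm, params)
    cap = params.session_cap(arm)
    policy = params.settings.session_policy

    states: list[StateDef] = []

    def add(state: StateDef) -> StateDef:
        states.append(state)
        return state

    if policy == "per_cycle_while_eligible":
        # local: treated with s = 1..cap, then an untreated follow-up state
        local = [add(StateDef("local", s, True)) for s in range(1, cap + 1)]
        local.append(add(StateDef("local", cap, False)))
        # eligible is only reachable with >= 2 sessions (entry delivers one)
        elig = {s: add(StateDef("eligible", s, True)) for s in range(2, cap + 1)}
        elig_fu = add(StateDef("eligible", cap, False))

        def next_local(s: StateDef) -> StateDef:
            return local[s.sessions] if s.treated and s.sessions < cap else (
                local[-1] if not s.treated or s.sessions == cap else local[s.sessions])

        def next_elig(s: StateDef) -> StateDef:
            if s.treated and s.sessions < cap:
                return elig[s.sessions + 1] if s.sessions + 1 >= 2 else elig_fu
            return elig_fu
    elif policy == "on_entry":
        local = [add(StateDef("local", 1, True)), add(StateDef("local", 1, False))]
        entry_treated = cap >= 2  # entry delivers a session only if one remains
        elig_entry = add(StateDef("eligible", 2 if entry_treated else 1, entry_treated))
        elig_fu = add(StateDef("eligible", 2 if entry_treated else 1, False))

        def next_local(s: StateDef) -> StateDef:
            return local[1]

        def next_elig(s: StateDef) -> StateDef:
            return elig_entry if s.kind == "local" else elig_fu
    else:  # pragma: no cover - rejected at parameter validation
        raise ValueError(f"unknown session policy: {policy}")

    refractory = add(StateDef("refractory"))
    decomp = add(StateDef("decomp"))
    dead = add(StateDef("dead"))

    idx = {id(s): i for i, s in enumerate(states)}
    n = len(states)
    mat = np.zeros((n, n))
    t, r, d = ts.treatment, ts.refractory, ts.decomp
    for s in states:
        i = idx[id(s)]
        if s.kind == "local":
            mat[i, idx[id(next_local(s))]] += t.p1
            if policy == "on_entry":
                mat[i, idx[id(next_elig(s))]] += t.p2
            else:
                # progression while a session remains delivers one on arrival
                if s.treated and s.sessions < cap:
                    target = elig[s.sessions + 1] if s.sessions + 1 >= 2 else elig_fu
                else:
                    target = elig_fu
                mat[i, idx[id(target)]] += t.p2
            mat[i, idx[id(decomp)]] += t.p3
            mat[i, idx[id(dead)]] += t.p4
        elif s.kind == "eligible":
            mat[i, idx[id(next_elig(s))]] += t.p1
            mat[i, idx[id(refractory)]] += t.p2
            mat[i, idx[id(decomp)]] += t.p3
            mat[i, idx[id(dead)]] += t.p4
        elif s.kind == "refractory":
            mat[i, idx[id(refractory)]] = r.p5
            mat[i, idx[id(decomp)]] = r.p6
            mat[i, idx[id(dead)]] = r.p7
        elif s.kind == "decomp":
            mat[i, idx[id(decomp)]] = d.p8
            mat[i, idx[id(dead)]] = d.p9
        else:  # dead: absorbing
            mat[i, i] = 1.0

    return TransitionMatrix(arm, tuple(states), mat, ts)
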