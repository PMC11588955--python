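"""Deterministic cohort simulation and a microsimulation cross-check.

The cohort engine propagates a state-occupancy vector through the
expanded transition matrix for a fixed number of cycles, accruing
discounted costs and QALYs each cycle. Rewards are attached to the state
occupied at the start of a cycle; the whole cycle's cost and utility are
accrued at that point with the discount factor of that cycle (cycle 0
undiscounted).

Per-cycle cost by state:

- treated local/eligible state: the arm's admission cost (DEB-TACE
  admission, or TARE admission plus the microsphere price), plus the
  one-time pre-procedural angiography and scintigraphy fees on the first
  TARE session, plus (by default) the outpatient management cost of the
  cycle and a contrast-CT fee;
- untreated local/eligible state: outpatient monthly cost times cycle
  length, plus a contrast-CT fee if the CT schedule includes follow-up
  cycles;
- TAE-refractory: systemic-therapy monthly cost times cycle length;
- decompensated cirrhosis: palliative monthly cost times cycle length;
- death: zero.

QALY accrual per cycle is the state utility times the cycle length in
years. The microsimulation draws individual patient trajectories from
the same matrix and reward structure and serves as an independent check
on the cohort arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters, _normalize_arm
from .transitions import StateDef, TransitionMatrix, build_matrix

__all__ = [
    "CohortTrace",
    "RunResult",
    "MicrosimResult",
    "discount_factor",
    "cycle_rewards",
    "run_cohort",
    "run_microsim",
]


def discount_factor(cycle_index: int, params: ModelParameters) -> float:
    """Discount factor for a 0-based cycle index (cycle 0 undiscounted)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    years = cycle_index * params.settings.cycle_months / 12.0
    return (1.0 + params.settings.discount_annual) ** (-years)


def cycle_rewards(
    state: StateDef, arm: str, params: ModelParameters
) -> tuple[float, float]:
    """(cost JPY, QALY) accrued during one cycle spent in ``state``."""
    arm = _normalize_arm(arm)
    c, u, st = params.costs, params.utilities, params.settings
    cycle_years = st.cycle_months / 12.0
    outpatient = c.outpatient_monthly * st.cycle_months

    if state.kind == "dead":
        return 0.0, 0.0
    if state.kind == "refractory":
        return c.systemic_monthly * st.cycle_months, u.u_refractory * cycle_years
    if state.kind == "decomp":
        return c.decomp_monthly * st.cycle_months, u.u_decomp * cycle_years
    if state.kind not in ("local", "eligible"):
        raise ValueError(f"unknown state kind: {state.kind}")

    utility = u.u_local if state.kind == "local" else u.u_eligible
    if state.treated:
        cost = (c.deb_admission if arm == "deb"
                else c.tare_admission_other + c.microsphere_price)
        if arm == "tare" and state.sessions == 1:
            cost += c.pre_angio + c.scinti  # one-time work-up, first session only
        if st.outpatient_in_treatment_cycles:
            cost += outpatient
        if st.ct_schedule in ("treatment", "every_cycle"):
            cost += c.ct_followup
    else:
        cost = outpatient
        if st.ct_schedule in ("follow_up", "every_cycle"):
            cost += c.ct_followup
    return cost, utility * cycle_years


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and reward accruals of a cohort run."""

    labels: tuple[str, ...]
    occupancy: np.ndarray        # (cycles, n_states), start-of-cycle
    cost: np.ndarray             # (cycles,), undiscounted
    qaly: np.ndarray             # (cycles,), undiscounted
    cost_discounted: np.ndarray  # (cycles,)
    qaly_discounted: np.ndarray  # (cycles,)
    sessions: np.ndarray         # (cycles,), sessions delivered per cycle

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy,
                          columns=[f"occ_{lab}" for lab in self.labels])
        df.insert(0, "cycle", np.arange(len(df)))
        for name in ("cost", "qaly", "cost_discounted", "qaly_discounted",
                     "sessions"):
            df[name] = getattr(self, name)
        return df

    def clinical_occupancy(self, matrix: TransitionMatrix) -> pd.DataFrame:
        """Occupancy collapsed to the five clinical states (the survival plot data)."""
        out = {}
        for kind in ("local", "eligible", "refractory", "decomp", "dead"):
            idx = matrix.index_of(kind)
            out[kind] = self.occupancy[:, idx].sum(axis=1)
        df = pd.DataFrame(out)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


@dataclass(frozen=True)
class RunResult:
    """Totals of one deterministic cohort run."""

    arm: str
    population: str
    total_cost: float
    total_qaly: float
    sessions_expected: float
    trace: CohortTrace
    matrix: TransitionMatrix

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.trace.cost.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.trace.qaly.sum())


def _reward_vectors(
    matrix: TransitionMatrix, arm: str, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    costs, qalys, treated = [], [], []
    for s in matrix.states:
        cost, qaly = cycle_rewards(s, arm, params)
        costs.append(cost)
        qalys.append(qaly)
        treated.append(1.0 if s.treated else 0.0)
    return np.array(costs), np.array(qalys), np.array(treated)


def run_cohort(
    arm: str,
    params: ModelParameters,
    matrix: TransitionMatrix | None = None,
) -> RunResult:
    """Run the deterministic cohort model for one arm.

    The cohort starts with the whole population in the first expanded
    state (local, receiving the first treatment session). Deterministic:
    identical inputs give bit-identical outputs.
    """
    arm = _normalize_arm(arm)
    if matrix is None:
        matrix = build_matrix(arm, params)
    elif matrix.arm != arm:
        raise ValueError(f"matrix built for arm {matrix.arm!r}, not {arm!r}")

    n = len(matrix.states)
    cycles = params.settings.total_cycles
    cost_vec, qaly_vec, treated_vec = _reward_vectors(matrix, arm, params)

    occ = np.zeros(n)
    occ[0] = 1.0
    occupancy = np.zeros((cycles, n))
    cost = np.zeros(cycles)
    qaly = np.zeros(cycles)
    cost_d = np.zeros(cycles)
    qaly_d = np.zeros(cycles)
    sessions = np.zeros(cycles)

    hc = params.settings.half_cycle_correction
    for t in range(cycles):
        occupancy[t] = occ
        w = 0.5 if hc and (t == 0 or t == cycles - 1) else 1.0
        df = discount_factor(t, params)
        cost[t] = w * occ @ cost_vec
        qaly[t] = w * occ @ qaly_vec
        cost_d[t] = df * cost[t]
        qaly_d[t] = df * qaly[t]
        sessions[t] = occ @ treated_vec
        occ = occ @ matrix.matrix

    trace = CohortTrace(tuple(matrix.labels), occupancy, cost, qaly,
                        cost_d, qaly_d, sessions)
    return RunResult(
        arm=arm,
        population=params.survival.population,
        total_cost=float(cost_d.sum()),
        total_qaly=float(qaly_d.sum()),
        sessions_expected=float(sessions.sum()),
        trace=trace,
        matrix=matrix,
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimate of per-patient discounted cost and QALY."""

    arm: str
    n_patients: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_sessions: float


def run_microsim(
    arm: str,
    params: ModelParameters,
    matrix: TransitionMatrix | None = None,
    n_patients: int = 10_000,
    seed: int = 0,
) -> MicrosimResult:
    """Individual-level simulation with the same probabilities and rewards.

    Used as an independent oracle for the cohort engine: the mean cost
    and QALY converge to the cohort totals as ``n_patients`` grows.
    """
    arm = _normalize_arm(arm)
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    if matrix is None:
        matrix = build_matrix(arm, params)

    rng = np.random.default_rng(seed)
    n = len(matrix.states)
    cycles = params.settings.total_cycles
    cost_vec, qaly_vec, treated_vec = _reward_vectors(matrix, arm, params)
    cum = np.cumsum(matrix.matrix, axis=1)

    state = np.zeros(n_patients, dtype=np.intp)  # everyone starts treated local
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    sessions = np.zeros(n_patients)
    hc = params.settings.half_cycle_correction
    for t in range(cycles):
        w = 0.5 if hc and (t == 0 or t == cycles - 1) else 1.0
        df = discount_factor(t, params)
        cost += df * w * cost_vec[state]
        qaly += df * w * qaly_vec[state]
        sessions += treated_vec[state]
        u = rng.random(n_patients)
        nxt = np.empty_like(state)
        for s in np.unique(state):
            mask = state == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        state = np.minimum(nxt, n - 1)

    return MicrosimResult(
        arm=arm,
        n_patients=n_patients,
        seed=seed,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n_patients)),
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n_patients)),
        mean_sessions=float(sessions.mean()),
    )
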