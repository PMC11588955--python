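"""Cost-effectiveness comparison and sensitivity analyses.

``compare`` computes the incremental cost-effectiveness ratio (ICER) and
net monetary benefit (NMB) of TARE versus DEB-TACE. ``one_way_dsa``
perturbs one parameter at a time over its plausible range and records
the ICER at each bound (tornado data); ``threshold_search`` finds the
parameter value at which the ICER equals the willingness-to-pay
threshold. ``run_psa`` draws all uncertain parameters jointly (gamma
for costs and survival medians, beta for utilities and annual rates,
triangular for the discount rate), reruns both arms per iteration, and
produces the incremental cost/effect cloud and the cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .engine import RunResult, run_cohort
from .parameters import ModelParameters

__all__ = [
    "CEAComparison",
    "DSAResult",
    "PSAResult",
    "compare",
    "run_arms",
    "one_way_dsa",
    "threshold_search",
    "beta_from_mean_sd",
    "gamma_from_mean_sd",
    "run_psa",
    "DSA_RANGES",
    "PSA_DISTRIBUTIONS",
]


@dataclass(frozen=True)
class CEAComparison:
    """Incremental comparison of TARE against DEB-TACE at a given WTP."""

    cost_tare: float
    cost_deb: float
    qaly_tare: float
    qaly_deb: float
    wtp: float
    population: str = ""

    @property
    def delta_cost(self) -> float:
        return self.cost_tare - self.cost_deb

    @property
    def delta_qaly(self) -> float:
        return self.qaly_tare - self.qaly_deb

    @property
    def icer(self) -> float | None:
        """Incremental cost per QALY; None when the QALY difference is zero."""
        if self.delta_qaly == 0:
            return None
        return self.delta_cost / self.delta_qaly

    @property
    def nmb_tare(self) -> float:
        return self.wtp * self.qaly_tare - self.cost_tare

    @property
    def nmb_deb(self) -> float:
        return self.wtp * self.qaly_deb - self.cost_deb

    @property
    def dominance(self) -> str:
        """'tare', 'deb', or 'none' (strict dominance: cheaper AND better)."""
        if self.delta_cost <= 0 and self.delta_qaly >= 0 and (
                self.delta_cost < 0 or self.delta_qaly > 0):
            return "tare"
        if self.delta_cost >= 0 and self.delta_qaly <= 0 and (
                self.delta_cost > 0 or self.delta_qaly < 0):
            return "deb"
        return "none"

    @property
    def cost_effective(self) -> bool:
        """Whether TARE is cost-effective at the WTP (higher NMB)."""
        if self.dominance == "tare":
            return True
        if self.dominance == "deb":
            return False
        icer = self.icer
        if icer is None:
            return self.delta_cost < 0
        return icer <= self.wtp if self.delta_qaly > 0 else icer > self.wtp

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "cost_tare": self.cost_tare, "cost_deb": self.cost_deb,
            "qaly_tare": self.qaly_tare, "qaly_deb": self.qaly_deb,
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "icer": self.icer, "wtp": self.wtp,
            "nmb_tare": self.nmb_tare, "nmb_deb": self.nmb_deb,
            "dominance": self.dominance, "cost_effective": self.cost_effective,
        }


def compare(
    result_tare: RunResult, result_deb: RunResult, wtp: float
) -> CEAComparison:
    """Build the incremental comparison from two arm runs."""
    if result_tare.population != result_deb.population:
        raise ValueError("arm results come from different populations")
    return CEAComparison(
        cost_tare=result_tare.total_cost,
        cost_deb=result_deb.total_cost,
        qaly_tare=result_tare.total_qaly,
        qaly_deb=result_deb.total_qaly,
        wtp=wtp,
        population=result_tare.population,
    )


def run_arms(params: ModelParameters) -> tuple[RunResult, RunResult]:
    """Run both arms under one parameter set (TARE first)."""
    return run_cohort("tare", params), run_cohort("deb", params)


def _icer_for(params: ModelParameters) -> float | None:
    tare, deb = run_arms(params)
    return compare(tare, deb, params.settings.wtp).icer


# One-way sensitivity ranges: costs +/-20%, utilities +/-10%, survival
# medians and annual rates +/-30% (multiplicative), discount rate 0-4%
# absolute. Work-up and CT fees have no published range and are omitted.
DSA_RANGES: dict[str, tuple[float, float]] = {
    **{k: (0.8, 1.2) for k in (
        "deb_admission", "microsphere_price", "tare_admission_other",
        "outpatient_monthly", "systemic_monthly", "decomp_monthly")},
    **{k: (0.9, 1.1) for k in (
        "u_local", "u_eligible", "u_refractory", "u_decomp")},
    **{k: (0.7, 1.3) for k in (
        "median_os_tare", "median_os_deb", "median_pfs_tare",
        "median_pfs_deb", "median_os_systemic",
        "annual_decomp_tae_eligible", "annual_decomp_systemic",
        "annual_survival_decomp")},
}


@dataclass(frozen=True)
class DSAResult:
    """One-way sensitivity analysis output."""

    base_icer: float
    wtp: float
    table: pd.DataFrame = field(repr=False)  # ordered by descending bar width

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _dsa_bounds(params: ModelParameters, ranges=None) -> dict[str, tuple[float, float]]:
    bounds: dict[str, tuple[float, float]] = {}
    for key, (lo_f, hi_f) in DSA_RANGES.items():
        base = params.get(key)
        bounds[key] = (base * lo_f, min(base * hi_f, 1.0)
                       if key.startswith(("u_", "annual_")) else base * hi_f)
    bounds["discount_annual"] = (0.0, 0.04)
    if ranges:
        bounds.update(ranges)
    return bounds


def one_way_dsa(
    params: ModelParameters,
    ranges: dict[str, tuple[float, float]] | None = None,
    wtp: float | None = None,
) -> DSAResult:
    """Vary each parameter to its bounds, holding everything else at base.

    ``ranges`` overrides the default bounds per flat parameter name; each
    range must bracket the base value. The base case is rebuilt from the
    untouched ``params`` for every parameter, so no state leaks between
    perturbations.
    """
    wtp = params.settings.wtp if wtp is None else wtp
    bounds = _dsa_bounds(params, ranges)
    base_icer = _icer_for(params)
    if base_icer is None:
        raise ValueError("base-case ICER is undefined")

    rows = []
    for key, (lo, hi) in bounds.items():
        base = params.get(key)
        if not lo <= base <= hi:
            raise ValueError(f"range for {key} does not bracket the base value")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            icer_lo = _icer_for(params.replace(**{key: lo}))
            icer_hi = _icer_for(params.replace(**{key: hi}))
        lo_v = icer_lo if icer_lo is not None else np.nan
        hi_v = icer_hi if icer_hi is not None else np.nan
        rows.append({
            "parameter": key, "base_value": base, "low": lo, "high": hi,
            "icer_low": lo_v, "icer_high": hi_v,
            "bar_width": abs(hi_v - lo_v),
        })
    table = pd.DataFrame(rows).sort_values(
        "bar_width", ascending=False, kind="mergesort").reset_index(drop=True)

    # threshold crossing within the scanned interval, where one exists
    thresholds = []
    for row in table.itertuples(index=False):
        crossing = None
        f_lo, f_hi = row.icer_low - wtp, row.icer_high - wtp
        if np.isfinite(f_lo) and np.isfinite(f_hi) and f_lo * f_hi < 0:
            crossing = threshold_search(row.parameter, params, wtp,
                                        (row.low, row.high))
        thresholds.append(crossing)
    table["threshold"] = thresholds
    return DSAResult(base_icer=base_icer, wtp=wtp, table=table)


def threshold_search(
    parameter: str,
    params: ModelParameters,
    wtp: float | None = None,
    interval: tuple[float, float] | None = None,
) -> float | None:
    """Find the parameter value where the ICER equals the WTP threshold.

    Uses Brent's bracketing root-finder on ``ICER(theta) - wtp`` to
    relative tolerance 1e-6. Returns None when the ICER minus WTP has the
    same sign at both interval endpoints (no crossing to find).
    """
    wtp = params.settings.wtp if wtp is None else wtp
    if interval is None:
        bounds = _dsa_bounds(params)
        if parameter not in bounds:
            raise ValueError(f"no default range for parameter {parameter!r}")
        interval = bounds[parameter]
    lo, hi = interval

    def f(theta: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            icer = _icer_for(params.replace(**{parameter: theta}))
        if icer is None:
            raise ValueError(f"ICER undefined at {parameter}={theta}")
        return icer - wtp

    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        return None
    root = optimize.brentq(f, lo, hi, rtol=1e-6)
    return float(root)


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters ``(alpha, beta)``."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be in (0, 1)")
    if sd <= 0 or sd * sd >= mean * (1.0 - mean):
        raise ValueError("sd infeasible for a beta distribution with this mean")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma ``(shape, scale)``."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


#: Distribution family per uncertain parameter in the probabilistic
#: analysis; every parameter uses sd = 10% of its mean.
PSA_DISTRIBUTIONS: dict[str, str] = {
    **{k: "gamma" for k in (
        "deb_admission", "microsphere_price", "tare_admission_other",
        "outpatient_monthly", "systemic_monthly", "decomp_monthly",
        "pre_angio", "scinti", "ct_followup",
        "median_os_tare", "median_os_deb", "median_pfs_tare",
        "median_pfs_deb", "median_os_systemic")},
    **{k: "beta" for k in (
        "u_local", "u_eligible", "u_refractory", "u_decomp",
        "annual_decomp_tae_eligible", "annual_decomp_systemic",
        "annual_survival_decomp")},
    "discount_annual": "triangular",  # mode 2%, range 0-4%
}

PSA_RELATIVE_SD = 0.10


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo sensitivity analysis output."""

    n_iterations: int
    seed: int
    wtp: float
    draws: pd.DataFrame = field(repr=False)   # delta_cost, delta_qaly per iter
    ceac: pd.DataFrame = field(repr=False)    # wtp grid -> P(cost-effective)
    n_resampled: int = 0

    @property
    def fraction_below_wtp(self) -> float:
        """Fraction of iterations below the WTP line (positive incremental NMB)."""
        d = self.draws
        return float((self.wtp * d["delta_qaly"] - d["delta_cost"] > 0).mean())

    def ceac_at(self, wtp: float) -> float:
        d = self.draws
        return float((wtp * d["delta_qaly"] - d["delta_cost"] > 0).mean())


def _draw_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> tuple[dict[str, float], int]:
    updates: dict[str, float] = {}
    n_resampled = 0
    for key, family in PSA_DISTRIBUTIONS.items():
        mean = params.get(key)
        if family == "triangular":
            updates[key] = float(rng.triangular(0.0, mean, 2.0 * mean)) \
                if mean > 0 else mean
            continue
        sd = PSA_RELATIVE_SD * mean
        if sd == 0:
            updates[key] = mean
            continue
        if family == "gamma":
            shape, scale = gamma_from_mean_sd(mean, sd)
            updates[key] = float(rng.gamma(shape, scale))
        else:
            a, b = beta_from_mean_sd(mean, sd)
            draw = float(rng.beta(a, b))
            while draw <= 0.0 or draw >= 1.0:  # guard degenerate draws
                draw = float(rng.beta(a, b))
                n_resampled += 1
            updates[key] = draw
    return updates, n_resampled


def run_psa(
    params: ModelParameters,
    n_iterations: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | list[float] | None = None,
) -> PSAResult:
    """Joint Monte-Carlo over all uncertain parameters.

    One value is drawn per physical parameter per iteration and shared
    across both arms, so each iteration compares the arms under the same
    economic environment; arm-specific survival medians are separate
    physical parameters and are drawn independently. Survival-median
    draws propagate into the transition probabilities. Reproducible
    given the seed.
    """
    if n_iterations <= 0:
        raise ValueError("n_iterations must be > 0")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 10_500_000.0, 500_000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.ndim != 1 or len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be a non-empty 1-D sequence")

    rng = np.random.default_rng(seed)
    wtp = params.settings.wtp
    d_cost = np.empty(n_iterations)
    d_qaly = np.empty(n_iterations)
    n_resampled = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PFS draws may exceed OS draws
        for i in range(n_iterations):
            updates, resampled = _draw_parameters(params, rng)
            n_resampled += resampled
            p = params.replace(**updates)
            tare, deb = run_arms(p)
            d_cost[i] = tare.total_cost - deb.total_cost
            d_qaly[i] = tare.total_qaly - deb.total_qaly

    draws = pd.DataFrame({"iteration": np.arange(n_iterations),
                          "delta_cost": d_cost, "delta_qaly": d_qaly})
    prob = [(lam * d_qaly - d_cost > 0).mean() for lam in wtp_grid]
    ceac = pd.DataFrame({"wtp": wtp_grid, "prob_tare_cost_effective": prob})
    return PSAResult(n_iterations=n_iterations, seed=seed, wtp=wtp,
                     draws=draws, ceac=ceac, n_resampled=n_resampled)
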