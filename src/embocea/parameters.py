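"""Model inputs: costs, utilities, survival medians, cycle settings.

All monetary amounts are Japanese yen (JPY); survival medians are months;
annual rates and utilities are fractions. Parameters are grouped into five
frozen dataclasses and composed into :class:`ModelParameters`, which is the
single object the transition builder, cohort engine, and sensitivity
analyses consume.

Configuration files are flat YAML/JSON key-value documents with a
``schema_version`` field; any key not listed in :data:`DEFAULTS` is
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "SurvivalInputs",
    "ClinicalRates",
    "CostInputs",
    "UtilityInputs",
    "ModelSettings",
    "ModelParameters",
    "ParameterError",
    "DEFAULTS",
    "load_parameters",
    "save_parameters",
    "jpy_to_usd",
    "gbp_to_jpy",
    "derive_u_eligible",
]

SCHEMA_VERSION = 1

#: Valid session-accounting policies (see the markov engine).
SESSION_POLICIES = ("per_cycle_while_eligible", "on_entry")

#: When the contrast-CT fee accrues: at treatment admissions, at every
#: local/eligible cycle, only at non-treatment follow-up cycles, or never.
CT_SCHEDULES = ("treatment", "every_cycle", "follow_up", "none")


class ParameterError(ValueError):
    """Raised when a configuration fails validation; names the offending key."""


@dataclass(frozen=True)
class SurvivalInputs:
    """Median time-to-event inputs (months) from the source trial.

    ``median_os_systemic`` is the overall survival under first-line
    atezolizumab + bevacizumab, used for the TAE-refractory state.
    The intention-to-treat and per-protocol populations differ only in
    ``median_pfs_tare`` (11.83 vs 12.83 months).
    """

    median_os_tare: float = 30.2
    median_os_deb: float = 15.6
    median_pfs_tare: float = 11.83
    median_pfs_deb: float = 9.10
    median_os_systemic: float = 19.2
    population: str = "itt"

    def __post_init__(self) -> None:
        for name in ("median_os_tare", "median_os_deb", "median_pfs_tare",
                     "median_pfs_deb", "median_os_systemic"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.population not in ("itt", "pp"):
            raise ParameterError("population must be 'itt' or 'pp'")
        for arm in ("tare", "deb"):
            pfs, os_ = getattr(self, f"median_pfs_{arm}"), getattr(self, f"median_os_{arm}")
            if pfs > os_:
                warnings.warn(
                    f"median_pfs_{arm} ({pfs}) exceeds median_os_{arm} ({os_}); "
                    "the progression hazard will be clamped to zero",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class ClinicalRates:
    """Annual event probabilities (fractions per year)."""

    annual_decomp_tae_eligible: float = 0.118
    annual_decomp_systemic: float = 0.534
    annual_survival_decomp: float = 0.25

    def __post_init__(self) -> None:
        for name in dataclasses.asdict(self):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class CostInputs:
    """Cost inputs in JPY.

    ``deb_admission`` and ``tare_admission_other`` are per-admission
    totals; ``microsphere_price`` is the per-session reimbursement price
    of the yttrium-90 microspheres; ``pre_angio`` and ``scinti`` are
    one-time work-up fees added to the first TARE session only; monthly
    costs are multiplied by the cycle length when accrued.
    """

    deb_admission: float = 845_320.0
    microsphere_price: float = 1_440_000.0
    tare_admission_other: float = 734_896.0
    outpatient_monthly: float = 98_455.0
    systemic_monthly: float = 1_242_800.0
    decomp_monthly: float = 247_690.0
    pre_angio: float = 36_000.0
    scinti: float = 22_215.0
    ct_followup: float = 30_000.0

    def __post_init__(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class UtilityInputs:
    """Quality-of-life weights per year of state occupancy, in [0, 1].

    ``u_eligible`` defaults to the mean of the local and refractory
    utilities (see :func:`derive_u_eligible`).
    """

    u_local: float = 0.788
    u_eligible: float = 0.768
    u_refractory: float = 0.748
    u_decomp: float = 0.524
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        for name in dataclasses.asdict(self):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.u_dead != 0.0:
            raise ParameterError("u_dead must be 0")


@dataclass(frozen=True)
class ModelSettings:
    """Cycle structure, discounting, decision threshold, and engine toggles."""

    cycle_months: float = 2.0
    total_cycles: int = 30
    discount_annual: float = 0.02
    wtp: float = 5_000_000.0
    max_sessions_deb: int = 6
    max_sessions_tare: int = 2
    jpy_per_usd: float = 160.0
    jpy_per_gbp: float = 180.0
    half_cycle_correction: bool = False
    session_policy: str = "per_cycle_while_eligible"
    outpatient_in_treatment_cycles: bool = True
    ct_schedule: str = "treatment"

    def __post_init__(self) -> None:
        if self.cycle_months <= 0:
            raise ParameterError("cycle_months must be > 0")
        if self.total_cycles < 0:
            raise ParameterError("total_cycles must be >= 0")
        if self.discount_annual < 0:
            raise ParameterError("discount_annual must be >= 0")
        if self.wtp < 0:
            raise ParameterError("wtp must be >= 0")
        if self.max_sessions_deb < 1 or self.max_sessions_tare < 1:
            raise ParameterError("session caps must be >= 1")
        if self.jpy_per_usd <= 0 or self.jpy_per_gbp <= 0:
            raise ParameterError("exchange rates must be > 0")
        if self.session_policy not in SESSION_POLICIES:
            raise ParameterError(
                f"session_policy must be one of {SESSION_POLICIES}")
        if self.ct_schedule not in CT_SCHEDULES:
            raise ParameterError(f"ct_schedule must be one of {CT_SCHEDULES}")


@dataclass(frozen=True)
class ModelParameters:
    """Immutable composite of all model inputs."""

    survival: SurvivalInputs = field(default_factory=SurvivalInputs)
    rates: ClinicalRates = field(default_factory=ClinicalRates)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    settings: ModelSettings = field(default_factory=ModelSettings)

    def replace(self, **flat_updates: Any) -> "ModelParameters":
        """Return a copy with flat keys (e.g. ``u_local=0.7``) replaced."""
        groups: dict[str, dict[str, Any]] = {}
        for key, value in flat_updates.items():
            group = _KEY_TO_GROUP.get(key)
            if group is None:
                raise ParameterError(f"unknown parameter: {key}")
            groups.setdefault(group, {})[key] = value
        kwargs = {}
        for group, upd in groups.items():
            kwargs[group] = dataclasses.replace(getattr(self, group), **upd)
        return dataclasses.replace(self, **kwargs)

    def get(self, key: str) -> Any:
        """Look up a parameter by its flat name."""
        group = _KEY_TO_GROUP.get(key)
        if group is None:
            raise ParameterError(f"unknown parameter: {key}")
        return getattr(getattr(self, group), key)

    def to_flat_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
        for group in ("survival", "rates", "costs", "utilities", "settings"):
            out.update(dataclasses.asdict(getattr(self, group)))
        return out

    def session_cap(self, arm: str) -> int:
        arm = _normalize_arm(arm)
        return (self.settings.max_sessions_tare if arm == "tare"
                else self.settings.max_sessions_deb)


def _normalize_arm(arm: str) -> str:
    a = arm.lower().replace("-", "_")
    if a in ("tare",):
        return "tare"
    if a in ("deb", "deb_tace", "debtace"):
        return "deb"
    raise ValueError(f"unknown arm: {arm!r}")


_GROUP_FIELDS = {
    "survival": [f.name for f in dataclasses.fields(SurvivalInputs)],
    "rates": [f.name for f in dataclasses.fields(ClinicalRates)],
    "costs": [f.name for f in dataclasses.fields(CostInputs)],
    "utilities": [f.name for f in dataclasses.fields(UtilityInputs)],
    "settings": [f.name for f in dataclasses.fields(ModelSettings)],
}
_KEY_TO_GROUP = {k: g for g, keys in _GROUP_FIELDS.items() for k in keys}

#: Flat default parameter dictionary (the base-case inputs of the model).
DEFAULTS: dict[str, Any] = ModelParameters().to_flat_dict()


def load_parameters(config: str | Mapping[str, Any] | None = None) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a flat config.

    ``config`` may be YAML/JSON text, an already-parsed mapping, or None
    (pure defaults). Unknown keys raise :class:`ParameterError`; missing
    keys are filled from the defaults.
    """
    if config is None:
        data: dict[str, Any] = {}
    elif isinstance(config, Mapping):
        data = dict(config)
    else:
        try:
            parsed = yaml.safe_load(io.StringIO(config))
        except yaml.YAMLError as exc:
            raise ParameterError(f"could not parse configuration: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ParameterError("configuration must be a mapping")
        data = parsed

    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ParameterError(f"unsupported schema_version: {version}")

    unknown = sorted(set(data) - set(_KEY_TO_GROUP))
    if unknown:
        raise ParameterError(f"unknown configuration keys: {', '.join(unknown)}")

    kwargs = {}
    for group, keys in _GROUP_FIELDS.items():
        overrides = {k: data[k] for k in keys if k in data}
        cls = type(getattr(ModelParameters(), group))
        try:
            kwargs[group] = cls(**overrides)
        except ParameterError:
            raise
        except (TypeError, ValueError) as exc:
            raise ParameterError(str(exc)) from exc
    return ModelParameters(**kwargs)


def save_parameters(params: ModelParameters) -> str:
    """Serialize to flat YAML; ``load_parameters`` round-trips the result."""
    return yaml.safe_dump(params.to_flat_dict(), sort_keys=True)


def jpy_to_usd(amount_jpy: float, params: ModelParameters | None = None) -> float:
    """Convert JPY to USD at the fixed model exchange rate (display only)."""
    if amount_jpy < 0:
        raise ValueError("amount must be >= 0")
    rate = (params or _DEFAULT_PARAMS).settings.jpy_per_usd
    return amount_jpy / rate


def gbp_to_jpy(amount_gbp: float, params: ModelParameters | None = None) -> float:
    """Convert GBP to JPY at the fixed model exchange rate."""
    if amount_gbp < 0:
        raise ValueError("amount must be >= 0")
    rate = (params or _DEFAULT_PARAMS).settings.jpy_per_gbp
    return amount_gbp * rate


def derive_u_eligible(u_local: float, u_refractory: float) -> float:
    """TAE-eligible progressive utility: mean of the local and refractory weights."""
    for name, v in (("u_local", u_local), ("u_refractory", u_refractory)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    return (u_local + u_refractory) / 2.0


_DEFAULT_PARAMS = ModelParameters()
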