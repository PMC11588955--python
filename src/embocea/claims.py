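"""Synthetic inpatient-claims records and the treatment-cost arithmetic.

The DEB-TACE admission cost in the model is built from nationwide
Japanese inpatient claims (DPC-style admission records): admissions are
selected by procedure/diagnosis criteria, split by whether a severe
hepatobiliary complication required an interventional procedure, and the
weighted mean over both strata becomes the per-admission cost. The same
aggregation yields the expected complication add-on that is carried into
the TARE cost build-up.

Because the real claims database cannot be redistributed, this module
also generates synthetic admission cohorts with the published stratum
means and complication prevalence so that the selection and aggregation
logic can be exercised end-to-end.

The canonical in-memory container is a pandas DataFrame with one row per
admission (see :data:`CLAIMS_COLUMNS`); ``procedure_codes`` holds a
semicolon-joined code list in CSV form. Individual records can also be
handled as :class:`ClaimRecord` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClaimRecord",
    "CohortCostSummary",
    "SELECT_PROCEDURE_CODE",
    "SELECT_ICD10",
    "COMPLICATION_CODES",
    "CLAIMS_COLUMNS",
    "select_debtace_admissions",
    "flag_severe_complication",
    "summarize_costs",
    "build_tare_cost",
    "generate_synthetic_claims",
    "claims_to_frame",
    "frame_to_claims",
    "read_claims_csv",
    "write_claims_csv",
]

#: Procedure claiming code for selective TACE.
SELECT_PROCEDURE_CODE = "K615_2"
#: ICD-10 code for hepatocellular carcinoma as the major disease.
SELECT_ICD10 = "C220"
#: Claim codes marking a severe hepatobiliary complication requiring an
#: interventional procedure (drainage, stenting, or abscess surgery).
COMPLICATION_CODES = frozenset({
    "J010-2",          # percutaneous gallbladder / liver abscess drainage
    "K682", "K696", "K697",  # surgical biliary drainage
    "K682-2",          # percutaneous transhepatic biliary drainage
    "K682-3",          # endoscopic biliary drainage
    "K688",            # endoscopic biliary stent
    "K689",            # percutaneous transhepatic biliary stent
    "K691",            # surgical liver abscess drainage
    "K691-2",          # percutaneous liver abscess drainage
    "K694",            # surgical liver abscess resection
})

CLAIMS_COLUMNS = [
    "admission_id", "major_icd10", "procedure_codes",
    "deb_claimed", "lipiodol_claimed", "total_cost", "age", "sex",
]


@dataclass(frozen=True)
class ClaimRecord:
    """One admission record (codes are uppercase-normalized)."""

    admission_id: str
    major_icd10: str
    procedure_codes: frozenset[str]
    deb_claimed: bool
    lipiodol_claimed: bool
    total_cost: float
    age: float = float("nan")
    sex: str = ""

    def __post_init__(self) -> None:
        if self.total_cost < 0:
            raise ValueError("total_cost must be >= 0")
        object.__setattr__(self, "major_icd10", self.major_icd10.upper())
        object.__setattr__(
            self, "procedure_codes",
            frozenset(c.upper() for c in self.procedure_codes))


def _as_frame(records: pd.DataFrame | Iterable[ClaimRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return claims_to_frame(records)


def claims_to_frame(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    rows = [{
        "admission_id": r.admission_id,
        "major_icd10": r.major_icd10,
        "procedure_codes": ";".join(sorted(r.procedure_codes)),
        "deb_claimed": r.deb_claimed,
        "lipiodol_claimed": r.lipiodol_claimed,
        "total_cost": r.total_cost,
        "age": r.age,
        "sex": r.sex,
    } for r in records]
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def frame_to_claims(frame: pd.DataFrame) -> list[ClaimRecord]:
    out = []
    for row in frame.itertuples(index=False):
        codes = frozenset(str(row.procedure_codes).split(";")) \
            if row.procedure_codes else frozenset()
        out.append(ClaimRecord(
            admission_id=str(row.admission_id),
            major_icd10=str(row.major_icd10),
            procedure_codes=codes,
            deb_claimed=bool(row.deb_claimed),
            lipiodol_claimed=bool(row.lipiodol_claimed),
            total_cost=float(row.total_cost),
            age=float(row.age),
            sex=str(row.sex),
        ))
    return out


def _codes_series(frame: pd.DataFrame) -> pd.Series:
    return frame["procedure_codes"].fillna("").str.upper().str.split(";")


def select_debtace_admissions(
    records: pd.DataFrame | Sequence[ClaimRecord],
) -> pd.DataFrame | list[ClaimRecord]:
    """Apply the four DEB-TACE selection criteria, preserving order.

    Kept records claim selective TACE (K615_2), carry hepatocellular
    carcinoma (C220) as the major diagnosis, claim drug-eluting beads,
    and do not claim lipiodol (which would mark conventional TACE).
    """
    if isinstance(records, pd.DataFrame):
        if len(records) == 0:
            return records.copy()
        codes = _codes_series(records)
        keep = (
            codes.apply(lambda cs: SELECT_PROCEDURE_CODE in cs)
            & (records["major_icd10"].str.upper() == SELECT_ICD10)
            & records["deb_claimed"].astype(bool)
            & ~records["lipiodol_claimed"].astype(bool)
        )
        return records.loc[keep].copy()
    return [r for r in records
            if SELECT_PROCEDURE_CODE in r.procedure_codes
            and r.major_icd10 == SELECT_ICD10
            and r.deb_claimed and not r.lipiodol_claimed]


def flag_severe_complication(record: ClaimRecord | Iterable[str]) -> bool:
    """True if any severe-hepatobiliary-complication procedure was claimed."""
    codes = record.procedure_codes if isinstance(record, ClaimRecord) else record
    return bool(COMPLICATION_CODES & {c.upper() for c in codes})


@dataclass(frozen=True)
class CohortCostSummary:
    """Stratified and weighted admission-cost summary of a selected cohort."""

    n_total: int
    n_complication: int
    mean_cost_no_comp: float
    mean_cost_comp: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if not 0 <= self.n_complication <= self.n_total:
            raise ValueError("n_complication must be in [0, n_total]")

    @property
    def complication_rate(self) -> float:
        return self.n_complication / self.n_total

    @property
    def expected_complication_cost(self) -> float:
        """Expected add-on per admission from rare severe complications."""
        if self.n_complication == 0:
            return 0.0
        return self.complication_rate * (self.mean_cost_comp - self.mean_cost_no_comp)

    @property
    def weighted_mean_cost(self) -> float:
        """Prevalence-weighted mean admission cost (= mean over all records)."""
        return self.mean_cost_no_comp + self.expected_complication_cost


def summarize_costs(
    records: pd.DataFrame | Sequence[ClaimRecord],
) -> CohortCostSummary:
    """Stratify selected admissions by complication status and average costs."""
    frame = _as_frame(records)
    if len(frame) == 0:
        raise ValueError("no records to summarize")
    comp = _codes_series(frame).apply(
        lambda cs: bool(COMPLICATION_CODES & set(cs)))
    n_total = int(len(frame))
    n_comp = int(comp.sum())
    if n_comp == n_total:
        raise ValueError("all records have complications; "
                         "the uncomplicated stratum mean is undefined")
    mean_no = float(frame.loc[~comp, "total_cost"].mean())
    mean_yes = float(frame.loc[comp, "total_cost"].mean()) if n_comp else float("nan")
    return CohortCostSummary(n_total, n_comp, mean_no, mean_yes)


def build_tare_cost(
    expected_complication_cost: float,
    procedure_fee: float = 200_400.0,
    devices: float = 71_800.0,
    per_diem: float = 456_599.0,
    microsphere_price: float = 1_440_000.0,
) -> tuple[float, float]:
    """TARE admission cost build-up from shared DEB-TACE components.

    Returns ``(admission_other, admission_total)``: the per-admission
    cost excluding the radioactive microspheres, and the total including
    them. The procedure fee, reimbursable devices, and per-diem payment
    are assumed identical to DEB-TACE; the complication add-on comes
    from the claims summary.
    """
    components = (expected_complication_cost, procedure_fee, devices,
                  per_diem, microsphere_price)
    if any(c < 0 for c in components):
        raise ValueError("cost components must be >= 0")
    admission_other = procedure_fee + devices + per_diem + expected_complication_cost
    return admission_other, admission_other + microsphere_price


def generate_synthetic_claims(
    n: int,
    complication_prob: float = 25 / 6986,
    cost_means: tuple[float, float] = (839_223.0, 2_543_046.0),
    cost_cv: float = 0.5,
    contaminant_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate a synthetic DPC-style admission cohort.

    Admission costs are gamma-distributed within each complication
    stratum with the given means and coefficient of variation; a severe
    complication adds one randomly chosen procedure code from
    :data:`COMPLICATION_CODES`. ``contaminant_fraction`` of records
    violate exactly one selection criterion (lipiodol claimed, wrong
    ICD-10, or missing the selective-TACE code) to exercise the filter.
    Age and sex mimic the described cohort (74.86 +/- 9.67 years;
    5,196 of 6,986 male) and are unused downstream. Reproducible given
    the seed.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    for name, v in (("complication_prob", complication_prob),
                    ("contaminant_fraction", contaminant_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if cost_cv <= 0:
        raise ValueError("cost_cv must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    comp = rng.random(n) < complication_prob
    # gamma with shape 1/cv^2 and scale mean*cv^2 has the requested moments
    shape = 1.0 / cost_cv ** 2
    means = np.where(comp, cost_means[1], cost_means[0])
    costs = rng.gamma(shape, means * cost_cv ** 2, size=n)

    comp_codes = np.array(sorted(COMPLICATION_CODES))
    extra = rng.integers(0, len(comp_codes), size=n)

    contaminated = rng.random(n) < contaminant_fraction
    cont_kind = rng.integers(0, 3, size=n)  # 0 lipiodol, 1 wrong ICD, 2 no K615_2

    codes = []
    icd = np.full(n, SELECT_ICD10, dtype=object)
    lipiodol = np.zeros(n, dtype=bool)
    for i in range(n):
        cs = {SELECT_PROCEDURE_CODE}
        if comp[i]:
            cs.add(comp_codes[extra[i]])
        if contaminated[i]:
            k = cont_kind[i]
            if k == 0:
                lipiodol[i] = True
            elif k == 1:
                icd[i] = "C221"  # intrahepatic cholangiocarcinoma
            else:
                cs.discard(SELECT_PROCEDURE_CODE)
        codes.append(";".join(sorted(cs)))

    age = rng.normal(74.86, 9.67, size=n)
    sex = np.where(rng.random(n) < 5196 / 6986, "M", "F")

    return pd.DataFrame({
        "admission_id": [f"A{i:07d}" for i in range(n)],
        "major_icd10": icd,
        "procedure_codes": codes,
        "deb_claimed": True,
        "lipiodol_claimed": lipiodol,
        "total_cost": costs,
        "age": age,
        "sex": sex,
    }, columns=CLAIMS_COLUMNS)


def write_claims_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_claims_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"admission_id": str, "major_icd10": str,
                                     "procedure_codes": str})
    frame["procedure_codes"] = frame["procedure_codes"].fillna("")
    return frame[CLAIMS_COLUMNS]
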