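"""New-user cohort selection: index events, enrollment, exclusions, covariates.

Implements the patient-selection funnel of a new-user, active-comparator
design: the index event is the first fill of either index drug inside the
index window; patients need continuous pharmacy-benefit enrollment for the
12 months before and 18 months after index, must be adults, must carry no
diagnosis incompatible with type 2 diabetes (type 1, gestational diabetes,
chronic kidney disease, Cushing syndrome, acromegaly, bariatric surgery),
fewer than two systemic glucocorticoid fills, and no pre-index fill of
pramlintide, sitagliptin, exenatide, or any insulin (the washout that makes
them new users).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from rxpatterns import drugs
from rxpatterns.config import ClassifyParams


class AmbiguousIndexError(ValueError):
    """Both index drugs first filled on the same day: the design cannot
    assign an arm, and the convention is to refuse rather than guess."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass(frozen=True)
class IndexEvent:
    patient_id: int
    index_day: int
    index_drug: str


@dataclass
class EligibilityResult:
    patient_id: int
    failed_rules: list[str] = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return not self.failed_rules


REQUIRED_COLUMNS = {
    "patients": ["patient_id", "birth_year", "sex", "region", "plan_type"],
    "enrollment": ["patient_id", "start_day", "end_day", "rx_benefit"],
    "pharmacy": ["patient_id", "fill_day", "drug_class", "days_supply"],
    "medical": ["patient_id", "service_day", "flag_type", "setting", "cost"],
}

DX_EXCLUSION_FLAGS = (
    "dx_type1",
    "dx_gestational",
    "dx_ckd",
    "dx_cushing",
    "dx_acromegaly",
    "dx_gastric_surgery",
)


def _check_schema(name: str, df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(f"{name} table is missing required column '{col}'")


# ---------------------------------------------------------------------------
# Index event
# ---------------------------------------------------------------------------


def find_index_event(
    pharmacy: pd.DataFrame, index_window: tuple[int, int], patient_id: Optional[int] = None
) -> Optional[IndexEvent]:
    """Earliest in-window fill of either index drug for one patient.

    Raises :class:`AmbiguousIndexError` when the earliest day carries a fill
    of each index drug.
    """
    fills = pharmacy[
        pharmacy["drug_class"].isin(drugs.INDEX_DRUGS)
        & (pharmacy["fill_day"] >= index_window[0])
        & (pharmacy["fill_day"] <= index_window[1])
    ]
    if fills.empty:
        return None
    first_day = int(fills["fill_day"].min())
    on_day = set(fills.loc[fills["fill_day"] == first_day, "drug_class"])
    if len(on_day) > 1:
        raise AmbiguousIndexError(
            f"patient {patient_id}: both index drugs first filled on day {first_day}"
        )
    if patient_id is None:
        patient_id = int(fills["patient_id"].iloc[0])
    return IndexEvent(patient_id, first_day, on_day.pop())


# ---------------------------------------------------------------------------
# Enrollment
# ---------------------------------------------------------------------------


def check_continuous_enrollment(
    enrollment: pd.DataFrame,
    index_day: int,
    pre_days: int = 365,
    post_days: int = 545,
) -> bool:
    """True iff [index - pre, index + post] is continuously covered.

    Coverage requires pharmacy benefit throughout (periods are inclusive
    [start_day, end_day]; adjacent periods merge) and, when a ``database``
    column is present, no commercial-to-Medicare transition inside the
    study interval.
    """
    lo, hi = index_day - pre_days, index_day + post_days
    periods = enrollment.sort_values("start_day")
    covering = periods[
        (periods["end_day"] >= lo) & (periods["start_day"] <= hi)
    ]
    useful = covering[covering["rx_benefit"].astype(bool)]
    if useful.empty:
        return False
    # all overlapping periods must carry the benefit, and must tile the window
    if len(useful) != len(covering):
        return False
    day = lo
    for row in useful.itertuples():
        if row.start_day > day:
            return False
        day = max(day, row.end_day + 1)
    if day <= hi:
        return False
    if "database" in enrollment.columns and covering["database"].nunique() > 1:
        return False
    return True


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------


def apply_exclusions(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    index_day: int,
    age_at_index: Optional[int] = None,
    params: Optional[ClassifyParams] = None,
) -> EligibilityResult:
    """Evaluate every exclusion rule for one patient (order-independent).

    Rules: (a) any study-incompatible diagnosis flag inside the study
    window; (b) >= 2 glucocorticoid fills in the pre-index window; (c) any
    pre-index fill of a washout drug (pramlintide, sitagliptin, exenatide,
    or any insulin); (d) age under 18 at index.
    """
    params = params or ClassifyParams()
    pid = int(medical["patient_id"].iloc[0]) if len(medical) else (
        int(pharmacy["patient_id"].iloc[0]) if len(pharmacy) else -1
    )
    lo, hi = index_day - params.pre_index_days, index_day + params.follow_up_days
    failed: list[str] = []

    window_dx = medical[
        (medical["service_day"] >= lo) & (medical["service_day"] <= hi)
    ]
    for flag in DX_EXCLUSION_FLAGS:
        if (window_dx["flag_type"] == flag).any():
            failed.append(flag)

    pre_rx = pharmacy[
        (pharmacy["fill_day"] >= lo) & (pharmacy["fill_day"] < index_day)
    ]
    n_gc = int((pre_rx["drug_class"] == drugs.GLUCOCORTICOID).sum())
    if n_gc >= 2:
        failed.append("glucocorticoid_ge2")
    washout = sorted(set(pre_rx["drug_class"]) & drugs.WASHOUT_CLASSES)
    if washout:
        failed.append("pre_index_washout_drug:" + ",".join(washout))
    if age_at_index is not None and age_at_index < 18:
        failed.append("age_under_18")
    return EligibilityResult(pid, sorted(failed))


# ---------------------------------------------------------------------------
# Covariates and cohort assembly
# ---------------------------------------------------------------------------


def build_cohort(
    patients: pd.DataFrame,
    enrollment: pd.DataFrame,
    pharmacy: pd.DataFrame,
    medical: pd.DataFrame,
    index_window: tuple[int, int],
    params: Optional[ClassifyParams] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select the study cohort.

    Returns ``(cohort, exclusions)``: one covariate row per eligible patient,
    and one row per patient with an index event who failed a rule (with all
    failed rules listed).  Patients without an in-window index fill appear in
    neither.
    """
    params = params or ClassifyParams()
    _check_schema("patients", patients)
    _check_schema("enrollment", enrollment)
    _check_schema("pharmacy", pharmacy)
    _check_schema("medical", medical)

    def _blocks(df: pd.DataFrame, cols: list[str]) -> dict:
        pid = df["patient_id"].to_numpy()
        order = np.argsort(pid, kind="mergesort")
        sorted_pid = pid[order]
        arrays = {c: df[c].to_numpy()[order] for c in cols}
        uniq, starts = np.unique(sorted_pid, return_index=True)
        ends = np.searchsorted(sorted_pid, uniq, side="right")
        return {
            p: {c: a[s:e] for c, a in arrays.items()}
            for p, s, e in zip(uniq, starts, ends)
        }

    rx_blocks = _blocks(pharmacy, ["fill_day", "drug_class"])
    med_blocks = _blocks(medical, ["service_day", "flag_type", "setting", "cost"])
    enr_by_pid = dict(tuple(enrollment.groupby("patient_id")))
    empty = {c: np.array([]) for c in ("fill_day", "drug_class")}
    empty_med = {c: np.array([]) for c in ("service_day", "flag_type", "setting", "cost")}
    glucose = frozenset(drugs.GLUCOSE_LOWERING_CLASSES)
    washout = drugs.WASHOUT_CLASSES

    cohort_rows: list[dict] = []
    excl_rows: list[dict] = []
    for prow in patients.itertuples():
        pid = prow.patient_id
        rx = rx_blocks.get(pid, empty)
        day, cls = rx["fill_day"], rx["drug_class"]
        in_window = (
            (day >= index_window[0])
            & (day <= index_window[1])
            & np.isin(cls, list(drugs.INDEX_DRUGS))
        )
        if not in_window.any():
            continue
        index_day = int(day[in_window].min())
        on_day = set(cls[in_window & (day == index_day)])
        if len(on_day) > 1:
            raise AmbiguousIndexError(
                f"patient {pid}: both index drugs first filled on day {index_day}"
            )
        index_drug = on_day.pop()
        med = med_blocks.get(pid, empty_med)
        enr = enr_by_pid.get(pid)

        lo = index_day - params.pre_index_days
        hi = index_day + params.follow_up_days
        failed: list[str] = []
        if enr is None or not check_continuous_enrollment(
            enr, index_day, params.pre_index_days, params.follow_up_days
        ):
            failed.append("enrollment")
        dx_window = (med["service_day"] >= lo) & (med["service_day"] <= hi)
        for flag in DX_EXCLUSION_FLAGS:
            if ((med["flag_type"] == flag) & dx_window).any():
                failed.append(flag)
        pre_rx = (day >= lo) & (day < index_day)
        if (pre_rx & (cls == drugs.GLUCOCORTICOID)).sum() >= 2:
            failed.append("glucocorticoid_ge2")
        washout_hit = sorted(set(cls[pre_rx]) & washout)
        if washout_hit:
            failed.append("pre_index_washout_drug:" + ",".join(washout_hit))
        age = int(index_day // 365 - prow.birth_year)
        if age < 18:
            failed.append("age_under_18")

        if failed:
            excl_rows.append(
                {"patient_id": pid, "index_day": index_day,
                 "index_drug": index_drug, "failed_rules": ";".join(sorted(failed))}
            )
            continue

        pre_med = (med["service_day"] >= lo) & (med["service_day"] < index_day)
        spec = med["setting"][pre_med & (med["flag_type"] == "provider_specialty")]
        classes = set(cls[pre_rx])
        cov = {
            "patient_id": pid,
            "arm": index_drug,
            "index_day": index_day,
            "age": age,
            "sex_female": int(prow.sex == "F"),
            "region": prow.region,
            "plan_type": prow.plan_type,
            "specialty": spec[0] if len(spec) else "unknown",
            "microvascular": int((pre_med & (med["flag_type"] == "dx_microvascular")).any()),
            "macrovascular": int((pre_med & (med["flag_type"] == "dx_macrovascular")).any()),
            "cci": int((pre_med & (med["flag_type"] == "cci_point")).sum()),
            "med_claims": int(pre_rx.sum()),
            "med_classes": int(len(classes)),
            "inpatient_admission": int((pre_med & (med["setting"] == "inpatient")).any()),
            "pre_index_cost": float(med["cost"][pre_med].sum()),
        }
        from rxpatterns.synthetic import PRE_CLASS_P  # canonical covariate classes

        for c in PRE_CLASS_P:
            cov[f"pre_{c}"] = int(c in classes)
        cohort_rows.append(cov)

    cohort = pd.DataFrame(cohort_rows)
    exclusions = pd.DataFrame(
        excl_rows, columns=["patient_id", "index_day", "index_drug", "failed_rules"]
    )
    return cohort, exclusions
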