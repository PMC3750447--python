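"""First-treatment-modification classification from pharmacy claims.

This is the analytical core of the package: given a patient's index-drug
refill history and their other glucose-lowering fills, determine the first
modification of the index therapy within the 18-month follow-up horizon —
**discontinuation** (a 90-day gap after a run-out with no other
glucose-lowering fill in the gap), **switching** (a non-index
glucose-lowering fill in such a gap, itself refilled within 90 days), or
**intensification** (addition of a glucose-lowering class not used
pre-index, overlapping the index supply, with both drugs subsequently
refilled; for the basal-insulin arm, alternatively a >=100% claim-to-claim
increase in the estimated daily dose) — or administrative censoring at the
horizon.

Conventions (documented in the methods note):

* Run-out of a claim is ``fill_day + days_supply``; overlapping early refills
  do **not** stack supply (each claim's run-out is computed from its own
  fill day).
* Same-day fills of the same drug are merged (units summed, longest supply
  kept) before the rules run.
* The discontinuation event day is the run-out that opens the gap, so
  time-to-modification equals time on therapy.
* A gap whose 90-day confirmation window extends past the horizon is not
  evaluable and the patient is censored instead (no right-edge bias).
* "Refilled" means a later fill occurring no later than 90 days after the
  relevant run-out (early refills count).
* On equal event days, intensification > switching > discontinuation
  (an intensification implies continued index use, the most specific
  evidence of what happened).

All detectors work in days since index; the cohort driver
(:func:`classify_cohort`) handles the shift from absolute claim days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from rxpatterns import drugs
from rxpatterns.config import ClassifyParams

MOD_PRIORITY = {"intensification": 0, "switch": 1, "discontinuation": 2}
MOD_TYPES = ("discontinuation", "switch", "intensification")


@dataclass(frozen=True)
class Candidate:
    """A potential first-modification event proposed by one detector."""

    mod_type: str
    event_day: int
    detail: Optional[str] = None

    def sort_key(self) -> tuple[int, int]:
        return (self.event_day, MOD_PRIORITY[self.mod_type])


@dataclass
class ModificationEvent:
    """The resolved first modification (or censoring) for one patient."""

    patient_id: int
    mod_type: str  # discontinuation | switch | intensification | censored
    event_day: int  # absolute day
    days_to_event: int  # event_day - index_day
    detail: Optional[str] = None
    audit_flag: Optional[str] = None


# ---------------------------------------------------------------------------
# Array-level rule engine (single source of truth for the definitions)
# ---------------------------------------------------------------------------


def _merge_fills(
    day: np.ndarray, cls: np.ndarray, supply: np.ndarray, units: np.ndarray
) -> list[tuple[int, str, int, float]]:
    """Merge same-day same-class fills; returns (day, class, supply, units)
    sorted by (day, class), units summed, longest supply kept."""
    merged: dict[tuple[int, str], list] = {}
    for d, c, s, u in zip(day, cls, supply, units):
        key = (int(d), c)
        if key in merged:
            rec = merged[key]
            rec[0] = max(rec[0], int(s))
            rec[1] += 0.0 if math.isnan(u) else float(u)
        else:
            merged[key] = [int(s), 0.0 if math.isnan(u) else float(u)]
    return [(d, c, rec[0], rec[1]) for (d, c), rec in sorted(merged.items())]


def _gap_runouts(
    timeline: Sequence[tuple[int, int]], index_days: np.ndarray, gap: int
) -> list[int]:
    """Run-outs that open a >gap-day hole in index therapy.

    A claim (f, R) opens a gap when no index fill occurs in (f, R + gap]: a
    fill inside (f, R] is an early refill, inside (R, R + gap] a timely
    one — either closes the gap.
    """
    out = []
    for f, r in timeline:
        lo = np.searchsorted(index_days, f, side="right")
        hi = np.searchsorted(index_days, r + gap, side="right")
        if hi == lo:
            out.append(r)
    return out


def _first_disc(
    timeline: Sequence[tuple[int, int]],
    index_days: np.ndarray,
    other_days: np.ndarray,
    params: ClassifyParams,
) -> Optional[int]:
    for r in _gap_runouts(timeline, index_days, params.gap_days):
        if r + params.gap_days > params.follow_up_days:
            continue
        lo = np.searchsorted(other_days, r, side="right")
        hi = np.searchsorted(other_days, r + params.gap_days, side="right")
        if hi == lo:
            return r
    return None


def _first_switch(
    timeline: Sequence[tuple[int, int]],
    index_days: np.ndarray,
    class_days: dict[str, np.ndarray],
    params: ClassifyParams,
) -> Optional[tuple[int, str]]:
    gap = params.gap_days
    for r in _gap_runouts(timeline, index_days, gap):
        best: Optional[tuple[int, str]] = None
        for c in sorted(class_days):
            days = class_days[c]
            lo = np.searchsorted(days, r, side="right")
            hi = np.searchsorted(days, r + gap, side="right")
            if hi == lo:
                continue
            first = int(days[lo])
            if first > params.follow_up_days:
                continue
            lo2 = np.searchsorted(days, first, side="right")
            hi2 = np.searchsorted(days, first + gap, side="right")
            if hi2 > lo2 and (best is None or (first, c) < best):
                best = (first, c)
        if best is not None:
            return best
    return None


def _first_intens(
    timeline: Sequence[tuple[int, int]],
    index_days: np.ndarray,
    non_fills: Sequence[tuple[int, str, int]],
    class_days: dict[str, np.ndarray],
    pre_classes: set[str],
    params: ClassifyParams,
) -> Optional[tuple[int, str]]:
    gap = params.gap_days
    for a, c, s in non_fills:  # sorted by (day, class)
        if c in pre_classes or s <= 0 or a > params.follow_up_days:
            continue
        ra = a + s
        days = class_days[c]
        lo = np.searchsorted(days, a, side="right")
        hi = np.searchsorted(days, ra + gap, side="right")
        if hi == lo:  # the added drug itself was never refilled in time
            continue
        for f, r in timeline:
            if not (a < r and f < ra):  # supply intervals must overlap
                continue
            ilo = np.searchsorted(index_days, f, side="right")
            ihi = np.searchsorted(index_days, r + gap, side="right")
            if ihi > ilo:
                return (a, c)
    return None


def _first_dose_escalation(
    merged_index: Sequence[tuple[int, str, int, float]], threshold: float
) -> Optional[int]:
    days = [d for d, *_ in merged_index]
    units = [u for *_, u in merged_index]
    doses = [
        units[i] / (days[i + 1] - days[i]) for i in range(len(days) - 1)
    ]
    for i in range(len(doses) - 1):
        if doses[i] > 0 and doses[i + 1] / doses[i] >= threshold:
            return days[i + 1]
    return None


def _classify_arrays(
    day: np.ndarray,
    cls: np.ndarray,
    supply: np.ndarray,
    units: np.ndarray,
    index_drug: str,
    pre_classes: set[str],
    params: ClassifyParams,
) -> tuple[str, int, Optional[str], Optional[str]]:
    """Resolve (mod_type, event_day_rel, detail, audit) from relative-day
    glucose-lowering claims (day >= 0)."""
    merged = _merge_fills(day, cls, supply, units)
    index_merged = [m for m in merged if m[1] == index_drug]
    non_merged = [(d, c, s) for d, c, s, _ in merged if c != index_drug and d > 0]

    timeline = [(d, d + s) for d, _, s, _ in index_merged if s > 0]
    index_days = np.array([d for d, _ in timeline])
    class_days: dict[str, np.ndarray] = {}
    for d, c, _ in non_merged:
        class_days.setdefault(c, []).append(d)  # type: ignore[arg-type]
    class_days = {c: np.array(v) for c, v in class_days.items()}
    other_days = np.array(sorted(d for d, _, _ in non_merged))

    candidates: list[Candidate] = []
    r = _first_disc(timeline, index_days, other_days, params)
    if r is not None:
        candidates.append(Candidate("discontinuation", r))
    sw = _first_switch(timeline, index_days, class_days, params)
    if sw is not None:
        candidates.append(Candidate("switch", sw[0], sw[1]))

    dose_day = None
    if index_drug == drugs.GLARGINE and len(index_merged) >= 3:
        dose_day = _first_dose_escalation(index_merged, params.dose_threshold)
    it = _first_intens(timeline, index_days, non_merged, class_days, pre_classes, params)
    # for the basal-insulin arm, the earlier of add-on and dose escalation
    # wins (add-on preferred on a tie: it names the added class)
    if it is not None and (dose_day is None or it[0] <= dose_day):
        candidates.append(Candidate("intensification", it[0], it[1]))
    elif dose_day is not None:
        candidates.append(Candidate("intensification", dose_day, "dose_increase"))

    candidates = [c for c in candidates if 0 < c.event_day <= params.follow_up_days]
    if candidates:
        chosen = min(candidates, key=Candidate.sort_key)
        return chosen.mod_type, chosen.event_day, chosen.detail, None

    audit = None
    for r in _gap_runouts(timeline, index_days, params.gap_days):
        if r + params.gap_days > params.follow_up_days:
            continue
        lo = np.searchsorted(other_days, r, side="right")
        hi = np.searchsorted(other_days, r + params.gap_days, side="right")
        if hi > lo:
            # non-index activity in an evaluable gap that confirmed nothing:
            # neither discontinuation nor switch fires (flagged for audit)
            audit = "gap_with_unconfirmed_nonindex"
            break
    return "censored", params.follow_up_days, None, audit


# ---------------------------------------------------------------------------
# DataFrame-facing operations (thin wrappers over the array engine)
# ---------------------------------------------------------------------------


def _frame_arrays(claims: pd.DataFrame) -> tuple[np.ndarray, ...]:
    units = (
        claims["units"].to_numpy(dtype=float)
        if "units" in claims.columns
        else np.full(len(claims), np.nan)
    )
    return (
        claims["fill_day"].to_numpy(),
        claims["drug_class"].to_numpy(),
        claims["days_supply"].to_numpy(),
        units,
    )


def build_supply_timeline(index_claims: pd.DataFrame) -> list[tuple[int, int]]:
    """Per-claim ``(fill_day, run_out_day)`` for the index drug, sorted.

    Claims with non-positive days' supply are dropped; no supply carryover:
    each claim's run-out is its own fill day plus its own supply.
    """
    if index_claims.empty:
        return []
    ok = index_claims[index_claims["days_supply"] > 0].sort_values(
        "fill_day", kind="mergesort"
    )
    return [
        (int(d), int(d + s)) for d, s in zip(ok["fill_day"], ok["days_supply"])
    ]


def estimate_daily_dose(index_claims: pd.DataFrame) -> pd.DataFrame:
    """Estimated daily dose per fill: units dispensed / days to the next fill.

    The final fill has no next dispense date, so its dose is undefined (NaN);
    same-day fills are merged (units summed) first.
    """
    merged = _merge_fills(*_frame_arrays(index_claims))
    days = np.array([d for d, *_ in merged])
    units = np.array([u for *_, u in merged], dtype=float)
    dose = np.full(len(merged), np.nan)
    if len(merged) >= 2:
        dose[:-1] = units[:-1] / np.diff(days)
    return pd.DataFrame({"fill_day": days, "units": units, "est_daily_dose": dose})


def detect_dose_escalation(
    dose_series: pd.DataFrame, threshold: float = 2.0
) -> Optional[Candidate]:
    """Earliest consecutive-fill dose ratio >= threshold -> intensification
    candidate dated at the second fill of the offending pair."""
    dose = dose_series["est_daily_dose"].to_numpy(dtype=float)
    days = dose_series["fill_day"].to_numpy()
    for i in range(len(dose) - 1):
        if not math.isnan(dose[i]) and not math.isnan(dose[i + 1]) and dose[i] > 0:
            if dose[i + 1] / dose[i] >= threshold:
                return Candidate("intensification", int(days[i + 1]), "dose_increase")
    return None


def _class_days_of(non_index_glucose: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        c: np.sort(g["fill_day"].to_numpy())
        for c, g in non_index_glucose.groupby("drug_class")
    }


def detect_discontinuation(
    timeline: Sequence[tuple[int, int]],
    non_index_glucose: pd.DataFrame,
    params: Optional[ClassifyParams] = None,
) -> Optional[Candidate]:
    """First evaluable empty gap -> discontinuation at the run-out day."""
    params = params or ClassifyParams()
    index_days = np.array([f for f, _ in timeline])
    other = np.sort(non_index_glucose["fill_day"].to_numpy())
    r = _first_disc(timeline, index_days, other, params)
    return None if r is None else Candidate("discontinuation", r)


def detect_switch(
    timeline: Sequence[tuple[int, int]],
    non_index_glucose: pd.DataFrame,
    params: Optional[ClassifyParams] = None,
) -> Optional[Candidate]:
    """First confirmed replacement therapy -> switch at its first fill day."""
    params = params or ClassifyParams()
    index_days = np.array([f for f, _ in timeline])
    sw = _first_switch(timeline, index_days, _class_days_of(non_index_glucose), params)
    return None if sw is None else Candidate("switch", sw[0], sw[1])


def detect_intensification(
    timeline: Sequence[tuple[int, int]],
    non_index_glucose: pd.DataFrame,
    pre_index_classes: Iterable[str],
    params: Optional[ClassifyParams] = None,
    dose_candidate: Optional[Candidate] = None,
) -> Optional[Candidate]:
    """First confirmed add-on (or the dose-escalation candidate, whichever is
    earlier) -> intensification."""
    params = params or ClassifyParams()
    index_days = np.array([f for f, _ in timeline])
    non_fills = sorted(
        (int(r.fill_day), r.drug_class, int(r.days_supply))
        for r in non_index_glucose.itertuples()
    )
    it = _first_intens(
        timeline, index_days, non_fills, _class_days_of(non_index_glucose),
        set(pre_index_classes), params,
    )
    best = None if it is None else Candidate("intensification", it[0], it[1])
    if dose_candidate is not None and dose_candidate.event_day <= params.follow_up_days:
        if best is None or dose_candidate.event_day < best.event_day:
            best = dose_candidate
    return best


def classify_first_modification(
    patient_claims: pd.DataFrame,
    index_day: int,
    index_drug: str,
    pre_index_classes: Iterable[str],
    params: Optional[ClassifyParams] = None,
    patient_id: int = -1,
) -> ModificationEvent:
    """Resolve the first treatment modification for one patient.

    ``patient_claims`` holds pharmacy claims from the index day onward
    (columns fill_day, drug_class, days_supply, units); claims past the
    horizon may be present and are used only to confirm refill windows,
    never to date events.
    """
    params = params or ClassifyParams()
    day, cls, supply, units = _frame_arrays(patient_claims)
    keep = (day >= index_day) & np.isin(cls, list(drugs.GLUCOSE_LOWERING_CLASSES))
    mod, rel_day, detail, audit = _classify_arrays(
        day[keep] - index_day, cls[keep], supply[keep], units[keep],
        index_drug, set(pre_index_classes), params,
    )
    return ModificationEvent(
        patient_id=patient_id,
        mod_type=mod,
        event_day=index_day + rel_day,
        days_to_event=rel_day,
        detail=detail,
        audit_flag=audit,
    )


# ---------------------------------------------------------------------------
# Cohort-level driver and summaries
# ---------------------------------------------------------------------------


def pre_index_class_set(
    pharmacy: pd.DataFrame, index_day: int, pre_index_days: int = 365
) -> set[str]:
    """Glucose-lowering classes filled in [index - pre_index_days, index - 1]."""
    window = pharmacy[
        (pharmacy["fill_day"] >= index_day - pre_index_days)
        & (pharmacy["fill_day"] < index_day)
    ]
    return set(window["drug_class"]) & set(drugs.GLUCOSE_LOWERING_CLASSES)


def classify_cohort(
    pharmacy: pd.DataFrame,
    cohort: pd.DataFrame,
    params: Optional[ClassifyParams] = None,
) -> pd.DataFrame:
    """One ModificationEvent row per cohort patient.

    ``cohort`` needs patient_id, index_day, and index_drug (or arm);
    ``pharmacy`` is the full claims table — pre-index fills define each
    patient's baseline class set.
    """
    params = params or ClassifyParams()
    drug_col = "index_drug" if "index_drug" in cohort.columns else "arm"
    glucose_set = frozenset(drugs.GLUCOSE_LOWERING_CLASSES)

    rx = pharmacy[pharmacy["drug_class"].isin(glucose_set)]
    pid_arr = rx["patient_id"].to_numpy()
    order = np.argsort(pid_arr, kind="mergesort")
    day_a = rx["fill_day"].to_numpy()[order]
    cls_a = rx["drug_class"].to_numpy()[order]
    sup_a = rx["days_supply"].to_numpy()[order]
    units_a = (
        rx["units"].to_numpy(dtype=float)[order]
        if "units" in rx.columns
        else np.full(len(rx), np.nan)
    )
    pid_sorted = pid_arr[order]
    uniq, starts = np.unique(pid_sorted, return_index=True)
    ends = np.searchsorted(pid_sorted, uniq, side="right")
    bounds = {p: (int(s), int(e)) for p, s, e in zip(uniq, starts, ends)}

    rows = []
    for rec in cohort.itertuples():
        pid = rec.patient_id
        index_drug = getattr(rec, drug_col)
        index_day = int(rec.index_day)
        lo, hi = bounds.get(pid, (0, 0))
        day, cls, sup, uni = day_a[lo:hi], cls_a[lo:hi], sup_a[lo:hi], units_a[lo:hi]
        pre_mask = (day >= index_day - params.pre_index_days) & (day < index_day)
        pre = set(cls[pre_mask])
        post = day >= index_day
        mod, rel_day, detail, audit = _classify_arrays(
            day[post] - index_day, cls[post], sup[post], uni[post],
            index_drug, pre, params,
        )
        rows.append(
            (pid, index_drug, mod, index_day + rel_day, rel_day, detail, audit)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "arm", "mod_type", "event_day",
            "days_to_event", "detail", "audit_flag",
        ],
    )


def summarize_modifications(
    events: pd.DataFrame, cutoffs: Sequence[int] = (180, 365, 545)
) -> pd.DataFrame:
    """Frequency-and-timing summary per arm and modification type.

    For "any" modification and each type: cumulative count and percentage of
    the arm by each cutoff day, plus mean and SD of days-to-event among
    patients with that event type (censored patients never enter the means).
    """
    rows = []
    for arm, arm_events in events.groupby("arm"):
        n_arm = len(arm_events)
        for mod in ("any",) + MOD_TYPES:
            if mod == "any":
                sub = arm_events[arm_events["mod_type"] != "censored"]
            else:
                sub = arm_events[arm_events["mod_type"] == mod]
            days = sub["days_to_event"]
            row: dict = {"arm": arm, "mod_type": mod, "n_arm": n_arm}
            for cut in cutoffs:
                k = int((days <= cut).sum())
                row[f"n_by_{cut}"] = k
                row[f"pct_by_{cut}"] = 100.0 * k / n_arm if n_arm else float("nan")
            row["mean_days"] = float(days.mean()) if len(days) else float("nan")
            row["sd_days"] = float(days.std(ddof=1)) if len(days) > 1 else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
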