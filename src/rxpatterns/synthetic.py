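"""Synthetic claims simulator with ground-truth treatment courses.

Emulates the statistical structure a new-user, active-comparator claims
analysis assumes: confounded (channelled) assignment to one of two index
drugs, competing cause-specific risks of discontinuation / switching /
intensification over 18 months of follow-up, stochastic refill slack, and
claim-to-claim dose titration for the basal-insulin arm.  Every patient
carries a ground-truth label so the modification classifier can be
validated by round trip.

Latent event times are independent exponentials per cause (first one wins,
administratively censored at the follow-up horizon).  Claim emission
quantises the latent time onto the refill grid using the same conventions
as the classifier: a discontinuation happens at the run-out of the last
fill, a switch at the first fill of the replacement class, an
intensification at the add-on fill (or at the escalated-dose fill).  Latent
events whose claim-grid realisation cannot be observed inside the horizon
(for example a discontinuation gap that would extend past day 545) are
relabelled persistent so that the emitted ground truth is exactly what a
correct classifier can recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from rxpatterns import drugs
from rxpatterns.config import GapDistribution, SimConfig

COURSES = ("persistent", "discontinued", "switched", "intensified")
CAUSES = ("discontinue", "switch", "intensify")
CAUSE_TO_COURSE = {
    "discontinue": "discontinued",
    "switch": "switched",
    "intensify": "intensified",
}
#: ground-truth course -> classifier event label
COURSE_TO_EVENT = {
    "persistent": "censored",
    "discontinued": "discontinuation",
    "switched": "switch",
    "intensified": "intensification",
}

REGIONS = ("northeast", "north_central", "south", "west")
REGION_P = (0.18, 0.25, 0.40, 0.17)
PLANS = ("ppo", "hmo", "pos", "other")
PLAN_P = (0.50, 0.25, 0.15, 0.10)
SPECIALTIES = ("primary_care", "endocrinology", "other_specialist", "unknown")
SPECIALTY_P = (0.70, 0.09, 0.12, 0.09)

#: prevalence of pre-index drug classes (Bernoulli per patient)
PRE_CLASS_P = {
    "biguanide": 0.71,
    "sulfonylurea": 0.53,
    "thiazolidinedione": 0.52,
    "meglitinide": 0.053,
    "alpha_glucosidase_inhibitor": 0.012,
    "fixed_dose_combination": 0.23,
    "antihyperlipidemic": 0.70,
    "antihypertensive": 0.84,
    "antidepressant": 0.29,
}
PRE_GLUCOSE_CLASSES = tuple(c for c in PRE_CLASS_P if c in drugs.GLUCOSE_LOWERING_CLASSES)

#: classes a patient can switch to / add on, per arm
SWITCH_POOL = {
    drugs.EXENATIDE: (
        drugs.GLARGINE, "sitagliptin", "sulfonylurea", "biguanide",
        "thiazolidinedione", "insulin_other", "fixed_dose_combination",
    ),
    drugs.GLARGINE: (
        drugs.EXENATIDE, "insulin_other", "insulin_premixed", "insulin_bolus",
        "sitagliptin", "sulfonylurea", "biguanide", "thiazolidinedione",
    ),
}
INTENSIFY_POOL = {
    drugs.EXENATIDE: (
        drugs.GLARGINE, "sitagliptin", "sulfonylurea", "biguanide",
        "thiazolidinedione", "fixed_dose_combination", "insulin_basal_other",
    ),
    drugs.GLARGINE: (
        drugs.EXENATIDE, "sitagliptin", "insulin_bolus", "insulin_premixed",
        "insulin_other", "sulfonylurea", "biguanide", "thiazolidinedione",
    ),
}

WASHOUT_TRIGGER_CLASSES = ("sitagliptin", "insulin_other", "pramlintide")

DX_TRIGGERS = (
    "dx_type1", "dx_gestational", "dx_ckd", "dx_cushing",
    "dx_acromegaly", "dx_gastric_surgery",
)

_EMIT_SEED_OFFSET = 1_000_003


@dataclass
class Population:
    patients: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame  # latent labels: patient_id, true_course, latent_day
    draws: list[dict]  # per-patient structural draws consumed by emit_claims


@dataclass
class SimData:
    patients: pd.DataFrame
    covariates: pd.DataFrame
    enrollment: pd.DataFrame
    pharmacy: pd.DataFrame
    medical: pd.DataFrame
    truth: pd.DataFrame  # finalized: patient_id, true_course, true_event_day


def _draw_slack(rng: np.random.Generator, dist: GapDistribution) -> int:
    if dist.kind == "constant":
        return dist.value
    return int(min(rng.poisson(dist.mean), dist.cap))


def _draw_supply(rng: np.random.Generator, cfg: SimConfig) -> int:
    supplies = [s for s, _ in cfg.days_supply_choices]
    probs = np.array([p for _, p in cfg.days_supply_choices], dtype=float)
    return int(rng.choice(supplies, p=probs / probs.sum()))


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


def generate_population(config: SimConfig) -> Population:
    """Draw patients, baseline covariates, treatment arms, and latent courses.

    Arms come from a logistic model on the propensity design columns
    (``assignment_coefficients``); the latent course is the minimum of
    independent exponential cause-specific times, censored at the follow-up
    horizon.
    """
    from rxpatterns.match import propensity_design  # local: avoid cycle at import

    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    index_day = rng.integers(config.index_window[0], config.index_window[1] + 1, n)
    age = np.clip(np.round(rng.normal(56, 11, n)), 21, 90).astype(int)
    sex_female = rng.random(n) < 0.52
    region = rng.choice(REGIONS, n, p=REGION_P)
    plan = rng.choice(PLANS, n, p=PLAN_P)
    specialty = rng.choice(SPECIALTIES, n, p=SPECIALTY_P)
    micro = rng.random(n) < 0.19
    macro = rng.random(n) < 0.21
    cci = np.minimum(rng.poisson(1.2, n) + micro + macro, 12).astype(int)
    inpatient = rng.random(n) < 0.12

    class_flags = {c: rng.random(n) < p for c, p in PRE_CLASS_P.items()}
    fills_per_class = {c: 1 + rng.poisson(9.0, n) for c in PRE_CLASS_P}

    # exclusion triggers
    triggers: dict[str, np.ndarray] = {}
    for name, frac in config.exclusion_fractions.items():
        triggers[name] = rng.random(n) < frac
    washout_class = rng.choice(WASHOUT_TRIGGER_CLASSES, n)
    under_18_age = rng.integers(15, 18, n)
    age = np.where(triggers.get("under_18", np.zeros(n, bool)), under_18_age, age)

    # pre-index medical costs (components drawn here so the covariate is exact)
    n_outpt = 2 + rng.poisson(3.0, n)
    outpt_costs = [
        np.round(rng.lognormal(np.log(800.0), 1.0, k), 2) for k in n_outpt
    ]
    inpt_cost = np.where(
        inpatient, np.round(rng.lognormal(np.log(12_000.0), 0.7, n), 2), 0.0
    )
    total_cost = np.array([c.sum() for c in outpt_costs]) + inpt_cost

    med_claims = np.zeros(n, dtype=int)
    med_classes = np.zeros(n, dtype=int)
    for c in PRE_CLASS_P:
        med_claims += np.where(class_flags[c], fills_per_class[c], 0)
        med_classes += class_flags[c].astype(int)
    gc = triggers.get("glucocorticoid", np.zeros(n, bool))
    wo = triggers.get("washout_drug", np.zeros(n, bool))
    med_claims += 2 * gc + 1 * wo
    med_classes += gc.astype(int) + wo.astype(int)

    covariates = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "index_day": index_day,
            "age": age,
            "sex_female": sex_female.astype(int),
            "region": region,
            "plan_type": plan,
            "specialty": specialty,
            "microvascular": micro.astype(int),
            "macrovascular": macro.astype(int),
            "cci": cci,
            "med_claims": med_claims,
            "med_classes": med_classes,
            "inpatient_admission": inpatient.astype(int),
            "pre_index_cost": total_cost,
            **{f"pre_{c}": class_flags[c].astype(int) for c in PRE_CLASS_P},
        }
    )

    # ----- confounded arm assignment -----
    design = propensity_design(covariates)
    lp = np.zeros(n)
    for name, coef in config.assignment_coefficients.items():
        if name not in design.columns:
            raise ValueError(f"unknown assignment covariate: {name}")
        lp += coef * design[name].to_numpy(dtype=float)
    p_glargine = 1.0 / (1.0 + np.exp(-lp))
    arm = np.where(rng.random(n) < p_glargine, drugs.GLARGINE, drugs.EXENATIDE)
    covariates.insert(1, "arm", arm)

    # ----- latent competing-risk course -----
    latent_day = np.full(n, np.nan)
    course = np.full(n, "persistent", dtype=object)
    times = np.empty((n, len(CAUSES)))
    for j, cause in enumerate(CAUSES):
        h = np.array([config.cause_specific_hazards[a][cause] for a in arm])
        u = rng.random(n)
        with np.errstate(divide="ignore"):
            times[:, j] = np.where(h > 0, -np.log(u) / np.where(h > 0, h, 1.0), np.inf)
    tmin = times.min(axis=1)
    winner = times.argmin(axis=1)
    observed = tmin <= config.follow_up_days
    latent_day[observed] = tmin[observed]
    course[observed] = [CAUSE_TO_COURSE[CAUSES[w]] for w in winner[observed]]

    truth = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "true_course": course,
            "latent_day": latent_day,
        }
    )

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "birth_year": (index_day // 365) - age,
            "sex": np.where(sex_female, "F", "M"),
            "region": region,
            "plan_type": plan,
        }
    )

    draws = []
    for i in range(n):
        draws.append(
            {
                "patient_id": i,
                "arm": arm[i],
                "index_day": int(index_day[i]),
                "course": course[i],
                "latent_day": float(latent_day[i]) if observed[i] else None,
                "class_flags": {c: bool(class_flags[c][i]) for c in PRE_CLASS_P},
                "fills_per_class": {c: int(fills_per_class[c][i]) for c in PRE_CLASS_P},
                "triggers": sorted(t for t, v in triggers.items() if v[i]),
                "washout_class": str(washout_class[i]),
                "specialty": specialty[i],
                "micro": bool(micro[i]),
                "macro": bool(macro[i]),
                "cci": int(cci[i]),
                "inpatient": bool(inpatient[i]),
                "outpt_costs": outpt_costs[i],
                "inpt_cost": float(inpt_cost[i]),
                "age": int(age[i]),
            }
        )
    return Population(patients, covariates, truth, draws)


# ---------------------------------------------------------------------------
# Claim emission
# ---------------------------------------------------------------------------


def _glargine_doses(
    rng: np.random.Generator, cfg: SimConfig, n_fills: int, escalate_at: Optional[int]
) -> np.ndarray:
    """Daily-dose sequence: mild upward titration, one x3 jump if escalating."""
    ts = cfg.titration_schedule
    d = max(10.0, min(rng.normal(ts.start_dose_mean, ts.start_dose_sd), ts.dose_cap))
    doses = np.empty(n_fills)
    for k in range(n_fills):
        if k > 0:
            if escalate_at is not None and k == escalate_at:
                d = d * ts.escalation_mult  # deliberately uncapped: a true escalation
            else:
                d = min(d * rng.uniform(ts.mult_low, ts.mult_high), ts.dose_cap)
        doses[k] = d
    return doses


def emit_claims(
    population: Population, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Materialise pharmacy, medical, and enrollment claims; finalize truth.

    Returns ``(pharmacy, medical, enrollment, truth)`` where ``truth`` holds
    the claim-grid ground truth (``true_event_day`` in days since index).
    Latent events that cannot be realised observably inside the horizon are
    relabelled persistent.
    """
    rng = np.random.default_rng(config.seed + _EMIT_SEED_OFFSET)
    fup = config.follow_up_days
    gap = config.gap_days

    rx_rows: list[tuple] = []
    med_rows: list[tuple] = []
    enr_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for d in population.draws:
        pid, arm, index = d["patient_id"], d["arm"], d["index_day"]
        emit_end = index + fup + config.emit_horizon_extra
        course, latent = d["course"], d["latent_day"]

        # ----- enrollment -----
        start = int(index - config.pre_index_days - rng.integers(0, 201))
        end = int(emit_end + rng.integers(0, 101))
        database = "medicare" if d["age"] >= 65 else "commercial"
        trig = d["triggers"]
        if "enrollment_gap" in trig:
            cut = index - 200
            enr_rows.append((pid, start, cut - 1, True, database))
            enr_rows.append((pid, cut + 30, end, True, database))
        elif "rx_benefit_lapse" in trig:
            cut = index + 100
            enr_rows.append((pid, start, cut - 1, True, database))
            enr_rows.append((pid, cut, end, False, database))
        elif "medicare_transition" in trig:
            cut = index + 200
            enr_rows.append((pid, start, cut - 1, True, "commercial"))
            enr_rows.append((pid, cut, end, True, "medicare"))
        else:
            enr_rows.append((pid, start, end, True, database))

        # ----- pre-index medical claims -----
        if d["micro"]:
            med_rows.append((pid, index - int(rng.integers(1, 366)), "dx_microvascular", "outpatient", 0.0))
        if d["macro"]:
            med_rows.append((pid, index - int(rng.integers(1, 366)), "dx_macrovascular", "outpatient", 0.0))
        for _ in range(d["cci"]):
            med_rows.append((pid, index - int(rng.integers(1, 366)), "cci_point", "outpatient", 0.0))
        med_rows.append((pid, index - 30, "provider_specialty", d["specialty"], 0.0))
        for c in d["outpt_costs"]:
            med_rows.append((pid, index - int(rng.integers(1, 366)), "visit", "outpatient", float(c)))
        if d["inpatient"]:
            med_rows.append((pid, index - int(rng.integers(1, 366)), "admission", "inpatient", d["inpt_cost"]))
        for t in trig:
            if t in ("dx_type1", "dx_gestational", "dx_ckd", "dx_cushing",
                     "dx_acromegaly", "dx_gastric_surgery"):
                med_rows.append((pid, index - int(rng.integers(1, 366)), t, "outpatient", 0.0))

        # ----- pre-index pharmacy -----
        pre_classes = [c for c, f in d["class_flags"].items() if f]
        for c in pre_classes:
            for _ in range(d["fills_per_class"][c]):
                day = index - int(rng.integers(1, 366))
                rx_rows.append((pid, day, c, 30, np.nan))
        if "glucocorticoid" in trig:
            for _ in range(2):
                rx_rows.append((pid, index - int(rng.integers(1, 366)), drugs.GLUCOCORTICOID, 10, np.nan))
        if "washout_drug" in trig:
            rx_rows.append((pid, index - int(rng.integers(30, 301)), d["washout_class"], 30, np.nan))

        # ----- index-drug refill chain -----
        stop_supply = None  # run-out (absolute) at which the chain stops, if any
        if course in ("discontinued", "switched"):
            stop_supply = index + latent
        fills: list[tuple[int, int]] = []  # (fill_day, supply)
        t = index
        while t <= emit_end:
            s = _draw_supply(rng, config)
            fills.append((t, s))
            runout = t + s
            if stop_supply is not None and runout >= stop_supply:
                break
            t = runout + _draw_slack(rng, config.refill_gap_distribution)

        event_day_rel: Optional[int] = None
        switch_class = None
        addon_class = None
        dose_escalation = False
        escalate_at: Optional[int] = None

        if course == "discontinued":
            r_rel = fills[-1][0] + fills[-1][1] - index
            if r_rel + gap > fup:
                course = "persistent"  # gap not observable inside the horizon
            else:
                event_day_rel = r_rel
        elif course == "switched":
            r_rel = fills[-1][0] + fills[-1][1] - index
            f_rel = r_rel + int(rng.integers(3, 46))
            if f_rel > fup:
                course = "persistent"
            else:
                event_day_rel = f_rel
                switch_class = str(rng.choice(SWITCH_POOL[arm]))
        elif course == "intensified":
            is_dose = arm == drugs.GLARGINE and (
                rng.random() < config.titration_schedule.dose_fraction
            )
            if is_dose:
                target = index + max(1.0, latent)
                j = next((k for k, (ft, _) in enumerate(fills) if k >= 1 and ft >= target), None)
                if j is None or fills[j][0] - index > fup:
                    course = "persistent"
                else:
                    dose_escalation = True
                    escalate_at = j
                    event_day_rel = fills[j][0] - index
            else:
                target = index + max(1, int(latent))
                a_abs = None
                for ft, s in fills:
                    if ft <= target < ft + s:
                        a_abs = target
                        break
                    if ft > target:  # target fell in a slack hole
                        a_abs = ft
                        break
                if a_abs is None or a_abs - index > fup:
                    course = "persistent"
                else:
                    pool = [c for c in INTENSIFY_POOL[arm] if not d["class_flags"].get(c, False)]
                    addon_class = str(rng.choice(pool)) if pool else "sitagliptin"
                    event_day_rel = a_abs - index

        if course == "persistent" and stop_supply is not None:
            # relabelled: resume the refill chain through the emission horizon
            t = fills[-1][0] + fills[-1][1] + _draw_slack(rng, config.refill_gap_distribution)
            while t <= emit_end:
                s = _draw_supply(rng, config)
                fills.append((t, s))
                t = t + s + _draw_slack(rng, config.refill_gap_distribution)

        # units dispensed
        if arm == drugs.GLARGINE:
            doses = _glargine_doses(rng, config, len(fills), escalate_at)
            units = [round(doses[k] * fills[k][1]) for k in range(len(fills))]
        else:
            units = [60.0] * len(fills)
        for (ft, s), u in zip(fills, units):
            rx_rows.append((pid, ft, arm, s, float(u)))

        # ----- replacement / add-on therapy -----
        if course == "switched":
            t = index + event_day_rel
            while t <= emit_end:
                rx_rows.append((pid, t, switch_class, 30, np.nan))
                t = t + 30 + _draw_slack(rng, config.refill_gap_distribution)
        elif course == "intensified" and not dose_escalation:
            t = index + event_day_rel
            while t <= emit_end:
                rx_rows.append((pid, t, addon_class, 30, np.nan))
                t = t + 30 + _draw_slack(rng, config.refill_gap_distribution)

        # ----- background therapy continuation -----
        if course in ("discontinued", "switched"):
            bg_stop = index + fills[-1][0] + fills[-1][1] - index  # run-out of last index fill
        else:
            bg_stop = emit_end
        for c in pre_classes:
            if c not in drugs.GLUCOSE_LOWERING_CLASSES:
                continue
            t = index + int(rng.integers(5, 35))
            while t <= bg_stop:
                rx_rows.append((pid, t, c, 90, np.nan))
                t = t + 90 + _draw_slack(rng, config.refill_gap_distribution)

        truth_rows.append((pid, course, event_day_rel))

    pharmacy = pd.DataFrame(
        rx_rows, columns=["patient_id", "fill_day", "drug_class", "days_supply", "units"]
    ).sort_values(["patient_id", "fill_day", "drug_class"], kind="mergesort").reset_index(drop=True)
    medical = pd.DataFrame(
        med_rows, columns=["patient_id", "service_day", "flag_type", "setting", "cost"]
    ).sort_values(["patient_id", "service_day", "flag_type"], kind="mergesort").reset_index(drop=True)
    enrollment = pd.DataFrame(
        enr_rows, columns=["patient_id", "start_day", "end_day", "rx_benefit", "database"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "true_course", "true_event_day"]
    )
    truth["true_event_day"] = truth["true_event_day"].astype("Int64")
    return pharmacy, medical, enrollment, truth


def simulate(config: SimConfig) -> SimData:
    """Full simulation: population + claims + finalized ground truth."""
    pop = generate_population(config)
    pharmacy, medical, enrollment, truth = emit_claims(pop, config)
    return SimData(pop.patients, pop.covariates, enrollment, pharmacy, medical, truth)


CSV_NAMES = ("patients", "enrollment", "pharmacy", "medical", "truth")


def write_csvs(data: SimData, out_dir: str | Path) -> dict[str, Path]:
    """Write the five claim tables; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in CSV_NAMES:
        path = out / f"{name}.csv"
        getattr(data, name).to_csv(path, index=False)
        paths[name] = path
    return paths


def read_csvs(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the claim tables back (truth optional)."""
    out = {}
    for name in CSV_NAMES:
        path = Path(in_dir) / f"{name}.csv"
        if name == "truth" and not path.exists():
            continue
        out[name] = pd.read_csv(path)
    return out
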