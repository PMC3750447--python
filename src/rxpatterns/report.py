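"""End-to-end pipeline driver and table rendering.

``run_pipeline`` chains simulation (or CSV input) -> cohort selection ->
propensity matching -> modification classification on the matched set ->
survival comparison, writing every intermediate artifact plus a manifest
with the config hash, seed, and row counts at each stage.  Two runs with
the same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from rxpatterns import classify, cohort as cohort_mod, match, survival, synthetic
from rxpatterns.classify import MOD_TYPES
from rxpatterns.config import PipelineConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    pairs: pd.DataFrame
    balance: pd.DataFrame
    events: pd.DataFrame
    results: dict
    manifest: dict
    truth: Optional[pd.DataFrame] = None


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def render_table2(summary: pd.DataFrame, cutoffs: list[int]) -> pd.DataFrame:
    """Frequency-and-timing layout: one block per modification type, one
    column pair per arm (count, cumulative % by each cutoff; mean/SD days)."""
    rows = []
    arms = sorted(summary["arm"].unique())
    for mod in ("any",) + MOD_TYPES:
        for cut in cutoffs:
            row = {"modification": mod, "measure": f"by_day_{cut}"}
            for arm in arms:
                s = summary[(summary["arm"] == arm) & (summary["mod_type"] == mod)].iloc[0]
                row[f"{arm}_n"] = int(s[f"n_by_{cut}"])
                row[f"{arm}_pct"] = _fmt_pct(s[f"pct_by_{cut}"])
            rows.append(row)
        row = {"modification": mod, "measure": "mean_days"}
        for arm in arms:
            s = summary[(summary["arm"] == arm) & (summary["mod_type"] == mod)].iloc[0]
            row[f"{arm}_n"] = "" if np.isnan(s["mean_days"]) else f"{s['mean_days']:.0f}"
            row[f"{arm}_pct"] = "" if np.isnan(s["sd_days"]) else f"{s['sd_days']:.0f}"
        rows.append(row)
    return pd.DataFrame(rows)


def render_table3(events: pd.DataFrame) -> pd.DataFrame:
    """Drugs used in switching and intensification.

    Among switchers and intensifiers per arm: the class of the new or added
    medication (``dose_increase`` for basal-insulin dose escalation), with
    counts and within-modification percentages summing to 100 per column.
    """
    arms = sorted(events["arm"].unique())
    details = sorted(
        d for d in events.loc[events["mod_type"].isin(("switch", "intensification")), "detail"]
        .dropna().unique()
    )
    rows = []
    header = {"detail": "total_n"}
    for mod in ("intensification", "switch"):
        for arm in arms:
            n = int(((events["arm"] == arm) & (events["mod_type"] == mod)).sum())
            header[f"{mod}_{arm}_n"] = n
            header[f"{mod}_{arm}_pct"] = "100.0" if n else "0.0"
    rows.append(header)
    for det in details:
        row = {"detail": det}
        for mod in ("intensification", "switch"):
            for arm in arms:
                sub = events[(events["arm"] == arm) & (events["mod_type"] == mod)]
                k = int((sub["detail"] == det).sum())
                row[f"{mod}_{arm}_n"] = k
                row[f"{mod}_{arm}_pct"] = _fmt_pct(100.0 * k / len(sub)) if len(sub) else "0.0"
        rows.append(row)
    return pd.DataFrame(rows)


def km_frame(results: dict) -> pd.DataFrame:
    """Long-format KM curves (outcome, arm, time, at_risk, events, survival)."""
    rows = []
    for outcome, entry in results["outcomes"].items():
        for arm, km in entry["km"].items():
            df = km.copy()
            df.insert(0, "arm", arm)
            df.insert(0, "outcome", outcome)
            rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _json_results(results: dict) -> dict:
    out = {}
    for outcome, entry in results["outcomes"].items():
        out[outcome] = {
            "logrank": entry.get("logrank"),
            "cox": entry.get("cox"),
        }
    return out


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis; returns in-memory results and (by default)
    writes all artifacts under ``config.output_dir``."""
    out_dir = Path(config.output_dir)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    # ----- input data -----
    truth = None
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate.model_copy(update={"seed": config.seed})
            data = synthetic.simulate(sim_cfg)
            tables = {
                "patients": data.patients,
                "enrollment": data.enrollment,
                "pharmacy": data.pharmacy,
                "medical": data.medical,
            }
            truth = data.truth
            index_window = sim_cfg.index_window
        else:
            raw = synthetic.read_csvs(config.input_dir)
            tables = {k: raw[k] for k in ("patients", "enrollment", "pharmacy", "medical")}
            truth = raw.get("truth")
            index_window = (
                int(tables["pharmacy"]["fill_day"].min()),
                int(tables["pharmacy"]["fill_day"].max()),
            )
    except Exception as exc:
        raise PipelineError("input", exc) from exc
    manifest["stages"]["population"] = int(len(tables["patients"]))

    # ----- cohort -----
    try:
        cohort, exclusions = cohort_mod.build_cohort(
            tables["patients"], tables["enrollment"], tables["pharmacy"],
            tables["medical"], index_window, config.classify_params,
        )
    except Exception as exc:
        raise PipelineError("cohort", exc) from exc
    manifest["stages"]["cohort"] = int(len(cohort))
    manifest["stages"]["excluded"] = int(len(exclusions))

    # ----- matching -----
    try:
        fit = match.fit_propensity_model(cohort, cohort["arm"].to_numpy())
        pairs, unmatched = match.match_pairs(
            fit.scores, cohort["arm"].to_numpy(),
            cohort["patient_id"].to_numpy(), config.caliper_sd,
        )
        balance = match.balance_table(cohort, cohort["arm"].to_numpy(), pairs)
        pairs_df = match.pairs_frame(pairs)
    except Exception as exc:
        raise PipelineError("match", exc) from exc
    manifest["stages"]["matched_pairs"] = int(len(pairs_df))
    manifest["stages"]["unmatched_treated"] = int(len(unmatched))

    # ----- classification -----
    try:
        if config.classify_full_cohort:
            analysis_set = cohort
        else:
            matched_ids = pd.concat(
                [pairs_df["glargine_patient_id"], pairs_df["exenatide_patient_id"]]
            )
            analysis_set = cohort[cohort["patient_id"].isin(matched_ids)]
        events = classify.classify_cohort(
            tables["pharmacy"], analysis_set, config.classify_params
        )
    except Exception as exc:
        raise PipelineError("classify", exc) from exc
    manifest["stages"]["classified"] = int(len(events))

    # ----- survival -----
    try:
        strata = None
        if config.pair_stratified_cox:
            strata = pd.concat(
                [
                    pd.Series(pairs_df["pair_id"].to_numpy(), index=pairs_df["glargine_patient_id"]),
                    pd.Series(pairs_df["pair_id"].to_numpy(), index=pairs_df["exenatide_patient_id"]),
                ]
            )
        results = survival.compare_arms(
            events, config.cutoffs, ties=config.cox_ties, pair_strata=strata
        )
    except Exception as exc:
        raise PipelineError("survival", exc) from exc

    result = PipelineResult(
        cohort=cohort, exclusions=exclusions, pairs=pairs_df, balance=balance,
        events=events, results=results, manifest=manifest, truth=truth,
    )

    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        exclusions.to_csv(out_dir / "exclusions.csv", index=False)
        pairs_df.to_csv(out_dir / "pairs.csv", index=False)
        balance.to_csv(out_dir / "balance.csv", index=False)
        events.to_csv(out_dir / "events.csv", index=False)
        results["summary"].to_csv(out_dir / "summary.csv", index=False)
        render_table2(results["summary"], config.cutoffs).to_csv(
            out_dir / "table2.csv", index=False
        )
        render_table3(events).to_csv(out_dir / "table3.csv", index=False)
        km_frame(results).to_csv(out_dir / "km_curves.tsv", sep="\t", index=False)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(_json_results(results), fh, indent=2, sort_keys=True)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if truth is not None:
            truth.to_csv(out_dir / "truth.csv", index=False)
    return result
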