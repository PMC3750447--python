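"""Propensity-score estimation, 1:1 greedy matching, and balance diagnostics.

The basal-insulin ("glargine") arm is modelled as treated (it is the smaller
arm under channelled assignment).  Scores come from a maximum-likelihood
logistic regression (IRLS, via statsmodels GLM); matching is greedy nearest
neighbour on the logit of the score, without replacement, treated patients
processed in descending score order, with a caliper of 0.2 standard
deviations of the logit score by default.  Balance is summarised with
standardized differences on the conventional x100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from rxpatterns import drugs


class SeparationError(ValueError):
    """A covariate perfectly separates the two arms."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PropensityFit:
    coefficients: dict[str, float]
    scores: np.ndarray  # P(treated | x), strictly in (0, 1)
    converged: bool
    iterations: int
    bse: dict[str, float]


@dataclass(frozen=True)
class MatchedPair:
    pair_id: int
    treated_id: int
    control_id: int
    treated_score: float
    control_score: float


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

#: baseline categorical levels absorbed into the intercept
_BASE_LEVELS = {"region": "south", "plan_type": "ppo", "specialty": "primary_care"}


def propensity_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix shared by the simulator's assignment model and
    the propensity fit (continuous covariates centred/scaled by fixed
    constants so coefficients are comparable across datasets)."""
    X = pd.DataFrame(index=covariates.index)
    X["intercept"] = 1.0
    X["age_c"] = (covariates["age"] - 55.0) / 10.0
    X["sex_female"] = covariates["sex_female"].astype(float)
    X["microvascular"] = covariates["microvascular"].astype(float)
    X["macrovascular"] = covariates["macrovascular"].astype(float)
    X["cci"] = covariates["cci"].astype(float)
    X["inpatient_admission"] = covariates["inpatient_admission"].astype(float)
    X["log_cost_c"] = np.log1p(covariates["pre_index_cost"].astype(float)) - 9.0
    X["med_claims_c"] = (covariates["med_claims"] - 40.0) / 25.0
    X["med_classes_c"] = (covariates["med_classes"] - 10.0) / 4.5
    canonical = {
        "region": ("northeast", "north_central", "south", "west"),
        "plan_type": ("ppo", "hmo", "pos", "other"),
        "specialty": ("primary_care", "endocrinology", "other_specialist", "unknown"),
    }
    for col, base in _BASE_LEVELS.items():
        prefix = "plan" if col == "plan_type" else col
        levels = sorted(set(canonical[col]) | set(covariates[col].unique()))
        for level in levels:
            if level != base:
                X[f"{prefix}_{level}"] = (covariates[col] == level).astype(float)
    for c in covariates.columns:
        if c.startswith("pre_"):
            if c == "pre_index_cost":
                continue
            X[c] = covariates[c].astype(float)
    return X


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        if col == "intercept":
            continue
        x = X[col].to_numpy(dtype=float)
        x1, x0 = x[y == 1], x[y == 0]
        if len(x1) == 0 or len(x0) == 0:
            continue
        if x1.min() > x0.max() or x0.min() > x1.max():
            raise SeparationError(f"covariate '{col}' perfectly separates the arms")


# ---------------------------------------------------------------------------
# Propensity model
# ---------------------------------------------------------------------------


def fit_propensity_model(
    covariates: pd.DataFrame,
    treatment: Sequence[int] | np.ndarray,
    tolerance: float = 1e-8,
    max_iter: int = 100,
) -> PropensityFit:
    """ML logistic regression of treatment (glargine = 1) on the design.

    ``treatment`` may be 0/1 or arm labels.  Raises
    :class:`SeparationError` naming the separating covariate, or
    :class:`ConvergenceError` after ``max_iter`` IRLS iterations.
    """
    y = np.asarray(
        [t if isinstance(t, (int, np.integer, bool, np.bool_)) else int(t == drugs.GLARGINE)
         for t in treatment],
        dtype=float,
    )
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 patients in each arm")
    X = propensity_design(covariates)
    # drop constant indicator columns (absent levels) to keep the fit full rank
    keep = [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]
    X = X[keep]
    _check_separation(X, y)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings(), np.errstate(over="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=max_iter, tol=tolerance)
        except Exception as exc:  # statsmodels own separation/convergence failures
            raise ConvergenceError(str(exc)) from exc
    iterations = int(getattr(res, "fit_history", {}).get("iteration", max_iter))
    converged = bool(getattr(res, "converged", True)) and iterations <= max_iter
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {iterations} iterations")
    with np.errstate(over="ignore"):
        scores = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
    return PropensityFit(
        coefficients=dict(zip(X.columns, res.params)),
        scores=np.asarray(scores),
        converged=converged,
        iterations=iterations,
        bse=dict(zip(X.columns, res.bse)),
    )


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match_pairs(
    scores: np.ndarray,
    treatment: np.ndarray,
    patient_ids: Optional[np.ndarray] = None,
    caliper_sd: Optional[float] = 0.2,
) -> tuple[list[MatchedPair], list[int]]:
    """Greedy 1:1 nearest-neighbour matching on the logit score.

    Treated patients are processed in descending score order (ties broken by
    patient id); each is matched to the nearest available control within the
    caliper (``caliper_sd`` x SD of the logit scores; ``None`` disables the
    caliper).  Returns the pairs and the ids of unmatched treated patients.
    """
    scores = np.asarray(scores, dtype=float)
    treatment = np.asarray(treatment)
    if treatment.dtype.kind in "OUS":
        treatment = (treatment == drugs.GLARGINE).astype(int)
    if patient_ids is None:
        patient_ids = np.arange(len(scores))
    patient_ids = np.asarray(patient_ids)
    t_mask = treatment == 1
    if t_mask.all() or not t_mask.any():
        raise ValueError("both arms must be non-empty")

    logit = np.log(scores) - np.log1p(-scores)
    caliper = np.inf if caliper_sd is None else caliper_sd * logit.std(ddof=1)

    # controls sorted by logit; availability mask enables nearest-alive scans
    c_order = np.lexsort((patient_ids[~t_mask], logit[~t_mask]))
    c_logit = logit[~t_mask][c_order]
    c_ids = patient_ids[~t_mask][c_order]
    c_scores = scores[~t_mask][c_order]
    alive = np.ones(len(c_logit), dtype=bool)

    t_order = np.lexsort((patient_ids[t_mask], -scores[t_mask]))
    pairs: list[MatchedPair] = []
    unmatched: list[int] = []
    for ti in t_order:
        tl = logit[t_mask][ti]
        pos = np.searchsorted(c_logit, tl)
        best_j, best_d = -1, np.inf
        j = pos - 1
        while j >= 0:
            d = tl - c_logit[j]
            if d >= best_d:
                break
            if alive[j]:
                best_j, best_d = j, d
                break
            j -= 1
        j = pos
        while j < len(c_logit):
            d = c_logit[j] - tl
            if d >= best_d:
                break
            if alive[j]:
                # strict improvement required: on equal distance keep the
                # lower-logit (earlier) control for determinism
                best_j, best_d = j, d
                break
            j += 1
        if best_j >= 0 and best_d <= caliper:
            alive[best_j] = False
            pairs.append(
                MatchedPair(
                    pair_id=len(pairs),
                    treated_id=int(patient_ids[t_mask][ti]),
                    control_id=int(c_ids[best_j]),
                    treated_score=float(scores[t_mask][ti]),
                    control_score=float(c_scores[best_j]),
                )
            )
        else:
            unmatched.append(int(patient_ids[t_mask][ti]))
    return pairs, unmatched


def pairs_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "glargine_patient_id": p.treated_id,
                "exenatide_patient_id": p.control_id,
                "score_glargine": p.treated_score,
                "score_exenatide": p.control_score,
            }
            for p in pairs
        ],
        columns=[
            "pair_id",
            "glargine_patient_id",
            "exenatide_patient_id",
            "score_glargine",
            "score_exenatide",
        ],
    )


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------


def standardized_difference(
    values_treated: np.ndarray, values_control: np.ndarray, kind: str = "continuous"
) -> float:
    """Standardized mean/proportion difference on the x100 scale (signed).

    continuous: 100 (m1 - m0) / sqrt((s1^2 + s0^2) / 2); binary uses
    p(1 - p) variances.  Zero pooled variance with unequal means gives
    +/- inf with a warning.
    """
    x1 = np.asarray(values_treated, dtype=float)
    x0 = np.asarray(values_control, dtype=float)
    m1, m0 = x1.mean(), x0.mean()
    if kind == "binary":
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    else:
        v1, v0 = x1.var(ddof=1), x0.var(ddof=1)
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0:
        if m1 == m0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return float(np.inf if m1 > m0 else -np.inf)
    return float(100.0 * (m1 - m0) / pooled)


#: (column, kind) pairs summarised in the balance table
def _balance_spec(covariates: pd.DataFrame) -> list[tuple[str, str]]:
    spec: list[tuple[str, str]] = [
        ("age", "continuous"),
        ("sex_female", "binary"),
        ("microvascular", "binary"),
        ("macrovascular", "binary"),
        ("cci", "continuous"),
        ("med_claims", "continuous"),
        ("med_classes", "continuous"),
        ("inpatient_admission", "binary"),
        ("pre_index_cost", "continuous"),
    ]
    for col in ("region", "plan_type", "specialty"):
        for level in sorted(covariates[col].unique()):
            spec.append((f"{col}={level}", "indicator"))
    for c in covariates.columns:
        if c.startswith("pre_") and c != "pre_index_cost":
            spec.append((c, "binary"))
    return spec


def _column(covariates: pd.DataFrame, name: str) -> tuple[np.ndarray, str]:
    if "=" in name:
        col, level = name.split("=", 1)
        return (covariates[col] == level).to_numpy(float), "binary"
    return covariates[name].to_numpy(float), ""


def balance_table(
    covariates: pd.DataFrame,
    treatment: np.ndarray,
    pairs: Optional[list[MatchedPair]] = None,
) -> pd.DataFrame:
    """Pre- and post-match summaries with standardized differences.

    One row per covariate (categoricals expanded to level indicators):
    means/proportions per arm, the pre-match p-value (chi-square for
    indicators, Welch t-test for continuous), and |standardized difference|
    before and, when pairs are given, after matching.
    """
    treatment = np.asarray(treatment)
    if treatment.dtype.kind in "OUS":
        treatment = (treatment == drugs.GLARGINE).astype(int)
    cov = covariates.reset_index(drop=True)
    t_mask = treatment == 1

    post_idx = None
    if pairs is not None:
        by_id = pd.Series(cov.index, index=cov["patient_id"].to_numpy())
        t_ids = [p.treated_id for p in pairs]
        c_ids = [p.control_id for p in pairs]
        post_idx = (by_id[t_ids].to_numpy(), by_id[c_ids].to_numpy())

    rows = []
    for name, kind in _balance_spec(cov):
        x, forced = _column(cov, name)
        k = forced or kind
        k = "binary" if k == "indicator" else k
        x1, x0 = x[t_mask], x[~t_mask]
        if k == "binary":
            tab = np.array(
                [[x1.sum(), len(x1) - x1.sum()], [x0.sum(), len(x0) - x0.sum()]]
            )
            if tab[:, 0].sum() in (0, tab.sum()):
                p = 1.0
            else:
                p = float(stats.chi2_contingency(tab, correction=False)[1])
        else:
            p = float(stats.ttest_ind(x1, x0, equal_var=False).pvalue) if (
                len(np.unique(x)) > 1
            ) else 1.0
        row = {
            "covariate": name,
            "kind": k,
            "mean_glargine_pre": x1.mean(),
            "mean_exenatide_pre": x0.mean(),
            "p_value_pre": p,
            "std_diff_pre": abs(standardized_difference(x1, x0, k)),
        }
        if post_idx is not None:
            p1, p0 = x[post_idx[0]], x[post_idx[1]]
            row["mean_glargine_post"] = p1.mean()
            row["mean_exenatide_post"] = p0.mean()
            row["std_diff_post"] = abs(standardized_difference(p1, p0, k))
        rows.append(row)
    return pd.DataFrame(rows)
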