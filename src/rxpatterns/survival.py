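"""Time-to-modification analysis: Kaplan-Meier, log-rank, Cox regression.

These estimators are implemented directly (product-limit formula, the
classical two-group log-rank O-E summation, and Newton-Raphson partial
likelihood with Breslow or Efron tie handling) so that the score test at
beta = 0 — identical to the log-rank statistic under Breslow ties — and the
exact tie conventions are available and verifiable; day-granularity claims
data make ties ubiquitous, and Breslow is the default.

Per-type ("cause-specific") analyses treat competing modification types as
censored at their event day — the standard first-event reading of per-type
hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rxpatterns import drugs
from rxpatterns.classify import MOD_TYPES, summarize_modifications


class NoEventsError(ValueError):
    """A test or fit was requested on data with no events."""


class MonotoneLikelihoodError(RuntimeError):
    """The Cox partial likelihood has no maximum (arms fully separated)."""


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    se: float
    z: float
    p_value: float
    ties: str
    iterations: int


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("no records")
    if (t <= 0).any():
        raise ValueError("non-positive times are not valid survival times")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    surv = np.empty(len(event_times))
    s = 1.0
    for i, et in enumerate(event_times):
        at_risk[i] = int((t >= et).sum())
        d[i] = int((t[e] == et).sum())
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KMCurve(event_times, surv, at_risk, d)


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank: ((sum O1 - E1)^2 / sum V), p from chi2(1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if g.dtype.kind in "OUS":
        g = (g == drugs.GLARGINE).astype(int)
    if not ((g == 0).any() and (g == 1).any()):
        raise ValueError("both groups must be non-empty")
    if not e.any():
        raise NoEventsError("log-rank is undefined with no events")
    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        dead = e & (t == et)
        d = dead.sum()
        d1 = (dead & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise NoEventsError("log-rank variance is zero")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, optional strata)
# ---------------------------------------------------------------------------


def _cox_derivatives(
    beta: float,
    t: np.ndarray,
    e: np.ndarray,
    x: np.ndarray,
    ties: str,
) -> tuple[float, float, float]:
    """(log partial likelihood, score U, information I) at beta."""
    order = np.argsort(-t, kind="mergesort")  # descending time
    t, e, x = t[order], e[order], x[order]
    w = np.exp(beta * x)
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(w * x)
    cs2 = np.cumsum(w * x * x)
    loglik = score = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        last = j - 1  # risk set at this time = rows 0..last
        dead = [k for k in range(i, j) if e[k]]
        d = len(dead)
        if d:
            s0, s1, s2 = cs0[last], cs1[last], cs2[last]
            xsum = sum(x[k] for k in dead)
            if ties == "breslow":
                loglik += beta * xsum - d * np.log(s0)
                score += xsum - d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # efron
                wd = sum(w[k] for k in dead)
                wxd = sum(w[k] * x[k] for k in dead)
                wxxd = sum(w[k] * x[k] * x[k] for k in dead)
                loglik += beta * xsum
                for r in range(d):
                    f = r / d
                    s0r = s0 - f * wd
                    s1r = s1 - f * wxd
                    s2r = s2 - f * wxxd
                    loglik -= np.log(s0r)
                    score += xsum / d - s1r / s0r
                    info += s2r / s0r - (s1r / s0r) ** 2
        i = j
    return loglik, score, info


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    covariate: Sequence[float],
    ties: str = "breslow",
    strata: Optional[Sequence[int]] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Newton-Raphson partial-likelihood fit for one covariate.

    ``covariate`` may be the arm indicator (glargine = 1) or any numeric
    column; ``strata`` enables a stratified partial likelihood (for
    matched-pair-stratified sensitivity analyses).  Convergence requires
    |score| < tol; monotone likelihood raises
    :class:`MonotoneLikelihoodError`.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x_raw = np.asarray(covariate)
    x = (
        (x_raw == drugs.GLARGINE).astype(float)
        if x_raw.dtype.kind in "OUS"
        else x_raw.astype(float)
    )
    if not e.any():
        raise NoEventsError("cannot fit a Cox model with no events")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be breslow or efron")

    if strata is None:
        parts = [(t, e, x)]
    else:
        s = np.asarray(strata)
        parts = [(t[s == v], e[s == v], x[s == v]) for v in np.unique(s)]

    beta = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        score = info = 0.0
        for tp, ep, xp in parts:
            _, u, i_ = _cox_derivatives(beta, tp, ep, xp, ties)
            score += u
            info += i_
        if info <= 0:
            raise MonotoneLikelihoodError("zero information: covariate constant among events")
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        # |log HR| beyond ~15 means the likelihood is flattening toward a
        # boundary (events fully separated by the covariate), not converging
        if abs(beta) > 15:
            raise MonotoneLikelihoodError(
                "partial likelihood is monotone (all events ordered by arm)"
            )
        if abs(score) < tol:
            break
    else:
        raise MonotoneLikelihoodError(f"Newton iteration did not converge in {max_iter} steps")

    info = sum(_cox_derivatives(beta, *p, ties)[2] for p in parts)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    return CoxResult(
        log_hr=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        z=float(z),
        p_value=float(2 * stats.norm.sf(abs(z))),
        ties=ties,
        iterations=it,
    )


def cox_score_test(
    times: Sequence[float],
    events: Sequence[bool],
    covariate: Sequence[float],
    ties: str = "breslow",
) -> float:
    """Score statistic U(0)^2 / I(0); equals the log-rank chi-square for a
    binary covariate under Breslow ties."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    _, u, i_ = _cox_derivatives(0.0, t, e, x, ties)
    if i_ == 0:
        raise NoEventsError("zero information at beta = 0")
    return float(u * u / i_)


# ---------------------------------------------------------------------------
# Arm comparison bundle
# ---------------------------------------------------------------------------


def survival_records(
    events: pd.DataFrame, outcome: str = "any", horizon: int = 545
) -> pd.DataFrame:
    """(time, event, arm) per patient for one outcome.

    ``outcome`` "any": any modification is the event.  A specific type:
    competing types censor at their own event day (cause-specific hazards).
    """
    if outcome == "any":
        ev = events["mod_type"] != "censored"
    else:
        if outcome not in MOD_TYPES:
            raise ValueError(f"unknown outcome: {outcome}")
        ev = events["mod_type"] == outcome
    return pd.DataFrame(
        {
            "patient_id": events["patient_id"],
            "time": events["days_to_event"].astype(float),
            "event": ev.to_numpy(),
            "arm": events["arm"],
        }
    )


def compare_arms(
    events: pd.DataFrame,
    cutoffs: Sequence[int] = (180, 365, 545),
    ties: str = "breslow",
    pair_strata: Optional[pd.Series] = None,
) -> dict:
    """KM curves, log-rank, and Cox HR for overall and per-type modification.

    Returns a nested dict: per outcome, per-arm KM frames, the log-rank
    (statistic, p), and the Cox hazard ratio (glargine vs exenatide) with
    95% CI, plus the frequency-and-timing summary table.
    """
    horizon = int(events["days_to_event"].max())
    out: dict = {"outcomes": {}, "summary": summarize_modifications(events, cutoffs)}
    arms = sorted(events["arm"].unique())
    for outcome in ("any",) + MOD_TYPES:
        rec = survival_records(events, outcome, horizon)
        entry: dict = {"km": {}}
        for arm in arms:
            sub = rec[rec["arm"] == arm]
            entry["km"][arm] = km_estimate(sub["time"], sub["event"]).frame()
        n_events = rec.groupby("arm")["event"].sum()
        if (n_events > 0).all() and len(n_events) == 2:
            chi2, p = logrank_test(rec["time"], rec["event"], rec["arm"])
            entry["logrank"] = {"chi2": chi2, "p": p}
            try:
                strata = None
                if pair_strata is not None:
                    strata = pair_strata.loc[rec["patient_id"]].to_numpy()
                cox = cox_fit(rec["time"], rec["event"], rec["arm"], ties=ties, strata=strata)
                entry["cox"] = {
                    "hr": cox.hr,
                    "log_hr": cox.log_hr,
                    "se": cox.se,
                    "p": cox.p_value,
                    "ci_low": float(np.exp(cox.log_hr - 1.96 * cox.se)),
                    "ci_high": float(np.exp(cox.log_hr + 1.96 * cox.se)),
                    "ties": cox.ties,
                }
            except (MonotoneLikelihoodError, NoEventsError) as exc:
                entry["cox"] = {"error": str(exc)}
        else:
            entry["logrank"] = {"error": "an arm has no events of this type"}
            entry["cox"] = {"error": "unestimable: an arm has no events of this type"}
        out["outcomes"][outcome] = entry
    return out
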