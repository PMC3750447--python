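"""Independent brute-force oracles used to validate the analysis engines.

These deliberately re-derive results from first principles with naive
scans (day-by-day application of the modification definitions, explicit
O-E tables for the log-rank test) and share no code with the package's
rule engine or survival module.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

PRIORITY = {"intensification": 0, "switch": 1, "discontinuation": 2}


def classify_day_scan(
    claims: Sequence[tuple[int, str, int, float]],
    index_drug: str,
    pre_classes: set[str],
    gap: int = 90,
    horizon: int = 545,
    dose_threshold: float = 2.0,
) -> tuple[str, int, Optional[str]]:
    """Day-by-day literal application of the modification definitions.

    ``claims``: (fill_day, drug_class, days_supply, units) in days since
    index (only glucose-lowering classes).  Returns
    (mod_type, event_day, detail) with censoring at the horizon.
    """
    # merge same-day same-class fills: units summed, longest supply kept
    merged: dict[tuple[int, str], list] = {}
    for d, c, s, u in claims:
        key = (int(d), c)
        u = 0.0 if (u is None or (isinstance(u, float) and math.isnan(u))) else float(u)
        if key in merged:
            merged[key][0] = max(merged[key][0], int(s))
            merged[key][1] += u
        else:
            merged[key] = [int(s), u]
    rows = [(d, c, s, u) for (d, c), (s, u) in sorted(merged.items())]

    idx = [(d, s, u) for d, c, s, u in rows if c == index_drug and s > 0]
    idx_days = [d for d, _, _ in idx]
    non = [(d, c, s) for d, c, s, u in rows if c != index_drug and d > 0]

    def index_fill_in(lo: int, hi: int) -> bool:
        return any(lo < d <= hi for d in idx_days)

    def non_fill_in(lo: int, hi: int, cls: Optional[str] = None) -> bool:
        return any(lo < d <= hi for d, c, _ in non if cls is None or c == cls)

    # glargine daily-dose series from merged index fills
    dose_events = []
    if index_drug == "glargine":
        doses = []
        for k in range(len(idx) - 1):
            elapsed = idx[k + 1][0] - idx[k][0]
            doses.append(idx[k][2] / elapsed if elapsed > 0 else float("nan"))
        for k in range(len(doses) - 1):
            if doses[k] > 0 and doses[k + 1] / doses[k] >= dose_threshold:
                dose_events.append(idx[k + 1][0])
                break

    candidates: list[tuple[int, int, str, Optional[str]]] = []
    for day in range(1, horizon + 1):
        # discontinuation dated at this day?
        for f, s, _ in idx:
            if f + s != day:
                continue
            if index_fill_in(f, day + gap):
                continue
            if day + gap > horizon:
                continue
            if not non_fill_in(day, day + gap):
                candidates.append((day, PRIORITY["discontinuation"], "discontinuation", None))
        # switch dated at this day?
        for d, c, _ in non:
            if d != day:
                continue
            for f, s, _ in idx:
                r = f + s
                if not (r < day <= r + gap):
                    continue
                if index_fill_in(f, r + gap):
                    continue
                if non_fill_in(day, day + gap, c):
                    candidates.append((day, PRIORITY["switch"], "switch", c))
        # add-on intensification dated at this day?
        for d, c, s in non:
            if d != day or c in pre_classes or s <= 0:
                continue
            if not non_fill_in(day, day + s + gap, c):
                continue
            for f, si, _ in idx:
                r = f + si
                overlap = d < r and f < d + s
                if overlap and index_fill_in(f, r + gap):
                    candidates.append((day, PRIORITY["intensification"], "intensification", c))
                    break
        for de in dose_events:
            if de == day:
                candidates.append((day, PRIORITY["intensification"], "intensification", "dose_increase"))

    if not candidates:
        return ("censored", horizon, None)
    # earliest day; intensification > switch > discontinuation on ties;
    # among same-day same-type candidates, an added class beats the dose
    # rule and class names order lexicographically
    def key(c):
        day, prio, _, detail = c
        return (day, prio, detail == "dose_increase", detail or "")

    day, _, mod, detail = min(candidates, key=key)
    return (mod, day, detail)


def logrank_by_hand(
    times: Sequence[float], events: Sequence[bool], groups: Sequence[int]
) -> float:
    """Two-group log-rank chi-square via explicit per-event-time 2x2 tables."""
    data = list(zip(times, events, groups))
    event_times = sorted({t for t, e, _ in data if e})
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        risk = [(t, e, g) for t, e, g in data if t >= et]
        n = len(risk)
        n1 = len([1 for t, e, g in risk if g == 1])
        d = len([1 for t, e, g in risk if e and t == et])
        d1 = len([1 for t, e, g in risk if e and t == et and g == 1])
        o_minus_e += d1 - d * (n1 / n)
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ZeroDivisionError("no log-rank variance")
    return o_minus_e * o_minus_e / var


def km_by_hand(times: Sequence[float], events: Sequence[bool]) -> list[tuple[float, float]]:
    """(event_time, S(t)) pairs via the product-limit recursion."""
    data = sorted(zip(times, events))
    s = 1.0
    out = []
    for et in sorted({t for t, e in data if e}):
        n = len([1 for t, _ in data if t >= et])
        d = len([1 for t, e in data if e and t == et])
        s *= 1 - d / n
        out.append((et, s))
    return out
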