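"""Idle/active phase decomposition and per-procedure metrics.

An annotated procedure is transformed into alternating *active phases*
(time covered by at least one gesture bout, after taking the union of
possibly-overlapping bouts from different robotic arms) and *idle phases*
(the internal gaps between consecutive active phases, where instrument
activity was minimal).  The procedure clock runs from the first annotated
start to the last annotated stop: leading un-annotated recording is not
idle time.

Per-procedure metrics: total duration, idle percentage, mean idle-phase
duration, phase counts, mean active-phase duration and per-gesture total
times (raw bout durations, so simultaneous gestures on different arms each
count toward their own totals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventLogError, Gesture, GestureEvent, Group, Module, ProcedureLog

FEATURE_COLUMNS = [
    "total_duration_s",
    "idle_pct",
    "idle_phase_mean_s",
    "n_idle_phases",
    "n_active_phases",
    "active_phase_mean_s",
]
GESTURE_COLUMNS = [f"gesture_s_{g.value}" for g in Gesture]

#: Metrics summarised in the group table, in publication order.
TABLE_METRICS = [
    "total_duration_s",
    "idle_phase_mean_s",
    "idle_pct",
    "active_phase_mean_s",
    "n_active_phases",
]


@dataclass(frozen=True)
class PhaseFeatures:
    """Per-procedure idle/active metrics.

    ``idle_phase_mean_s`` is ``None`` when the procedure has no idle phase.
    Active and idle durations always sum to ``total_duration_s``.
    """

    total_duration_s: float
    idle_pct: float
    idle_phase_mean_s: float | None
    n_idle_phases: int
    n_active_phases: int
    active_phase_mean_s: float
    gesture_total_s: dict[Gesture, float]


def merge_active_intervals(
    events: Iterable[GestureEvent],
) -> list[tuple[float, float]]:
    """Union of all event intervals as maximal disjoint intervals.

    Touching intervals (one stops exactly where the next starts) merge into
    a single active phase.  Order of the input events is irrelevant.
    """
    intervals = sorted((e.start_s, e.stop_s) for e in events)
    if not intervals:
        raise EventLogError("cannot merge an empty event list")
    merged = [list(intervals[0])]
    for start, stop in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [(a, b) for a, b in merged]


def extract_features(log: ProcedureLog) -> PhaseFeatures:
    """Compute the per-procedure metrics for one log."""
    active = merge_active_intervals(log.events)
    total = active[-1][1] - active[0][0]
    active_durs = np.array([b - a for a, b in active])
    idle_durs = np.array(
        [active[i + 1][0] - active[i][1] for i in range(len(active) - 1)]
    )
    idle_total = float(idle_durs.sum())
    gesture_total = {g: 0.0 for g in Gesture}
    for ev in log.events:
        gesture_total[ev.gesture] += ev.duration_s
    return PhaseFeatures(
        total_duration_s=float(total),
        idle_pct=100.0 * idle_total / total if total > 0 else 0.0,
        idle_phase_mean_s=float(idle_durs.mean()) if len(idle_durs) else None,
        n_idle_phases=int(len(idle_durs)),
        n_active_phases=int(len(active)),
        active_phase_mean_s=float(active_durs.mean()),
        gesture_total_s=gesture_total,
    )


def features_table(logs: Sequence[ProcedureLog]) -> pd.DataFrame:
    """Feature extraction over many logs -> tidy per-procedure table.

    One row per procedure with identification columns
    (participant_id, group, module, repetition) followed by the phase
    metrics and the five per-gesture total times.
    """
    records = []
    for log in logs:
        f = extract_features(log)
        rec = {
            "participant_id": log.participant_id,
            "group": log.group.value,
            "module": log.module.value,
            "repetition": log.repetition,
            "total_duration_s": f.total_duration_s,
            "idle_pct": f.idle_pct,
            "idle_phase_mean_s": np.nan
            if f.idle_phase_mean_s is None
            else f.idle_phase_mean_s,
            "n_idle_phases": f.n_idle_phases,
            "n_active_phases": f.n_active_phases,
            "active_phase_mean_s": f.active_phase_mean_s,
        }
        for g in Gesture:
            rec[f"gesture_s_{g.value}"] = f.gesture_total_s[g]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_participants(
    features: pd.DataFrame, overall: str = "module_mean"
) -> pd.DataFrame:
    """Average each participant's repetitions, per module and overall.

    Every analysis downstream is based on these repetition averages.  The
    ``overall`` row pools a participant's modules either with equal module
    weight (``"module_mean"``: mean of the per-module means, the default —
    this is the aggregation that makes a pooled group table internally
    consistent with its per-module rows) or with equal procedure weight
    (``"procedure_mean"``).

    Returns a long table with a ``module`` column in which the pooled row is
    labelled ``"overall"``.
    """
    if features.empty:
        raise EventLogError("empty feature table")
    if overall not in ("module_mean", "procedure_mean"):
        raise ValueError(f"unknown overall rule {overall!r}")
    value_cols = [c for c in features.columns if c in FEATURE_COLUMNS + GESTURE_COLUMNS]
    per_module = (
        features.groupby(["participant_id", "group", "module"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    if overall == "module_mean":
        pooled = (
            per_module.groupby(["participant_id", "group"], sort=True)[value_cols]
            .mean()
            .reset_index()
        )
    else:
        pooled = (
            features.groupby(["participant_id", "group"], sort=True)[value_cols]
            .mean()
            .reset_index()
        )
    pooled.insert(2, "module", "overall")
    return pd.concat([per_module, pooled], ignore_index=True)


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-sample t-test with explicit handling of degenerate variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0  # perfectly separated constants
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def group_table(
    summaries: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Group mean (SD) per metric, per module and overall, with two-sample
    t-tests comparing novices and experienced surgeons.

    ``summaries`` is the output of :func:`summarize_participants`.  The
    classical equal-variance t-test is the default; ``equal_var=False``
    switches to Welch.
    """
    rows = []
    for module, sub in summaries.groupby("module", sort=False):
        nov = sub[sub["group"] == Group.NOVICE.value]
        exp = sub[sub["group"] == Group.EXPERIENCED.value]
        if len(nov) < 2 or len(exp) < 2:
            raise EventLogError(
                f"module {module}: each group needs >= 2 participants "
                f"(got {len(nov)} novice, {len(exp)} experienced)"
            )
        for metric in TABLE_METRICS:
            a = nov[metric].dropna().to_numpy()
            b = exp[metric].dropna().to_numpy()
            t, p = _ttest(a, b, equal_var)
            rows.append(
                {
                    "module": module,
                    "metric": metric,
                    "novice_mean": a.mean(),
                    "novice_sd": a.std(ddof=1),
                    "experienced_mean": b.mean(),
                    "experienced_sd": b.std(ddof=1),
                    "t": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
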