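"""Snail tracks: one-dimensional gesture-occupancy heat maps.

A procedure's clock is rescaled to [0, 1] (first annotated start to last
annotated stop) and divided into ``n_bins`` equal bins.  For each gesture,
a bin's occupancy is the fraction of the bin's span covered by that
gesture's bouts (same-gesture overlaps unioned first), giving a
gesture x bin matrix with entries in [0, 1].  Averaging these matrices over
a group's procedures (element-wise, on the normalised clock — procedures
differ in length) yields the group's mean temporal gesture distribution:
rendered as stacked coloured strips these are the *snail tracks*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventLogError, Gesture, Group, Module, ProcedureLog
from .phases import merge_active_intervals

DEFAULT_N_BINS = 200


@dataclass(frozen=True)
class SnailTrack:
    """Mean gesture x time-bin occupancy for a group on one module."""

    module: Module
    group: Group | None  # None when the averaged logs mix groups
    n_bins: int
    occupancy: np.ndarray  # shape (5 gestures, n_bins), cells in [0, 1]
    n_procedures: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy,
            index=[g.value for g in Gesture],
            columns=[f"bin_{i}" for i in range(self.n_bins)],
        )


def _binned_coverage(
    intervals: list[tuple[float, float]], t0: float, span: float, n_bins: int
) -> np.ndarray:
    """Fraction of each of n_bins equal bins of [t0, t0+span] covered."""
    cover = np.zeros(n_bins)
    width = span / n_bins
    for a, b in intervals:
        lo = (a - t0) / width
        hi = (b - t0) / width
        first = max(int(np.floor(lo)), 0)
        last = min(int(np.ceil(hi)), n_bins)
        for i in range(first, last):
            cover[i] += max(0.0, min(hi, i + 1) - max(lo, i))
    return np.clip(cover, 0.0, 1.0)


def occupancy_track(log: ProcedureLog, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Gesture x bin occupancy matrix of one procedure on its normalised clock."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    merged_all = merge_active_intervals(log.events)
    t0 = merged_all[0][0]
    span = merged_all[-1][1] - t0
    if span <= 0:
        raise EventLogError("procedure has zero span")
    out = np.zeros((len(Gesture), n_bins))
    for gi, gesture in enumerate(Gesture):
        evs = [e for e in log.events if e.gesture is gesture]
        if not evs:
            continue
        intervals = merge_active_intervals(evs)
        out[gi] = _binned_coverage(intervals, t0, span, n_bins)
    return out


def group_track(
    logs: list[ProcedureLog], n_bins: int = DEFAULT_N_BINS
) -> SnailTrack:
    """Element-wise mean of the individual occupancy tracks of one module."""
    if not logs:
        raise EventLogError("group_track needs at least one log")
    modules = {log.module for log in logs}
    if len(modules) > 1:
        raise EventLogError(f"mixed modules in group_track: {sorted(m.value for m in modules)}")
    groups = {log.group for log in logs}
    group = groups.pop() if len(groups) == 1 else None
    tracks = np.stack([occupancy_track(log, n_bins) for log in logs])
    return SnailTrack(
        module=modules.pop(),
        group=group,
        n_bins=n_bins,
        occupancy=tracks.mean(axis=0),
        n_procedures=len(logs),
    )
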