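"""Expert-referenced z-scoring and contrasting-groups standard setting.

Each procedure's per-gesture total times are transformed into z-scores
against the experienced group's distribution for that gesture and
part-procedure (pooled over the experienced surgeons' repetitions):
``z = (x - mu_ref) / sigma_ref``.  A participant's cells are averaged into
one composite, and the sign is flipped (``performance_score = -mean_z``) so
that taking longer than the reference maps to a lower score: experienced
surgeons centre near zero and slower novices fall on the negative side, the
orientation in which a pass/fail cutoff in SD units reads naturally.

The pass/fail cutoff is set by the contrasting-groups method: a normal
distribution is fitted to each group's composite scores and the cutoff is
placed where the two densities intersect between the group means.
Classification quality is reported as sensitivity (% of the fail group
below the cutoff), specificity (% of the pass group at or above it), false
positives (novices passing) and false negatives (experienced failing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import Group
from .phases import GESTURE_COLUMNS


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ZScoreResult:
    participant_id: str
    group: Group
    cell_z: dict[tuple[str, str, int], float]  # (gesture, module, repetition) -> z
    mean_z: float
    performance_score: float
    excluded_cells: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class CutoffResult:
    """Contrasting-groups cutoff and its classification quality.

    ``cutoff`` is in composite-score units; ``cutoff_sd`` re-expresses it as
    standard deviations from the pass group's mean.  ``fit`` holds the
    per-group fitted normal parameters.
    """

    cutoff: float
    cutoff_sd: float
    fit: dict[str, tuple[float, float]]
    sensitivity: float
    specificity: float
    false_positives: int
    false_negatives: int


def gesture_zscores(
    features: pd.DataFrame,
    reference_group: Group = Group.EXPERIENCED,
    min_ref: int = 2,
) -> list[ZScoreResult]:
    """Per-cell z-scores of gesture total times against a reference group.

    Reference mean and SD are computed per (gesture, module) from the
    reference group's procedures pooled over repetitions.  Cells whose
    reference SD is zero (a gesture unused by the reference in a module)
    are excluded from every participant's composite, with a warning.
    """
    ref = features[features["group"] == reference_group.value]
    if ref.empty:
        raise ScoringError(f"no procedures from reference group {reference_group}")

    ref_stats: dict[tuple[str, str], tuple[float, float]] = {}
    excluded: list[tuple[str, str]] = []
    for module, sub in ref.groupby("module", sort=False):
        for col in GESTURE_COLUMNS:
            gesture = col.removeprefix("gesture_s_")
            vals = sub[col].to_numpy(dtype=float)
            if len(vals) < min_ref:
                raise ScoringError(
                    f"reference group has {len(vals)} procedures for "
                    f"({gesture}, {module}); need >= {min_ref}"
                )
            mu, sd = float(vals.mean()), float(vals.std(ddof=1))
            if sd == 0:
                excluded.append((gesture, module))
                warnings.warn(
                    f"cell ({gesture}, {module}) excluded: zero reference SD",
                    stacklevel=2,
                )
            else:
                ref_stats[(gesture, module)] = (mu, sd)

    results = []
    for (pid, group), sub in features.groupby(["participant_id", "group"], sort=True):
        cells: dict[tuple[str, str, int], float] = {}
        for _, row in sub.iterrows():
            for col in GESTURE_COLUMNS:
                gesture = col.removeprefix("gesture_s_")
                key = (gesture, row["module"])
                if key not in ref_stats:
                    continue
                mu, sd = ref_stats[key]
                cells[(gesture, row["module"], int(row["repetition"]))] = (
                    float(row[col]) - mu
                ) / sd
        if not cells:
            raise ScoringError(f"participant {pid} has no defined z-score cells")
        mean_z = float(np.mean(list(cells.values())))
        results.append(
            ZScoreResult(
                participant_id=pid,
                group=Group(group),
                cell_z=cells,
                mean_z=mean_z,
                performance_score=-mean_z,
                excluded_cells=tuple(excluded),
            )
        )
    return results


def _density_intersection(
    mu1: float, sd1: float, mu2: float, sd2: float
) -> float:
    """Root of N(mu1, sd1) = N(mu2, sd2) lying between the two means.

    Equal SDs give the midpoint in closed form; otherwise the quadratic from
    equating log-densities is solved and the root between the means kept.
    When the SDs differ so much that the densities do not cross between the
    means (the wider density dominates throughout the gap), the cutoff falls
    back to the equal-standardised-distance point
    ``(mu1*sd2 + mu2*sd1) / (sd1 + sd2)``, which always lies strictly
    between the means and coincides with the crossing point as the SDs
    approach each other.
    """
    if mu1 == mu2:
        raise ScoringError("group means are identical: no cutoff between means")
    lo, hi = min(mu1, mu2), max(mu1, mu2)
    if np.isclose(sd1, sd2):
        return (mu1 + mu2) / 2.0
    a = 1.0 / (2 * sd2**2) - 1.0 / (2 * sd1**2)
    b = mu1 / sd1**2 - mu2 / sd2**2
    c = mu2**2 / (2 * sd2**2) - mu1**2 / (2 * sd1**2) + np.log(sd2 / sd1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    between = [r for r in roots if lo < r < hi]
    if not between:
        warnings.warn(
            "densities do not intersect between the group means; using the "
            "equal-standardised-distance cutoff",
            stacklevel=3,
        )
        return (mu1 * sd2 + mu2 * sd1) / (sd1 + sd2)
    return float(between[0])


def contrasting_groups_cutoff(
    fail_group_scores: Sequence[float],
    pass_group_scores: Sequence[float],
) -> CutoffResult:
    """Contrasting-groups pass/fail standard from two score samples.

    ``fail_group_scores`` come from the group that should fail (novices),
    ``pass_group_scores`` from the group that should pass (experienced).
    A score passes iff it is at or above the cutoff.
    """
    fail = np.asarray(fail_group_scores, dtype=float)
    pas = np.asarray(pass_group_scores, dtype=float)
    if len(fail) < 2 or len(pas) < 2:
        raise ScoringError("each group needs >= 2 scores to fit a normal")
    mu_f, sd_f = float(fail.mean()), float(fail.std(ddof=1))
    mu_p, sd_p = float(pas.mean()), float(pas.std(ddof=1))
    if sd_f == 0 or sd_p == 0:
        raise ScoringError("zero variance in a group: cannot fit a normal")
    cutoff = _density_intersection(mu_f, sd_f, mu_p, sd_p)
    sensitivity = 100.0 * float((fail < cutoff).mean())
    specificity = 100.0 * float((pas >= cutoff).mean())
    return CutoffResult(
        cutoff=cutoff,
        cutoff_sd=(cutoff - mu_p) / sd_p,
        fit={"fail": (mu_f, sd_f), "pass": (mu_p, sd_p)},
        sensitivity=sensitivity,
        specificity=specificity,
        false_positives=int((fail >= cutoff).sum()),
        false_negatives=int((pas < cutoff).sum()),
    )


def classify(scores: Sequence[float], cutoff: float) -> list[str]:
    """Label each score "pass" iff it is at or above the cutoff."""
    if not np.isfinite(cutoff):
        raise ScoringError("cutoff must be finite")
    return ["pass" if s >= cutoff else "fail" for s in np.asarray(scores, dtype=float)]


def standard_set(
    zresults: Sequence[ZScoreResult],
    fail_group: Group = Group.NOVICE,
    pass_group: Group = Group.EXPERIENCED,
) -> CutoffResult:
    """Contrasting-groups standard from per-participant composites."""
    fail = [r.performance_score for r in zresults if r.group is fail_group]
    pas = [r.performance_score for r in zresults if r.group is pass_group]
    return contrasting_groups_cutoff(fail, pas)
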