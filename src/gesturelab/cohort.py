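"""Semi-Markov simulator of gesture event logs for two skill groups.

A procedure is generated as an alternating sequence of *active phases*
(annotated gesture bouts) and *idle gaps*.  The number of active phases is
Poisson (truncated at one), phase and gap durations are lognormal
(moment-matched to a target mean/SD, giving positive, right-skewed task
times), and each boundary between consecutive phases carries an idle gap
with probability ``p_gap``.  ``p_gap`` is calibrated in closed form so the
expected idle share of the procedure matches the group's target idle
percentage; when the target is unattainable with the given phase counts and
durations the probability clips at 1.

Participant-level heterogeneity enters as one multiplicative lognormal
``subject_effect`` per participant (mean 1, coefficient of variation
``between_subject_cv``) applied to every duration, and practice enters as a
per-repetition multiplicative ``learning_factor`` (< 1 means durations
shrink with each repetition).

Default parameters are the published group x part-procedure summary
statistics for simulated robot-assisted radical prostatectomy (novice and
experienced surgeons across bladder-neck dissection, neurovascular-bundle
dissection and urethrovesical anastomosis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .events import CohortDesign, Gesture, GestureEvent, Group, Module, ProcedureLog

__all__ = [
    "ModuleParams",
    "GeneratorParams",
    "calibrate_gaps",
    "sample_procedure",
    "sample_cohort",
    "default_params",
    "completer_design",
    "study_design",
]


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class ModuleParams:
    """Duration/count parameters for one skill group on one part-procedure.

    Units: seconds for durations, counts for phases, percent for
    ``idle_pct_target``.
    """

    n_active_mean: float
    active_dur_mean_s: float
    active_dur_sd_s: float
    idle_dur_mean_s: float
    idle_dur_sd_s: float
    idle_pct_target: float
    gesture_mix: Mapping[Gesture, float]

    def __post_init__(self) -> None:
        for name in ("n_active_mean", "active_dur_mean_s", "idle_dur_mean_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("active_dur_sd_s", "idle_dur_sd_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 < self.idle_pct_target < 100:
            raise ParameterError("idle_pct_target must be in (0, 100)")
        total = sum(self.gesture_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"gesture_mix must sum to 1, sums to {total}")
        if any(p < 0 for p in self.gesture_mix.values()):
            raise ParameterError("gesture_mix probabilities must be >= 0")


# Published group summary rows (mean idle-phase duration and SD, idle share of
# the procedure, mean active-phase duration and SD, mean phase count) for each
# part-procedure; these are the generator's defaults.
_TABLE_ROWS: dict[tuple[Group, Module], tuple[float, float, float, float, float, float]] = {
    # (idle_mean, idle_sd, idle_pct, active_mean, active_sd, n_phases)
    (Group.NOVICE, Module.BLADDER_NECK): (15, 5, 40.0, 10, 3, 39),
    (Group.NOVICE, Module.NEUROVASCULAR_BUNDLE): (20, 5, 64.0, 9, 3, 47),
    (Group.NOVICE, Module.ANASTOMOSIS): (29, 6, 83.0, 12, 2, 48),
    (Group.EXPERIENCED, Module.BLADDER_NECK): (13, 5, 45.0, 10, 3, 26),
    (Group.EXPERIENCED, Module.NEUROVASCULAR_BUNDLE): (14, 5, 59.0, 8, 2, 27),
    (Group.EXPERIENCED, Module.ANASTOMOSIS): (16, 4, 84.0, 7, 2, 51),
}

#: Default gesture mixes: dissection gestures in the dissection modules (clip
#: application only during neurovascular-bundle dissection), needle handling
#: and suturing in the anastomosis.
DEFAULT_GESTURE_MIX: dict[Module, dict[Gesture, float]] = {
    Module.BLADDER_NECK: {
        Gesture.REGULAR_DISSECTION: 0.75,
        Gesture.HEMOSTATIC_CONTROL: 0.25,
    },
    Module.NEUROVASCULAR_BUNDLE: {
        Gesture.REGULAR_DISSECTION: 0.70,
        Gesture.HEMOSTATIC_CONTROL: 0.25,
        Gesture.CLIP_APPLICATION: 0.05,
    },
    Module.ANASTOMOSIS: {
        Gesture.NEEDLE_HANDLING: 0.50,
        Gesture.SUTURING: 0.50,
    },
}


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterisation of the cohort simulator.

    ``between_subject_cv`` is the coefficient of variation of the
    participant-level duration multiplier (0 disables heterogeneity);
    ``learning_factor`` maps each group to the per-repetition duration
    scaling (1 disables practice effects).
    """

    modules: Mapping[tuple[Group, Module], ModuleParams]
    between_subject_cv: float = 0.25
    learning_factor: Mapping[Group, float] = field(
        default_factory=lambda: {Group.NOVICE: 0.85, Group.EXPERIENCED: 0.95}
    )

    def __post_init__(self) -> None:
        if self.between_subject_cv < 0:
            raise ParameterError("between_subject_cv must be >= 0")
        for g, lf in self.learning_factor.items():
            if not 0 < lf <= 1:
                raise ParameterError(f"learning_factor[{g}] must be in (0, 1]")

    def cell(self, group: Group, module: Module) -> ModuleParams:
        try:
            return self.modules[(group, module)]
        except KeyError:
            raise ParameterError(f"no parameters for ({group}, {module})") from None

    def with_learning(self, novice: float, experienced: float) -> "GeneratorParams":
        return replace(
            self,
            learning_factor={Group.NOVICE: novice, Group.EXPERIENCED: experienced},
        )


def default_params(
    between_subject_cv: float = 0.25,
    learning_factor: Mapping[Group, float] | None = None,
) -> GeneratorParams:
    """Generator parameterised by the published group summary statistics."""
    modules = {}
    for (group, module), row in _TABLE_ROWS.items():
        idle_m, idle_sd, idle_pct, act_m, act_sd, n = row
        modules[(group, module)] = ModuleParams(
            n_active_mean=n,
            active_dur_mean_s=act_m,
            active_dur_sd_s=act_sd,
            idle_dur_mean_s=idle_m,
            idle_dur_sd_s=idle_sd,
            idle_pct_target=idle_pct,
            gesture_mix=dict(DEFAULT_GESTURE_MIX[module]),
        )
    kwargs = {} if learning_factor is None else {"learning_factor": dict(learning_factor)}
    return GeneratorParams(
        modules=modules, between_subject_cv=between_subject_cv, **kwargs
    )


def calibrate_gaps(params: ModuleParams) -> float:
    """Gap probability making the expected idle share match the target.

    With ``n`` active phases of mean duration ``a`` and up to ``n - 1`` idle
    gaps of mean duration ``g`` placed independently with probability
    ``p``, the expected idle fraction is ``p(n-1)g / (na + p(n-1)g)``.
    Solving for the target fraction ``f`` gives
    ``p = (f / (1 - f)) * n * a / (g * (n - 1))``, clipped to [0, 1].
    """
    n = params.n_active_mean
    if n <= 1:
        raise ParameterError(
            "calibrate_gaps requires n_active_mean > 1 (no boundaries for gaps)"
        )
    f = params.idle_pct_target / 100.0
    raw = (f / (1.0 - f)) * (n * params.active_dur_mean_s) / (
        params.idle_dur_mean_s * (n - 1.0)
    )
    return float(min(max(raw, 0.0), 1.0))


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_durations(
    rng: np.random.Generator, n: int, mean: float, sd: float, scale: float
) -> np.ndarray:
    """n lognormal durations with mean ``mean * scale`` and the CV of (mean, sd)."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, mean * scale)
    mu, sigma = _lognormal_moments(mean * scale, (sd / mean) * mean * scale)
    return rng.lognormal(mu, sigma, size=n)


def sample_procedure(
    params: GeneratorParams,
    group: Group,
    module: Module,
    repetition: int,
    subject_effect: float,
    rng: np.random.Generator,
    n_active: int | None = None,
) -> ProcedureLog:
    """Generate one procedure log.

    All durations are scaled by
    ``subject_effect * learning_factor[group] ** (repetition - 1)``.
    ``n_active`` overrides the Poisson phase-count draw (used for
    deterministic tests); otherwise the count is Poisson truncated at >= 1.
    Events are laid down left to right from t = 0 and never overlap.
    """
    if subject_effect <= 0:
        raise ParameterError("subject_effect must be > 0")
    mp = params.cell(group, module)
    scale = subject_effect * params.learning_factor[group] ** (repetition - 1)

    if n_active is None:
        n_active = 0
        while n_active < 1:
            n_active = int(rng.poisson(mp.n_active_mean))
    if n_active < 1:
        raise ParameterError("n_active must be >= 1")

    p_gap = calibrate_gaps(mp) if mp.n_active_mean > 1 else 0.0
    active = _draw_durations(
        rng, n_active, mp.active_dur_mean_s, mp.active_dur_sd_s, scale
    )
    has_gap = rng.random(max(n_active - 1, 0)) < p_gap
    gaps = np.zeros(max(n_active - 1, 0))
    n_gaps = int(has_gap.sum())
    gaps[has_gap] = _draw_durations(
        rng, n_gaps, mp.idle_dur_mean_s, mp.idle_dur_sd_s, scale
    )

    gestures_list = list(mp.gesture_mix)
    probs = np.array([mp.gesture_mix[g] for g in gestures_list])
    labels = rng.choice(len(gestures_list), size=n_active, p=probs)

    events = []
    t = 0.0
    for i in range(n_active):
        start = t
        stop = t + float(active[i])
        events.append(
            GestureEvent(gesture=gestures_list[labels[i]], start_s=start, stop_s=stop)
        )
        t = stop
        if i < n_active - 1:
            t += float(gaps[i])

    return ProcedureLog(
        participant_id="anon",
        group=group,
        module=module,
        repetition=repetition,
        events=tuple(events),
    )


def completer_design(n_novices: int = 10, n_experienced: int = 6) -> CohortDesign:
    """Design with only completers: every module x repetition cell exists."""
    groups: dict[str, Group] = {}
    for i in range(1, n_novices + 1):
        groups[f"N{i:02d}"] = Group.NOVICE
    for i in range(1, n_experienced + 1):
        groups[f"E{i:02d}"] = Group.EXPERIENCED
    return CohortDesign(groups=groups)


def study_design() -> CohortDesign:
    """The enrolled cohort: 11 novices and 9 experienced surgeons, of whom
    10 and 6 completed all three repetitions of all three part-procedures.
    Non-completers are assigned only the first repetition of each module."""
    groups: dict[str, Group] = {}
    for i in range(1, 12):
        groups[f"N{i:02d}"] = Group.NOVICE
    for i in range(1, 10):
        groups[f"E{i:02d}"] = Group.EXPERIENCED
    partial = frozenset((m, 1) for m in Module)
    mask = {pid: partial for pid in ("N11", "E07", "E08", "E09")}
    return CohortDesign(groups=groups, completion_mask=mask)


def sample_cohort(
    design: CohortDesign,
    params: GeneratorParams,
    seed: int | np.random.SeedSequence,
) -> list[ProcedureLog]:
    """Generate every cell of the design; fully reproducible from the seed.

    One ``subject_effect`` is drawn per participant (lognormal, mean 1,
    CV = ``between_subject_cv``) and shared across all of that participant's
    procedures.
    """
    rng = np.random.default_rng(seed)
    module_order = {m: i for i, m in enumerate(Module)}
    logs: list[ProcedureLog] = []
    for pid in sorted(design.groups):
        group = design.groups[pid]
        cv = params.between_subject_cv
        if cv > 0:
            mu, sigma = _lognormal_moments(1.0, cv)
            subject_effect = float(rng.lognormal(mu, sigma))
        else:
            subject_effect = 1.0
        cells = sorted(
            design.completion_mask[pid], key=lambda c: (module_order[c[0]], c[1])
        )
        for module, rep in cells:
            log = sample_procedure(params, group, module, rep, subject_effect, rng)
            logs.append(replace(log, participant_id=pid))
    return logs
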