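"""End-to-end pipeline: simulate or load event logs, then run every
analysis stage and write a consolidated report bundle.

A run is reproducible from (config, seed) alone.  Stages whose
preconditions are not met (e.g. reliability on a cohort without repeated
measurements) are skipped with a logged reason instead of aborting the
bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    GeneratorParams,
    ModuleParams,
    completer_design,
    default_params,
    sample_cohort,
)
from .events import Dialect, Gesture, Group, Module, read_event_log, sort_logs, write_event_log
from .phases import features_table, group_table, summarize_participants
from .progression import fit_progress
from .reliability import icc_by_module
from .scoring import classify, gesture_zscores, standard_set
from .snailtracks import DEFAULT_N_BINS, group_track

log = logging.getLogger("gesturelab")


@dataclass
class PipelineConfig:
    """Serializable configuration of a full analysis run."""

    simulate: bool = True
    input_path: str | None = None
    output_dir: str = "gesturelab_out"
    seed: int = 0
    n_novices: int = 10
    n_experienced: int = 6
    between_subject_cv: float = 0.25
    learning_factor_novice: float = 0.85
    learning_factor_experienced: float = 0.95
    equal_var_ttest: bool = True
    icc_score_field: str = "total_duration_s"
    pca_components: int = 2
    pca_per_module: bool = True
    n_bins: int = DEFAULT_N_BINS
    overall_rule: str = "module_mean"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def generator_params(self) -> GeneratorParams:
        return default_params(
            between_subject_cv=self.between_subject_cv,
            learning_factor={
                Group.NOVICE: self.learning_factor_novice,
                Group.EXPERIENCED: self.learning_factor_experienced,
            },
        )


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every analysis stage; write the report bundle to the output dir.

    Returns a manifest dict listing written artifacts and skipped stages.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    skipped: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    if config.simulate:
        design = completer_design(config.n_novices, config.n_experienced)
        logs = sample_cohort(design, config.generator_params(), config.seed)
        write_event_log(logs, out / "events.csv")
        written.append("events.csv")
    else:
        if not config.input_path:
            raise ValueError("input_path required when simulate is false")
        logs = sort_logs(read_event_log(config.input_path, Dialect()))

    features = features_table(logs)
    save(features, "features.csv")

    summaries = summarize_participants(features, overall=config.overall_rule)
    save(summaries, "participant_summaries.csv")

    both_groups = features["group"].nunique() == 2
    if both_groups and features.groupby("group")["participant_id"].nunique().min() >= 2:
        save(group_table(summaries, equal_var=config.equal_var_ttest), "group_table.csv")
    else:
        skipped["group_table"] = "needs >= 2 participants in each group"

    counts = features.groupby(["participant_id", "module"])["repetition"].nunique()
    if (
        features["repetition"].nunique() >= 2
        and (counts == counts.max()).all()
        and features["participant_id"].nunique() >= 2
    ):
        icc = icc_by_module(features, score_field=config.icc_score_field)
        icc_df = pd.DataFrame(
            [
                {"module": m, **asdict(r)}
                for m, r in icc.items()
            ]
        )
        save(icc_df, "icc.csv")
    else:
        skipped["reliability"] = "insufficient or unbalanced repetitions"

    if both_groups:
        try:
            zres = gesture_zscores(features)
            cutoff = standard_set(zres)
            scores = pd.DataFrame(
                {
                    "participant_id": [r.participant_id for r in zres],
                    "group": [r.group.value for r in zres],
                    "mean_z": [r.mean_z for r in zres],
                    "performance_score": [r.performance_score for r in zres],
                }
            )
            scores["label"] = classify(scores["performance_score"], cutoff.cutoff)
            save(scores, "scores.csv")
            with open(out / "standard_setting.json", "w") as fh:
                json.dump(
                    {
                        "cutoff": cutoff.cutoff,
                        "cutoff_sd": cutoff.cutoff_sd,
                        "fit": cutoff.fit,
                        "sensitivity": cutoff.sensitivity,
                        "specificity": cutoff.specificity,
                        "false_positives": cutoff.false_positives,
                        "false_negatives": cutoff.false_negatives,
                    },
                    fh,
                    indent=2,
                )
            written.append("standard_setting.json")
        except ValueError as exc:
            skipped["standard_setting"] = str(exc)
    else:
        skipped["standard_setting"] = "needs both skill groups"

    if len(features) >= 3 and both_groups:
        try:
            prog = fit_progress(
                features,
                n_components=config.pca_components,
                per_module=config.pca_per_module,
            )
            save(prog.coordinates, "pca_coordinates.csv")
            save(prog.magnitudes, "pca_magnitudes.csv")
            save(prog.group_stats, "pca_group_stats.csv")
        except ValueError as exc:
            skipped["progression_pca"] = str(exc)
    else:
        skipped["progression_pca"] = "needs >= 3 attempts and both groups"

    by_cell: dict[tuple[str, str], list] = {}
    for lg in logs:
        by_cell.setdefault((lg.group.value, lg.module.value), []).append(lg)
    for (grp, mod), cell_logs in sorted(by_cell.items()):
        track = group_track(cell_logs, n_bins=config.n_bins)
        name = f"snailtrack_{grp}_{mod}.csv"
        track.to_frame().to_csv(out / name)
        written.append(name)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "python": sys.version.split()[0],
        "n_logs": len(logs),
        "written": written,
        "skipped": skipped,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
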