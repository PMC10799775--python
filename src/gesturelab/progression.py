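"""Learning-trajectory metrics in a PCA plane.

Attempt-level feature vectors (phase metrics plus per-gesture totals) are
standardised and reduced to two principal components per part-procedure.
Two metrics describe progression in that plane:

* **distance to target** — Euclidean distance from an attempt's point to
  the centroid of the experienced group's attempts (the "target"
  performance region);
* **magnitude** — Euclidean distance between a participant's consecutive
  repetitions, the step length of their progress.

Both are invariant to the sign indeterminacy of principal components.
Groups are compared per module and pooled with independent t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .events import Group
from .phases import FEATURE_COLUMNS, GESTURE_COLUMNS, _ttest

#: Default attempt-level feature set entering the PCA.
DEFAULT_PCA_FEATURES = FEATURE_COLUMNS + GESTURE_COLUMNS


@dataclass
class ProgressResult:
    """PCA coordinates plus distance/magnitude metrics and group tests.

    ``coordinates``: one row per attempt with PC scores and
    ``distance_to_target``; ``magnitudes``: one row per consecutive
    repetition pair; ``group_stats``: per-module and pooled group means with
    t statistics and p-values; ``explained_variance_ratio``: per module.
    """

    coordinates: pd.DataFrame
    magnitudes: pd.DataFrame
    group_stats: pd.DataFrame
    explained_variance_ratio: dict[str, np.ndarray] = field(default_factory=dict)


def _prepare_matrix(
    sub: pd.DataFrame, feature_cols: list[str]
) -> tuple[np.ndarray, list[str]]:
    x = sub[feature_cols].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing feature cells; impute or drop before PCA")
    keep = []
    for j, col in enumerate(feature_cols):
        if x[:, j].std() == 0:
            warnings.warn(f"constant feature column {col!r} dropped", stacklevel=3)
        else:
            keep.append(j)
    if len(keep) < 2:
        raise ValueError("need >= 2 non-constant feature columns")
    x = x[:, keep]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x, [feature_cols[j] for j in keep]


def fit_progress(
    features: pd.DataFrame,
    n_components: int = 2,
    feature_cols: list[str] | None = None,
    per_module: bool = True,
    target_group: Group = Group.EXPERIENCED,
    equal_var: bool = True,
) -> ProgressResult:
    """Fit PCA per module (or pooled) and compute progression metrics.

    ``features`` is an attempt-level table (one row per participant x
    module x repetition).  Feature columns are z-standardised over all
    attempts in a fit; the target is the centroid of ``target_group``'s
    attempts in the component plane.
    """
    feature_cols = list(feature_cols or DEFAULT_PCA_FEATURES)
    feature_cols = [c for c in feature_cols if c in features.columns]
    if len(features) < 3:
        raise ValueError("need >= 3 attempts to fit a PCA")

    groups = [("all", features)] if not per_module else list(
        features.groupby("module", sort=False)
    )
    coord_frames = []
    evr: dict[str, np.ndarray] = {}
    for module, sub in groups:
        sub = sub.reset_index(drop=True)
        x, kept = _prepare_matrix(sub, feature_cols)
        if n_components > len(kept):
            raise ValueError(
                f"n_components={n_components} exceeds {len(kept)} usable features"
            )
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(x)
        evr[str(module)] = pca.explained_variance_ratio_
        target = scores[sub["group"] == target_group.value].mean(axis=0)
        dist = np.linalg.norm(scores - target, axis=1)
        frame = sub[["participant_id", "group", "module", "repetition"]].copy()
        for c in range(n_components):
            frame[f"pc{c + 1}"] = scores[:, c]
        frame["distance_to_target"] = dist
        coord_frames.append(frame)
    coordinates = pd.concat(coord_frames, ignore_index=True)

    mag_rows = []
    pc_cols = [f"pc{c + 1}" for c in range(n_components)]
    for (pid, group, module), sub in coordinates.groupby(
        ["participant_id", "group", "module"], sort=True
    ):
        sub = sub.sort_values("repetition")
        pts = sub[pc_cols].to_numpy()
        reps = sub["repetition"].to_numpy()
        for i in range(len(sub) - 1):
            if reps[i + 1] == reps[i] + 1:
                mag_rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "module": module,
                        "from_repetition": int(reps[i]),
                        "to_repetition": int(reps[i + 1]),
                        "magnitude": float(np.linalg.norm(pts[i + 1] - pts[i])),
                    }
                )
    magnitudes = pd.DataFrame(mag_rows)

    stat_rows = []
    modules = list(coordinates["module"].unique()) + ["overall"]
    for module in modules:
        for metric, table, col in (
            ("distance_to_target", coordinates, "distance_to_target"),
            ("magnitude", magnitudes, "magnitude"),
        ):
            sub = table if module == "overall" else table[table["module"] == module]
            nov = sub[sub["group"] == Group.NOVICE.value][col].to_numpy()
            exp = sub[sub["group"] == Group.EXPERIENCED.value][col].to_numpy()
            if len(nov) < 2 or len(exp) < 2:
                continue
            t, p = _ttest(nov, exp, equal_var)
            stat_rows.append(
                {
                    "module": module,
                    "metric": metric,
                    "novice_mean": nov.mean(),
                    "experienced_mean": exp.mean(),
                    "t": t,
                    "p": p,
                }
            )
    return ProgressResult(
        coordinates=coordinates,
        magnitudes=magnitudes,
        group_stats=pd.DataFrame(stat_rows),
        explained_variance_ratio=evr,
    )
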