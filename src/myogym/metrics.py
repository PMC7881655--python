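"""EMG pattern-quality metrics.

Consistency and separability of the per-movement feature clouds are
summarised by three centroid-based quantities in the normalized feature
space:

* **WD** (within-class distance): per class, the mean distance of its
  vectors to the class centroid, averaged over classes. Lower means more
  consistent contractions.
* **IDNN** (inter-class distance, nearest neighbour): per class, the
  distance from its centroid to the closest other centroid, averaged over
  classes.
* **IDAN** (inter-class distance, all neighbours): per class, the mean
  distance from its centroid to every other centroid, averaged over
  classes. IDNN <= IDAN always; higher means more separable patterns.

The distance is Euclidean by default with a pooled-covariance Mahalanobis
variant behind ``metric="mahalanobis"``. The spider-plot profile -- the
per-channel RMS of each movement, the simplified feature-space view used
for coaching -- is exported as a table.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .recording import EmgRecording, Procedure


def _distance_fn(groups: Mapping[str, np.ndarray], metric: str):
    if metric == "euclidean":
        return lambda a, b: float(np.linalg.norm(np.asarray(a) - np.asarray(b)))
    if metric == "mahalanobis":
        pooled = np.vstack([np.asarray(v, float) for v in groups.values()])
        cov = np.cov(pooled, rowvar=False)
        vi = np.linalg.pinv(np.atleast_2d(cov))

        def mahal(a, b):
            d = np.asarray(a, float) - np.asarray(b, float)
            return float(np.sqrt(max(d @ vi @ d, 0.0)))

        return mahal
    raise ValueError(f"unknown metric {metric!r}")


def _validate(groups: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for label, X in groups.items():
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 0:
            raise ValueError(f"class {label!r} is empty")
        out[label] = X
    return out


def within_class_distance(
    groups: Mapping[str, np.ndarray], metric: str = "euclidean"
) -> tuple[float, dict[str, float]]:
    """Mean distance of each class's vectors to its centroid (WD).

    Returns the mean over classes and the per-class breakdown.
    """
    groups = _validate(groups)
    dist = _distance_fn(groups, metric)
    per_class = {}
    for label, X in groups.items():
        centroid = X.mean(axis=0)
        per_class[label] = float(np.mean([dist(x, centroid) for x in X]))
    return float(np.mean(list(per_class.values()))), per_class


def interclass_distances(
    groups: Mapping[str, np.ndarray], metric: str = "euclidean"
) -> tuple[float, float, dict[str, dict[str, float]]]:
    """Centroid separability: (IDNN, IDAN, per-class breakdown).

    Requires at least two classes; with exactly two, IDNN equals IDAN.
    """
    groups = _validate(groups)
    if len(groups) < 2:
        raise ValueError(
            "inter-class distances require at least 2 movement classes, "
            f"got {len(groups)}"
        )
    dist = _distance_fn(groups, metric)
    centroids = {label: X.mean(axis=0) for label, X in groups.items()}
    per_class = {}
    for label, mu in centroids.items():
        others = [dist(mu, mv) for k, mv in centroids.items() if k != label]
        per_class[label] = {
            "nearest": float(min(others)),
            "all": float(np.mean(others)),
        }
    idnn = float(np.mean([v["nearest"] for v in per_class.values()]))
    idan = float(np.mean([v["all"] for v in per_class.values()]))
    return idnn, idan, per_class


def labelled_features(
    recordings: Iterable[EmgRecording],
    normalizer: ft.Normalizer | None = None,
    plateau_only: bool = True,
    feature_config=None,
) -> dict[str, np.ndarray]:
    """Group normalized Hudgins features by movement label.

    Plateau windows only by default (the sustained part of each trapezoid
    trial, where the contraction represents the movement). If no normalizer
    is supplied, one is fitted on the pooled features of this input.
    """
    from .regressor import FeatureConfig

    fc = feature_config or FeatureConfig()
    groups: dict[str, list[np.ndarray]] = {}
    for rec in recordings:
        wins = (
            ft.plateau_windows(rec, fc.window_ms, fc.step_ms)
            if plateau_only
            else ft.segment_windows(rec, fc.window_ms, fc.step_ms)
        )
        if not wins:
            continue
        groups.setdefault(rec.movement, []).append(
            ft.feature_matrix(wins, fc.zc_threshold, fc.ssc_threshold)
        )
    stacked = {m: np.vstack(v) for m, v in groups.items()}
    if not stacked:
        raise ValueError("no plateau windows found in the supplied recordings")
    if normalizer is None:
        normalizer = ft.Normalizer().fit(np.vstack(list(stacked.values())))
    return {m: normalizer.transform(X) for m, X in stacked.items()}


def metric_report(
    procedures: Sequence[Procedure],
    metric: str = "euclidean",
    feature_config=None,
) -> pd.DataFrame:
    """Per-procedure WD/IDNN/IDAN table; session values are the column means.

    Rest and MVC trials are excluded: the metrics describe the graded
    movement patterns the regressor must separate.
    """
    rows = []
    for proc in procedures:
        recs = [r for r in proc.recordings
                if r.movement != "rest" and r.level < 1.0]
        groups = labelled_features(recs, feature_config=feature_config)
        wd, _ = within_class_distance(groups, metric)
        idnn, idan, _ = interclass_distances(groups, metric)
        rows.append(
            {"procedure": proc.index, "posture": proc.posture,
             "wd": wd, "idnn": idnn, "idan": idan}
        )
    return pd.DataFrame(rows)


def session_summary(report: pd.DataFrame) -> dict[str, float]:
    """Session means of the three metrics from a :func:`metric_report`."""
    return {
        "wd": float(report["wd"].mean()),
        "idnn": float(report["idnn"].mean()),
        "idan": float(report["idan"].mean()),
    }


def spider_profile(
    recordings: Iterable[EmgRecording],
    feature_config=None,
) -> pd.DataFrame:
    """Per-movement mean 8-channel plateau RMS (the coaching spider plot).

    Rows are movements, columns ``channel_1`` .. ``channel_8``.
    """
    from .regressor import FeatureConfig

    fc = feature_config or FeatureConfig()
    acc: dict[str, list[np.ndarray]] = {}
    for rec in recordings:
        wins = ft.plateau_windows(rec, fc.window_ms, fc.step_ms)
        acc.setdefault(rec.movement, []).extend(
            ft.channel_rms(w) for w in wins
        )
    rows = {}
    for movement, values in acc.items():
        if not values:
            raise ValueError(
                f"movement {movement!r} has no plateau windows"
            )
        rows[movement] = np.mean(values, axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"channel_{i + 1}" for i in range(8)],
    )
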