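"""Feed-forward regression from EMG features to movement strengths.

The network maps a z-normalized 32-dimensional Hudgins feature vector to one
nonnegative strength per trained movement (up to seven: fine pinch, lateral
pinch, wrist rotation CW/CCW, wrist flexion/extension, hand open). The
architecture is fixed: two fully connected hidden layers of 50 and 25 units,
each followed by tanh, and a linear output layer. Training minimises mean
squared error with Adam on mini-batches of 64 windows, with early stopping
on a randomly held-out 10% validation split.

Regression targets are built from the trapezoidal force reference of each
recording: the reference value (fraction of MVC) at the window's end time on
the prompted movement's output, zero on all other outputs, and all-zero for
rest recordings.

Training is delegated to scikit-learn's ``MLPRegressor``; the fitted weights
are copied out and inference runs through an explicit forward pass, so a
serialized model is a plain JSON document independent of the trainer.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from . import features as ft
from .recording import MOVEMENTS, REST, EmgRecording

HIDDEN_SIZES = (50, 25)


@dataclass
class TrainConfig:
    """Training hyperparameters. Batch size and validation fraction follow
    the published recipe; patience, epoch budget and learning rate are
    config-exposed choices."""

    seed: int
    batch_size: int = 64
    validation_fraction: float = 0.10
    patience: int = 10
    max_epochs: int = 500
    learning_rate: float = 1e-3

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class FeatureConfig:
    """Windowing/feature parameters a model was trained with; stored in the
    model file so streaming inference reproduces them exactly."""

    window_ms: float = ft.WINDOW_MS
    step_ms: float = ft.STEP_MS
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0


def validation_split_size(n_samples: int, validation_fraction: float) -> int:
    """Number of windows held out for early stopping (10% of 1000 -> 100)."""
    return int(n_samples * validation_fraction)


def make_targets(
    recording: EmgRecording,
    movements: Sequence[str],
    window_ms: float = ft.WINDOW_MS,
    step_ms: float = ft.STEP_MS,
) -> np.ndarray:
    """Per-window regression targets from the recording's force reference.

    Returns an (n_windows, n_movements) array: the reference value at each
    window's final sample on the prompted movement's column, zero elsewhere.
    Rest recordings yield all-zero rows.
    """
    if recording.movement != REST and recording.movement not in movements:
        raise ValueError(
            f"recording movement {recording.movement!r} is not in the "
            f"trained movement list {list(movements)}"
        )
    windows = ft.segment_windows(recording, window_ms, step_ms)
    w = ft._to_samples(window_ms, recording.fs)
    Y = np.zeros((len(windows), len(movements)))
    if recording.movement == REST:
        return Y
    col = list(movements).index(recording.movement)
    for i, win in enumerate(windows):
        i0 = ft._to_samples(win.start_ms, recording.fs)
        Y[i, col] = recording.reference[i0 + w - 1]
    return Y


class EmgRegressor:
    """A trained movement-strength regressor plus its frozen normalizer.

    Attributes
    ----------
    movements : tuple of str
        Output ordering; length equals the number of output units.
    normalizer : Normalizer
        The z-scoring statistics frozen at fit time.
    weights, biases : lists of ndarray
        Layer parameters for the 32 -> 50 -> 25 -> n_outputs network.
    """

    def __init__(
        self,
        movements: Sequence[str],
        normalizer: ft.Normalizer,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        feature_config: FeatureConfig | None = None,
        train_config: TrainConfig | None = None,
        mvc_mav: dict[str, np.ndarray] | None = None,
    ):
        self.movements = tuple(movements)
        self.normalizer = normalizer
        self.weights = [np.asarray(w, float) for w in weights]
        self.biases = [np.asarray(b, float) for b in biases]
        self.feature_config = feature_config or FeatureConfig()
        self.train_config = train_config
        self.mvc_mav = mvc_mav or {}
        self.loss_curve_: list[float] = []
        self.validation_scores_: list[float] = []
        sizes = [w.shape for w in self.weights]
        if len(sizes) != 3 or sizes[0][1] != HIDDEN_SIZES[0] or sizes[1][1] != HIDDEN_SIZES[1]:
            raise ValueError(
                f"hidden layers must be {HIDDEN_SIZES}, got shapes {sizes}"
            )

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw (unrectified) network output for normalized features."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model input "
                f"size {self.weights[0].shape[0]}"
            )
        h = np.tanh(X @ self.weights[0] + self.biases[0])
        h = np.tanh(h @ self.weights[1] + self.biases[1])
        return h @ self.weights[2] + self.biases[2]

    def predict_strengths(self, fv: np.ndarray) -> np.ndarray:
        """Nonnegative movement strengths for normalized feature vector(s).

        Negative raw outputs are rectified to zero, enforcing the
        nonnegativity contract of the strength vector.
        """
        raw = self.forward(fv)
        out = np.maximum(raw, 0.0)
        return out[0] if np.asarray(fv).ndim == 1 else out

    def strengths_from_window(self, window: ft.Window) -> np.ndarray:
        """Features -> normalize -> predict, for one raw-signal window."""
        fc = self.feature_config
        fv = ft.hudgins_features(window, fc.zc_threshold, fc.ssc_threshold)
        return self.predict_strengths(self.normalizer.transform(fv[None, :])[0])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "movements": list(self.movements),
            "layer_sizes": [self.weights[0].shape[0], *HIDDEN_SIZES, self.n_outputs],
            "activations": ["tanh", "tanh", "linear"],
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "normalizer": self.normalizer.to_dict(),
            "feature_config": asdict(self.feature_config),
            "train_config": asdict(self.train_config) if self.train_config else None,
            "config_hash": self.train_config.hash() if self.train_config else None,
            "mvc_mav": {k: v.tolist() for k, v in self.mvc_mav.items()},
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()) + "\n")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "EmgRegressor":
        tc = TrainConfig(**d["train_config"]) if d.get("train_config") else None
        model = cls(
            movements=d["movements"],
            normalizer=ft.Normalizer.from_dict(d["normalizer"]),
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            feature_config=FeatureConfig(**d["feature_config"]),
            train_config=tc,
            mvc_mav={k: np.asarray(v) for k, v in d.get("mvc_mav", {}).items()},
        )
        return model

    @classmethod
    def load(cls, path: str | Path) -> "EmgRegressor":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_regressor(
    X: np.ndarray,
    Y: np.ndarray,
    movements: Sequence[str],
    config: TrainConfig,
    normalizer: ft.Normalizer | None = None,
    feature_config: FeatureConfig | None = None,
) -> EmgRegressor:
    """Fit the strength regressor on raw (unnormalized) features X.

    The normalizer is fitted on X unless one is supplied, then frozen into
    the returned model. Training is deterministic given ``config.seed``; the
    weights kept are those of the best validation epoch (early stopping).
    """
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    n = X.shape[0]
    n_val = validation_split_size(n, config.validation_fraction)
    if n - n_val < 2:
        raise ValueError(
            f"{n} windows leave fewer than 2 training samples after the "
            f"{config.validation_fraction:.0%} validation split"
        )
    if normalizer is None:
        normalizer = ft.Normalizer().fit(X)
    Xn = normalizer.transform(X)
    mlp = MLPRegressor(
        hidden_layer_sizes=HIDDEN_SIZES,
        activation="tanh",
        solver="adam",
        alpha=0.0,
        batch_size=min(config.batch_size, n - n_val),
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        shuffle=True,
        random_state=config.seed,
        early_stopping=True,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.patience,
    )
    with warnings.catch_warnings():
        # hitting the epoch budget is an accepted outcome, not a defect
        warnings.simplefilter("ignore")
        mlp.fit(Xn, Y)
    model = EmgRegressor(
        movements=movements,
        normalizer=normalizer,
        weights=[np.array(w) for w in mlp.coefs_],
        biases=[np.array(b).ravel() for b in mlp.intercepts_],
        feature_config=feature_config,
        train_config=config,
    )
    model.loss_curve_ = list(mlp.loss_curve_)
    model.validation_scores_ = list(mlp.validation_scores_)
    return model


def assemble_training_data(
    recordings: Iterable[EmgRecording],
    movements: Sequence[str],
    feature_config: FeatureConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Window every recording and stack (raw features, targets)."""
    fc = feature_config or FeatureConfig()
    xs, ys = [], []
    for rec in recordings:
        windows = ft.segment_windows(rec, fc.window_ms, fc.step_ms)
        if not windows:
            continue
        xs.append(ft.feature_matrix(windows, fc.zc_threshold, fc.ssc_threshold))
        ys.append(make_targets(rec, movements, fc.window_ms, fc.step_ms))
    if not xs:
        raise ValueError("no usable windows in the supplied recordings")
    return np.vstack(xs), np.vstack(ys)


def train_from_recordings(
    recordings: Iterable[EmgRecording],
    movements: Sequence[str],
    config: TrainConfig,
    feature_config: FeatureConfig | None = None,
) -> EmgRegressor:
    """End-to-end convenience: features + targets + fit, with MVC profiles.

    MVC trials (level 1.0) contribute per-movement mean-absolute-value
    channel profiles, stored on the model for force estimation.
    """
    from .protocols import mvc_mav_profiles  # local import avoids a cycle

    recordings = list(recordings)
    fc = feature_config or FeatureConfig()
    X, Y = assemble_training_data(recordings, movements, fc)
    model = train_regressor(X, Y, movements, config, feature_config=fc)
    model.mvc_mav = mvc_mav_profiles(recordings, fc)
    return model


def full_strengths(strengths: np.ndarray, movements: Sequence[str]) -> np.ndarray:
    """Expand an n-output strength vector to the canonical 7-slot layout,
    zero-filling movements the model was not trained on."""
    out = np.zeros(len(MOVEMENTS))
    for value, name in zip(np.asarray(strengths, float), movements):
        out[MOVEMENTS.index(name)] = value
    return out
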