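"""Target construction, training contract and prediction behaviour."""

import numpy as np
import pytest

import myogym
from myogym.features import Normalizer
from myogym.regressor import (
    EmgRegressor,
    TrainConfig,
    full_strengths,
    make_targets,
    train_regressor,
    validation_split_size,
)

MOVS = list(myogym.MOVEMENTS)


def _crafted_model(W3=None, b3=None, n_out=7):
    """A model with hand-set weights for deterministic prediction tests."""
    rng = np.random.default_rng(0)
    weights = [
        rng.standard_normal((32, 50)) * 0.1,
        rng.standard_normal((50, 25)) * 0.1,
        W3 if W3 is not None else rng.standard_normal((25, n_out)) * 0.1,
    ]
    biases = [np.zeros(50), np.zeros(25),
              b3 if b3 is not None else np.zeros(n_out)]
    norm = Normalizer()
    norm.mean_ = np.zeros(32)
    norm.scale_ = np.ones(32)
    return EmgRegressor(MOVS[:n_out], norm, weights, biases)


class TestMakeTargets:
    def setup_method(self):
        self.params = myogym.GeneratorParams(
            seed=2, noise=0.0, amplitude_jitter=0.0
        )

    def test_plateau_windows_carry_the_level(self):
        rec = myogym.generate_recording("fine_pinch", 0.6, self.params)
        Y = make_targets(rec, MOVS)
        wins = myogym.segment_windows(rec)
        plateau_rows = [
            i for i, w in enumerate(wins)
            if 1500 <= w.start_ms and w.start_ms + 128 <= 6000
        ]
        assert plateau_rows
        col = MOVS.index("fine_pinch")
        for i in plateau_rows:
            assert Y[i, col] == pytest.approx(0.6)
            assert np.all(Y[i, np.arange(7) != col] == 0)

    def test_ramp_targets_interpolate_linearly(self):
        rec = myogym.generate_recording("hand_open", 0.9, self.params)
        Y = make_targets(rec, MOVS)
        col = MOVS.index("hand_open")
        # window ending at 500 ms sits mid-ramp (1 s ramp to 0.9)
        wins = myogym.segment_windows(rec)
        idx = next(i for i, w in enumerate(wins) if w.start_ms == 350)
        end_s = (350 + 128 - 1) / 1000.0
        assert Y[idx, col] == pytest.approx(0.9 * end_s, abs=1e-3)

    def test_rest_recording_targets_are_zero(self):
        rec = myogym.generate_recording("rest", 0.0, self.params)
        assert np.all(make_targets(rec, MOVS) == 0)

    def test_unlisted_movement_rejected(self):
        rec = myogym.generate_recording("wrist_flexion", 0.3, self.params)
        with pytest.raises(ValueError, match="wrist_flexion"):
            make_targets(rec, ["fine_pinch", "hand_open"])


class TestTrainingContract:
    def test_validation_split_of_1000_holds_out_100(self):
        assert validation_split_size(1000, 0.10) == 100

    def test_too_few_windows_after_split_errors(self, rng):
        X = rng.standard_normal((2, 32))
        Y = rng.standard_normal((2, 2))
        with pytest.raises(ValueError, match="validation split"):
            train_regressor(X, Y, MOVS[:2],
                            TrainConfig(seed=0, validation_fraction=0.5))

    def test_same_seed_and_data_give_identical_weights(self, rng):
        X = rng.standard_normal((80, 32))
        Y = np.abs(rng.standard_normal((80, 2)))
        cfg = TrainConfig(seed=7, max_epochs=12, patience=3)
        m1 = train_regressor(X, Y, MOVS[:2], cfg)
        m2 = train_regressor(X, Y, MOVS[:2], cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_validation_improves_on_separable_data(self, tiny_two_movement_model):
        scores = tiny_two_movement_model.validation_scores_
        assert len(scores) >= 2
        assert max(scores) > scores[0]

    def test_hidden_sizes_are_locked(self):
        with pytest.raises(ValueError, match="hidden layers"):
            EmgRegressor(
                MOVS[:2], Normalizer(),
                weights=[np.zeros((32, 10)), np.zeros((10, 25)), np.zeros((25, 2))],
                biases=[np.zeros(10), np.zeros(25), np.zeros(2)],
            )


class TestPrediction:
    def test_zero_weight_model_outputs_zero_strengths(self):
        model = _crafted_model(W3=np.zeros((25, 7)))
        assert np.all(model.predict_strengths(np.ones(32)) == 0)

    def test_negative_raw_outputs_are_rectified(self):
        model = _crafted_model(W3=np.zeros((25, 2)),
                               b3=np.array([-0.2, 0.5]), n_out=2)
        out = model.predict_strengths(np.zeros(32))
        assert out.tolist() == [0.0, 0.5]

    def test_dimension_mismatch_errors(self):
        model = _crafted_model()
        with pytest.raises(ValueError, match="dimension"):
            model.predict_strengths(np.zeros(16))

    def test_forward_pass_is_lipschitz_bounded(self, rng):
        model = _crafted_model()
        L = np.prod([np.linalg.norm(w, 2) for w in model.weights])
        for _ in range(20):
            a, b = rng.standard_normal((2, 32))
            gap = np.linalg.norm(model.forward(a) - model.forward(b))
            assert gap <= L * np.linalg.norm(a - b) + 1e-9

    def test_full_strengths_places_outputs_by_movement_name(self):
        out = full_strengths([0.4, 0.7], ["wrist_flexion", "hand_open"])
        assert out[MOVS.index("wrist_flexion")] == 0.4
        assert out[MOVS.index("hand_open")] == 0.7
        assert out.sum() == pytest.approx(1.1)


class TestParameterRecovery:
    def test_orthogonal_patterns_recover_movement_argmax(
        self, trained_model, ortho_params, rng
    ):
        """Near-perfect held-out plateau argmax on noise-light orthogonal data."""
        correct = total = 0
        for m in MOVS:
            rec = myogym.generate_recording(m, 0.6, ortho_params, rng=rng)
            for w in myogym.plateau_windows(rec):
                s = trained_model.strengths_from_window(w)
                correct += trained_model.movements[int(np.argmax(s))] == m
                total += 1
        assert total > 500
        assert correct / total >= 0.99

    def test_predicted_strength_tracks_contraction_level(
        self, trained_model, ortho_params, rng
    ):
        col = trained_model.movements.index("wrist_flexion")
        means = []
        for lvl in myogym.LEVELS:
            rec = myogym.generate_recording(
                "wrist_flexion", lvl, ortho_params, rng=rng
            )
            vals = [
                trained_model.strengths_from_window(w)[col]
                for w in myogym.plateau_windows(rec)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]  # proportional control


def test_model_json_roundtrip(tmp_path, tiny_two_movement_model, rng):
    model = tiny_two_movement_model
    path = model.save(tmp_path / "model.json")
    back = myogym.EmgRegressor.load(path)
    X = rng.standard_normal((5, 32))
    assert np.allclose(back.predict_strengths(X), model.predict_strengths(X))
    assert back.movements == model.movements
    assert set(back.mvc_mav) == set(model.mvc_mav)
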