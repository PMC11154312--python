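import numpy as np
import pytest

from pulsegaze import face
from pulsegaze import synthetic as syn


def _landmarks(offset=(0.0, 0.0), angle=0.0):
    """A plausible 5-point face, optionally rotated then translated."""
    pts = {
        "left_eye": (-2.0, 0.0),
        "right_eye": (2.0, 0.0),
        "nose": (0.0, 2.0),
        "mouth_left": (-1.0, 4.0),
        "mouth_right": (1.0, 4.0),
    }
    c, s = np.cos(angle), np.sin(angle)
    out = {}
    for k, (x, y) in pts.items():
        out[k] = (c * x - s * y + offset[0], s * x + c * y + offset[1])
    return face.LandmarkSet(**out)


class TestEyeBoxes:
    def test_horizontal_eyes_have_zero_rotation(self):
        lm = face.LandmarkSet((0, 0), (4, 0), (2, 2), (1, 4), (3, 4))
        left, right = face.eye_boxes(lm)
        assert left.rotation == 0.0

    def test_diagonal_eyes_rotate_by_45_degrees(self):
        lm = face.LandmarkSet((0, 0), (4, 4), (2, 2), (1, 4), (3, 4))
        left, _ = face.eye_boxes(lm)
        assert left.rotation == pytest.approx(np.pi / 4)

    def test_box_dimensions_follow_interocular_distance(self):
        lm = face.LandmarkSet((0, 0), (4, 0), (2, 2), (1, 4), (3, 4))
        left, right = face.eye_boxes(lm, scale=0.6)
        assert left.width == pytest.approx(2.4)
        assert left.height == pytest.approx(1.2)  # h = w/2
        assert right.center == (4.0, 0.0)

    def test_coincident_eyes_rejected(self):
        lm = face.LandmarkSet((1, 1), (1, 1), (2, 2), (1, 4), (3, 4))
        with pytest.raises(ValueError):
            face.eye_boxes(lm)


class TestMouthBox:
    def test_known_geometry(self):
        lm = face.LandmarkSet((0, 0), (4, 0), (2, 1), (1, 3), (3, 3))
        box = face.mouth_box(lm)
        # nose is d=2 above the lip line: height 13d/6
        assert box.height == pytest.approx(13 / 3)
        assert box.width == pytest.approx(2.0)
        assert box.rotation == 0.0

    def test_translation_equivariance(self):
        a = face.mouth_box(_landmarks())
        b = face.mouth_box(_landmarks(offset=(10.0, 10.0)))
        assert b.center[0] == pytest.approx(a.center[0] + 10)
        assert b.center[1] == pytest.approx(a.center[1] + 10)
        assert b.width == pytest.approx(a.width)
        assert b.height == pytest.approx(a.height)

    def test_rotation_equivariance(self):
        theta = 0.3
        a = face.mouth_box(_landmarks())
        b = face.mouth_box(_landmarks(angle=theta))
        assert b.height == pytest.approx(a.height)
        assert b.width == pytest.approx(a.width)
        assert (b.rotation - a.rotation) == pytest.approx(theta)
        ae, _ = face.eye_boxes(_landmarks())
        be, _ = face.eye_boxes(_landmarks(angle=theta))
        assert (be.rotation - ae.rotation) == pytest.approx(theta)
        assert be.width == pytest.approx(ae.width)

    def test_height_scales_linearly_with_nose_distance(self):
        near = face.LandmarkSet((0, 0), (4, 0), (2, 2), (1, 3), (3, 3))
        far = face.LandmarkSet((0, 0), (4, 0), (2, 1), (1, 3), (3, 3))
        assert face.mouth_box(far).height == pytest.approx(2 * face.mouth_box(near).height)

    def test_nose_on_lip_line_rejected(self):
        lm = face.LandmarkSet((0, 0), (4, 0), (2, 3), (1, 3), (3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            face.mouth_box(lm)


class TestStateClassification:
    def test_fully_open_eyes_never_closed(self):
        states = face.classify_states(np.ones(100), np.zeros(100), eye_threshold=0.3)
        assert not states.eye_closed.any()

    def test_alternating_scores_close_half_the_frames(self):
        eye = np.tile([0.1, 0.9], 50)
        states = face.classify_states(eye, np.zeros(100), eye_threshold=0.3)
        assert int(states.eye_closed.sum()) == 50

    def test_brief_mouth_opening_is_not_a_yawn(self):
        mouth = np.zeros(50)
        mouth[10:12] = 1.0  # 2 frames < min run
        mouth[30:40] = 1.0  # sustained
        states = face.classify_states(np.ones(50), mouth, min_yawn_run=3)
        assert not states.mouth_yawn[10:12].any()
        assert states.mouth_yawn[30:40].all()

    def test_missing_scores_listed(self):
        eye = np.ones(10)
        eye[3] = np.nan
        with pytest.raises(ValueError, match="frames \\[3\\]"):
            face.classify_states(eye, np.zeros(10))

    def test_pluggable_classifier_wins(self):
        called = {}

        def cls(eye, mouth):
            called["yes"] = True
            return face.FrameStates(np.ones_like(eye, bool), np.zeros_like(eye, bool))

        states = face.classify_states(np.ones(5), np.zeros(5), classifier=cls)
        assert called and states.eye_closed.all()


class TestLandmarkIO:
    def test_csv_round_trip_and_box_export(self, tmp_path):
        import pandas as pd

        rows = []
        for f in range(3):
            lm = _landmarks(offset=(f, 0.0))
            rows.append({
                "frame": f,
                "lx": lm.left_eye[0], "ly": lm.left_eye[1],
                "rx": lm.right_eye[0], "ry": lm.right_eye[1],
                "nx": lm.nose[0], "ny": lm.nose[1],
                "mlx": lm.mouth_left[0], "mly": lm.mouth_left[1],
                "mrx": lm.mouth_right[0], "mry": lm.mouth_right[1],
            })
        path = tmp_path / "landmarks.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        lms = face.load_landmarks_csv(path)
        assert len(lms) == 3
        assert lms[1].nose[0] == pytest.approx(_landmarks(offset=(1, 0)).nose[0])
        boxes = face.boxes_to_frame(lms)
        assert len(boxes) == 9  # three regions per frame
        mouth_rows = boxes[boxes.region == "mouth"]
        np.testing.assert_allclose(mouth_rows.cx.diff().dropna(), 1.0)


class TestWindowRates:
    @pytest.mark.parametrize(
        "closed, yawn, p, l",
        [(0, 0, 0.0, 0.0), (360, 0, 0.30, 0.0), (300, 120, 0.25, 0.10)],
    )
    def test_exact_count_ratios(self, closed, yawn, p, l):
        e = np.zeros(1200, bool)
        e[:closed] = True
        m = np.zeros(1200, bool)
        m[:yawn] = True
        r = face.window_rates(face.FrameStates(e, m), 1200)
        assert r.perclos == p
        assert r.yawn_rate == l

    def test_underfull_window_rejected(self):
        states = face.FrameStates(np.zeros(100, bool), np.zeros(100, bool))
        with pytest.raises(ValueError):
            face.window_rates(states, 1200)

    def test_simulator_round_trip_is_exact_at_zero_noise(self):
        for seed in range(5):
            cfg = syn.EyeStateSimConfig(
                closed_fraction=0.22, yawn_fraction=0.08, score_noise_sd=0.0, seed=seed
            )
            _, _, eye_sc, mouth_sc, gt = syn.simulate_eye_state_stream(cfg)
            states = face.classify_states(eye_sc, mouth_sc)
            r = face.window_rates(states, cfg.n_frames)
            assert r.perclos == gt.true_perclos
            assert r.yawn_rate == gt.true_yawn_rate
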