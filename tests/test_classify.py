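"""Ball network training, frame classification rules, events, evaluation."""

import numpy as np
import pytest

from larvatrack import classify as cl
from larvatrack.features import FeatureFrame


# ---------------------------------------------------------------------------
# ball network
# ---------------------------------------------------------------------------


def _separable_set(n=200, seed=0):
    rng = np.random.default_rng(seed)
    balls = np.column_stack([rng.uniform(0.0, 0.3, n),       # eig_reduced
                             rng.uniform(1.0, 1.1, n),       # arc ratio
                             rng.uniform(0.85, 1.0, n)])     # area ratio
    nonballs = np.column_stack([rng.uniform(0.6, 1.0, n),
                                rng.uniform(1.0, 1.4, n),
                                rng.uniform(0.5, 0.9, n)])
    x = np.vstack([balls, nonballs])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    return x, y


class TestBallNetwork:
    def test_architecture(self):
        x, y = _separable_set()
        net = cl.train_ball_network(x, y, seed=1)
        assert net.w1.shape == (3, 5)
        assert net.w2.shape == (5, 1)

    def test_separable_accuracy(self):
        x, y = _separable_set()
        net = cl.train_ball_network(x, y, seed=1)
        acc = (net.predict(x) == y.astype(bool)).mean()
        assert acc >= 0.99

    def test_deterministic_given_seed(self):
        x, y = _separable_set()
        a = cl.train_ball_network(x, y, seed=7)
        b = cl.train_ball_network(x, y, seed=7)
        assert np.array_equal(a.w1, b.w1)
        assert np.array_equal(a.w2, b.w2)

    def test_single_class_rejected(self):
        x, y = _separable_set()
        with pytest.raises(ValueError):
            cl.train_ball_network(x, np.ones_like(y))

    def test_default_epochs_500(self):
        import inspect
        assert inspect.signature(cl.train_ball_network).parameters["epochs"].default == 500

    def test_save_load_roundtrip(self, tmp_path):
        x, y = _separable_set()
        net = cl.train_ball_network(x, y, seed=3)
        net.save(tmp_path / "ball.npz")
        back = cl.BallNetwork.load(tmp_path / "ball.npz")
        assert np.allclose(net.forward(x), back.forward(x))


# ---------------------------------------------------------------------------
# frame classification
# ---------------------------------------------------------------------------


def _ff(t, angle_deg=0.0, asym=0.0, tail_par=0.0, tail_raw=None,
        eig=0.9, arc=1.05, area=0.85, crab=0.0):
    """Hand-build a post-smoothing FeatureFrame for rule tests."""
    ang = np.deg2rad(angle_deg)
    v = {
        "angle_upper_lower_filtered": ang,
        "asymmetry_filtered": asym,
        "parallel_speed_tail_raw_filtered": tail_par,
        "parallel_speed_tail_raw": tail_par if tail_raw is None else tail_raw,
        "eig_reduced": eig, "eig_reduced_filtered": eig,
        "larva_arc_ratio": arc, "larva_area_ratio": area,
        "crab_speed_filtered": crab,
    }
    ff = FeatureFrame(time_s=t, values=v)
    ff.warm_up = False
    return ff


def _run(frames):
    clf = cl.BehaviorClassifier()
    return [clf.classify_frame(f) for f in frames]


class TestRules:
    def test_left_bend_detected(self):
        flags = _run([_ff(i * 0.05, angle_deg=40, asym=0.5) for i in range(30)])
        last = flags[-1]
        assert last.bend and last.left and not last.right

    def test_right_bend_detected(self):
        flags = _run([_ff(i * 0.05, angle_deg=40, asym=-0.5) for i in range(30)])
        last = flags[-1]
        assert last.bend and last.right and not last.left

    def test_left_right_never_both(self):
        rng = np.random.default_rng(0)
        frames = [_ff(i * 0.05, angle_deg=rng.uniform(0, 60),
                      asym=rng.uniform(-1, 1), tail_par=rng.uniform(-1, 1),
                      eig=rng.uniform(0, 1), crab=rng.uniform(-2, 2))
                  for i in range(300)]
        for fl in _run(frames):
            assert not (fl.left and fl.right)

    def test_bend_channel_is_smoothed(self):
        """A single above-threshold frame must not set the bend flag."""
        frames = [_ff(i * 0.05) for i in range(20)]
        frames[10] = _ff(0.5, angle_deg=45, asym=0.5)
        assert not any(fl.bend for fl in _run(frames))

    def test_forward_and_peristaltic(self):
        frames = [_ff(i * 0.05, tail_par=0.8, tail_raw=1.0) for i in range(20)]
        last = _run(frames)[-1]
        assert last.forward and last.forward_peristaltic

    def test_back_detected(self):
        frames = [_ff(i * 0.05, tail_par=-0.5) for i in range(20)]
        assert _run(frames)[-1].back

    def test_roll_suppresses_locomotion_for_1500ms(self):
        """After a roll, back/forward/forward_peristaltic stay reset for
        the following 1.5 s."""
        frames = []
        for i in range(20):   # rolling: C-shaped (not a closed ball), fast sideways
            frames.append(_ff(i * 0.05, eig=0.3, arc=1.3, area=0.7, crab=1.5))
        for i in range(20, 60):  # then backing up
            frames.append(_ff(i * 0.05, tail_par=-0.6))
        flags = _run(frames)
        roll_frames = [f.time_s for f in flags if f.roll]
        assert roll_frames, "roll must trigger"
        t_roll = max(roll_frames)
        for fl in flags:
            if t_roll < fl.time_s <= t_roll + 1.5:
                assert not (fl.back or fl.forward or fl.forward_peristaltic)
        late = [fl for fl in flags if fl.time_s > t_roll + 1.5]
        assert any(fl.back for fl in late)

    def test_ball_suppresses_back_and_forces_side(self):
        """A ball within the past 1.5 s vetoes back and locks the bend
        side to the last pre-ball direction."""
        frames = []
        for i in range(30):   # bending right
            frames.append(_ff(i * 0.05, angle_deg=40, asym=-0.5))
        for i in range(30, 40):  # ball (shape circular)
            frames.append(_ff(i * 0.05, eig=0.05, arc=1.02, area=0.97))
        for i in range(40, 55):  # bend geometry says left, but ball recent
            frames.append(_ff(i * 0.05, angle_deg=40, asym=+0.5,
                              tail_par=-0.6))
        flags = _run(frames)
        assert any(f.ball for f in flags[30:40])
        for fl in flags[40:55]:
            assert not fl.back
            if fl.bend:
                assert fl.right and not fl.left  # pre-ball side retained

    def test_warm_up_frames_yield_no_flags(self):
        ff = _ff(0.0, angle_deg=60, asym=1.0)
        ff.warm_up = True
        fl = cl.BehaviorClassifier().classify_frame(ff)
        assert not any([fl.bend, fl.left, fl.right, fl.ball, fl.back,
                        fl.forward, fl.forward_peristaltic, fl.roll])


# ---------------------------------------------------------------------------
# events and evaluation
# ---------------------------------------------------------------------------


def _flags(times_on, n=60, side="left"):
    out = []
    for i in range(n):
        f = cl.FrameFlags(time_s=i * 0.05)
        if i in times_on:
            f.bend = True
            setattr(f, side, True)
        out.append(f)
    return out


class TestEvents:
    def test_contiguous_run_single_event(self):
        evs = cl.extract_events(_flags(range(10, 30)))
        bends = [e for e in evs if e.behavior == "bend"]
        assert len(bends) == 1
        assert bends[0].t_start == pytest.approx(0.5)
        assert bends[0].t_end == pytest.approx(1.5)
        assert bends[0].side == "left"

    def test_alternating_single_frames(self):
        evs = cl.extract_events(_flags({10, 12, 14}))
        bends = [e for e in evs if e.behavior == "bend"]
        assert len(bends) == 3
        assert all(e.duration == pytest.approx(0.05) for e in bends)

    def test_empty(self):
        assert cl.extract_events([]) == []


class TestEvaluation:
    def _events(self, spec):
        return [cl.BehaviorEvent("bend", s, a, b) for (a, b, s) in spec]

    def test_perfect_predictions(self):
        t = self._events([(0, 1, "left"), (2, 3, "right")])
        table = cl.evaluate_classifiers(t, t)
        row = table[table.behavior == "bend"].iloc[0]
        assert row.precision == 1.0
        assert row.recall == 1.0
        assert row.side_accuracy == 1.0

    def test_counting_oracle(self):
        """8 of 10 truth events matched plus one spurious prediction:
        recall 0.8, precision 8/9."""
        truth = self._events([(i * 2, i * 2 + 1, "left") for i in range(10)])
        pred = self._events([(i * 2 + 0.2, i * 2 + 0.8, "left")
                             for i in range(8)])
        pred += self._events([(100, 101, "left")])  # spurious
        table = cl.evaluate_classifiers(pred, truth)
        row = table[table.behavior == "bend"].iloc[0]
        assert row.recall == pytest.approx(0.8)
        assert row.precision == pytest.approx(8 / 9)

    def test_split_wave_counted(self):
        truth = [cl.BehaviorEvent("forward_peristaltic", "", 0.0, 1.0)]
        pred = [cl.BehaviorEvent("forward_peristaltic", "", 0.0, 0.4),
                cl.BehaviorEvent("forward_peristaltic", "", 0.6, 1.0)]
        table = cl.evaluate_classifiers(pred, truth)
        row = table[table.behavior == "forward_peristaltic"].iloc[0]
        assert row.split_rate == pytest.approx(1.0)

    def test_combined_wave_counted(self):
        truth = [cl.BehaviorEvent("forward_peristaltic", "", 0.0, 1.0),
                 cl.BehaviorEvent("forward_peristaltic", "", 1.5, 2.5)]
        pred = [cl.BehaviorEvent("forward_peristaltic", "", 0.0, 2.5)]
        table = cl.evaluate_classifiers(pred, truth)
        row = table[table.behavior == "forward_peristaltic"].iloc[0]
        assert row.combined_rate == pytest.approx(1.0)

    def test_matching_is_one_to_one_greedy_by_overlap(self):
        truth = self._events([(0, 10, "left")])
        pred = self._events([(0, 6, "left"), (6.5, 10, "left")])
        pairs = cl.match_events(
            [p for p in pred], [t for t in truth])
        assert len(pairs) == 1
        assert pairs[0][0].t_end == 6  # larger overlap wins
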