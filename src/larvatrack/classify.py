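"""Per-frame behaviour classification and event-level evaluation.

Channels: bend (+ left/right side), ball, back, forward,
forward_peristaltic, roll.  The bend channel thresholds the temporally
smoothed body-bend angle and is itself exponentially smoothed before
thresholding; left/right are the bend flag AND-ed with the sign of the
smoothed asymmetry.  The ball detector is a tiny feed-forward network
(3 inputs -> 5 tanh units -> 1 sigmoid unit) over z-normalised
eig_reduced, larva_arc_ratio and larva_area_ratio.  Cross-suppression: a
ball within the previous 1.5 s forces the bend side to the last pre-ball
side and vetoes back/forward/roll; a roll within the previous 1.5 s
resets forward, forward_peristaltic and back.

All scalar thresholds are unpublished in the source system; the defaults
here are calibrated once against the bundled simulator and kept in
:class:`ClassifierThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields as dc_fields

import numpy as np
import pandas as pd

from .features import FeatureFrame, exp_smooth

SUPPRESSION_WINDOW_S = 1.5
FRAME_DT = 0.05


# ---------------------------------------------------------------------------
# ball network
# ---------------------------------------------------------------------------

BALL_INPUTS = ("eig_reduced", "larva_arc_ratio", "larva_area_ratio")


@dataclass
class BallNetwork:
    """3 -> 5 (tanh) -> 1 (sigmoid) feed-forward ball classifier."""

    w1: np.ndarray            # (3, 5)
    b1: np.ndarray            # (5,)
    w2: np.ndarray            # (5, 1)
    b2: np.ndarray            # (1,)
    mean: np.ndarray          # input normalisation, (3,)
    scale: np.ndarray         # input normalisation, (3,)
    threshold: float = 0.5

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(x) - self.mean) / self.scale
        h = np.tanh(x @ self.w1 + self.b1)
        z = h @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-z[:, 0]))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x) >= self.threshold

    def save(self, path) -> None:
        np.savez(path, **{f.name: getattr(self, f.name) for f in dc_fields(self)})

    @classmethod
    def load(cls, path) -> "BallNetwork":
        d = np.load(path)
        return cls(w1=d["w1"], b1=d["b1"], w2=d["w2"], b2=d["b2"],
                   mean=d["mean"], scale=d["scale"],
                   threshold=float(d["threshold"]))


def train_ball_network(features: np.ndarray, labels: np.ndarray,
                       epochs: int = 500, seed: int = 0,
                       learning_rate: float = 0.5) -> BallNetwork:
    """Train the ball network by full-batch gradient descent.

    ``features``: (n, 3) rows of (eig_reduced, larva_arc_ratio,
    larva_area_ratio); ``labels``: boolean ball annotation.  Minimises
    cross-entropy for ``epochs`` epochs; deterministic for a given seed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if x.ndim != 2 or x.shape[1] != len(BALL_INPUTS):
        raise ValueError("features must be (n, 3)")
    if y.min() == y.max():
        raise ValueError("both classes must be present in the training set")
    mean = x.mean(axis=0)
    scale = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
    xn = (x - mean) / scale

    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 0.5, size=(3, 5))
    b1 = np.zeros(5)
    w2 = rng.normal(0.0, 0.5, size=(5, 1))
    b2 = np.zeros(1)
    n = len(y)
    for _ in range(epochs):
        h = np.tanh(xn @ w1 + b1)
        p = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)[:, 0]))
        # cross-entropy gradient through the sigmoid output
        delta = (p - y)[:, None] / n
        g_w2 = h.T @ delta
        g_b2 = delta.sum(axis=0)
        dh = delta @ w2.T * (1.0 - h ** 2)
        g_w1 = xn.T @ dh
        g_b1 = dh.sum(axis=0)
        w2 -= learning_rate * g_w2
        b2 -= learning_rate * g_b2
        w1 -= learning_rate * g_w1
        b1 -= learning_rate * g_b1
    return BallNetwork(w1=w1, b1=b1, w2=w2, b2=b2, mean=mean, scale=scale)


def geometric_ball_score(eig_reduced: float, larva_arc_ratio: float,
                         larva_area_ratio: float) -> float:
    """Rule-based stand-in score used when no trained network is supplied:
    a ball is elongation-free (low eig_reduced) yet convex (area ratio
    near 1, arc ratio near 1)."""
    score = (1.0 - eig_reduced) * larva_area_ratio / max(larva_arc_ratio, 1.0)
    return float(score)


# ---------------------------------------------------------------------------
# frame classifier
# ---------------------------------------------------------------------------


@dataclass
class ClassifierThresholds:
    """Versioned default thresholds, calibrated once against the simulator."""

    bend_angle_rad: float = np.deg2rad(20.0)   # on angle_upper_lower_filtered
    bend_smooth_alpha: float = 0.2
    bend_on: float = 0.5                       # on the smoothed bend flag
    asymmetry_eps: float = 0.0                 # left/right sign cutoff
    back_tail_speed: float = -0.25             # mm/s, parallel_speed_tail_raw_filtered
    forward_tail_speed: float = 0.45           # mm/s, parallel_speed_tail_raw_filtered
    peristaltic_wave_speed: float = 0.90       # mm/s, instantaneous wave crest
    roll_eig_max: float = 0.55                 # ball-like shape ...
    roll_crab_speed: float = 0.60              # ... moving sideways (mm/s)
    roll_smooth_alpha: float = 0.2
    roll_on: float = 0.5
    ball_score_on: float = 0.52                # geometric fallback threshold
    suppression_s: float = SUPPRESSION_WINDOW_S


@dataclass
class FrameFlags:
    time_s: float
    bend: bool = False
    left: bool = False
    right: bool = False
    ball: bool = False
    back: bool = False
    forward: bool = False
    forward_peristaltic: bool = False
    roll: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


class BehaviorClassifier:
    """Stateful per-larva classifier applying the cross-suppression rules."""

    def __init__(self, thresholds: ClassifierThresholds | None = None,
                 ball_network: BallNetwork | None = None):
        self.th = thresholds or ClassifierThresholds()
        self.net = ball_network
        self.reset()

    def reset(self) -> None:
        self._bend_smooth = 0.0
        self._roll_smooth = 0.0
        self._last_ball_time = -np.inf
        self._last_roll_time = -np.inf
        self._last_side_before_ball = ""
        self._last_side = ""

    # -- helpers -----------------------------------------------------------
    def _ball_detected(self, ff: FeatureFrame) -> bool:
        x = np.array([ff["eig_reduced"], ff["larva_arc_ratio"],
                      ff["larva_area_ratio"]])
        if self.net is not None:
            return bool(self.net.predict(x)[0])
        return geometric_ball_score(*x) >= self.th.ball_score_on

    def classify_frame(self, ff: FeatureFrame) -> FrameFlags:
        th = self.th
        t = ff.time_s
        flags = FrameFlags(time_s=t)
        if not ff.valid or ff.warm_up:
            return flags

        ball_now = self._ball_detected(ff)
        if ball_now:
            self._last_ball_time = t
        ball_recent = (t - self._last_ball_time) <= th.suppression_s
        flags.ball = ball_now

        # bend: thresholded smoothed shape, smoothed again, re-thresholded
        bend_raw = ff["angle_upper_lower_filtered"] > th.bend_angle_rad
        self._bend_smooth = exp_smooth(self._bend_smooth, float(bend_raw),
                                       th.bend_smooth_alpha)
        flags.bend = self._bend_smooth > th.bend_on

        if flags.bend:
            if ball_recent and self._last_side_before_ball:
                side = self._last_side_before_ball
            else:
                side = "left" if ff["asymmetry_filtered"] > th.asymmetry_eps else "right"
            flags.left = side == "left"
            flags.right = side == "right"
            self._last_side = side
            if not ball_recent:
                self._last_side_before_ball = side

        # roll: ball-like shape moving sideways, no concurrent ball, smoothed
        roll_raw = (ff["eig_reduced_filtered"] < th.roll_eig_max
                    and abs(ff["crab_speed_filtered"]) > th.roll_crab_speed
                    and not ball_now)
        self._roll_smooth = exp_smooth(self._roll_smooth, float(roll_raw),
                                       th.roll_smooth_alpha)
        flags.roll = self._roll_smooth > th.roll_on
        if flags.roll:
            self._last_roll_time = t
        roll_recent = (t - self._last_roll_time) <= th.suppression_s

        # locomotion channels, vetoed by recent balls and rolls
        tail = ff["parallel_speed_tail_raw_filtered"]
        flags.back = tail < th.back_tail_speed and not ball_recent and not roll_recent
        flags.forward = tail > th.forward_tail_speed and not ball_recent and not roll_recent
        flags.forward_peristaltic = (
            flags.forward
            and ff["parallel_speed_tail_raw"] > th.peristaltic_wave_speed)
        return flags


def classify_frame(ff: FeatureFrame, net: BallNetwork | None = None,
                   history: BehaviorClassifier | None = None,
                   thresholds: ClassifierThresholds | None = None) -> FrameFlags:
    """One-shot functional interface; pass ``history`` to keep state."""
    clf = history or BehaviorClassifier(thresholds, net)
    return clf.classify_frame(ff)


# ---------------------------------------------------------------------------
# events and evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorEvent:
    behavior: str
    side: str
    t_start: float
    t_end: float          # exclusive

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def overlaps(self, other: "BehaviorEvent") -> float:
        return max(0.0, min(self.t_end, other.t_end)
                   - max(self.t_start, other.t_start))


def extract_events(flags: list[FrameFlags] | pd.DataFrame,
                   dt: float = FRAME_DT,
                   channels: tuple[str, ...] = ("bend", "ball", "back",
                                                "forward",
                                                "forward_peristaltic",
                                                "roll")) -> list[BehaviorEvent]:
    """Interval-ise per-frame flags into maximal-run events.

    Bend events carry the majority side label of their frames.
    """
    if isinstance(flags, list):
        df = pd.DataFrame([f.as_dict() for f in flags])
    else:
        df = flags
    if df.empty:
        return []
    events: list[BehaviorEvent] = []
    times = df["time_s"].to_numpy()
    for ch in channels:
        col = df[ch].to_numpy(dtype=bool)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], col.astype(int), [0]])))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            side = ""
            if ch == "bend":
                lefts = df["left"].to_numpy()[i0:i1].sum()
                rights = df["right"].to_numpy()[i0:i1].sum()
                side = "left" if lefts >= rights else "right"
            events.append(BehaviorEvent(
                behavior=ch, side=side, t_start=float(times[i0]),
                t_end=float(times[i1 - 1]) + dt))
    events.sort(key=lambda e: (e.behavior, e.t_start))
    return events


def _truth_events_from_log(gt_table: pd.DataFrame, larva_id: int,
                           dt: float = FRAME_DT) -> list[BehaviorEvent]:
    """Ground-truth behaviour intervals for one larva from the simulator log."""
    sub = gt_table[gt_table["larva_id"] == larva_id].sort_values("frame")
    state_to_channel = {"bend_left": "bend", "bend_right": "bend",
                        "roll": "roll", "back": "back", "crawl": "forward",
                        "ball": "ball"}
    events: list[BehaviorEvent] = []
    cur = None
    for _, row in sub.iterrows():
        ch = state_to_channel.get(row["state"])
        side = row["side"]
        key = (ch, side)
        if cur is None or key != cur[0]:
            if cur is not None and cur[0][0] is not None:
                events.append(BehaviorEvent(cur[0][0], cur[0][1], cur[1], cur[2]))
            cur = [key, row["time_s"], row["time_s"] + dt]
        else:
            cur[2] = row["time_s"] + dt
    if cur is not None and cur[0][0] is not None:
        events.append(BehaviorEvent(cur[0][0], cur[0][1], cur[1], cur[2]))
    return events


def match_events(predicted: list[BehaviorEvent], truth: list[BehaviorEvent]
                 ) -> list[tuple[BehaviorEvent, BehaviorEvent]]:
    """One-to-one greedy matching by descending interval overlap."""
    cand = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            ov = p.overlaps(t)
            if ov > 0:
                cand.append((ov, i, j))
    cand.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for ov, i, j in cand:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((predicted[i], truth[j]))
    return pairs


def evaluate_run(behavior: pd.DataFrame, track_to_larva: dict[int, int],
                 gt_table: pd.DataFrame) -> pd.DataFrame:
    """Per-larva event evaluation of a whole tracked run.

    Predicted events of each track are matched only against the ground
    truth of the larva that track follows; counts are then pooled into
    one precision/recall table.
    """
    pred_by_larva: dict[int, list[BehaviorEvent]] = {}
    for tid, sub in behavior.groupby("id"):
        lid = track_to_larva.get(int(tid))
        if lid is None:
            continue
        pred_by_larva.setdefault(lid, []).extend(
            extract_events(sub.reset_index(drop=True)))
    tables = []
    for lid in sorted(gt_table["larva_id"].unique()):
        truth = _truth_events_from_log(gt_table, lid)
        pred = sorted(pred_by_larva.get(lid, []),
                      key=lambda e: (e.behavior, e.t_start))
        tables.append(evaluate_classifiers(pred, truth).assign(larva=lid))
    per = pd.concat(tables, ignore_index=True)
    rows = []
    for ch, sub in per.groupby("behavior"):
        tp, fp, fn = sub.tp.sum(), sub.fp.sum(), sub.fn.sum()
        row = {"behavior": ch, "tp": tp, "fp": fp, "fn": fn,
               "precision": tp / (tp + fp) if tp + fp else np.nan,
               "recall": tp / (tp + fn) if tp + fn else np.nan}
        if ch == "bend" and "side_accuracy" in sub:
            w = sub.dropna(subset=["side_accuracy"])
            if len(w):
                row["side_accuracy"] = float(
                    (w.side_accuracy * w.tp).sum() / w.tp.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_classifiers(predicted: list[BehaviorEvent],
                         truth: list[BehaviorEvent]) -> pd.DataFrame:
    """Event-level precision/recall per behaviour, left/right accuracy on
    true-positive bends, and forward-peristaltic merge/split rates."""
    rows = []
    behaviors = sorted({e.behavior for e in truth} | {e.behavior for e in predicted})
    for ch in behaviors:
        p = [e for e in predicted if e.behavior == ch]
        t = [e for e in truth if e.behavior == ch]
        pairs = match_events(p, t)
        tp = len(pairs)
        fp = len(p) - tp
        fn = len(t) - tp
        row = {"behavior": ch, "tp": tp, "fp": fp, "fn": fn,
               "precision": tp / (tp + fp) if tp + fp else np.nan,
               "recall": tp / (tp + fn) if tp + fn else np.nan}
        if ch == "bend" and pairs:
            correct = sum(1 for pe, te in pairs if pe.side == te.side)
            row["side_accuracy"] = correct / len(pairs)
        if ch == "forward_peristaltic" and t:
            # a truth wave covered by a prediction that also covers another
            # truth wave counts as falsely combined; a truth wave overlapped
            # by >1 prediction counts as split
            combined = 0
            split = 0
            for te in t:
                overlapping = [pe for pe in p if pe.overlaps(te) > 0]
                if len(overlapping) > 1:
                    split += 1
                for pe in overlapping:
                    others = [t2 for t2 in t if t2 is not te and pe.overlaps(t2) > 0]
                    if others:
                        combined += 1
                        break
            row["combined_rate"] = combined / len(t)
            row["split_rate"] = split / len(t)
        rows.append(row)
    return pd.DataFrame(rows)
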