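"""Head/tail detection, vote-system flip correction, 11-point spine, the
six landmarks, world-coordinate transform and exponential spine smoothing.

Head and tail are the contour points of sharpest and second-sharpest
curvature (turning angle over a +/-5 point window of the 100-point regular
contour), subject to a minimum contour separation.  A near-circular
contour (ball) makes curvature uninformative; the detector then raises an
ambiguity flag and the vote tallies are reset.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .contour import RegularContour
from .features import exp_smooth  # shared smoothing recurrence

CURVATURE_WINDOW = 5          # +/- contour points of 100
MIN_HEAD_TAIL_SEPARATION = 25  # contour points of 100
BALL_CURVATURE_TOLERANCE = 0.35  # relative spread of curvature below which
                                 # the contour counts as near-circular
VOTE_WINDOW_FRAMES = 20       # 1 s sliding vote memory at 20 Hz
VOTE_FLIP_QUORUM = 15         # flip votes needed to overturn orientation


class AmbiguousHeadTail(RuntimeError):
    """Raised when curvature is too uniform to tell head from tail (ball)."""


@dataclass
class LandmarkSet:
    head: np.ndarray
    neck_top: np.ndarray
    neck: np.ndarray
    neck_down: np.ndarray
    tail: np.ndarray
    centroid: np.ndarray
    spine: np.ndarray            # (11, 2) head -> tail

    @property
    def landmarks(self) -> dict[str, np.ndarray]:
        return {"head": self.head, "neck_top": self.neck_top, "neck": self.neck,
                "neck_down": self.neck_down, "tail": self.tail,
                "centroid": self.centroid}


@dataclass
class HeadTailVoteState:
    """Sliding-window tally of correct versus flipped head/tail detections."""

    votes: deque = field(default_factory=lambda: deque(maxlen=VOTE_WINDOW_FRAMES))
    flipped: bool = False        # current majority orientation
    prev_head: np.ndarray | None = None
    prev_tail: np.ndarray | None = None

    @property
    def correct_votes(self) -> int:
        return sum(1 for v in self.votes if not v)

    @property
    def flipped_votes(self) -> int:
        return sum(1 for v in self.votes if v)

    def reset(self) -> None:
        self.votes.clear()
        self.flipped = False


def contour_curvature(points: np.ndarray, window: int = CURVATURE_WINDOW) -> np.ndarray:
    """Unsigned turning angle at each contour point over +/-``window``."""
    n = len(points)
    prev = np.roll(points, window, axis=0)
    nxt = np.roll(points, -window, axis=0)
    v1 = points - prev
    v2 = nxt - points
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    return np.abs(np.arctan2(cross, dot))


def initial_head_tail(contour: RegularContour,
                      curvature_window: int = CURVATURE_WINDOW,
                      min_separation: int = MIN_HEAD_TAIL_SEPARATION,
                      ball_tolerance: float = BALL_CURVATURE_TOLERANCE,
                      ) -> tuple[int, int]:
    """Indices of head (sharpest curvature) and tail (second sharpest).

    Raises :class:`AmbiguousHeadTail` for near-circular contours.
    """
    pts = contour.points
    curv = contour_curvature(pts, curvature_window)
    mean = curv.mean()
    if mean <= 0 or (curv.max() - curv.min()) < ball_tolerance * max(curv.max(), 1e-9):
        raise AmbiguousHeadTail("uniform curvature: ball candidate")
    head = int(np.argmax(curv))
    n = len(pts)
    idx = np.arange(n)
    sep = np.minimum((idx - head) % n, (head - idx) % n)
    masked = np.where(sep >= min_separation, curv, -np.inf)
    tail = int(np.argmax(masked))
    return head, tail


def correct_head_tail(candidate: tuple[np.ndarray, np.ndarray],
                      state: HeadTailVoteState,
                      ball_detected: bool = False,
                      ) -> tuple[tuple[np.ndarray, np.ndarray], HeadTailVoteState]:
    """Flip-correct a (head, tail) candidate using travelled distance votes.

    If swapping head and tail reduces the summed displacement relative to
    the previous frame, a flip vote is cast, otherwise a correct vote; the
    output orientation follows the majority of the sliding window.  Ball
    events reset the tallies.
    """
    head, tail = candidate
    if ball_detected:
        state.reset()
    if state.prev_head is not None:
        d_keep = (np.linalg.norm(head - state.prev_head)
                  + np.linalg.norm(tail - state.prev_tail))
        d_swap = (np.linalg.norm(tail - state.prev_head)
                  + np.linalg.norm(head - state.prev_tail))
        candidate_flipped = d_swap < d_keep
        if candidate_flipped:
            # continuity wins frame to frame: align to the previous output
            head, tail = tail, head
        state.votes.append(candidate_flipped)
        if (state.flipped_votes > state.correct_votes
                and state.flipped_votes >= VOTE_FLIP_QUORUM):
            # the curvature detector has persistently disagreed with the
            # tracked orientation: trust it once, flip, and start over
            head, tail = tail, head
            state.votes.clear()
            state.flipped = not state.flipped
    state.prev_head = head
    state.prev_tail = tail
    return (head, tail), state


def _arc(points: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Contour points from index i0 to i1 inclusive, wrapping forward."""
    n = len(points)
    if i1 >= i0:
        idx = np.arange(i0, i1 + 1)
    else:
        idx = np.concatenate([np.arange(i0, n), np.arange(0, i1 + 1)])
    return points[idx]


def _sample_arc(arc: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = max(s[-1], 1e-12)
    t = fractions * total
    x = np.interp(t, s, arc[:, 0])
    y = np.interp(t, s, arc[:, 1])
    return np.column_stack([x, y])


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return points.mean(axis=0)
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


# spine indices (0..10) of the equally distributed interior landmarks
NECK_TOP_INDEX, NECK_INDEX, NECK_DOWN_INDEX = 3, 5, 7


def compute_spine_landmarks(contour: RegularContour, head_idx: int,
                            tail_idx: int) -> LandmarkSet:
    """Spine as midpoints of arclength-matched contour pairs, plus landmarks.

    The contour is split at head and tail into two arcs; spine point i is
    the midpoint of the two arc points at fraction i/10 of each arc's
    length.  neck_top/neck/neck_down sit at spine indices 3/5/7; the
    centroid is the contour polygon centroid.
    """
    if head_idx == tail_idx:
        raise ValueError("head and tail indices coincide")
    pts = contour.points
    frac = np.linspace(0.0, 1.0, 11)
    side_a = _sample_arc(_arc(pts, head_idx, tail_idx), frac)
    side_b = _sample_arc(_arc(pts, tail_idx, head_idx)[::-1], frac)
    spine = (side_a + side_b) / 2.0
    spine[0] = pts[head_idx]
    spine[10] = pts[tail_idx]
    return LandmarkSet(
        head=spine[0], neck_top=spine[NECK_TOP_INDEX], neck=spine[NECK_INDEX],
        neck_down=spine[NECK_DOWN_INDEX], tail=spine[10],
        centroid=polygon_centroid(pts), spine=spine)


@dataclass
class SpineSmoother:
    """Exponential smoothing of spine points in world coordinates.

    alpha = dt/tau with dt = 0.05 s and tau = 0.25 s.  The state resets
    whenever identity changes or stable-detection criteria fail.
    """

    alpha: float = 0.05 / 0.25
    state: np.ndarray | None = None

    def reset(self) -> None:
        self.state = None

    def update(self, spine_mm: np.ndarray) -> np.ndarray:
        if self.state is None:
            self.state = spine_mm.copy()
        else:
            self.state = exp_smooth(self.state, spine_mm, self.alpha)
        return self.state.copy()


def to_world(points_px: np.ndarray, pixel_scale_um: float) -> np.ndarray:
    """Camera pixels -> world mm (pixel_scale in µm/pixel)."""
    return np.asarray(points_px, dtype=float) * pixel_scale_um / 1000.0


def to_world_and_smooth(lm: LandmarkSet, pixel_scale_um: float,
                        smoother: SpineSmoother,
                        stable: bool = True) -> LandmarkSet:
    """Transform a pixel-space landmark set to mm and smooth the spine."""
    if not stable:
        smoother.reset()
    spine_mm = to_world(lm.spine, pixel_scale_um)
    smoothed = smoother.update(spine_mm)
    return LandmarkSet(
        head=smoothed[0], neck_top=smoothed[NECK_TOP_INDEX],
        neck=smoothed[NECK_INDEX], neck_down=smoothed[NECK_DOWN_INDEX],
        tail=smoothed[10], centroid=to_world(lm.centroid, pixel_scale_um),
        spine=smoothed)
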