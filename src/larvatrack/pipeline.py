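"""Frame-to-behaviour tracking pipeline.

Binds detection/tracking, contour extraction, landmark/spine computation,
feature extraction and classification into a per-frame update, with
per-larva state (smoothers, vote tallies, classifiers) keyed by track id.
Detection may run every k-th frame (default 3, as on the original host
computer) with the contour stage reusing the last known locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contour as ct
from . import landmarks as lmk
from .classify import BehaviorClassifier, BallNetwork, ClassifierThresholds, FrameFlags
from .detection import DetectionCriteria, DetectedObject, IdentityTracker, detect_candidates
from .features import FeatureExtractor, FeatureFrame

ROI_SIDE_MM = 14.14          # window of ~2 cm² around the object centre


@dataclass
class LarvaState:
    smoother: lmk.SpineSmoother
    votes: lmk.HeadTailVoteState
    extractor: FeatureExtractor
    classifier: BehaviorClassifier
    prev_head_idx: int | None = None
    prev_tail_idx: int | None = None


@dataclass
class TrackedLarva:
    id: int
    box: tuple[int, int, int, int]
    centroid_px: np.ndarray
    raw_contour: ct.RawContour | None
    contour: ct.RegularContour | None
    landmarks: lmk.LandmarkSet | None
    features: FeatureFrame | None
    flags: FrameFlags | None
    contour_fallback: bool = False
    hard_miss: bool = False


class TrackingPipeline:
    def __init__(self, pixel_scale_um: float = 72.92,
                 criteria: DetectionCriteria | None = None,
                 background: np.ndarray | None = None,
                 detect_every: int = 3,
                 contour_threshold: float = 60.0,
                 harmonics: int = 12,
                 thresholds: ClassifierThresholds | None = None,
                 ball_network: BallNetwork | None = None,
                 frame_dt: float = 0.05):
        self.pixel_scale = pixel_scale_um
        self.criteria = criteria or DetectionCriteria()
        self.background = background
        self.detect_every = max(1, detect_every)
        self.contour_threshold = contour_threshold
        self.harmonics = harmonics
        self.thresholds = thresholds or ClassifierThresholds()
        self.ball_network = ball_network
        self.frame_dt = frame_dt
        self.tracker = IdentityTracker(criteria=self.criteria)
        # last valid (raw, full-frame xy) contour per larva id
        self._contour_cache: dict[int, tuple[ct.RawContour, np.ndarray]] = {}
        self.states: dict[int, LarvaState] = {}
        self.frame_index = 0
        self._last_objects: list[DetectedObject] = []

    # -- state management --------------------------------------------------
    def _state_for(self, larva_id: int) -> LarvaState:
        st = self.states.get(larva_id)
        if st is None:
            st = LarvaState(smoother=lmk.SpineSmoother(),
                            votes=lmk.HeadTailVoteState(),
                            extractor=FeatureExtractor(),
                            classifier=BehaviorClassifier(
                                self.thresholds, self.ball_network))
            self.states[larva_id] = st
        return st

    def _prune_states(self, live_ids: set[int]) -> None:
        for gone in [i for i in self.states if i not in live_ids]:
            del self.states[gone]
            self._contour_cache.pop(gone, None)

    # -- per-frame processing ----------------------------------------------
    def process_frame(self, frame: np.ndarray, time_s: float | None = None
                      ) -> list[TrackedLarva]:
        if self.background is None:
            self.background = frame.copy()
        t = self.frame_index * self.frame_dt if time_s is None else time_s

        if self.frame_index % self.detect_every == 0:
            objs = detect_candidates(frame, self.background, self.criteria)
            objs = self.tracker.update(objs, time_s=t)
            self._last_objects = objs
        else:
            objs = self._last_objects  # reuse last known locations

        out: list[TrackedLarva] = []
        live = set()
        for obj in objs:
            live.add(obj.id)
            out.append(self._process_object(frame, obj, t))
        self._prune_states(live)
        self.frame_index += 1
        return out

    def _roi(self, frame: np.ndarray, centre_px: np.ndarray
             ) -> tuple[np.ndarray, tuple[int, int]]:
        half = int(round(ROI_SIDE_MM * 1000.0 / self.pixel_scale / 2.0))
        r = int(round(centre_px[1]))
        c = int(round(centre_px[0]))
        r0, c0 = max(0, r - half), max(0, c - half)
        r1 = min(frame.shape[0], r + half)
        c1 = min(frame.shape[1], c + half)
        return frame[r0:r1, c0:c1], (r0, c0)

    def _process_object(self, frame: np.ndarray, obj: DetectedObject,
                        t: float) -> TrackedLarva:
        st = self._state_for(obj.id)
        roi, (r0, c0) = self._roi(frame, obj.centroid)
        edges = ct.extract_edge_pixels(roi, threshold=self.contour_threshold)
        hint = (obj.centroid[1] - r0, obj.centroid[0] - c0)
        fallback = False
        raw = None
        for start in (hint, None):  # retry from the topmost edge pixel: the
            try:                    # walk may pick the shorter inner ring
                raw = ct.trace_moore_boundary(edges, start_hint=start,
                                              source_frame=self.frame_index)
                break
            except (ct.ContourRejected, ValueError):
                continue
        if raw is not None:
            # raw points are ROI (row, col); convert to full-frame (x, y)
            xy = np.column_stack([raw.points[:, 1] + c0, raw.points[:, 0] + r0])
            self._contour_cache[obj.id] = (raw, xy)
        elif obj.id in self._contour_cache:
            raw, xy = self._contour_cache[obj.id]  # last valid contour
            fallback = True
        else:
            return TrackedLarva(obj.id, obj.box, obj.centroid, None, None,
                                None, None, None, hard_miss=True)
        reg = ct.regularize_contour(xy, n_out=100, harmonics=self.harmonics)
        reg.source_frame = self.frame_index

        ball_flag = False
        try:
            h_idx, t_idx = lmk.initial_head_tail(reg)
        except lmk.AmbiguousHeadTail:
            ball_flag = True
            h_idx, t_idx = self._fallback_head_tail(reg, st)
        pts = reg.points
        (head_pt, tail_pt), st.votes = lmk.correct_head_tail(
            (pts[h_idx], pts[t_idx]), st.votes, ball_detected=ball_flag)
        if not np.array_equal(head_pt, pts[h_idx]):
            h_idx, t_idx = t_idx, h_idx
        st.prev_head_idx, st.prev_tail_idx = h_idx, t_idx

        lm_px = lmk.compute_spine_landmarks(reg, h_idx, t_idx)
        stable = not fallback
        lm_mm = lmk.to_world_and_smooth(lm_px, self.pixel_scale, st.smoother,
                                        stable=stable)
        contour_mm = lmk.to_world(pts, self.pixel_scale)
        ff = st.extractor.compute(lm_mm, contour_mm, time_s=t)
        flags = st.classifier.classify_frame(ff)
        if ball_flag:
            flags.ball = True
        return TrackedLarva(obj.id, obj.box, obj.centroid, raw, reg, lm_mm,
                            ff, flags, contour_fallback=fallback)

    def _fallback_head_tail(self, reg: ct.RegularContour,
                            st: LarvaState) -> tuple[int, int]:
        pts = reg.points
        if st.votes.prev_head is not None:
            # contour indices shift between frames; anchor on the previous
            # head/tail positions instead
            h = int(np.argmin(np.linalg.norm(pts - st.votes.prev_head, axis=1)))
            t = int(np.argmin(np.linalg.norm(pts - st.votes.prev_tail, axis=1)))
            if h != t:
                return h, t
        curv = lmk.contour_curvature(pts)
        h = int(np.argmax(curv))
        return h, (h + len(pts) // 2) % len(pts)


def associate_tracks(track: pd.DataFrame, gt_table: pd.DataFrame,
                     max_dist_mm: float = 2.0) -> dict[int, int]:
    """Map each track id to the ground-truth larva id it follows.

    Uses the mean distance between the track's mm positions and each
    simulated larva's centroid over the frames they share; tracks farther
    than ``max_dist_mm`` from every larva stay unmapped.
    """
    mapping: dict[int, int] = {}
    gt_pos = {lid: sub.set_index("frame")[["x_mm", "y_mm"]]
              for lid, sub in gt_table.groupby("larva_id")}
    for tid, sub in track.dropna(subset=["x_mm"]).groupby("id"):
        pos = sub.set_index("frame")[["x_mm", "y_mm"]]
        best, best_d = None, np.inf
        for lid, gpos in gt_pos.items():
            common = pos.index.intersection(gpos.index)
            if len(common) == 0:
                continue
            d = np.hypot(*(pos.loc[common].to_numpy()
                           - gpos.loc[common].to_numpy()).T).mean()
            if d < best_d:
                best, best_d = lid, d
        if best is not None and best_d <= max_dist_mm:
            mapping[int(tid)] = int(best)
    return mapping


def results_to_tables(per_frame: list[list[TrackedLarva]],
                      frame_dt: float = 0.05
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten pipeline output into (track, behavior) DataFrames."""
    track_rows = []
    beh_rows = []
    for fi, larvae in enumerate(per_frame):
        t = fi * frame_dt
        for lv in larvae:
            track_rows.append({
                "frame": fi, "time_s": t, "id": lv.id,
                "x_px": lv.centroid_px[0], "y_px": lv.centroid_px[1],
                "box_r0": lv.box[0], "box_c0": lv.box[1],
                "box_r1": lv.box[2], "box_c1": lv.box[3],
                "x_mm": lv.landmarks.centroid[0] if lv.landmarks else np.nan,
                "y_mm": lv.landmarks.centroid[1] if lv.landmarks else np.nan,
                "eligible": not lv.hard_miss,
            })
            if lv.flags is not None:
                beh_rows.append({"frame": fi, "id": lv.id,
                                 **lv.flags.as_dict()})
    return pd.DataFrame(track_rows), pd.DataFrame(beh_rows)
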