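"""Per-frame candidate detection and distance-based identity tracking.

Detection combines background subtraction with binary thresholding, encloses
each blob in a minimal axis-aligned box and filters on pixel intensity,
box side lengths, width+height, and box area.  The largest 16 eligible
objects are kept.  Identities are maintained greedily by centroid distance
with a hard 40-pixel threshold; ids are never reused within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops


@dataclass(frozen=True)
class DetectionCriteria:
    pixel_intensity: tuple[int, int] = (25, 170)
    box_side_px: tuple[int, int] = (6, 100)
    box_w_plus_h_px: tuple[int, int] = (12, 200)
    box_area_px2: tuple[int, int] = (300, 900)
    id_distance_px: float = 40.0
    max_objects: int = 16

    def __post_init__(self) -> None:
        for lo, hi in (self.pixel_intensity, self.box_side_px,
                       self.box_w_plus_h_px, self.box_area_px2):
            if lo > hi:
                raise ValueError("criteria minima must not exceed maxima")
        if self.id_distance_px <= 0:
            raise ValueError("id_distance_px must be positive")


@dataclass
class DetectedObject:
    id: int | None
    box: tuple[int, int, int, int]     # (min_row, min_col, max_row, max_col), exclusive max
    centroid: np.ndarray               # (x, y) px
    pixel_pattern: np.ndarray          # binary mask within box
    first_seen: float = 0.0
    last_seen: float = 0.0

    @property
    def width(self) -> int:
        return self.box[3] - self.box[1]

    @property
    def height(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def box_area(self) -> int:
        return self.width * self.height


def estimate_background(frames: np.ndarray, n: int = 20) -> np.ndarray:
    """Temporal median of the first ``n`` frames (8-bit)."""
    take = np.asarray(frames[: max(1, n)])
    return np.median(take, axis=0).astype(np.uint8)


def detect_candidates(frame: np.ndarray, background: np.ndarray,
                      criteria: DetectionCriteria = DetectionCriteria(),
                      threshold: int = 15) -> list[DetectedObject]:
    """Detect eligible larva-like blobs in one frame (ids unassigned).

    ``threshold`` applies to the background-subtracted image.  Every
    returned object satisfies all four eligibility criteria; if more than
    ``max_objects`` qualify, the largest by box area are kept.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = frame.astype(np.int16) - background.astype(np.int16)
    mask = diff > threshold
    lab = label(mask, connectivity=2)
    out: list[DetectedObject] = []
    for rp in regionprops(lab, intensity_image=frame):
        r0, c0, r1, c1 = rp.bbox
        w, h = c1 - c0, r1 - r0
        vals = frame[rp.coords[:, 0], rp.coords[:, 1]]
        crit = criteria
        if not (crit.pixel_intensity[0] <= vals.min() and vals.max() <= crit.pixel_intensity[1]):
            continue
        if not (crit.box_side_px[0] <= w <= crit.box_side_px[1]
                and crit.box_side_px[0] <= h <= crit.box_side_px[1]):
            continue
        if not (crit.box_w_plus_h_px[0] <= w + h <= crit.box_w_plus_h_px[1]):
            continue
        if not (crit.box_area_px2[0] <= w * h <= crit.box_area_px2[1]):
            continue
        pattern = np.zeros((h, w), dtype=bool)
        pattern[rp.coords[:, 0] - r0, rp.coords[:, 1] - c0] = True
        cy, cx = rp.centroid
        out.append(DetectedObject(
            id=None, box=(r0, c0, r1, c1),
            centroid=np.array([cx, cy]), pixel_pattern=pattern))
    out.sort(key=lambda o: -o.box_area)
    return out[: criteria.max_objects]


@dataclass
class IdentityTracker:
    """Greedy nearest-neighbour identity assignment with a 40 px gate.

    Matching proceeds in ascending distance order (ties broken by lower
    previous id); unmatched current objects receive fresh, never-reused
    ids.  Objects undetected in a frame are dropped (no coasting), so a
    larva re-emerging after contact gets a new identity.
    """

    criteria: DetectionCriteria = field(default_factory=DetectionCriteria)
    _next_id: int = 0
    previous: list[DetectedObject] = field(default_factory=list)

    def fresh_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def update(self, current: list[DetectedObject], time_s: float = 0.0) -> list[DetectedObject]:
        assigned = assign_identities(self.previous, current, self.criteria,
                                     id_source=self.fresh_id)
        for obj in assigned:
            prev = next((p for p in self.previous if p.id == obj.id), None)
            obj.first_seen = prev.first_seen if prev is not None else time_s
            obj.last_seen = time_s
        self.previous = assigned
        return assigned


def assign_identities(prev: list[DetectedObject], current: list[DetectedObject],
                      criteria: DetectionCriteria = DetectionCriteria(),
                      id_source=None) -> list[DetectedObject]:
    """Assign ids to ``current`` from ``prev`` by gated greedy matching."""
    if id_source is None:
        counter = [max([p.id for p in prev if p.id is not None], default=-1) + 1]

        def id_source() -> int:  # noqa: E731 - local fallback
            counter[0] += 1
            return counter[0] - 1

    pairs = []
    for ci, cur in enumerate(current):
        for pj, pr in enumerate(prev):
            d = float(np.linalg.norm(cur.centroid - pr.centroid))
            if d <= criteria.id_distance_px:
                pairs.append((d, pr.id, ci, pj))
    pairs.sort(key=lambda t: (t[0], t[1]))
    used_prev: set[int] = set()
    matched: dict[int, int] = {}
    for d, pid, ci, pj in pairs:
        if ci in matched or pj in used_prev:
            continue
        matched[ci] = pid
        used_prev.add(pj)
    for ci, cur in enumerate(current):
        cur.id = matched[ci] if ci in matched else id_source()
    return current
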