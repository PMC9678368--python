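"""Contour extraction: XOR edge detection, Moore boundary tracing with
error captures, and Fourier regularization to a fixed 100-point contour.

The edge detector marks a pixel as an edge pixel iff it differs from its
right neighbour or from its lower neighbour in the thresholded image (two
2x1 XOR convolutions, OR-combined).  The tracer walks the Moore (8-)
neighbourhood clockwise with three error-capture procedures: backtracking
by up to 16 contour points out of dead ends and small loops, a hard budget
on pixel comparisons emulating the original 10,000-clock-cycle cap, and
rejection of contours shorter than 63 points so the caller can fall back
to the last valid contour for that larva id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_CONTOUR_POINTS = 63
DEFAULT_BUDGET = 10_000
BACKTRACK_LIMIT = 16

# Moore neighbourhood scanned clockwise (image convention, y down),
# starting west: W, NW, N, NE, E, SE, S, SW as (drow, dcol)
_NEIGH = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


class ContourRejected(RuntimeError):
    """Traced contour failed the 63-point minimum; caller should substitute
    the last valid contour for this larva id."""

    def __init__(self, contour: "RawContour"):
        super().__init__(f"contour of {len(contour.points)} points rejected")
        self.contour = contour


@dataclass
class RawContour:
    points: np.ndarray           # (n, 2) int pixel coordinates (row, col)
    closed: bool = False
    source_frame: int = -1

    def __len__(self) -> int:
        return len(self.points)

    @property
    def accepted(self) -> bool:
        return len(self.points) >= MIN_CONTOUR_POINTS


@dataclass
class RegularContour:
    points: np.ndarray           # (100, 2) float (x, y)
    harmonics_used: int = 0
    source_frame: int = -1


def extract_edge_pixels(roi: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Edge map of a (possibly pre-thresholded) region of interest.

    A pixel is an edge pixel iff its thresholded value differs from its
    right neighbour or its lower neighbour (out-of-bounds neighbours count
    as background).
    """
    roi = np.asarray(roi)
    if roi.size == 0:
        return np.zeros_like(roi, dtype=bool)
    binary = roi.astype(bool) if threshold is None else roi > threshold
    # 2x1 XOR with the right and lower neighbour; pixels on the last
    # row/column have no neighbour inside the clipped window and are never
    # marked there, so a uniform window yields no edges
    right = np.zeros_like(binary)
    right[:, :-1] = binary[:, :-1] ^ binary[:, 1:]
    lower = np.zeros_like(binary)
    lower[:-1, :] = binary[:-1, :] ^ binary[1:, :]
    return right | lower


def trace_moore_boundary(edges: np.ndarray, start_hint: tuple[int, int] | None = None,
                         budget: int = DEFAULT_BUDGET,
                         source_frame: int = -1) -> RawContour:
    """Trace a closed contour through the edge map.

    Raises :class:`ContourRejected` when the result has fewer than 63
    points; returns the partial contour when the comparison budget is
    exhausted.  Raises ``ValueError`` on an empty edge map.
    """
    edges = np.asarray(edges, dtype=bool)
    ys, xs = np.nonzero(edges)
    if len(ys) == 0:
        raise ValueError("edge map is empty")
    if start_hint is None:
        start = (int(ys[0]), int(xs[0]))
    else:
        hr, hc = float(start_hint[0]), float(start_hint[1])
        k = int(np.argmin((ys - hr) ** 2 + (xs - hc) ** 2))
        start = (int(ys[k]), int(xs[k]))

    h, w = edges.shape
    contour: list[tuple[int, int]] = [start]
    # per contour point: (clockwise scan start index, neighbours checked so far)
    scan: list[list[int]] = [[0, 0]]
    comparisons = 0

    def is_edge(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and edges[p]

    while True:
        p = contour[-1]
        advanced = False
        while scan[-1][1] < 8:
            j = (scan[-1][0] + scan[-1][1]) % 8
            scan[-1][1] += 1
            dq = _NEIGH[j]
            q = (p[0] + dq[0], p[1] + dq[1])
            comparisons += 1
            if comparisons >= budget:
                return _finish(contour, False, source_frame)
            if not is_edge(q):
                continue
            if q == start and len(contour) > BACKTRACK_LIMIT:
                return _finish(contour, True, source_frame)
            prev = contour[-2] if len(contour) >= 2 else None
            if q == prev:
                continue
            if q in contour[-BACKTRACK_LIMIT:]:
                continue  # small loop: refuse this neighbour, keep scanning
            # enter q; its clockwise scan starts just past the backtracked
            # entry pixel (Moore-Jacob convention)
            back = _NEIGH.index((p[0] - q[0], p[1] - q[1]))
            contour.append(q)
            scan.append([(back + 1) % 8, 0])
            advanced = True
            break
        if advanced:
            continue
        # dead end: backtrack up to 16 contour points seeking an alternative
        backtracked = 0
        while len(contour) > 1 and backtracked < BACKTRACK_LIMIT and scan[-1][1] >= 8:
            contour.pop()
            scan.pop()
            backtracked += 1
        if scan[-1][1] >= 8:
            # nothing left to try within the backtrack window
            return _finish(contour, False, source_frame)


def _finish(points: list[tuple[int, int]], closed: bool, source_frame: int) -> RawContour:
    rc = RawContour(points=np.array(points, dtype=int), closed=closed,
                    source_frame=source_frame)
    if not rc.accepted:
        raise ContourRejected(rc)
    return rc


@dataclass
class ContourCache:
    """Per-larva fallback store implementing the 'last valid contour' rule."""

    _last: dict[int, RawContour] = field(default_factory=dict)

    def trace(self, edges: np.ndarray, larva_id: int,
              start_hint: tuple[int, int] | None = None,
              budget: int = DEFAULT_BUDGET, source_frame: int = -1) -> RawContour:
        try:
            rc = trace_moore_boundary(edges, start_hint, budget, source_frame)
        except (ContourRejected, ValueError):
            if larva_id in self._last:
                return self._last[larva_id]
            raise HardMiss(larva_id, source_frame) from None
        self._last[larva_id] = rc
        return rc


class HardMiss(RuntimeError):
    """No valid contour and no cached fallback for this larva on this frame."""

    def __init__(self, larva_id: int, frame: int):
        super().__init__(f"no contour for larva {larva_id} at frame {frame}")
        self.larva_id = larva_id
        self.frame = frame


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` uniform-arclength points."""
    pts = np.asarray(points, dtype=float)
    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) contour")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, loop[:, 0])
    y = np.interp(t, s, loop[:, 1])
    return np.column_stack([x, y])


def regularize_contour(raw: RawContour | np.ndarray, n_out: int = 100,
                       harmonics: int | None = 12,
                       oversample: int = 256) -> RegularContour:
    """Fourier-regularize a raw contour to exactly ``n_out`` smooth points.

    The raw contour is resampled to uniform arclength, decomposed into
    complex Fourier coefficients, truncated to ``harmonics`` (``None`` for
    no truncation), and reconstructed at ``n_out`` uniformly spaced
    parameter values.  Truncation removes high-frequency pixelation.
    """
    pts = raw.points if isinstance(raw, RawContour) else np.asarray(raw)
    if isinstance(raw, RawContour) and not raw.accepted:
        raise ValueError("cannot regularize a rejected contour")
    m = max(oversample, 2 * len(pts))
    res = _resample_closed(pts, m)
    z = res[:, 0] + 1j * res[:, 1]
    coeff = np.fft.fft(z) / m
    freqs = np.fft.fftfreq(m, d=1.0 / m).astype(int)
    if harmonics is None:
        keep = np.ones(m, dtype=bool)
        used = m // 2
    else:
        keep = np.abs(freqs) <= harmonics
        used = int(harmonics)
    t = np.arange(n_out) / n_out
    zk = coeff[keep]
    fk = freqs[keep]
    z_out = (zk[None, :] * np.exp(2j * np.pi * fk[None, :] * t[:, None])).sum(axis=1)
    out = np.column_stack([z_out.real, z_out.imag])
    frame = raw.source_frame if isinstance(raw, RawContour) else -1
    return RegularContour(points=out, harmonics_used=used, source_frame=frame)
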