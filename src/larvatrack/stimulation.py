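"""Virtual actuators: DMD light planning and galvanometer/laser control.

The DMD is modelled as a programmable light field projecting 1 cm² squares
of configurable intensity (µW/cm²) onto tracked larvae; overlapping
squares take the minimum of the overlapping commands.  The IR laser is
time-multiplexed across larvae by a galvanometer within each 50 ms control
frame with 1.5 ms off-gaps, and larval temperature is held by a sigmoid
feedback controller on the measured-minus-target temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

CONTROL_FRAME_MS = 50.0
GALVO_GAP_MS = 1.5
LIGHT_LATENCY_LIMIT_MS = 50.0
THERMO_LATENCY_LIMIT_MS = 100.0
SQUARE_SIDE_MM = 10.0          # 1 cm² stimulation square


# ---------------------------------------------------------------------------
# DMD calibration
# ---------------------------------------------------------------------------


def fit_dmd_calibration(dmd_points: np.ndarray, camera_points: np.ndarray
                        ) -> tuple[np.ndarray, float]:
    """Least-squares affine map DMD px -> camera px.

    Returns the 2x3 affine matrix and the RMS residual.  Requires at least
    three non-collinear point pairs.
    """
    d = np.asarray(dmd_points, dtype=float)
    c = np.asarray(camera_points, dtype=float)
    if d.shape != c.shape or d.ndim != 2 or d.shape[0] < 3:
        raise ValueError("need >= 3 matched point pairs")
    a = np.column_stack([d, np.ones(len(d))])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("calibration points are collinear")
    coef, *_ = np.linalg.lstsq(a, c, rcond=None)
    resid = a @ coef - c
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return coef.T, rms


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(points)
    return p @ affine[:, :2].T + affine[:, 2]


@dataclass
class IntensityLookup:
    """Bilinear per-location intensity normalisation.

    Scale factors are ``min(measured)/measured`` so that the commanded
    uniform output is achievable everywhere: scale = 1 at the dimmest
    sampled location.  Queries outside the sampled box are clamped to the
    nearest edge (with a warning flag on construction if holes exist).
    """

    x_grid: np.ndarray
    y_grid: np.ndarray
    scales: np.ndarray           # (ny, nx)
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._interp = RegularGridInterpolator(
            (self.y_grid, self.x_grid), self.scales,
            method="linear", bounds_error=False, fill_value=None)

    def scale_at(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        q = np.column_stack([
            np.clip(p[:, 1], self.y_grid[0], self.y_grid[-1]),
            np.clip(p[:, 0], self.x_grid[0], self.x_grid[-1])])
        return self._interp(q)


def build_intensity_lookup(x_grid: np.ndarray, y_grid: np.ndarray,
                           measured: np.ndarray) -> IntensityLookup:
    """Scale table from a grid of measured intensities (~100 samples)."""
    measured = np.asarray(measured, dtype=float)
    if measured.shape != (len(y_grid), len(x_grid)):
        raise ValueError("measured grid shape mismatch")
    if np.any(measured <= 0):
        raise ValueError("measured intensities must be positive")
    scales = measured.min() / measured
    return IntensityLookup(np.asarray(x_grid, float), np.asarray(y_grid, float),
                           scales)


# ---------------------------------------------------------------------------
# DMD frame planning
# ---------------------------------------------------------------------------


@dataclass
class LightField:
    """Planned per-control-frame light field as a set of squares.

    ``intensity_at`` evaluates the field at world points applying the
    min-intensity overlap rule.
    """

    squares: list[tuple[float, float, float]]  # (x_mm, y_mm, intensity)
    side_mm: float = SQUARE_SIDE_MM
    control_frame_index: int = 0
    latency_ms: float = LIGHT_LATENCY_LIMIT_MS

    def intensity_at(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        out = np.full(len(p), np.inf)
        covered = np.zeros(len(p), dtype=bool)
        half = self.side_mm / 2.0
        for x, y, inten in self.squares:
            inside = ((np.abs(p[:, 0] - x) <= half)
                      & (np.abs(p[:, 1] - y) <= half))
            out[inside] = np.minimum(out[inside], inten)
            covered |= inside
        out[~covered] = 0.0
        return out


def plan_dmd_frame(larvae: dict[int, tuple[np.ndarray, float]],
                   lookup: IntensityLookup | None = None,
                   plate_size_mm: tuple[float, float] = (230.0, 230.0),
                   control_frame_index: int = 0) -> LightField:
    """Plan one 50 ms DMD control frame.

    ``larvae``: id -> (position mm, commanded intensity µW/cm²).  Squares
    are clipped to the plate; overlaps resolve to the minimum command
    (order-independent).  The plan is timestamped within one control frame
    of the triggering detection.
    """
    squares = []
    for _id in sorted(larvae):
        pos, inten = larvae[_id]
        x = float(np.clip(pos[0], 0.0, plate_size_mm[0]))
        y = float(np.clip(pos[1], 0.0, plate_size_mm[1]))
        squares.append((x, y, float(inten)))
    return LightField(squares=squares, control_frame_index=control_frame_index,
                      latency_ms=CONTROL_FRAME_MS)


# ---------------------------------------------------------------------------
# galvanometer scheduling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GalvoSlot:
    target_mm: tuple[float, float]
    laser_pct: float
    dwell_ms: float


def schedule_galvanometer(positions: list[tuple[float, float] | None],
                          laser_pct: float = 100.0,
                          frame_budget_ms: float = CONTROL_FRAME_MS,
                          gap_ms: float = GALVO_GAP_MS,
                          plate_centre_mm: tuple[float, float] = (115.0, 115.0),
                          ) -> list[GalvoSlot]:
    """Dwell schedule cycling the beam over all expected larvae at 20 Hz.

    ``positions`` holds one entry per expected larva; ``None`` marks a
    larva missing this frame — its slot is aimed at the plate centre with
    zero intensity.  Dwell = (budget - n*gap)/n, i.e. 11 ms per larva for
    four larvae with 1.5 ms off-gaps.
    """
    n = len(positions)
    if not 1 <= n <= 16:
        raise ValueError("1 to 16 larvae per schedule")
    dwell = (frame_budget_ms - n * gap_ms) / n
    if dwell <= 0:
        raise ValueError("frame budget insufficient for dwell schedule")
    slots = []
    for pos in positions:
        if pos is None:
            slots.append(GalvoSlot(plate_centre_mm, 0.0, dwell))
        else:
            slots.append(GalvoSlot((float(pos[0]), float(pos[1])),
                                   laser_pct, dwell))
    return slots


def schedule_total_ms(slots: list[GalvoSlot], gap_ms: float = GALVO_GAP_MS) -> float:
    return sum(s.dwell_ms for s in slots) + len(slots) * gap_ms


# ---------------------------------------------------------------------------
# thermal control
# ---------------------------------------------------------------------------


@dataclass
class ThermalController:
    """Sigmoid closed-loop laser intensity controller.

    I = 100 / (1 + exp(x / w)) with x = measured - target (℃); the
    exponent is read as x/2 by default (the printed form is typographically
    ambiguous); ``exponent`` selects among "x/w", "x" and "x**2".
    """

    target_temp: float = 30.0
    width: float = 2.0
    exponent: str = "x/w"

    def intensity(self, measured_temp: float) -> float:
        x = measured_temp - self.target_temp
        if self.exponent == "x/w":
            e = x / self.width
        elif self.exponent == "x":
            e = x
        elif self.exponent == "x**2":
            e = x * x
        else:
            raise ValueError(f"unknown exponent convention {self.exponent!r}")
        e = np.clip(e, -60.0, 60.0)
        return float(np.clip(100.0 / (1.0 + np.exp(e)), 0.0, 100.0))


def thermal_feedback_intensity(controller: ThermalController,
                               measured_temp: float) -> float:
    """Functional wrapper over :meth:`ThermalController.intensity`."""
    return controller.intensity(measured_temp)
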