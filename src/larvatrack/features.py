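"""Per-frame behavioural feature catalogue.

Computes the motion-direction, body-shape and velocity features from the
regularized contour and the smoothed spine, together with their smoothed
(``_filtered``, tau = 0.25 s), long-smoothed (``_long``, tau = 5 s) and
convolution-squared (``_convolved_squared``) variants.

Conventions
-----------
* world coordinates in mm, image convention (y increases downward);
* ``asymmetry`` is the sine of the angle from the body axis to the head
  axis, signed so that a bend toward the larva's left is positive;
* landmark velocities are measured over dt = 0.2 s (four frames at 20 Hz);
* tanh bounding of speeds uses x -> X*tanh(x/X) with X = 1.5 mm/s.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

FRAME_DT = 0.05           # s, 20 Hz
VELOCITY_DT = 0.2         # s, four frames
SPEED_BOUND = 1.5         # mm/s tanh bound for v_norm and friends


@dataclass(frozen=True)
class SmoothingParams:
    dt: float = FRAME_DT
    tau: float = 0.25
    tau_long: float = 5.0

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def alpha_long(self) -> float:
        return self.dt / self.tau_long

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 < self.alpha_long <= 1:
            raise ValueError("smoothing constants must lie in (0, 1]")


def exp_smooth(prev, new, alpha: float):
    """One step of exponential smoothing: (1 - alpha)*prev + alpha*new."""
    return (1.0 - alpha) * prev + alpha * new


def tanh_bound(x: float, bound: float = SPEED_BOUND) -> float:
    """Soft-limit ``x`` to (-bound, bound) preserving small values."""
    return bound * float(np.tanh(x / bound))


@dataclass
class ConvolutionState:
    """State of the convolution-squared derivative approximation.

    Recurrences (dt = 0.05 s, lambda = 1/tau, tau = 0.25 s)::

        f1_t = (1 - lambda*dt) * f1_{t-dt} + dt/2 * (f_{t-dt} + f_t)
        f2_t = lambda*dt * f1_{t-dt} + (1 - lambda*dt) * f2_{t-dt}
        out  = k * (f1_t - f2_t)**2

    Both accumulators start at the trapezoid equilibrium of the first
    sample (f1 = f2 = f0/lambda) so a constant input yields zero output.
    A short history buffer of the delayed term is retained (the printed
    delay of the second recurrence is ambiguous; the one-step reading is
    used, with the buffer length configurable).
    """

    k: float = 1.0
    tau: float = 0.25
    dt: float = FRAME_DT
    history_s: float = 5.0
    f1: float | None = None
    f2: float | None = None
    f_prev: float | None = None
    f2_history: deque = field(default_factory=deque)

    @property
    def lam(self) -> float:
        return 1.0 / self.tau

    def step(self, f_now: float) -> float:
        lam_dt = self.lam * self.dt
        if self.f1 is None:
            self.f1 = self.f2 = f_now / self.lam
            self.f_prev = f_now
        f1_prev = self.f1
        self.f1 = (1.0 - lam_dt) * f1_prev + 0.5 * self.dt * (self.f_prev + f_now)
        self.f2 = lam_dt * f1_prev + (1.0 - lam_dt) * self.f2
        self.f_prev = f_now
        self.f2_history.append(self.f2)
        while len(self.f2_history) > int(self.history_s / self.dt):
            self.f2_history.popleft()
        return self.k * (self.f1 - self.f2) ** 2


def convolved_squared_step(state: ConvolutionState, f_now: float) -> tuple[ConvolutionState, float]:
    """Functional wrapper over :meth:`ConvolutionState.step`."""
    return state, state.step(f_now)


#: scalar features that receive _filtered / _long / _convolved_squared variants
SMOOTHED_FEATURES = (
    "skeleton_length", "perimeter", "larva_arc_ratio", "larva_area_ratio",
    "eig_reduced", "s", "asymmetry", "angle_upper_lower",
    "head_speed", "neck_top_speed", "neck_speed", "neck_down_speed",
    "tail_speed", "v_centroid", "v_norm", "speed_reduced",
    "crab_speed", "parallel_speed", "parallel_speed_tail_raw",
    "parallel_speed_tail",
)


@dataclass
class FeatureFrame:
    """All per-frame scalar features plus vector directions."""

    time_s: float = 0.0
    valid: bool = True
    warm_up: bool = False
    direction_vector: np.ndarray = field(default_factory=lambda: np.zeros(2))
    direction_head_vector: np.ndarray = field(default_factory=lambda: np.zeros(2))
    direction_tail_vector: np.ndarray = field(default_factory=lambda: np.zeros(2))
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def get(self, key: str, default: float = np.nan) -> float:
        return self.values.get(key, default)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([0.0, 0.0])


def _signed_sin(a: np.ndarray, b: np.ndarray) -> float:
    """Sine of the angle from unit vector a to unit vector b.

    With the y-down image convention and the camera above the plate,
    positive values correspond to the head axis deviating toward the
    larva's left."""
    return float(a[0] * b[1] - a[1] * b[0])


def structure_tensor_eig_reduced(contour: np.ndarray, neck: np.ndarray) -> float:
    """|l1 - l2| / (l1 + l2) of the contour's second-moment matrix about neck."""
    d = contour - neck
    m = d.T @ d / len(d)
    ev = np.linalg.eigvalsh(m)
    tot = ev.sum()
    if tot <= 1e-12:
        return 0.0
    return float(abs(ev[1] - ev[0]) / tot)


class FeatureExtractor:
    """Stateful per-larva feature computation.

    Feed one (landmarks, contour) pair per frame; the extractor maintains
    the 0.2 s landmark history, the smoothing and convolution states, and
    the damped-distance accumulator.  Call :meth:`reset` when identity
    changes or detection becomes unstable.
    """

    def __init__(self, params: SmoothingParams | None = None,
                 k_convolved: dict[str, float] | None = None,
                 damped_tau: float = 5.0):
        self.params = params or SmoothingParams()
        self.k_convolved = k_convolved or {}
        self.damped_tau = damped_tau
        self.reset()

    def reset(self) -> None:
        n_hist = int(round(VELOCITY_DT / self.params.dt))
        self._lm_history: deque = deque(maxlen=n_hist)  # 4 frames = 0.2 s
        self._filtered: dict[str, float] = {}
        self._long: dict[str, float] = {}
        self._conv: dict[str, ConvolutionState] = {}
        self._dir_filtered: dict[str, np.ndarray] = {}
        self._vel_filtered: dict[str, np.ndarray] = {}
        self._damped_distance = 0.0
        self._frames_seen = 0

    # -- helpers -----------------------------------------------------------
    def _smooth_scalar(self, name: str, value: float) -> tuple[float, float, float]:
        a, al = self.params.alpha, self.params.alpha_long
        f = exp_smooth(self._filtered.get(name, value), value, a)
        fl = exp_smooth(self._long.get(name, value), value, al)
        self._filtered[name] = f
        self._long[name] = fl
        st = self._conv.get(name)
        if st is None:
            st = ConvolutionState(k=self.k_convolved.get(name, 1.0),
                                  tau=self.params.tau, dt=self.params.dt)
            self._conv[name] = st
        conv = st.step(value)
        return f, fl, conv

    def _smooth_vector(self, name: str, v: np.ndarray) -> np.ndarray:
        a = self.params.alpha
        prev = self._dir_filtered.get(name, v)
        sm = exp_smooth(prev, v, a)
        self._dir_filtered[name] = sm
        return _unit(sm) if np.linalg.norm(sm) > 1e-12 else sm

    def _landmark_speed(self, name: str, now: np.ndarray) -> tuple[float, np.ndarray]:
        """Speed (mm/s) and velocity vector of one landmark over 0.2 s."""
        if len(self._lm_history) < self._lm_history.maxlen:
            return 0.0, np.zeros(2)  # warm-up: velocities reported as 0
        past = self._lm_history[0][name]
        vel = (now - past) / VELOCITY_DT
        return float(np.linalg.norm(vel)), vel

    # -- main entry --------------------------------------------------------
    def compute(self, lm, contour_mm: np.ndarray, time_s: float = 0.0) -> FeatureFrame:
        """Compute a :class:`FeatureFrame` from mm-space landmarks/contour."""
        ff = FeatureFrame(time_s=time_s)
        spine = lm.spine
        poly = Polygon(contour_mm)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area <= 1e-9:
            ff.valid = False
            return ff
        hull = poly.convex_hull

        # --- motion direction ---
        direction_vector = _unit(lm.neck - lm.tail)
        direction_head_vector = _unit(lm.head - lm.neck_top)
        direction_tail_vector = _unit(lm.neck_down - lm.tail)
        ff.direction_vector = direction_vector
        ff.direction_head_vector = direction_head_vector
        ff.direction_tail_vector = direction_tail_vector

        v: dict[str, float] = {}
        # --- body shape ---
        v["skeleton_length"] = float(
            np.linalg.norm(np.diff(spine, axis=0), axis=1).sum())
        v["perimeter"] = float(poly.exterior.length)
        v["larva_arc_ratio"] = max(1.0, v["perimeter"] / max(hull.exterior.length, 1e-12))
        v["larva_area_ratio"] = min(1.0, poly.area / max(hull.area, 1e-12))
        v["eig_reduced"] = structure_tensor_eig_reduced(contour_mm, lm.neck)
        sin_ul = _signed_sin(direction_vector, direction_head_vector)
        cos_ul = float(np.dot(direction_vector, direction_head_vector))
        theta = float(np.arctan2(abs(sin_ul), cos_ul))
        v["asymmetry"] = sin_ul
        v["angle_upper_lower"] = theta
        v["s"] = 1.0 - 1.5 * theta / np.pi

        # --- velocities over 0.2 s ---
        lm_dict = {**lm.landmarks}
        ff.warm_up = len(self._lm_history) < (self._lm_history.maxlen or 1)
        speeds = {}
        vels = {}
        for name in ("head", "neck_top", "neck", "neck_down", "tail", "centroid"):
            sp, vel = self._landmark_speed(name, lm_dict[name])
            speeds[name] = sp
            vels[name] = vel
        v["head_speed"] = speeds["head"]
        v["neck_top_speed"] = speeds["neck_top"]
        v["neck_speed"] = speeds["neck"]
        v["neck_down_speed"] = speeds["neck_down"]
        v["tail_speed"] = speeds["tail"]
        v["v_centroid"] = speeds["centroid"]

        mean_neck = (speeds["neck_top"] + speeds["neck"] + speeds["neck_down"]) / 3.0
        v["v_norm"] = tanh_bound(mean_neck)
        v["speed_reduced"] = tanh_bound(
            speeds["neck_top"] / (v["v_norm"] + 1e-6) - 1.0)

        # damped distance: exponentially discounted accumulated neck travel
        if self._lm_history:
            step = float(np.linalg.norm(lm_dict["neck"] - self._lm_history[-1]["neck"]))
        else:
            step = 0.0
        a_d = self.params.dt / self.damped_tau
        self._damped_distance = (1.0 - a_d) * self._damped_distance + step
        v["damped_distance"] = self._damped_distance

        # filtered directions and velocity projections
        dir_f = self._smooth_vector("direction_vector", direction_vector)
        dir_tail_f = self._smooth_vector("direction_tail_vector", direction_tail_vector)
        neck_vel_f = exp_smooth(self._vel_filtered.get("neck", vels["neck"]),
                                vels["neck"], self.params.alpha)
        tail_vel_f = exp_smooth(self._vel_filtered.get("tail", vels["tail"]),
                                vels["tail"], self.params.alpha)
        self._vel_filtered["neck"] = neck_vel_f
        self._vel_filtered["tail"] = tail_vel_f

        v["crab_speed"] = _signed_sin(dir_f, vels["neck"]) if np.any(dir_f) else 0.0
        v["parallel_speed"] = float(np.dot(neck_vel_f, dir_f))
        v["parallel_speed_tail_raw"] = float(np.dot(tail_vel_f, dir_tail_f))
        tail_dir = _unit(tail_vel_f)
        v["parallel_speed_tail"] = float(np.dot(tail_dir, dir_tail_f)) if np.any(tail_dir) else 0.0

        # --- smoothed / long / convolved variants ---
        for name in SMOOTHED_FEATURES:
            f, fl, conv = self._smooth_scalar(name, v[name])
            v[name + "_filtered"] = f
            v[name + "_long"] = fl
            v[name + "_convolved_squared"] = conv

        self._lm_history.append(lm_dict)
        self._frames_seen += 1
        ff.values = v
        return ff
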