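"""Synthetic multi-larva scene simulator.

Stands in for the camera / heat-camera hardware: renders deformable
bright-on-dark larva bodies on an agarose plate at 20 Hz, scripts or
stochastically drives the behavioural repertoire (crawl, left/right bend,
ball, roll, back-up, still), logs ground truth per frame, and integrates a
first-order tissue-heating plant for the virtual IR laser.

All world coordinates are in mm (y increasing downward, image convention);
images are 8-bit greyscale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

BEHAVIOR_STATES = ("crawl", "bend_left", "bend_right", "ball", "roll", "back", "still")

#: default body model (mm): sized so the bounding box stays inside the
#: default 300-900 px² detection window at 72.92 µm/px in every pose and
#: orientation, while the traced contour stays above the 63-point minimum
DEFAULT_BODY_LENGTH_MM = 2.3
DEFAULT_HALF_WIDTH_MM = 0.36


def default_half_width_profile(n: int = 11, peak: float = DEFAULT_HALF_WIDTH_MM) -> np.ndarray:
    """Tapered half-width profile along the 11 spine points (mm).

    The anterior is a narrow near-cylindrical snout with a small end cap,
    so the head carries a full, tightly localized half-turn of contour
    curvature; the blunt tail spreads its half-turn over a much longer
    cap arc.  The curvature-based landmark detector then finds the head
    as the sharpest contour point reliably, at pixel scale and on the
    exact geometry alike."""
    s = np.linspace(0.0, 1.0, n)
    anchors_s = np.array([0.0, 0.15, 0.5, 0.85, 1.0])
    anchors_w = np.array([0.26, 0.30, 1.0, 1.0, 0.85]) * peak
    return np.interp(s, anchors_s, anchors_w)


@dataclass
class ResponseModel:
    """Maps stimulus (light µW/cm², temperature ℃) to behaviour-transition
    probabilities per 50 ms frame.

    The dose–response of rolling versus light intensity is not constrained
    by published data; these per-frame probabilities are free simulator
    knobs, defaulted so that a sustained 5 s stimulus triggers at least one
    roll in well over 90% of responder agents.
    """

    light_threshold: float = 50.0      # µW/cm²
    temp_threshold: float = 28.0       # ℃
    roll_prob: float = 0.05            # per frame while stimulated (responder)
    roll_stop_prob: float = 0.10       # per frame chance a roll ends
    responds_to_light: bool = False
    responds_to_temp: bool = False

    def roll_probability(self, light: float, temperature: float) -> float:
        trig = (self.responds_to_light and light >= self.light_threshold) or (
            self.responds_to_temp and temperature >= self.temp_threshold
        )
        return self.roll_prob if trig else 0.0


@dataclass
class PlantParams:
    """First-order heating plant dT/dt = k1*I - k2*(T - ambient).

    Gains chosen so the closed loop with the sigmoid controller settles a
    22 -> 30 ℃ step within 4 s with no overshoot (k1*100/k2 = 16 ℃ ceiling,
    cooling time constant 2 s)."""

    k1: float = 0.08   # ℃ / (s · %intensity)
    k2: float = 0.5    # 1/s
    ambient: float = 22.0  # ℃


def simulate_plant_temperature(
    current: float, laser_intensity: float, dt: float, params: PlantParams | None = None
) -> float:
    """Advance larva temperature one step under the first-order plant.

    Uses the exact exponential solution of the linear ODE so the update is
    unconditionally stable and monotone toward the intensity-dependent
    equilibrium T_eq = ambient + k1*I/k2.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if not 0.0 <= laser_intensity <= 100.0:
        raise ValueError("laser intensity must be in [0, 100] %")
    p = params or PlantParams()
    t_eq = p.ambient + p.k1 * laser_intensity / p.k2
    return t_eq + (current - t_eq) * float(np.exp(-p.k2 * dt))


@dataclass
class LarvaAgent:
    """One simulated larva: 11-point ground-truth spine plus behaviour state."""

    id: int
    spine_gt: np.ndarray                     # (11, 2) mm, head -> tail
    half_width_profile: np.ndarray = field(default_factory=default_half_width_profile)
    behavior_state: str = "crawl"
    phase: float = 0.0                       # peristalsis / bend phase in [0, 1)
    heading: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    temperature: float = 22.0
    response_model: ResponseModel = field(default_factory=ResponseModel)
    speed_mm_s: float = 0.7                  # mean crawl speed
    max_speed_mm_s: float = 1.5
    bend_angle_deg: float = 60.0             # C-bend amplitude of the head sweep
    _bend_level: float = 0.0                 # current bend fraction of target
    _curl_level: float = 0.0                 # ball curl fraction
    _contract_level: float = 1.0             # body contraction (balled larvae)

    def __post_init__(self) -> None:
        self.spine_gt = np.asarray(self.spine_gt, dtype=float)
        if self.spine_gt.shape != (11, 2):
            raise ValueError("spine_gt must be 11 ordered 2D points")
        if np.any(np.asarray(self.half_width_profile) <= 0):
            raise ValueError("half_width_profile must be positive")

    # -- pose construction -------------------------------------------------
    @property
    def segment_length(self) -> float:
        return DEFAULT_BODY_LENGTH_MM / 10.0

    @property
    def centroid(self) -> np.ndarray:
        return self.spine_gt.mean(axis=0)

    def bend_side(self) -> str:
        if self.behavior_state == "bend_left":
            return "left"
        if self.behavior_state == "bend_right":
            return "right"
        return ""

    def contour(self, n_cap: int = 9) -> np.ndarray:
        """Closed ground-truth outline (mm) from the spine and width profile."""
        return spine_to_contour(self.spine_gt, self.half_width_profile, n_cap=n_cap)


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    # y-down image convention: positive angle turns toward +y (the larva's left)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def build_spine(tail: np.ndarray, heading: np.ndarray, seg_len: float,
                bend_angle: float = 0.0, curl: float = 0.0) -> np.ndarray:
    """Construct an 11-point spine (head->tail) from the tail anchor.

    ``bend_angle`` (rad, + = left) rotates the anterior five segments
    progressively about the neck; ``curl`` is uniform per-segment curvature
    (rad) used for ball/roll poses.
    """
    pts = np.zeros((11, 2))
    pts[10] = tail
    d = heading / np.linalg.norm(heading)
    for i in range(9, -1, -1):
        turn = curl
        if i < 5:  # anterior segments bend about the neck (index 5)
            turn += bend_angle / 5.0
        d = _rot(d, turn)
        pts[i] = pts[i + 1] + d * seg_len
    return pts


def spine_to_contour(spine: np.ndarray, half_widths: np.ndarray, n_cap: int = 9) -> np.ndarray:
    """Offset a spine by its half-width profile into a closed polygon (mm)."""
    spine = np.asarray(spine, float)
    hw = np.asarray(half_widths, float)
    tang = np.gradient(spine, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    norm /= np.maximum(np.linalg.norm(norm, axis=1, keepdims=True), 1e-12)
    left = spine + norm * hw[:, None]
    right = spine - norm * hw[:, None]
    head_dir = spine[0] - spine[1]
    head_dir /= max(np.linalg.norm(head_dir), 1e-12)
    tail_dir = spine[-1] - spine[-2]
    tail_dir /= max(np.linalg.norm(tail_dir), 1e-12)
    # rounded caps at head and tail
    cap_h = []
    cap_t = []
    for k in range(1, n_cap + 1):
        a = np.pi * k / (n_cap + 1)
        cap_h.append(spine[0] + _rot(head_dir, a - np.pi / 2) * hw[0])
        cap_t.append(spine[-1] + _rot(tail_dir, a - np.pi / 2) * hw[-1])
    pts = np.concatenate([
        left[::-1],              # tail -> head on the left side
        np.array(cap_h)[::-1],   # around the head
        right,                   # head -> tail on the right side
        np.array(cap_t)[::-1],
    ])
    return pts


@dataclass
class SceneConfig:
    """Stated world of the plate and camera."""

    plate_size_mm: tuple[float, float] = (230.0, 230.0)
    pixel_scale: float = 72.92           # µm per pixel
    frame_rate: float = 20.0             # Hz
    n_larvae: int = 1
    seed: int = 0
    ambient_temp: float = 22.0
    background_level: float = 12.0
    noise_sd: float = 2.0
    body_intensity: float = 110.0
    plant: PlantParams = field(default_factory=PlantParams)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if self.n_larvae > 16:
            raise ValueError("at most 16 larvae are tracked")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = int(round(self.plate_size_mm[1] * 1000.0 / self.pixel_scale))
        w = int(round(self.plate_size_mm[0] * 1000.0 / self.pixel_scale))
        return (h, w)

    def mm_to_px(self, pts_mm: np.ndarray) -> np.ndarray:
        return np.asarray(pts_mm) * 1000.0 / self.pixel_scale


@dataclass
class GroundTruthLog:
    """Per-(frame, larva) ground truth: state, side, spine, stimulus."""

    table: pd.DataFrame
    spines: dict = field(default_factory=dict)  # (frame, id) -> (11,2) mm

    def spine(self, frame: int, larva_id: int) -> np.ndarray:
        return self.spines[(frame, larva_id)]


class PlacementError(RuntimeError):
    """Raised when overlap-free initial placement fails."""


class SceneSimulator:
    """Stepwise scene simulator usable inside a closed control loop.

    ``step(stimuli)`` advances all agents one frame under the given
    per-larva stimulus (light µW/cm², laser %), renders the 8-bit frame and
    appends ground-truth records.  Identical (config, seed, script) yield
    bitwise-identical output.
    """

    def __init__(self, config: SceneConfig,
                 script: str | Sequence[tuple[str, float]] | None = "crawl",
                 response_model: ResponseModel | None = None,
                 agent_factory: Callable[[int], LarvaAgent] | None = None):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(config.n_larvae + 1)
        self.rng = np.random.default_rng(children[0])
        self._agent_rngs = [np.random.default_rng(c) for c in children[1:]]
        self.frame_index = 0
        self.time_s = 0.0
        self._records: list[dict] = []
        self._spines: dict = {}
        self.script = script
        self.agents: list[LarvaAgent] = []
        self._place_agents(response_model, agent_factory)
        # per-agent behaviour script cursor
        self._script_t0 = [0.0] * len(self.agents)
        self._script_idx = [0] * len(self.agents)
        self._roll_cooldown = [0.0] * len(self.agents)
        self._rw_until = [0.0] * len(self.agents)

    # -- setup -------------------------------------------------------------
    def _place_agents(self, response_model, agent_factory) -> None:
        cfg = self.config
        margin = DEFAULT_BODY_LENGTH_MM * 1.2
        min_sep = DEFAULT_BODY_LENGTH_MM * 2.0
        placed: list[np.ndarray] = []
        for i in range(cfg.n_larvae):
            ok = False
            for _ in range(400):
                pos = self.rng.uniform(margin, np.array(cfg.plate_size_mm) - margin)
                if all(np.linalg.norm(pos - p) > min_sep for p in placed):
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"could not place {cfg.n_larvae} larvae without overlap")
            placed.append(pos)
            ang = self.rng.uniform(0, 2 * np.pi)
            heading = np.array([np.cos(ang), np.sin(ang)])
            tail = pos - heading * DEFAULT_BODY_LENGTH_MM / 2.0
            spine = build_spine(tail, heading, DEFAULT_BODY_LENGTH_MM / 10.0)
            if agent_factory is not None:
                agent = agent_factory(i)
                shift = pos - agent.spine_gt.mean(axis=0)
                agent.spine_gt = agent.spine_gt + shift
            else:
                agent = LarvaAgent(
                    id=i, spine_gt=spine, heading=heading,
                    temperature=cfg.ambient_temp,
                    response_model=replace(response_model) if response_model else ResponseModel(),
                )
            self.agents.append(agent)

    # -- behaviour scheduling ----------------------------------------------
    def _scripted_state(self, i: int) -> str | None:
        s = self.script
        if s is None or s == "random-walk":
            return None
        if isinstance(s, str):
            if s not in BEHAVIOR_STATES:
                raise ValueError(f"unknown scripted state {s!r}")
            return s
        # list of (state, duration)
        t = self.time_s - self._script_t0[i]
        idx = self._script_idx[i]
        while idx < len(s) and t >= s[idx][1]:
            t -= s[idx][1]
            self._script_t0[i] = self.time_s - t
            idx += 1
        self._script_idx[i] = idx
        if idx >= len(s):
            state = s[-1][0]
        else:
            state = s[idx][0]
        if state not in BEHAVIOR_STATES:
            raise ValueError(f"unknown scripted state {state!r}")
        return state

    def _random_walk_state(self, i: int, agent: LarvaAgent,
                           rng: np.random.Generator) -> str:
        # dwell-time wandering: crawl runs punctuated by head sweeps and
        # pauses, with durations typical of freely behaving third instars
        if self.time_s < self._rw_until[i]:
            return agent.behavior_state
        st = agent.behavior_state
        if st == "crawl":
            u = rng.random()
            if u < 0.45:
                nxt = "bend_left" if rng.random() < 0.5 else "bend_right"
                dur = rng.uniform(0.8, 2.5)
            elif u < 0.55:
                nxt, dur = "still", rng.uniform(0.5, 2.0)
            else:
                nxt, dur = "crawl", rng.uniform(2.0, 6.0)
        else:
            nxt, dur = "crawl", rng.uniform(2.0, 6.0)
        self._rw_until[i] = self.time_s + dur
        return nxt

    # -- dynamics ----------------------------------------------------------
    def step(self, stimuli: dict[int, tuple[float, float]] | None = None) -> np.ndarray:
        """Advance one frame.  ``stimuli``: id -> (light µW/cm², laser %)."""
        cfg = self.config
        dt = cfg.dt
        for i, agent in enumerate(self.agents):
            rng = self._agent_rngs[i]
            light, laser = (stimuli or {}).get(agent.id, (0.0, 0.0))
            agent.temperature = simulate_plant_temperature(
                agent.temperature, laser, dt, cfg.plant)
            # stimulus-driven rolling takes precedence over the script
            if agent.behavior_state == "roll":
                if rng.random() < agent.response_model.roll_stop_prob:
                    agent.behavior_state = "crawl"
                    self._roll_cooldown[i] = 1.0
            else:
                p_roll = agent.response_model.roll_probability(light, agent.temperature)
                if self._roll_cooldown[i] > 0:
                    self._roll_cooldown[i] -= dt
                elif rng.random() < p_roll:
                    agent.behavior_state = "roll"
            if agent.behavior_state != "roll":
                scripted = self._scripted_state(i)
                if scripted is not None:
                    agent.behavior_state = scripted
                else:
                    agent.behavior_state = self._random_walk_state(i, agent, rng)
            step_larva(agent, dt, rng=rng)
            self._keep_on_plate(agent)
            self._spines[(self.frame_index, agent.id)] = agent.spine_gt.copy()
            c = agent.centroid
            self._records.append({
                "frame": self.frame_index, "time_s": self.time_s,
                "larva_id": agent.id, "state": agent.behavior_state,
                "side": agent.bend_side(), "x_mm": c[0], "y_mm": c[1],
                "light_uW_cm2": light, "laser_pct": laser,
                "temp_C": agent.temperature,
            })
        frame = self.render()
        self.frame_index += 1
        self.time_s = self.frame_index * dt
        return frame

    def _keep_on_plate(self, agent: LarvaAgent, max_turn: float = 0.12) -> None:
        margin = DEFAULT_BODY_LENGTH_MM
        lo = np.array([margin, margin])
        hi = np.array(self.config.plate_size_mm) - margin
        c = agent.centroid
        if np.any(c < lo) or np.any(c > hi):
            # turn back toward the plate centre, rate-limited so the pose
            # stays kinematically continuous
            to_centre = np.array(self.config.plate_size_mm) / 2.0 - c
            to_centre /= np.linalg.norm(to_centre)
            h = agent.heading / np.linalg.norm(agent.heading)
            ang = np.arctan2(h[0] * to_centre[1] - h[1] * to_centre[0],
                             float(h @ to_centre))
            agent.heading = _rot(h, np.clip(ang, -max_turn, max_turn))

    def render(self) -> np.ndarray:
        cfg = self.config
        h, w = cfg.frame_shape
        img = np.full((h, w), cfg.background_level, dtype=float)
        for agent in self.agents:
            poly_px = cfg.mm_to_px(agent.contour())
            rr, cc = draw_polygon(poly_px[:, 1], poly_px[:, 0], shape=(h, w))
            img[rr, cc] = cfg.body_intensity
        img += self.rng.normal(0.0, cfg.noise_sd, size=img.shape)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    def ground_truth(self) -> GroundTruthLog:
        cols = ["frame", "time_s", "larva_id", "state", "side", "x_mm",
                "y_mm", "light_uW_cm2", "laser_pct", "temp_C"]
        table = pd.DataFrame(self._records, columns=cols)
        return GroundTruthLog(table=table, spines=self._spines)


def step_larva(agent: LarvaAgent, dt: float, rng: np.random.Generator | None = None) -> LarvaAgent:
    """Advance one agent's pose by ``dt`` according to its behaviour state.

    Kinematics are continuous: per-frame spine displacement is bounded by
    the agent's maximum speed.  Mutates and returns ``agent``.
    """
    rng = rng or np.random.default_rng(0)
    st = agent.behavior_state
    seg = agent.segment_length
    tail = agent.spine_gt[10].copy()
    heading = agent.heading / np.linalg.norm(agent.heading)

    if st == "still":
        return agent

    bend_target = np.deg2rad(agent.bend_angle_deg)
    if st == "bend_left":
        agent._bend_level = min(1.0, agent._bend_level + dt / 0.4)
        bend = bend_target * agent._bend_level
        agent._curl_level = max(0.0, agent._curl_level - dt / 0.3)
    elif st == "bend_right":
        agent._bend_level = max(-1.0, agent._bend_level - dt / 0.4)
        bend = bend_target * agent._bend_level
        agent._curl_level = max(0.0, agent._curl_level - dt / 0.3)
    else:
        # relax any bend
        agent._bend_level *= max(0.0, 1.0 - dt / 0.3)
        bend = bend_target * agent._bend_level
        if st == "ball":
            agent._curl_level = min(1.0, agent._curl_level + dt / 0.4)
        elif st == "roll":
            # rolling larvae hold a C-shape, not a closed ball
            target = 0.55
            if agent._curl_level < target:
                agent._curl_level = min(target, agent._curl_level + dt / 0.4)
            else:
                agent._curl_level = max(target, agent._curl_level - dt / 0.3)
        else:
            agent._curl_level = max(0.0, agent._curl_level - dt / 0.3)
    curl = agent._curl_level * (2 * np.pi * 0.95) / 10.0
    # balled larvae contract, closing the C-gap into a compact disc
    target_contract = 0.90 if st == "ball" else 1.0
    step = dt / 0.4
    if agent._contract_level < target_contract:
        agent._contract_level = min(target_contract, agent._contract_level + step)
    else:
        agent._contract_level = max(target_contract, agent._contract_level - step)
    seg = seg * agent._contract_level

    max_step = agent.max_speed_mm_s * dt
    if st == "crawl":
        agent.phase = (agent.phase + dt * 1.0) % 1.0
        v = agent.speed_mm_s * (1.0 + 0.9 * np.sin(2 * np.pi * agent.phase))
        heading = _rot(heading, rng.normal(0.0, 0.01))  # slow course drift
        tail = tail + heading * min(v * dt, max_step)
    elif st == "back":
        agent.phase = (agent.phase + dt * 1.0) % 1.0
        v = 0.6 * agent.speed_mm_s * (1.0 + 0.9 * np.sin(2 * np.pi * agent.phase))
        tail = tail - heading * min(v * dt, max_step)
    elif st == "roll":
        # corkscrew escape: curled body translating laterally
        lateral = _rot(heading, np.pi / 2.0)
        tail = tail + lateral * min(1.4 * dt, max_step)
    agent.heading = heading
    agent.spine_gt = build_spine(tail, heading, seg, bend_angle=bend, curl=curl)
    return agent


def generate_bend_cohort(n_larvae: int, duration_s: float,
                         rate_per_min: float = 6.0,
                         delta_per_min: float = 0.0,
                         seed: int = 0,
                         mean_duration_s: float = 1.2):
    """Synthetic per-larva bend event streams with a known side bias.

    Each larva is assigned a stimulated side (50/50); bends to the
    stimulated side initiate at ``rate_per_min + delta_per_min`` per
    minute, the unstimulated side at ``rate_per_min`` (Poisson).  Returns
    (events_by_larva, side_assignment) where events are
    ``classify.BehaviorEvent`` bends sorted by onset.
    """
    from .classify import BehaviorEvent

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBE]))
    events_by_larva: dict[int, list] = {}
    sides: dict[int, str] = {}
    for lid in range(n_larvae):
        side = "left" if rng.random() < 0.5 else "right"
        sides[lid] = side
        evs = []
        for bend_side in ("left", "right"):
            rate = rate_per_min + (delta_per_min if bend_side == side else 0.0)
            t = 0.0
            while True:
                t += rng.exponential(60.0 / max(rate, 1e-9))
                if t >= duration_s:
                    break
                dur = min(rng.exponential(mean_duration_s) + 0.25, 5.0)
                evs.append(BehaviorEvent("bend", bend_side, t,
                                         min(t + dur, duration_s)))
        evs.sort(key=lambda e: e.t_start)
        # enforce non-overlap by shifting later events after earlier ones
        cleaned = []
        for e in evs:
            if cleaned and e.t_start < cleaned[-1].t_end:
                shift = cleaned[-1].t_end - e.t_start + 0.05
                e = BehaviorEvent(e.behavior, e.side, e.t_start + shift,
                                  e.t_end + shift)
                if e.t_start >= duration_s:
                    continue
            cleaned.append(e)
        events_by_larva[lid] = cleaned
    return events_by_larva, sides


def generate_scene(config: SceneConfig,
                   script: str | Sequence[tuple[str, float]] | None = "crawl",
                   duration_s: float = 10.0,
                   response_model: ResponseModel | None = None,
                   stimulus_fn: Callable[[float], dict[int, tuple[float, float]]] | None = None,
                   ) -> tuple[np.ndarray, GroundTruthLog]:
    """Render a full open-loop scene.

    Returns the (T, H, W) uint8 frame stack and the ground-truth log.
    ``stimulus_fn(time_s)`` may supply open-loop stimuli per larva id.
    """
    sim = SceneSimulator(config, script=script, response_model=response_model)
    n = int(round(duration_s * config.frame_rate))
    frames = np.empty((n, *config.frame_shape), dtype=np.uint8)
    for t in range(n):
        stim = stimulus_fn(sim.time_s) if stimulus_fn is not None else None
        frames[t] = sim.step(stim)
    return frames, sim.ground_truth()
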