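"""Experiment protocols and the closed-loop run engine.

Implements the three experiment families as phase schedules over the
synthetic scene:

* proof-of-principle (open-loop light or heat): 15 s initialisation then
  three rounds of 5 s stimulation + 10 s rest (60 s total);
* classical (trace) conditioning: 30 s initialisation, eight 105 s
  training rounds (20 s light CS, 5 s gap, 20 s IR heating held at the
  target temperature, 60 s rest; backward training swaps CS and US), 60 s
  rest, then three 20 s test illuminations separated by 45 s;
* operant conditioning: 1 min test, four 3 min training rounds in which
  bends to the randomly assigned side trigger light for the bend's full
  duration, separated by 3 min breaks with recentring after the first
  minute, and a final 1 min test.  An uncorrelated-stimulation control
  replays donor stimulus trains per 60 s bin, and a single-larva variant
  runs two training rounds at 385 µW/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import TrackingPipeline, results_to_tables
from .simulate import SceneConfig, SceneSimulator, ResponseModel
from .stimulation import (ThermalController, plan_dmd_frame,
                          schedule_galvanometer, CONTROL_FRAME_MS)

PROTOCOL_KINDS = ("proof_light", "proof_heat", "classical_forward",
                  "classical_backward", "operant", "operant_uncorrelated",
                  "operant_single")


@dataclass(frozen=True)
class Phase:
    name: str
    duration_s: float
    mode: str = "none"        # none | light_open | heat_open | heat_hold | light_on_bend | light_replay
    intensity: float = 0.0    # µW/cm² for light, % for open-loop laser
    target_temp: float | None = None
    recentre_at_s: float | None = None   # offset into the phase

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("phase durations must be positive")


@dataclass
class ProtocolSpec:
    kind: str
    phases: list[Phase]
    light_intensity: float = 285.0

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    def phase_at(self, t: float) -> tuple[Phase, float]:
        """Active phase and offset into it at time ``t``."""
        acc = 0.0
        for p in self.phases:
            if t < acc + p.duration_s:
                return p, t - acc
            acc += p.duration_s
        return self.phases[-1], t - (acc - self.phases[-1].duration_s)


def build_protocol(kind: str, params: dict | None = None) -> ProtocolSpec:
    """Build one of the experiment protocols; ``params`` may scale the
    stated durations/intensities (e.g. for desk-scale simulation runs)."""
    p = params or {}
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}")

    if kind in ("proof_light", "proof_heat"):
        init = p.get("init_s", 15.0)
        stim = p.get("stim_s", 5.0)
        rest = p.get("rest_s", 10.0)
        rounds = p.get("rounds", 3)
        inten = p.get("intensity", 285.0 if kind == "proof_light" else 40.0)
        mode = "light_open" if kind == "proof_light" else "heat_open"
        phases = [Phase("init", init)]
        for r in range(rounds):
            phases.append(Phase(f"stim{r}", stim, mode, inten))
            phases.append(Phase(f"rest{r}", rest))
        return ProtocolSpec(kind, phases, light_intensity=inten)

    if kind in ("classical_forward", "classical_backward"):
        init = p.get("init_s", 30.0)
        cs_s = p.get("cs_s", 20.0)
        gap_s = p.get("gap_s", 5.0)
        us_s = p.get("us_s", 20.0)
        rest_s = p.get("rest_s", 60.0)
        rounds = p.get("rounds", 8)
        inten = p.get("intensity", 550.0)
        target = p.get("target_temp", 27.5)
        test_s = p.get("test_s", 20.0)
        test_gap = p.get("test_gap_s", 45.0)
        test_rounds = p.get("test_rounds", 3)
        phases = [Phase("init", init)]
        for r in range(rounds):
            cs = Phase(f"cs{r}", cs_s, "light_open", inten)
            us = Phase(f"us{r}", us_s, "heat_hold", target_temp=target)
            first, second = (cs, us) if kind == "classical_forward" else (us, cs)
            phases += [first, Phase(f"gap{r}", gap_s), second,
                       Phase(f"rest{r}", rest_s)]
        phases.append(Phase("pre_test", p.get("pre_test_s", 60.0)))
        for r in range(test_rounds):
            phases.append(Phase(f"test{r}", test_s, "light_open", inten))
            phases.append(Phase(f"test_rest{r}", test_gap))
        return ProtocolSpec(kind, phases, light_intensity=inten)

    # operant family
    test_s = p.get("test_s", 60.0)
    train_s = p.get("train_s", 180.0)
    break_s = p.get("break_s", 180.0)
    rounds = p.get("rounds", 2 if kind == "operant_single" else 4)
    inten = p.get("intensity", 385.0 if kind == "operant_single" else 285.0)
    mode = "light_replay" if kind == "operant_uncorrelated" else "light_on_bend"
    phases = [Phase("test_pre", test_s)]
    for r in range(rounds):
        phases.append(Phase(f"train{r}", train_s, mode, inten))
        if r < rounds - 1 or kind != "operant_single":
            phases.append(Phase(f"break{r}", break_s,
                                recentre_at_s=None if kind == "operant_single"
                                else min(60.0, break_s / 3.0)))
    if kind == "operant_single" and rounds > 1:
        # single-larva variant: one break between the two training rounds
        phases = [Phase("test_pre", test_s),
                  Phase("train0", train_s, mode, inten),
                  Phase("break0", break_s),
                  Phase("train1", train_s, mode, inten)]
    phases.append(Phase("test_post", test_s))
    return ProtocolSpec(kind, phases, light_intensity=inten)


# ---------------------------------------------------------------------------
# closed-loop run
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    track: pd.DataFrame
    behavior: pd.DataFrame
    stimulus: pd.DataFrame
    ground_truth: pd.DataFrame
    side_assignment: dict[int, str] = field(default_factory=dict)
    seed: int = 0
    kind: str = ""


def reassign_uncorrelated_stimuli(donor_stimulus: pd.DataFrame,
                                  recipient_ids: list[int],
                                  duration_s: float,
                                  rng: np.random.Generator,
                                  bin_s: float = 60.0,
                                  frame_dt: float = 0.05) -> dict:
    """Sample per-(bin, recipient) donor light trains.

    For each 60 s bin every recipient receives the stimulus train of a
    donor object from the same bin, chosen uniformly at random (with
    replacement when recipients outnumber donors), time-shifted to
    bin-relative coordinates.  Returns {(bin, recipient_id): train array}.
    """
    if donor_stimulus.empty:
        raise ValueError("donor stimulus log is empty")
    n_bins = int(np.ceil(duration_s / bin_s))
    frames_per_bin = int(round(bin_s / frame_dt))
    donor = donor_stimulus[donor_stimulus["modality"] == "light"]
    out = {}
    for b in range(n_bins):
        t0, t1 = b * bin_s, (b + 1) * bin_s
        sub = donor[(donor["time_s"] >= t0) & (donor["time_s"] < t1)]
        donor_ids = sorted(sub["id"].unique())
        if not donor_ids:
            raise ValueError(f"donor bin {b} is empty")
        trains = {}
        for did in donor_ids:
            tr = np.zeros(frames_per_bin)
            dsub = sub[sub["id"] == did]
            idx = np.round((dsub["time_s"].to_numpy() - t0) / frame_dt).astype(int)
            idx = np.clip(idx, 0, frames_per_bin - 1)
            tr[idx] = dsub["intensity"].to_numpy()
            trains[did] = tr
        for rid in recipient_ids:
            pick = donor_ids[rng.integers(len(donor_ids))]
            out[(b, rid)] = trains[pick]
    return out


class ClosedLoopRunner:
    """Steps simulator, pipeline, protocol rule and virtual actuators."""

    def __init__(self, scene_config: SceneConfig, protocol: ProtocolSpec,
                 seed: int = 0,
                 response_model: ResponseModel | None = None,
                 script="random-walk",
                 detect_every: int = 1,
                 donor_stimulus: pd.DataFrame | None = None,
                 thresholds=None):
        self.config = scene_config
        self.protocol = protocol
        self.seed = seed
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1]))
        self.sim = SceneSimulator(scene_config, script=script,
                                  response_model=response_model)
        bg = np.full(scene_config.frame_shape, scene_config.background_level,
                     dtype=np.uint8)
        self.pipeline = TrackingPipeline(
            pixel_scale_um=scene_config.pixel_scale, background=bg,
            detect_every=detect_every, thresholds=thresholds,
            frame_dt=scene_config.dt)
        self.controller = ThermalController()
        self.side_assignment: dict[int, str] = {}
        self.donor_stimulus = donor_stimulus
        self._replay = None
        self._stim_rows: list[dict] = []
        self._per_frame: list = []
        self._pending: dict[int, tuple[float, float]] = {}
        self._recentred: set[str] = set()

    def _assigned_side(self, track_id: int) -> str:
        if track_id not in self.side_assignment:
            self.side_assignment[track_id] = (
                "left" if self.rng.random() < 0.5 else "right")
        return self.side_assignment[track_id]

    def run(self) -> RunResult:
        cfg = self.config
        n_frames = int(round(self.protocol.total_duration_s * cfg.frame_rate))
        if self.protocol.kind == "operant_uncorrelated":
            if self.donor_stimulus is None:
                raise ValueError("uncorrelated control requires a donor log")
        for fi in range(n_frames):
            t = fi * cfg.dt
            phase, offset = self.protocol.phase_at(t)
            self._maybe_recentre(phase, offset)
            frame = self.sim.step(self._pending)   # stimuli from last frame
            larvae = self.pipeline.process_frame(frame, time_s=t)
            self._per_frame.append(larvae)
            self._pending = self._plan_stimuli(phase, larvae, fi, t)
        track, behavior = results_to_tables(self._per_frame, cfg.dt)
        gt = self.sim.ground_truth().table
        stim = pd.DataFrame(self._stim_rows, columns=[
            "control_frame", "time_s", "id", "modality", "intensity",
            "x_mm", "y_mm", "dwell_ms", "latency_ms"])
        return RunResult(track=track, behavior=behavior, stimulus=stim,
                         ground_truth=gt, side_assignment=dict(self.side_assignment),
                         seed=self.seed, kind=self.protocol.kind)

    def _maybe_recentre(self, phase: Phase, offset: float) -> None:
        if phase.recentre_at_s is None or phase.name in self._recentred:
            return
        if offset >= phase.recentre_at_s:
            self._recentred.add(phase.name)
            centre = np.array(self.config.plate_size_mm) / 2.0
            n = len(self.sim.agents)
            for i, agent in enumerate(self.sim.agents):
                ang = 2 * np.pi * i / max(n, 1)
                target = centre + 8.0 * np.array([np.cos(ang), np.sin(ang)])
                shift = target - agent.centroid
                agent.spine_gt = agent.spine_gt + shift

    # -- stimulus planning per control frame -------------------------------
    def _plan_stimuli(self, phase: Phase, larvae, fi: int, t: float) -> dict:
        cfg = self.config
        mm = cfg.pixel_scale / 1000.0
        light_cmds: dict[int, tuple[np.ndarray, float]] = {}
        heat = phase.mode in ("heat_open", "heat_hold")

        if phase.mode == "light_open":
            for lv in larvae:
                light_cmds[lv.id] = (lv.centroid_px * mm, phase.intensity)
        elif phase.mode == "light_on_bend":
            for lv in larvae:
                if lv.flags is None:
                    continue
                side = self._assigned_side(lv.id)
                bending_to_side = (lv.flags.left if side == "left"
                                   else lv.flags.right)
                if bending_to_side:
                    light_cmds[lv.id] = (lv.centroid_px * mm, phase.intensity)
        elif phase.mode == "light_replay":
            if self._replay is None:
                ids = sorted({lv.id for fr in self._per_frame for lv in fr}
                             | {lv.id for lv in larvae} | set(range(64)))
                self._replay = reassign_uncorrelated_stimuli(
                    self.donor_stimulus, list(ids),
                    self.protocol.total_duration_s, self.rng,
                    frame_dt=cfg.dt)
            b = int(t // 60.0)
            k = fi - int(round(b * 60.0 / cfg.dt))
            for lv in larvae:
                train = self._replay.get((b, lv.id))
                if train is None or k >= len(train):
                    continue
                if train[k] > 0:
                    light_cmds[lv.id] = (lv.centroid_px * mm, float(train[k]))

        stimuli: dict[int, tuple[float, float]] = {}
        if light_cmds:
            field_plan = plan_dmd_frame(light_cmds, plate_size_mm=cfg.plate_size_mm,
                                        control_frame_index=fi)
            for agent in self.sim.agents:
                inten = float(field_plan.intensity_at(agent.centroid)[0])
                if inten > 0:
                    stimuli[agent.id] = (inten, 0.0)
            for lid, (pos, inten) in light_cmds.items():
                self._stim_rows.append({
                    "control_frame": fi, "time_s": t, "id": lid,
                    "modality": "light", "intensity": inten,
                    "x_mm": pos[0], "y_mm": pos[1], "dwell_ms": np.nan,
                    "latency_ms": CONTROL_FRAME_MS})

        if heat:
            positions = [tuple(lv.centroid_px * mm) for lv in larvae] or [None]
            if phase.mode == "heat_open":
                laser = phase.intensity
                slots = schedule_galvanometer(
                    positions, laser_pct=laser,
                    plate_centre_mm=tuple(np.array(cfg.plate_size_mm) / 2.0))
            else:
                self.controller.target_temp = phase.target_temp or 30.0
                slots = []
                for lv, pos in zip(larvae, positions):
                    agent = self._nearest_agent(np.array(pos))
                    measured = agent.temperature if agent else cfg.ambient_temp
                    laser = self.controller.intensity(measured)
                    slots += schedule_galvanometer(
                        [pos], laser_pct=laser,
                        frame_budget_ms=CONTROL_FRAME_MS / max(len(positions), 1),
                        gap_ms=0.0,
                        plate_centre_mm=tuple(np.array(cfg.plate_size_mm) / 2.0))
            for slot, lv in zip(slots, larvae):
                agent = self._nearest_agent(np.array(slot.target_mm))
                if agent is not None and slot.laser_pct > 0:
                    prev = stimuli.get(agent.id, (0.0, 0.0))
                    stimuli[agent.id] = (prev[0], slot.laser_pct)
                self._stim_rows.append({
                    "control_frame": fi, "time_s": t, "id": lv.id,
                    "modality": "heat", "intensity": slot.laser_pct,
                    "x_mm": slot.target_mm[0], "y_mm": slot.target_mm[1],
                    "dwell_ms": slot.dwell_ms, "latency_ms": 2 * CONTROL_FRAME_MS})
        return stimuli

    def _nearest_agent(self, pos_mm: np.ndarray, radius_mm: float = 6.0):
        best, best_d = None, np.inf
        for agent in self.sim.agents:
            d = float(np.linalg.norm(agent.centroid - pos_mm))
            if d < best_d:
                best, best_d = agent, d
        return best if best_d <= radius_mm else None


def run_closed_loop(scene_config: SceneConfig, protocol: ProtocolSpec,
                    seed: int = 0, **kwargs) -> RunResult:
    """Convenience wrapper: build a runner and execute the protocol."""
    return ClosedLoopRunner(scene_config, protocol, seed=seed, **kwargs).run()
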