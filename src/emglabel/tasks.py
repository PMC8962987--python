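"""2D cursor task environments and performance measures.

Aiming task (AT): a target circle sits 400 px from the screen center along a
cardinal axis; the cursor integrates the decoder's velocity command (scaled
to about 600 px/s at command 1) and must dwell inside the circle for 500 ms
within a 10 s timeout.  Tracking task (TT): the target moves at constant
speed along one DoF, center -> +400 -> -400 -> center (1600 px, two turns),
and the cursor should stay on it.

Performance measures: success, completion/gross/fine motion time, path
efficiency and speeds over the gross-motion section, overshoot count for the
AT; time-averaged cursor-target distance and average travel speed for the TT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import sliding_td_features
from .synth import (EMGEmitter, OperatorConfig, SynthConfig,
                    simulated_operator_step)

__all__ = [
    "TaskConfig",
    "TrialLog",
    "TrialMetrics",
    "TrialAbort",
    "OraclePolicy",
    "ScriptedPolicy",
    "DecoderPolicy",
    "run_aiming_trial",
    "run_tracking_trial",
    "aiming_metrics",
    "tracking_metrics",
    "run_experiment",
    "DIRECTION_VECTORS",
]

DIRECTION_VECTORS = {
    "+x": np.array([1.0, 0.0]), "-x": np.array([-1.0, 0.0]),
    "+y": np.array([0.0, 1.0]), "-y": np.array([0.0, -1.0]),
}


@dataclass
class TaskConfig:
    at_target_distance: float = 400.0   # px
    target_radius: float = 40.0         # px (not printed in the study; see docs)
    dwell_to_succeed: float = 500.0     # ms
    timeout: float = 10.0               # s
    start_rest_dwell: float = 2.0       # s (modeled as inter-trial reset)
    max_cursor_speed: float = 600.0     # px/s at command magnitude 1
    tt_target_speed: float = 100.0      # px/s
    tt_total_travel: float = 1600.0     # px
    tt_turns: int = 2
    sequences_per_experiment: int = 5
    tick_rate: float = 50.0             # Hz

    def __post_init__(self) -> None:
        for name in ("at_target_distance", "target_radius", "dwell_to_succeed",
                     "timeout", "max_cursor_speed", "tt_target_speed",
                     "tt_total_travel", "sequences_per_experiment",
                     "tick_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # center -> +e -> -e -> center along one axis: travel = 4 * excursion
        if self.tt_turns != 2:
            raise ValueError("only the two-turn tracking profile is supported")
        self.tt_excursion = self.tt_total_travel / 4.0


class TrialAbort(RuntimeError):
    """The command source produced non-finite output."""


@dataclass
class TrialLog:
    t: np.ndarray                # (n,)
    cursor: np.ndarray           # (n, 2)
    target: np.ndarray           # (n, 2)
    commands: np.ndarray         # (n, 2)
    events: list = field(default_factory=list)   # (name, time) ordered
    task: str = "AT"
    direction: str = "+x"

    def event_time(self, name: str) -> float | None:
        for ev, t in self.events:
            if ev == name:
                return t
        return None

    @property
    def success(self) -> bool:
        return self.event_time("success") is not None


@dataclass
class TrialMetrics:
    success: bool = False
    completion_time: float = np.nan
    gross_motion_time: float = np.nan
    fine_motion_time: float = np.nan
    path_efficiency: float = np.nan
    avg_speed: float = np.nan
    max_speed: float = np.nan
    overshoot_count: int = 0
    tt_avg_distance: float = np.nan
    tt_avg_speed: float = np.nan


# ---------------------------------------------------------------------------
# command sources ("policies"): start_trial(rng) then command(cursor, target, dt)

class OraclePolicy:
    """Ideal operator bypassing EMG: aims straight, eases off near the target."""

    def __init__(self, ramp_distance: float = 60.0, gain: float = 1.0):
        self.ramp_distance = ramp_distance
        self.gain = gain

    def start_trial(self, rng) -> None:
        pass

    def command(self, cursor, target, dt) -> np.ndarray:
        delta = np.asarray(target, float) - np.asarray(cursor, float)
        dist = float(np.hypot(*delta))
        if dist == 0.0:
            return np.zeros(2)
        return (self.gain * min(1.0, dist / self.ramp_distance)
                * delta / dist)


class ScriptedPolicy:
    """Replays a fixed command sequence (zeros once exhausted)."""

    def __init__(self, commands):
        self.commands = [np.asarray(c, dtype=float) for c in commands]

    def start_trial(self, rng) -> None:
        self._it = iter(self.commands)

    def command(self, cursor, target, dt) -> np.ndarray:
        return next(self._it, np.zeros(2))


class DecoderPolicy:
    """Closed loop: simulated operator -> synthetic EMG -> features -> decoder.

    Per tick the operator's intended direction/intensity drives the EMG
    emitter for ``sample_rate * dt`` raw samples; TD features of the trailing
    window (DC-removed with the rest profile) are decoded into the velocity
    command.
    """

    def __init__(self, decoder, profile, synth_cfg: SynthConfig,
                 operator: OperatorConfig | None = None):
        self.decoder = decoder
        self.profile = profile
        self.synth_cfg = synth_cfg
        self.operator = operator if operator is not None else OperatorConfig()
        self._emitter = None
        self._rng = None

    def start_trial(self, rng) -> None:
        self._rng = rng
        self._emitter = EMGEmitter(self.synth_cfg, self.profile.window, rng)
        self._t = 0.0

    def command(self, cursor, target, dt) -> np.ndarray:
        if self._t < self.operator.reaction_delay:
            direction, intensity = np.zeros(2), 0.0
        else:
            direction, intensity = simulated_operator_step(
                cursor, target, self.operator, self._rng)
        self._t += dt
        n_new = max(1, int(round(self.synth_cfg.sample_rate * dt)))
        window = self._emitter.advance(direction, intensity, n_new)
        frame = sliding_td_features(window - self.profile.dc_offset,
                                    self.profile.window,
                                    self.profile.deadband)[-1]
        vx, vy = self.decoder.predict_command(frame)
        return np.array([vx, vy])


# ---------------------------------------------------------------------------
# trial loops

def _step(policy, cursor, target, dt, cfg):
    cmd = np.asarray(policy.command(cursor, target, dt), dtype=float)
    if not np.all(np.isfinite(cmd)):
        raise TrialAbort(f"non-finite command {cmd!r}")
    cmd = np.clip(cmd, -1.0, 1.0)
    return cmd, cursor + cmd * cfg.max_cursor_speed * dt


def run_aiming_trial(policy, direction: str, cfg: TaskConfig,
                     rng: np.random.Generator | None = None) -> TrialLog:
    """One aiming trial from screen center toward a cardinal target."""
    rng = np.random.default_rng(0) if rng is None else rng
    target = DIRECTION_VECTORS[direction] * cfg.at_target_distance
    dt = 1.0 / cfg.tick_rate
    dwell_s = cfg.dwell_to_succeed / 1000.0
    policy.start_trial(rng)

    cursor = np.zeros(2)
    ts, cursors, targets, cmds = [0.0], [cursor.copy()], [target.copy()], [np.zeros(2)]
    events = [("start", 0.0)]
    t = 0.0
    contact = False
    inside_since = None
    while t < cfg.timeout:
        cmd, cursor = _step(policy, cursor, target, dt, cfg)
        t += dt
        ts.append(t)
        cursors.append(cursor.copy())
        targets.append(target.copy())
        cmds.append(cmd)
        inside = np.hypot(*(cursor - target)) <= cfg.target_radius
        if inside:
            if not contact:
                contact = True
                events.append(("first_contact", t))
            if inside_since is None:
                inside_since = t
            if t - inside_since >= dwell_s - 0.5 * dt:
                events.append(("success", t))
                break
        else:
            if contact and inside_since is not None:
                events.append(("overshoot", t))
            inside_since = None
    else:
        events.append(("failure", t))
    return TrialLog(np.array(ts), np.array(cursors), np.array(targets),
                    np.array(cmds), events, task="AT", direction=direction)


def tracking_target_position(t, cfg: TaskConfig) -> np.ndarray:
    """Signed 1D target offset at time ``t`` for the two-turn profile."""
    e, v = cfg.tt_excursion, cfg.tt_target_speed
    t = np.asarray(t, dtype=float)
    t1, t2 = e / v, 3 * e / v            # turn instants
    dur = 4 * e / v
    pos = np.where(t < t1, v * t,
                   np.where(t < t2, e - v * (t - t1),
                            -e + v * (np.minimum(t, dur) - t2)))
    return pos


def run_tracking_trial(policy, dof: str, cfg: TaskConfig,
                       rng: np.random.Generator | None = None) -> TrialLog:
    """One tracking trial along one DoF ('x' or 'y')."""
    if dof not in ("x", "y"):
        raise ValueError("dof must be 'x' or 'y'")
    rng = np.random.default_rng(0) if rng is None else rng
    axis = 0 if dof == "x" else 1
    dt = 1.0 / cfg.tick_rate
    duration = cfg.tt_total_travel / cfg.tt_target_speed
    n_ticks = int(round(duration / dt))
    policy.start_trial(rng)

    cursor = np.zeros(2)
    ts, cursors, targets, cmds = [0.0], [cursor.copy()], [np.zeros(2)], [np.zeros(2)]
    events = [("start", 0.0)]
    for k in range(1, n_ticks + 1):
        t = k * dt
        target = np.zeros(2)
        target[axis] = tracking_target_position(t, cfg)
        cmd, cursor = _step(policy, cursor, target, dt, cfg)
        ts.append(t)
        cursors.append(cursor.copy())
        targets.append(target.copy())
        cmds.append(cmd)
    events.append(("path_complete", n_ticks * dt))
    return TrialLog(np.array(ts), np.array(cursors), np.array(targets),
                    np.array(cmds), events, task="TT", direction=dof)


# ---------------------------------------------------------------------------
# metrics

def _path_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def aiming_metrics(log: TrialLog, cfg: TaskConfig) -> TrialMetrics:
    """All aiming-task measures from one trial log."""
    if len(log.t) < 2:
        raise ValueError("incomplete trial log")
    m = TrialMetrics()
    t_contact = log.event_time("first_contact")
    t_success = log.event_time("success")
    m.overshoot_count = sum(1 for ev, _ in log.events if ev == "overshoot")
    m.success = t_success is not None
    if t_contact is None:
        return m
    ic = int(np.searchsorted(log.t, t_contact))
    gross = log.cursor[: ic + 1]
    m.gross_motion_time = t_contact
    straight = float(np.linalg.norm(gross[-1] - gross[0]))
    traveled = _path_length(gross)
    m.path_efficiency = straight / traveled if traveled > 0 else np.nan
    dt = np.diff(log.t[: ic + 1])
    steps = np.linalg.norm(np.diff(gross, axis=0), axis=1)
    m.avg_speed = traveled / t_contact
    m.max_speed = float((steps / dt).max())
    if m.success:
        m.completion_time = t_success
        m.fine_motion_time = t_success - t_contact
    return m


def tracking_metrics(log: TrialLog) -> TrialMetrics:
    """Average cursor-target distance and cursor travel speed of a TT trial."""
    if len(log.t) < 2:
        raise ValueError("empty trial log")
    m = TrialMetrics()
    m.success = True
    dists = np.linalg.norm(log.cursor - log.target, axis=1)
    m.tt_avg_distance = float(dists.mean())
    duration = float(log.t[-1] - log.t[0])
    m.tt_avg_speed = _path_length(log.cursor) / duration
    return m


# ---------------------------------------------------------------------------
# experiment runner

def run_experiment(policies: dict, cfg: TaskConfig, n_subjects: int = 1,
                   seed: int = 0, include_tracking: bool = True) -> pd.DataFrame:
    """Full evaluation: per subject x strategy, 5 AT sequences of all 4
    directions in random order (20 trials) and, optionally, 5 TT sequences of
    both DoFs.  Strategy order follows a Latin square over subjects.

    ``policies`` maps strategy name -> command source.  Returns one row per
    trial with all metrics.
    """
    if not policies:
        raise ValueError("at least one policy is required")
    names = list(policies)
    master = np.random.default_rng(seed)
    rows = []
    for subj in range(n_subjects):
        order = names[subj % len(names):] + names[:subj % len(names)]
        subj_seed = int(master.integers(2**31 - 1))
        for strat in order:
            policy = policies[strat]
            rng = np.random.default_rng((subj_seed, names.index(strat)))
            for seq in range(cfg.sequences_per_experiment):
                dirs = list(DIRECTION_VECTORS)
                rng.shuffle(dirs)
                for d in dirs:
                    log = run_aiming_trial(policy, d, cfg, rng)
                    met = aiming_metrics(log, cfg)
                    rows.append({"subject": subj, "strategy": strat,
                                 "task": "AT", "sequence": seq, "direction": d,
                                 **met.__dict__})
                if include_tracking:
                    for dof in ("x", "y"):
                        log = run_tracking_trial(policy, dof, cfg, rng)
                        met = tracking_metrics(log)
                        rows.append({"subject": subj, "strategy": strat,
                                     "task": "TT", "sequence": seq,
                                     "direction": dof, **met.__dict__})
    return pd.DataFrame(rows)
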