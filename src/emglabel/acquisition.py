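"""Supervised training-protocol state machine.

One cue at a time: accumulate threshold-exceeding ("active") feature frames
for the cued direction until a quota is reached (3000 by default), then wait
for an unbroken run of inactive frames (the rest dwell, 1000 by default)
before cueing the next direction; sweep all directions, repeat for a number
of repetitions.  Only a configurable subset of repetitions (the last three by
default) enters the training set.

Because counting starts at the threshold crossing, the bookkeeping is
invariant to when the operator actually reacts to a cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureStream
from .synth import DIRECTIONS

__all__ = [
    "ProtocolConfig",
    "Segment",
    "TrainingSession",
    "IncompleteSessionError",
    "run_protocol",
    "segment_active_samples",
]


class IncompleteSessionError(RuntimeError):
    """The feature stream ended before the protocol completed."""

    def __init__(self, direction: str, repetition: int, phase: str):
        self.direction = direction
        self.repetition = repetition
        self.phase = phase
        super().__init__(
            f"stream exhausted during {phase} of direction {direction!r}, "
            f"repetition {repetition}")


@dataclass
class ProtocolConfig:
    directions: tuple[str, ...] = DIRECTIONS
    active_quota: int = 3000
    rest_dwell: int = 1000
    repetitions: int = 4
    repetitions_used: tuple[int, ...] | None = None   # default: all but first

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("directions must be non-empty")
        if self.active_quota <= 0 or self.rest_dwell <= 0:
            raise ValueError("active_quota and rest_dwell must be > 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.repetitions_used is None:
            self.repetitions_used = tuple(range(2, self.repetitions + 1)) or (1,)
        self.repetitions_used = tuple(sorted(self.repetitions_used))
        if not self.repetitions_used:
            raise ValueError("repetitions_used must be non-empty")
        if not set(self.repetitions_used) <= set(range(1, self.repetitions + 1)):
            raise ValueError("repetitions_used must be within 1..repetitions")


@dataclass
class Segment:
    """Bookkeeping for one (direction, repetition) cue."""

    direction: str
    repetition: int
    active_idx: np.ndarray    # frame positions counted toward the quota
    pre_idx: np.ndarray       # frames between previous segment and onset
    decay_idx: np.ndarray     # post-quota frames up to rest confirmation
    last_active_decay: int = -1   # last above-threshold frame in the decay
                                  # (end of activation; -1 if none)


@dataclass
class TrainingSession:
    segments: dict = field(default_factory=dict)   # (direction, rep) -> Segment
    cfg: ProtocolConfig | None = None
    stream: FeatureStream | None = None

    def segment(self, direction: str, repetition: int) -> Segment:
        key = (direction, repetition)
        if key not in self.segments:
            raise KeyError(f"no segment for direction {direction!r}, "
                           f"repetition {repetition}")
        return self.segments[key]

    def used_segments(self):
        for rep in self.cfg.repetitions_used:
            for d in self.cfg.directions:
                yield self.segment(d, rep)

    def all_active_positions(self) -> np.ndarray:
        if not self.segments:
            return np.empty(0, dtype=int)
        return np.concatenate(
            [s.active_idx for s in self.segments.values()])


def _first_quiet_run(active: np.ndarray, start: int, dwell: int) -> int:
    """First position >= start where ``dwell`` consecutive frames are inactive.

    Returns the position of the run start, or -1 if the stream ends first.
    A single active frame inside a candidate run restarts the dwell counter.
    """
    n = len(active)
    if start + dwell > n:
        return -1
    cs = np.concatenate([[0], np.cumsum(active[start:])])
    runs = cs[dwell:] - cs[:-dwell]          # active count in each window
    hits = np.flatnonzero(runs == 0)
    return -1 if len(hits) == 0 else start + int(hits[0])


def run_protocol(stream: FeatureStream, cfg: ProtocolConfig) -> TrainingSession:
    """Walk the activity-gated stream through the cue/quota/dwell protocol."""
    active = np.asarray(stream.active, dtype=bool)
    n = len(active)
    session = TrainingSession(cfg=cfg, stream=stream)
    pos = 0
    for rep in range(1, cfg.repetitions + 1):
        for d in cfg.directions:
            hits = np.flatnonzero(active[pos:]) + pos
            if len(hits) < cfg.active_quota:
                raise IncompleteSessionError(d, rep, "active-sample quota")
            active_idx = hits[:cfg.active_quota]
            pre_idx = np.arange(pos, active_idx[0])
            quota_end = int(active_idx[-1])
            rest_start = _first_quiet_run(active, quota_end + 1, cfg.rest_dwell)
            if rest_start < 0:
                raise IncompleteSessionError(d, rep, "rest dwell")
            rest_confirmed = rest_start + cfg.rest_dwell
            decay_idx = np.arange(quota_end + 1, rest_confirmed)
            decay_active = np.flatnonzero(active[quota_end + 1:rest_confirmed])
            last_active = (quota_end + 1 + int(decay_active[-1])
                           if len(decay_active) else -1)
            session.segments[(d, rep)] = Segment(
                direction=d, repetition=rep, active_idx=active_idx,
                pre_idx=pre_idx, decay_idx=decay_idx,
                last_active_decay=last_active)
            pos = rest_confirmed
    return session


def segment_active_samples(session: TrainingSession, direction: str,
                           repetition: int) -> np.ndarray:
    """Frame positions counted toward one segment's active-sample quota."""
    return session.segment(direction, repetition).active_idx
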