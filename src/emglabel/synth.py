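"""Synthetic surface-EMG generation.

Interference-pattern sEMG is emulated as zero-mean Gaussian noise whose
standard deviation is amplitude-modulated by an activation envelope, plus a
per-channel DC offset.  A contraction burst has the phase structure the
labeling method exploits: rest baseline, rising transient, steady-state
plateau, falling flank.  Direction-specific muscle recruitment is modeled by
a (direction x channel) mixing-weight matrix.

A closed-loop simulated operator is also provided so the 2D cursor tasks can
be exercised without a human in the loop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DIRECTIONS",
    "REST_CUE",
    "SynthConfig",
    "OperatorConfig",
    "RawRecording",
    "default_activation_gain",
    "activation_envelope",
    "generate_rest",
    "generate_training_session",
    "simulated_operator_step",
    "EMGEmitter",
]

#: canonical cue tokens for the four cardinal directions, in default cue order
DIRECTIONS: tuple[str, ...] = ("+x", "-x", "+y", "-y")

#: cue token used for rest (no direction cued)
REST_CUE = "rest"


def default_activation_gain(n_channels: int = 8,
                            n_directions: int = 4,
                            crosstalk: float = 0.05) -> np.ndarray:
    """Default direction x channel mixing weights.

    Each direction gets two dominant channels (weight 1.0) — mimicking an
    agonist pair on the forearm/upper arm — and a small cross-talk weight on
    all other channels.  Requires ``n_channels >= 2 * n_directions`` for
    disjoint dominant pairs; otherwise dominant channels wrap around.
    """
    gain = np.full((n_directions, n_channels), crosstalk)
    for d in range(n_directions):
        gain[d, (2 * d) % n_channels] = 1.0
        gain[d, (2 * d + 1) % n_channels] = 1.0
    return gain


@dataclass
class SynthConfig:
    """Parameters of the synthetic EMG model.

    Amplitudes are in volts on the +-5 V scale of a typical wireless sEMG
    system digitized at 1 kHz.  ``burst_amplitude`` is the noise standard
    deviation a fully recruited dominant channel reaches at envelope 1.
    """

    n_channels: int = 8
    sample_rate: float = 1000.0
    rest_noise_sd: float = 0.01
    dc_offset: np.ndarray | None = None
    activation_gain: np.ndarray | None = None
    directions: tuple[str, ...] = DIRECTIONS
    rise_time: float = 400.0       # ms
    fall_time: float = 400.0       # ms
    steady_level: float = 0.8      # relative plateau amplitude in (0, 1]
    envelope_jitter_sd: float = 0.05   # relative sd of per-burst plateau level
    burst_amplitude: float = 0.5   # volts (sd at envelope == 1)
    envelope_shape: str = "linear"     # "linear" | "smoothstep"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.rise_time < 0 or self.fall_time < 0:
            raise ValueError("rise_time and fall_time must be >= 0")
        if not 0 < self.steady_level <= 1:
            raise ValueError("steady_level must be in (0, 1]")
        if self.rest_noise_sd < 0 or self.burst_amplitude <= 0:
            raise ValueError("noise amplitudes must be positive")
        if self.envelope_shape not in ("linear", "smoothstep"):
            raise ValueError(f"unknown envelope_shape {self.envelope_shape!r}")
        if self.dc_offset is None:
            # small channel-dependent offsets so DC removal is exercised
            self.dc_offset = np.linspace(-0.05, 0.05, self.n_channels)
        self.dc_offset = np.asarray(self.dc_offset, dtype=float)
        if self.dc_offset.shape != (self.n_channels,):
            raise ValueError("dc_offset must have one entry per channel")
        if self.activation_gain is None:
            self.activation_gain = default_activation_gain(
                self.n_channels, len(self.directions))
        self.activation_gain = np.asarray(self.activation_gain, dtype=float)
        if self.activation_gain.shape != (len(self.directions), self.n_channels):
            raise ValueError("activation_gain must be (n_directions, n_channels)")
        if np.any(self.activation_gain < 0) or np.any(self.activation_gain > 1):
            raise ValueError("mixing weights must lie in [0, 1]")
        if np.any(self.activation_gain.max(axis=1) <= 0):
            raise ValueError("each direction needs at least one nonzero weight")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def gain_row(self, direction: str) -> np.ndarray:
        try:
            return self.activation_gain[self.directions.index(direction)]
        except ValueError as err:
            raise KeyError(f"unknown direction {direction!r}") from err

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class OperatorConfig:
    """Simulated operator: aims at the target, easing off as it closes in.

    ``ramp_distance`` is the distance (px) below which intended intensity
    scales down linearly — this is what enables fine motion.  Noise terms add
    trial-to-trial human variability.
    """

    ramp_distance: float = 120.0       # px
    max_intensity: float = 0.9
    reaction_delay: float = 0.15       # s at trial start
    direction_noise_sd: float = 0.10   # radians
    intensity_noise_sd: float = 0.05


@dataclass
class RawRecording:
    """Raw multi-channel EMG with per-sample cue annotations."""

    samples: np.ndarray          # (n_samples, n_channels) volts
    sample_rate: float
    cue: np.ndarray              # (n_samples,) cue token per sample
    repetition: np.ndarray       # (n_samples,) repetition index (0 = none)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (time, channel) matrix")
        self.cue = np.asarray(self.cue)
        self.repetition = np.asarray(self.repetition, dtype=int)
        n = self.samples.shape[0]
        if len(self.cue) != n or len(self.repetition) != n:
            raise ValueError("annotations must match the sample count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def concat(self, other: "RawRecording") -> "RawRecording":
        if other.sample_rate != self.sample_rate:
            raise ValueError("sample rates differ")
        return RawRecording(
            np.vstack([self.samples, other.samples]),
            self.sample_rate,
            np.concatenate([self.cue, other.cue]),
            np.concatenate([self.repetition, other.repetition]),
        )


def _ramp(u: np.ndarray, shape: str) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    if shape == "smoothstep":
        return u * u * (3.0 - 2.0 * u)
    return u


def activation_envelope(t, onset: float, offset: float,
                        cfg: SynthConfig) -> np.ndarray:
    """Relative contraction amplitude at time ``t`` (seconds).

    Zero before ``onset``, ramps to ``cfg.steady_level`` over ``rise_time``,
    holds the plateau until ``offset``, then ramps back to zero over
    ``fall_time``.  Ramps are linear by default ("smoothstep" optional).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or onset < 0 or offset < 0:
        raise ValueError("times must be non-negative")
    if offset < onset:
        raise ValueError("offset must be >= onset")
    rise = cfg.rise_time / 1000.0
    fall = cfg.fall_time / 1000.0
    if rise > 0:
        up = _ramp((t - onset) / rise, cfg.envelope_shape)
    else:
        up = (t >= onset).astype(float)
    if fall > 0:
        down = _ramp((offset + fall - t) / fall, cfg.envelope_shape)
    else:
        down = (t <= offset).astype(float)
    return cfg.steady_level * np.minimum(up, down)


def generate_rest(duration: float, cfg: SynthConfig,
                  rng: np.random.Generator | None = None) -> RawRecording:
    """Rest-state recording: per-channel DC offset plus baseline noise."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = cfg.rng() if rng is None else rng
    n = int(round(duration * cfg.sample_rate))
    samples = cfg.dc_offset[None, :] + cfg.rest_noise_sd * rng.standard_normal(
        (n, cfg.n_channels))
    cue = np.full(n, REST_CUE, dtype=object)
    rep = np.zeros(n, dtype=int)
    return RawRecording(samples, cfg.sample_rate, cue, rep)


def generate_training_session(directions, cfg: SynthConfig, protocol,
                              rng: np.random.Generator | None = None,
                              plateau_margin: float = 0.6,
                              rest_margin: float = 0.7) -> RawRecording:
    """Cue-guided training session: one contraction burst per cued direction.

    For each repetition sweep and each cued direction, an envelope-modulated
    burst on that direction's weighted channels is generated, long enough for
    the acquisition protocol's active-sample quota, separated by rest gaps
    long enough for its rest dwell.  ``protocol`` needs ``active_quota``,
    ``rest_dwell`` and ``repetitions`` attributes (see
    :class:`emglabel.acquisition.ProtocolConfig`).

    ``plateau_margin`` (seconds) is slack beyond the exact quota duration,
    absorbing the onset-detection latency of the threshold crossing and the
    feature-window warm-up.  Rest gaps last about twice the dwell requirement
    plus ``rest_margin`` — a comfortable pause rather than a sample-exact one,
    which keeps the dwell robust to rare above-threshold rest excursions.
    """
    directions = list(directions)
    for d in directions:
        cfg.gain_row(d)   # validates
    rng = cfg.rng() if rng is None else rng
    fs = cfg.sample_rate
    rise = cfg.rise_time / 1000.0
    fall = cfg.fall_time / 1000.0
    plateau = protocol.active_quota / fs + plateau_margin
    gap = 2.0 * protocol.rest_dwell / fs + rest_margin

    n_lead = int(round(gap * fs))
    n_burst = int(round((rise + plateau + fall) * fs))
    n_gap = int(round(gap * fs))
    reps = protocol.repetitions if directions else 0
    n_total = n_lead + reps * len(directions) * (n_burst + n_gap)
    if not directions:
        n_total = n_lead

    amp = np.zeros(n_total)
    cue = np.full(n_total, REST_CUE, dtype=object)
    rep_idx = np.zeros(n_total, dtype=int)
    sd = np.full((n_total, cfg.n_channels), cfg.rest_noise_sd)

    pos = n_lead
    for rep in range(1, reps + 1):
        for d in directions:
            t_local = np.arange(n_burst) / fs
            level = float(np.clip(
                cfg.steady_level * (1.0 + cfg.envelope_jitter_sd
                                    * rng.standard_normal()),
                0.05, 1.0))
            burst_cfg = cfg.replace(steady_level=level)
            env = activation_envelope(t_local, 0.0, rise + plateau, burst_cfg)
            sl = slice(pos, pos + n_burst)
            amp[sl] = env
            cue[sl] = d
            rep_idx[sl] = rep
            sd[sl] = (cfg.rest_noise_sd
                      + env[:, None] * cfg.gain_row(d)[None, :]
                      * cfg.burst_amplitude)
            pos += n_burst + n_gap

    samples = cfg.dc_offset[None, :] + sd * rng.standard_normal(
        (n_total, cfg.n_channels))
    return RawRecording(samples, fs, cue, rep_idx)


def simulated_operator_step(cursor, target, ocfg: OperatorConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, float]:
    """Intended movement of the simulated operator for one control tick.

    Returns a unit direction vector pointing from cursor to target and an
    intensity in [0, 1] that falls off linearly inside ``ramp_distance``.
    With ``rng`` given, direction and intensity noise are applied.
    """
    cursor = np.asarray(cursor, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(cursor)) and np.all(np.isfinite(target))):
        raise ValueError("coordinates must be finite")
    delta = target - cursor
    dist = float(np.hypot(*delta))
    if dist == 0.0:
        return np.zeros(2), 0.0
    direction = delta / dist
    intensity = ocfg.max_intensity * min(1.0, dist / ocfg.ramp_distance)
    if rng is not None:
        if ocfg.direction_noise_sd > 0:
            ang = ocfg.direction_noise_sd * rng.standard_normal()
            c, s = np.cos(ang), np.sin(ang)
            direction = np.array([c * direction[0] - s * direction[1],
                                  s * direction[0] + c * direction[1]])
        if ocfg.intensity_noise_sd > 0:
            intensity += ocfg.intensity_noise_sd * rng.standard_normal()
    return direction, float(np.clip(intensity, 0.0, 1.0))


class EMGEmitter:
    """Streams raw EMG for a commanded direction/intensity (closed loop).

    Keeps a rolling buffer so a trailing feature window is always available.
    The mixing of a non-cardinal intended direction interpolates between the
    two relevant cardinal gain rows, weighted by the direction components —
    full intensity reproduces the training plateau amplitude.
    """

    def __init__(self, cfg: SynthConfig, window: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.window = int(window)
        self.rng = rng
        self.reset()

    def reset(self) -> None:
        cfg = self.cfg
        self._buffer = (cfg.dc_offset[None, :]
                        + cfg.rest_noise_sd * self.rng.standard_normal(
                            (self.window, cfg.n_channels)))

    def _mix(self, direction: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        dx, dy = float(direction[0]), float(direction[1])
        mix = np.zeros(cfg.n_channels)
        if dx > 0:
            mix += dx * cfg.gain_row("+x")
        elif dx < 0:
            mix += -dx * cfg.gain_row("-x")
        if dy > 0:
            mix += dy * cfg.gain_row("+y")
        elif dy < 0:
            mix += -dy * cfg.gain_row("-y")
        return np.minimum(mix, 1.0)

    def advance(self, direction, intensity: float, n_samples: int) -> np.ndarray:
        """Generate ``n_samples`` new raw samples; return the trailing window."""
        cfg = self.cfg
        mix = self._mix(np.asarray(direction, dtype=float))
        amp = float(np.clip(intensity, 0.0, 1.0)) * cfg.steady_level
        sd = cfg.rest_noise_sd + amp * mix * cfg.burst_amplitude
        new = (cfg.dc_offset[None, :]
               + sd[None, :] * self.rng.standard_normal(
                   (int(n_samples), cfg.n_channels)))
        self._buffer = np.vstack([self._buffer, new])[-self.window:]
        return self._buffer
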