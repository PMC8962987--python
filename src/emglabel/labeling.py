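"""Continuous label generation from the EMG feature stream.

The core idea: the training feature stream itself carries the intensity
information needed for proportional control, so labels can be computed from
it directly — no force sensor, data glove or tracked visual stimulus.  Per
direction, the 32-feature frames are reduced to 4 electrode-summed streams,
each stream is min-max normalized between the rest mean and its training
maximum, the four are summed and rescaled so the strongest training frame
gets label 1, and the direction's sign is applied.

Five labeling strategies are supported:

A  binary  labels, including the rising transient phase;
B  continuous labels, including the rising transient phase;
C  binary  labels, steady state only (first 1000 active samples discarded);
D  continuous labels, steady state only;
E  continuous labels, including both the rising and the falling transient.

Every strategy takes 2000 of the 3000 active samples available per direction
and repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import TrainingSession
from .features import N_FEATURES_PER_CHANNEL, FeatureStream, RestProfile

__all__ = [
    "LabelStrategy",
    "strategy",
    "STRATEGY_NAMES",
    "NormalizationStats",
    "TrainingData",
    "select_samples",
    "sum_over_electrodes",
    "normalize_feature_stream",
    "combine_to_label",
    "build_training_labels",
    "fraction_below",
]

STRATEGY_NAMES = ("A", "B", "C", "D", "E")

#: degree-of-freedom index and sign per direction token
DOF_SIGN = {"+x": (0, +1.0), "-x": (0, -1.0), "+y": (1, +1.0), "-y": (1, -1.0)}


@dataclass(frozen=True)
class LabelStrategy:
    name: str
    label_kind: str              # "binary" | "continuous"
    segment_rule: str            # "include-rising" | "steady-only" | "rising-and-falling"
    samples_per_segment: int = 2000
    steady_discard: int = 1000   # leading active samples dropped when steady-only
    rising_count: int = 1500     # K: rising/steady samples for rising-and-falling

    def __post_init__(self) -> None:
        if self.label_kind not in ("binary", "continuous"):
            raise ValueError("label_kind must be 'binary' or 'continuous'")
        if self.segment_rule not in ("include-rising", "steady-only",
                                     "rising-and-falling"):
            raise ValueError(f"unknown segment_rule {self.segment_rule!r}")
        if self.samples_per_segment <= 0:
            raise ValueError("samples_per_segment must be > 0")
        if not 0 < self.rising_count <= self.samples_per_segment:
            raise ValueError("rising_count must be in (0, samples_per_segment]")


_STRATEGIES = {
    "A": ("binary", "include-rising"),
    "B": ("continuous", "include-rising"),
    "C": ("binary", "steady-only"),
    "D": ("continuous", "steady-only"),
    "E": ("continuous", "rising-and-falling"),
}


def strategy(name: str, **overrides) -> LabelStrategy:
    """The named labeling strategy (A-E) with optional parameter overrides."""
    try:
        kind, rule = _STRATEGIES[name.upper()]
    except KeyError as err:
        raise ValueError(f"unknown strategy {name!r}; expected one of "
                         f"{STRATEGY_NAMES}") from err
    return LabelStrategy(name=name.upper(), label_kind=kind,
                         segment_rule=rule, **overrides)


@dataclass
class NormalizationStats:
    """Per-direction normalization constants of the label equations."""

    x_min: np.ndarray                       # (4,) rest means, shared
    max_f: dict = field(default_factory=dict)       # direction -> (4,)
    label_max: dict = field(default_factory=dict)   # direction -> float


def select_samples(session: TrainingSession, direction: str, repetition: int,
                   strat: LabelStrategy) -> np.ndarray:
    """Frame positions a strategy draws from one (direction, repetition).

    include-rising: the first ``samples_per_segment`` active samples (the
    rising transient plus early steady state).  steady-only: active samples
    after discarding the first ``steady_discard``.  rising-and-falling: the
    first ``rising_count`` active samples plus a trailing block of
    ``samples_per_segment - rising_count`` decay-context frames ending at the
    end of activation (the last above-threshold frame), so it spans the late
    plateau and the complete falling flank.
    """
    seg = session.segment(direction, repetition)
    n_sel = strat.samples_per_segment
    act = seg.active_idx
    if strat.segment_rule == "include-rising":
        if len(act) < n_sel:
            raise ValueError("segment smaller than samples_per_segment")
        return act[:n_sel]
    if strat.segment_rule == "steady-only":
        lo, hi = strat.steady_discard, strat.steady_discard + n_sel
        if len(act) < hi:
            raise ValueError("segment too short for steady-only selection")
        return act[lo:hi]
    # rising-and-falling
    k = strat.rising_count
    n_trail = n_sel - k
    if len(act) < k:
        raise ValueError("segment too short for the rising block")
    if len(seg.decay_idx) < n_trail:
        raise ValueError(
            f"decay context ({len(seg.decay_idx)} frames) too short for the "
            f"{n_trail}-frame falling block of strategy {strat.name}")
    if n_trail == 0:
        return act[:k]
    decay_start = int(seg.decay_idx[0])
    if seg.last_active_decay >= 0:
        start = max(decay_start, seg.last_active_decay - n_trail + 1)
    else:
        start = decay_start
    return np.concatenate([act[:k], np.arange(start, start + n_trail)])


def sum_over_electrodes(stream: FeatureStream | np.ndarray,
                        indices=None) -> np.ndarray:
    """Reduce 32-feature frames to 4 electrode-summed streams.

    Per feature f, ``x_f[i] = sum_e x_{e,f}[i]`` over all electrodes e.
    """
    feats = stream.features if isinstance(stream, FeatureStream) else np.asarray(stream)
    if indices is not None:
        feats = feats[np.asarray(indices, dtype=int)]
    nf = N_FEATURES_PER_CHANNEL
    return feats.reshape(feats.shape[0], -1, nf).sum(axis=1)


def normalize_feature_stream(x_f: np.ndarray, max_f: np.ndarray,
                             x_min: np.ndarray) -> np.ndarray:
    """Min-max normalize each electrode-summed stream between the rest mean
    and its training maximum.

    Frames quieter than the rest mean are clipped to 0 (the label domain has
    no negative intensities).
    """
    x_f = np.asarray(x_f, dtype=float)
    max_f = np.asarray(max_f, dtype=float)
    x_min = np.asarray(x_min, dtype=float)
    span = max_f - x_min
    if np.any(span <= 0):
        bad = np.flatnonzero(span <= 0)
        raise ValueError(
            f"degenerate normalization: max <= x_min for feature(s) {bad.tolist()}")
    return np.clip((x_f - x_min) / span, 0.0, None)


def combine_to_label(x_prime: np.ndarray, label_max: float | None = None
                     ) -> tuple[np.ndarray, float]:
    """Sum the four normalized streams and rescale so the maximum label is 1.

    Returns the unsigned label stream and the normalizer used.  When
    ``label_max`` is None it is taken from the data (training mode).
    """
    s = np.asarray(x_prime, dtype=float).sum(axis=1)
    if label_max is None:
        label_max = float(s.max()) if s.size else 0.0
    if label_max <= 0:
        raise ValueError("no activity to normalize (label maximum is 0)")
    return s / label_max, label_max


@dataclass
class TrainingData:
    """Feature rows paired with per-DoF labels, ready for decoder fitting."""

    X: np.ndarray                 # (n_rows, 32)
    y: np.ndarray                 # (n_rows, 2): x-DoF, y-DoF labels
    frame_idx: np.ndarray         # stream frame positions of the rows
    strategy: LabelStrategy | None = None
    stats: NormalizationStats | None = None


def _continuous_unsigned(stream: FeatureStream, idx: np.ndarray,
                         x_min: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Run the three label equations on the selected frames of one direction."""
    x_f = sum_over_electrodes(stream, idx)
    max_f = x_f.max(axis=0)
    x_prime = normalize_feature_stream(x_f, max_f, x_min)
    labels, label_max = combine_to_label(x_prime)
    return labels, max_f, label_max


def build_training_labels(session: TrainingSession, strat: LabelStrategy,
                          profile: RestProfile,
                          stream: FeatureStream | None = None,
                          rest_rows: int | None = None,
                          per_repetition_norm: bool = False,
                          rng: np.random.Generator | None = None
                          ) -> TrainingData:
    """Assemble the labeled training set for both DoFs under one strategy.

    Binary strategies label every selected active frame +-1 on the cued DoF;
    continuous strategies compute the electrode-sum / normalize / combine
    chain per direction (normalization pooled over the repetitions used, or
    per repetition with ``per_repetition_norm``) and apply the direction's
    sign.  The other DoF is 0 on every selected frame.  ``rest_rows``
    threshold-inactive frames labeled (0, 0) are appended (defaults to
    ``samples_per_segment``) so the decoder returns to zero at rest.
    """
    stream = stream if stream is not None else session.stream
    if stream is None:
        raise ValueError("a FeatureStream is required")
    cfg = session.cfg
    stats = NormalizationStats(x_min=np.asarray(profile.x_min, dtype=float))
    rows_idx, rows_y = [], []

    for direction in cfg.directions:
        dof, sign = DOF_SIGN[direction]
        per_rep_idx = [select_samples(session, direction, rep, strat)
                       for rep in cfg.repetitions_used]
        if strat.label_kind == "binary":
            for idx in per_rep_idx:
                y = np.zeros((len(idx), 2))
                y[:, dof] = sign
                rows_idx.append(idx)
                rows_y.append(y)
            continue
        if per_repetition_norm:
            for idx in per_rep_idx:
                labels, _, _ = _continuous_unsigned(stream, idx, stats.x_min)
                y = np.zeros((len(idx), 2))
                y[:, dof] = sign * labels
                rows_idx.append(idx)
                rows_y.append(y)
        else:
            idx = np.concatenate(per_rep_idx)
            labels, max_f, label_max = _continuous_unsigned(
                stream, idx, stats.x_min)
            stats.max_f[direction] = max_f
            stats.label_max[direction] = label_max
            y = np.zeros((len(idx), 2))
            y[:, dof] = sign * labels
            rows_idx.append(idx)
            rows_y.append(y)

    # rest rows: frames below the activity threshold, outside any active set
    n_rest = strat.samples_per_segment if rest_rows is None else int(rest_rows)
    if n_rest > 0:
        taken = np.zeros(stream.n_frames, dtype=bool)
        taken[session.all_active_positions()] = True
        candidates = np.flatnonzero(~stream.active & ~taken)
        if len(candidates) < n_rest:
            raise ValueError("not enough inactive frames for the rest rows")
        rng = np.random.default_rng(0) if rng is None else rng
        pick = np.sort(rng.choice(candidates, size=n_rest, replace=False))
        rows_idx.append(pick)
        rows_y.append(np.zeros((n_rest, 2)))

    frame_idx = np.concatenate(rows_idx)
    y = np.vstack(rows_y)
    return TrainingData(X=stream.features[frame_idx], y=y,
                        frame_idx=frame_idx, strategy=strat, stats=stats)


def fraction_below(y: np.ndarray, cut: float = 0.5) -> float:
    """Fraction of nonzero labels with magnitude below ``cut``.

    Mirrors the label-histogram view: rest labels (exactly 0) are excluded.
    """
    mags = np.abs(np.asarray(y, dtype=float)).ravel()
    mags = mags[mags > 0]
    if mags.size == 0:
        raise ValueError("no nonzero labels")
    return float(np.mean(mags < cut))
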