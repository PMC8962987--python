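"""Hudgins time-domain features, rest profile and activity gating.

The four time-domain (TD) features — mean absolute value (MAV), waveform
length (WL), zero crossings (ZC) and slope-sign changes (SSC) — are computed
per channel on a causal sliding window of 150 samples with step 1, exactly as
an online 1 kHz control loop would.  With 8 channels this yields the
32-element feature frame consumed by labeling and decoding.

A rest recording provides the rest profile: per-channel DC offsets, the
per-feature rest means of the electrode-summed streams (the ``x_min`` of the
label normalization) and the activity threshold that separates voluntary
contraction from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import RawRecording

__all__ = [
    "FEATURE_NAMES",
    "RestProfile",
    "FeatureStream",
    "td_features",
    "sliding_td_features",
    "TDFeatureExtractor",
    "compute_rest_profile",
    "feature_stream",
    "activity_signal",
]

#: per-channel feature order within a frame (channel-major layout)
FEATURE_NAMES = ("mav", "wl", "zc", "ssc")

N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)


def _windowed_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Sum of each length-``w`` trailing window along axis 0 (step 1)."""
    cs = np.cumsum(a, axis=0, dtype=float)
    cs = np.concatenate([np.zeros((1,) + a.shape[1:]), cs], axis=0)
    return cs[w:] - cs[:-w]


def sliding_td_features(samples: np.ndarray, window: int = 150,
                        deadband: float = 0.0) -> np.ndarray:
    """TD features of every causal window of a (time x channel) signal.

    Returns a ``(n - window + 1, n_channels * 4)`` matrix; frame ``i`` covers
    samples ``i .. i + window - 1`` (so frame 0 is aligned with sample index
    ``window - 1``).  Columns are channel-major: ``ch0-mav, ch0-wl, ch0-zc,
    ch0-ssc, ch1-mav, ...``.  DC offset must already be removed for ZC to be
    meaningful.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.ndim != 2:
        raise ValueError("samples must be (time, channel)")
    n, c = x.shape
    if n < window:
        raise ValueError(f"need at least {window} samples, got {n}")
    if window < 3:
        raise ValueError("window must be >= 3")

    mav = _windowed_sum(np.abs(x), window) / window

    d = np.diff(x, axis=0)                       # (n-1, c)
    wl = _windowed_sum(np.abs(d), window - 1)

    # zero crossing between consecutive samples: strict sign change, with the
    # amplitude step exceeding the deadband when one is configured
    zc_ind = (x[:-1] * x[1:]) < 0
    if deadband > 0:
        zc_ind &= np.abs(d) > deadband
    zc = _windowed_sum(zc_ind, window - 1)

    # slope-sign change at an interior sample: both neighboring slopes exist
    # and have opposite sign
    ssc_ind = (d[:-1] * d[1:]) < 0               # (n-2, c)
    if deadband > 0:
        ssc_ind &= np.maximum(np.abs(d[:-1]), np.abs(d[1:])) > deadband
    ssc = _windowed_sum(ssc_ind, window - 2)

    out = np.stack([mav, wl, zc, ssc], axis=2)   # (m, c, 4)
    return out.reshape(n - window + 1, c * N_FEATURES_PER_CHANNEL)


def td_features(window_samples: np.ndarray, deadband: float = 0.0,
                window: int | None = None) -> tuple[float, float, int, int]:
    """TD features of one single-channel window (DC already removed)."""
    x = np.asarray(window_samples, dtype=float).ravel()
    if window is not None and len(x) != window:
        raise ValueError(f"window must have exactly {window} samples")
    frame = sliding_td_features(x[:, None], window=len(x), deadband=deadband)[0]
    return float(frame[0]), float(frame[1]), int(frame[2]), int(frame[3])


@dataclass
class RestProfile:
    """Baseline statistics estimated from a rest recording."""

    dc_offset: np.ndarray          # (n_channels,) volts
    x_min: np.ndarray              # (4,) rest mean of electrode-summed features
    activity_threshold: float
    activity_mean: float
    activity_sd: float
    window: int = 150
    deadband: float = 0.0

    def __post_init__(self) -> None:
        self.dc_offset = np.asarray(self.dc_offset, dtype=float)
        self.x_min = np.asarray(self.x_min, dtype=float)
        if not np.all(np.isfinite(self.x_min)):
            raise ValueError("x_min must be finite")
        if self.activity_threshold <= self.activity_mean:
            raise ValueError("activity_threshold must exceed rest mean activity")


@dataclass
class FeatureStream:
    """Time-indexed feature frames with activity gating.

    ``frame_index[i]`` is the raw-sample index the causal window of frame
    ``i`` ends at (1 kHz sample clock).
    """

    features: np.ndarray           # (n_frames, n_channels * 4)
    activity: np.ndarray           # (n_frames,)
    active: np.ndarray             # (n_frames,) bool
    frame_index: np.ndarray        # (n_frames,)
    sample_rate: float
    cue: np.ndarray | None = None         # per-frame cue token
    repetition: np.ndarray | None = None  # per-frame repetition index

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1] // N_FEATURES_PER_CHANNEL

    def mav_columns(self) -> np.ndarray:
        return self.features[:, 0::N_FEATURES_PER_CHANNEL]


class TDFeatureExtractor(TransformerMixin, BaseEstimator):
    """Rest-calibrated TD feature extraction.

    ``fit`` learns the rest profile from a rest-state recording (DC offsets,
    rest feature means, activity threshold at rest mean + ``threshold_k``
    standard deviations of the rest activity signal).  ``transform`` removes
    the DC offset and emits one 4-features-per-channel frame per causal
    sliding window.

    Parameters
    ----------
    window : sliding-window length in samples (150 at 1 kHz).
    deadband : amplitude gate (volts) for the ZC/SSC counts; 0 disables it.
        The default of 0.02 V sits a little above typical baseline noise so
        the crossing counts reflect contraction rather than noise chatter —
        on a Gaussian baseline a zero deadband makes ZC/SSC amplitude-
        invariant and therefore uninformative.
    threshold_k : multiples of the rest activity standard deviation added to
        the rest activity mean to form the activity threshold.  The default
        of 4 keeps rare rest excursions of the smooth activity signal below
        threshold so a strict consecutive rest dwell can complete.
    """

    def __init__(self, window: int = 150, deadband: float = 0.02,
                 threshold_k: float = 4.0):
        self.window = window
        self.deadband = deadband
        self.threshold_k = threshold_k

    @staticmethod
    def _as_samples(X) -> np.ndarray:
        if isinstance(X, RawRecording):
            return X.samples
        return np.asarray(X, dtype=float)

    def fit(self, X, y=None) -> "TDFeatureExtractor":
        rest = self._as_samples(X)
        if rest.ndim != 2:
            raise ValueError("rest input must be (time, channel)")
        if rest.shape[0] < self.window:
            raise ValueError("rest recording shorter than the feature window")
        self.dc_offset_ = rest.mean(axis=0)
        feats = sliding_td_features(rest - self.dc_offset_,
                                    self.window, self.deadband)
        nf = N_FEATURES_PER_CHANNEL
        summed = feats.reshape(feats.shape[0], -1, nf).sum(axis=1)
        self.x_min_ = summed.mean(axis=0)
        act = feats[:, 0::nf].sum(axis=1)
        self.activity_mean_ = float(act.mean())
        self.activity_sd_ = float(act.std())
        margin = self.threshold_k * self.activity_sd_
        if margin == 0.0:
            # noiseless baseline: keep a strictly positive onset margin
            margin = max(1e-9, 1e-6 * max(self.activity_mean_, 1.0))
        self.activity_threshold_ = self.activity_mean_ + margin
        self.n_features_in_ = rest.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "dc_offset_"):
            raise RuntimeError("extractor is not fitted")
        samples = self._as_samples(X)
        if samples.shape[1] != self.n_features_in_:
            raise ValueError("channel count differs from the fitted rest data")
        return sliding_td_features(samples - self.dc_offset_,
                                   self.window, self.deadband)

    def rest_profile(self) -> RestProfile:
        return RestProfile(self.dc_offset_, self.x_min_,
                           self.activity_threshold_, self.activity_mean_,
                           self.activity_sd_, self.window, self.deadband)

    def activity(self, features: np.ndarray) -> np.ndarray:
        """Scalar activity signal: MAV summed over all channels."""
        return np.asarray(features)[:, 0::N_FEATURES_PER_CHANNEL].sum(axis=1)


def compute_rest_profile(rest: RawRecording, window: int = 150,
                         deadband: float = 0.02,
                         threshold_k: float = 4.0) -> RestProfile:
    """Estimate DC offsets, rest feature means and the activity threshold."""
    return TDFeatureExtractor(window, deadband, threshold_k).fit(rest).rest_profile()


def feature_stream(recording: RawRecording, profile: RestProfile) -> FeatureStream:
    """Feature frames of a recording, activity-gated by the rest profile."""
    samples = recording.samples
    if samples.shape[0] <= profile.window:
        raise ValueError("recording not longer than the feature window")
    feats = sliding_td_features(samples - profile.dc_offset,
                                profile.window, profile.deadband)
    act = feats[:, 0::N_FEATURES_PER_CHANNEL].sum(axis=1)
    active = act > profile.activity_threshold
    idx = np.arange(profile.window - 1, samples.shape[0])
    return FeatureStream(
        features=feats, activity=act, active=active, frame_index=idx,
        sample_rate=recording.sample_rate,
        cue=recording.cue[idx], repetition=recording.repetition[idx])


def activity_signal(stream: FeatureStream, profile: RestProfile
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Scalar activity per frame plus boolean active flags."""
    if stream.n_frames == 0:
        raise ValueError("empty feature stream")
    act = stream.mav_columns().sum(axis=1)
    return act, act > profile.activity_threshold
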