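"""Shared fixtures: small and full-scale synthetic study bundles."""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import emglabel as el

settings.register_profile("ci", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("ci")


@dataclass
class Bundle:
    """One simulated subject: recordings, profile, stream, session."""

    synth: el.SynthConfig
    protocol: el.ProtocolConfig
    rest: el.RawRecording
    recording: el.RawRecording
    profile: el.RestProfile
    stream: el.FeatureStream
    session: el.TrainingSession


def make_bundle(synth: el.SynthConfig, protocol: el.ProtocolConfig,
                rest_duration: float = 3.0) -> Bundle:
    rng = synth.rng()
    rest = el.generate_rest(rest_duration, synth, rng)
    rec = el.generate_training_session(protocol.directions, synth, protocol, rng)
    profile = el.compute_rest_profile(rest)
    stream = el.feature_stream(rec, profile)
    session = el.run_protocol(stream, protocol)
    return Bundle(synth, protocol, rest, rec, profile, stream, session)


#: reduced-scale strategy parameters matching the small protocol below
SMALL_STRATEGY_KW = dict(samples_per_segment=400, steady_discard=200,
                         rising_count=300)


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """Scaled-down session: 600-sample quota, 150-frame dwell, 2 sweeps."""
    synth = el.SynthConfig(seed=7, rise_time=200.0, fall_time=200.0)
    protocol = el.ProtocolConfig(active_quota=600, rest_dwell=150,
                                 repetitions=2, repetitions_used=(2,))
    return make_bundle(synth, protocol)


@pytest.fixture(scope="session")
def full_bundle() -> Bundle:
    """Full-scale session: 3000-sample quota, 1000-frame dwell, 4 sweeps."""
    return make_bundle(el.SynthConfig(seed=11), el.ProtocolConfig(),
                       rest_duration=5.0)


def small_strategy(name: str) -> el.LabelStrategy:
    return el.strategy(name, **SMALL_STRATEGY_KW)


@pytest.fixture(scope="session")
def small_labeled(small_bundle):
    """Labeled training sets for all five strategies on the small session."""
    out = {}
    for name in el.STRATEGY_NAMES:
        out[name] = el.build_training_labels(
            small_bundle.session, small_strategy(name), small_bundle.profile,
            small_bundle.stream, rng=np.random.default_rng(3))
    return out


@pytest.fixture(scope="session")
def full_decoders(full_bundle):
    """GP decoders for strategies A and B at full-scale study conditions."""
    out = {}
    for name in ("A", "B"):
        data = el.build_training_labels(
            full_bundle.session, el.strategy(name), full_bundle.profile,
            full_bundle.stream, rng=np.random.default_rng(3))
        out[name] = el.GPVelocityDecoder(
            budget=400, random_state=0).fit(data.X, data.y)
    return out


@pytest.fixture(scope="session")
def small_decoders(small_labeled):
    """Fitted GP decoders for the binary (A) and continuous (B) strategies."""
    out = {}
    for name in ("A", "B"):
        data = small_labeled[name]
        out[name] = el.GPVelocityDecoder(
            budget=250, random_state=0).fit(data.X, data.y)
    return out
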