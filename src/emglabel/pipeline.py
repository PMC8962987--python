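"""End-to-end pipeline: simulate -> featurize -> acquire -> label -> train ->
evaluate -> stats, driven by one nested configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .acquisition import ProtocolConfig, run_protocol
from .decoder import GPVelocityDecoder
from .features import TDFeatureExtractor, feature_stream
from .labeling import STRATEGY_NAMES, build_training_labels, strategy
from .stats import MEASURES, compare_methods
from .synth import OperatorConfig, SynthConfig, generate_rest, generate_training_session
from .tasks import DecoderPolicy, TaskConfig, run_experiment

log = logging.getLogger("emglabel")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Nested configuration mirroring each stage's own config."""

    seed: int = 0
    strategies: tuple[str, ...] = STRATEGY_NAMES
    strategy_params: dict = field(default_factory=dict)   # LabelStrategy overrides
    rest_duration: float = 5.0          # s of rest recording for calibration
    n_subjects: int = 1                 # simulated operators in evaluation
    decoder_budget: int = 500           # pipeline-scale GP row budget
    synth: SynthConfig = field(default_factory=SynthConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    operator: OperatorConfig = field(default_factory=OperatorConfig)
    feature_window: int = 150
    feature_deadband: float = 0.02
    threshold_k: float = 4.0

    def __post_init__(self) -> None:
        bad = set(s.upper() for s in self.strategies) - set(STRATEGY_NAMES)
        if bad:
            raise ConfigError(f"unknown strategies {sorted(bad)}")
        self.strategies = tuple(s.upper() for s in self.strategies)
        if self.rest_duration <= 0 or self.n_subjects < 1:
            raise ConfigError("rest_duration and n_subjects must be positive")

    def digest(self) -> str:
        blob = json.dumps(_to_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    return obj


_SECTIONS = {"synth": SynthConfig, "protocol": ProtocolConfig,
             "task": TaskConfig, "operator": OperatorConfig}


def load_config(path_or_dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a YAML file or a nested dict."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            try:
                kwargs[key] = _SECTIONS[key](**val)
            except (TypeError, ValueError) as err:
                raise ConfigError(f"section {key!r}: {err}") from err
        else:
            kwargs[key] = val
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages for every requested strategy; artifacts on disk.

    Returns a manifest of artifact paths and stage record counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest = {"config_digest": cfg.digest(), "seed": cfg.seed,
                "stages": {}, "artifacts": {}}

    def stage(name):
        t0 = time.perf_counter()
        def done(**counts):
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3), **counts}
            log.info("stage %-10s %6.2fs %s", name, dt,
                     " ".join(f"{k}={v}" for k, v in counts.items()))
        return done

    done = stage("simulate")
    rest = generate_rest(cfg.rest_duration, cfg.synth, rng)
    session_rec = generate_training_session(
        cfg.protocol.directions, cfg.synth, cfg.protocol, rng)
    rest_path, sess_path = outdir / "rest.csv", outdir / "session.csv"
    eio.write_recording(rest, rest_path)
    eio.write_recording(session_rec, sess_path)
    manifest["artifacts"]["rest"] = str(rest_path)
    manifest["artifacts"]["session"] = str(sess_path)
    done(rest_samples=rest.n_samples, session_samples=session_rec.n_samples)

    done = stage("featurize")
    extractor = TDFeatureExtractor(cfg.feature_window, cfg.feature_deadband,
                                   cfg.threshold_k).fit(rest)
    profile = extractor.rest_profile()
    stream = feature_stream(session_rec, profile)
    feat_path = outdir / "features.csv"
    eio.write_feature_table(stream, feat_path)
    manifest["artifacts"]["features"] = str(feat_path)
    done(frames=stream.n_frames, active=int(stream.active.sum()))

    done = stage("acquire")
    session = run_protocol(stream, cfg.protocol)
    manifest_path = outdir / "session_manifest.json"
    eio.write_session_manifest(session, manifest_path)
    manifest["artifacts"]["session_manifest"] = str(manifest_path)
    done(segments=len(session.segments))

    policies = {}
    for name in cfg.strategies:
        done = stage(f"label[{name}]")
        strat = strategy(name, **cfg.strategy_params)
        data = build_training_labels(session, strat, profile, stream, rng=rng)
        lbl_path = outdir / f"labels_{name}.csv"
        eio.write_label_table(data, lbl_path)
        manifest["artifacts"][f"labels_{name}"] = str(lbl_path)
        done(rows=len(data.y))

        done = stage(f"train[{name}]")
        dec = GPVelocityDecoder(
            budget=cfg.decoder_budget,
            random_state=int(rng.integers(2**31 - 1)))
        dec.fit(data.X, data.y)
        mdl_path = outdir / f"model_{name}.pkl"
        eio.save_model(dec, mdl_path, meta={"strategy": name,
                                            "config_digest": cfg.digest(),
                                            "rows": len(data.y)})
        manifest["artifacts"][f"model_{name}"] = str(mdl_path)
        policies[name] = DecoderPolicy(dec, profile, cfg.synth, cfg.operator)
        done(rows=len(data.y))

    done = stage("evaluate")
    trials = run_experiment(policies, cfg.task, n_subjects=cfg.n_subjects,
                            seed=int(rng.integers(2**31 - 1)))
    trials_path = outdir / "trials.csv"
    trials.to_csv(trials_path, index=False)
    manifest["artifacts"]["trials"] = str(trials_path)
    done(trials=len(trials))

    done = stage("stats")
    reports = []
    for measure in MEASURES:
        if measure not in trials.columns:
            continue
        try:
            cmp_res = compare_methods(trials, measure)
        except ValueError:
            continue
        row = {"measure": measure, "kw_h": cmp_res.kw_h, "kw_p": cmp_res.kw_p}
        reports.append(row)
    stats_path = outdir / "stats.csv"
    import pandas as pd
    pd.DataFrame(reports).to_csv(stats_path, index=False)
    manifest["artifacts"]["stats"] = str(stats_path)
    done(measures=len(reports))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
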