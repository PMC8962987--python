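"""Readers and writers for the pipeline's interchange artifacts.

Canonical interchange is columnar text (CSV with ``#``-prefixed header
metadata).  Recordings can also round-trip through a compact NPZ container
for large runs.  Floats are printed with 17 significant digits so text
round-trips are bit-identical.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureStream
from .synth import DIRECTIONS, REST_CUE, RawRecording

__all__ = [
    "read_recording", "write_recording",
    "read_feature_table", "write_feature_table",
    "read_session_manifest", "write_session_manifest",
    "write_label_table", "read_label_table",
    "save_model", "load_model",
]

_FLOAT_FMT = "%.17g"
_VALID_CUES = set(DIRECTIONS) | {REST_CUE}


class FormatError(ValueError):
    """Malformed artifact file."""


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def write_recording(rec: RawRecording, path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "npz":
        np.savez_compressed(path, samples=rec.samples,
                            sample_rate=rec.sample_rate,
                            cue=np.asarray(rec.cue, dtype=str),
                            repetition=rec.repetition)
        return
    if fmt != "csv":
        raise ValueError(f"unknown recording format {fmt!r}")
    cols = {"time": rec.time}
    for c in range(rec.n_channels):
        cols[f"ch{c + 1}"] = rec.samples[:, c]
    cols["cue"] = rec.cue
    cols["repetition"] = rec.repetition
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={rec.sample_rate}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_recording(path, fmt: str | None = None) -> RawRecording:
    path = Path(path)
    if fmt is None:
        fmt = "npz" if path.suffix == ".npz" else "csv"
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            return RawRecording(z["samples"], float(z["sample_rate"]),
                                z["cue"].astype(object), z["repetition"])
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty recording file")
    meta = _read_meta(path)
    if "sample_rate" not in meta:
        raise FormatError(f"{path}: missing '# sample_rate=' header")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise FormatError(f"{path}: {err}") from err
    if df.empty:
        raise FormatError(f"{path}: no sample rows")
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    for col in ("time", "cue", "repetition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if not chan_cols:
        raise FormatError(f"{path}: no channel columns")
    bad = ~df["cue"].astype(str).isin(_VALID_CUES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: unknown cue token {df['cue'].iloc[row]!r} "
            f"at data row {row + 1}")
    return RawRecording(df[chan_cols].to_numpy(float), float(meta["sample_rate"]),
                        df["cue"].astype(object).to_numpy(),
                        df["repetition"].to_numpy(int))


def write_feature_table(stream: FeatureStream, path) -> None:
    df = pd.DataFrame(stream.features,
                      columns=[f"f{i}" for i in range(stream.features.shape[1])])
    df.insert(0, "frame_index", stream.frame_index)
    df["activity"] = stream.activity
    df["active"] = stream.active.astype(int)
    if stream.cue is not None:
        df["cue"] = stream.cue
    if stream.repetition is not None:
        df["repetition"] = stream.repetition
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={stream.sample_rate}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path) -> FeatureStream:
    path = Path(path)
    meta = _read_meta(path)
    if "sample_rate" not in meta:
        raise FormatError(f"{path}: missing '# sample_rate=' header")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not feat_cols:
        raise FormatError(f"{path}: no feature columns")
    feat_cols = sorted(feat_cols, key=lambda c: int(c[1:]))
    return FeatureStream(
        features=df[feat_cols].to_numpy(float),
        activity=df["activity"].to_numpy(float),
        active=df["active"].to_numpy(bool),
        frame_index=df["frame_index"].to_numpy(int),
        sample_rate=float(meta["sample_rate"]),
        cue=df["cue"].astype(object).to_numpy() if "cue" in df else None,
        repetition=df["repetition"].to_numpy(int) if "repetition" in df else None)


def write_session_manifest(session, path) -> None:
    payload = {
        "directions": list(session.cfg.directions),
        "active_quota": session.cfg.active_quota,
        "rest_dwell": session.cfg.rest_dwell,
        "repetitions": session.cfg.repetitions,
        "repetitions_used": list(session.cfg.repetitions_used),
        "segments": [
            {"direction": s.direction, "repetition": s.repetition,
             "active_idx": s.active_idx.tolist(),
             "pre_range": [int(s.pre_idx[0]), int(s.pre_idx[-1]) + 1]
                          if len(s.pre_idx) else [0, 0],
             "decay_range": [int(s.decay_idx[0]), int(s.decay_idx[-1]) + 1]
                            if len(s.decay_idx) else [0, 0],
             "last_active_decay": int(s.last_active_decay)}
            for s in session.segments.values()
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_session_manifest(path, stream=None):
    from .acquisition import ProtocolConfig, Segment, TrainingSession
    payload = json.loads(Path(path).read_text())
    cfg = ProtocolConfig(
        directions=tuple(payload["directions"]),
        active_quota=payload["active_quota"],
        rest_dwell=payload["rest_dwell"],
        repetitions=payload["repetitions"],
        repetitions_used=tuple(payload["repetitions_used"]))
    session = TrainingSession(cfg=cfg, stream=stream)
    for s in payload["segments"]:
        session.segments[(s["direction"], s["repetition"])] = Segment(
            direction=s["direction"], repetition=s["repetition"],
            active_idx=np.asarray(s["active_idx"], dtype=int),
            pre_idx=np.arange(*s["pre_range"]),
            decay_idx=np.arange(*s["decay_range"]),
            last_active_decay=int(s.get("last_active_decay", -1)))
    return session


def write_label_table(data, path) -> None:
    df = pd.DataFrame(data.X, columns=[f"f{i}" for i in range(data.X.shape[1])])
    df.insert(0, "frame_index", data.frame_idx)
    df["label_x"] = data.y[:, 0]
    df["label_y"] = data.y[:, 1]
    with open(path, "w") as fh:
        name = data.strategy.name if data.strategy is not None else "?"
        fh.write(f"# strategy={name}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_label_table(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    feat_cols = sorted((c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
    if not feat_cols or "label_x" not in df or "label_y" not in df:
        raise FormatError(f"{path}: not a label table")
    return (df[feat_cols].to_numpy(float),
            df[["label_x", "label_y"]].to_numpy(float),
            df["frame_index"].to_numpy(int),
            meta.get("strategy", "?"))


def save_model(model, path, meta: dict | None = None) -> None:
    payload = {"model": model, "meta": meta or {}}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return payload["model"], payload.get("meta", {})
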