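"""Readers and writers: long-format CSV tables, JSON reports, checkpoints.

All tables are plain CSV; model checkpoints are a single ``.npz`` archive
holding the weight arrays plus a JSON metadata entry (model configuration,
feature preset, standardizer statistics, format version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Standardizer
from .model import ModelConfig, SITSFormer

CHECKPOINT_VERSION = 1

LONG_COLUMNS = ["sample_id", "polygon_id", "class_name", "label", "doy",
                "B2", "B4", "B8", "B11", "quality"]


class ParseError(ValueError):
    pass


def write_long_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def read_long_csv(path) -> dict:
    """Read a long-format band table back into model-ready arrays.

    Returns a dict with bands (N, 4, T), doys (T,), quality (N, T),
    labels (N,), polygon_ids (N,), class_names (N,), sample_ids (N,).
    Every sample must cover the same DOY grid.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in LONG_COLUMNS if c not in df.columns
               and c != "class_name"]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df.sort_values(["sample_id", "doy"], kind="stable")
    doys = np.sort(df["doy"].unique())
    sample_ids = df["sample_id"].unique()
    n, t = len(sample_ids), len(doys)
    if len(df) != n * t:
        raise ParseError(f"{path}: samples do not share one DOY grid "
                         f"({len(df)} rows, expected {n * t})")
    bands = np.stack([df[b].to_numpy().reshape(n, t)
                      for b in ("B2", "B4", "B8", "B11")], axis=1)
    head = df.iloc[::t]
    return {
        "bands": bands.astype(np.float32),
        "doys": doys.astype(int),
        "quality": df["quality"].to_numpy().reshape(n, t).astype(int),
        "labels": head["label"].to_numpy().astype(int),
        "polygon_ids": head["polygon_id"].to_numpy(),
        "class_names": (head["class_name"].to_numpy()
                        if "class_name" in df.columns else None),
        "sample_ids": sample_ids,
    }


def write_feature_csv(path, features: np.ndarray, channel_names,
                      doys, valid, labels, polygon_ids,
                      sample_ids=None) -> None:
    """features: (N, T, C) -> long table with one row per sample-timestep."""
    n, t, c = features.shape
    sample_ids = (np.arange(n) if sample_ids is None
                  else np.asarray(sample_ids))
    data = {
        "sample_id": np.repeat(sample_ids, t),
        "polygon_id": np.repeat(np.asarray(polygon_ids), t),
        "label": np.repeat(np.asarray(labels), t),
        "doy": np.tile(np.asarray(doys), n),
        "valid": np.asarray(valid, dtype=int).reshape(-1),
    }
    for j, name in enumerate(channel_names):
        data[name] = features[:, :, j].reshape(-1)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")


def read_feature_csv(path) -> dict:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    meta = {"sample_id", "polygon_id", "label", "doy", "valid"}
    channels = [c for c in df.columns if c not in meta]
    df = df.sort_values(["sample_id", "doy"], kind="stable")
    doys = np.sort(df["doy"].unique())
    n, t = df["sample_id"].nunique(), len(doys)
    if len(df) != n * t:
        raise ParseError(f"{path}: samples do not share one DOY grid")
    feats = np.stack([df[ch].to_numpy().reshape(n, t) for ch in channels],
                     axis=-1)
    head = df.iloc[::t]
    return {"features": feats, "channel_names": channels,
            "doys": doys.astype(int),
            "valid": df["valid"].to_numpy().reshape(n, t).astype(bool),
            "labels": head["label"].to_numpy().astype(int),
            "polygon_ids": head["polygon_id"].to_numpy(),
            "sample_ids": df["sample_id"].unique()}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))


def save_checkpoint(path, model: SITSFormer,
                    standardizer: Standardizer | None = None,
                    feature_preset: str | None = None,
                    extra: dict | None = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": dataclasses.asdict(model.config),
        "feature_preset": feature_preset,
        "standardizer": (json.loads(standardizer.to_json())
                         if standardizer is not None and standardizer.fitted
                         else None),
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, default=_json_default).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (model, standardizer_or_None, feature_preset, meta)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: "
                             f"{meta.get('version')}")
        state = {k[len("param:"):]: z[k] for k in z.files
                 if k.startswith("param:")}
    mc = dict(meta["model_config"])
    mc["stage_bins"] = tuple(mc["stage_bins"])
    model = SITSFormer(ModelConfig(**mc), seed=0)
    model.load_state_dict(state)
    model.eval()
    std = None
    if meta.get("standardizer"):
        std = Standardizer.from_json(json.dumps(meta["standardizer"]))
    return model, std, meta.get("feature_preset"), meta
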