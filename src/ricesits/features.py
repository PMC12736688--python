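"""Phenological feature set: NDVI, LSWI, EVI and their temporal derivatives.

The base indices are normalized band ratios computed per timestep. Two
derivative families describe growth dynamics between consecutive valid
observations: TDVI (plain difference, positive during green-up, negative
during senescence) and NCRVI (relative change as a percentage of the
starting value, baseline-insensitive). Feature presets assemble these into
per-timestep matrices; a train-set-fitted Standardizer provides the
per-channel scaling applied to both splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

ZERO_DENOM_GUARD = 1e-8
NCRVI_BASELINE_GUARD = 1e-6

# EVI constants: gain, red/blue aerosol-resistance terms, canopy adjustment
EVI_G, EVI_C1, EVI_C2, EVI_L = 2.5, 6.0, 7.5, 1.0

BASE_INDICES = ("ndvi", "lswi", "evi")

#: preset -> (base channels, derivative-bearing indices, derivative kinds)
PRESETS = {
    "baseline": (BASE_INDICES, (), ()),
    "+tdvi": (BASE_INDICES, BASE_INDICES, ("tdvi",)),
    "+ncrvi": (BASE_INDICES, BASE_INDICES, ("ncrvi",)),
    "complete": (BASE_INDICES, BASE_INDICES, ("tdvi", "ncrvi")),
    "ndvi-only-derivatives": (BASE_INDICES, ("ndvi",), ("tdvi", "ncrvi")),
}


def _safe_ratio(num, denom, guard):
    num = np.asarray(num, dtype=float)
    denom = np.asarray(denom, dtype=float)
    flag = np.abs(denom) < guard
    out = np.where(flag, 0.0, num / np.where(flag, 1.0, denom))
    return out, flag


def ndvi(b8, b4, return_flag: bool = False):
    """(B8 - B4) / (B8 + B4); 0 (flagged) on a vanishing denominator."""
    out, flag = _safe_ratio(np.asarray(b8, float) - np.asarray(b4, float),
                            np.asarray(b8, float) + np.asarray(b4, float),
                            ZERO_DENOM_GUARD)
    return (out, flag) if return_flag else out


def lswi(b8, b11, return_flag: bool = False):
    """(B8 - B11) / (B8 + B11); sensitive to canopy/field moisture."""
    out, flag = _safe_ratio(np.asarray(b8, float) - np.asarray(b11, float),
                            np.asarray(b8, float) + np.asarray(b11, float),
                            ZERO_DENOM_GUARD)
    return (out, flag) if return_flag else out


def evi(b8, b4, b2, return_flag: bool = False):
    """2.5 (B8 - B4) / (B8 + 6 B4 - 7.5 B2 + 1), the 3-band formulation."""
    b8 = np.asarray(b8, float)
    b4 = np.asarray(b4, float)
    b2 = np.asarray(b2, float)
    out, flag = _safe_ratio(EVI_G * (b8 - b4),
                            b8 + EVI_C1 * b4 - EVI_C2 * b2 + EVI_L,
                            ZERO_DENOM_GUARD)
    return (out, flag) if return_flag else out


def tdvi(vi_t, vi_t_next):
    """Temporal difference VI_{t+dt} - VI_t between consecutive steps."""
    return np.asarray(vi_t_next, float) - np.asarray(vi_t, float)


def ncrvi(vi_t1, vi_t2, return_flag: bool = False):
    """Relative change (VI_t2 - VI_t1)/VI_t1 x 100 (%); 0 when the
    baseline value is within the near-zero guard."""
    vi_t1 = np.asarray(vi_t1, float)
    vi_t2 = np.asarray(vi_t2, float)
    flag = np.abs(vi_t1) < NCRVI_BASELINE_GUARD
    out = np.where(flag, 0.0,
                   (vi_t2 - vi_t1) / np.where(flag, 1.0, vi_t1) * 100.0)
    return (out, flag) if return_flag else out


@dataclass
class FeatureSequence:
    """Per-timestep feature matrix with validity mask and DOY stamps."""

    features: np.ndarray       # (T, C)
    channel_names: list[str]
    doys: np.ndarray           # (T,)
    valid: np.ndarray          # (T,) bool
    delta_t: np.ndarray        # (T,) day gap to previous valid step (0 at
                               # first valid step and at invalid steps)

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]


def preset_channels(preset: str) -> list[str]:
    if preset not in PRESETS:
        raise ValueError(f"unknown feature preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    base, deriv_idx, deriv_kinds = PRESETS[preset]
    names = list(base)
    for kind in deriv_kinds:
        names += [f"{kind}_{ix}" for ix in deriv_idx]
    return names


def _derivative_channels(values: np.ndarray, valid: np.ndarray):
    """Per-row TDVI/NCRVI between consecutive valid steps (vectorised).

    values, valid: (N, T). Returns (tdvi, ncrvi) arrays of shape (N, T),
    zero at invalid steps and at each row's first valid step.
    """
    n, t = values.shape
    pos = np.arange(t)[None, :].repeat(n, axis=0)
    pos = np.where(valid, pos, -1)
    prev = np.maximum.accumulate(np.concatenate(
        [np.full((n, 1), -1), pos[:, :-1]], axis=1), axis=1)
    has_prev = valid & (prev >= 0)
    prev_safe = np.where(prev >= 0, prev, 0)
    rows = np.arange(n)[:, None]
    vprev = values[rows, prev_safe]
    d = np.where(has_prev, values - vprev, 0.0)
    guard = np.abs(vprev) < NCRVI_BASELINE_GUARD
    r = np.where(has_prev & ~guard,
                 (values - vprev) / np.where(guard, 1.0, vprev) * 100.0, 0.0)
    return d, r, has_prev, prev_safe


def assemble_features_batch(index_series: dict[str, np.ndarray],
                            doys: np.ndarray, valid: np.ndarray,
                            preset: str = "complete"):
    """Assemble (N, T, C) feature tensors for a batch of samples.

    index_series maps index name -> (N, T) reconstructed values; all series
    share the DOY grid and validity mask. Derivative channels are computed
    between consecutive valid steps only; the first valid step of each
    sample carries 0 by convention. Invalid steps emit all-zero features.
    Returns (features, channel_names, delta_t).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown feature preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    base, deriv_idx, deriv_kinds = PRESETS[preset]
    missing = [ix for ix in set(base) | set(deriv_idx)
               if ix not in index_series]
    if missing:
        raise ValueError(f"index series missing for {missing}")
    valid = np.asarray(valid, dtype=bool)
    n, t = valid.shape
    doys = np.asarray(doys)

    channels = [np.where(valid, index_series[ix], 0.0) for ix in base]
    deriv_cache = {ix: _derivative_channels(
        np.asarray(index_series[ix], float), valid) for ix in deriv_idx}
    for kind in deriv_kinds:
        for ix in deriv_idx:
            d, r, _, _ = deriv_cache[ix]
            channels.append(d if kind == "tdvi" else r)
    features = np.stack(channels, axis=-1)
    if not np.isfinite(features).all():
        raise ValueError("non-finite feature values encountered")

    if deriv_idx:
        _, _, has_prev, prev_safe = next(iter(deriv_cache.values()))
    else:
        _, _, has_prev, prev_safe = _derivative_channels(
            np.zeros((n, t)), valid)
    dt = np.where(has_prev, doys[None, :] - doys[prev_safe], 0)
    return features, preset_channels(preset), dt


def assemble_features(index_series: dict[str, np.ndarray],
                      doys: np.ndarray, valid: np.ndarray,
                      preset: str = "complete") -> FeatureSequence:
    """Single-sample convenience wrapper around the batch assembler."""
    batch = {k: np.asarray(v, float)[None, :] for k, v in
             index_series.items()}
    feats, names, dt = assemble_features_batch(
        batch, doys, np.asarray(valid, bool)[None, :], preset)
    return FeatureSequence(features=feats[0], channel_names=names,
                           doys=np.asarray(doys),
                           valid=np.asarray(valid, bool), delta_t=dt[0])


class Standardizer:
    """Per-channel zero-mean/unit-sd scaling fitted on training data only."""

    SD_FLOOR = 1e-8

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, features: np.ndarray, valid: np.ndarray) -> "Standardizer":
        """features: (N, T, C); statistics pooled over valid steps."""
        features = np.asarray(features, dtype=float)
        m = np.asarray(valid, bool)
        pool = features[m]          # (n_valid_steps, C)
        self.mean_ = pool.mean(axis=0)
        self.std_ = np.maximum(pool.std(axis=0), self.SD_FLOOR)
        return self

    def transform(self, features: np.ndarray,
                  valid: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("standardizer must be fitted before use")
        features = np.asarray(features, dtype=float)
        z = (features - self.mean_) / self.std_
        return np.where(np.asarray(valid, bool)[..., None], z, 0.0)

    def to_json(self) -> str:
        if not self.fitted:
            raise RuntimeError("cannot serialise an unfitted standardizer")
        return json.dumps({"mean": self.mean_.tolist(),
                           "std": self.std_.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "Standardizer":
        d = json.loads(s)
        obj = cls()
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.std_ = np.asarray(d["std"], dtype=float)
        return obj
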