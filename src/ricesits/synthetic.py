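"""Synthetic Sentinel-2-like scene generator for paddy-rice time series.

Emulates the data the classifier is designed for: per-point multispectral
reflectance series on a 5-day revisit over the rice season (default DOY
152-304), with class-specific phenological index trajectories, polygon
grouping (points sampled inside the same field share a trajectory), cloud
gaps encoded in an SCL-style quality band, and band reflectances constructed
so that NDVI/LSWI recomputed from them reproduce the target curves.

Rice NDVI follows a double-logistic curve (the standard phenology family):
flat at a base level through transplanting, a logistic green-up through the
growth stage, and a logistic decline through ripening. Rice LSWI starts high
(flooded transplanting) and decays to a dry level. Non-rice classes use flat
or gently seasonal templates; ``other_crop`` is a phase-shifted double
logistic without the flooding signal, the designated confuser class.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

# SCL-style quality codes used by the generator
CLEAR_CODE = 4        # vegetation / clear
CLOUD_CODE = 9        # high-probability cloud
DEFAULT_MASK_CODES = frozenset({3, 6, 8, 9, 10, 11})

BAND_NAMES = ("B2", "B4", "B8", "B11")


class ConfigurationError(ValueError):
    pass


@dataclass
class PhenologyParams:
    """Stage timing and index levels for a double-logistic phenology class.

    Durations follow the single-season japonica calendar: transplanting
    ~15-20 d, growth ~85-95 d (tillering through heading), ripening ~40-45 d.
    """

    transplant_doy: int = 165
    transplant_len: int = 18
    growth_len: int = 90
    ripen_len: int = 42
    ndvi_base: float = 0.18
    ndvi_peak: float = 0.85
    lswi_flood: float = 0.45
    lswi_dry: float = 0.05
    noise_sd: float = 0.05

    def validate(self) -> None:
        if not 10 <= self.transplant_len <= 30:
            raise ConfigurationError("transplant_len must be in [10, 30] days")
        if not 60 <= self.growth_len <= 110:
            raise ConfigurationError("growth_len must be in [60, 110] days")
        if not 30 <= self.ripen_len <= 60:
            raise ConfigurationError("ripen_len must be in [30, 60] days")
        if self.ndvi_peak <= self.ndvi_base:
            raise ConfigurationError("ndvi_peak must exceed ndvi_base")
        for v in (self.ndvi_base, self.ndvi_peak):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("NDVI levels must be in [0, 1]")
        for v in (self.lswi_flood, self.lswi_dry):
            if not -1.0 <= v <= 1.0:
                raise ConfigurationError("LSWI levels must be in [-1, 1]")

    # stage windows on the DOY axis
    @property
    def growth_start(self) -> float:
        return self.transplant_doy + self.transplant_len

    @property
    def growth_end(self) -> float:
        return self.growth_start + self.growth_len

    @property
    def ripen_end(self) -> float:
        return self.growth_end + self.ripen_len


@dataclass
class FlatParams:
    """Flat / gently seasonal template for non-phenology classes."""

    ndvi_level: float = 0.1
    lswi_level: float = 0.0
    seasonal_amp: float = 0.0  # sinusoidal NDVI modulation amplitude
    noise_sd: float = 0.05

    def validate(self) -> None:
        if not -1.0 <= self.ndvi_level <= 1.0:
            raise ConfigurationError("ndvi_level must be in [-1, 1]")
        if not -1.0 <= self.lswi_level <= 1.0:
            raise ConfigurationError("lswi_level must be in [-1, 1]")


DEFAULT_CLASS_PARAMS: dict[str, PhenologyParams | FlatParams] = {
    "rice": PhenologyParams(),
    # earlier-planted upland crop: similar greenness levels, shifted timing,
    # no transplanting flood -> separable only through temporal dynamics
    "other_crop": PhenologyParams(
        transplant_doy=130, transplant_len=15, growth_len=80, ripen_len=40,
        ndvi_base=0.22, ndvi_peak=0.78, lswi_flood=0.12, lswi_dry=0.05),
    "water": FlatParams(ndvi_level=-0.15, lswi_level=0.60),
    "urban": FlatParams(ndvi_level=0.12, lswi_level=-0.05),
    "forest": FlatParams(ndvi_level=0.72, lswi_level=0.25, seasonal_amp=0.06),
}


@dataclass
class SceneConfig:
    classes: tuple[str, ...] = ("rice", "water", "urban", "forest",
                                "other_crop")
    class_params: dict[str, PhenologyParams | FlatParams] | None = None
    n_polygons_per_class: int = 2000
    points_per_polygon: int = 3
    patch_size: int = 5
    doy_start: int = 152
    doy_end: int = 304
    revisit: int = 5
    gap_rate: float = 0.3
    seed: int = 0

    def resolved_params(self) -> dict[str, PhenologyParams | FlatParams]:
        params = dict(DEFAULT_CLASS_PARAMS)
        if self.class_params:
            params.update(self.class_params)
        missing = [c for c in self.classes if c not in params]
        if missing:
            raise ConfigurationError(f"unknown class(es): {missing}")
        return {c: params[c] for c in self.classes}

    def validate(self) -> None:
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ConfigurationError("patch_size must be an odd integer >= 1")
        if self.revisit < 1:
            raise ConfigurationError("revisit must be >= 1 day")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ConfigurationError("gap_rate must be in [0, 1)")
        if self.n_polygons_per_class < 1:
            raise ConfigurationError("need at least one polygon per class")
        if self.points_per_polygon < 1:
            raise ConfigurationError("need at least one point per polygon")
        if not (1 <= self.doy_start < self.doy_end <= 366):
            raise ConfigurationError("DOY window must satisfy 1 <= start < end <= 366")
        for p in self.resolved_params().values():
            p.validate()

    @property
    def doys(self) -> np.ndarray:
        return np.arange(self.doy_start, self.doy_end + 1, self.revisit)

    @property
    def n_samples(self) -> int:
        return len(self.classes) * self.n_polygons_per_class \
            * self.points_per_polygon


@dataclass
class PatchSample:
    """One labeled sample: a P x P x 4 x T reflectance patch and metadata."""

    bands: np.ndarray          # (P, P, 4, T) reflectances in [0, 1]
    doys: np.ndarray           # (T,) strictly increasing DOY stamps
    quality: np.ndarray        # (T,) SCL-style codes
    label: int                 # 1 = rice, 0 = non-rice
    polygon_id: int
    class_name: str


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _double_logistic_ndvi(p, doys, base, peak, transplant_doy):
    """Vectorised rice-family NDVI curve; params may be per-polygon arrays."""
    m1 = transplant_doy + p.transplant_len + 0.35 * p.growth_len
    s1 = p.growth_len / 6.0
    m2 = transplant_doy + p.transplant_len + p.growth_len + 0.5 * p.ripen_len
    s2 = p.ripen_len / 8.0
    up = _logistic((doys - m1) / s1)
    down = _logistic(-(doys - m2) / s2)
    return base + (peak - base) * up * down


def _lswi_decay(p, doys, flood, dry, transplant_doy):
    md = transplant_doy + p.transplant_len + 0.55 * p.growth_len
    sd = p.growth_len / 7.0
    return dry + (flood - dry) * _logistic(-(doys - md) / sd)


def simulate_trajectory(class_name: str,
                        params: PhenologyParams | FlatParams,
                        doys: np.ndarray,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, np.ndarray]:
    """Noiseless-or-noisy true NDVI/LSWI curves for one class template."""
    doys = np.asarray(doys, dtype=float)
    if doys.min() < 1 or doys.max() > 366 or np.any(np.diff(doys) <= 0):
        raise ValueError("doys must be increasing and within [1, 366]")
    if isinstance(params, PhenologyParams):
        if class_name not in ("rice", "other_crop"):
            raise ConfigurationError(
                f"class {class_name!r} does not take PhenologyParams")
        ndvi = _double_logistic_ndvi(params, doys, params.ndvi_base,
                                     params.ndvi_peak, params.transplant_doy)
        lswi = _lswi_decay(params, doys, params.lswi_flood, params.lswi_dry,
                           params.transplant_doy)
    elif isinstance(params, FlatParams):
        if class_name not in ("water", "urban", "forest"):
            raise ConfigurationError(
                f"class {class_name!r} does not take FlatParams")
        ndvi = params.ndvi_level + params.seasonal_amp * np.sin(
            2 * np.pi * (doys - 120.0) / 365.0)
        lswi = np.full_like(doys, params.lswi_level)
    else:
        raise ConfigurationError(f"unknown class {class_name!r}")
    if rng is not None and params.noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, params.noise_sd, size=ndvi.shape)
        lswi = lswi + rng.normal(0.0, params.noise_sd, size=lswi.shape)
    return {"ndvi": np.clip(ndvi, -0.95, 0.95),
            "lswi": np.clip(lswi, -0.95, 0.95)}


def invert_bands(ndvi: np.ndarray, lswi: np.ndarray,
                 b8_profile: np.ndarray | float,
                 b2_level: float = 0.04):
    """Back out (B2, B4, B8, B11) reflectances from target index values.

    Chosen so that recomputing NDVI from (B8, B4) and LSWI from (B8, B11)
    reproduces the inputs exactly when no [0, 1] clipping occurs:
    B4 = B8 (1-NDVI)/(1+NDVI), B11 = B8 (1-LSWI)/(1+LSWI).
    """
    ndvi = np.asarray(ndvi, dtype=float)
    lswi = np.asarray(lswi, dtype=float)
    if np.any(ndvi <= -1.0) or np.any(lswi <= -1.0) \
            or np.any(ndvi >= 1.0) or np.any(lswi >= 1.0):
        raise ValueError("indices must lie strictly inside (-1, 1)")
    b8 = np.broadcast_to(np.asarray(b8_profile, dtype=float),
                         ndvi.shape).copy()
    if np.any(b8 <= 0) or np.any(b8 >= 1):
        raise ValueError("b8_profile must lie in (0, 1)")
    b4 = b8 * (1.0 - ndvi) / (1.0 + ndvi)
    b11 = b8 * (1.0 - lswi) / (1.0 + lswi)
    b2 = np.broadcast_to(np.asarray(b2_level, dtype=float), ndvi.shape)
    clip = lambda a: np.clip(a, 0.0, 1.0)  # noqa: E731
    return clip(b2), clip(b4), clip(b8), clip(b11)


def default_b8_profile(ndvi: np.ndarray) -> np.ndarray:
    """NIR level tied to greenness: brighter canopy at higher NDVI."""
    return 0.12 + 0.28 * np.clip(ndvi, 0.0, 1.0)


def inject_gaps(quality: np.ndarray, gap_rate: float,
                rng: np.random.Generator,
                cloud_code: int = CLOUD_CODE) -> np.ndarray:
    """Set quality codes to a cloud code at Bernoulli(gap_rate) timesteps.

    Guarantees at least one clear step per sample (row).
    """
    if not 0.0 <= gap_rate < 1.0:
        raise ConfigurationError("gap_rate must be in [0, 1)")
    q = np.array(quality, copy=True)
    flat = q.ndim == 1
    if flat:
        q = q[None, :]
    orig = q.copy()
    cloudy = rng.random(q.shape) < gap_rate
    q[cloudy] = cloud_code
    all_cloud = cloudy.all(axis=1)
    if all_cloud.any():
        keep = rng.integers(0, q.shape[1], size=int(all_cloud.sum()))
        rows = np.flatnonzero(all_cloud)
        q[rows, keep] = orig[rows, keep]
    return q[0] if flat else q


class SceneDataset:
    """Array-backed scene: indexable as a sequence of :class:`PatchSample`."""

    def __init__(self, bands, doys, quality, labels, polygon_ids,
                 class_names, config, true_ndvi=None, true_lswi=None):
        self.bands = bands              # (N, P, P, 4, T) float32
        self.doys = doys                # (T,) int
        self.quality = quality          # (N, T) uint8
        self.labels = labels            # (N,) int8
        self.polygon_ids = polygon_ids  # (N,) int64
        self.class_names = class_names  # (N,) object/str array
        self.config = config
        self.true_ndvi = true_ndvi      # (N, T) polygon-level clean curves
        self.true_lswi = true_lswi

    def __len__(self) -> int:
        return self.bands.shape[0]

    def __getitem__(self, i: int) -> PatchSample:
        return PatchSample(bands=self.bands[i], doys=self.doys,
                           quality=self.quality[i],
                           label=int(self.labels[i]),
                           polygon_id=int(self.polygon_ids[i]),
                           class_name=str(self.class_names[i]))

    def center_bands(self) -> np.ndarray:
        """Center-pixel reflectances, shape (N, 4, T)."""
        c = self.bands.shape[1] // 2
        return self.bands[:, c, c, :, :]

    def valid_mask(self, mask_codes=DEFAULT_MASK_CODES) -> np.ndarray:
        return ~np.isin(self.quality, list(mask_codes))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table of the center-pixel series (one row per
        sample x timestep)."""
        n, t = self.quality.shape
        cb = self.center_bands()
        return pd.DataFrame({
            "sample_id": np.repeat(np.arange(n), t),
            "polygon_id": np.repeat(self.polygon_ids, t),
            "class_name": np.repeat(self.class_names, t),
            "label": np.repeat(self.labels, t).astype(int),
            "doy": np.tile(self.doys, n),
            "B2": cb[:, 0, :].reshape(-1),
            "B4": cb[:, 1, :].reshape(-1),
            "B8": cb[:, 2, :].reshape(-1),
            "B11": cb[:, 3, :].reshape(-1),
            "quality": self.quality.reshape(-1).astype(int),
        })

    def serialize_bytes(self) -> bytes:
        """Deterministic CSV serialisation (used by determinism checks)."""
        buf = _io.StringIO()
        self.to_long_frame().to_csv(buf, index=False, float_format="%.6g")
        return buf.getvalue().encode()


def build_dataset(config: SceneConfig) -> SceneDataset:
    """Generate a full labeled scene; fully reproducible from config.seed."""
    config.validate()
    params = config.resolved_params()
    doys = config.doys
    t = len(doys)
    ppp = config.points_per_polygon
    npoly = config.n_polygons_per_class
    pts_per_class = npoly * ppp
    n = config.n_samples
    p = config.patch_size

    # independent child streams: polygon jitter / pixel noise / gaps / patch
    ss = np.random.SeedSequence(config.seed)
    rng_jit, rng_noise, rng_gap, rng_patch = \
        (np.random.default_rng(s) for s in ss.spawn(4))

    bands = np.empty((n, p, p, 4, t), dtype=np.float32)
    labels = np.empty(n, dtype=np.int8)
    polygon_ids = np.empty(n, dtype=np.int64)
    class_names = np.empty(n, dtype=object)
    true_ndvi = np.empty((n, t), dtype=np.float32)
    true_lswi = np.empty((n, t), dtype=np.float32)

    poly_counter = 0
    row = 0
    dg = doys[None, :].astype(float)
    for cname in config.classes:
        cp = params[cname]
        # polygon-level trajectory: jittered template parameters
        if isinstance(cp, PhenologyParams):
            tdoy = cp.transplant_doy + rng_jit.normal(0, 4.0, (npoly, 1))
            base = cp.ndvi_base + rng_jit.normal(0, 0.02, (npoly, 1))
            peak = cp.ndvi_peak + rng_jit.normal(0, 0.03, (npoly, 1))
            flood = cp.lswi_flood + rng_jit.normal(0, 0.03, (npoly, 1))
            dry = cp.lswi_dry + rng_jit.normal(0, 0.02, (npoly, 1))
            ndvi_poly = _double_logistic_ndvi(cp, dg, base, peak, tdoy)
            lswi_poly = _lswi_decay(cp, dg, flood, dry, tdoy)
        else:
            lvl_n = cp.ndvi_level + rng_jit.normal(0, 0.02, (npoly, 1))
            lvl_l = cp.lswi_level + rng_jit.normal(0, 0.02, (npoly, 1))
            ndvi_poly = lvl_n + cp.seasonal_amp * np.sin(
                2 * np.pi * (dg - 120.0) / 365.0)
            lswi_poly = np.broadcast_to(lvl_l, (npoly, t)).copy()
        # expand to points and add per-pixel index noise
        ndvi_pt = np.repeat(ndvi_poly, ppp, axis=0)
        lswi_pt = np.repeat(lswi_poly, ppp, axis=0)
        if cp.noise_sd > 0:
            ndvi_pt = ndvi_pt + rng_noise.normal(0, cp.noise_sd, ndvi_pt.shape)
            lswi_pt = lswi_pt + rng_noise.normal(0, cp.noise_sd, lswi_pt.shape)
        ndvi_pt = np.clip(ndvi_pt, -0.95, 0.95)
        lswi_pt = np.clip(lswi_pt, -0.95, 0.95)

        b2, b4, b8, b11 = invert_bands(ndvi_pt, lswi_pt,
                                       default_b8_profile(ndvi_pt))
        center = np.stack([b2, b4, b8, b11], axis=1)  # (pts, 4, T)
        sl = slice(row, row + pts_per_class)
        if p == 1:
            bands[sl, 0, 0] = center
        else:
            # neighbours share the centre trajectory plus small reflectance
            # perturbations (sub-field texture)
            noise = rng_patch.normal(0, 0.01,
                                     (pts_per_class, p, p, 4, t))
            c = p // 2
            noise[:, c, c, :, :] = 0.0
            bands[sl] = np.clip(center[:, None, None, :, :] + noise, 0, 1)
        labels[sl] = 1 if cname == "rice" else 0
        polygon_ids[sl] = poly_counter + np.repeat(np.arange(npoly), ppp)
        class_names[sl] = cname
        true_ndvi[sl] = np.clip(np.repeat(ndvi_poly, ppp, axis=0), -0.95, 0.95)
        true_lswi[sl] = np.clip(np.repeat(lswi_poly, ppp, axis=0), -0.95, 0.95)
        poly_counter += npoly
        row += pts_per_class

    quality = np.full((n, t), CLEAR_CODE, dtype=np.uint8)
    if config.gap_rate > 0:
        quality = inject_gaps(quality, config.gap_rate, rng_gap)
    return SceneDataset(bands, doys, quality, labels, polygon_ids,
                        class_names, config, true_ndvi, true_lswi)


def config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("class_params"):
        d["class_params"] = {
            k: {"_kind": type(v).__name__, **dataclasses.asdict(v)}
            for k, v in config.class_params.items()}
    return d


def config_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    cp = d.get("class_params")
    if cp:
        parsed = {}
        for k, v in cp.items():
            v = dict(v)
            kind = v.pop("_kind")
            cls = {"PhenologyParams": PhenologyParams,
                   "FlatParams": FlatParams}[kind]
            parsed[k] = cls(**v)
        d["class_params"] = parsed
    if "classes" in d:
        d["classes"] = tuple(d["classes"])
    return SceneConfig(**d)
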