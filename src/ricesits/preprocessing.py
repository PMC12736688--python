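"""Quality masking and vegetation-index time-series reconstruction.

Order of operations: SCL-style quality masking, Savitzky-Golay smoothing of
the valid subsequence, then harmonic (sine/cosine) least-squares regression
on the valid points to estimate values at cloud-obscured dates. Gap filling
replaces only the invalid slots; valid observations are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import DEFAULT_MASK_CODES

DEFAULT_SG_WINDOW = 7
DEFAULT_SG_POLYORDER = 2
DEFAULT_HARMONICS = 2
DEFAULT_PERIOD = 365.0


class ReconstructionError(RuntimeError):
    pass


@dataclass
class MaskedSeries:
    """A per-sample index or band series with a validity mask."""

    values: np.ndarray
    doys: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.doys = np.asarray(self.doys)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.values) == len(self.doys) == len(self.valid)):
            raise ValueError("values, doys and valid must share length")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class HarmonicFit:
    """Least-squares harmonic coefficients: a0 + sum_k a_k cos + b_k sin."""

    a0: float
    a: np.ndarray  # (K,) cosine coefficients
    b: np.ndarray  # (K,) sine coefficients
    period: float = DEFAULT_PERIOD

    def predict(self, doys: np.ndarray) -> np.ndarray:
        doys = np.asarray(doys, dtype=float)
        y = np.full(doys.shape, self.a0, dtype=float)
        for k in range(len(self.a)):
            w = 2 * np.pi * (k + 1) * doys / self.period
            y += self.a[k] * np.cos(w) + self.b[k] * np.sin(w)
        return y


def apply_quality_mask(values: np.ndarray, doys: np.ndarray,
                       quality: np.ndarray,
                       mask_set=DEFAULT_MASK_CODES) -> MaskedSeries:
    """Mark observations whose quality code is in ``mask_set`` as invalid."""
    values = np.asarray(values, dtype=float)
    quality = np.asarray(quality)
    if len(values) != len(quality):
        raise ValueError("values and quality codes must align")
    valid = ~np.isin(quality, list(mask_set))
    return MaskedSeries(values=values, doys=np.asarray(doys), valid=valid)


def sg_smooth(series: MaskedSeries, window: int = DEFAULT_SG_WINDOW,
              polyorder: int = DEFAULT_SG_POLYORDER) -> MaskedSeries:
    """Savitzky-Golay smoothing of the valid subsequence.

    The valid observations are treated as an equally spaced subsequence
    (standard practice for quasi-regular revisit series); boundaries use
    polynomial extrapolation (``mode='interp'``), which reproduces
    polynomials of degree <= polyorder exactly. If fewer valid points than
    the window exist, the series is returned unchanged with a warning.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    out = series.values.copy()
    idx = np.flatnonzero(series.valid)
    if len(idx) < window:
        warnings.warn("fewer valid points than SG window; smoothing skipped",
                      stacklevel=2)
        return MaskedSeries(out, series.doys, series.valid.copy())
    out[idx] = savgol_filter(series.values[idx], window, polyorder,
                             mode="interp")
    return MaskedSeries(out, series.doys, series.valid.copy())


def _design_matrix(doys: np.ndarray, k: int, period: float) -> np.ndarray:
    doys = np.asarray(doys, dtype=float)
    cols = [np.ones_like(doys)]
    for j in range(1, k + 1):
        w = 2 * np.pi * j * doys / period
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def harmonic_fit_fill(series: MaskedSeries, k: int = DEFAULT_HARMONICS,
                      period: float = DEFAULT_PERIOD,
                      sample_id=None) -> tuple[HarmonicFit, MaskedSeries]:
    """OLS harmonic fit on valid points; invalid slots get fitted values.

    Valid observations are kept as observed (fill-only policy).
    """
    nv = series.n_valid
    if nv < 2 * k + 1:
        raise ReconstructionError(
            f"sample {sample_id!r}: {nv} valid points < {2 * k + 1} "
            "coefficients required")
    x = _design_matrix(series.doys, k, period)
    xv = x[series.valid]
    if np.linalg.matrix_rank(xv) < x.shape[1]:
        raise ReconstructionError(
            f"sample {sample_id!r}: rank-deficient harmonic design "
            "(too few distinct DOYs)")
    coef, *_ = np.linalg.lstsq(xv, series.values[series.valid], rcond=None)
    fit = HarmonicFit(a0=float(coef[0]), a=coef[1::2].copy(),
                      b=coef[2::2].copy(), period=period)
    filled = series.values.copy()
    inv = ~series.valid
    if inv.any():
        filled[inv] = (x @ coef)[inv]
    return fit, MaskedSeries(filled, series.doys, series.valid.copy())


def reconstruct_series(values: np.ndarray, doys: np.ndarray,
                       quality: np.ndarray,
                       mask_set=DEFAULT_MASK_CODES,
                       sg_window: int = DEFAULT_SG_WINDOW,
                       sg_polyorder: int = DEFAULT_SG_POLYORDER,
                       harmonics: int = DEFAULT_HARMONICS,
                       period: float = DEFAULT_PERIOD,
                       sample_id=None) -> tuple[MaskedSeries, HarmonicFit]:
    """Mask -> SG smooth -> harmonic gap fill, for one index series."""
    ms = apply_quality_mask(values, doys, quality, mask_set)
    ms = sg_smooth(ms, sg_window, sg_polyorder)
    fit, filled = harmonic_fit_fill(ms, harmonics, period, sample_id)
    return filled, fit


def reconstruct_batch(values: np.ndarray, doys: np.ndarray,
                      valid: np.ndarray,
                      sg_window: int = DEFAULT_SG_WINDOW,
                      sg_polyorder: int = DEFAULT_SG_POLYORDER,
                      harmonics: int = DEFAULT_HARMONICS,
                      period: float = DEFAULT_PERIOD) -> np.ndarray:
    """Vectorised reconstruction of many series sharing one DOY grid.

    values: (N, T); valid: (N, T) boolean. Returns the gap-filled (N, T)
    array (valid slots smoothed-in-place only by SG, invalid slots replaced
    by the per-sample harmonic fit). Samples with too few valid points for
    the harmonic design raise :class:`ReconstructionError`.
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n, t = values.shape
    ncoef = 2 * harmonics + 1
    nv = valid.sum(axis=1)
    bad = np.flatnonzero(nv < ncoef)
    if bad.size:
        raise ReconstructionError(
            f"sample {int(bad[0])}: {int(nv[bad[0]])} valid points < "
            f"{ncoef} coefficients required")

    smoothed = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            idx = np.flatnonzero(valid[i])
            if len(idx) >= sg_window:
                smoothed[i, idx] = savgol_filter(values[i, idx], sg_window,
                                                 sg_polyorder, mode="interp")

    x = _design_matrix(doys, harmonics, period)          # (T, C)
    w = valid.astype(float)                              # (N, T)
    gram = np.einsum("tj,nt,tk->njk", x, w, x)           # (N, C, C)
    rhs = np.einsum("tj,nt,nt->nj", x, w, smoothed)      # (N, C)
    try:
        coef = np.linalg.solve(gram, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        ranks = np.linalg.matrix_rank(gram)
        bad = int(np.argmin(ranks))
        raise ReconstructionError(
            f"sample {bad}: rank-deficient harmonic design") from None
    fitted = coef @ x.T                                  # (N, T)
    return np.where(valid, smoothed, fitted)
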