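"""Lagged phase synchronization (LPS) between ROI current time series.

Connectivity measures built on raw coherence are inflated by volume
conduction: a single source reaches many sensors (and source estimates)
instantaneously, producing strong zero-lag dependence.  LPS discards the
instantaneous component by scoring, per frequency bin, only the part of
the phase coherency that is out of phase with the zero-lag axis:

    lps_f = Im(rho_f)^2 / (1 - Re(rho_f)^2)

where ``rho_f`` is the window-averaged phase-only coherency (Fourier
coefficients normalized to unit modulus before averaging).  The band
value is the unweighted mean over the band's FFT bins.  In the degenerate
limit |Re rho| -> 1 (pure instantaneous coupling) the value is 0 by
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import CONNECTIVITY6, band_bins
from .inverse import EstimationError, _csd_windows

MIN_WINDOWS = 8
_DENOM_EPS = 1e-12


@dataclass(frozen=True)
class LPSMatrix:
    """Symmetric ROI x ROI x band lagged-phase-synchronization values."""

    values: np.ndarray  # (n_roi, n_roi, n_bands); diagonal NaN
    roi_names: tuple[str, ...]
    band_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long format: roi_a, roi_b, band, value (upper triangle only)."""
        rows = []
        for i, a in enumerate(self.roi_names):
            for j in range(i + 1, len(self.roi_names)):
                for k, band in enumerate(self.band_names):
                    rows.append((a, self.roi_names[j], band, self.values[i, j, k]))
        return pd.DataFrame(rows, columns=["roi_a", "roi_b", "band", "value"])


def _phase_coherency(data: np.ndarray, rate: float, window_s: float,
                     overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Phase-only coherency rho_f for every channel pair.

    Returns (rho, freqs) with rho of shape (ch, ch, bins).
    """
    X, freqs = _csd_windows(data, rate, window_s, overlap)
    if X.shape[0] < MIN_WINDOWS:
        raise EstimationError(
            f"only {X.shape[0]} windows; need at least {MIN_WINDOWS}")
    mod = np.abs(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(mod > 0, X / np.where(mod > 0, mod, 1.0), 0.0)
    rho = np.einsum("wcf,wdf->cdf", P, np.conj(P)) / X.shape[0]
    return rho, freqs


def _lagged_from_rho(rho: np.ndarray) -> np.ndarray:
    """Im^2/(1-Re^2) per bin with the degenerate-bin convention."""
    re2 = rho.real**2
    denom = 1.0 - re2
    val = np.where(denom > _DENOM_EPS, rho.imag**2 / np.maximum(denom, _DENOM_EPS), 0.0)
    return np.clip(val, 0.0, 1.0)


def lagged_phase_synchronization(x: np.ndarray, y: np.ndarray,
                                 band: tuple[float, float], rate: float,
                                 window_s: float = 2.0,
                                 overlap: float = 0.5) -> float:
    """LPS between two scalar series in one frequency band."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if not (0 < band[0] < band[1] < rate / 2):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    rho, freqs = _phase_coherency(np.vstack([x, y]), rate, window_s, overlap)
    idx = band_bins(freqs, band)
    if idx.size == 0:
        raise ValueError(f"band {band} contains no FFT bins at this window length")
    return float(_lagged_from_rho(rho[0, 1, idx]).mean())


def first_principal_component(series3: np.ndarray) -> np.ndarray:
    """Score of the first PC across the 3 current components.

    The sign is fixed so the loading vector's largest-magnitude entry is
    positive, making the reduction deterministic.
    """
    x = series3 - series3.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    load = u[:, 0]
    if load[np.argmax(np.abs(load))] < 0:
        load = -load
    return load @ x


def roi_connectivity(roi_series: dict[str, np.ndarray], rate: float,
                     bands: dict[str, tuple[float, float]] | None = None,
                     window_s: float = 2.0, overlap: float = 0.5) -> LPSMatrix:
    """All-pairs LPS over the six connectivity bands.

    Each ROI's 3-component current series is reduced to a scalar by its
    first principal component.  An ROI with a constant series yields NaN
    values for its pairs (with a warning) rather than an exception.
    """
    bands = bands if bands is not None else CONNECTIVITY6
    names = tuple(roi_series)
    if len(names) < 2:
        raise ValueError("need at least 2 ROIs")
    scalars, constant = [], []
    for n in names:
        s = first_principal_component(np.atleast_2d(roi_series[n]))
        if np.ptp(s) == 0:
            warnings.warn(f"ROI {n!r} has a constant series; pairs set to NaN")
            constant.append(True)
        else:
            constant.append(False)
        scalars.append(s)
    data = np.vstack(scalars)
    rho, freqs = _phase_coherency(data, rate, window_s, overlap)
    lag = _lagged_from_rho(rho)
    R, B = len(names), len(bands)
    values = np.full((R, R, B), np.nan)
    for k, (bname, band) in enumerate(bands.items()):
        idx = band_bins(freqs, band)
        vb = lag[:, :, idx].mean(axis=2)
        np.fill_diagonal(vb, np.nan)
        values[:, :, k] = vb
    for i, bad in enumerate(constant):
        if bad:
            values[i, :, :] = np.nan
            values[:, i, :] = np.nan
    values = 0.5 * (values + values.transpose(1, 0, 2))
    return LPSMatrix(values=values, roi_names=names, band_names=tuple(bands))
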