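"""sLORETA inverse solution, band power maps, ROI log power and time series.

The inverse operator is the Tikhonov-regularized minimum-norm solution
``T = K' (K' K'^T + alpha H)^+`` for an average-referenced lead field K'
(H is the sensor-space centering matrix).  sLORETA standardizes the
current estimate at each voxel by the corresponding 3x3 diagonal block of
the resolution matrix ``T K'``; the standardized single-source power map
attains its maximum at the true source voxel for noiseless data, for any
regularization strength (the measure's defining zero-localization-error
property).

Band power follows the average-Fourier-cross-spectrum recipe: Hann
windows of 2 s with 50% overlap are Fourier transformed, the sensor
cross-spectral matrix is averaged over windows and over the FFT bins of
each band, and the voxel value is the trace of the standardized 3x3
source cross-spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import ACTIVITY8, band_bins
from .headmodel import LeadField, ROIAtlas
from .io import Recording

LOG_FLOOR = 1e-12  # fractions below this are clipped before the log


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class InverseOperator:
    """Minimum-norm weights plus per-voxel sLORETA standardization blocks."""

    weights: np.ndarray       # (3 * voxels, sensors)
    stand_inv: np.ndarray     # (voxels, 3, 3)  R_vv^{-1}
    stand_inv_sqrt: np.ndarray  # (voxels, 3, 3)  R_vv^{-1/2}
    alpha: float

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0] // 3


@dataclass(frozen=True)
class SourceBandPower:
    """Nonnegative voxels x bands current-density power map."""

    power: np.ndarray  # (voxels, n_bands)
    band_names: tuple[str, ...]
    scheme: str = "activity8"


def compute_inverse_operator(leadfield: LeadField,
                             alpha_frac: float = 0.05) -> InverseOperator:
    """Build the sLORETA operator from an average-referenced lead field.

    ``alpha = alpha_frac * trace(K K^T) / n_sensors`` scales the
    regularization to the mean sensor-space signal power of the gain.
    """
    K = leadfield.gain
    E = K.shape[0]
    if not leadfield.average_referenced:
        raise ValueError("lead field must be average-referenced")
    H = np.eye(E) - np.ones((E, E)) / E
    C = K @ K.T + alpha_frac * (np.trace(K @ K.T) / E) * H
    # C annihilates the constant vector; invert on its range
    w, U = np.linalg.eigh(C)
    tol = w.max() * 1e-12
    inv_w = np.where(w > tol, 1.0 / np.maximum(w, tol), 0.0)
    Cinv = (U * inv_w) @ U.T
    if alpha_frac == 0.0 and np.sum(w > tol) < E - 1:
        raise np.linalg.LinAlgError(
            "rank-deficient gain with alpha=0; use alpha_frac > 0")
    T = K.T @ Cinv
    V = K.shape[1] // 3
    Kr = K.reshape(E, V, 3)
    Mr = (Cinv @ K).reshape(E, V, 3)
    R = np.einsum("evi,evj->vij", Kr, Mr)  # resolution diagonal blocks
    R = 0.5 * (R + np.transpose(R, (0, 2, 1)))
    lam, Q = np.linalg.eigh(R)
    lam = np.maximum(lam, lam[:, -1:] * 1e-12)
    stand_inv = np.einsum("vij,vj,vkj->vik", Q, 1.0 / lam, Q)
    stand_inv_sqrt = np.einsum("vij,vj,vkj->vik", Q, 1.0 / np.sqrt(lam), Q)
    alpha = float(alpha_frac * np.trace(K @ K.T) / E)
    return InverseOperator(weights=T, stand_inv=stand_inv,
                           stand_inv_sqrt=stand_inv_sqrt, alpha=alpha)


def apply_inverse(inv: InverseOperator, data: np.ndarray) -> np.ndarray:
    """Raw (unstandardized) current estimates, (3 * voxels) x samples."""
    return inv.weights @ data


def standardized_power(inv: InverseOperator, scalp: np.ndarray) -> np.ndarray:
    """Per-voxel sLORETA power for one scalp vector (sensors,)."""
    j = (inv.weights @ scalp).reshape(-1, 3)
    return np.einsum("vi,vij,vj->v", j, inv.stand_inv, j)


def _csd_windows(data: np.ndarray, rate: float, window_s: float = 2.0,
                 overlap: float = 0.5):
    """Hann-windowed FFTs: (n_windows, channels, bins) and bin freqs."""
    win = int(round(window_s * rate))
    if data.shape[1] < win:
        raise EstimationError(
            f"recording ({data.shape[1]} samples) shorter than one "
            f"{window_s:g}-s window")
    step = max(1, int(round(win * (1 - overlap))))
    starts = range(0, data.shape[1] - win + 1, step)
    taper = np.hanning(win)
    segs = np.stack([data[:, s:s + win] * taper for s in starts])
    X = np.fft.rfft(segs, axis=2)
    freqs = np.fft.rfftfreq(win, d=1.0 / rate)
    # Welch-style scaling so values are PSD-like per bin
    X /= np.sqrt(rate * (taper**2).sum())
    return X, freqs


def estimate_band_power(rec: Recording, inv: InverseOperator,
                        bands: dict[str, tuple[float, float]] | None = None,
                        window_s: float = 2.0,
                        overlap: float = 0.5) -> SourceBandPower:
    """Voxelwise sLORETA band power from averaged sensor cross-spectra."""
    bands = bands if bands is not None else ACTIVITY8
    X, freqs = _csd_windows(rec.data, rec.rate, window_s, overlap)
    nW = X.shape[0]
    V = inv.n_sources
    E = rec.n_channels
    T = inv.weights
    Tr = T.reshape(V, 3, E)
    power = np.empty((V, len(bands)))
    for bi, (name, band) in enumerate(bands.items()):
        idx = band_bins(freqs, band)
        if idx.size == 0:
            power[:, bi] = 0.0
            continue
        Xb = X[:, :, idx]
        C = np.einsum("wcf,wdf->cd", Xb, np.conj(Xb)) / (nW * idx.size)
        M = np.einsum("vae,ec->vac", Tr, C)
        B = np.einsum("vae,vbe->vab", M, np.conj(Tr))
        power[:, bi] = np.einsum("vab,vba->v", inv.stand_inv, B).real
    return SourceBandPower(power=np.maximum(power, 0.0),
                           band_names=tuple(bands))


def roi_log_power(src_power: SourceBandPower, atlas: ROIAtlas) -> pd.DataFrame:
    """Log-transformed fraction of whole-map power captured by each ROI.

    Per band, voxel powers are normalized to total 1; an ROI's value is
    the log of the summed fraction over its voxels.  Zero fractions are
    clipped at ``LOG_FLOOR`` to keep downstream statistics finite.
    """
    totals = src_power.power.sum(axis=0)
    if np.any(totals <= 0):
        bad = src_power.band_names[int(np.argmax(totals <= 0))]
        raise EstimationError(f"band {bad!r} has zero total power")
    frac = src_power.power / totals
    rows = {}
    for name, idx in atlas.rois.items():
        rows[name] = np.log(np.maximum(frac[idx].sum(axis=0), LOG_FLOOR))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(src_power.band_names))


def extract_roi_timeseries(rec: Recording, inv: InverseOperator,
                           atlas: ROIAtlas) -> dict[str, np.ndarray]:
    """Standardized 3-component current time series per ROI.

    Each voxel's current vector is whitened by its sLORETA block
    (R_vv^{-1/2}) and the ROI series is the unweighted voxel mean of the
    three components.
    """
    J = (inv.weights @ rec.data).reshape(inv.n_sources, 3, -1)
    Js = np.einsum("vij,vjt->vit", inv.stand_inv_sqrt, J)
    out = {}
    for name, idx in atlas.rois.items():
        if idx.size == 0:
            raise EstimationError(f"ROI {name!r} is empty")
        out[name] = Js[idx].mean(axis=0)
    return out
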