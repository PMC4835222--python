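"""Alpha-gamma nesting: correlation of the alpha waveform with the gamma envelope.

The statistic follows a five-step recipe applied to an ROI's 3-component
current series: (1) band-pass the three components in the alpha (8-12 Hz)
and gamma (30-44 Hz) ranges; (2) within each band, reduce the three
components to their first principal component (sign fixed by the
largest-loading rule); (3) Hilbert-transform the gamma component and keep
the modulus as the envelope; (4) trim the filter-edge margins; (5)
Pearson-correlate the alpha component with the gamma envelope.

Note this correlates the signed alpha *waveform* (not its phase or
envelope) with the gamma envelope, so the result measures waveform-to-
envelope locking; it is zero in expectation when the gamma amplitude is
unmodulated, and grows with the depth of alpha-phase modulation of the
gamma amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .bands import NESTING_ALPHA, NESTING_GAMMA
from .connectivity import first_principal_component

MIN_SAMPLES = 256  # >= 2 s at 128 Hz after trimming


class NestingError(ValueError):
    pass


@dataclass(frozen=True)
class NestingScore:
    roi: str
    r: float
    n_samples: int


def _bandpassed(series3: np.ndarray, band: tuple[float, float],
                rate: float) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, series3, axis=1)


def compute_nesting(roi_series: np.ndarray, rate: float = 128.0,
                    roi: str = "", edge_trim: float = 1.0,
                    alpha_band: tuple[float, float] = NESTING_ALPHA,
                    gamma_band: tuple[float, float] = NESTING_GAMMA) -> NestingScore:
    """Alpha-gamma nesting score for one ROI's (3, samples) current series."""
    x = np.atleast_2d(np.asarray(roi_series, float))
    if not np.all(np.isfinite(x)):
        raise NestingError("non-finite input series")
    alpha = first_principal_component(_bandpassed(x, alpha_band, rate))
    gamma = first_principal_component(_bandpassed(x, gamma_band, rate))
    envelope = np.abs(signal.hilbert(gamma))
    trim = int(round(edge_trim * rate))
    sl = slice(trim, x.shape[1] - trim if trim else None)
    a, e = alpha[sl], envelope[sl]
    if a.size < MIN_SAMPLES:
        raise NestingError(f"only {a.size} samples after trimming; need {MIN_SAMPLES}")
    if np.ptp(a) == 0 or np.ptp(e) == 0:
        raise NestingError("constant component; correlation undefined")
    r = float(stats.pearsonr(a, e).statistic)
    return NestingScore(roi=roi, r=r, n_samples=int(a.size))
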