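"""Frequency band schemes.

Two fixed schemes are used throughout:

``activity8``
    Eight narrow bands used for voxelwise current-density power maps:
    delta, theta, alpha1, alpha2, beta1, beta2, beta3, gamma.

``connectivity6``
    Six broader bands used for inter-ROI lagged phase synchronization:
    delta, theta, alpha, low beta, high beta, gamma.

Band edges are closed intervals on FFT bin centers; a bin belongs to the
band whose interval contains it.  The small gaps between printed band
edges (e.g. 3.5-4 Hz) belong to no band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ACTIVITY8: dict[str, tuple[float, float]] = {
    "delta": (2.0, 3.5),
    "theta": (4.0, 7.5),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 12.0),
    "beta1": (13.0, 18.0),
    "beta2": (18.5, 21.0),
    "beta3": (21.5, 30.0),
    "gamma": (30.5, 44.0),
}

CONNECTIVITY6: dict[str, tuple[float, float]] = {
    "delta": (2.0, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.0),
    "low_beta": (13.0, 21.0),
    "high_beta": (21.5, 30.0),
    "gamma": (30.5, 44.0),
}

#: Alpha/gamma filter bands for the cross-frequency nesting statistic.
NESTING_ALPHA: tuple[float, float] = (8.0, 12.0)
NESTING_GAMMA: tuple[float, float] = (30.0, 44.0)


@dataclass(frozen=True)
class BandScheme:
    """A named, ordered collection of frequency bands (Hz)."""

    name: str
    bands: dict[str, tuple[float, float]]

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def __iter__(self):
        return iter(self.bands.items())

    def __len__(self) -> int:
        return len(self.bands)


def scheme(name: str) -> BandScheme:
    """Return a band scheme by name (``activity8`` or ``connectivity6``)."""
    if name == "activity8":
        return BandScheme("activity8", dict(ACTIVITY8))
    if name == "connectivity6":
        return BandScheme("connectivity6", dict(CONNECTIVITY6))
    raise ValueError(f"unknown band scheme: {name!r}")


def band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices of FFT bin centers falling in the closed interval ``band``."""
    lo, hi = band
    return np.nonzero((freqs >= lo) & (freqs <= hi))[0]
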