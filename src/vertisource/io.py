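"""Recording container and file I/O (EDF and a plain CSV dialect).

EDF reading goes through :func:`mne.io.read_raw_edf`.  EDF *writing* is a
minimal standard-compliant 16-bit writer sufficient for round-tripping
synthetic recordings; it writes one data record per second.

The CSV dialect: an optional leading comment ``# rate=<Hz>``, then a
header row of channel labels, then one row per sample, one column per
channel, values in microvolts.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .headmodel import CHANNELS_1020, MontageError, normalize_label


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    reference: str = "original"  # or "common_average"

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count does not match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, rate: float | None = None,
                  reference: str | None = None) -> "Recording":
        return replace(self, data=data, rate=self.rate if rate is None else rate,
                       reference=self.reference if reference is None else reference)


def _normalize_labels(labels: list[str]) -> tuple[str, ...]:
    out = tuple(normalize_label(l) for l in labels)
    if len(set(out)) != len(out):
        raise MontageError(f"duplicate channel labels after aliasing: {out}")
    return out


def load_recording(path: str | Path, dialect: str | None = None) -> Recording:
    """Load an EEG recording from EDF or the CSV dialect.

    ``dialect`` is inferred from the suffix when omitted.  Channel labels
    are normalized to 10-20 nomenclature (T3/T4/T5/T6 become T7/T8/P7/P8);
    an unrecognized label raises :class:`MontageError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "csv"
    if dialect == "edf":
        return _load_edf(path)
    if dialect == "csv":
        return _load_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_edf(path: Path) -> Recording:
    from mne.io import read_raw_edf

    raw = read_raw_edf(str(path), preload=True, verbose="error")
    labels = _normalize_labels(list(raw.ch_names))
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(data=np.asarray(data, dtype=float), rate=float(raw.info["sfreq"]),
                     labels=labels)


def _load_csv(path: Path) -> Recording:
    rate = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].replace(",", " ").split():
                if token.startswith("rate="):
                    rate = float(token.split("=", 1)[1])
            header = fh.readline()
        else:
            header = first
        labels = _normalize_labels([c.strip() for c in header.strip().split(",")])
        body = fh.read()
    try:
        data = np.loadtxt(_io.StringIO(body), delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"ragged or non-numeric CSV body in {path}") from exc
    if data.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {data.shape[1]} columns but {len(labels)} header labels")
    if rate is None:
        raise FormatError(f"{path}: no '# rate=<Hz>' comment and no sidecar rate")
    return Recording(data=data.T.astype(float), rate=rate, labels=labels)


def save_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording in the CSV dialect (rate comment + label header)."""
    with open(path, "w") as fh:
        fh.write(f"# rate={rec.rate:g}\n")
        fh.write(",".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.6f")


# ---------------------------------------------------------------------------
# EDF writer (16-bit, one record per second)


def write_edf(rec: Recording, path: str | Path, physical_max: float | None = None) -> None:
    """Write a recording as EDF.

    Samples are quantized to 16-bit integers over a symmetric physical
    range (default: the recording's absolute maximum, at least 1 uV).
    Trailing samples that do not fill a whole 1-s record are dropped.
    """
    data = np.asarray(rec.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot write non-finite samples to EDF")
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per record per channel
    n_rec = data.shape[1] // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    nch = data.shape[0]
    pmax = float(physical_max if physical_max is not None else
                 max(np.abs(data).max(), 1.0))
    dmin, dmax = -32768, 32767
    scale = dmax / pmax
    header = bytearray()

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header += f("0", 8)                      # version
    header += f("X X X X", 80)               # patient id
    header += f("Startdate X X X X", 80)     # recording id
    header += f("01.01.00", 8)               # start date
    header += f("00.00.00", 8)               # start time
    header += f(str(256 * (nch + 1)), 8)     # header bytes
    header += f("", 44)                      # reserved
    header += f(str(n_rec), 8)               # number of records
    header += f("1", 8)                      # record duration (s)
    header += f(str(nch), 4)                 # number of signals
    for lab in rec.labels:
        header += f(lab, 16)
    for _ in range(nch):
        header += f("AgAgCl electrode", 80)
    for _ in range(nch):
        header += f("uV", 8)
    for _ in range(nch):
        header += f(f"{-pmax:.6g}"[:8], 8)   # physical min
    for _ in range(nch):
        header += f(f"{pmax:.6g}"[:8], 8)    # physical max
    for _ in range(nch):
        header += f(str(dmin), 8)
    for _ in range(nch):
        header += f(str(dmax), 8)
    for _ in range(nch):
        header += f("", 80)                  # prefiltering
    for _ in range(nch):
        header += f(str(spr), 8)
    for _ in range(nch):
        header += f("", 32)                  # reserved

    digital = np.clip(np.round(data * scale), dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())


#: Physical-unit step of a 16-bit EDF file with the given physical range.
def edf_resolution(physical_max: float) -> float:
    return physical_max / 32767.0
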