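"""Synthetic resting-EEG cohorts with planted spectral, coupling and PAC structure.

Each subject is a set of cortical dipole sources projected to the 19
scalp sensors through the three-shell spherical lead field, plus sensor
noise at a configured SNR.  Sources are built from:

* a 1/f colored-noise background (spectrally shaped white noise),
* band-limited oscillatory peaks (band-pass filtered noise, not pure
  sinusoids, so coherence and PAC estimators face realistic bandwidth),
* alpha-phase -> gamma-amplitude coupling: the gamma component's
  amplitude is multiplied by ``(1 + m cos(phi_alpha)) / (1 + m)`` with
  modulation index ``m`` in [0, 1],
* lagged inter-source coupling: a delayed, scaled copy of a shared
  band-limited driver is mixed into each coupled source's band component
  (``sqrt(1-c^2) * own + c * delayed(driver)``), with per-source lags so
  the dependence is genuinely non-instantaneous.

The default cohort mirrors the study design this generator emulates:
23 patients and 23 controls, 5-minute recordings acquired at 500 Hz.
Patients receive an alpha2 power increase at a posterior-midline source
and a reduced gamma coupling strength among the 12 ROIs; the left
frontal-eye-field source carries per-subject phase-amplitude modulation
whose planted index correlates with the VAS intensity score at a target
correlation.  Behavioral scores are drawn to match the patient sample
moments of the emulated study (VAS intensity 6.26 +/- 2.30, discomfort
6.89 +/- 2.26, DHI 50.52 +/- 16.14) and clipped to instrument ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .headmodel import (
    CHANNELS_1020,
    DEFAULT_CONDUCTIVITIES,
    DEFAULT_ROI_CENTERS,
    DEFAULT_SHELL_RADII,
    build_montage,
    forward_gain,
)
from .io import Recording

POSTERIOR_MIDLINE = (0.0, -58.0, 40.0)  # posterior cingulate / precuneus area


# ---------------------------------------------------------------------------
# Primitive signal builders


def colored_noise(n: int, rate: float, exponent: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def band_noise(n: int, rate: float, band: tuple[float, float],
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order Butterworth on white)."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    out = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return out / out.std()


def pac_modulate(carrier: np.ndarray, phase_provider: np.ndarray,
                 m: float) -> np.ndarray:
    """Amplitude-modulate ``carrier`` by the phase of ``phase_provider``.

    The envelope factor is ``(1 + m cos(phi)) / (1 + m)``, so m=0 leaves
    the carrier untouched and m=1 gates it fully.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation index m must be in [0, 1]")
    if m == 0.0:
        return carrier
    phi = np.angle(signal.hilbert(phase_provider))
    return carrier * (1.0 + m * np.cos(phi)) / (1.0 + m)


# ---------------------------------------------------------------------------
# Source specification


@dataclass(frozen=True)
class Peak:
    center: float  # Hz
    bandwidth: float  # Hz (full width)
    power: float  # variance relative to unit background

    @property
    def band(self) -> tuple[float, float]:
        return (self.center - self.bandwidth / 2.0,
                self.center + self.bandwidth / 2.0)


@dataclass(frozen=True)
class SourceSpec:
    """One dipole source: location, spectrum, and optional PAC."""

    location: tuple[float, float, float]
    background_exponent: float = 1.0
    background_level: float = 1.0
    peaks: tuple[Peak, ...] = ()
    pac_m: float = 0.0
    pac_phase_band: tuple[float, float] = (8.0, 12.0)
    pac_amp_band: tuple[float, float] = (30.0, 44.0)

    def __post_init__(self):
        if not 0.0 <= self.pac_m <= 1.0:
            raise ValueError("pac_m must be in [0, 1]")
        for p in self.peaks:
            if not (2.0 <= p.band[0] and p.band[1] <= 44.0):
                raise ValueError(f"peak {p} outside the 2-44 Hz range")


def _overlaps(band_a: tuple[float, float], band_b: tuple[float, float]) -> bool:
    return band_a[0] <= band_b[1] and band_b[0] <= band_a[1]


def build_source_parts(spec: SourceSpec, n: int, rate: float,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Generate the additive parts of a source's scalar activity.

    Returns named unit pieces already scaled to their target power; PAC
    is *not* yet applied (couplings may modify the carrier first — see
    :func:`assemble_source`).
    """
    parts: dict[str, np.ndarray] = {
        "background": spec.background_level * colored_noise(
            n, rate, spec.background_exponent, rng)
    }
    for i, p in enumerate(spec.peaks):
        parts[f"peak{i}"] = np.sqrt(p.power) * band_noise(n, rate, p.band, rng)
    if spec.pac_m > 0:
        if not any(_overlaps(p.band, spec.pac_phase_band) for p in spec.peaks):
            parts["pac_phase"] = band_noise(n, rate, spec.pac_phase_band, rng)
        if not any(_overlaps(p.band, spec.pac_amp_band) for p in spec.peaks):
            parts["pac_amp"] = np.sqrt(0.5) * band_noise(n, rate, spec.pac_amp_band, rng)
    return parts


def _part_in_band(spec: SourceSpec, parts: dict[str, np.ndarray],
                  band: tuple[float, float]) -> str | None:
    for i, p in enumerate(spec.peaks):
        if _overlaps(p.band, band):
            return f"peak{i}"
    for key, fallback_band in (("pac_phase", spec.pac_phase_band),
                               ("pac_amp", spec.pac_amp_band)):
        if key in parts and _overlaps(fallback_band, band):
            return key
    return None


def source_orientation(location: tuple[float, float, float]) -> np.ndarray:
    """Deterministic dipole orientation for a source location.

    Orientations are a fixed pseudo-random function of the coordinates,
    shared by every subject of a cohort — emulating the fact that a
    cohort shares cortical anatomy, so a given region projects to the
    scalp the same way in everyone.
    """
    h = np.abs(np.asarray(location, float)).sum() + 31.0 * np.asarray(location)[0]
    rng = np.random.default_rng(np.int64(abs(h) * 1013 + 17))
    u = rng.standard_normal(3)
    return u / np.linalg.norm(u)


def assemble_source(spec: SourceSpec, parts: dict[str, np.ndarray],
                    rate: float, rng: np.random.Generator,
                    component_noise: float = 0.1,
                    orientation: np.ndarray | None = None) -> np.ndarray:
    """Apply PAC and embed the scalar activity as a 3-component moment.

    The scalar signal is placed along the given unit orientation (drawn
    from ``rng`` when omitted); independent low-level colored noise on
    the three components keeps the per-ROI PCA well conditioned.
    """
    parts = dict(parts)
    if spec.pac_m > 0:
        amp_key = _part_in_band(spec, parts, spec.pac_amp_band)
        phase_key = _part_in_band(spec, parts, spec.pac_phase_band)
        if amp_key is None or phase_key is None:
            raise ValueError("PAC requested but carrier/phase part missing")
        parts[amp_key] = pac_modulate(parts[amp_key], parts[phase_key], spec.pac_m)
    scalar = sum(parts.values())
    n = scalar.shape[0]
    if orientation is None:
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
    else:
        u = np.asarray(orientation, float)
        u = u / np.linalg.norm(u)
    iso = np.stack([colored_noise(n, rate, spec.background_exponent, rng)
                    for _ in range(3)])
    return u[:, None] * scalar + component_noise * scalar.std() * iso


def generate_source(spec: SourceSpec, duration: float, rate: float,
                    seed: int) -> np.ndarray:
    """Standalone 3-component dipole moment series for one source spec."""
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    parts = build_source_parts(spec, n, rate, rng)
    return assemble_source(spec, parts, rate, rng)


# ---------------------------------------------------------------------------
# Cohort specification


@dataclass(frozen=True)
class CohortSpec:
    """Study-level design of a synthetic cohort.

    Defaults are the emulated study conditions: 23 + 23 subjects,
    5-minute eyes-closed recordings at 500 Hz.  ``alpha2_offset`` is the
    patients' log-power increase of the posterior-midline alpha2 peak;
    ``coupling_patient``/``coupling_control`` set the shared gamma
    network coupling strength; ``pac_roi`` carries per-subject
    alpha-gamma modulation whose index correlates with VAS intensity at
    ``r_target`` among patients.
    """

    n_patients: int = 23
    n_controls: int = 23
    duration: float = 300.0
    rate: float = 500.0
    snr_db: float = 10.0
    seed: int = 0
    background_exponent: float = 1.0
    alpha2_offset: float = 1.0
    posterior_source: tuple[float, float, float] = POSTERIOR_MIDLINE
    coupling_control: float = 0.6
    coupling_patient: float = 0.25
    gamma_band: tuple[float, float] = (30.5, 44.0)
    pac_roi: str = "FEF_L"
    pac_m_range: tuple[float, float] = (0.1, 0.9)
    r_target: float = 0.5
    roi_centers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_CENTERS))
    shell_radii: tuple[float, float, float] = DEFAULT_SHELL_RADII
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES

    def __post_init__(self):
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if not -1.0 < self.r_target < 1.0:
            raise ValueError("r_target must be in (-1, 1)")
        if not (0 <= self.coupling_patient <= 1 and 0 <= self.coupling_control <= 1):
            raise ValueError("coupling strengths must be in [0, 1]")


@dataclass
class SubjectTruth:
    """Planted parameters of one synthetic subject."""

    subject: str
    group: str
    pac_m: float
    coupling: float
    alpha2_peak_power: float
    orientation_seed: int


def _source_specs(spec: CohortSpec, group: str, pac_m: float) -> list[SourceSpec]:
    """The 13 source specs (12 ROIs + posterior midline) for one subject."""
    specs = []
    for name, center in spec.roi_centers.items():
        m = pac_m if name == spec.pac_roi else 0.0
        # non-PAC sources keep their alpha peak in alpha1 (8-10 Hz) so the
        # planted posterior alpha2 offset is spatially identifiable; the PAC
        # ROI's gamma carrier matches its alpha peak in variance so the
        # modulation survives the blur of a 19-channel inverse
        peaks = [Peak(9.0, 2.0, 1.0), Peak(37.25, 13.5, 1.0 if m > 0 else 0.5)]
        specs.append(SourceSpec(location=tuple(center),
                                background_exponent=spec.background_exponent,
                                peaks=tuple(peaks), pac_m=m))
    alpha2_power = 1.0 * (np.exp(spec.alpha2_offset) if group == "patient" else 1.0)
    specs.append(SourceSpec(location=tuple(spec.posterior_source),
                            background_exponent=spec.background_exponent,
                            peaks=(Peak(11.0, 2.0, alpha2_power),)))
    return specs


def generate_subject(spec: CohortSpec, idx: int, group: str,
                     pac_m: float, gain: np.ndarray | None = None
                     ) -> tuple[Recording, SubjectTruth]:
    """One subject's sensor recording plus its planted-parameter record.

    ``gain`` may be precomputed (sensors x 3*13) to amortize the forward
    model across a cohort.
    """
    rng = np.random.default_rng([spec.seed, 7919, idx])
    n = int(round(spec.duration * spec.rate))
    coupling = spec.coupling_patient if group == "patient" else spec.coupling_control
    specs = _source_specs(spec, group, pac_m)
    if gain is None:
        gain = cohort_gain(spec)

    # per-source parts, then mix the shared gamma driver with per-source lags
    all_parts = [build_source_parts(s, n, spec.rate, rng) for s in specs]
    driver = band_noise(n, spec.rate, spec.gamma_band, rng)
    n_roi = len(spec.roi_centers)
    for i in range(n_roi):
        key = _part_in_band(specs[i], all_parts[i], spec.gamma_band)
        if key is None or coupling == 0.0:
            continue
        own = all_parts[i][key]
        lag = int(round((8.0 + 4.0 * i) * 1e-3 * spec.rate))  # 8..52 ms
        delayed = np.roll(driver, lag)
        scale = own.std()
        all_parts[i][key] = scale * (np.sqrt(1.0 - coupling**2) * own / own.std()
                                     + coupling * delayed)

    sensors = np.zeros((len(CHANNELS_1020), n))
    for i, (s, parts) in enumerate(zip(specs, all_parts)):
        moment = assemble_source(s, parts, spec.rate, rng,
                                 orientation=source_orientation(s.location))
        sensors += gain[:, 3 * i: 3 * i + 3] @ moment

    snr_lin = 10.0 ** (spec.snr_db / 10.0)
    if snr_lin <= 0:
        raise ValueError("SNR must be positive in linear units")
    sig_power = sensors.var(axis=1).mean()
    noise = rng.standard_normal(sensors.shape) * np.sqrt(sig_power / snr_lin)
    data = sensors + noise
    # scale to a plausible band-limited resting-EEG range (~8 uV RMS)
    data *= 8.0 / np.sqrt(data.var(axis=1).mean())
    rec = Recording(data=data, rate=spec.rate, labels=CHANNELS_1020)
    truth = SubjectTruth(subject=f"S{idx:03d}", group=group, pac_m=float(pac_m),
                         coupling=float(coupling),
                         alpha2_peak_power=float(
                             np.exp(spec.alpha2_offset) if group == "patient" else 1.0),
                         orientation_seed=idx)
    return rec, truth


def cohort_gain(spec: CohortSpec) -> np.ndarray:
    """Forward gain for the cohort's 13 source locations (avg-referenced)."""
    montage = build_montage()
    positions = np.array(list(spec.roi_centers.values())
                         + [list(spec.posterior_source)], dtype=float)
    g = forward_gain(montage.positions, positions, spec.shell_radii,
                     spec.conductivities)
    return g - g.mean(axis=0, keepdims=True)


def _behavioral_scores(spec: CohortSpec, pac_m: np.ndarray, group: np.ndarray,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Scores with the planted nesting->VAS-intensity correlation.

    Patients: VAS intensity is a linear-plus-noise function of the
    planted modulation index calibrated to ``r_target`` in expectation;
    discomfort, DHI and HADS are drawn with the emulated study's sample
    moments and inter-score correlations, then clipped/rounded to
    instrument ranges.  Controls receive near-floor symptom scores.
    """
    n = len(group)
    pat = group == "patient"
    z_m = np.zeros(n)
    if pat.sum() > 1 and np.ptp(pac_m[pat]) > 0:
        z_m[pat] = (pac_m[pat] - pac_m[pat].mean()) / pac_m[pat].std()
    r = spec.r_target
    eps = rng.standard_normal(n)
    z_int = r * z_m + np.sqrt(1.0 - r**2) * eps
    vas_int = np.where(pat, 6.26 + 2.30 * z_int, np.abs(0.5 * rng.standard_normal(n)))
    z2 = 0.87 * z_int + np.sqrt(1 - 0.87**2) * rng.standard_normal(n)
    vas_disc = np.where(pat, 6.89 + 2.26 * z2, np.abs(0.5 * rng.standard_normal(n)))
    z3 = 0.71 * z_int + np.sqrt(1 - 0.71**2) * rng.standard_normal(n)
    dhi = np.where(pat, 50.52 + 16.14 * z3, 2.0 * np.abs(rng.standard_normal(n)))
    hads_a = np.where(pat, 7.5 + 3.9 * rng.standard_normal(n),
                      2.0 + 1.5 * rng.standard_normal(n))
    hads_d = np.where(pat, 6.4 + 3.7 * rng.standard_normal(n),
                      1.5 + 1.5 * rng.standard_normal(n))
    return pd.DataFrame({
        "vas_intensity": np.clip(np.round(vas_int, 1), 0, 10),
        "vas_discomfort": np.clip(np.round(vas_disc, 1), 0, 10),
        "dhi": np.clip(np.round(dhi), 0, 100).astype(int),
        "hads_a": np.clip(np.round(hads_a), 0, 21).astype(int),
        "hads_d": np.clip(np.round(hads_d), 0, 21).astype(int),
    })


@dataclass
class Cohort:
    """Generated recordings plus the behavioral table and planted truth."""

    recordings: list[Recording]
    table: pd.DataFrame  # subject, group + behavioral columns
    truth: list[SubjectTruth]
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort deterministically from ``spec.seed``."""
    rng = np.random.default_rng([spec.seed, 104729])
    n = spec.n_patients + spec.n_controls
    group = np.array(["patient"] * spec.n_patients + ["control"] * spec.n_controls)
    lo, hi = spec.pac_m_range
    pac_m = rng.uniform(lo, hi, size=n)
    gain = cohort_gain(spec)
    recs, truths = [], []
    for i in range(n):
        rec, truth = generate_subject(spec, i, group[i], float(pac_m[i]), gain)
        recs.append(rec)
        truths.append(truth)
    scores = _behavioral_scores(spec, pac_m, group, rng)
    table = pd.concat([
        pd.DataFrame({"subject": [t.subject for t in truths], "group": group}),
        scores,
    ], axis=1)
    return Cohort(recordings=recs, table=table, truth=truths, spec=spec)
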