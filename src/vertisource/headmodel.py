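"""Spherical head model: 10-20 montage, source grid, lead field, ROI atlas.

The forward model is a three-shell concentric-sphere volume conductor
(brain, skull, scalp) with an analytic Legendre-series solution.  For each
harmonic order ``n`` the radial two-point boundary problem across the
shells is solved exactly by a small linear system, which gives the
transfer coefficient from the dipole's interior expansion to the scalp
surface.  The series converges geometrically in ``(b / scalp_radius)**n``
for a dipole at eccentricity ``b`` and is truncated once the remaining
terms are negligible.

Coordinates are head-centered millimetres, right-handed: +x right,
+y anterior, +z superior.  Conductivities are in S/m.  Gain values are in
consistent linear units (potential per unit dipole moment); all downstream
statistics are invariant to the overall scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: The 19 channels of the clinical 10-20 montage, in conventional order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Old-nomenclature aliases accepted on input.
CHANNEL_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

DEFAULT_SHELL_RADII = (80.0, 85.0, 92.0)  # brain, skull, scalp (mm)
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)  # S/m

#: Radial band of the brain sphere treated as gray matter.
GRAY_BAND = (0.55, 0.95)


class MontageError(ValueError):
    """Unknown or ill-formed channel labels."""


class GeometryError(ValueError):
    """Source/sensor positions incompatible with the shell geometry."""


class AtlasError(ValueError):
    """ROI assignment produced an invalid atlas."""


def normalize_label(label: str) -> str:
    """Map a channel label to canonical 10-20 nomenclature (T3 -> T7 etc.)."""
    label = label.strip()
    canon = {c.lower(): c for c in CHANNELS_1020}
    alias = {a.lower(): b for a, b in CHANNEL_ALIASES.items()}
    key = label.lower()
    if key in canon:
        return canon[key]
    if key in alias:
        return alias[key]
    raise MontageError(f"unknown 10-20 channel label: {label!r}")


# ---------------------------------------------------------------------------
# Montage


@dataclass(frozen=True)
class SensorMontage:
    """Unit-sphere sensor positions for the 19-channel 10-20 montage."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_sensors, 3) unit vectors

    def index(self, label: str) -> int:
        return self.labels.index(normalize_label(label))

    def to_json(self) -> str:
        return json.dumps(
            {lab: self.positions[i].tolist() for i, lab in enumerate(self.labels)},
            indent=1,
        )


def _sph(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def build_montage() -> SensorMontage:
    """Idealized 10-20 placement on the unit sphere.

    The outer ring (Fp1/2, F7/8, T7/8, P7/8, O1/2) sits on the equator at
    36-degree steps; Fz, Pz, C3, C4 lie halfway between Cz and the ring;
    F3/F4/P3/P4 lie on the great circle halfway between the midline and
    lateral electrodes, following the proportional 10-20 construction.
    Azimuth is measured from +x (right ear) toward +y (nasion).
    """
    pos: dict[str, np.ndarray] = {"Cz": np.array([0.0, 0.0, 1.0])}
    ring = {
        "T8": 0, "F8": 36, "Fp2": 72, "Fp1": 108, "F7": 144,
        "T7": 180, "P7": 216, "O1": 252, "O2": 288, "P8": 324,
    }
    for lab, phi in ring.items():
        pos[lab] = _sph(90.0, phi)
    pos["Fz"] = _sph(45.0, 90.0)
    pos["Pz"] = _sph(45.0, 270.0)
    pos["C3"] = _sph(45.0, 180.0)
    pos["C4"] = _sph(45.0, 0.0)
    pos["F3"] = _slerp(pos["Fz"], pos["F7"], 0.5)
    pos["F4"] = _slerp(pos["Fz"], pos["F8"], 0.5)
    pos["P3"] = _slerp(pos["Pz"], pos["P7"], 0.5)
    pos["P4"] = _slerp(pos["Pz"], pos["P8"], 0.5)
    arr = np.vstack([pos[c] for c in CHANNELS_1020])
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return SensorMontage(labels=CHANNELS_1020, positions=arr)


# ---------------------------------------------------------------------------
# Source grid


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic grid clipped to the gray-matter radial band."""

    coords: np.ndarray  # (n_voxels, 3) mm
    spacing: float  # mm
    shell_radii: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


def build_source_grid(
    spacing: float = 11.0,
    shell_radii: tuple[float, float, float] = DEFAULT_SHELL_RADII,
    gray_band: tuple[float, float] = GRAY_BAND,
) -> SourceGrid:
    """Cubic lattice (multiples of ``spacing``, centered at the origin)
    restricted to ``gray_band[0]*R <= |r| <= gray_band[1]*R`` of the brain
    sphere.  Raises if no voxel survives.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r_brain = shell_radii[0]
    lo, hi = gray_band[0] * r_brain, gray_band[1] * r_brain
    kmax = int(np.floor(hi / spacing))
    ax = np.arange(-kmax, kmax + 1) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(coords, axis=1)
    coords = coords[(r >= lo) & (r <= hi)]
    if coords.shape[0] == 0:
        raise ValueError(f"spacing {spacing} mm yields an empty source grid")
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return SourceGrid(coords=coords[order], spacing=float(spacing),
                      shell_radii=tuple(float(r_) for r_ in shell_radii))


# ---------------------------------------------------------------------------
# Lead field


@dataclass(frozen=True)
class LeadField:
    """Sensors x (3 * voxels) gain matrix of a three-shell sphere model."""

    gain: np.ndarray  # (n_sensors, 3 * n_sources)
    shell_radii: tuple[float, float, float]
    conductivities: tuple[float, float, float]
    average_referenced: bool = True
    model: str = "three_shell_sphere"

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3

    def columns(self, source: int) -> np.ndarray:
        """The (n_sensors, 3) gain block of one source."""
        return self.gain[:, 3 * source: 3 * source + 3]


def _shell_transfer(n: np.ndarray, radii_norm: tuple[float, float],
                    cond: tuple[float, float, float]) -> np.ndarray:
    """Surface transfer coefficient t_n for each harmonic order.

    For a unit interior source term u**-(n+1) in the brain region, solve
    the potential continuity / radial-current continuity conditions at the
    two internal interfaces and the insulating condition at the scalp
    surface (u = 1); t_n is the resulting surface potential coefficient.
    Radii are normalized by the scalp radius.
    """
    p1, p2 = radii_norm
    s1, s2, s3 = cond
    out = np.empty(n.shape, dtype=float)
    for i, nn in enumerate(n):
        np1 = nn + 1
        # unknowns: A1, A2, B2, A3, B3
        m = np.array([
            [p1**nn, -p1**nn, -p1**(-np1), 0.0, 0.0],
            [s1 * nn * p1**(nn - 1), -s2 * nn * p1**(nn - 1),
             s2 * np1 * p1**(-(nn + 2)), 0.0, 0.0],
            [0.0, p2**nn, p2**(-np1), -p2**nn, -p2**(-np1)],
            [0.0, s2 * nn * p2**(nn - 1), -s2 * np1 * p2**(-(nn + 2)),
             -s3 * nn * p2**(nn - 1), s3 * np1 * p2**(-(nn + 2))],
            [0.0, 0.0, 0.0, nn, -np1],
        ])
        rhs = np.array([-p1**(-np1), s1 * np1 * p1**(-(nn + 2)), 0.0, 0.0, 0.0])
        sol = np.linalg.solve(m, rhs)
        out[i] = sol[3] + sol[4]  # A3 + B3 at u = 1
    return out


def _series_order(f_max: float, tol: float = 1e-7) -> int:
    """Smallest N with n * f**(n-1) below tol (relative term bound)."""
    n = 20
    while n < 400 and n * f_max ** (n - 1) > tol:
        n += 10
    return n


def forward_gain(
    sensor_dirs: np.ndarray,
    source_coords: np.ndarray,
    shell_radii: tuple[float, float, float] = DEFAULT_SHELL_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
) -> np.ndarray:
    """Raw (no reference projection) gain matrix, sensors x (3 * sources).

    ``sensor_dirs`` are unit vectors (sensors sit on the scalp shell);
    ``source_coords`` are dipole positions in mm, strictly inside the
    brain shell.
    """
    r1, _, r3 = shell_radii[0], shell_radii[1], shell_radii[2]
    src = np.atleast_2d(np.asarray(source_coords, dtype=float))
    ehat = np.asarray(sensor_dirs, dtype=float)
    b = np.linalg.norm(src, axis=1)
    if np.any(b >= r1):
        raise GeometryError("source outside the brain shell")
    zhat = np.where(b[:, None] > 1e-9, src / np.maximum(b, 1e-9)[:, None],
                    np.array([0.0, 0.0, 1.0]))
    f = b / r3
    n_terms = _series_order(float(f.max()) if f.size else 0.0)
    n = np.arange(1, n_terms + 1)
    t_n = _shell_transfer(n, (r1 / r3, shell_radii[1] / r3), conductivities)

    x = np.clip(zhat @ ehat.T, -1.0, 1.0)  # cos(gamma), (S, E)
    # Legendre recurrences accumulated into the two angular sums:
    #   A = sum_n n f**(n-1) t_n P_n(x),  B = sum_n f**(n-1) t_n P_n'(x)
    p_prev = np.ones_like(x)   # P_0
    p_cur = x.copy()           # P_1
    dp_prev = np.zeros_like(x)  # P_0'
    dp_cur = np.ones_like(x)    # P_1'
    fpow = np.ones_like(f)      # f**(n-1) at n = 1
    A = np.zeros_like(x)
    B = np.zeros_like(x)
    for k, nn in enumerate(n):
        w = fpow * t_n[k]
        A += (nn * w)[:, None] * p_cur
        B += w[:, None] * dp_cur
        # advance recurrences to order nn + 1
        p_next = ((2 * nn + 1) * x * p_cur - nn * p_prev) / (nn + 1)
        dp_next = dp_prev + (2 * nn + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        fpow = fpow * f

    c = 1.0 / (4.0 * np.pi * conductivities[0] * r3**2)
    # column for unit moment along axis a:
    #   V = c * [ (a . zhat) A + ((a . ehat) - (a . zhat) cos(gamma)) B ]
    S, E = src.shape[0], ehat.shape[0]
    gain = np.empty((E, 3 * S))
    for a in range(3):
        az = zhat[:, a][:, None]          # (S, 1)
        ae = ehat[:, a][None, :]          # (1, E)
        V = c * (az * A + (ae - az * x) * B)  # (S, E)
        gain[:, a::3] = V.T
    # interleave as (x, y, z) per source
    out = np.empty_like(gain)
    for a in range(3):
        out[:, a::3] = gain[:, a::3]
    return out


def compute_leadfield(
    montage: SensorMontage,
    grid: SourceGrid,
    shell_radii: tuple[float, float, float] | None = None,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
) -> LeadField:
    """Three-shell spherical lead field for a montage and source grid.

    Columns are average-reference projected (zero mean across sensors),
    matching the reference convention of the inverse stage.
    """
    radii = tuple(shell_radii or grid.shell_radii)
    gain = forward_gain(montage.positions, grid.coords, radii, conductivities)
    gain = gain - gain.mean(axis=0, keepdims=True)
    if not np.all(np.isfinite(gain)):
        raise GeometryError("non-finite lead field")
    return LeadField(gain=gain, shell_radii=radii, conductivities=tuple(conductivities))


# ---------------------------------------------------------------------------
# ROI atlas

#: Approximate head-centered centroids (mm) for the 12 Brodmann-area ROIs.
#: BA43 = (secondary somatosensory/parietal operculum) vestibular cortex,
#: BA7 = precuneus, BA8 = frontal eye field, BA40 = intraparietal sulcus,
#: BA11 = orbitofrontal cortex, BA24 = dorsal anterior cingulate.
DEFAULT_ROI_CENTERS: dict[str, tuple[float, float, float]] = {
    "VC_L": (-58.0, -12.0, 12.0),
    "VC_R": (58.0, -12.0, 12.0),
    "Precuneus_L": (-8.0, -56.0, 48.0),
    "Precuneus_R": (8.0, -56.0, 48.0),
    "FEF_L": (-26.0, 26.0, 50.0),
    "FEF_R": (26.0, 26.0, 50.0),
    "IPS_L": (-44.0, -40.0, 44.0),
    "IPS_R": (44.0, -40.0, 44.0),
    "OFC_L": (-20.0, 44.0, -12.0),
    "OFC_R": (20.0, 44.0, -12.0),
    "dACC_L": (-6.0, 28.0, 38.0),
    "dACC_R": (6.0, 28.0, 38.0),
}

ROI_BRODMANN = {
    "VC": 43, "Precuneus": 7, "FEF": 8, "IPS": 40, "OFC": 11, "dACC": 24,
}

ROI_NAMES = tuple(DEFAULT_ROI_CENTERS)


@dataclass(frozen=True)
class ROIAtlas:
    """Disjoint voxel-index sets for named ROIs on a source grid."""

    rois: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.rois)

    def to_json(self) -> str:
        return json.dumps({k: v.tolist() for k, v in self.rois.items()}, indent=1)


def default_roi_spec(radius: float = 18.0) -> dict[str, tuple[tuple[float, float, float], float]]:
    """The shipped centroid table with a common sphere radius (mm)."""
    return {name: (c, radius) for name, c in DEFAULT_ROI_CENTERS.items()}


def assign_rois(
    grid: SourceGrid,
    roi_spec: dict[str, tuple[tuple[float, float, float], float]] | None = None,
) -> ROIAtlas:
    """Assign grid voxels to spherical ROIs.

    A voxel belongs to an ROI iff it lies within that ROI's radius of its
    center; a voxel inside several spheres goes to the nearest center, so
    the sets are disjoint by construction.  A voxel exactly equidistant to
    its two nearest centers (a midline voxel between mirrored ROIs) is
    assigned to neither, which keeps left/right sets mirror-symmetric.
    An ROI left empty raises :class:`AtlasError` naming it.
    """
    spec = roi_spec if roi_spec is not None else default_roi_spec()
    names = list(spec)
    centers = np.array([spec[n][0] for n in names], dtype=float)
    radii = np.array([spec[n][1] for n in names], dtype=float)
    if np.any(radii <= 0):
        bad = names[int(np.argmax(radii <= 0))]
        raise AtlasError(f"ROI {bad!r} has non-positive radius")
    d = np.linalg.norm(grid.coords[:, None, :] - centers[None, :, :], axis=2)
    inside = d <= radii[None, :]
    dmask = np.where(inside, d, np.inf)
    nearest = np.argmin(dmask, axis=1)
    if len(names) > 1:
        dsort = np.sort(dmask, axis=1)
        with np.errstate(invalid="ignore"):
            tied = np.isfinite(dsort[:, 1]) & (dsort[:, 1] - dsort[:, 0] < 1e-9)
    else:
        tied = np.zeros(len(nearest), dtype=bool)
    rois: dict[str, np.ndarray] = {}
    any_inside = inside.any(axis=1) & ~tied
    for i, name in enumerate(names):
        idx = np.nonzero(any_inside & (nearest == i))[0]
        if idx.size == 0:
            raise AtlasError(f"ROI {name!r} contains no voxels at this grid spacing")
        rois[name] = idx
    return ROIAtlas(rois=rois)
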