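"""Montage geometry, source grid, analytic lead field and ROI atlas."""

import numpy as np
import pytest

from vertisource.headmodel import (
    AtlasError,
    CHANNELS_1020,
    GeometryError,
    assign_rois,
    build_montage,
    build_source_grid,
    compute_leadfield,
    default_roi_spec,
    forward_gain,
    normalize_label,
)

RADII = (80.0, 85.0, 92.0)
COND = (0.33, 0.0042, 0.33)


class TestMontage:
    def test_vertex_and_unit_norms(self, montage):
        assert np.allclose(montage.positions[montage.index("Cz")], [0, 0, 1])
        assert np.allclose(np.linalg.norm(montage.positions, axis=1), 1.0)

    def test_left_right_mirror_symmetry(self, montage):
        for left, right in [("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"),
                            ("T7", "T8"), ("C3", "C4"), ("P7", "P8"),
                            ("P3", "P4"), ("O1", "O2")]:
            pl = montage.positions[montage.index(left)]
            pr = montage.positions[montage.index(right)]
            assert np.allclose(pl * [-1, 1, 1], pr, atol=1e-12)

    def test_all_sensors_distinct(self, montage):
        dots = montage.positions @ montage.positions.T
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 1.0 - 1e-6  # pairwise angular distance > 0

    def test_label_aliases(self):
        assert normalize_label("T3") == "T7"
        assert normalize_label("T6") == "P8"


class TestSourceGrid:
    def test_count_matches_brute_force_enumeration(self):
        spacing, rb = 20.0, 80.0
        grid = build_source_grid(spacing=spacing)
        count = 0
        k = int(np.floor(0.95 * rb / spacing))
        for i in range(-k, k + 1):
            for j in range(-k, k + 1):
                for l in range(-k, k + 1):
                    r = spacing * np.sqrt(i * i + j * j + l * l)
                    if 0.55 * rb <= r <= 0.95 * rb:
                        count += 1
        assert grid.n_voxels == count

    def test_all_voxels_inside_gray_band(self, small_grid):
        r = np.linalg.norm(small_grid.coords, axis=1)
        assert np.all(r >= 0.55 * 80.0 - 1e-9)
        assert np.all(r <= 0.95 * 80.0 + 1e-9)

    def test_halving_spacing_increases_count(self):
        assert (build_source_grid(spacing=10.0).n_voxels
                > build_source_grid(spacing=20.0).n_voxels)

    def test_degenerate_spacing_raises(self):
        with pytest.raises(ValueError):
            build_source_grid(spacing=500.0)


def _closed_form_homogeneous(sensor_dirs, r0, q, R, sigma):
    """Independent oracle: dipole in a homogeneous sphere, surface potential.

    Derived from the Legendre generating function: with f = b/R,
    x = cos(gamma), g = sqrt(1 - 2 f x + f^2), h = 1 - f x + g,
      radial sum  = (2 f (x-f)/g^3 + 1/g - 1) / (b R)
      tangential  = (2/g^3 + (g+1)/(g h)) / R^2
    """
    b = np.linalg.norm(r0)
    zhat = r0 / b
    f = b / R
    qr = q @ zhat
    qt = q - qr * zhat
    out = []
    for e in sensor_dirs:
        x = float(np.clip(e @ zhat, -1, 1))
        g = np.sqrt(1 - 2 * f * x + f * f)
        h = 1 - f * x + g
        Sr = (2 * f * (x - f) / g**3 + 1.0 / g - 1.0) / (b * R)
        St = (2.0 / g**3 + (g + 1.0) / (g * h)) / R**2
        out.append((qr * Sr + (qt @ e) * St) / (4 * np.pi * sigma))
    return np.array(out)


class TestLeadField:
    def test_homogeneous_limit_matches_closed_form(self, montage, rng):
        R = 92.0
        radii = (91.999, 91.9995, 92.0)  # collapse shells onto one sphere
        for _ in range(3):
            r0 = rng.uniform(-40, 40, 3)
            q = rng.standard_normal(3)
            G = forward_gain(montage.positions, r0[None], radii, (0.33, 0.33, 0.33))
            got = G[:, :3] @ q
            want = _closed_form_homogeneous(montage.positions, r0, q, R, 0.33)
            assert np.max(np.abs(got - want)) < 1e-3 * np.max(np.abs(want))

    def test_tangential_dipole_under_vertex_peaks_nearby(self, montage):
        G = forward_gain(montage.positions, np.array([[0.0, 0.0, 70.0]]),
                         RADII, COND)
        v = G[:, :3] @ np.array([1.0, 0.0, 0.0])  # tangential along +x
        best = CHANNELS_1020[int(np.argmax(np.abs(v)))]
        assert best in {"C3", "C4", "Cz"}  # Cz-adjacent ring

    def test_linearity_in_dipole_moment(self, montage):
        G = forward_gain(montage.positions, np.array([[10.0, 20.0, 30.0]]),
                         RADII, COND)
        q = np.array([0.3, -1.2, 0.5])
        assert np.allclose(G[:, :3] @ (2 * q), 2 * (G[:, :3] @ q))

    def test_sensor_swap_permutes_gain_rows(self, montage, small_grid):
        lf = compute_leadfield(montage, small_grid)
        perm = np.arange(19)
        perm[[0, 5]] = perm[[5, 0]]
        swapped = forward_gain(montage.positions[perm], small_grid.coords,
                               RADII, COND)
        swapped -= swapped.mean(axis=0, keepdims=True)
        assert np.allclose(swapped, lf.gain[perm], atol=1e-12)

    def test_average_reference_and_rank(self, small_leadfield):
        g = small_leadfield.gain
        assert np.abs(g.mean(axis=0)).max() < 1e-12
        assert np.linalg.matrix_rank(g @ g.T) >= 18

    def test_source_outside_brain_raises(self, montage):
        with pytest.raises(GeometryError):
            forward_gain(montage.positions, np.array([[0.0, 0.0, 85.0]]),
                         RADII, COND)


class TestROIAtlas:
    def test_membership_matches_brute_force(self, small_grid):
        spec = {"A": ((-30.0, 0.0, 40.0), 22.0), "B": ((40.0, 10.0, 30.0), 22.0)}
        atlas = assign_rois(small_grid, spec)
        for name, (center, radius) in spec.items():
            want = {i for i, c in enumerate(small_grid.coords)
                    if np.linalg.norm(c - np.array(center)) <= radius}
            # spheres are disjoint here, so membership is exactly the ball
            assert set(atlas.rois[name].tolist()) == want

    def test_mirrored_centers_give_mirrored_sets(self, small_grid, small_atlas):
        for base in ("VC", "FEF", "OFC", "Precuneus", "IPS", "dACC"):
            L = small_grid.coords[small_atlas.rois[f"{base}_L"]]
            R = small_grid.coords[small_atlas.rois[f"{base}_R"]]
            assert (sorted(map(tuple, L * [-1, 1, 1]))
                    == sorted(map(tuple, R)))

    def test_sets_pairwise_disjoint(self, small_atlas):
        seen = set()
        for idx in small_atlas.rois.values():
            s = set(idx.tolist())
            assert not (s & seen)
            seen |= s

    def test_zero_radius_raises(self, small_grid):
        with pytest.raises(AtlasError):
            assign_rois(small_grid, {"X": ((0.0, 0.0, 50.0), 0.0)})

    def test_all_twelve_rois_non_empty(self, small_atlas):
        assert set(small_atlas.names) == set(default_roi_spec())
        assert all(v.size > 0 for v in small_atlas.rois.values())
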