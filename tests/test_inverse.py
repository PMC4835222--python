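"""sLORETA inverse: localization, band power, ROI log power and time series."""

import numpy as np
import pytest

from vertisource.bands import ACTIVITY8
from vertisource.headmodel import CHANNELS_1020
from vertisource.inverse import (
    EstimationError,
    SourceBandPower,
    apply_inverse,
    compute_inverse_operator,
    estimate_band_power,
    extract_roi_timeseries,
    roi_log_power,
    standardized_power,
)
from vertisource.io import Recording
from vertisource.synth import band_noise


def _rec(data, rate=128.0):
    return Recording(data=np.atleast_2d(data), rate=rate,
                     labels=CHANNELS_1020[: np.atleast_2d(data).shape[0]],
                     reference="common_average")


class TestLocalization:
    def test_noiseless_dipoles_localize_to_their_voxel(self, small_leadfield,
                                                       small_inverse, rng):
        V = small_leadfield.n_sources
        for v in rng.choice(V, size=25, replace=False):
            q = rng.standard_normal(3)
            scalp = small_leadfield.columns(int(v)) @ q
            p = standardized_power(small_inverse, scalp)
            assert int(np.argmax(p)) == int(v)

    def test_zero_scalp_gives_zero_current(self, small_inverse):
        j = apply_inverse(small_inverse, np.zeros(19))
        assert np.allclose(j, 0.0)

    def test_linearity_in_scalp_data(self, small_leadfield, small_inverse, rng):
        scalp = small_leadfield.columns(10) @ rng.standard_normal(3)
        assert np.allclose(apply_inverse(small_inverse, 3.0 * scalp),
                           3.0 * apply_inverse(small_inverse, scalp))

    def test_alpha_zero_with_rank_deficient_gain_raises(self, small_leadfield):
        from dataclasses import replace
        gain = small_leadfield.gain.copy()
        gain[5:] = gain[:14]  # duplicate rows: rank collapses
        broken = replace(small_leadfield, gain=gain - gain.mean(0))
        with pytest.raises(np.linalg.LinAlgError):
            compute_inverse_operator(broken, alpha_frac=0.0)
        # a full-rank average-referenced gain is fine even unregularized
        compute_inverse_operator(small_leadfield, alpha_frac=0.0)


class TestBandPower:
    def test_white_noise_gives_positive_power_everywhere(self, small_inverse, rng):
        rec = _rec(rng.standard_normal((19, 128 * 30)))
        bp = estimate_band_power(rec, small_inverse)
        assert bp.power.shape == (small_inverse.n_sources, 8)
        assert np.all(bp.power > 0)

    def test_planted_alpha_source_dominates_alpha_bands(self, small_leadfield,
                                                        small_inverse, rng):
        v = 40
        src = band_noise(128 * 60, 128.0, (9.0, 11.0), rng)
        q = rng.standard_normal(3)
        scalp = (small_leadfield.columns(v) @ q)[:, None] * src
        rec = _rec(scalp + 1e-3 * rng.standard_normal(scalp.shape))
        bp = estimate_band_power(rec, small_inverse)
        names = list(bp.band_names)
        alpha = max(bp.power[v, names.index("alpha1")],
                    bp.power[v, names.index("alpha2")])
        for other in ("delta", "theta", "beta1", "beta2", "beta3", "gamma"):
            assert alpha > bp.power[v, names.index(other)]

    def test_power_scales_quadratically(self, small_inverse, rng):
        data = rng.standard_normal((19, 128 * 20))
        p1 = estimate_band_power(_rec(data), small_inverse).power
        p2 = estimate_band_power(_rec(2.0 * data), small_inverse).power
        assert np.allclose(p2, 4.0 * p1, rtol=1e-9)

    def test_too_short_recording_raises(self, small_inverse):
        with pytest.raises(EstimationError):
            estimate_band_power(_rec(np.zeros((19, 100))), small_inverse)


class TestROILogPower:
    def test_uniform_power_gives_log_fraction(self, small_atlas, small_grid):
        V = small_grid.n_voxels
        sp = SourceBandPower(power=np.ones((V, 8)),
                             band_names=tuple(ACTIVITY8))
        table = roi_log_power(sp, small_atlas)
        for name, idx in small_atlas.rois.items():
            assert np.allclose(table.loc[name], np.log(idx.size / V))

    def test_concentrated_power_saturates_and_clips(self, small_atlas, small_grid):
        V = small_grid.n_voxels
        power = np.zeros((V, 8))
        target = "FEF_L"
        power[small_atlas.rois[target][0], :] = 5.0
        table = roi_log_power(SourceBandPower(power=power,
                                              band_names=tuple(ACTIVITY8)),
                              small_atlas)
        assert np.allclose(table.loc[target], 0.0)  # log(1)
        others = table.drop(index=target)
        assert np.allclose(others.to_numpy(), np.log(1e-12))

    def test_fractions_conserved(self, small_atlas, small_grid, rng):
        V = small_grid.n_voxels
        power = rng.uniform(0.1, 2.0, size=(V, 8))
        table = roi_log_power(SourceBandPower(power=power,
                                              band_names=tuple(ACTIVITY8)),
                              small_atlas)
        # ROI fractions are disjoint subsets of a unit total
        sums = np.exp(table.to_numpy()).sum(axis=0)
        assert np.all(sums <= 1.0 + 1e-9)
        frac = power / power.sum(axis=0)
        assert np.allclose(frac.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_band_raises(self, small_atlas, small_grid):
        power = np.ones((small_grid.n_voxels, 8))
        power[:, 3] = 0.0
        with pytest.raises(EstimationError):
            roi_log_power(SourceBandPower(power=power,
                                          band_names=tuple(ACTIVITY8)),
                          small_atlas)


class TestROITimeSeries:
    def test_zero_input_zero_series(self, small_inverse, small_atlas):
        rts = extract_roi_timeseries(_rec(np.zeros((19, 600))), small_inverse,
                                     small_atlas)
        assert set(rts) == set(small_atlas.names)
        assert all(np.allclose(v, 0.0) for v in rts.values())

    def test_linearity(self, small_inverse, small_atlas, rng):
        a = rng.standard_normal((19, 400))
        b = rng.standard_normal((19, 400))
        ra = extract_roi_timeseries(_rec(a), small_inverse, small_atlas)
        rb = extract_roi_timeseries(_rec(b), small_inverse, small_atlas)
        rab = extract_roi_timeseries(_rec(a + b), small_inverse, small_atlas)
        for roi in ra:
            assert np.allclose(rab[roi], ra[roi] + rb[roi], atol=1e-9)

    def test_planted_fef_source_louder_than_homologue(self, small_leadfield,
                                                      small_inverse,
                                                      small_atlas, small_grid,
                                                      rng):
        from vertisource.headmodel import DEFAULT_ROI_CENTERS
        center = np.array(DEFAULT_ROI_CENTERS["FEF_L"])
        v = int(np.argmin(np.linalg.norm(small_grid.coords - center, axis=1)))
        src = rng.standard_normal(128 * 10)
        scalp = (small_leadfield.columns(v) @ rng.standard_normal(3))[:, None] * src
        rts = extract_roi_timeseries(_rec(scalp), small_inverse, small_atlas)
        assert rts["FEF_L"].var() > rts["FEF_R"].var()
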