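"""Single-cell parameter extraction: segmentation, morphometry, Hb,
height maps and membrane fluctuations."""

import math

import numpy as np
import pytest

from erythrotomo.containers import HeightSeries, RIVolume
from erythrotomo.cell_params import (
    NoCellFoundError,
    fluctuation,
    hb_concentration,
    hb_content,
    height_series,
    measure_cell,
    measure_morphology,
    projection_mask,
    segment_cell,
    sphericity,
)
from erythrotomo.synthetic_cell import (
    DiscocyteSpec,
    FluctuationSpec,
    make_discocyte,
    make_fluctuating_membrane,
)

N_M = 1.337


def spheroid_volume(a, c, dn=0.06, dv=0.05, n_m=N_M):
    """Oblate spheroid x²+y² ≤ a², z semi-axis c, with z fractional fill."""
    nxy = int(2 * a / dv) + 20
    nz = int(2 * c / dv) + 20
    x = (np.arange(nxy) - nxy // 2) * dv
    z = (np.arange(nz) - nz // 2) * dv
    rho2 = x[None, :] ** 2 + x[:, None] ** 2
    inside = np.clip(1.0 - rho2 / a ** 2, 0.0, None)
    half = c * np.sqrt(inside)
    lo = np.maximum(z[:, None, None] - dv / 2, -half[None])
    hi = np.minimum(z[:, None, None] + dv / 2, half[None])
    fill = np.clip((hi - lo) / dv, 0.0, 1.0)
    return RIVolume(n_m + dn * fill, dv, n_m, 532.0)


def oblate_area(a, c):
    e = math.sqrt(1.0 - (c / a) ** 2)
    return 2.0 * math.pi * a ** 2 * (1.0 + (1.0 - e * e) / e * math.atanh(e))


class TestSegmentCell:
    def test_threshold_is_strict_inequality_at_1p35(self):
        data = np.full((5, 5, 5), N_M)
        data[2, 2, 2] = 1.36
        data[2, 2, 1] = 1.34
        vol = RIVolume(data, 0.1, N_M, 532.0)
        mask = segment_cell(vol, 1.35)
        assert mask.mask[2, 2, 2]
        assert not mask.mask[2, 2, 1]

    def test_uniform_medium_raises(self):
        vol = RIVolume(np.full((8, 8, 8), N_M), 0.1, N_M, 532.0)
        with pytest.raises(NoCellFoundError):
            segment_cell(vol, 1.35)

    def test_sphere_voxel_count_matches_truth(self, sphere_volume):
        """Voxel counting at the half-fill threshold (where partial-volume
        voxels average out) reproduces the analytic volume within 2%; the
        lower 1.35 rendering threshold sits at 22% of the fill contrast and
        counts a sub-voxel shell extra."""
        vol, truth = sphere_volume
        dn = 0.18 * (100.0 / 3.0) / 100.0
        mask = segment_cell(vol, vol.n_m + 0.5 * dn)
        v_count = mask.voxel_count * vol.voxel_size ** 3
        assert v_count == pytest.approx(truth.volume_fl, rel=0.02)
        mask135 = segment_cell(vol, 1.35)
        v135 = mask135.voxel_count * vol.voxel_size ** 3
        assert v135 == pytest.approx(truth.volume_fl, rel=0.04)

    def test_largest_component_kept(self):
        data = np.full((16, 16, 16), N_M)
        data[4:10, 4:10, 4:10] = 1.40  # main blob
        data[13, 13, 13] = 1.40  # speck
        vol = RIVolume(data, 0.1, N_M, 532.0)
        mask = segment_cell(vol, 1.35)
        assert not mask.mask[13, 13, 13]
        assert mask.mask[6, 6, 6]


class TestMorphology:
    def test_sphere_mesh_morphometry(self, sphere_volume):
        """The marching-cubes mesh at the half-fill isolevel (the phantom's
        true boundary under fractional-fill voxelisation) reproduces the
        closed-form V and S within 2%."""
        vol, truth = sphere_volume
        dn = 0.18 * (100.0 / 3.0) / 100.0
        mask = segment_cell(vol, vol.n_m + 0.5 * dn)
        V, S, SI = measure_morphology(vol, mask)
        assert V == pytest.approx(truth.volume_fl, rel=0.02)
        assert S == pytest.approx(truth.surface_um2, rel=0.02)
        assert SI == pytest.approx(1.0, abs=0.02)

    def test_cube_sphericity_closed_form(self):
        # V = a³, S = 6a² → SI = (π/6)^{1/3}
        a = 3.7
        assert sphericity(a ** 3, 6 * a ** 2) == pytest.approx(
            (math.pi / 6.0) ** (1.0 / 3.0), rel=1e-12)
        assert (math.pi / 6.0) ** (1.0 / 3.0) == pytest.approx(0.806, abs=5e-4)

    def test_oblate_spheroid_surface_within_two_percent(self):
        a, c = 2.0, 0.6  # c/a = 0.3
        vol = spheroid_volume(a, c)
        mask = segment_cell(vol, N_M + 0.03)
        V, S, SI = measure_morphology(vol, mask)
        V_true = 4.0 / 3.0 * math.pi * a * a * c
        S_true = oblate_area(a, c)
        assert S == pytest.approx(S_true, rel=0.02)
        assert V == pytest.approx(V_true, rel=0.02)
        assert SI == pytest.approx(
            sphericity(V_true, S_true), abs=0.02)

    def test_sphericity_monotone_under_flattening(self):
        """SI decreases along a family of progressively flatter
        spheroids (c/a from 1.0 down to 0.1)."""
        prev = 1.1
        for ca in (1.0, 0.7, 0.4, 0.2, 0.1):
            V = 4.0 / 3.0 * math.pi * 2.0 ** 3 * ca
            S = oblate_area(2.0, 2.0 * ca) if ca < 1 else 4 * math.pi * 4.0
            si = sphericity(V, S)
            assert si < prev
            prev = si


class TestHaemoglobin:
    def test_closed_form_concentration(self):
        data = np.full((8, 8, 8), N_M)
        data[2:6, 2:6, 2:6] = 1.3970
        vol = RIVolume(data, 0.1, N_M, 532.0)
        mask = segment_cell(vol, 1.35)
        hb, dn = hb_concentration(vol, mask, alpha=0.18)
        assert dn == pytest.approx(0.0600, abs=1e-9)
        assert hb == pytest.approx(33.3, abs=0.05)

    def test_zero_contrast_zero_concentration(self):
        data = np.full((8, 8, 8), N_M)
        data[4, 4, 4] = 1.36
        vol = RIVolume(data, 0.1, N_M, 532.0)
        mask = segment_cell(vol, 1.35)
        hb, _ = hb_concentration(vol, mask, n_m=1.36)
        assert hb == 0.0

    @pytest.mark.parametrize("v,hb,expected", [
        (90.2, 34.6, 31.2),   # printed diabetic means reproduce the
                              # printed mean Hb content
        (0.0, 30.0, 0.0),
        (100.0, 30.0, 30.0),
    ])
    def test_hb_content_unit_arithmetic(self, v, hb, expected):
        assert hb_content(v, hb) == pytest.approx(expected, abs=0.05)

    def test_record_conserves_defining_product(self, sphere_volume):
        vol, _ = sphere_volume
        rec = measure_cell(vol)
        assert rec.hb_pg == pytest.approx(rec.hb_g_dl * rec.volume_fl * 0.01,
                                          rel=1e-12)


class TestHeightSeries:
    def test_slab_phase_inverts_to_thickness(self):
        """Δφ = 1.417 rad at 〈Δn〉 = 0.06, λ = 532 nm → h = 2.0 μm."""
        phi = np.full((2, 4, 4), 2.0 * math.pi * 0.12 / 0.532)
        hs = height_series(phi, 0.06, 532.0, 125.0, 0.1)
        assert hs.heights_nm[0, 0, 0] == pytest.approx(2000.0, rel=1e-9)

    def test_zero_phase_zero_height(self):
        hs = height_series(np.zeros((3, 4, 4)), 0.05, 532.0, 125.0, 0.1)
        assert np.all(hs.heights_nm == 0.0)

    def test_linear_in_phase(self, rng):
        phi = rng.random((3, 8, 8))
        h1 = height_series(phi, 0.06, 532.0, 125.0, 0.1).heights_nm
        h2 = height_series(2 * phi, 0.06, 532.0, 125.0, 0.1).heights_nm
        assert np.allclose(h2, 2 * h1)

    def test_nonpositive_contrast_rejected(self):
        with pytest.raises(ValueError):
            height_series(np.zeros((2, 4, 4)), 0.0, 532.0, 125.0, 0.1)


class TestFluctuation:
    def test_constant_series_zero_sigma(self):
        h = np.ones((10, 6, 6)) * 5.0
        hs = HeightSeries(h, 0.1, 125.0, support=np.ones((6, 6), bool))
        sd_map, sigma = fluctuation(hs)
        assert sigma == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_population_sd_closed_form(self):
        """A sinusoid of amplitude A over integer periods has temporal SD
        A/√2 under the divisor-N convention."""
        t = np.arange(200)
        a = 12.0
        h = a * np.sin(2 * math.pi * t / 50.0)[:, None, None] * \
            np.ones((1, 4, 4))
        hs = HeightSeries(h, 125.0, 125.0, support=np.ones((4, 4), bool))
        sd_map, sigma = fluctuation(hs)
        assert sigma == pytest.approx(a / math.sqrt(2.0), abs=1e-9)

    def test_synthetic_membrane_sigma_recovered(self, discocyte_spec):
        hs, gt = make_fluctuating_membrane(
            discocyte_spec, FluctuationSpec(sigma_target=50.0, seed=2))
        _, sigma = fluctuation(hs)
        assert sigma == pytest.approx(50.0, rel=0.06)

    def test_single_frame_rejected(self):
        hs = HeightSeries(np.zeros((1, 4, 4)), 0.1, 125.0,
                          support=np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            fluctuation(hs)

    def test_sample_convention_available(self, rng):
        h = rng.normal(size=(50, 5, 5))
        hs = HeightSeries(h, 0.1, 125.0, support=np.ones((5, 5), bool))
        _, pop = fluctuation(hs, ddof=0)
        _, samp = fluctuation(hs, ddof=1)
        assert samp > pop


class TestProjectionMask:
    def test_footprint_from_mean_phase(self, discocyte_spec):
        hs, _ = make_fluctuating_membrane(
            discocyte_spec, FluctuationSpec(sigma_target=0.0, seed=0))
        phase = hs.heights_nm[0] * 1e-3 * 0.06 * 2 * math.pi / 0.532
        mask = projection_mask(phase)
        # recovered footprint matches the generator's support closely
        overlap = (mask & hs.support).sum() / hs.support.sum()
        assert overlap > 0.93
        assert (mask & ~hs.support).sum() < 0.05 * hs.support.sum()

    def test_flat_image_raises(self):
        with pytest.raises(NoCellFoundError):
            projection_mask(np.zeros((32, 32)))
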