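import numpy as np
import pytest
from scipy import stats

from ppgmc.chromophores import BLOOD_ID, DERMIS_ID, EPIDERMIS_ID, PHANTOM_BOTTOM_ID, PHANTOM_TOP_ID
from ppgmc.geometry import (PhantomSpec, SkinSpec, build_phantom_volume,
                            build_skin_volume, dilate_vessels, resolve_centers,
                            sample_vessel_centers, vessel_count)

EXTENT = (2.0, 4.7, 1.1)
SMALL = (2.0, 0.4, 1.1)  # thin slab along the vessel axis, same cross-section


class TestPhantomVolume:
    def test_zero_top_thickness_is_homogeneous(self):
        vol = build_phantom_volume(PhantomSpec(0.0), extent=(2.0, 2.0, 1.0),
                                   voxel_size=0.05)
        assert np.all(vol.labels == PHANTOM_BOTTOM_ID)

    def test_top_layer_voxel_planes(self):
        vol = build_phantom_volume(PhantomSpec(0.20), extent=(2.0, 2.0, 1.0),
                                   voxel_size=0.02)
        n_top = int((vol.labels == PHANTOM_TOP_ID).any(axis=(0, 1)).sum())
        assert n_top == 10

    def test_deterministic(self):
        a = build_phantom_volume(PhantomSpec(0.1), extent=(1.0, 1.0, 1.0), voxel_size=0.02)
        b = build_phantom_volume(PhantomSpec(0.1), extent=(1.0, 1.0, 1.0), voxel_size=0.02)
        assert np.array_equal(a.labels, b.labels)

    def test_top_thicker_than_volume_errors(self):
        with pytest.raises(ValueError):
            build_phantom_volume(PhantomSpec(1.5), extent=(1.0, 1.0, 1.0), voxel_size=0.02)


class TestSkinVolume:
    def test_vessel_count_from_density(self):
        spec = SkinSpec(epidermal_thickness_um=100.0)
        assert vessel_count(spec, EXTENT) == 74  # round(33.75 * 2 * 1.1)

    def test_zero_density_has_no_blood(self):
        spec = SkinSpec(epidermal_thickness_um=100.0, vessel_density_per_mm2=0.0)
        vol = build_skin_volume(spec, SMALL)
        assert vol.volume_fraction(BLOOD_ID) == 0.0
        assert set(vol.label_counts()) == {EPIDERMIS_ID, DERMIS_ID}

    def test_label_conservation(self):
        vol = build_skin_volume(SkinSpec(epidermal_thickness_um=100.0,
                                         placement_seed=1), SMALL)
        counts = vol.label_counts()
        assert sum(counts.values()) == vol.labels.size
        assert set(counts) <= {EPIDERMIS_ID, DERMIS_ID, BLOOD_ID}

    def test_reproducible_for_fixed_seed(self):
        mk = lambda: build_skin_volume(
            SkinSpec(epidermal_thickness_um=100.0, placement_seed=5), SMALL)
        assert np.array_equal(mk().labels, mk().labels)

    def test_blood_fraction_matches_analytic_cylinder_volume(self):
        """Voxelized vessel volume approaches N*pi*r^2*L at fine voxels."""
        spec = resolve_centers(SkinSpec(epidermal_thickness_um=100.0,
                                        placement_seed=2), SMALL)
        vol = build_skin_volume(spec, SMALL, voxel_size=spec.diameter_mm / 10.0)
        n = spec.centers.shape[0]
        analytic = n * np.pi * (spec.diameter_mm / 2) ** 2 / (SMALL[0] * SMALL[2])
        assert vol.volume_fraction(BLOOD_ID) == pytest.approx(analytic, rel=0.10)

    def test_coarse_voxels_rejected(self):
        with pytest.raises(ValueError):
            build_skin_volume(SkinSpec(epidermal_thickness_um=100.0), SMALL,
                              voxel_size=0.05)

    def test_epidermis_slab_on_top(self):
        vol = build_skin_volume(SkinSpec(epidermal_thickness_um=100.0,
                                         placement_seed=1), SMALL)
        assert np.all(vol.labels[:, :, :10] == EPIDERMIS_ID)
        assert not np.any(vol.labels[:, :, 10:] == EPIDERMIS_ID)


class TestVesselPlacement:
    def test_no_overlap_and_inside_band(self):
        spec = SkinSpec(epidermal_thickness_um=100.0, placement_seed=4)
        c = sample_vessel_centers(spec, EXTENT)
        r = spec.diameter_mm / 2
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        d2[np.diag_indices_from(d2)] = np.inf
        assert np.sqrt(d2.min()) >= 2 * r - 1e-12
        assert np.all(c[:, 1] - r >= spec.d_mm)
        assert np.all(c[:, 1] + r <= EXTENT[2])

    def test_depth_distribution_uniform(self):
        """Many small vessels: depth histogram consistent with uniform."""
        spec = SkinSpec(epidermal_thickness_um=50.0, vessel_diameter_um=10.0,
                        vessel_density_per_mm2=500.0, placement_seed=8,
                        depth_band=(0.1, 1.0))
        c = sample_vessel_centers(spec, EXTENT)
        assert c.shape[0] == vessel_count(spec, EXTENT)
        hist, _ = np.histogram(c[:, 1], bins=8, range=(0.105, 0.995))
        assert stats.chisquare(hist).pvalue > 1e-3

    def test_grid_placement_deterministic(self):
        spec = SkinSpec(epidermal_thickness_um=100.0, placement="grid")
        a = sample_vessel_centers(spec, EXTENT)
        b = sample_vessel_centers(spec, EXTENT)
        np.testing.assert_array_equal(a, b)
        assert a.shape[0] == vessel_count(spec, EXTENT)


class TestDilateVessels:
    def test_identity(self):
        spec = resolve_centers(SkinSpec(epidermal_thickness_um=100.0,
                                        placement_seed=6), SMALL)
        same = dilate_vessels(spec, spec.vessel_diameter_um, SMALL)
        np.testing.assert_array_equal(same.centers, spec.centers)
        assert same.vessel_diameter_um == spec.vessel_diameter_um

    def test_preserves_count_and_centers(self):
        dia = resolve_centers(SkinSpec(epidermal_thickness_um=100.0,
                                       vessel_diameter_um=117.0,
                                       placement_seed=6), SMALL)
        sys_ = dilate_vessels(dia, 75.0, SMALL)
        assert sys_.vessel_diameter_um == 75.0
        np.testing.assert_array_equal(sys_.centers, dia.centers)

    def test_blood_fraction_ratio_tracks_area_ratio(self):
        """Diastole/systole blood volume ratio ~ (117/75)^2 ~ 2.43."""
        dia = resolve_centers(SkinSpec(epidermal_thickness_um=100.0,
                                       vessel_diameter_um=117.0,
                                       placement_seed=6), SMALL)
        sys_ = dilate_vessels(dia, 75.0, SMALL)
        f_d = build_skin_volume(dia, SMALL, 0.008).volume_fraction(BLOOD_ID)
        f_s = build_skin_volume(sys_, SMALL, 0.008).volume_fraction(BLOOD_ID)
        assert f_d / f_s == pytest.approx((117.0 / 75.0) ** 2, rel=0.08)

    def test_dilation_out_of_dermis_errors(self):
        spec = resolve_centers(
            SkinSpec(epidermal_thickness_um=100.0, vessel_diameter_um=75.0,
                     vessel_density_per_mm2=3.0,
                     depth_band=(0.11, 0.30), placement_seed=6), SMALL)
        with pytest.raises(ValueError):
            dilate_vessels(spec, 400.0, SMALL)


def test_volume_hdf5_round_trip(tmp_path):
    from ppgmc.geometry import load_volume, save_volume

    vol = build_phantom_volume(PhantomSpec(0.1), extent=(1.0, 1.0, 0.5), voxel_size=0.02)
    save_volume(tmp_path / "v.h5", vol)
    back = load_volume(tmp_path / "v.h5")
    assert np.array_equal(back.labels, vol.labels)
    assert back.voxel_size == vol.voxel_size
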