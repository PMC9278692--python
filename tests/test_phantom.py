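import dataclasses

import numpy as np
import pytest

from sctkit.grid import ImageVolume
from sctkit.metrics import mae, rmse
from sctkit.phantom import (
    TABLE_CT_HU,
    AnatomyPerturbation,
    DegradationSpec,
    OrganSpec,
    PhantomSpec,
    default_degradation_spec,
    default_phantom_spec,
    degrade_to_cbct,
    generate_dataset,
    make_ctdef_surrogate,
    make_phantom_ct,
    perturb_anatomy,
)


class TestMakePhantomCT:
    def test_organ_means_recover_spec_targets(self, abdominal_phantom):
        """Sample mean over each organ mask is within 3 standard errors of
        the requested mean (and inside the generating-table tolerances)."""
        _, vol, structs = abdominal_phantom
        for name, (mean, std) in TABLE_CT_HU.items():
            organ = name if name in structs else name
            m = structs[organ]
            vals = vol.data[m.data]
            se = std / np.sqrt(vals.size)
            assert abs(vals.mean() - mean) <= 3 * se + 1e-9, name

    def test_liver_and_lung_means_within_measured_tolerance(self, abdominal_phantom):
        _, vol, structs = abdominal_phantom
        assert vol.data[structs["liver"].data].mean() == pytest.approx(54, abs=1.0)
        assert vol.data[structs["lungs"].data].mean() == pytest.approx(-719, abs=5.0)

    def test_deterministic_given_seed(self, small_spec):
        v1, s1 = make_phantom_ct(small_spec)
        v2, s2 = make_phantom_ct(small_spec)
        assert np.array_equal(v1.data, v2.data)
        for n in s1.names():
            assert np.array_equal(s1[n].data, s2[n].data)

    def test_air_outside_body(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        outside = ~structs["body"].data
        assert np.all(vol.data[outside] == -1000.0)

    def test_masks_strictly_inside_body(self, abdominal_phantom):
        _, _, structs = abdominal_phantom
        body = structs["body"].data
        for name, m in structs.items():
            if name == "body":
                continue
            assert not m.is_empty(), name
            assert np.all(body[m.data]), name

    def test_later_organ_wins_overlap(self):
        organs = (
            OrganSpec("first", "sphere", (0, 0, 0), (20.0,) * 3, 100.0, 0.0),
            OrganSpec("second", "sphere", (0, 0, 10), (20.0,) * 3, 300.0, 0.0),
        )
        spec = PhantomSpec(grid_shape=(16, 24, 24), spacing=(4, 4, 4),
                           body_semiaxes_mm=(44, 44), organs=organs,
                           ptv_center_mm=(0, 0, 0), ptv_radius_mm=8)
        vol, structs = make_phantom_ct(spec)
        assert not np.any(structs["first"].data & structs["second"].data)
        assert np.all(vol.data[structs["first"].data] == 100.0)
        assert np.all(vol.data[structs["second"].data] == 300.0)

    def test_organ_outside_grid_rejected(self, small_spec):
        bad = dataclasses.replace(
            small_spec,
            organs=(OrganSpec("huge", "sphere", (0, 0, 0), (500.0,) * 3,
                              0.0, 0.0),),
        )
        with pytest.raises(ValueError, match="outside the grid"):
            make_phantom_ct(bad)

    def test_organ_volume_matches_primitive_within_5pct(self, abdominal_phantom):
        """Voxel count x voxel volume reproduces the analytic volume."""
        spec, _, structs = abdominal_phantom
        organ = spec.organs[2]  # liver ellipsoid, no overlap with later organs
        analytic = 4.0 / 3.0 * np.pi * np.prod(organ.semi_axes)
        voxelized = structs[organ.name].voxel_count * structs[organ.name].voxel_volume_mm3
        assert voxelized == pytest.approx(analytic, rel=0.05)


class TestDegradeToCBCT:
    def test_zero_spec_is_identity(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        spec = DegradationSpec(cupping_hu=0, noise_sigma_hu=0, streak_count=0,
                               streak_amplitude_hu=0, blur_fwhm_mm=0)
        out = degrade_to_cbct(vol, structs["body"], spec)
        assert np.array_equal(out.data, vol.data)

    def test_per_tissue_bias_moves_organ_mean(self, small_spec):
        """A +38 HU heart bias drifts the simulated heart mean from its CT
        value (36) to the CBCT value (~74)."""
        vol, structs = make_phantom_ct(small_spec)
        spec = DegradationSpec(cupping_hu=0, noise_sigma_hu=0, streak_count=0,
                               blur_fwhm_mm=0, tissue_bias_hu={"heart": 38.0})
        out = degrade_to_cbct(vol, structs["body"], spec, structs)
        heart = out.data[structs["heart"].data]
        assert heart.mean() == pytest.approx(74.0, abs=1.5)

    def test_noise_only_rmse_matches_sigma(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        spec = DegradationSpec(cupping_hu=0, noise_sigma_hu=20.0,
                               streak_count=0, blur_fwhm_mm=0, seed=11)
        out = degrade_to_cbct(vol, structs["body"], spec)
        assert rmse(vol, out, structs["body"]) == pytest.approx(20.0, rel=0.1)

    def test_air_outside_body_untouched(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        out = degrade_to_cbct(vol, structs["body"], default_degradation_spec(),
                              structs)
        outside = ~structs["body"].data
        assert np.array_equal(out.data[outside], vol.data[outside])

    def test_cupping_depresses_centre_not_surface(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        spec = DegradationSpec(cupping_hu=50.0, noise_sigma_hu=0,
                               streak_count=0, blur_fwhm_mm=0)
        out = degrade_to_cbct(vol, structs["body"], spec)
        diff = out.data - vol.data
        centre = diff[12, 20, 20]
        assert centre == pytest.approx(-50.0, abs=2.0)
        assert diff[structs["body"].data].max() > -5.0  # near surface ~0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            DegradationSpec(noise_sigma_hu=-1.0)

    def test_mae_increases_with_noise_sigma(self, small_spec):
        """Degradation severity is monotone in noise sigma (averaged over
        several seeds)."""
        vol, structs = make_phantom_ct(small_spec)
        maes = []
        for sigma in (5.0, 15.0, 30.0):
            vals = []
            for seed in range(5):
                spec = DegradationSpec(cupping_hu=0, noise_sigma_hu=sigma,
                                       streak_count=0, blur_fwhm_mm=0,
                                       seed=seed)
                vals.append(mae(vol, degrade_to_cbct(vol, structs["body"], spec),
                                structs["body"]))
            maes.append(np.mean(vals))
        assert maes[0] < maes[1] < maes[2]


class TestPerturbAnatomy:
    def test_zero_perturbation_returns_same_phantom(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        v2, s2 = perturb_anatomy(small_spec, AnatomyPerturbation())
        assert np.array_equal(vol.data, v2.data)

    def test_shifted_liver_centroid_moves_as_requested(self, small_spec):
        _, structs = make_phantom_ct(small_spec)
        p = AnatomyPerturbation(organ_shifts_mm={"liver": (0.0, 5.0, 0.0)})
        _, s2 = perturb_anatomy(small_spec, p)
        d = s2["liver"].centroid_mm() - structs["liver"].centroid_mm()
        assert d[1] == pytest.approx(5.0, abs=small_spec.spacing[1] / 2)
        assert abs(d[0]) < small_spec.spacing[0] / 2
        assert abs(d[2]) < small_spec.spacing[2] / 2

    def test_air_pocket_volume_matches_sphere(self, small_spec):
        r = 8.0
        p = AnatomyPerturbation(air_pockets=(((0.0, 20.0, -20.0), r),))
        vol, s2 = perturb_anatomy(small_spec, p)
        pocket = s2["air_pocket_0"]
        analytic = 4.0 / 3.0 * np.pi * r**3
        # voxelization error on an 8 mm sphere at 4-5 mm spacing is large
        assert pocket.voxel_count * pocket.voxel_volume_mm3 == pytest.approx(
            analytic, rel=0.35)
        assert np.all(vol.data[pocket.data] == -1000.0)

    def test_air_pocket_outside_body_rejected(self, small_spec):
        p = AnatomyPerturbation(air_pockets=(((0.0, 0.0, 120.0), 5.0),))
        with pytest.raises(ValueError, match="inside the body"):
            perturb_anatomy(small_spec, p)

    def test_shift_beyond_bound_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            AnatomyPerturbation(organ_shifts_mm={"liver": (0, 12.0, 0)})


class TestCtdefSurrogate:
    def test_zero_error_is_identity(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        v2, s2 = make_ctdef_surrogate(vol, structs, 0.0)
        assert np.array_equal(vol.data, v2.data)
        assert np.array_equal(s2["liver"].data, structs["liver"].data)

    def test_max_displacement_equals_requested_error(self, small_spec):
        from sctkit.phantom import _smooth_unit_field

        rng = np.random.default_rng(4)
        field = 7.0 * _smooth_unit_field((24, 40, 40), (5, 4, 4), 50.0, rng)
        mag = np.sqrt((field**2).sum(axis=0))
        assert mag.max() == pytest.approx(7.0, abs=0.1)

    def test_misalignment_strictly_degrades_dice(self, small_spec):
        from sctkit.contours import dice

        vol, structs = make_phantom_ct(small_spec)
        _, s2 = make_ctdef_surrogate(vol, structs, 7.0, seed=2)
        assert dice(s2["liver"], structs["liver"]) < 1.0

    def test_deterministic(self, small_spec):
        vol, structs = make_phantom_ct(small_spec)
        v1, _ = make_ctdef_surrogate(vol, structs, 5.0, seed=9)
        v2, _ = make_ctdef_surrogate(vol, structs, 5.0, seed=9)
        assert np.array_equal(v1.data, v2.data)


class TestGenerateDataset:
    def test_manifest_reproducible_and_split(self, tmp_path, small_spec):
        m1 = generate_dataset(3, tmp_path / "a", template=small_spec,
                              master_seed=5, write_volumes=False)
        m2 = generate_dataset(3, tmp_path / "b", template=small_spec,
                              master_seed=5, write_volumes=False)
        m1.pop("root"), m2.pop("root")
        assert m1 == m2
        assert m1["n_train"] == 2 and m1["n_test"] == 1

    def test_seventeen_subjects_split_11_train_6_test(self, tmp_path, small_spec):
        m = generate_dataset(17, tmp_path, template=small_spec,
                             write_volumes=False)
        assert m["n_train"] == 11
        assert m["n_test"] == 6

    def test_single_subject_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="at least 2"):
            generate_dataset(1, tmp_path)

    def test_volumes_written_with_sidecars(self, tmp_path, small_spec):
        m = generate_dataset(2, tmp_path, template=small_spec, master_seed=1)
        sub = m["subjects"][0]
        for tag in ("ct", "cbct", "ctdef"):
            assert (tmp_path / sub[tag]).exists()
            assert (tmp_path / (sub[tag] + ".json")).exists()
        assert (tmp_path / sub["masks_daily"] / "liver.nii.gz").exists()
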