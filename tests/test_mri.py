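"""Geometric features from cardiac segmentation masks."""

import numpy as np
import pytest

from latmap.mri import (CardiacStudy, classify_dcm, ejection_fraction,
                        extract_case_features, myocardial_mass,
                        structure_volume, wall_thickness_stats,
                        GEOMETRIC_FEATURE_NAMES, studies_to_feature_matrix)
from latmap.synthetic import (PhantomSpec, gen_cardiac_phantom,
                              lv_radius_for_volume)


def _annulus_study(inner_mm, outer_mm, n_slices=5, px=1.0, size=96):
    """Constant annulus myocardium with an LV cavity inside, RV far corner."""
    x = (np.arange(size) + 0.5) * px
    xx, yy = np.meshgrid(x, x, indexing="ij")
    c = size * px / 2
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    sl = np.zeros((size, size), dtype=np.int16)
    sl[r2 <= inner_mm ** 2] = 3
    sl[(r2 > inner_mm ** 2) & (r2 <= outer_mm ** 2)] = 2
    sl[:3, :3] = 1  # token RV so ratios stay defined
    vol = np.stack([sl] * n_slices, axis=2)
    return CardiacStudy(ed_mask=vol, es_mask=vol.copy(),
                        spacing=(px, px, 8.0))


class TestStructureVolume:
    def test_voxel_counting(self):
        mask = np.full((10, 10, 10), 3, dtype=np.int16)
        assert structure_volume(mask, 3, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_empty_label(self):
        mask = np.zeros((4, 4, 4), dtype=np.int16)
        assert structure_volume(mask, 3, (1.0, 1.0, 1.0)) == 0.0

    def test_digitized_sphere_matches_analytic(self):
        # radius 20 mm at 0.5 mm isotropic spacing: error < 1%
        r_mm, px = 20.0, 0.5
        n = int(2 * r_mm / px) + 8
        coords = (np.arange(n) + 0.5) * px - n * px / 2
        xx, yy, zz = np.meshgrid(coords, coords, coords, indexing="ij")
        mask = (xx ** 2 + yy ** 2 + zz ** 2 <= r_mm ** 2).astype(np.int16)
        vol = structure_volume(mask, 1, (px, px, px))
        analytic = 4 / 3 * np.pi * r_mm ** 3 / 1000
        assert abs(vol - analytic) / analytic < 0.01

    def test_volume_additivity(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 4, size=(9, 7, 5)).astype(np.int16)
        spacing = (1.1, 0.9, 2.0)
        total = sum(structure_volume(mask, lab, spacing) for lab in range(4))
        bbox = np.prod(mask.shape) * np.prod(spacing) / 1000
        assert total == pytest.approx(bbox, abs=1e-12)


class TestEjectionFraction:
    def test_no_contraction(self):
        assert ejection_fraction(100, 100) == 0.0

    def test_half_emptied(self):
        assert ejection_fraction(120, 60) == pytest.approx(50.0)

    def test_complete_emptying_limit(self):
        assert ejection_fraction(80, 0) == pytest.approx(100.0)

    def test_rejects_nonpositive_edv(self):
        with pytest.raises(ValueError):
            ejection_fraction(0, 0)


class TestMyocardialMass:
    def test_standard_density(self):
        assert myocardial_mass(100, 1.05) == pytest.approx(105.0)

    def test_zero_volume(self):
        assert myocardial_mass(0) == 0.0

    def test_unit_density_identity(self):
        assert myocardial_mass(87.3, 1.0) == pytest.approx(87.3)


class TestWallThickness:
    def test_constant_annulus(self):
        study = _annulus_study(25, 35)
        stats = wall_thickness_stats(study, "ed")
        # within one voxel diagonal of the analytic 10 mm
        assert stats["max_mean"] == pytest.approx(10.0, abs=np.sqrt(2))
        assert stats["sd_mean"] == 0.0
        assert stats["sd_sd"] == 0.0

    def test_slice_dependent_thickness(self):
        slices = []
        inner = 25.0
        outers = [33.0, 35.0, 37.0]
        for outer in outers:
            s = _annulus_study(inner, outer, n_slices=1)
            slices.append(s.ed_mask[:, :, 0])
        vol = np.stack(slices, axis=2)
        study = CardiacStudy(ed_mask=vol, es_mask=vol.copy(),
                             spacing=(1.0, 1.0, 8.0))
        stats = wall_thickness_stats(study, "ed")
        analytic = np.array(outers) - inner
        assert stats["sd_mean"] == pytest.approx(analytic.std(), abs=0.5)
        np.testing.assert_allclose(stats["per_slice_mean"], analytic,
                                   atol=np.sqrt(2))

    def test_single_slice_zero_sds(self):
        study = _annulus_study(25, 35, n_slices=1)
        stats = wall_thickness_stats(study, "ed")
        assert stats["sd_mean"] == 0.0
        assert stats["sd_sd"] == 0.0

    def test_no_myocardium_names_phase(self):
        vol = np.zeros((8, 8, 2), dtype=np.int16)
        study = CardiacStudy(ed_mask=vol, es_mask=vol,
                             spacing=(1.0, 1.0, 8.0))
        with pytest.raises(ValueError, match="ED"):
            wall_thickness_stats(study, "ed")

    def test_radial_method_close_to_edt(self):
        study = _annulus_study(25, 35)
        edt = wall_thickness_stats(study, "ed", method="edt")
        radial = wall_thickness_stats(study, "ed", method="radial")
        assert radial["max_mean"] == pytest.approx(edt["max_mean"], abs=2.0)


class TestExtractCaseFeatures:
    def test_phantom_ef(self):
        res = gen_cardiac_phantom(PhantomSpec())
        fv = extract_case_features(res["study"])
        assert fv.lv_ef_pct == pytest.approx(60.0, abs=1.0)
        assert fv.lv_vol_ed_ml == pytest.approx(150.0, rel=0.01)
        assert fv.myo_mass_ed_g == pytest.approx(
            1.05 * res["truth"]["myo_vol_ed_ml"], rel=0.02)

    def test_identical_phases_symmetric(self):
        res = gen_cardiac_phantom(PhantomSpec())
        study = res["study"]
        sym = CardiacStudy(ed_mask=study.ed_mask, es_mask=study.ed_mask,
                           spacing=study.spacing)
        fv = extract_case_features(sym)
        assert fv.lv_ef_pct == 0.0
        assert fv.rv_ef_pct == 0.0
        assert fv.lv_vol_ed_ml == fv.lv_vol_es_ml
        assert fv.wall_max_mean_ed_mm == fv.wall_max_mean_es_mm

    def test_equal_lv_rv_ratio_one(self):
        height = 10 * 8.0
        spec = PhantomSpec(rv_volume_target_ml=150.0,
                           lv_radius_ed=lv_radius_for_volume(150.0, height))
        res = gen_cardiac_phantom(spec)
        fv = extract_case_features(res["study"])
        assert fv.lv_rv_ratio_ed == pytest.approx(1.0, abs=0.03)

    def test_memory_layout_independent(self):
        res = gen_cardiac_phantom(PhantomSpec())
        study = res["study"]
        f_order = CardiacStudy(ed_mask=np.asfortranarray(study.ed_mask),
                               es_mask=np.asfortranarray(study.es_mask),
                               spacing=study.spacing)
        a = extract_case_features(study).as_row()
        b = extract_case_features(f_order).as_row()
        assert a == b

    def test_ef_invariant_to_isotropic_rescale(self):
        res = gen_cardiac_phantom(PhantomSpec())
        study = res["study"]
        scaled = CardiacStudy(ed_mask=study.ed_mask, es_mask=study.es_mask,
                              spacing=tuple(2 * s for s in study.spacing))
        assert extract_case_features(scaled).lv_ef_pct == \
            pytest.approx(extract_case_features(study).lv_ef_pct)

    def test_feature_matrix_columns(self):
        res = gen_cardiac_phantom(PhantomSpec())
        fm = studies_to_feature_matrix([res["study"]])
        assert fm.feature_names == GEOMETRIC_FEATURE_NAMES
        assert fm.n_samples == 1


class TestClassifyDcm:
    def test_dilated_low_ef(self):
        row = {"lv_ef_pct": 30.0, "lv_vol_ed_ml": 250.0}
        assert classify_dcm(row) == "DCM"

    def test_preserved_ef_never_dcm(self):
        row = {"lv_ef_pct": 60.0, "lv_vol_ed_ml": 400.0}
        assert classify_dcm(row) == "not_DCM"

    def test_boundary_45_is_not_dcm(self):
        row = {"lv_ef_pct": 45.0, "lv_vol_ed_ml": 250.0}
        assert classify_dcm(row) == "not_DCM"

    def test_missing_feature_named(self):
        with pytest.raises(ValueError, match="lv_vol_ed_ml"):
            classify_dcm({"lv_ef_pct": 30.0})


def test_nifti_roundtrip(tmp_path):
    import nibabel as nib
    res = gen_cardiac_phantom(PhantomSpec(shape=(96, 64, 4),
                                          lv_radius_ed=10.0, lv_radius_es=7.0,
                                          wall_thickness=4.0,
                                          rv_volume_target_ml=15.0))
    study = res["study"]
    affine = np.diag(list(study.spacing) + [1.0])
    nib.save(nib.Nifti1Image(study.ed_mask.astype(np.int16), affine),
             tmp_path / "ed.nii")
    nib.save(nib.Nifti1Image(study.es_mask.astype(np.int16), affine),
             tmp_path / "es.nii")
    back = CardiacStudy.from_nifti(tmp_path / "ed.nii", tmp_path / "es.nii")
    np.testing.assert_array_equal(back.ed_mask, study.ed_mask)
    assert back.spacing == pytest.approx(study.spacing)


def test_npy_roundtrip(tmp_path):
    res = gen_cardiac_phantom(PhantomSpec(shape=(96, 64, 4),
                                          lv_radius_ed=10.0, lv_radius_es=7.0,
                                          wall_thickness=4.0,
                                          rv_volume_target_ml=15.0))
    study = res["study"]
    study.save_npy(tmp_path / "ph")
    back = CardiacStudy.load_npy(tmp_path / "ph")
    np.testing.assert_array_equal(back.ed_mask, study.ed_mask)
    assert back.label_map == study.label_map
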