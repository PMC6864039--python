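"""Geometry, normalization and NIfTI round-trip of the volume layer."""

import numpy as np
import pytest

from mpmap import volumes
from mpmap.volumes import (
    CONTRAST_NAMES,
    ContrastVolume,
    PatientVolumeSet,
    SphereROI,
    normalize_to_wm,
    radius_from_volume,
    read_patient,
    sphere_mask,
    write_patient,
)


def make_pvs(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), wm_center=(7.0, 7.0, 7.0)):
    contrasts = {
        n: ContrastVolume(n, 100.0 * (i + 1) + rng.standard_normal(shape), spacing)
        for i, n in enumerate(CONTRAST_NAMES)
    }
    mask = np.ones(shape, dtype=bool)
    return PatientVolumeSet(1, contrasts, mask, SphereROI(wm_center, 3.0))


class TestRadiusFromVolume:
    @pytest.mark.parametrize(
        "volume,expected",
        [
            (4.0 * np.pi / 3.0, 1.0),  # unit sphere
            (8.0 * 4.0 * np.pi / 3.0, 2.0),  # cube-root scaling
            (4119.5, 9.9446),  # typical biopsy core volume
        ],
    )
    def test_values(self, volume, expected):
        assert radius_from_volume(volume) == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_volume(self):
        v = np.linspace(0.5, 5000, 200)
        r = np.array([radius_from_volume(x) for x in v])
        assert np.all(np.diff(r) > 0)

    @pytest.mark.parametrize("bad", [0.0, -3.0, np.nan])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            radius_from_volume(bad)


class TestSphereMask:
    def test_small_radius_hits_single_voxel(self):
        m = sphere_mask(SphereROI((8.0, 8.0, 8.0), 0.5), (16, 16, 16), (1, 1, 1))
        assert m.sum() == 1
        assert m[8, 8, 8]

    def test_agrees_with_bruteforce_distance_scan(self, rng):
        shape, spacing, origin = (14, 11, 9), (0.7, 1.1, 1.9), (-2.0, 0.5, 3.0)
        for _ in range(20):
            center = tuple(
                origin[a] + spacing[a] * rng.uniform(0, shape[a] - 1) for a in range(3)
            )
            r = rng.uniform(0.3, 6.0)
            m = sphere_mask(SphereROI(center, r), shape, spacing, origin)
            brute = np.zeros(shape, dtype=bool)
            for i in range(shape[0]):
                for j in range(shape[1]):
                    for k in range(shape[2]):
                        p = np.array(origin) + np.array(spacing) * np.array([i, j, k])
                        brute[i, j, k] = np.linalg.norm(p - np.array(center)) <= r
            assert np.array_equal(m, brute)

    def test_zero_radius_forbidden(self):
        with pytest.raises(ValueError):
            SphereROI((1.0, 1.0, 1.0), 0.0)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            sphere_mask(SphereROI((99.0, 0.0, 0.0), 1.0), (16, 16, 16), (1, 1, 1))

    def test_empty_mask_warns(self):
        # radius small, center between voxel centers
        with pytest.warns(UserWarning, match="no voxel centers"):
            sphere_mask(SphereROI((7.5, 7.5, 7.5), 0.2), (16, 16, 16), (1, 1, 1))

    def test_volume_converges_to_core_volume(self):
        # fine 0.25 mm grid: discretized sphere volume within 5% of analytic
        vol = 150.0
        r = radius_from_volume(vol)
        spacing = (0.25, 0.25, 0.25)
        shape = (64, 64, 64)
        center = (8.0, 8.0, 8.0)
        m = sphere_mask(SphereROI(center, r), shape, spacing)
        assert m.sum() * 0.25**3 == pytest.approx(vol, rel=0.05)


class TestNormalizeToWM:
    def test_uniform_volume_becomes_ones(self, rng):
        pvs = make_pvs(rng)
        for n in CONTRAST_NAMES:
            pvs.contrasts[n].data[:] = 200.0
        out = normalize_to_wm(pvs)
        for n in CONTRAST_NAMES:
            assert np.allclose(out.contrasts[n].data, 1.0)

    def test_wm_mean_is_one_for_all_contrasts(self, rng):
        out = normalize_to_wm(make_pvs(rng))
        wm = sphere_mask(out.wm_roi, out.shape, out.spacing, out.origin)
        for n in CONTRAST_NAMES:
            assert out.contrasts[n].data[wm].mean() == pytest.approx(1.0, abs=1e-12)

    def test_simple_ratio(self, rng):
        pvs = make_pvs(rng)
        pvs.contrasts["T1w"].data[:] = 200.0
        pvs.contrasts["T1w"].data[0, 0, 0] = 300.0  # outside the WM ROI
        out = normalize_to_wm(pvs)
        assert out.contrasts["T1w"].data[0, 0, 0] == pytest.approx(1.5)

    def test_idempotent_and_scale_invariant(self, rng):
        pvs = make_pvs(rng)
        once = normalize_to_wm(pvs)
        twice = normalize_to_wm(once)
        for n in CONTRAST_NAMES:
            assert np.allclose(once.contrasts[n].data, twice.contrasts[n].data)
        scaled = make_pvs(np.random.default_rng(20240917))
        for n in CONTRAST_NAMES:
            scaled.contrasts[n].data *= 7.3
        out_scaled = normalize_to_wm(scaled)
        for n in CONTRAST_NAMES:
            assert np.allclose(out_scaled.contrasts[n].data, once.contrasts[n].data)

    def test_nonpositive_wm_mean_names_contrast(self, rng):
        pvs = make_pvs(rng)
        pvs.contrasts["ADC"].data[:] = -5.0
        with pytest.raises(ValueError, match="ADC"):
            normalize_to_wm(pvs)


class TestPatientIO:
    def test_roundtrip_preserves_voxels(self, rng, tmp_path):
        pvs = make_pvs(rng)
        paths = write_patient(pvs, tmp_path)
        back = read_patient(paths, 1, pvs.wm_roi)
        for n in CONTRAST_NAMES:
            # float32 storage precision
            assert np.allclose(back.contrasts[n].data, pvs.contrasts[n].data, rtol=1e-6)
        assert np.array_equal(back.brain_mask, pvs.brain_mask)
        assert back.spacing == pvs.spacing

    def test_missing_contrast_named_in_error(self, rng, tmp_path):
        pvs = make_pvs(rng)
        paths = write_patient(pvs, tmp_path)
        del paths["T2-FLAIR"]
        with pytest.raises(ValueError, match="missing contrast T2-FLAIR"):
            read_patient(paths, 1, pvs.wm_roi)

    def test_grid_mismatch_reports_both_shapes(self, rng):
        contrasts = {
            n: ContrastVolume(n, np.ones((8, 8, 8)), (1, 1, 1)) for n in CONTRAST_NAMES
        }
        contrasts["ADC"] = ContrastVolume("ADC", np.ones((8, 8, 9)), (1, 1, 1))
        with pytest.raises(volumes.GridMismatchError, match=r"\(8, 8, 9\).*\(8, 8, 8\)"):
            PatientVolumeSet(1, contrasts, np.ones((8, 8, 8), bool), SphereROI((4, 4, 4), 2.0))

    def test_triaged_outcome_must_be_negative(self):
        sphere = SphereROI((1.0, 1.0, 1.0), radius_from_volume(10.0))
        with pytest.raises(ValueError, match="triaged"):
            volumes.BiopsySample(
                1,
                sphere,
                10.0,
                {"idh1": 1, "mgmt": 0, "cnec": 0, "mvp": 0},
                {"idh1": "triaged", "mgmt": "tested", "cnec": "tested", "mvp": "tested"},
            )
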