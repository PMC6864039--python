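"""Phantom generator: determinism, noiseless limit, prevalence, disk round trip."""

import numpy as np
import pytest

from mpmap import phantom
from mpmap.volumes import CONTRAST_NAMES, OUTCOMES, sphere_mask
from mpmap.features import compute_background_distribution, build_feature_matrix
from mpmap.pipeline import prepare_cohort


class TestSpecValidation:
    def test_default_spec_is_valid(self):
        spec = phantom.default_spec()
        assert spec.n_patients == 29
        assert spec.shape == (64, 64, 64)

    def test_null_spec_zeroes_signatures(self):
        spec = phantom.null_spec()
        assert all(all(v == 0 for v in sig) for sig in spec.signatures.values())

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"noise_sd": 0.0},
            {"prevalence": {"idh1": 1.5, "mgmt": 0.1, "cnec": 0.1, "mvp": 0.1}},
            {"tumor_radius_range": (9.0, 30.0)},
            {"brain_radius": 40.0},  # exceeds the 64 mm grid
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            phantom.PhantomSpec(**kwargs)


class TestGeneration:
    def test_same_seed_identical_cohort(self, tiny_spec):
        a = phantom.generate_cohort(tiny_spec)
        b = phantom.generate_cohort(tiny_spec)
        for pa, pb in zip(a.patients, b.patients):
            assert pa.truth == pb.truth
            assert pa.recorded == pb.recorded
            for n in CONTRAST_NAMES:
                assert np.array_equal(pa.pvs.contrasts[n].data, pb.pvs.contrasts[n].data)
            assert len(pa.samples) == len(pb.samples)
            for sa, sb in zip(pa.samples, pb.samples):
                assert sa.sphere.center == sb.sphere.center

    def test_different_seed_differs(self, tiny_spec):
        from dataclasses import replace

        b = phantom.generate_cohort(replace(tiny_spec, seed=tiny_spec.seed + 1))
        a = phantom.generate_cohort(tiny_spec)
        assert not np.array_equal(
            a.patients[0].pvs.contrasts["T1w"].data, b.patients[0].pvs.contrasts["T1w"].data
        )

    def test_noiseless_limit_expressing_voxels_equal_background_plus_signature(self):
        # full within-core expression, no generic lesion offset, vanishing
        # noise: expressing voxels must equal background + signature exactly
        spec = phantom.PhantomSpec(
            n_patients=3,
            shape=(32, 32, 32),
            spacing=(1.5, 1.5, 1.5),
            brain_radius=18.0,
            tumor_radius_range=(5.0, 7.0),
            tumor_center_max_offset=5.0,
            core_volume_mm3=(300.0, 0.001),
            noise_sd=1e-9,
            tumor_variability=0.0,
            tumor_base=(0.0,) * 5,
            base_heterogeneity=0.0,
            expression_volume_mm3={o: 2000.0 for o in OUTCOMES},  # blob fills its core
            prevalence={o: 1.0 if o == "cnec" else 0.0 for o in OUTCOMES},
            wm_roi_radius=2.0,
            seed=2,
        )
        cohort = phantom.generate_cohort(spec)
        prep = prepare_cohort(cohort.as_pipeline_input())
        for (pvs, _), pat in zip(prep.patients, cohort.patients):
            sig = dict(zip(CONTRAST_NAMES, spec.signatures["cnec"]))
            blob = pat.truth_fields["cnec"]
            assert blob.any()
            for n in CONTRAST_NAMES:
                inside = pvs.contrasts[n].data[blob]
                outside = pvs.contrasts[n].data[pat.pvs.brain_mask & ~blob]
                assert np.allclose(inside, 1.0 + sig[n], atol=1e-5)
                assert np.allclose(outside, 1.0, atol=1e-5)

    def test_prevalence_within_binomial_error(self):
        spec = phantom.PhantomSpec(
            n_patients=200,
            shape=(24, 24, 24),
            spacing=(2.0, 2.0, 2.0),
            brain_radius=18.0,
            tumor_radius_range=(5.0, 7.0),
            tumor_center_max_offset=5.0,
            core_volume_mm3=(300.0, 50.0),
            wm_roi_radius=2.0,
            seed=5,
        )
        cohort = phantom.generate_cohort(spec)
        for o in OUTCOMES:
            p = spec.prevalence[o]
            observed = np.mean([pat.truth[o] for pat in cohort.patients])
            se = np.sqrt(p * (1 - p) / 200)
            assert abs(observed - p) <= 3 * se + 1e-9

    def test_triage_bookkeeping_matches_generator_truth(self, tiny_cohort):
        # recorded labels follow informative triage: triaged => truly negative
        # with every specimen negative; a truly positive outcome has at least
        # one positive specimen (the one sampling expressing tissue)
        for p in tiny_cohort.patients:
            for o in OUTCOMES:
                if p.recorded[o] == "triaged":
                    assert not p.truth[o]
                    assert all(s.provenance[o] == "triaged" for s in p.samples)
                    assert all(s.outcomes[o] == 0 for s in p.samples)
                if p.recorded[o] == "pos":
                    assert p.truth[o]
                    assert any(s.outcomes[o] == 1 for s in p.samples)
                if not p.truth[o]:
                    assert all(s.outcomes[o] == 0 for s in p.samples)

    def test_backgrounds_strictly_between_zero_and_one(self, tiny_prepared):
        for o in OUTCOMES:
            bg = compute_background_distribution(tiny_prepared.feature_matrix, o)
            assert 0.0 < bg.p_pos < 1.0

    def test_cores_lie_inside_tumor(self, tiny_cohort):
        for p in tiny_cohort.patients:
            for s in p.samples:
                m = sphere_mask(s.sphere, p.pvs.shape, p.pvs.spacing, p.pvs.origin)
                assert (m & p.tumor_mask).sum() == m.sum()  # spheres fully inside

    def test_expression_fields_inside_tumor(self, tiny_cohort):
        for p in tiny_cohort.patients:
            for o in OUTCOMES:
                tf = p.truth_fields[o]
                if p.truth[o]:
                    assert tf.any()
                    assert not (tf & ~p.tumor_mask).any()
                else:
                    assert not tf.any()


class TestDiskRoundTrip:
    def test_write_then_read_through_public_io(self, tiny_cohort, tmp_path):
        out = phantom.write_cohort(tiny_cohort, tmp_path / "cohort")
        back = phantom.read_cohort(out)
        assert len(back) == len(tiny_cohort.patients)
        for (pvs, samples), orig in zip(back, tiny_cohort.patients):
            assert pvs.patient_id == orig.pvs.patient_id
            for n in CONTRAST_NAMES:
                assert np.allclose(
                    pvs.contrasts[n].data, orig.pvs.contrasts[n].data, rtol=1e-5, atol=1e-3
                )
            assert len(samples) == len(orig.samples)
            for sa, sb in zip(samples, orig.samples):
                assert sa.outcomes == sb.outcomes
                assert sa.sphere.radius == pytest.approx(sb.sphere.radius)
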