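"""RFT layer: Gaussianization, smoothness recovery, EC, cluster inference."""

import numpy as np
import pytest
from scipy import stats

from mpmap.rft import (
    ClusterTable,
    chi2_field_to_z,
    cluster_inference,
    cluster_p_value,
    ec_density_3d,
    estimate_smoothness,
    expected_ec,
    simulate_smooth_field,
)


def flood_fill_labels(mask, connectivity=26):
    """Independent flood-fill connected-component oracle."""
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
        and (connectivity == 26 or abs(a) + abs(b) + abs(c) == 1)
    ]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        stack = [seed]
        labels[seed] = current
        while stack:
            i, j, k = stack.pop()
            for a, b, c in offsets:
                x, y, z = i + a, j + b, k + c
                if (
                    0 <= x < mask.shape[0]
                    and 0 <= y < mask.shape[1]
                    and 0 <= z < mask.shape[2]
                    and mask[x, y, z]
                    and not labels[x, y, z]
                ):
                    labels[x, y, z] = current
                    stack.append((x, y, z))
    return labels, current


class TestChi2FieldToZ:
    def test_zero_statistic_clips_low(self):
        assert chi2_field_to_z(np.array([0.0]))[0] == pytest.approx(-8.2)

    def test_alpha_quantile_maps_to_normal_quantile(self):
        z = chi2_field_to_z(np.array([3.841459]), df=1)[0]
        assert z == pytest.approx(stats.norm.ppf(0.95), abs=1e-4)

    def test_monotone_and_clipped(self):
        grid = np.linspace(0, 200, 300)
        z = chi2_field_to_z(grid, df=1)
        assert np.all(np.diff(z) >= 0)
        assert z.min() >= -8.2 and z.max() <= 8.2


class TestSmoothness:
    def test_white_noise_fwhm_near_one_voxel(self, rng):
        f = rng.standard_normal((64, 64, 64))
        est = estimate_smoothness(f, np.ones(f.shape, bool))
        # white noise has ~1 voxel effective FWHM; forward differences give ~1.18
        assert np.all(np.abs(est.fwhm - 1.0) < 0.2)

    def test_recovers_known_fwhm_6mm(self):
        errs = []
        for seed in range(10):
            f = simulate_smooth_field((64, 64, 64), 6.0, np.random.default_rng(seed))
            est = estimate_smoothness(f, np.ones(f.shape, bool))
            errs.append(np.abs(est.fwhm - 6.0) / 6.0)
        assert np.max(errs) < 0.15

    def test_doubling_spacing_doubles_fwhm_mm(self, rng):
        f = simulate_smooth_field((48, 48, 48), 4.0, rng)
        mask = np.ones(f.shape, bool)
        est1 = estimate_smoothness(f, mask, (1.0, 1.0, 1.0))
        est2 = estimate_smoothness(f, mask, (2.0, 2.0, 2.0))
        assert np.allclose(est2.fwhm, 2.0 * est1.fwhm)

    def test_resel_definition(self, rng):
        f = simulate_smooth_field((32, 32, 32), 4.0, rng)
        mask = np.ones(f.shape, bool)
        est = estimate_smoothness(f, mask, (1.0, 1.0, 1.0))
        assert est.resels == pytest.approx(mask.sum() / np.prod(est.fwhm))

    def test_too_few_voxels_rejected(self, rng):
        f = rng.standard_normal((10, 10, 10))
        mask = np.zeros(f.shape, bool)
        mask[:3, :3, :3] = True
        with pytest.raises(ValueError):
            estimate_smoothness(f, mask)

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness(np.ones((16, 16, 16)), np.ones((16, 16, 16), bool))


class TestExpectedEC:
    def test_zero_at_unit_threshold(self):
        assert expected_ec(1.0, 500.0) == pytest.approx(0.0)

    def test_linear_in_resels(self):
        assert expected_ec(3.0, 200.0) == pytest.approx(2.0 * expected_ec(3.0, 100.0))

    def test_matches_max_exceedance_probability_high_threshold(self):
        """P(max z > t) on simulated stationary fields vs E[EC] (32^3, FWHM 8)."""
        shape, fwhm = (32, 32, 32), 8.0
        resels = np.prod(shape) / fwhm**3
        hits = {3.5: 0, 4.0: 0}
        reps = 200
        for seed in range(reps):
            f = simulate_smooth_field(shape, fwhm, np.random.default_rng(1000 + seed))
            mx = f.max()
            for t in hits:
                hits[t] += mx > t
        for t, n in hits.items():
            expected = expected_ec(t, resels)
            se = np.sqrt(max(expected, 1e-3) * (1 - min(expected, 0.99)) / reps)
            assert abs(n / reps - expected) < 3 * se + 0.02


class TestClusterInference:
    def smoothness(self, shape=(32, 32, 32), fwhm=6.0):
        f = simulate_smooth_field(shape, fwhm, np.random.default_rng(5))
        return estimate_smoothness(f, np.ones(shape, bool))

    def test_zero_field_empty_table(self):
        sm = self.smoothness()
        res = cluster_inference(np.zeros((32, 32, 32)), np.ones((32, 32, 32), bool), sm)
        assert len(res.table) == 0
        assert not res.surviving_mask.any()

    def test_two_blobs_counted_with_sizes(self):
        sm = self.smoothness()
        z = np.zeros((32, 32, 32))
        z[4:7, 4:7, 4:7] = 5.0  # 27 voxels
        z[20:24, 20:24, 20:24] = 5.0  # 64 voxels
        res = cluster_inference(z, np.ones(z.shape, bool), sm, z_threshold=2.3)
        assert len(res.table) == 2
        assert sorted(res.table["size_vox"]) == [27, 64]
        assert np.all(res.table["peak_z"] == 5.0)

    def test_labeling_matches_flood_fill_oracle(self, rng):
        sm = self.smoothness()
        for conn in (6, 26):
            for trial in range(5):
                z = rng.standard_normal((32, 32, 32)) * 2.0
                res = cluster_inference(z, np.ones(z.shape, bool), sm, 2.3, connectivity=conn)
                oracle, n = flood_fill_labels((z > 2.3), connectivity=conn)
                assert res.labels.max() == n
                # identical partitions up to label permutation
                for lbl in range(1, n + 1):
                    got = res.labels[oracle == lbl]
                    assert len(set(got.tolist())) == 1 and got[0] > 0

    def test_cluster_p_monotone_decreasing_in_size(self):
        sm = self.smoothness()
        sizes = [1, 5, 20, 80, 320, 1280]
        ps = [cluster_p_value(s, sm, 2.3) for s in sizes]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_null_fwer_calibrated(self):
        """500 null smooth 64^3 fields: FWER of surviving clusters in [0.02, 0.09].

        Runs at the package's default cluster-forming threshold, where the
        classical Gaussian-field cluster-size distribution is accurate.
        """
        shape, fwhm, alpha = (64, 64, 64), 6.0, 0.05
        mask = np.ones(shape, bool)
        false_positives = 0
        reps = 500
        for seed in range(reps):
            f = simulate_smooth_field(shape, fwhm, np.random.default_rng(30_000 + seed))
            est = estimate_smoothness(f, mask)
            res = cluster_inference(f, mask, est, alpha=alpha)
            if res.table["survives"].any():
                false_positives += 1
        assert 0.02 <= false_positives / reps <= 0.09
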