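import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis.extra import numpy as hnp
from scipy import stats

from priorseg import (
    BinaryMask,
    aggregate_report,
    directed_hausdorff,
    dsc,
    hausdorff,
    paired_compare,
)
from priorseg.volumes import DegenerateInputError

from conftest import random_mask


def brute_force_dsc(a, b):
    return 2 * np.logical_and(a.voxels, b.voxels).sum() / (a.voxels.sum() + b.voxels.sum())


def brute_force_directed_hd(a, b):
    pa = a.foreground_points_mm()
    pb = b.foreground_points_mm()
    return max(min(np.linalg.norm(p - q) for q in pb) for p in pa)


def mask_from_points(points, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, bool)
    for p in points:
        vox[p] = True
    return BinaryMask(vox, spacing)


class TestDsc:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = mask_from_points([(0, 0, 0)])
        b = mask_from_points([(5, 5, 5)])
        assert dsc(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        vox_a = np.zeros((20, 10, 1), bool)
        vox_b = np.zeros((20, 10, 1), bool)
        vox_a[:10] = True  # |A| = 100
        vox_b[5:15] = True  # |B| = 100, overlap 50
        a = BinaryMask(vox_a, (1, 1, 1))
        b = BinaryMask(vox_b, (1, 1, 1))
        assert dsc(a, b) == 0.5

    def test_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert dsc(a, b) == dsc(b, a)

    def test_both_empty_rejected(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(DegenerateInputError):
            dsc(e, e)


class TestHausdorff:
    def test_3_4_5_triangle(self):
        a = mask_from_points([(0, 0, 0)])
        b = mask_from_points([(3, 4, 0)])
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        assert hausdorff(m, m) == 0.0

    def test_subset_directed_zero(self):
        a = mask_from_points([(2, 2, 2)])
        b = mask_from_points([(2, 2, 2), (5, 5, 5)])
        assert directed_hausdorff(a, b) == 0.0
        assert directed_hausdorff(b, a) > 0.0

    def test_one_slice_shift_on_anisotropic_grid(self):
        vox = np.zeros((6, 6, 4), bool)
        vox[2:4, 2:4, 1] = True
        a = BinaryMask(vox, (1, 1, 5))
        shifted = np.roll(vox, 1, axis=2)
        b = BinaryMask(shifted, (1, 1, 5))
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_symmetry_on_random_masks(self, rng):
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            assert hausdorff(a, b) == hausdorff(b, a)

    def test_matches_brute_force_on_point_sets(self, rng):
        for _ in range(30):
            na, nb = rng.integers(1, 20, 2)
            pts_a = {tuple(rng.integers(0, 8, 3)) for _ in range(na)}
            pts_b = {tuple(rng.integers(0, 8, 3)) for _ in range(nb)}
            a = mask_from_points(pts_a, spacing=(1.0, 1.0, 5.0))
            b = mask_from_points(pts_b, spacing=(1.0, 1.0, 5.0))
            assert directed_hausdorff(a, b) == pytest.approx(
                brute_force_directed_hd(a, b), abs=1e-12
            )

    def test_triangle_inequality_spot_check(self, rng):
        for _ in range(10):
            a, b, c = (random_mask(rng, shape=(6, 6, 3)) for _ in range(3))
            assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9

    def test_empty_mask_rejected(self, rng):
        e = BinaryMask(np.zeros((4, 4, 4), bool), (1.0, 1.0, 5.0))
        with pytest.raises(DegenerateInputError):
            hausdorff(random_mask(rng, shape=(4, 4, 4)), e)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    a=hnp.arrays(bool, (6, 6, 3)),
    b=hnp.arrays(bool, (6, 6, 3)),
)
def test_metric_properties_on_arbitrary_masks(a, b):
    """DSC is symmetric and in [0,1]; HD is symmetric, nonnegative, and
    zero iff the masks coincide (for any non-empty pair)."""
    assume(a.any() and b.any())
    ma = BinaryMask(a, (1.0, 1.0, 5.0))
    mb = BinaryMask(b, (1.0, 1.0, 5.0))
    d = dsc(ma, mb)
    assert 0.0 <= d <= 1.0
    assert d == dsc(mb, ma)
    h = hausdorff(ma, mb)
    assert h == hausdorff(mb, ma)
    assert h >= 0.0
    assert (h == 0.0) == np.array_equal(a, b)


class TestPairedCompare:
    def test_normal_differences_use_paired_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.8, 0.05, 30)
        y = x - rng.normal(0.07, 0.02, 30)
        res = paired_compare(x, y)
        assert res.test_name == "paired-t"
        stat, p = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(float(stat), abs=1e-6)
        assert res.p_value == pytest.approx(float(p), abs=1e-6)
        assert res.significant

    def test_skewed_differences_prefer_wilcoxon(self):
        chosen = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.8, 0.01, 30)
            y = x - rng.exponential(0.08, 30)  # heavily skewed differences
            chosen.append(paired_compare(x, y).test_name)
        assert chosen.count("wilcoxon") >= 80

    def test_identical_samples_flagged_degenerate(self):
        x = [0.7, 0.8, 0.9, 0.6]
        res = paired_compare(x, list(x))
        assert res.test_name == "degenerate"
        assert not res.significant

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2])


class TestAggregateReport:
    def test_mean_and_sample_sd(self):
        rows = [
            {"case_id": "a", "dsc": 0.7},
            {"case_id": "b", "dsc": 0.8},
            {"case_id": "c", "dsc": 0.9},
        ]
        rep = aggregate_report(rows)
        mean, sd, n = rep.aggregate["dsc"]
        assert mean == pytest.approx(0.8)
        assert sd == pytest.approx(0.1)
        assert n == 3

    def test_single_case_sd_zero_with_flag(self):
        rep = aggregate_report([{"case_id": "a", "dsc": 0.7}])
        assert rep.aggregate["dsc"] == (0.7, 0.0, 1)
        assert rep.single_case

    def test_nan_values_excluded_from_aggregate(self):
        rows = [
            {"case_id": "a", "hd_mm": 10.0},
            {"case_id": "b", "hd_mm": float("nan")},
            {"case_id": "c", "hd_mm": 20.0},
        ]
        mean, sd, n = aggregate_report(rows).aggregate["hd_mm"]
        assert mean == pytest.approx(15.0)
        assert n == 2

    def test_csv_round_trip_matches(self, tmp_path):
        import pandas as pd

        rows = [{"case_id": f"c{i}", "dsc": v} for i, v in enumerate([0.71, 0.82, 0.93])]
        rep = aggregate_report(rows)
        path = rep.to_csv(tmp_path / "rows.csv")
        back = pd.read_csv(path)
        rep2 = aggregate_report(back.to_dict("records"))
        assert rep2.aggregate["dsc"][0] == pytest.approx(rep.aggregate["dsc"][0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])
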