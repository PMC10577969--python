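import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis.extra import numpy as hnp

from priorseg import (
    BinaryMask,
    MarginSpec,
    PathologyRecord,
    build_prior_rois,
    calibrate_margin,
    expand_margin,
    pathological_volume,
)
from priorseg.volumes import DegenerateInputError

from conftest import random_mask, sphere_mask


class TestExpandMargin:
    def test_zero_margin_is_identity(self, rng):
        mask = random_mask(rng)
        out = expand_margin(mask, MarginSpec(0.0))
        assert np.array_equal(out.voxels, mask.voxels)

    def test_single_voxel_matches_brute_force_enumeration(self):
        vox = np.zeros((11, 11, 5), bool)
        vox[5, 5, 2] = True
        mask = BinaryMask(vox, (1.0, 1.0, 5.0))
        out = expand_margin(mask, 5.0)
        # brute force: every voxel center within 5 mm of the seed center
        idx = np.indices(vox.shape, dtype=float)
        d2 = (idx[0] - 5) ** 2 + (idx[1] - 5) ** 2 + ((idx[2] - 2) * 5.0) ** 2
        expected = d2 <= 25.0
        assert np.array_equal(out.voxels, expected)
        # anisotropy: one adjacent slice axially, a 5-voxel radius disk in-plane
        assert out.voxels[:, :, 1].sum() == 1 and out.voxels[:, :, 3].sum() == 1
        assert out.voxels[0, 5, 2] == out.voxels[5, 0, 2] == True

    def test_sphere_expansion_matches_analytic_volume(self):
        sph = sphere_mask(10.0, spacing=(1.0, 1.0, 2.0), pad_mm=22.0)
        out = expand_margin(sph, 20.0)
        analytic = 4.0 / 3.0 * np.pi * 30.0 ** 3
        assert out.volume_mm3 == pytest.approx(analytic, rel=0.05)

    def test_monotone_nesting_on_random_blobs(self, rng):
        for _ in range(20):
            mask = random_mask(rng, shape=(12, 12, 4), p=0.05)
            m1, m2 = sorted(rng.uniform(0.0, 8.0, 2))
            a = expand_margin(mask, m1)
            b = expand_margin(mask, m2)
            assert np.all(b.voxels[a.voxels]), "smaller margin must nest in larger"
            assert np.all(a.voxels[mask.voxels]), "expansion is a superset"

    def test_composition_supersets_single_expansion(self):
        sph = sphere_mask(6.0, spacing=(1.0, 1.0, 1.0), pad_mm=12.0)
        ab = expand_margin(expand_margin(sph, 4.0), 5.0)
        direct = expand_margin(sph, 9.0)
        # composition equals the direct expansion up to one voxel of
        # discretization: mismatches sit in a thin shell at distance ~9 mm
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~sph.voxels, sampling=sph.spacing)
        mismatch = ab.voxels ^ direct.voxels
        diag = np.linalg.norm(sph.spacing)
        assert np.all(np.abs(dist[mismatch] - 9.0) <= diag)
        assert mismatch.sum() <= 0.1 * direct.n_foreground

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            expand_margin(BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)), 5.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(vox=hnp.arrays(bool, (8, 8, 3)))
def test_expansion_is_extensive_and_monotone_property(vox):
    """Any expansion contains its input, and larger margins contain smaller."""
    assume(vox.any())
    mask = BinaryMask(vox, (1.0, 1.0, 5.0))
    small = expand_margin(mask, 1.5)
    large = expand_margin(mask, 4.0)
    assert np.all(small.voxels[mask.voxels])
    assert np.all(large.voxels[small.voxels])


class TestPathologicalVolume:
    @pytest.mark.parametrize(
        "diameters, expected",
        [
            ((20.0, 20.0, 20.0), 4188.79),
            ((10.0, 20.0, 30.0), 3141.59),
        ],
    )
    def test_ellipsoid_closed_form(self, diameters, expected):
        assert pathological_volume(PathologyRecord(diameters)) == pytest.approx(
            expected, abs=0.01
        )

    def test_sphere_special_case(self):
        d = 17.0
        assert pathological_volume(PathologyRecord((d, d, d))) == pytest.approx(
            np.pi / 6 * d ** 3
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            PathologyRecord((10.0, -1.0, 5.0))


class TestCalibrateMargin:
    def test_exact_match_construction(self, rng):
        pt = sphere_mask(8.0, spacing=(1.0, 1.0, 2.0), pad_mm=25.0)
        target_vol = expand_margin(pt, 20.0).volume_mm3
        # choose diameters whose ellipsoid volume equals the 20 mm expansion
        d = (6.0 * target_vol / np.pi) ** (1.0 / 3.0)
        rec = PathologyRecord((d, d, d))
        assert calibrate_margin(pt, rec, [10.0, 20.0, 30.0]) == 20.0

    def test_tiny_pv_selects_smallest_candidate(self):
        pt = sphere_mask(8.0, spacing=(1.0, 1.0, 2.0), pad_mm=25.0)
        rec = PathologyRecord((1.0, 1.0, 1.0))
        assert calibrate_margin(pt, rec, [10.0, 20.0, 30.0]) == 10.0

    def test_returned_candidate_minimizes_volume_gap(self, rng):
        pt = sphere_mask(6.0, spacing=(1.5, 1.5, 3.0), pad_mm=28.0)
        rec = PathologyRecord((45.0, 50.0, 55.0))
        candidates = [5.0, 10.0, 15.0, 20.0, 25.0]
        best = calibrate_margin(pt, rec, candidates)
        pv = pathological_volume(rec)
        gaps = {
            m: abs(expand_margin(pt, m).volume_mm3 - pv) for m in candidates
        }
        assert gaps[best] == min(gaps.values())

    def test_empty_candidates_rejected(self):
        pt = sphere_mask(5.0, spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            calibrate_margin(pt, PathologyRecord((10, 10, 10)), [])


class TestBuildPriorRois:
    def test_zero_margins_collapse_to_pt(self, rng):
        pt = random_mask(rng, label="PT")
        ev, ev1 = build_prior_rois(pt, 0.0, 0.0)
        assert np.array_equal(ev.voxels, pt.voxels)
        assert np.array_equal(ev1.voxels, pt.voxels)
        assert ev.label == "EV" and ev1.label == "EV_1cm"

    def test_sphere_margins_analytic_volume(self):
        pt = sphere_mask(5.0, spacing=(1.0, 1.0, 2.0), pad_mm=32.0)
        _, ev1 = build_prior_rois(pt, 20.0, 10.0)
        analytic = 4.0 / 3.0 * np.pi * 35.0 ** 3
        assert ev1.volume_mm3 == pytest.approx(analytic, rel=0.05)

    def test_nesting_on_random_blobs(self, rng):
        for _ in range(20):
            pt = random_mask(rng, shape=(12, 12, 4), p=0.05, label="PT")
            ev, ev1 = build_prior_rois(pt, 4.0, 3.0)
            assert np.all(ev.voxels[pt.voxels])
            assert np.all(ev1.voxels[ev.voxels])
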