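"""Feature extraction: discretization, rosters, invariances, degeneracies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcc_radiomics.features import (
    FEATURE_CLASS_COUNTS,
    FEATURE_NAMES,
    combine_phases,
    discretize,
    extract_single_phase,
    first_order_features,
    glcm_features,
    shape_features,
    voxel_volume,
)
from rcc_radiomics.features.matrices import glszm_matrix


def _roi_from_values(values, bin_width=25.0):
    """Embed a 1D value list as a single row of a 3D volume, full mask."""
    v = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return discretize(v, np.ones_like(v, dtype=bool), bin_width=bin_width)


class TestDiscretize:
    def test_binning_formula_example(self):
        roi = _roi_from_values([0, 10, 30, 60], bin_width=25)
        assert roi.levels.ravel().tolist() == [1, 1, 2, 3]
        assert roi.ng == 3

    def test_constant_roi_single_level(self):
        roi = _roi_from_values([7.5] * 6)
        assert roi.ng == 1 and set(roi.levels.ravel()) == {1}

    def test_matches_per_voxel_loop(self, rng):
        vox = rng.normal(50, 40, (4, 5, 3))
        mask = rng.random((4, 5, 3)) < 0.7
        mask[0, 0, 0] = True
        roi = discretize(vox, mask, bin_width=17.0)
        vmin = vox[mask].min()
        for idx in np.argwhere(mask):
            expected = int(np.floor((vox[tuple(idx)] - vmin) / 17.0)) + 1
            assert roi.levels[tuple(idx)] == expected
        assert (roi.levels[~mask] == 0).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-1000, max_value=2000, allow_nan=False),
            min_size=1, max_size=27,
        ),
        width=st.floats(min_value=0.5, max_value=200),
        shift=st.floats(min_value=-500, max_value=500),
    )
    def test_level_invariants(self, values, width, shift):
        """Levels always span 1..Ng with the minimum at level 1, and are
        invariant to adding a constant to every voxel."""
        v = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        v.ravel()[: len(values)] = values
        mask.ravel()[: len(values)] = True
        roi = discretize(v, mask, bin_width=width)
        levels = roi.levels[mask]
        assert levels.min() == 1
        assert levels.max() == roi.ng
        shifted = discretize(v + shift, mask, bin_width=width)
        assert np.array_equal(shifted.levels, roi.levels)

    def test_invalid_inputs_rejected(self):
        vox = np.zeros((3, 3, 3))
        with pytest.raises(ValueError):
            discretize(vox, np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError):
            discretize(vox, np.ones((3, 3, 3), dtype=bool), bin_width=0)


class TestFirstOrder:
    def test_hand_sums(self):
        roi = _roi_from_values([1, 2, 3, 4], bin_width=1.0)
        f = first_order_features(roi)
        assert f["fo_mean"] == pytest.approx(2.5)
        assert f["fo_energy"] == pytest.approx(30.0)
        assert f["fo_range"] == pytest.approx(3.0)

    def test_uniform_four_bins_entropy(self):
        # four equally frequent gray levels -> entropy 2 bits, uniformity 1/4
        roi = _roi_from_values([0, 0, 25, 25, 50, 50, 75, 75], bin_width=25)
        f = first_order_features(roi)
        assert f["fo_entropy"] == pytest.approx(2.0)
        assert f["fo_uniformity"] == pytest.approx(0.25)


class TestShape:
    def test_cube_closed_form(self):
        """A 10^3 cube: voxel volume exact; mesh volume within 2% of the
        closed form; sphericity above the ideal 0.806 by the edge-chamfer
        bias of level-set meshing, shrinking as the cube grows."""
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True
        assert voxel_volume(mask) == pytest.approx(1000.0)
        f = shape_features(mask)
        ideal = np.pi ** (1 / 3) * (6 * 1000) ** (2 / 3) / 600  # ~0.806
        assert f["shape_mesh_volume"] == pytest.approx(1000.0, rel=0.02)
        assert ideal < f["shape_sphericity"] < ideal * 1.06
        big = np.zeros((34, 34, 34), dtype=bool)
        big[2:32, 2:32, 2:32] = True
        fb = shape_features(big)
        assert ideal < fb["shape_sphericity"] < f["shape_sphericity"]

    def test_sphere_rounder_than_cube_and_converges(self):
        def sphere(r, n):
            c = (n - 1) / 2
            zz, yy, xx = np.indices((n, n, n))
            return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2

        cube = np.zeros((14, 14, 14), dtype=bool)
        cube[2:12, 2:12, 2:12] = True
        s_cube = shape_features(cube)["shape_sphericity"]
        s_small = shape_features(sphere(4, 12))["shape_sphericity"]
        s_big = shape_features(sphere(9, 22))["shape_sphericity"]
        assert s_small > s_cube
        assert abs(1 - s_big) < abs(1 - s_small)
        f = shape_features(sphere(9, 22))
        assert f["shape_elongation"] == pytest.approx(1.0, abs=0.02)

    def test_single_voxel_defined(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        f = shape_features(mask)
        assert all(np.isfinite(v) for v in f.values())
        assert f["shape_major_axis_length"] == 0.0

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        assert voxel_volume(mask, (2.0, 1.0, 1.0)) == pytest.approx(128.0)


class TestTextureDegenerate:
    def test_constant_roi_glcm(self):
        roi = _roi_from_values([5.0] * 27)
        f = glcm_features(roi)
        assert f["glcm_joint_entropy"] == 0.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_correlation"] == 1.0
        assert f["glcm_maximum_probability"] == 1.0

    def test_constant_roi_single_zone(self):
        vox = np.full((3, 3, 3), 10.0)
        roi = discretize(vox, np.ones((3, 3, 3), dtype=bool))
        Z = glszm_matrix(roi.levels, roi.ng)
        assert Z.shape == (1, 27) and Z[0, -1] == 1 and Z.sum() == 1

    def test_single_pair_glcm(self):
        # two adjacent voxels with levels {1, 2}: normalized symmetric
        # GLCM is [[0, .5], [.5, 0]] in the one populated direction
        roi = _roi_from_values([0.0, 25.0])
        f = glcm_features(roi)
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_maximum_probability"] == pytest.approx(0.5)
        assert f["glcm_joint_entropy"] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def subject_vec(small_cohort):
    s = small_cohort[0]
    vol = s.volumes["CMP"]
    return extract_single_phase(vol.voxels, s.masks[1].voxels, vol.spacing)


class TestExtraction:
    def test_roster_counts(self, subject_vec):
        assert len(subject_vec) == 105
        prefixes = {"fo": 18, "shape": 13, "glcm": 23, "glrlm": 16,
                    "glszm": 16, "gldm": 14, "ngtdm": 5}
        for pre, n in prefixes.items():
            assert sum(name.startswith(pre + "_") for name in subject_vec.index) == n
        assert sum(FEATURE_CLASS_COUNTS.values()) == 105
        assert all(np.isfinite(subject_vec.to_numpy()))

    def test_extraction_deterministic(self, small_cohort):
        s = small_cohort[1]
        vol = s.volumes["NP"]
        a = extract_single_phase(vol.voxels, s.masks[1].voxels, vol.spacing)
        b = extract_single_phase(vol.voxels, s.masks[1].voxels, vol.spacing)
        pd.testing.assert_series_equal(a, b)

    def test_translation_invariance(self, rng):
        core = rng.normal(60, 30, (4, 4, 4))
        cmask = rng.random((4, 4, 4)) < 0.8
        cmask[2, 2, 2] = True
        vox1 = np.full((12, 12, 12), -10.0)
        vox2 = np.full((12, 12, 12), -10.0)
        m1 = np.zeros((12, 12, 12), dtype=bool)
        m2 = np.zeros((12, 12, 12), dtype=bool)
        vox1[2:6, 2:6, 2:6] = core
        m1[2:6, 2:6, 2:6] = cmask
        vox2[5:9, 6:10, 3:7] = core
        m2[5:9, 6:10, 3:7] = cmask
        a = extract_single_phase(vox1, m1)
        b = extract_single_phase(vox2, m2)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-10, atol=1e-10)

    def test_constant_hu_shift(self, rng):
        """+c HU shifts location features by c and leaves discretized
        texture untouched (ROI-min anchored binning)."""
        vox = rng.normal(40, 30, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.85
        mask[2, 2, 2] = True
        a = extract_single_phase(vox, mask)
        b = extract_single_phase(vox + 100.0, mask)
        for name in ("fo_mean", "fo_median", "fo_minimum", "fo_maximum",
                     "fo_p10", "fo_p90"):
            assert b[name] == pytest.approx(a[name] + 100.0)
        for name in a.index:
            if name.split("_")[0] in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert b[name] == pytest.approx(a[name], rel=1e-12)
        for name in a.index:
            if name.startswith("shape_"):
                assert b[name] == a[name]

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            extract_single_phase(np.zeros((4, 4, 4)), np.ones((5, 4, 4), dtype=bool))


class TestCombinePhases:
    def test_concatenation_and_order(self, small_cohort):
        s = small_cohort[0]
        vecs = {
            ph: extract_single_phase(s.volumes[ph].voxels, s.masks[1].voxels,
                                     s.volumes[ph].spacing)
            for ph in ("NCP", "CMP", "NP", "EP")
        }
        allp = combine_phases(vecs)
        assert len(allp) == 420
        assert allp.index.is_unique
        assert allp.index[0].startswith("NCP_")
        assert allp.index[-1].startswith("EP_")
        # input dict order must not matter
        reordered = combine_phases({ph: vecs[ph] for ph in ("EP", "NP", "NCP", "CMP")})
        pd.testing.assert_series_equal(allp, reordered)

    def test_missing_phase_rejected(self, small_cohort):
        s = small_cohort[0]
        v = extract_single_phase(s.volumes["CMP"].voxels, s.masks[1].voxels)
        with pytest.raises(ValueError):
            combine_phases({"CMP": v})
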