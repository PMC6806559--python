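import numpy as np
import pandas as pd
import pytest

from ictos.features import (
    FEATURES_PER_PATIENT,
    FEATURES_PER_ROI,
    default_catalogue,
    extract_patient_features,
    fit_standardizer,
    apply_standardizer,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    intensity_features,
    shape_features,
)
from ictos.images import MRVolume, ROIMask

from .conftest import make_gray


def test_catalogue_totals():
    cat = default_catalogue()
    assert len(cat.names) == FEATURES_PER_ROI == 273
    assert len(cat.patient_names) == FEATURES_PER_PATIENT == 819
    fam = pd.Series(cat.families)
    assert (fam == "intensity").sum() == 19
    assert (fam == "shape").sum() == 10
    assert (fam == "glcm").sum() == 24 * 8
    assert (fam == "glrlm").sum() == 13 * 4


class TestGLCM:
    def test_single_horizontal_pair(self):
        gray = make_gray([[1, 2]], n_bins=2)
        g = glcm_matrix(gray, distance=1, angle=0)
        np.testing.assert_allclose(g.matrix, [[0.0, 0.5], [0.5, 0.0]])

    def test_matrix_sums_to_one(self, random_gray_maps):
        for labels in random_gray_maps[:20]:
            g = glcm_matrix(make_gray(labels, 6), distance=1, angle=45)
            if not g.degenerate:
                assert g.matrix.sum() == pytest.approx(1.0)

    def test_three_by_three_map_matches_enumeration(self):
        labels = [[1, 1, 2], [1, 2, 2], [2, 2, 3]]
        g = glcm_matrix(make_gray(labels, 3), distance=1, angle=0)
        # horizontal neighbor pairs: (1,1) (1,2) | (1,2) (2,2) | (2,2) (2,3),
        # symmetrized over 12 directed pairs
        expected = np.array([[2, 2, 0], [2, 4, 1], [0, 1, 0]]) / 12.0
        np.testing.assert_allclose(g.matrix, expected)

    def test_joint_variance_hand_value(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(P)
        assert f["joint_average"] == pytest.approx(1.5)
        assert f["variance"] == pytest.approx(0.25)

    def test_one_level_roi_has_zero_variance(self):
        gray = make_gray([[1, 1, 1]], n_bins=2)
        f = glcm_features(glcm_matrix(gray, 1, 0))
        assert f["variance"] == 0.0

    def test_variance_nonnegative_energy_bounded(self, random_gray_maps):
        for labels in random_gray_maps[:30]:
            g = glcm_matrix(make_gray(labels, 6), 1, 90)
            f = glcm_features(g)
            assert f["variance"] >= 0.0
            assert 0.0 < f["joint_energy"] <= 1.0

    def test_no_valid_pair_flagged_degenerate(self):
        gray = make_gray([[1], [0], [1]], n_bins=2)  # no horizontal neighbor
        g = glcm_matrix(gray, distance=1, angle=0)
        assert g.degenerate


class TestGLRLM:
    def test_single_run(self):
        R = glrlm_matrix(make_gray([[3, 3, 3]], 3), angle=0).matrix
        assert R[2, 2] == 1 and R.sum() == 1

    def test_alternating_runs(self):
        R = glrlm_matrix(make_gray([[1, 2, 1]], 2), angle=0).matrix
        assert R[0, 0] == 2 and R[1, 0] == 1 and R.sum() == 3

    def test_run_lengths_cover_roi(self, random_gray_maps):
        for labels in random_gray_maps[:30]:
            for angle in (0, 45, 90, 135):
                g = glrlm_matrix(make_gray(labels, 6), angle=angle)
                ls = np.arange(1, g.matrix.shape[1] + 1)
                assert (g.matrix @ ls).sum() == (labels > 0).sum()

    def test_lrhgle_closed_forms(self):
        R1 = np.zeros((3, 3)); R1[2, 2] = 1.0  # one run: level 3, length 3
        assert glrlm_features(R1)["lrhgle"] == pytest.approx(81.0)
        R2 = np.zeros((2, 2)); R2[0, 0] = 5.0  # all runs length 1, level 1
        assert glrlm_features(R2)["lrhgle"] == pytest.approx(1.0)

    def test_zero_runs_rejected(self):
        with pytest.raises(ValueError, match="no runs"):
            glrlm_features(np.zeros((2, 2)))


class TestFirstOrder:
    @staticmethod
    def roi_of(values):
        arr = np.asarray(values, float).reshape(1, 1, -1)
        vol = MRVolume("T1", arr)
        mask = ROIMask(np.ones_like(arr, dtype=bool))
        return vol, mask

    def test_symmetric_sample_has_zero_skewness(self):
        f = intensity_features(*self.roi_of([1.0, 2.0, 3.0]))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_positive_skew_matches_moment_formula(self):
        f = intensity_features(*self.roi_of([0.0, 0.0, 0.0, 1.0]))
        assert f["skewness"] == pytest.approx(2.0 / np.sqrt(3.0))

    def test_mean_variance_match_direct_summation(self):
        sample = [2.0, 4.0, 4.0, 4.0, 5.0]
        f = intensity_features(*self.roi_of(sample))
        x = np.asarray(sample)
        assert f["mean"] == pytest.approx(x.mean())
        assert f["variance"] == pytest.approx(((x - x.mean()) ** 2).mean())
        assert f["energy"] == pytest.approx((x**2).sum())

    def test_constant_roi_skewness_zero_by_convention(self):
        f = intensity_features(*self.roi_of([2.0, 2.0, 2.0]))
        assert f["skewness"] == 0.0 and f["variance"] == 0.0


class TestShape:
    def test_square_area(self):
        m = np.zeros((1, 20, 20), bool)
        m[0, 5:15, 5:15] = True
        f = shape_features(ROIMask(m, in_plane_spacing=1.0))
        assert f["area_mm2"] == pytest.approx(100.0)

    def test_circle_more_circular_than_ellipse(self):
        rr, cc = np.mgrid[0:40, 0:40]
        circle = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
        ellipse = ((rr - 20) / 4.0) ** 2 + ((cc - 20) / 25.0) ** 2 <= 1
        f_c = shape_features(ROIMask(circle[None]))
        f_e = shape_features(ROIMask(ellipse[None]))
        assert f_c["circularity"] > f_e["circularity"]

    def test_area_scales_with_spacing_squared(self):
        m = np.zeros((1, 12, 12), bool)
        m[0, 2:8, 2:8] = True
        a1 = shape_features(ROIMask(m, in_plane_spacing=1.0))["area_mm2"]
        a2 = shape_features(ROIMask(m, in_plane_spacing=2.0))["area_mm2"]
        assert a2 == pytest.approx(4.0 * a1)


class TestPatientExtraction:
    def test_exactly_819_named_values(self, default_phantom):
        _, volumes, mask = default_phantom
        f = extract_patient_features(volumes, mask)
        assert len(f) == 819
        assert all(np.isfinite(list(f.values())))

    def test_duplicate_sequences_give_identical_blocks(self, default_phantom):
        _, volumes, mask = default_phantom
        dup = {lab: volumes["T1C"] for lab in ("T1", "T2", "T1C")}
        f = extract_patient_features(dup, mask)
        t1 = {k.removeprefix("T1_"): v for k, v in f.items() if k.startswith("T1_")}
        t2 = {k.removeprefix("T2_"): v for k, v in f.items() if k.startswith("T2_")}
        assert t1 == t2

    def test_missing_sequence_rejected(self, default_phantom):
        _, volumes, mask = default_phantom
        partial = {k: v for k, v in volumes.items() if k != "T2"}
        with pytest.raises(ValueError, match="missing sequence"):
            extract_patient_features(partial, mask)


class TestDirectionality:
    def test_quarter_rotation_swaps_0_and_90_degree_features(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(1, 5, size=(9, 9)).astype(np.int32)
        rotated = np.rot90(labels)
        for d in (1, 2):
            a0 = glcm_features(glcm_matrix(make_gray(labels, 4), d, 0))
            a90r = glcm_features(glcm_matrix(make_gray(rotated, 4), d, 90))
            for k in a0:
                assert a0[k] == pytest.approx(a90r[k]), k
        r0 = glrlm_features(glrlm_matrix(make_gray(labels, 4), 0))
        r90 = glrlm_features(glrlm_matrix(make_gray(rotated, 4), 90))
        for k in r0:
            assert r0[k] == pytest.approx(r90[k]), k


class TestStandardizer:
    def test_training_table_centered_after_apply(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        params = fit_standardizer(df)
        out = apply_standardizer(params, df)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=0), 1.0, atol=1e-12)

    def test_single_row_validation_uses_training_params(self):
        train = pd.DataFrame({"a": [1.0, 3.0]})
        params = fit_standardizer(train)
        assert params.means["a"] == 2.0 and params.sds["a"] == 1.0  # population SD
        out = apply_standardizer(params, pd.DataFrame({"a": [2.0]}))
        assert out["a"].iloc[0] == pytest.approx(0.0)
        np.testing.assert_allclose(
            apply_standardizer(params, train)["a"], [-1.0, 1.0]
        )

    def test_zero_sd_feature_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            params = fit_standardizer(df)
        assert params.dropped == ["b"]
        assert "b" not in apply_standardizer(params, df).columns


def test_features_invariant_to_affine_intensity_rescale(default_phantom):
    """With z-score preprocessing enabled, a*x + b leaves all non-shape
    features unchanged."""
    _, volumes, mask = default_phantom
    f1 = extract_patient_features(volumes, mask)
    scaled = {
        lab: v.with_voxels(np.where(v.voxels != 0, 2.5 * v.voxels + 7.0, 0.0))
        for lab, v in volumes.items()
    }
    f2 = extract_patient_features(scaled, mask)
    for k, v in f1.items():
        if "shape" in k or "energy" in k:
            continue  # shape ignores intensity; energy scales with ROI size only
        assert f2[k] == pytest.approx(v, rel=1e-8, abs=1e-10), k
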