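"""ROI distribution metrics, pooled voxel vectors, KDE summaries."""

import numpy as np
import pytest

from deltat1.exceptions import DegenerateInputError, EmptyRoiError
from deltat1.roi import kde_summary, pooled_voxel_values, roi_metrics


def _as_cube(values):
    values = np.asarray(values, float)
    n = values.size
    side = int(np.ceil(n ** (1 / 3)))
    cube = np.full(side**3, np.nan)
    cube[:n] = values
    mask = np.isfinite(cube)
    return cube.reshape(side, side, side), mask.reshape(side, side, side)


def test_hand_computed_metrics():
    data, mask = _as_cube([1, 2, 3, 4, 5])
    m = roi_metrics(data, mask)
    assert m.n_voxels == 5
    assert m.mean == pytest.approx(3.0)
    assert m.median == pytest.approx(3.0)
    assert m.variance == pytest.approx(2.5)  # n-1 denominator
    assert m.iqr == pytest.approx(2.0)  # linear-interpolation quartiles


def test_normal_sample_has_pearson_kurtosis_three(rng):
    data, mask = _as_cube(rng.standard_normal(10**5))
    m = roi_metrics(data, mask)
    assert m.kurtosis == pytest.approx(3.0, abs=0.1)
    assert roi_metrics(data, mask, excess_kurtosis=True).kurtosis == pytest.approx(
        m.kurtosis - 3.0
    )


def test_constant_roi_degenerates_gracefully():
    data, mask = _as_cube([2.0] * 10)
    m = roi_metrics(data, mask)
    assert m.variance == 0.0
    assert m.iqr == 0.0
    assert np.isnan(m.kurtosis)


def test_permutation_invariance(rng):
    values = rng.random(200)
    a = roi_metrics(*_as_cube(values))
    b = roi_metrics(*_as_cube(rng.permutation(values)))
    for attr in ("mean", "median", "variance", "iqr", "kurtosis"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr))


def test_empty_roi_rejected():
    data, _ = _as_cube([1.0])
    with pytest.raises(EmptyRoiError):
        roi_metrics(data, np.zeros(data.shape, bool))


def test_missing_values_excluded_not_imputed():
    data, mask = _as_cube([1, 2, np.nan, 4])
    m = roi_metrics(data, np.ones(data.shape, bool))
    assert m.n_voxels == 3
    assert m.mean == pytest.approx(7 / 3)


class TestPooledVoxels:
    def test_concatenation_conserves_counts(self, rng):
        subjects = []
        for n in (10, 15):
            pre = rng.random((4, 4, 4))
            delta = rng.random((4, 4, 4))
            mask = np.zeros((4, 4, 4), bool)
            mask.flat[:n] = True
            subjects.append((pre, delta, mask))
        pre_all, delta_all = pooled_voxel_values(subjects, "nel")
        assert pre_all.size == delta_all.size == 25

    def test_single_subject_identity(self, rng):
        pre = rng.random((4, 4, 4))
        delta = rng.random((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        pre_all, delta_all = pooled_voxel_values([(pre, delta, mask)], "nel")
        np.testing.assert_array_equal(pre_all, pre.ravel())
        np.testing.assert_array_equal(delta_all, delta.ravel())

    def test_independent_generation_gives_null_spearman(self, rng):
        from deltat1.stats import correlate

        pre = rng.random((22, 22, 22))
        delta = rng.random((22, 22, 22))  # independent of pre by construction
        mask = np.ones(pre.shape, bool)
        pre_all, delta_all = pooled_voxel_values([(pre, delta, mask)], "nel")
        assert pre_all.size >= 10**4
        res = correlate(pre_all, delta_all, method="spearman")
        assert abs(res.estimate) < 0.05

    def test_no_subjects_rejected(self):
        with pytest.raises(EmptyRoiError):
            pooled_voxel_values([], "nel")


class TestKde:
    def test_standard_normal_density_at_zero(self, rng):
        grid, density = kde_summary(rng.standard_normal(10**4))
        at_zero = density[np.argmin(np.abs(grid))]
        assert at_zero == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.1)

    def test_density_integrates_to_one(self, rng):
        grid, density = kde_summary(rng.exponential(size=2000))
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-3)

    def test_two_point_sample_is_symmetric(self):
        grid, density = kde_summary(np.array([-1.0, 1.0]))
        np.testing.assert_allclose(density, density[::-1], atol=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            kde_summary(np.array([1.0, 1.0, 1.0]))
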