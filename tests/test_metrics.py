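"""Segmentation metrics: count arithmetic, surface extraction, and
distance-transform surface distances vs an all-pairs brute force."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from risunet.metrics import (MetricsReport, UndefinedMetricError, assd, dpc,
                             evaluate_case, extract_surface, ravd, rmsd,
                             summarize, voe)


def brute_surface(mask):
    """Foreground voxels with a background 6-neighbor, by explicit scan."""
    mask = mask.astype(bool)
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            inside = (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                      and 0 <= nk < mask.shape[2])
            if not inside or not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def brute_surface_distances(a, b, spacing):
    """All-pairs nearest surface distances in mm."""
    sa = np.argwhere(brute_surface(a)) * np.asarray(spacing)
    sb = np.argwhere(brute_surface(b)) * np.asarray(spacing)
    d = cdist(sa, sb)
    return d.min(axis=1), d.min(axis=0)


def random_blob(rng, shape=(12, 12, 12)):
    """A nonempty random connected-ish mask (thresholded smoothed noise)."""
    from scipy import ndimage
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    mask = noise > np.quantile(noise, 0.8)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask.astype(np.uint8)


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = random_blob(rng)
        assert dpc(m, m) == 1.0
        assert voe(m, m) == 0.0
        assert ravd(m, m) == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=int)
        b = np.zeros((4, 4, 4), dtype=int)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dpc(a, b) == 0.0
        assert voe(a, b) == 1.0

    def test_counted_overlap(self):
        a = np.zeros((4, 4, 1), dtype=int)
        b = np.zeros((4, 4, 1), dtype=int)
        a[0, :4, 0] = 1           # |A| = 4
        b[0, 2:4, 0] = 1          # overlap 2
        b[1, 2:4, 0] = 1          # |B| = 4
        assert dpc(a, b) == pytest.approx(0.5)

    def test_ravd_conventions(self):
        a = np.zeros((4, 4, 2), dtype=int)
        b = np.zeros((4, 4, 2), dtype=int)
        a[0, :2, 0] = 1
        b[0, :4, 0] = 1           # |B| = 2|A|
        assert ravd(a, b) == pytest.approx(1.0)
        assert ravd(b, a) == pytest.approx(0.5)   # absolute value, directional
        with pytest.raises(UndefinedMetricError):
            ravd(np.zeros((2, 2, 2), dtype=int), b[:2, :2, :])

    def test_empty_mask_conventions(self):
        empty = np.zeros((3, 3, 3), dtype=int)
        assert dpc(empty, empty) == 1.0
        assert voe(empty, empty) == 0.0

    def test_voe_dpc_identity(self, rng):
        for _ in range(20):
            a, b = random_blob(rng), random_blob(rng)
            d = dpc(a, b)
            np.testing.assert_allclose(voe(a, b), 1 - d / (2 - d), atol=1e-12)

    def test_count_arithmetic_oracle(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        na, nb = a.sum(), b.sum()
        inter = (a & b).sum()
        union = (a | b).sum()
        assert dpc(a, b) == pytest.approx(2 * inter / (na + nb), abs=0)
        assert voe(a, b) == pytest.approx(1 - inter / union, abs=0)
        assert ravd(a, b) == pytest.approx(abs(int(nb) - int(na)) / na, abs=0)


class TestSurfaceExtraction:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=int)
        m[2, 2, 2] = 1
        surf = extract_surface(m, spacing=(2.0, 3.0, 4.0))
        np.testing.assert_array_equal(surf.voxels, [[2, 2, 2]])
        np.testing.assert_allclose(surf.coords_mm, [[4.0, 6.0, 8.0]])

    def test_solid_cube_surface(self):
        m = np.zeros((5, 5, 5), dtype=int)
        m[1:4, 1:4, 1:4] = 1
        surf = extract_surface(m)
        assert len(surf) == 26           # all but the center voxel

    def test_volume_boundary_counts_as_background(self):
        m = np.ones((3, 3, 3), dtype=int)
        assert len(extract_surface(m)) == 26   # everything but the center

    def test_cavity_walls_are_surface(self):
        m = np.ones((7, 7, 7), dtype=int)
        m[3, 3, 3] = 0                   # hollow center
        surf_mask = np.zeros_like(m)
        surf_mask[tuple(extract_surface(m).voxels.T)] = 1
        np.testing.assert_array_equal(surf_mask, brute_surface(m).astype(int))

    def test_matches_brute_force(self, rng):
        m = random_blob(rng, (10, 10, 10))
        surf = extract_surface(m)
        np.testing.assert_array_equal(surf.voxels, np.argwhere(brute_surface(m)))


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = random_blob(rng)
        assert assd(m, m) == 0.0
        assert rmsd(m, m) == 0.0

    def test_two_voxels_k_mm_apart(self):
        a = np.zeros((9, 5, 5), dtype=int)
        b = np.zeros((9, 5, 5), dtype=int)
        a[1, 2, 2] = 1
        b[7, 2, 2] = 1                   # 6 voxels * 1.5 mm = 9 mm apart
        spacing = (1.5, 1.0, 1.0)
        assert assd(a, b, spacing) == pytest.approx(9.0)
        assert rmsd(a, b, spacing) == pytest.approx(9.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(30):
            a, b = random_blob(rng), random_blob(rng)
            spacing = tuple(rng.uniform(0.5, 3.0, size=3))
            da, db = brute_surface_distances(a, b, spacing)
            expected_assd = (da.sum() + db.sum()) / (da.size + db.size)
            expected_rmsd = np.sqrt((np.square(da).sum() + np.square(db).sum())
                                    / (da.size + db.size))
            np.testing.assert_allclose(assd(a, b, spacing), expected_assd, atol=1e-9)
            np.testing.assert_allclose(rmsd(a, b, spacing), expected_rmsd, atol=1e-9)
            assert rmsd(a, b, spacing) >= assd(a, b, spacing) - 1e-12

    def test_spacing_covariance(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        base = (1.0, 1.2, 2.0)
        scaled = tuple(3.0 * s for s in base)
        np.testing.assert_allclose(assd(a, b, scaled), 3.0 * assd(a, b, base),
                                   rtol=1e-12)
        np.testing.assert_allclose(rmsd(a, b, scaled), 3.0 * rmsd(a, b, base),
                                   rtol=1e-12)
        assert dpc(a, b) == dpc(a, b)    # overlap metrics ignore spacing

    def test_empty_mask_undefined(self, rng):
        m = random_blob(rng)
        empty = np.zeros_like(m)
        with pytest.raises(UndefinedMetricError):
            assd(m, empty)
        with pytest.raises(UndefinedMetricError):
            rmsd(empty, m)


class TestEvaluateCase:
    def test_perfect_prediction(self, rng):
        m = random_blob(rng)
        report = evaluate_case(m, m, spacing=(1, 1, 2))
        assert (report.dpc, report.voe, report.ravd, report.assd, report.rmsd) == \
            (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_symmetric_metrics_swap_invariant(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        r1 = evaluate_case(a, b, spacing=(1, 1.5, 2))
        r2 = evaluate_case(b, a, spacing=(1, 1.5, 2))
        assert (r1.dpc, r1.voe, r1.assd, r1.rmsd) == (r2.dpc, r2.voe, r2.assd, r2.rmsd)

    def test_empty_prediction_reports_missing_surfaces(self, rng):
        m = random_blob(rng)
        report = evaluate_case(m, np.zeros_like(m))
        assert report.dpc == 0.0
        assert report.assd is None and report.rmsd is None
        assert report.ravd == 1.0

    def test_hand_counted_fixture(self):
        gt = np.zeros((6, 6, 2), dtype=int)
        pred = np.zeros((6, 6, 2), dtype=int)
        gt[2:4, 2:4, 0] = 1              # |A| = 4
        pred[2:4, 2:4, 0] = 1
        pred[2, 4, 0] = 1                # |B| = 5, overlap 4
        report = evaluate_case(gt, pred)
        assert report.dpc == pytest.approx(2 * 4 / 9)
        assert report.voe == pytest.approx(1 - 4 / 5)
        assert report.ravd == pytest.approx(1 / 4)

    def test_summarize_appends_mean_and_std(self, rng):
        reports = [evaluate_case(random_blob(rng), random_blob(rng))
                   for _ in range(3)]
        frame = summarize(reports)
        assert list(frame["case_id"].iloc[-2:]) == ["mean", "std"]
        assert frame["dpc"].iloc[-2] == pytest.approx(
            np.mean([r.dpc for r in reports]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dpc(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))
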