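"""Enrichment scores, Gaussian boundary fitting, curve comparison."""

import numpy as np
import pytest

from vusmamba.boundary import (BoundaryCurve, cells_to_plane, classify_by_sign,
                               compare_curves, enrichment_scores,
                               estimate_boundary, fit_boundary,
                               normal_deviation, slab_cells)
from vusmamba.io import CellRecord


def _cell(y_um, x_um, vglut1, z_um=0.0, cid=0):
    return CellRecord(cell_id=cid, centroid_vox=(z_um / 2, y_um / 2, x_um / 2),
                      centroid_um=(z_um, y_um, x_um), volume_um3=200.0,
                      genes={"vglut1": vglut1, "vgat": not vglut1})


class TestEnrichment:
    def test_isolated_cells_saturate(self):
        cells = [_cell(0, 0, True), _cell(0, 500, False)]
        f = enrichment_scores(cells, r_um=50)
        np.testing.assert_array_equal(f.scores, [1.0, -1.0])

    def test_mixed_pair_scores_zero(self):
        cells = [_cell(0, 0, True), _cell(0, 10, False)]
        f = enrichment_scores(cells, r_um=50)
        np.testing.assert_array_equal(f.scores, [0.0, 0.0])

    def test_two_to_one_neighborhood(self):
        cells = [_cell(0, 0, True), _cell(0, 10, True), _cell(0, 20, False)]
        f = enrichment_scores(cells, r_um=50)
        np.testing.assert_allclose(f.scores, [1 / 3, 1 / 3, 1 / 3])

    def test_antisymmetric_under_label_swap(self, rng):
        ys, xs = rng.uniform(0, 200, 30), rng.uniform(0, 200, 30)
        flags = rng.random(30) > 0.5
        a = enrichment_scores([_cell(y, x, f) for y, x, f in zip(ys, xs, flags)])
        b = enrichment_scores([_cell(y, x, not f) for y, x, f in zip(ys, xs, flags)])
        np.testing.assert_allclose(a.scores, -b.scores, atol=1e-12)

    def test_scores_bounded(self, rng):
        cells = [_cell(y, x, bool(f)) for y, x, f in zip(
            rng.uniform(0, 100, 50), rng.uniform(0, 100, 50),
            rng.integers(0, 2, 50))]
        f = enrichment_scores(cells, r_um=30)
        assert np.all(f.scores >= -1) and np.all(f.scores <= 1)

    def test_double_positive_rejected(self):
        bad = CellRecord(1, (0, 0, 0), (0, 0, 0), 200.0,
                         {"vglut1": True, "vgat": True})
        with pytest.raises(ValueError, match="xor"):
            cells_to_plane([bad])

    def test_tie_goes_to_group_plus(self):
        cells = [_cell(0, 0, True), _cell(0, 10, False)]
        f = enrichment_scores(cells, r_um=50)  # both scores exactly 0
        plus, minus = classify_by_sign(f)
        assert len(plus) == 2 and len(minus) == 0


class TestFitBoundary:
    def test_symmetric_gaussians_give_midline(self, rng):
        n = 400
        gp = np.column_stack([rng.normal(0, 50, n), rng.normal(-40, 15, n)])
        gm = np.column_stack([gp[:, 0], -gp[:, 1]])  # mirrored across x=0
        curve = fit_boundary(gp, gm)
        np.testing.assert_allclose(curve.x_um, 0.0, atol=1e-9)

    def test_equal_covariance_matches_lda_line(self, rng):
        """With shared covariance and equal weights the locus is the LDA
        hyperplane: x such that (mu1-mu2)^T P [y,x] = (mu1-mu2)^T P (mu1+mu2)/2."""
        n = 300
        base = rng.normal(size=(n, 2)) @ np.array([[30.0, 5.0], [5.0, 12.0]])
        mu1, mu2 = np.array([10.0, -35.0]), np.array([-5.0, 42.0])
        gp, gm = base + mu1, base + mu2
        curve = fit_boundary(gp, gm, n_samples=50)
        # closed-form LDA with the pooled (here: identical) sample covariances
        from vusmamba.boundary import _gaussian_fit
        m1, S1 = _gaussian_fit(gp)
        m2, S2 = _gaussian_fit(gm)
        S = 0.5 * (S1 + S2)
        P = np.linalg.inv(S)
        w = P @ (m1 - m2)
        rhs = w @ ((m1 + m2) / 2)
        x_expected = (rhs - w[0] * curve.dv_um) / w[1]
        np.testing.assert_allclose(curve.x_um, x_expected, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_boundary(np.zeros((3, 2)), np.ones((10, 2)))

    def test_disjoint_dv_extents_rejected(self, rng):
        gp = np.column_stack([rng.uniform(0, 10, 10), rng.normal(size=10)])
        gm = np.column_stack([rng.uniform(20, 30, 10), rng.normal(size=10)])
        with pytest.raises(ValueError, match="DV extent"):
            fit_boundary(gp, gm)

    def test_estimate_boundary_on_clean_split(self, rng):
        cells = ([_cell(y, x, True) for y, x in
                  zip(rng.uniform(0, 200, 100), rng.uniform(0, 90, 100))]
                 + [_cell(y, x, False) for y, x in
                    zip(rng.uniform(0, 200, 100), rng.uniform(110, 200, 100))])
        curve = estimate_boundary(cells, r_um=30)
        assert np.all((curve.x_um > 70) & (curve.x_um < 130))

    def test_single_population_rejected(self, rng):
        cells = [_cell(y, 0, True) for y in rng.uniform(0, 100, 20)]
        with pytest.raises(ValueError, match="empty"):
            estimate_boundary(cells)


class TestCompareCurves:
    def test_identical_curves(self):
        c = BoundaryCurve(np.linspace(0, 100, 50),
                          np.sin(np.linspace(0, 3, 50)) * 20 + 50)
        out = compare_curves(c, c)
        assert out["mae"] == 0.0 and out["auc"] == 0.0
        assert out["pearson"] == pytest.approx(1.0)

    def test_constant_offset(self):
        dv = np.linspace(0, 100, 101)
        x = np.sin(dv / 15) * 10 + 40
        a = BoundaryCurve(dv, x)
        b = BoundaryCurve(dv, x + 7.0)
        out = compare_curves(a, b)
        assert out["mae"] == pytest.approx(7.0, abs=1e-9)
        assert out["auc"] == pytest.approx(7.0 * 100, rel=1e-9)
        assert out["pearson"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_polyline(self):
        a = BoundaryCurve([0.0, 10.0], [0.0, 0.0])
        b = BoundaryCurve([0.0, 10.0], [0.0, 10.0])
        out = compare_curves(a, b, n_samples=201)
        # |difference| rises linearly 0 -> 10: mean 5, area 50
        assert out["mae"] == pytest.approx(5.0, abs=1e-9)
        assert out["auc"] == pytest.approx(50.0, rel=1e-9)

    def test_auc_equals_mae_times_span_for_uniform_offset(self):
        dv = np.linspace(5, 45, 81)
        a = BoundaryCurve(dv, dv * 0.5)
        b = BoundaryCurve(dv, dv * 0.5 + 3.0)
        out = compare_curves(a, b)
        assert out["auc"] == pytest.approx(out["mae"] * 40.0, rel=1e-9)

    def test_constant_curves_caveat(self):
        dv = np.linspace(0, 10, 11)
        a = BoundaryCurve(dv, np.full(11, 3.0))
        out_same = compare_curves(a, BoundaryCurve(dv, np.full(11, 3.0)))
        assert out_same["constant_curve"] and out_same["pearson"] == 1.0
        out_diff = compare_curves(a, BoundaryCurve(dv, np.full(11, 4.0)))
        assert np.isnan(out_diff["pearson"])

    def test_non_monotone_dv_rejected(self):
        with pytest.raises(ValueError):
            BoundaryCurve([0.0, 2.0, 1.0], [0.0, 0.0, 0.0])

    def test_disjoint_extents_rejected(self):
        a = BoundaryCurve([0.0, 1.0], [0.0, 0.0])
        b = BoundaryCurve([5.0, 6.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            compare_curves(a, b)


class TestNormalDeviation:
    def test_identical_curves_zero(self):
        c = BoundaryCurve(np.linspace(0, 10, 21), np.linspace(0, 5, 21))
        dev, flagged = normal_deviation(c, c)
        np.testing.assert_allclose(dev, 0.0, atol=1e-9)
        assert not flagged.any()

    def test_parallel_horizontal_lines(self):
        a = BoundaryCurve(np.linspace(0, 10, 11), np.full(11, 5.0))
        b = BoundaryCurve(np.linspace(0, 10, 11), np.full(11, 2.0))
        dev, flagged = normal_deviation(a, b)
        # b's tangent is +DV, normal is +ML: a sits +3 along the normal
        np.testing.assert_allclose(np.abs(dev), 3.0, atol=1e-9)
        assert len(set(np.sign(dev))) == 1
        assert not flagged.any()

    def test_45_degree_line_vs_horizontal(self):
        """From point (d, d) on the diagonal, the normal (-1, 1)/sqrt(2) meets
        the x=0 curve after a signed step of length d*sqrt(2)."""
        b = BoundaryCurve(np.linspace(1, 9, 9), np.linspace(1, 9, 9))
        a = BoundaryCurve(np.linspace(-100, 100, 3), np.zeros(3))
        dev, flagged = normal_deviation(a, b)
        expected = b.dv_um * np.sqrt(2)
        np.testing.assert_allclose(np.abs(dev), expected, atol=1e-9)
        assert not flagged.any()

    def test_fallback_flagged_when_normal_misses(self):
        a = BoundaryCurve([0.0, 1.0], [100.0, 100.0])   # short, far away
        b = BoundaryCurve(np.linspace(50, 60, 5), np.zeros(5))
        dev, flagged = normal_deviation(a, b)
        assert flagged.all()
        assert np.all(np.isfinite(dev))


class TestSlab:
    def test_half_open_interval(self):
        cells = [_cell(0, 0, True, z_um=z, cid=i)
                 for i, z in enumerate([0.0, 31.9, 32.0, 63.9])]
        picked = slab_cells(cells, 0.0, 32.0)
        assert [c.centroid_um[0] for c in picked] == [0.0, 31.9]
        picked2 = slab_cells(cells, 32.0)
        assert [c.centroid_um[0] for c in picked2] == [32.0, 63.9]
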