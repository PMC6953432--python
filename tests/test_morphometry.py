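import numpy as np
import pytest

from neoquant import morphometry as mm
from neoquant import synthgen


def _disk(r, pad=20):
    n = 2 * (r + pad)
    yy, xx = np.mgrid[:n, :n]
    c = n / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


class TestCountCells:
    def test_planted_non_touching_cells_counted(self):
        iba, _, truth = synthgen.gen_microglia_stack(
            n_cells=7, n_puncta_inside=0, n_puncta_outside=0,
            shape=(12, 512, 512), seed=0,
        )
        assert mm.count_cells(iba)["count"] == 7

    def test_small_blob_below_gate_ignored(self, rng):
        # a speckle whose smoothed footprint stays below the 150 px gate
        img = rng.normal(0.05, 0.01, (256, 256))
        yy, xx = np.mgrid[:256, :256]
        img[(yy - 128) ** 2 + (xx - 128) ** 2 <= 2.5**2] = 1.0  # ~20 px
        assert mm.count_cells(img)["count"] == 0

    def test_count_invariant_to_intensity_scaling(self):
        iba, _, _ = synthgen.gen_microglia_stack(
            n_cells=5, n_puncta_inside=0, n_puncta_outside=0,
            shape=(12, 512, 512), seed=1,
        )
        assert (
            mm.count_cells(iba)["count"] == mm.count_cells(2.0 * iba)["count"]
        )

    def test_flat_image_counts_zero(self):
        assert mm.count_cells(np.zeros((10, 64, 64)))["count"] == 0


class TestSegmentCells2d:
    def test_isolated_blob_within_gate_segmented(self, rng):
        img = rng.normal(0.05, 0.01, (300, 300))
        img[_disk(14, pad=136)] = 1.0  # ~600 px blob centered
        cells = mm.segment_cells_2d(img)
        assert len(cells) == 1

    def test_oversized_blob_excluded(self, rng):
        img = rng.normal(0.05, 0.01, (300, 300))
        img[_disk(24, pad=126)] = 1.0  # ~1800 px
        assert mm.segment_cells_2d(img) == []

    def test_cells_sharing_roi_both_excluded(self, rng):
        img = rng.normal(0.05, 0.01, (400, 400))
        yy, xx = np.mgrid[:400, :400]
        for cx in (190, 230):  # 40 px apart: same 110x110 ROI
            img[(yy - 200) ** 2 + (xx - cx) ** 2 <= 14**2] = 1.0
        assert mm.segment_cells_2d(img) == []

    def test_default_synthetic_layout_recovers_all_cells(self):
        iba, _, truth = synthgen.gen_microglia_stack(
            n_cells=7, n_puncta_inside=0, n_puncta_outside=0,
            shape=(12, 512, 512), seed=2,
        )
        cells = mm.segment_cells_2d(mm.max_projection(iba))
        assert len(cells) == len(truth.cells)


class TestCellFeatures:
    def test_circle_is_round_and_not_eccentric(self):
        disk = _disk(40)
        cell = mm.CellMask(disk, (0, 0), float(disk.sum()))
        f = mm.cell_features(cell)
        assert f["roundness"] >= 0.95
        assert f["eccentricity"] <= 0.2
        assert f["area_px"] == pytest.approx(np.pi * 40**2, rel=0.02)
        assert f["spread_px"] == pytest.approx(40.0, rel=0.03)

    @pytest.mark.parametrize("side", [100, 200])
    def test_large_square_roundness_approaches_pi_over_4(self, side):
        sq = np.zeros((side + 20, side + 20), bool)
        sq[10 : 10 + side, 10 : 10 + side] = True
        f = mm.cell_features(mm.CellMask(sq, (0, 0), float(sq.sum())))
        assert f["roundness"] == pytest.approx(np.pi / 4, abs=0.05)

    def test_four_to_one_ellipse_eccentricity(self):
        yy, xx = np.mgrid[:140, :140]
        e = ((yy - 70) / 14.0) ** 2 + ((xx - 70) / 56.0) ** 2 <= 1
        f = mm.cell_features(mm.CellMask(e, (0, 0), float(e.sum())))
        assert f["eccentricity"] == pytest.approx(np.sqrt(1 - 1 / 16), abs=0.02)

    def test_degenerate_mask_rejected(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(ValueError):
            mm.cell_features(mm.CellMask(m, (2, 2), 1.0))


class TestHysteresis3d:
    def test_uniform_zero_stack_empty(self):
        assert not mm.hysteresis_3d(np.zeros((5, 20, 20))).any()

    def test_halo_connected_to_core_retained(self):
        stack = np.zeros((7, 40, 40))
        stack[2:5, 15:25, 15:25] = 0.3  # halo
        stack[3, 18:22, 18:22] = 0.8  # core seeds the halo
        out = mm.hysteresis_3d(stack, median_filter=False)
        assert out[3, 19, 19]
        assert out[2, 16, 16]

    def test_isolated_low_voxels_removed(self):
        stack = np.zeros((7, 40, 40))
        stack[1, 5:8, 5:8] = 0.3  # no seed anywhere near
        stack[5, 30:33, 30:33] = 0.9  # distant seed block
        out = mm.hysteresis_3d(stack, median_filter=False)
        assert not out[1, 5:8, 5:8].any()
        assert out[5, 31, 31]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            mm.hysteresis_3d(np.zeros((3, 5, 5)), low=0.6, high=0.5)


class TestPuncta:
    def test_planted_puncta_detected_with_volume_fidelity(self, microglia_stack):
        _, vglut, truth = microglia_stack
        puncta = mm.detect_puncta(vglut)
        assert len(puncta) == len(truth.puncta)
        mean_truth = np.mean([p.volume_px for p in truth.puncta])
        mean_det = np.mean([p.volume_px for p in puncta])
        assert abs(mean_det - mean_truth) / mean_truth <= 0.15

    def test_tiny_punctum_discarded_by_volume_gate(self, rng):
        stack = np.clip(rng.normal(0, 0.02, (10, 80, 80)), 0, None)
        zz, yy, xx = np.mgrid[:10, :80, :80].astype(float)
        d = np.sqrt(
            ((zz - 5) / 1.2) ** 2 + ((yy - 40) / 2.0) ** 2 + ((xx - 40) / 2.0) ** 2
        )
        stack = np.maximum(stack, np.where(d <= 1, np.exp(-3 * d**2), 0))
        assert mm.detect_puncta(stack) == []  # ~50 px, below the 100 gate


class TestEngulfment:
    def test_planted_containment_is_exact(self, microglia_stack):
        iba, vglut, truth = microglia_stack
        mask = mm.hysteresis_3d(iba)
        puncta = mm.detect_puncta(vglut)
        n_inside = sum(1 for p in truth.puncta if p.inside_cell is not None)
        assert mm.engulfment_metrics(mask, puncta)["count"] == n_inside

    def test_single_voxel_outside_disqualifies(self):
        mask = np.zeros((5, 20, 20), bool)
        mask[1:4, 5:15, 5:15] = True
        inside = np.argwhere(mask)[:120]
        outside = np.vstack([inside[:-1], [[0, 0, 0]]])
        p_in = mm.Punctum(1, inside, len(inside), (2, 10, 10))
        p_out = mm.Punctum(2, outside, len(outside), (2, 10, 10))
        res = mm.engulfment_metrics(mask, [p_in, p_out])
        assert res["count"] == 1
        assert res["total_volume_px"] == len(inside)

    def test_shape_mismatch_rejected(self):
        p = mm.Punctum(1, np.array([[0, 0]]), 1, (0, 0))
        with pytest.raises(ValueError):
            mm.engulfment_metrics(np.ones((3, 4, 5), bool), [p])


class TestDistalVolume:
    def _sphere(self, radius_um, pixel=0.103, z=0.75):
        rz, rxy = radius_um / z, radius_um / pixel
        shape = (int(2 * rz) + 5, int(2 * rxy) + 5, int(2 * rxy) + 5)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
        c = [(s - 1) / 2 for s in shape]
        return (
            ((zz - c[0]) * z) ** 2
            + ((yy - c[1]) * pixel) ** 2
            + ((xx - c[2]) * pixel) ** 2
        ) <= radius_um**2

    def test_small_sphere_has_no_distal_volume(self):
        assert mm.distal_volume(self._sphere(5.0), 7.0) == 0.0

    def test_shell_volume_matches_analytic(self):
        dv = mm.distal_volume(self._sphere(10.0), 7.0)
        analytic = 4 / 3 * np.pi * (10**3 - 7**3)
        assert dv == pytest.approx(analytic, rel=0.05)

    def test_zero_cutoff_returns_total_volume(self):
        sph = self._sphere(8.0)
        dv = mm.distal_volume(sph, 0.0)
        assert dv == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.02)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            mm.distal_volume(np.ones((3, 3, 3), bool), 7.0, pixel_size_um=0.0)


def test_rasterized_primitive_area_within_2_percent():
    for r in (40, 60, 80):
        disk = _disk(r)
        assert disk.sum() == pytest.approx(np.pi * r**2, rel=0.02)


def test_behavior_tables_invert_discrimination_ratio():
    from neoquant import robuststats as rs

    df = synthgen.gen_behavior(
        200, {"control": 0.3, "GE": 0.0}, noise_sd=0.1, seed=0
    )
    ctl = df[df.group == "control"]
    drs = [
        rs.discrimination_ratio(r.t_novel_s, r.t_familiar_s)
        for r in ctl.itertuples()
    ]
    se = np.std(drs) / np.sqrt(len(drs))
    assert abs(np.mean(drs) - 0.3) < 3 * se

    exact = synthgen.gen_behavior(5, {"g": 0.5}, noise_sd=0.0, seed=1)
    for r in exact.itertuples():
        assert rs.discrimination_ratio(r.t_novel_s, r.t_familiar_s) == pytest.approx(0.5)

    zero = synthgen.gen_behavior(5, {"g": 0.0}, noise_sd=0.0, seed=2)
    for r in zero.itertuples():
        assert rs.discrimination_ratio(r.t_novel_s, r.t_familiar_s) == pytest.approx(0.0)

    with pytest.raises(ValueError):
        synthgen.gen_behavior(5, {"g": 1.5}, seed=3)
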