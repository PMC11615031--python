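"""Scan conversion geometry, nearest-slice compositing against the rule
oracle, contrast enhancement, and tuner fixed-point behaviour."""

import numpy as np
import pytest

import coloct
from coloct.mosaic import _overlap_ncc
from coloct.reconstruct import ProcessedScan


def uniform_sector(value=1.0, n_depth=300, n_ang=48, pitch_um=4.0,
                   apex=(0.0, 0.0), lane=0, step=0):
    cols = np.full((n_depth, n_ang), value)
    angles = np.linspace(-10, 10, n_ang)
    return coloct.BScanSector(cols, angles, pitch_um, apex=apex, lane=lane,
                              step=step)


def processed_from(bscans, plan, intr, origin=(0.0, 0.0)):
    positions = np.zeros((plan.n_lanes, plan.steps_per_lane, 2))
    for ln in range(plan.n_lanes):
        for st in range(plan.steps_per_lane):
            positions[ln, st] = (origin[0] + st * plan.step_size,
                                 origin[1] + ln * plan.lane_spacing)
    return ProcessedScan(bscans=bscans, plan=plan, intrinsics_true=intr,
                         stage_positions=positions, origin_mm=origin)


@pytest.fixture
def intr():
    return coloct.scan_intrinsics()


class TestScanConvert:
    def test_constant_radius_arc_maps_to_circle(self, intr):
        """A bright arc at fixed r in the sector lands at radius r from the
        apex in Cartesian space, within a pixel."""
        n_depth, pitch = 300, 4.0
        b = uniform_sector(0.0, n_depth, 64, pitch)
        r_arc_px = 220
        b.columns[r_arc_px - 1:r_arc_px + 2, :] = 1.0
        img = coloct.scan_convert(b, intr, 0.004)
        r_arc = r_arc_px * pitch * 1e-3
        ys, zs = img.y_coords, img.z_coords
        Z, Y = np.meshgrid(zs, ys, indexing="ij")
        bright = img.valid_mask & (img.pixels > 0.5)
        assert bright.any()
        r_of_bright = np.hypot(Y[bright], Z[bright])
        assert np.all(np.abs(r_of_bright - r_arc) <= 2.5 * 0.004)

    def test_valid_width_matches_chord_formula(self, intr):
        """fov 20 deg, max radius r: lateral valid width = 2 r sin(10deg)."""
        b = uniform_sector(1.0, n_depth=500, pitch_um=4.0)
        img = coloct.scan_convert(b, intr, 0.004)
        r_max = 499 * 4e-3
        width_expect = 2 * r_max * np.sin(np.deg2rad(10))
        ys = img.y_coords
        cols_valid = img.valid_mask.any(axis=0)
        width = ys[cols_valid][-1] - ys[cols_valid][0]
        assert width == pytest.approx(width_expect, abs=2.5 * 0.004)

    def test_single_column_maps_to_vertical_line(self, intr):
        a = coloct.AScan(np.ones(200), 4.0)
        b = coloct.assemble_bscan([a], [0.0])
        img = coloct.scan_convert(b, intr, 0.004)
        cols_valid = np.flatnonzero(img.valid_mask.any(axis=0))
        # degenerate fan: only the column under the apex is populated
        assert cols_valid.size >= 1
        y_span = img.y_coords[cols_valid[-1]] - img.y_coords[cols_valid[0]]
        assert y_span <= 2 * 0.004

    def test_round_trip_of_coordinate_fields(self, intr):
        """Sector filled with its own r (or theta) reproduces the analytic
        coordinate field on the Cartesian grid within a pixel."""
        n_depth, n_ang, pitch = 300, 64, 4.0
        rows = np.arange(n_depth) * pitch * 1e-3
        angles = np.linspace(-10, 10, n_ang)
        r_field = np.tile(rows[:, None], (1, n_ang))
        th_field = np.tile(angles[None, :], (n_depth, 1))
        for field, expect in (("r", r_field), ("theta", th_field)):
            b = coloct.BScanSector(expect.copy(), angles, pitch)
            img = coloct.scan_convert(b, intr, 0.004)
            Z, Y = np.meshgrid(img.z_coords, img.y_coords, indexing="ij")
            analytic = np.hypot(Y, Z) if field == "r" \
                else np.degrees(np.arctan2(Y, Z))
            m = img.valid_mask
            tol = 1.2 * (pitch * 1e-3 if field == "r"
                         else angles[1] - angles[0])
            assert np.nanmax(np.abs(img.pixels[m] - analytic[m])) <= tol

    def test_rejects_bad_pixel_size(self, intr):
        with pytest.raises(ValueError):
            coloct.scan_convert(uniform_sector(), intr, 0.0)


class TestBuildSlice:
    def test_single_lane_equals_scan_converted_bscan(self, intr):
        b = uniform_sector(2.0)
        plan = coloct.ScanPlan(n_lanes=1, steps_per_lane=1)
        pr = processed_from({(0, 0): b}, plan, intr)
        sl = coloct.build_slice(pr, 0, intr, 0.004)
        direct = coloct.scan_convert(b, intr, 0.004)
        assert sl.image.pixels.shape == direct.pixels.shape
        both = sl.image.valid_mask & direct.valid_mask
        # resampling onto the global grid may conservatively drop a thin rim
        assert both.sum() >= 0.95 * direct.valid_mask.sum()
        assert np.allclose(sl.image.pixels[both], direct.pixels[both])

    def test_two_lane_composite_obeys_nearest_rule_pixelwise(self, intr):
        """Constant-A lane vs constant-B lane: composite equals the direct
        evaluation of the nearest-apex rule everywhere."""
        a = uniform_sector(1.0, apex=(0.0, 0.0), lane=0)
        b = uniform_sector(3.0, apex=(0.0, 0.3), lane=1, step=0)
        plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=1, lane_spacing=0.3)
        pr = processed_from({(0, 0): a, (1, 0): b}, plan, intr)
        sl = coloct.build_slice(pr, 0, intr, 0.004)
        y = sl.image.y_coords
        mid = 0.15
        for row in range(0, sl.image.pixels.shape[0], 37):
            for col in range(0, len(y), 11):
                if not sl.image.valid_mask[row, col]:
                    continue
                v = sl.image.pixels[row, col]
                lane = sl.provenance[row, col]
                d0, d1 = abs(y[col] - 0.0), abs(y[col] - 0.3)
                if sl.provenance[row, col] == 0:
                    assert d0 <= d1 and v == pytest.approx(1.0)
                else:
                    assert d1 <= d0 and v == pytest.approx(3.0)

    def test_equidistant_pixels_take_lower_lane(self, intr):
        """Coincident apexes: every pixel is an exact tie, so the whole
        slice must come from lane 0 (declared tie-break)."""
        a = uniform_sector(1.0, apex=(0.0, 0.0), lane=0)
        b = uniform_sector(3.0, apex=(0.0, 0.0), lane=1)
        plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=1,
                               lane_spacing=1e-15)
        positions = np.zeros((2, 1, 2))
        pr = ProcessedScan(bscans={(0, 0): a, (1, 0): b}, plan=plan,
                           intrinsics_true=intr, stage_positions=positions,
                           origin_mm=(0.0, 0.0))
        sl = coloct.build_slice(pr, 0, intr, 0.004)
        m = sl.image.valid_mask
        assert np.all(sl.provenance[m] == 0)
        assert np.allclose(sl.image.pixels[m], 1.0)

    def test_duplicate_lane_composite_is_idempotent(self, intr):
        b0 = uniform_sector(2.0, apex=(0.0, 0.0), lane=0)
        b1 = uniform_sector(2.0, apex=(0.0, 0.0), lane=1)
        plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=1, lane_spacing=1e-9)
        positions = np.zeros((2, 1, 2))
        pr = ProcessedScan(bscans={(0, 0): b0, (1, 0): b1}, plan=plan,
                           intrinsics_true=intr, stage_positions=positions,
                           origin_mm=(0.0, 0.0))
        sl = coloct.build_slice(pr, 0, intr, 0.004)
        single = coloct.build_slice(
            processed_from({(0, 0): b0},
                           coloct.ScanPlan(n_lanes=1, steps_per_lane=1),
                           intr), 0, intr, 0.004)
        assert np.allclose(sl.image.pixels[sl.image.valid_mask],
                           single.image.pixels[single.image.valid_mask])

    def test_every_pixel_traceable_to_one_source(self, intr):
        """No averaging: each composited value equals the chosen lane's own
        interpolated value."""
        rng = np.random.default_rng(3)
        a = uniform_sector(1.0, apex=(0.0, 0.0), lane=0)
        a.columns += rng.random(a.columns.shape)
        b = uniform_sector(5.0, apex=(0.0, 0.3), lane=1)
        b.columns += rng.random(b.columns.shape)
        plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=1, lane_spacing=0.3)
        pr = processed_from({(0, 0): a, (1, 0): b}, plan, intr)
        sl = coloct.build_slice(pr, 0, intr, 0.004)
        # values from lane 0 stay below 2; lane 1 above 5: no blending
        vals = sl.image.pixels[sl.image.valid_mask]
        prov = sl.provenance[sl.image.valid_mask]
        assert np.all(vals[prov == 0] < 2.0 + 1e-9)
        assert np.all(vals[prov == 1] >= 5.0 - 1e-9)

    def test_missing_step_rejected(self, intr):
        plan = coloct.ScanPlan(n_lanes=1, steps_per_lane=2)
        pr = processed_from({(0, 0): uniform_sector()}, plan, intr)
        with pytest.raises(ValueError, match="no lane"):
            with pytest.warns(UserWarning, match="skipped"):
                coloct.build_slice(pr, 1, intr, 0.004)


class TestEnhanceContrast:
    def _slice(self, pixels):
        img = coloct.CartesianImage(pixels.astype(float), 0.01, (0.0, 0.0))
        prov = np.where(img.valid_mask, 0, -1)
        return coloct.MosaicSlice(image=img, provenance=prov, x_position=0.0)

    def test_identity_window_and_gamma(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 1, (40, 40))
        px[0, 0], px[1, 1] = 0.0, 1.0
        out = coloct.enhance_contrast(self._slice(px), (0, 100), 1.0)
        assert np.allclose(out.image.pixels, px)

    def test_gamma_half_at_quarter_signal(self):
        px = np.zeros((20, 20))
        px[0, 0], px[10, 10] = 1.0, 0.25
        out = coloct.enhance_contrast(self._slice(px), (0, 100), 0.5)
        assert out.image.pixels[10, 10] == pytest.approx(0.5)

    def test_joint_normalization_shares_parameters(self):
        rng = np.random.default_rng(1)
        s1 = self._slice(rng.uniform(0, 1, (30, 30)))
        s2 = self._slice(rng.uniform(2, 3, (30, 30)))
        o1, o2 = coloct.enhance_contrast([s1, s2])
        assert o1.normalization["p_low"] == o2.normalization["p_low"]
        assert o1.normalization["p_high"] == o2.normalization["p_high"]

    def test_constant_image_warns_and_zeroes(self):
        s = self._slice(np.full((10, 10), 2.0))
        with pytest.warns(UserWarning, match="constant"):
            out = coloct.enhance_contrast(s)
        assert np.all(out.image.pixels[out.image.valid_mask] == 0)

    def test_invalid_args_rejected(self):
        s = self._slice(np.random.default_rng(0).uniform(0, 1, (5, 5)))
        with pytest.raises(ValueError):
            coloct.enhance_contrast(s, (0, 100), 0.0)
        with pytest.raises(ValueError):
            coloct.enhance_contrast(s, (60, 40), 1.0)


class TestTuning:
    def test_single_lane_rejected(self, intr):
        plan = coloct.ScanPlan(n_lanes=1, steps_per_lane=1)
        pr = processed_from({(0, 0): uniform_sector()}, plan, intr)
        with pytest.raises(ValueError, match="two lanes"):
            coloct.tune_intrinsics(pr, intr)

    def test_unknown_parameter_rejected(self, intr):
        plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=1, lane_spacing=0.3)
        pr = processed_from({(0, 0): uniform_sector(lane=0),
                             (1, 0): uniform_sector(apex=(0, 0.3), lane=1)},
                            plan, intr)
        with pytest.raises(ValueError, match="subset"):
            coloct.tune_intrinsics(pr, intr, ("working_distance",))

    def test_no_overlap_diagnosed(self, intr):
        plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=1, lane_spacing=5.0)
        pr = processed_from({(0, 0): uniform_sector(lane=0),
                             (1, 0): uniform_sector(apex=(0, 5.0), lane=1)},
                            plan, intr)
        with pytest.raises(ValueError, match="overlap"):
            coloct.tune_intrinsics(pr, intr, ("fov_angle",))
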