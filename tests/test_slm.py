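import numpy as np
import pytest

from simscope.slm import (FourierMask, PatternSearchInfeasible, SlmGrating,
                          binary_grating_pattern, export_pattern_set,
                          multicolor_pattern_search, predicted_spot_positions,
                          read_pattern_bitmap, score_mask_transmission)


class TestBinaryGrating:
    def test_phase_step_is_exact_translation(self):
        g = SlmGrating(normal=(1, 0), period_px=6.0)
        b0 = binary_grating_pattern((60, 60), g, 0)  # width is a period multiple
        b1 = binary_grating_pattern((60, 60), g, 1)
        b2 = binary_grating_pattern((60, 60), g, 2)
        assert np.array_equal(np.roll(b0, 2, axis=1), b1)
        assert np.array_equal(np.roll(b0, 4, axis=1), b2)

    def test_duty_cycle(self):
        for period in (6.0, 9.0, 12.0):
            g = SlmGrating(normal=(1, 0), period_px=period)
            b = binary_grating_pattern((240, 240), g, 0)
            assert abs(b.mean() - 0.5) <= 1.0 / period

    def test_strictly_binary(self):
        g = SlmGrating(normal=(2, 1), period_px=6.0 / np.sqrt(5))
        b = binary_grating_pattern((64, 64), g, 1)
        assert b.dtype == bool

    def test_unrealizable_phase_step(self):
        g = SlmGrating(normal=(1, 0), period_px=2.0)  # 2/3 px shift
        with pytest.raises(ValueError, match="unrealizable"):
            binary_grating_pattern((64, 64), g, 1)

    def test_period_below_two_rejected(self):
        with pytest.raises(ValueError):
            SlmGrating(normal=(1, 0), period_px=1.5)

    def test_non_coprime_normal_rejected(self):
        with pytest.raises(ValueError):
            SlmGrating(normal=(2, 4), period_px=6.0)

    def test_phase_step_crosscorrelation_peak(self):
        g = SlmGrating(normal=(1, 0), period_px=12.0)
        b0 = binary_grating_pattern((120, 120), g, 0).astype(float)
        b1 = binary_grating_pattern((120, 120), g, 1).astype(float)
        row0, row1 = b0[0] - 0.5, b1[0] - 0.5
        corr = np.fft.ifft(np.fft.fft(row0).conj() * np.fft.fft(row1)).real
        best = np.argmax(corr)
        assert best % 12 == 4  # translation by period/3


class TestSpotPositions:
    def test_position_scaling_with_period(self):
        s1 = predicted_spot_positions(SlmGrating((1, 0), 6.0), 515.0)
        s2 = predicted_spot_positions(SlmGrating((1, 0), 12.0), 515.0)
        p1 = next(s.position for s in s1 if s.order == 1)
        p2 = next(s.position for s in s2 if s.order == 1)
        assert p1[0] == pytest.approx(2 * p2[0])

    def test_wavelength_radius_ratio(self):
        g = SlmGrating((1, 0), 9.0)
        r = {wl: next(s.position[0] for s in predicted_spot_positions(g, wl)
                      if s.order == 1) for wl in (488.0, 647.0)}
        assert r[647.0] / r[488.0] == pytest.approx(1.3258, abs=1e-4)

    def test_even_order_suppression_integer_period(self):
        for period in (6.0, 8.0, 12.0):
            spots = {s.order: s.intensity
                     for s in predicted_spot_positions(SlmGrating((1, 0), period), 515.0)}
            assert spots[2] / spots[1] < 1e-3
            assert spots[0] / spots[1] < 1e-3  # phase grating kills 0th order


class TestMaskScoring:
    def test_perfect_transmission(self):
        g = SlmGrating((1, 0), 9.0)
        spots = predicted_spot_positions(g, 515.0)
        r = 515.0 / 9.0
        mask = FourierMask(hole_positions=[(r, 0.0), (-r, 0.0)], hole_radius=1.0)
        wanted, leakage = score_mask_transmission(spots, mask)
        assert wanted == 1.0 and leakage == 0.0

    def test_rotated_mask_blocks_everything(self):
        g = SlmGrating((1, 0), 9.0)
        spots = predicted_spot_positions(g, 515.0)
        r = 515.0 / 9.0
        mask = FourierMask(hole_positions=[(0.0, r), (0.0, -r)], hole_radius=1.0)
        wanted, _ = score_mask_transmission(spots, mask)
        assert wanted == 0.0

    def test_third_order_clear_of_holes(self):
        g = SlmGrating((1, 0), 9.0)
        spots = predicted_spot_positions(g, 515.0)
        r = 515.0 / 9.0
        mask = FourierMask(hole_positions=[(r, 0.0), (-r, 0.0)], hole_radius=1.0)
        _, leakage = score_mask_transmission(spots, mask)
        assert leakage == 0.0

    def test_mask_must_exclude_dc(self):
        with pytest.raises(ValueError):
            FourierMask(hole_positions=[(0.0, 0.0)], hole_radius=1.0)


class TestMulticolorSearch:
    def test_single_wavelength_period_near_target(self):
        ps, mask, report = multicolor_pattern_search(
            [515.0], target_spot_radius=30.0, radius_tolerance=1.0, realize=False)
        for (wl, a), period in ps.periods.items():
            assert abs(wl / period - 30.0) <= 1.0
            assert period == pytest.approx(515.0 / 30.0, rel=0.05)

    def test_two_color_period_ratio_matches_wavelengths(self):
        ps, mask, report = multicolor_pattern_search(
            [488.0, 647.0], target_spot_radius=30.0, radius_tolerance=1.0,
            realize=False)
        for a in range(3):
            ratio = ps.periods[(647.0, a)] / ps.periods[(488.0, a)]
            assert ratio == pytest.approx(647.0 / 488.0, abs=2 * 1.0 / 30.0)

    def test_spot_coincidence_within_tolerance(self):
        ps, mask, _ = multicolor_pattern_search(
            [488.0, 568.0, 647.0], target_spot_radius=30.0, radius_tolerance=1.0,
            realize=False)
        for a in range(3):
            radii = [ps.periods[(wl, a)] and wl / ps.periods[(wl, a)]
                     for wl in (488.0, 568.0, 647.0)]
            assert max(radii) - min(radii) < 2 * 1.0

    def test_accepted_set_passes_mask_scoring(self):
        ps, mask, _ = multicolor_pattern_search(
            [488.0, 647.0], target_spot_radius=30.0, radius_tolerance=1.0,
            realize=False)
        for (wl, a), grating in ps.gratings.items():
            wanted, leakage = score_mask_transmission(
                predicted_spot_positions(grating, wl), mask)
            assert wanted >= 0.95
            assert leakage <= 0.01

    def test_infeasible_target_reports_constraint(self):
        with pytest.raises(PatternSearchInfeasible) as exc:
            multicolor_pattern_search([488.0], target_spot_radius=500.0,
                                      radius_tolerance=0.5,
                                      period_search_range=(4.0, 60.0))
        assert exc.value.report["tightest_constraint"]

    def test_mask_symmetric_under_point_reflection(self):
        _, mask, _ = multicolor_pattern_search(
            [488.0, 647.0], target_spot_radius=30.0, radius_tolerance=1.0,
            realize=False)
        positions = {tuple(np.round(h, 6)) for h in mask.hole_positions}
        for hx, hy in positions:
            assert (round(-hx, 6), round(-hy, 6)) in positions


class TestExport:
    def test_export_roundtrip_and_counts(self, tmp_path):
        ps, mask, _ = multicolor_pattern_search(
            [488.0, 568.0, 647.0], target_spot_radius=30.0, radius_tolerance=1.0,
            slm_shape=(128, 160))
        paths = export_pattern_set(ps, mask, tmp_path)
        bitmaps = [p for p in paths if p.suffix == ".png"]
        assert len(bitmaps) == 27  # 3 colors x 3 angles x 3 phases
        for p in bitmaps[:5]:
            name = p.stem.split("_")
            wl = float(name[1][2:])
            a, j = int(name[2][1:]), int(name[3][1:])
            assert np.array_equal(read_pattern_bitmap(p), ps.patterns[(wl, a, j)])
        table = (tmp_path / "mask_holes.tsv").read_text()
        assert len(table.strip().splitlines()) == 1 + len(mask.hole_positions)
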