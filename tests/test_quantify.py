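"""Rim construction, rim-corrected ratio formula, per-cell aggregation."""

import numpy as np
import pytest

import evaquant as ev
from evaquant.detection import Locus, SpotCandidate
from evaquant.io import ImageStack
from evaquant.quantify import (
    LocusMeasurement,
    make_rim,
    measure_all_loci,
    measure_locus,
    measurements_to_frame,
)


def coords_of(mask_bool):
    return np.argwhere(mask_bool)


class TestMakeRim:
    def test_isolated_pixel_rim_is_disc_annulus(self):
        nucleus = np.ones((41, 41), dtype=bool)
        locus = np.array([[20, 20]])
        rim = make_rim(locus, width=5, nucleus_mask=nucleus)
        # set-algebra oracle: all pixels within distance 5 except the locus
        yy, xx = np.mgrid[0:41, 0:41]
        d2 = (yy - 20) ** 2 + (xx - 20) ** 2
        expected = coords_of((d2 <= 25) & (d2 > 0))
        assert np.array_equal(rim, expected)

    def test_rim_clipped_to_nucleus(self):
        nucleus = np.zeros((41, 41), dtype=bool)
        nucleus[15:26, 15:26] = True
        locus = np.array([[16, 16]])  # at nucleus corner
        rim = make_rim(locus, width=5, nucleus_mask=nucleus)
        assert len(rim) > 0
        assert all(nucleus[y, x] for y, x in rim)

    def test_adjacent_loci_excluded_from_each_others_rim(self):
        nucleus = np.ones((41, 41), dtype=bool)
        a = np.array([[20, 15]])
        b = np.array([[20, 22]])
        rim_a = make_rim(a, width=5, nucleus_mask=nucleus, other_loci_masks=[b])
        # oracle: annulus around a, minus b dilated by 1 (chebyshev... disk(1))
        yy, xx = np.mgrid[0:41, 0:41]
        da = (yy - 20) ** 2 + (xx - 15) ** 2
        db = (yy - 20) ** 2 + (xx - 22) ** 2
        expected = coords_of((da <= 25) & (da > 0) & (db > 1))
        assert np.array_equal(rim_a, expected)

    def test_fully_excluded_rim_is_empty(self):
        nucleus = np.zeros((41, 41), dtype=bool)  # locus outside any nucleus
        rim = make_rim(np.array([[20, 20]]), width=3, nucleus_mask=nucleus)
        assert len(rim) == 0


def _toy_stack(det_plane, sen_plane):
    return ImageStack(np.stack([det_plane, sen_plane])[:, np.newaxis],
                      ("detector", "sensor"))


def _toy_locus(mask):
    spot = SpotCandidate("detector", 10.0, 10.0, 1.77, 100.0, mask)
    return Locus(0, spot, None, nucleus_id=1, unified_mask=mask, status="detector_only")


class TestMeasureAndRatio:
    def test_paper_formula_direct_substitution(self):
        # detector locus 300 / rim 100, sensor locus 200 / rim 100 -> 0.5
        m = ev.compute_ratio(LocusMeasurement(
            0, 1, i_locus_ch1=300, i_rim_ch1=100, i_locus_ch2=200, i_rim_ch2=100))
        assert m.ratio_gr == pytest.approx(0.5)
        assert m.valid

    def test_sensor_at_rim_level_floors_to_zero(self):
        m = ev.compute_ratio(LocusMeasurement(
            0, 1, i_locus_ch1=300, i_rim_ch1=100, i_locus_ch2=90, i_rim_ch2=100))
        assert m.ratio_gr == 0.0 and m.valid

    def test_identical_channels_give_unity(self):
        m = ev.compute_ratio(LocusMeasurement(
            0, 1, i_locus_ch1=300, i_rim_ch1=100, i_locus_ch2=300, i_rim_ch2=100))
        assert m.ratio_gr == pytest.approx(1.0)

    def test_constant_image_is_invalid(self):
        det = np.full((41, 41), 77.0)
        stack = _toy_stack(det, det.copy())
        yy, xx = np.mgrid[0:41, 0:41]
        mask = coords_of((yy - 10) ** 2 + (xx - 10) ** 2 <= 4)
        nucleus = np.ones((41, 41), dtype=bool)
        rim = make_rim(mask, 5, nucleus)
        m = measure_locus(stack, _toy_locus(mask), rim)
        assert not m.valid
        assert m.i_locus_ch1 == m.i_rim_ch1 == 77.0

    def test_masks_out_of_frame_invalid(self):
        stack = _toy_stack(np.ones((20, 20)), np.ones((20, 20)))
        mask = np.array([[19, 19], [20, 19]])  # second pixel out of frame
        m = measure_locus(stack, _toy_locus(mask), np.array([[5, 5]]))
        assert not m.valid and m.reason == "mask_out_of_frame"

    def test_offset_invariance_of_ratio(self, noise_free_specimen):
        stack, _, _ = noise_free_specimen
        res = ev.quantify_stack(stack)
        shifted = ImageStack(stack.data.copy(), stack.channels)
        shifted.data[stack.index("sensor")] += 250.0
        res2 = ev.quantify_stack(shifted)
        r1 = [m.ratio_gr for m in res.measurements if m.valid]
        r2 = [m.ratio_gr for m in res2.measurements if m.valid]
        assert np.allclose(sorted(r1), sorted(r2), atol=1e-3)

    def test_gain_linearity_of_ratio(self, noise_free_specimen):
        stack, _, _ = noise_free_specimen
        base = [m.ratio_gr for m in ev.quantify_stack(stack).measurements if m.valid]

        sens_gain = ImageStack(stack.data.copy(), stack.channels)
        sens_gain.data[stack.index("sensor")] *= 1.7
        up = [m.ratio_gr for m in ev.quantify_stack(sens_gain).measurements if m.valid]
        assert np.allclose(sorted(up), 1.7 * np.asarray(sorted(base)), rtol=1e-3)

        det_gain = ImageStack(stack.data.copy(), stack.channels)
        det_gain.data[stack.index("detector")] *= 2.0
        down = [m.ratio_gr for m in ev.quantify_stack(det_gain).measurements if m.valid]
        assert np.allclose(sorted(down), np.asarray(sorted(base)) / 2.0, rtol=1e-3)

    def test_noise_free_recovery_within_two_percent(self, noise_free_specimen):
        stack, _, truth = noise_free_specimen
        res = ev.quantify_stack(stack)
        ratios = np.array([m.ratio_gr for m in res.measurements if m.valid])
        assert len(ratios) == len(truth)
        assert np.all(np.abs(ratios - 0.8) <= 0.02)

    def test_noisy_recovery_median_error_within_ten_percent(self, noisy_specimen):
        stack, _, truth = noisy_specimen
        res = ev.quantify_stack(stack)
        ratios = np.array([m.ratio_gr for m in res.measurements if m.valid])
        rel_err = np.abs(ratios - 0.8) / 0.8
        assert np.median(rel_err) <= 0.10


class TestZModes:
    def test_per_slice_mode_recovers_ratio(self, noise_free_specimen):
        stack, _, _ = noise_free_specimen
        cfg = ev.QuantConfig(z_mode="per_slice", k_slices=3)
        res = ev.quantify_stack(stack, cfg)
        ratios = [m.ratio_gr for m in res.measurements if m.valid]
        assert len(ratios) > 0
        assert np.all(np.abs(np.array(ratios) - 0.8) < 0.05)
        assert all(m.n_slices_used == 3 for m in res.measurements)

    def test_more_slices_do_not_increase_measurement_cv(self):
        # repeated noisy measurements of one fixed locus: averaging the
        # per-slice ratios over more slices must not inflate the spread
        rng = np.random.default_rng(13)
        shape, nz, zc, sigma, amp, ratio, bg = (41, 41), 5, 2, 1.5, 400.0, 0.8, 200.0
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        radial = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * sigma**2))
        ideal = np.zeros((2, nz) + shape) + bg
        for z in range(nz):
            az = np.exp(-((z - zc) ** 2) / (2 * sigma**2))
            ideal[0, z] += amp * az * radial
            ideal[1, z] += ratio * amp * az * radial
        mask = coords_of((yy - 20) ** 2 + (xx - 20) ** 2 <= 4)
        rim = make_rim(mask, 5, np.ones(shape, dtype=bool))

        ratios = {1: [], 5: []}
        for _ in range(40):
            noisy = rng.poisson(ideal).astype(float)
            stack = ImageStack(noisy, ("detector", "sensor"))
            for k in ratios:
                m = measure_locus(stack, _toy_locus(mask), rim,
                                  z_mode="per_slice", k_slices=k)
                assert m.valid
                ratios[k].append(m.ratio_gr)
        cv = {k: np.std(v, ddof=1) / np.mean(v) for k, v in ratios.items()}
        assert cv[5] <= cv[1]


class TestAggregation:
    def _measurements(self, counts):
        out = []
        lid = 0
        for nid, n in counts.items():
            for _ in range(n):
                out.append(LocusMeasurement(lid, nid, ratio_gr=0.5, valid=True))
                lid += 1
        return out

    def test_allelic_mode_excludes_wrong_focus_counts(self):
        ms = self._measurements({1: 3, 2: 2, 3: 1})
        cells = ev.aggregate_cells(ms, mode="allelic")
        assert [c.nucleus_id for c in cells] == [2]

    def test_population_mode_keeps_everything_valid(self):
        ms = self._measurements({1: 3, 2: 2, 3: 1})
        cells = ev.aggregate_cells(ms, mode="population")
        assert sum(c.n_loci for c in cells) == 6

    def test_invalid_loci_never_counted(self):
        ms = self._measurements({1: 2})
        ms.append(LocusMeasurement(99, 1, ratio_gr=np.nan, valid=False))
        cells = ev.aggregate_cells(ms, mode="allelic")
        assert len(cells) == 1 and cells[0].n_loci == 2

    def test_round_trip_of_per_locus_table(self, noisy_specimen):
        stack, _, _ = noisy_specimen
        res = ev.quantify_stack(stack)
        df = measurements_to_frame(res.measurements)
        again = measurements_to_frame(res.measurements)
        assert df.equals(again)
        assert {"i_locus_ch1", "i_rim_ch1", "i_locus_ch2", "i_rim_ch2",
                "ratio_gr", "valid", "reason"} <= set(df.columns)
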