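"""Statistical layer: normalization, CV, rank-sum, sample size,
calibration, classification, allelic ratios."""

import itertools
import math

import numpy as np
import pytest

import evaquant as ev
from evaquant.stats import (
    CellRecord,
    StatParams,
    positivity_threshold_from_controls,
    specimen_summary,
)


class TestNormalization:
    def test_divides_by_control_mean(self):
        out = ev.normalize_to_control([0.4], [0.8, 0.8, 0.8])
        assert out[0] == pytest.approx(0.5)

    def test_controls_normalize_to_mean_one(self, rng):
        controls = rng.uniform(0.5, 1.5, size=40)
        assert ev.normalize_to_control(controls, controls).mean() == pytest.approx(1.0)

    def test_empty_or_degenerate_controls_rejected(self):
        with pytest.raises(ValueError):
            ev.normalize_to_control([1.0], [])
        with pytest.raises(ValueError):
            ev.normalize_to_control([1.0], [0.0, 0.0])


class TestCV:
    def test_equal_values_have_zero_cv(self):
        assert ev.coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        # {2, 4}: mean 3, sample SD sqrt(2)
        assert ev.coefficient_of_variation([2.0, 4.0]) == pytest.approx(
            math.sqrt(2) / 3, abs=1e-12
        )

    def test_uses_sample_sd(self):
        v = [1.0, 2.0, 3.0]
        assert ev.coefficient_of_variation(v) == pytest.approx(1.0 / 2.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            ev.coefficient_of_variation([-1.0, 1.0])


def enumeration_rank_sum_p(x, y, alternative):
    """Independent oracle: exact p by enumerating all rank assignments."""
    n, m = len(x), len(y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    pooled = sorted(x + y)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        us.append(sum(xi > yj for xi in xs for yj in ys))
    us = np.array(us)
    p_less = np.mean(us <= u_obs)
    p_greater = np.mean(us >= u_obs)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


class TestWilcoxon:
    def test_textbook_one_sided_exact_p(self):
        # complete separation of 3 vs 3: p = 1/C(6,3) = 0.05
        _, p = ev.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)

    def test_identical_samples_give_no_evidence(self):
        _, p = ev.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_large_shifted_samples_highly_significant(self, rng):
        x = rng.normal(0, 1, 100)
        y = rng.normal(2, 1, 100)
        _, p = ev.wilcoxon_rank_sum(x, y)
        assert p < 1e-3

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_path_agrees_with_full_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        x = list(np.round(rng.normal(0, 1, n), 6))
        y = list(np.round(rng.normal(0.5, 1, m), 6))
        _, p = ev.wilcoxon_rank_sum(x, y, alternative=alternative)
        assert p == pytest.approx(enumeration_rank_sum_p(x, y, alternative), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.wilcoxon_rank_sum([], [1.0])


class TestSampleSize:
    def test_reference_configuration_gives_16(self):
        n = ev.sample_size_two_groups(StatParams(alpha=0.05, power=0.8, sd=0.5, fold=1.5))
        assert n == 16

    def test_halving_sd_quarters_n(self):
        n = ev.sample_size_two_groups(StatParams(sd=0.25, fold=1.5))
        assert n == 4

    def test_fold_two_gives_4(self):
        n = ev.sample_size_two_groups(StatParams(sd=0.5, fold=2.0))
        assert n == 4

    def test_monotonicity(self):
        base = StatParams()
        n0 = ev.sample_size_two_groups(base)
        assert ev.sample_size_two_groups(StatParams(fold=1.8)) <= n0
        assert ev.sample_size_two_groups(StatParams(sd=0.8)) >= n0
        assert ev.sample_size_two_groups(StatParams(power=0.95)) >= n0
        assert ev.sample_size_two_groups(StatParams(baseline_mean=2.0)) <= n0

    def test_fold_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            StatParams(fold=1.0)


class TestCalibration:
    def test_hand_computed_percent_of_max(self):
        # floor 0.1, ceiling 1.1, query mean 0.97 -> (0.97-0.1)/(1.1-0.1) = 87%
        cal = ev.calibrate_dynamic_range(
            {0.0: [0.1, 0.1], 0.5: [0.97, 0.97], 1.0: [1.1, 1.1]}
        )
        assert cal.percent_of_max[0.5] == pytest.approx(87.0)
        assert cal.percent_of_max[0.0] == 0.0
        assert cal.percent_of_max[1.0] == 100.0

    def test_perfectly_linear_series(self):
        cond = {f: [0.2 + 0.9 * f] * 3 for f in (0.0, 0.33, 0.67, 1.0)}
        cal = ev.calibrate_dynamic_range(cond)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.slope == pytest.approx(cal.ceiling_gr - cal.floor_gr)

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError):
            ev.calibrate_dynamic_range({0.0: [0.1], 0.5: [0.5]})
        with pytest.raises(ValueError):
            ev.calibrate_dynamic_range({0.5: [0.5], 1.0: [1.0]})

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            ev.calibrate_dynamic_range({0.0: [1.0, 1.0], 1.0: [0.2, 0.2]})


def _cell(nid, ratios, rna_pos=None):
    return CellRecord(nucleus_id=nid, locus_ids=list(range(len(ratios))),
                      ratios=list(ratios), rna_positive_locus=rna_pos)


class TestClassification:
    def test_three_classes_by_hand_count(self):
        cells = (
            [_cell(i, (0.5, 0.6)) for i in range(4)]      # di+/+
            + [_cell(i + 4, (0.5, 0.05)) for i in range(3)]  # mono+/-
            + [_cell(i + 7, (0.05, 0.01)) for i in range(3)]  # di-/-
        )
        fr = ev.classify_cells(cells, positivity_threshold=0.2)
        assert fr == {"di+/+": 0.4, "mono+/-": 0.3, "di-/-": 0.3}

    def test_fractions_sum_to_one_and_order_invariant(self, rng):
        cells = [_cell(i, rng.uniform(0, 1, 2)) for i in range(30)]
        fr = ev.classify_cells(cells, 0.5)
        assert sum(fr.values()) == pytest.approx(1.0)
        shuffled = list(cells)
        rng.shuffle(shuffled)
        assert ev.classify_cells(shuffled, 0.5) == fr

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.classify_cells([], 0.5)

    def test_threshold_rule_from_floor_controls(self):
        v = [0.1, 0.12, 0.08, 0.1]
        t = positivity_threshold_from_controls(v)
        assert t == pytest.approx(np.mean(v) + 3 * np.std(v, ddof=1))


class TestAllelicRatio:
    def test_identical_alleles_give_ratio_one(self):
        cells = [_cell(i, (0.5, 0.5), rna_pos=0) for i in range(6)]
        table, summary = ev.allelic_fold_ratio(cells)
        assert np.allclose(table.allelic_ratio, 1.0)
        assert summary["median_ratio"] == pytest.approx(1.0)

    def test_constructed_twofold_difference(self):
        cells = [_cell(i, (1.0, 0.5), rna_pos=1) for i in range(8)]
        _, summary = ev.allelic_fold_ratio(cells)
        assert summary["median_ratio"] == pytest.approx(2.0)
        assert summary["p_value"] < 0.05

    def test_invalid_rna_positive_ratio_skips_cell(self):
        cells = [_cell(0, (1.0, float("nan")), rna_pos=1),
                 _cell(1, (1.0, 0.5), rna_pos=1)]
        table, summary = ev.allelic_fold_ratio(cells)
        assert summary["n_cells"] == 1
        assert list(table.nucleus_id) == [1]

    def test_untagged_cells_rejected(self):
        with pytest.raises(ValueError):
            ev.allelic_fold_ratio([_cell(0, (1.0, 0.5))])


def test_specimen_summary_reports_mean_median_cv():
    cells = [_cell(i, (0.4, 0.6)) for i in range(30)]
    s = specimen_summary(cells, label="x")
    assert s["n_cells"] == 30 and s["n_loci"] == 60
    assert s["mean_gr"] == pytest.approx(0.5)
    assert s["cv"] == pytest.approx(np.std([0.4, 0.6] * 30, ddof=1) / 0.5)
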