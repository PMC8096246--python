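"""Statistical layer for ratio-imaging experiments.

Covers the downstream analysis of per-locus sensor/detector (G/R) ratios:
normalization to the negative-control mean, coefficient of variation,
Wilcoxon rank-sum comparison, two-group sample-size estimation,
dynamic-range calibration from a labeled-fraction mixing series, per-cell
allelic positivity classification, and per-cell allelic fold ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Below this many analyzed cells per specimen a warning is emitted.
MIN_CELLS_WARN = 25


@dataclass(frozen=True)
class StatParams:
    """Inputs of the two-group sample-size calculation.

    alpha          two-sided significance level
    power          1 - beta
    sd             common standard deviation, in ratio units
    fold           detectable fold difference between group means (> 1)
    baseline_mean  mean of the reference group, in ratio units
    """

    alpha: float = 0.05
    power: float = 0.8
    sd: float = 0.5
    fold: float = 1.5
    baseline_mean: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0,1), got {self.power}")
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if self.fold <= 1:
            raise ValueError(f"fold must be > 1, got {self.fold}")


@dataclass
class CellRecord:
    """One nucleus with its (valid) loci and derived per-cell statistics."""

    nucleus_id: int
    locus_ids: list[int] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)
    normalized: list[float] | None = None
    rna_positive_locus: int | None = None
    cell_class: str | None = None  # "di+/+" | "mono+/-" | "di-/-"
    allelic_ratio: float | None = None

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass
class CalibrationResult:
    """Dynamic-range calibration from a labeled-fraction mixing series."""

    per_condition: pd.DataFrame  # columns: fraction, n, mean, sd, cv
    floor_gr: float
    ceiling_gr: float
    percent_of_max: dict[float, float]
    slope: float
    intercept: float
    r_squared: float


def normalize_to_control(ratios, control_ratios) -> np.ndarray:
    """Divide ratios by the mean G/R of the negative controls."""
    control = np.asarray(control_ratios, dtype=float)
    if control.size == 0:
        raise ValueError("control_ratios is empty")
    m = control.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"degenerate control mean {m}")
    return np.asarray(ratios, dtype=float) / m


def coefficient_of_variation(values) -> float:
    """CV = sample SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    Uses the exact null distribution when the pooled sample is small
    (n_x + n_y <= 12) and tie-free, otherwise the normal approximation with
    tie and continuity corrections.  Returns (U statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def sample_size_two_groups(p: StatParams) -> int:
    """Minimum n per group to detect a fold difference between two means.

    Normal-approximation two-sample formula:
    n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2 ),
    delta = baseline_mean * (fold - 1).
    """
    delta = p.baseline_mean * (p.fold - 1.0)
    z_a = sps.norm.ppf(1.0 - p.alpha / 2.0)
    z_b = sps.norm.ppf(p.power)
    n = 2.0 * (z_a + z_b) ** 2 * p.sd**2 / delta**2
    return math.ceil(n)


def calibrate_dynamic_range(condition_ratios: dict[float, object]) -> CalibrationResult:
    """Map per-condition G/R samples of a mixing series onto a 0-100% scale.

    ``condition_ratios`` maps labeled fraction (0..1) to a sample of G/R
    values; the 0 and 1 conditions define the floor and ceiling.
    percent_of_max(f) = 100 (mean(f) - floor) / (ceiling - floor).
    The least-squares line of condition mean vs. fraction and per-condition
    CVs (the technical-noise estimate) are reported alongside.
    """
    fractions = sorted(condition_ratios)
    if not any(math.isclose(f, 0.0, abs_tol=1e-9) for f in fractions):
        raise ValueError("calibration requires a 0 (unlabeled) condition")
    if not any(math.isclose(f, 1.0, abs_tol=1e-9) for f in fractions):
        raise ValueError("calibration requires a 1 (fully labeled) condition")

    rows = []
    for f in fractions:
        v = np.asarray(condition_ratios[f], dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"condition {f} has no finite ratios")
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
        cv = sd / mean if (v.size > 1 and mean != 0) else float("nan")
        rows.append({"fraction": f, "n": int(v.size), "mean": mean, "sd": sd, "cv": cv})
    per_condition = pd.DataFrame(rows)

    floor = float(per_condition.loc[np.isclose(per_condition.fraction, 0.0), "mean"].iloc[0])
    ceiling = float(per_condition.loc[np.isclose(per_condition.fraction, 1.0), "mean"].iloc[0])
    if ceiling <= floor:
        raise ValueError(f"ceiling G/R ({ceiling}) must exceed floor ({floor})")

    pom = {
        f: 100.0 * (m - floor) / (ceiling - floor)
        for f, m in zip(per_condition.fraction, per_condition["mean"])
    }
    fit = sps.linregress(per_condition.fraction, per_condition["mean"])
    return CalibrationResult(
        per_condition=per_condition,
        floor_gr=floor,
        ceiling_gr=ceiling,
        percent_of_max=pom,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def percent_of_max(value: float, cal: CalibrationResult) -> float:
    """Express a G/R value on the calibrated 0-100% scale."""
    return 100.0 * (value - cal.floor_gr) / (cal.ceiling_gr - cal.floor_gr)


def positivity_threshold_from_controls(control_normalized, n_sd: float = 3.0) -> float:
    """Default positivity rule: mean + n_sd * SD of the floor-control ratios."""
    v = np.asarray(control_normalized, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 control ratios for a threshold")
    return float(v.mean() + n_sd * v.std(ddof=1))


def classify_cells(cells: list[CellRecord], positivity_threshold: float) -> dict[str, float]:
    """Fractions of 2-locus cells by sensor positivity of their two alleles.

    A locus is sensor-positive when its (normalized, if available) G/R
    exceeds ``positivity_threshold``.  Returns fractions for di+/+ (both
    positive), mono+/- (one positive) and di-/- (none), summing to 1.
    Each cell's class is recorded on the CellRecord.
    """
    two_locus = [c for c in cells if c.n_loci == 2]
    if not two_locus:
        raise ValueError("no 2-locus cells to classify")
    counts = {"di+/+": 0, "mono+/-": 0, "di-/-": 0}
    for c in two_locus:
        vals = c.normalized if c.normalized is not None else c.ratios
        n_pos = sum(v > positivity_threshold for v in vals)
        c.cell_class = {2: "di+/+", 1: "mono+/-", 0: "di-/-"}[n_pos]
        counts[c.cell_class] += 1
    n = len(two_locus)
    return {k: v / n for k, v in counts.items()}


def allelic_fold_ratio(cells: list[CellRecord]) -> tuple[pd.DataFrame, dict]:
    """Per-cell high/low allelic ratio for RNA-tagged 2-locus cells.

    For each cell with an RNA-positive locus tag, computes
    ratio = G/R(RNA- locus) / G/R(RNA+ locus) and records it on the cell.
    Returns the per-cell table plus a summary with the median and mean
    ratio and a rank-sum comparison of the RNA- vs RNA+ ratio sets.
    """
    rows = []
    neg_set, pos_set = [], []
    for c in cells:
        if c.rna_positive_locus is None or c.n_loci != 2:
            continue
        try:
            i_pos = c.locus_ids.index(c.rna_positive_locus)
        except ValueError:
            logger.info("cell %d: RNA+ locus %s not among valid loci, skipped",
                        c.nucleus_id, c.rna_positive_locus)
            continue
        r_pos = c.ratios[i_pos]
        r_neg = c.ratios[1 - i_pos]
        if not np.isfinite(r_pos) or r_pos <= 0:
            logger.info("cell %d: RNA+ locus ratio invalid, skipped", c.nucleus_id)
            continue
        c.allelic_ratio = r_neg / r_pos
        rows.append({"nucleus_id": c.nucleus_id, "ratio_neg": r_neg,
                     "ratio_pos": r_pos, "allelic_ratio": c.allelic_ratio})
        neg_set.append(r_neg)
        pos_set.append(r_pos)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no RNA-tagged 2-locus cells with a valid RNA+ ratio")
    u, p = wilcoxon_rank_sum(neg_set, pos_set, alternative="two-sided")
    summary = {
        "n_cells": int(len(table)),
        "median_ratio": float(table.allelic_ratio.median()),
        "mean_ratio": float(table.allelic_ratio.mean()),
        "rank_sum_U": u,
        "p_value": p,
    }
    return table, summary


def specimen_summary(cells: list[CellRecord], label: str = "") -> dict:
    """Per-specimen summary of normalized ratios; warns below 25 cells."""
    n_cells = len(cells)
    if n_cells < MIN_CELLS_WARN:
        logger.warning("specimen %s: only %d analyzed cells (< %d recommended)",
                       label, n_cells, MIN_CELLS_WARN)
    ratios = [v for c in cells
              for v in (c.normalized if c.normalized is not None else c.ratios)]
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    out = {"label": label, "n_cells": n_cells, "n_loci": int(ratios.size)}
    if ratios.size:
        out["mean_gr"] = float(ratios.mean())
        out["median_gr"] = float(np.median(ratios))
    if ratios.size >= 2 and ratios.mean() != 0:
        out["cv"] = coefficient_of_variation(ratios)
    return out
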