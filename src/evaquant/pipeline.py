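"""End-to-end quantification: register → segment → detect → measure → aggregate.

Ties the stage modules into the full per-field chain, applies the
negative-control normalization across specimens of a manifest, and runs
the dynamic-range calibration over a labeled-fraction series.  All
parameters live in :class:`QuantConfig` (YAML-loadable; every key has a
CLI override) and every per-field decision — registration shift, counts of
kept and dropped nuclei/loci — is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detection, quantify, registration, segmentation, stats
from .io import ImageStack, SpecimenManifest, read_stack

logger = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    """All tunable parameters of the quantification chain."""

    max_shift: float = 10.0
    smooth_sigma: float = 4.0
    min_area: int = 500
    max_area: int | None = None
    exclude_border: bool = True
    split_touching: bool = False
    spot_diameter: float = 5.0
    min_snr: float = 5.0
    match_radius: float = 3.0
    rim_width: int = 5
    z_mode: str = "projection"  # or "per_slice"
    k_slices: int = 3
    mode: str = "population"  # or "allelic"
    rna_overlap: float = 0.5
    normalize: bool = True
    detector_channel: str = "detector"
    sensor_channel: str = "sensor"
    rna_channel: str = "rna"

    @classmethod
    def from_yaml(cls, path) -> "QuantConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FieldResult:
    """Everything measured on one field of view."""

    measurements: list[quantify.LocusMeasurement]
    cells: list[stats.CellRecord]
    label_map: segmentation.NucleusLabelMap
    loci: list[detection.Locus]
    shift: registration.Shift

    def to_frame(self) -> pd.DataFrame:
        df = quantify.measurements_to_frame(self.measurements)
        df["shift_dy"] = self.shift.dy
        df["shift_dx"] = self.shift.dx
        return df


def quantify_stack(stack: ImageStack, config: QuantConfig | None = None) -> FieldResult:
    """Run the full measurement chain on one image stack."""
    cfg = config or QuantConfig()
    det_name, sen_name = cfg.detector_channel, cfg.sensor_channel

    shift = registration.estimate_shift(
        stack.projection(det_name), stack.projection(sen_name), cfg.max_shift
    )
    logger.info("registration shift: dy=%.3f dx=%.3f", shift.dy, shift.dx)
    stack = registration.apply_shift(stack, sen_name, shift, cfg.max_shift)

    label_map = segmentation.segment_nuclei(
        stack.projection(det_name),
        smooth_sigma=cfg.smooth_sigma,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        split_touching=cfg.split_touching,
    )
    label_map = segmentation.filter_cells(label_map, exclude_border=cfg.exclude_border)
    logger.info("segmented %d nuclei", label_map.n_nuclei)

    det_spots = detection.detect_spots(
        stack.projection(det_name), cfg.spot_diameter, cfg.min_snr, det_name
    )
    sen_spots = detection.detect_spots(
        stack.projection(sen_name), cfg.spot_diameter, cfg.min_snr, sen_name
    )
    loci = detection.match_loci(det_spots, sen_spots, cfg.match_radius)
    loci = detection.assign_to_nuclei(loci, label_map)
    logger.info("detected %d detector spots, %d sensor spots -> %d in-nucleus loci",
                len(det_spots), len(sen_spots), len(loci))

    measurements = quantify.measure_all_loci(
        stack, loci, label_map.labels, rim_width=cfg.rim_width,
        z_mode=cfg.z_mode, k_slices=cfg.k_slices, sensor=sen_name,
    )
    cells = quantify.aggregate_cells(measurements, mode=cfg.mode)

    if cfg.mode == "allelic" and cfg.rna_channel in stack.channels:
        tag_rna_positive(stack, loci, cells, channel=cfg.rna_channel,
                         overlap=cfg.rna_overlap)
    return FieldResult(measurements, cells, label_map, loci, shift)


def tag_rna_positive(stack: ImageStack, loci: list[detection.Locus],
                     cells: list[stats.CellRecord], channel: str = "rna",
                     overlap: float = 0.5) -> None:
    """Mark each cell's RNA-positive locus from the auxiliary channel.

    The auxiliary (RNA FISH) projection is thresholded at median + 5 robust
    SDs; a locus is RNA-positive when more than ``overlap`` of its mask
    pixels fall inside that signal.  For a 2-locus cell with exactly one
    positive locus, the tag is recorded on the CellRecord.
    """
    proj = stack.projection(channel)
    med = np.median(proj)
    mad = 1.4826 * np.median(np.abs(proj - med))
    rna_mask = proj > med + 5 * mad
    by_id = {l.locus_id: l for l in loci}
    for cell in cells:
        positives = []
        for lid in cell.locus_ids:
            m = by_id[lid].unified_mask
            if len(m) and rna_mask[m[:, 0], m[:, 1]].mean() > overlap:
                positives.append(lid)
        if len(positives) == 1:
            cell.rna_positive_locus = positives[0]
        elif positives:
            logger.info("cell %d: %d RNA-positive loci, tag ambiguous",
                        cell.nucleus_id, len(positives))


def per_cell_means(result: FieldResult) -> list[float]:
    """Mean valid G/R per cell — the per-cell summary used for calibration."""
    return [float(np.mean(c.ratios)) for c in result.cells if c.ratios]


def run_quantify(manifest: SpecimenManifest, config: QuantConfig | None = None,
                 outdir=None) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every specimen of a manifest and normalize to controls.

    Test-specimen ratios are divided by the mean G/R of the
    no-exonuclease-control specimens (error if normalization is requested
    but no such control exists).  Writes per-locus CSV and a JSON summary
    when ``outdir`` is given; returns (per-locus table, per-specimen
    summaries).
    """
    cfg = config or QuantConfig()
    names = manifest.channel_names
    results: dict[str, tuple[FieldResult, str]] = {}
    frames = []
    for entry in manifest.specimens:
        stack = read_stack(entry.path, channel_names=names)
        res = quantify_stack(stack, cfg)
        results[entry.label] = (res, entry.role)
        df = res.to_frame()
        df.insert(0, "specimen", entry.label)
        df.insert(1, "role", entry.role)
        frames.append(df)
    per_locus = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    if cfg.normalize:
        control_ratios = [
            v for (res, role) in results.values() if role == "no_exonuclease_control"
            for c in res.cells for v in c.ratios
        ]
        if not control_ratios:
            raise ValueError(
                "normalization requested but manifest has no "
                "no_exonuclease_control specimen"
            )
        mean_ctrl = float(np.mean(control_ratios))
        logger.info("normalizing by control mean G/R = %.4f", mean_ctrl)
        for res, _role in results.values():
            for c in res.cells:
                c.normalized = [v / mean_ctrl for v in c.ratios]
        if not per_locus.empty:
            per_locus["ratio_gr_normalized"] = per_locus["ratio_gr"] / mean_ctrl

    summaries = [
        stats.specimen_summary(res.cells, label=label) | {"role": role,
            "shift_dy": res.shift.dy, "shift_dx": res.shift.dx}
        for label, (res, role) in results.items()
    ]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_locus.to_csv(outdir / "per_locus.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2)
    return per_locus, summaries


def run_calibrate(manifest: SpecimenManifest, config: QuantConfig | None = None,
                  out=None) -> stats.CalibrationResult:
    """Dynamic-range calibration from a manifest's calibration series.

    Each ``calibration:<fraction>`` specimen is quantified; the calibration
    uses the per-cell mean G/R of each condition.  Requires fractions 0 and
    1 to anchor the floor and ceiling.
    """
    cfg = config or QuantConfig()
    series = manifest.calibration_series()
    if not series:
        raise ValueError("manifest has no calibration:<fraction> specimens")
    condition_ratios: dict[float, list[float]] = {}
    for fraction, entries in series.items():
        vals: list[float] = []
        for entry in entries:
            stack = read_stack(entry.path, channel_names=manifest.channel_names)
            vals.extend(per_cell_means(quantify_stack(stack, cfg)))
        condition_ratios[fraction] = vals
    cal = stats.calibrate_dynamic_range(condition_ratios)
    if out is not None:
        payload = {
            "floor_gr": cal.floor_gr,
            "ceiling_gr": cal.ceiling_gr,
            "percent_of_max": {str(k): v for k, v in cal.percent_of_max.items()},
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r_squared": cal.r_squared,
            "per_condition": cal.per_condition.to_dict(orient="records"),
        }
        with open(out, "w") as fh:
            json.dump(payload, fh, indent=2)
    return cal
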