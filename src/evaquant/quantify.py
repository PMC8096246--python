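"""Rim-corrected per-locus intensity ratios — the pipeline's core readout.

Around each locus a concentric band ("rim", default 5 px wide) samples the
local background inside the same nucleus.  Per channel the locus and rim
mean intensities are measured and the locus ratio is

    G/R = (I_Locus_Ch2 - I_Rim_Ch2) / (I_Locus_Ch1 - I_Rim_Ch1)

with Ch1 the detector (reference) channel and Ch2 the sensor channel.
Means (not sums) make locus and rim directly subtractable despite their
different areas, and make the ratio exactly invariant to adding a constant
to a channel and exactly linear in per-channel gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .detection import Locus
from .io import ImageStack
from .stats import CellRecord

logger = logging.getLogger(__name__)

RIM_WIDTH_DEFAULT = 5


@dataclass
class LocusMeasurement:
    """Per-locus, per-channel intensities and the rim-corrected ratio."""

    locus_id: int
    nucleus_id: int
    i_locus_ch1: float = np.nan  # detector, mean counts/pixel
    i_rim_ch1: float = np.nan
    i_locus_ch2: float = np.nan  # sensor
    i_rim_ch2: float = np.nan
    ratio_gr: float = np.nan
    valid: bool = False
    reason: str = ""
    epsilon: float = 0.0  # denominator validity floor (3 x rim SE)
    n_slices_used: int = 0


def make_rim(
    locus_mask: np.ndarray,
    width: int,
    nucleus_mask: np.ndarray,
    other_loci_masks: list[np.ndarray] | None = None,
    frame_invalid: np.ndarray | None = None,
) -> np.ndarray:
    """Concentric background band around a locus, inside its nucleus.

    The rim is the ``width``-pixel morphological dilation of the locus mask
    minus the locus itself, intersected with the nucleus, minus all other
    loci (each dilated by 1 px) and any resampling-invalidated pixels.
    Masks are (n, 2) integer pixel-coordinate arrays.  Returns a possibly
    empty coordinate array; the caller marks the locus invalid if empty.
    """
    if width < 1:
        raise ValueError(f"rim width must be >= 1, got {width}")
    if len(locus_mask) == 0:
        return np.empty((0, 2), dtype=int)
    h, w = nucleus_mask.shape
    # all work happens in a window around the locus: dilation radius + 1 px
    y0 = max(0, locus_mask[:, 0].min() - width - 1)
    y1 = min(h, locus_mask[:, 0].max() + width + 2)
    x0 = max(0, locus_mask[:, 1].min() - width - 1)
    x1 = min(w, locus_mask[:, 1].max() + width + 2)

    local = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    local[locus_mask[:, 0] - y0, locus_mask[:, 1] - x0] = True
    dilated = ndi.binary_dilation(local, structure=disk(width))
    rim = dilated & ~local & nucleus_mask[y0:y1, x0:x1]
    if other_loci_masks:
        other = np.zeros_like(local)
        for m in other_loci_masks:
            inside = (
                (m[:, 0] >= y0) & (m[:, 0] < y1) & (m[:, 1] >= x0) & (m[:, 1] < x1)
            )
            sel = m[inside]
            other[sel[:, 0] - y0, sel[:, 1] - x0] = True
        if other.any():
            rim &= ~ndi.binary_dilation(other, structure=disk(1))
    if frame_invalid is not None:
        rim &= ~frame_invalid[y0:y1, x0:x1]
    coords = np.argwhere(rim)
    coords[:, 0] += y0
    coords[:, 1] += x0
    return coords


def compute_ratio(m: LocusMeasurement) -> LocusMeasurement:
    """Fill in ratio_gr from the four intensity fields.

    The corrected sensor signal (numerator) is floored at 0 — a locus
    cannot carry negative signal; a corrected detector signal (denominator)
    at or below epsilon invalidates the locus, because the detector signal
    is what defines locus existence.
    """
    den = m.i_locus_ch1 - m.i_rim_ch1
    if not np.isfinite(den) or den <= m.epsilon:
        return replace(m, ratio_gr=np.nan, valid=False,
                       reason=m.reason or "detector_signal_below_epsilon")
    num = max(m.i_locus_ch2 - m.i_rim_ch2, 0.0)
    return replace(m, ratio_gr=num / den, valid=True, reason="")


def measure_locus(
    stack: ImageStack,
    locus: Locus,
    rim: np.ndarray,
    z_mode: str = "projection",
    k_slices: int = 3,
    detector: str = "detector",
    sensor: str = "sensor",
) -> LocusMeasurement:
    """Measure locus and rim mean intensities in both channels.

    z_mode "projection" measures on the maximum-intensity projection;
    "per_slice" measures on each of the k brightest slices (ranked by
    detector locus mean) and averages the per-slice ratios, which buffers
    z-axis chromatic offsets at the cost of per-slice noise.
    """
    m = LocusMeasurement(locus_id=locus.locus_id, nucleus_id=locus.nucleus_id or 0)
    mask = locus.unified_mask
    if len(mask) == 0:
        return replace(m, reason="empty_locus_mask")
    if len(rim) == 0:
        return replace(m, reason="empty_rim")
    h, w = stack.frame_shape
    allpix = np.vstack([mask, rim])
    if (allpix < 0).any() or (allpix[:, 0] >= h).any() or (allpix[:, 1] >= w).any():
        return replace(m, reason="mask_out_of_frame")

    det = stack.channel(detector)
    sen = stack.channel(sensor)

    def means(plane_det: np.ndarray, plane_sen: np.ndarray) -> tuple[float, ...]:
        return (
            float(plane_det[mask[:, 0], mask[:, 1]].mean()),
            float(plane_det[rim[:, 0], rim[:, 1]].mean()),
            float(plane_sen[mask[:, 0], mask[:, 1]].mean()),
            float(plane_sen[rim[:, 0], rim[:, 1]].mean()),
        )

    if z_mode == "projection" or stack.n_z == 1:
        pd_, pr, sd_, sr = means(det.max(axis=0), sen.max(axis=0))
        rim_px = det.max(axis=0)[rim[:, 0], rim[:, 1]]
        eps = 3.0 * float(rim_px.std(ddof=1)) / np.sqrt(len(rim)) if len(rim) > 1 else 0.0
        m = replace(m, i_locus_ch1=pd_, i_rim_ch1=pr, i_locus_ch2=sd_, i_rim_ch2=sr,
                    epsilon=eps, n_slices_used=stack.n_z if z_mode == "projection" else 1)
        return compute_ratio(m)

    if z_mode != "per_slice":
        raise ValueError(f"unknown z_mode {z_mode!r}")
    k = min(k_slices, stack.n_z)
    slice_means = det[:, mask[:, 0], mask[:, 1]].mean(axis=1)
    order = np.argsort(slice_means)[::-1][:k]
    ratios, fields = [], []
    for z in sorted(order):
        vals = means(det[z], sen[z])
        rim_px = det[z][rim[:, 0], rim[:, 1]]
        eps = 3.0 * float(rim_px.std(ddof=1)) / np.sqrt(len(rim)) if len(rim) > 1 else 0.0
        mz = compute_ratio(
            LocusMeasurement(m.locus_id, m.nucleus_id, *vals, epsilon=eps)
        )
        fields.append(vals)
        if mz.valid:
            ratios.append(mz.ratio_gr)
    avg = np.mean(fields, axis=0)
    m = replace(m, i_locus_ch1=float(avg[0]), i_rim_ch1=float(avg[1]),
                i_locus_ch2=float(avg[2]), i_rim_ch2=float(avg[3]),
                n_slices_used=k)
    if not ratios:
        return replace(m, valid=False, reason="no_valid_slice")
    return replace(m, ratio_gr=float(np.mean(ratios)), valid=True)


def measure_all_loci(
    stack: ImageStack,
    loci: list[Locus],
    nucleus_labels: np.ndarray,
    rim_width: int = RIM_WIDTH_DEFAULT,
    z_mode: str = "projection",
    k_slices: int = 3,
    sensor: str = "sensor",
) -> list[LocusMeasurement]:
    """Rim construction + measurement for every locus of one field."""
    frame_invalid = stack.invalid.get(sensor)
    by_nucleus: dict[int, list[Locus]] = {}
    for locus in loci:
        by_nucleus.setdefault(locus.nucleus_id, []).append(locus)

    out = []
    for nid, group in by_nucleus.items():
        nmask = nucleus_labels == nid
        for locus in group:
            others = [o.unified_mask for o in group if o.locus_id != locus.locus_id]
            rim = make_rim(locus.unified_mask, rim_width, nmask, others, frame_invalid)
            if len(rim) == 0:
                logger.info("locus %d: empty rim after exclusions", locus.locus_id)
                out.append(LocusMeasurement(locus.locus_id, nid, reason="empty_rim"))
                continue
            out.append(measure_locus(stack, locus, rim, z_mode=z_mode,
                                     k_slices=k_slices, sensor=sensor))
    out.sort(key=lambda m: m.locus_id)
    return out


def aggregate_cells(
    measurements: list[LocusMeasurement], mode: str = "population"
) -> list[CellRecord]:
    """Group valid locus measurements into per-cell records.

    ``population`` keeps every cell with >= 1 valid locus.  ``allelic``
    keeps only cells with exactly 2 valid loci: cells with more (typically
    replicated loci) or fewer are excluded from allelic analysis.
    """
    if mode not in ("population", "allelic"):
        raise ValueError(f"unknown mode {mode!r}")
    by_nucleus: dict[int, list[LocusMeasurement]] = {}
    for m in measurements:
        if m.valid:
            by_nucleus.setdefault(m.nucleus_id, []).append(m)
    cells = []
    n_excluded = 0
    for nid in sorted(by_nucleus):
        ms = by_nucleus[nid]
        if mode == "allelic" and len(ms) != 2:
            n_excluded += 1
            continue
        cells.append(CellRecord(
            nucleus_id=nid,
            locus_ids=[m.locus_id for m in ms],
            ratios=[m.ratio_gr for m in ms],
        ))
    if n_excluded:
        logger.info("aggregate_cells(allelic): excluded %d cells without exactly 2 valid loci",
                    n_excluded)
    return cells


def measurements_to_frame(measurements: list[LocusMeasurement]) -> pd.DataFrame:
    """Lossless per-locus table (one row per LocusMeasurement)."""
    return pd.DataFrame([vars(m) for m in measurements])
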