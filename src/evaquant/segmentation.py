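"""Nucleus segmentation from the reference channel's diffuse background.

The detector (reference) channel carries enough diffuse nuclear signal
that a smoothed version of it outlines each nucleus.  Segmentation is a
Gaussian smooth, a data-driven global threshold (Otsu by default), hole
filling, and an area filter; touching nuclei can optionally be split by a
watershed on the distance transform.  Nuclei are the per-cell analysis
units of the whole pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation as skseg
from skimage.morphology import h_maxima

logger = logging.getLogger(__name__)

SMOOTH_SIGMA_DEFAULT = 4.0
MIN_AREA_DEFAULT = 500


@dataclass
class NucleusLabelMap:
    """Integer-labeled nucleus segmentation (0 = background) plus a table
    of per-label area, centroid and border-touching flag."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: label, area, centroid_y, centroid_x, border_touching

    @property
    def n_nuclei(self) -> int:
        return len(self.table)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _make_table(labels: np.ndarray) -> pd.DataFrame:
    rows = []
    h, w = labels.shape
    for rp in measure.regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        rows.append(
            {
                "label": rp.label,
                "area": int(rp.area),
                "centroid_y": float(rp.centroid[0]),
                "centroid_x": float(rp.centroid[1]),
                "border_touching": bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "area", "centroid_y", "centroid_x", "border_touching"]
    )


def segment_nuclei(
    reference_projection: np.ndarray,
    smooth_sigma: float = SMOOTH_SIGMA_DEFAULT,
    min_area: int = MIN_AREA_DEFAULT,
    max_area: int | None = None,
    threshold: Callable[[np.ndarray], float] | None = None,
    split_touching: bool = False,
) -> NucleusLabelMap:
    """Segment nuclei from a smoothed reference-channel projection.

    The threshold is data-driven (Otsu unless another callable is given),
    so the result is invariant to adding a constant to the image.  An image
    with no surviving object yields an empty map with a warning, not an
    error.
    """
    img = np.asarray(reference_projection, dtype=float)
    if img.min() < 0:
        raise ValueError("reference projection must be nonnegative")
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    if np.ptp(smoothed) == 0:
        logger.warning("constant image: no nuclei found")
        return NucleusLabelMap(np.zeros(img.shape, dtype=np.int32), _make_table(np.zeros(img.shape, int)))

    thresh_fn = threshold or filters.threshold_otsu
    mask = smoothed > thresh_fn(smoothed)
    mask = ndi.binary_fill_holes(mask)

    if split_touching:
        distance = ndi.distance_transform_edt(mask)
        peaks = h_maxima(distance, h=2.0)
        markers, _ = ndi.label(peaks)
        labels = skseg.watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)
    labels = labels.astype(np.int32)

    # area filter (min again after watershed fragments, plus optional max)
    for rp in measure.regionprops(labels):
        if rp.area < min_area or (max_area is not None and rp.area > max_area):
            labels[labels == rp.label] = 0
    labels, _, _ = skseg.relabel_sequential(labels)
    labels = labels.astype(np.int32)

    if labels.max() == 0:
        logger.warning("no nuclei passed the area filter")
    return NucleusLabelMap(labels, _make_table(labels))


def filter_cells(label_map: NucleusLabelMap, exclude_border: bool = True) -> NucleusLabelMap:
    """Drop border-touching nuclei (optional) and relabel contiguously."""
    if not exclude_border or label_map.table.empty:
        return label_map
    drop = label_map.table.loc[label_map.table.border_touching, "label"].tolist()
    if not drop:
        return label_map
    labels = label_map.labels.copy()
    labels[np.isin(labels, drop)] = 0
    labels, _, _ = skseg.relabel_sequential(labels)
    labels = labels.astype(np.int32)
    logger.info("filter_cells: dropped %d border-touching nuclei", len(drop))
    return NucleusLabelMap(labels, _make_table(labels))
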