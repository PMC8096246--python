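"""Laplacian-of-Gaussian spot detection, cross-channel pairing, and
assignment of loci to nuclei.

Diffraction-limited gene foci are detected on maximum-intensity
projections of each channel with a single-scale, scale-normalized LoG
filter.  The detector (red) channel is authoritative for locus existence;
a matched sensor (green) spot is a measurement, not a requirement — loci
without detectable sensor signal are kept with status ``detector_only`` so
that fully unmethylated alleles remain quantifiable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .segmentation import NucleusLabelMap

logger = logging.getLogger(__name__)

SPOT_DIAMETER_DEFAULT = 5.0
MIN_SNR_DEFAULT = 5.0
MATCH_RADIUS_DEFAULT = 3.0


@dataclass(frozen=True)
class SpotCandidate:
    """A local maximum of the LoG response with its half-max support mask."""

    channel: str
    y: float
    x: float
    sigma: float
    response: float
    mask: np.ndarray  # (n, 2) int pixel coordinates (rows, cols)


@dataclass
class Locus:
    """A gene focus anchored by a detector-channel spot."""

    locus_id: int
    detector_spot: SpotCandidate
    sensor_spot: SpotCandidate | None = None
    nucleus_id: int | None = None
    unified_mask: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    status: str = "detector_only"  # "paired" | "detector_only"

    @property
    def center(self) -> tuple[float, float]:
        return self.detector_spot.y, self.detector_spot.x


def detect_spots(
    channel_projection: np.ndarray,
    expected_diameter: float = SPOT_DIAMETER_DEFAULT,
    min_snr: float = MIN_SNR_DEFAULT,
    channel: str = "",
    max_mask_area: int | None = None,
    min_rel_response: float = 0.05,
) -> list[SpotCandidate]:
    """Detect spots with a single-scale LoG filter.

    The filter scale is sigma = expected_diameter / (2 sqrt(2)), the scale
    at which a Gaussian spot of that diameter maximizes the normalized LoG
    response.  Local maxima are kept when their response exceeds
    ``min_snr`` times the robust noise of the response map (1.4826 x MAD)
    and ``min_rel_response`` times the strongest response in the image.
    Each spot's mask is the connected response region above half its peak.

    Intensity edges (e.g. the nucleus boundary) also excite the LoG; their
    half-max regions are elongated bands rather than compact blobs, so
    candidates whose mask exceeds ``max_mask_area`` (default 4 pi sigma^2,
    about 4x a matched spot's support) or runs out of the local analysis
    window are rejected.  The LoG of a constant is zero, so detection is
    invariant to intensity offsets.
    """
    if expected_diameter < 3:
        raise ValueError(f"expected_diameter must be >= 3 px, got {expected_diameter}")
    img = np.asarray(channel_projection, dtype=float)
    h, w = img.shape
    sigma = expected_diameter / (2.0 * math.sqrt(2.0))
    if max_mask_area is None:
        max_mask_area = int(math.ceil(4.0 * math.pi * sigma**2))
    # negated, scale-normalized LoG: bright blobs -> positive peaks
    response = -(sigma**2) * ndi.gaussian_laplace(img, sigma)

    peak_max = response.max()
    med = np.median(response)
    noise = 1.4826 * np.median(np.abs(response - med))
    if peak_max <= 0 or (noise == 0 and peak_max <= med):
        return []
    threshold = max(med + min_snr * noise, min_rel_response * peak_max)

    peaks = peak_local_max(
        response,
        min_distance=max(1, int(round(sigma))),
        threshold_abs=threshold,
        exclude_border=False,
    )
    win = int(math.ceil(6 * sigma))
    spots: list[SpotCandidate] = []
    for py, px in peaks:
        peak_val = response[py, px]
        y0, y1 = max(0, py - win), min(h, py + win + 1)
        x0, x1 = max(0, px - win), min(w, px + win + 1)
        region, _ = ndi.label(response[y0:y1, x0:x1] >= 0.5 * peak_val)
        comp = region == region[py - y0, px - x0]
        if comp.sum() > max_mask_area:
            continue  # elongated band or merged blob, not a spot
        if _touches_interior_border(comp, y0, y1, x0, x1, h, w):
            continue  # extends beyond the analysis window: an edge band
        mask = np.argwhere(comp)
        weights = response[y0:y1, x0:x1][comp]
        cy = float(np.average(mask[:, 0], weights=weights)) + y0
        cx = float(np.average(mask[:, 1], weights=weights)) + x0
        mask[:, 0] += y0
        mask[:, 1] += x0
        spots.append(SpotCandidate(channel, cy, cx, sigma, float(peak_val), mask))
    spots.sort(key=lambda s: (s.y, s.x))
    return spots


def _touches_interior_border(comp: np.ndarray, y0: int, y1: int, x0: int, x1: int,
                             h: int, w: int) -> bool:
    """True when a component reaches a window edge that is not a frame edge."""
    return (
        (y0 > 0 and comp[0, :].any())
        or (y1 < h and comp[-1, :].any())
        or (x0 > 0 and comp[:, 0].any())
        or (x1 < w and comp[:, -1].any())
    )


def match_loci(
    detector_spots: list[SpotCandidate],
    sensor_spots: list[SpotCandidate],
    match_radius: float = MATCH_RADIUS_DEFAULT,
) -> list[Locus]:
    """Pair detector and sensor spots greedily by distance, each used once.

    Unpaired detector spots stay as ``detector_only`` loci (their sensor
    intensity is later measured on the detector-defined mask); unpaired
    sensor spots are discarded with a logged count.  Ties are broken by
    smallest distance, then lowest indices, so matching is deterministic
    and symmetric in the two lists.
    """
    pairs = []
    for i, d in enumerate(detector_spots):
        for j, s in enumerate(sensor_spots):
            dist = math.hypot(d.y - s.y, d.x - s.x)
            if dist <= match_radius:
                pairs.append((dist, i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_s: set[int] = set()
    assigned: dict[int, int] = {}
    for dist, i, j in pairs:
        if i in used_d or j in used_s:
            continue
        used_d.add(i)
        used_s.add(j)
        assigned[i] = j

    loci = []
    for i, d in enumerate(detector_spots):
        if i in assigned:
            s = sensor_spots[assigned[i]]
            mask = np.unique(np.vstack([d.mask, s.mask]), axis=0)
            loci.append(Locus(i, d, s, unified_mask=mask, status="paired"))
        else:
            loci.append(Locus(i, d, None, unified_mask=d.mask.copy(),
                              status="detector_only"))
    n_dropped = len(sensor_spots) - len(used_s)
    if n_dropped:
        logger.info("match_loci: %d sensor-only spots discarded", n_dropped)
    return loci


def assign_to_nuclei(loci: list[Locus], label_map: NucleusLabelMap) -> list[Locus]:
    """Attach each locus to the nucleus under its detector-spot center.

    Loci on background (label 0) are discarded with a logged count; the
    unified mask is clipped to the nucleus.
    """
    labels = label_map.labels
    h, w = labels.shape
    kept = []
    n_dropped = 0
    for locus in loci:
        y = int(round(locus.detector_spot.y))
        x = int(round(locus.detector_spot.x))
        if not (0 <= y < h and 0 <= x < w) or labels[y, x] == 0:
            n_dropped += 1
            continue
        nid = int(labels[y, x])
        m = locus.unified_mask
        inside = labels[m[:, 0], m[:, 1]] == nid
        kept.append(replace_locus(locus, nucleus_id=nid, unified_mask=m[inside]))
    if n_dropped:
        logger.info("assign_to_nuclei: %d loci on background discarded", n_dropped)
    return kept


def replace_locus(locus: Locus, **kw) -> Locus:
    return replace(locus, **kw)
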