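"""Ground-truth synthetic specimens for the ratio-imaging pipeline.

Renders fields of elliptical nuclei with textured diffuse background,
diffraction-limited gene foci (isotropic Gaussians at the PSF scale) in a
detector and a sensor channel, an additive background gradient, a global
chromatic translation of the sensor channel, and Poisson shot noise plus
Gaussian read noise.  Every focus's true sensor/detector ratio, position
and amplitude are recorded in a truth table, so each downstream stage can
be tested by parameter recovery with no real microscopy data.

Condition generators mirror the assay's experimental designs: a
labeled-fraction mixing series (dynamic-range calibration, where the true
ratio is proportional to the labeled fraction) and heterozygous two-focus
nuclei whose two alleles differ by a known fold (with an auxiliary
RNA-positivity channel marking the low allele).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack

logger = logging.getLogger(__name__)

MAX_INTENSITY = 65535.0  # 16-bit camera range


@dataclass
class SimParams:
    """Parameters of one synthetic specimen (all intensities in counts).

    image_shape         (Y, X) frame size in pixels
    n_z_slices          number of optical slices (>= 1)
    n_nuclei            nuclei per field
    nucleus_axes        (min, max) of ellipse semi-axes, pixels
    foci_per_nucleus    focus count per nucleus, int or inclusive (lo, hi)
    true_ratio          ground-truth sensor/detector ratio: scalar applied
                        to all foci, or a sequence sampled per focus
    detector_amplitude  focus peak amplitude above background, detector ch.
    psf_sigma           Gaussian PSF sigma, pixels (isotropic, also in z)
    background_level    additive camera/sample background, counts
    background_gradient additive slope along x, counts/pixel
    chromatic_shift     (dy, dx) translation applied to the sensor channel
    shot_noise          apply Poisson noise to the rendered signal
    read_sigma          Gaussian read-noise SD, counts (0 disables)
    nucleus_level       diffuse interior intensity (detector, sensor); the
                        detector term is what makes nuclei segmentable
    texture_strength    relative amplitude of the smooth nuclear texture
    texture_sigma       correlation length of the texture, pixels
    min_separation      minimum focus-focus distance in PSF sigmas
    seed                RNG seed; fully determines the output
    condition_label     free-text label copied into the truth table
    """

    image_shape: tuple[int, int] = (512, 512)
    n_z_slices: int = 5
    n_nuclei: int = 8
    nucleus_axes: tuple[float, float] = (18.0, 30.0)
    foci_per_nucleus: int | tuple[int, int] = (1, 4)
    true_ratio: float | tuple[float, ...] = 1.0
    detector_amplitude: float = 2000.0
    psf_sigma: float = 1.5
    background_level: float = 200.0
    background_gradient: float = 0.05
    chromatic_shift: tuple[float, float] = (1.5, -1.0)
    shot_noise: bool = True
    read_sigma: float = 10.0
    nucleus_level: tuple[float, float] = (300.0, 50.0)
    texture_strength: float = 0.15
    texture_sigma: float = 15.0
    min_separation: float = 6.0
    seed: int = 0
    condition_label: str = ""

    def validate(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError(f"psf_sigma must be > 0, got {self.psf_sigma}")
        for name in ("detector_amplitude", "background_level", "read_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_z_slices < 1:
            raise ValueError("n_z_slices must be >= 1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        ratios = np.atleast_1d(np.asarray(self.true_ratio, dtype=float))
        if (ratios < 0).any():
            raise ValueError("true_ratio values must be >= 0")
        lo, hi = self._foci_range()
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid foci_per_nucleus {self.foci_per_nucleus}")

    def _foci_range(self) -> tuple[int, int]:
        if isinstance(self.foci_per_nucleus, (tuple, list)):
            return int(self.foci_per_nucleus[0]), int(self.foci_per_nucleus[1])
        return int(self.foci_per_nucleus), int(self.foci_per_nucleus)


@dataclass(frozen=True)
class _Nucleus:
    nucleus_id: int
    cy: float
    cx: float
    a: float  # semi-axis along the rotated y'
    b: float
    theta: float


@dataclass(frozen=True)
class _Focus:
    nucleus_id: int
    z: int
    y: float
    x: float
    true_ratio: float
    amplitude: float
    rna_positive: bool = False


def generate_specimen(params: SimParams):
    """Render one field: (ImageStack, truth label map, truth table).

    The detector channel contains Gaussian foci of ``detector_amplitude``;
    the sensor channel contains the same foci scaled by their true ratio
    and translated by ``chromatic_shift`` (the shift is applied by
    rendering at the shifted coordinates, so no interpolation is
    involved); noise is applied last.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nuclei = _place_nuclei(params, rng)
    foci = _place_foci(params, nuclei, rng)
    stack, labels = _render(params, nuclei, foci, rng)
    truth = _truth_table(params, foci)
    return stack, labels, truth


def generate_mixing_series(
    fractions,
    n_nuclei_per_condition: int,
    params: SimParams,
    ratio_scale: float = 1.0,
    foci_per_nucleus: int | tuple[int, int] = 4,
):
    """One specimen per labeled fraction; true ratio = fraction x scale.

    Emulates a dynamic-range calibration in which labeled sensor oligo is
    mixed with unlabeled oligo at the given fractions (0 = floor,
    1 = ceiling).  Returns a list of (fraction, (stack, labels, truth)).
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions list is empty")
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    out = []
    for i, f in enumerate(fractions):
        p = dataclasses.replace(
            params,
            true_ratio=f * ratio_scale,
            n_nuclei=n_nuclei_per_condition,
            foci_per_nucleus=foci_per_nucleus,
            seed=params.seed + i,
            condition_label=f"{f:g}",
        )
        out.append((f, generate_specimen(p)))
    return out


def generate_allelic_specimen(
    fold_difference: float,
    n_nuclei: int,
    params: SimParams,
    rna_amplitude: float = 1500.0,
    rna_sigma_factor: float = 2.5,
):
    """Heterozygous nuclei: 2 foci each, alleles differing by a known fold.

    Per nucleus one focus is tagged RNA-positive; its true ratio is the
    RNA-negative ratio divided by ``fold_difference``.  A third ("rna")
    channel carries a broader Gaussian blob at the RNA-positive focus so
    the tag can be recovered by mask overlap, as with an RNA FISH
    counterstain.  Returns (ImageStack with channels detector/sensor/rna,
    truth label map, truth table with an ``rna_positive`` column).
    """
    if fold_difference <= 0:
        raise ValueError(f"fold_difference must be > 0, got {fold_difference}")
    base_ratio = float(np.mean(np.atleast_1d(np.asarray(params.true_ratio, float))))
    p = dataclasses.replace(params, n_nuclei=n_nuclei, foci_per_nucleus=2)
    p.validate()
    rng = np.random.default_rng(p.seed)
    nuclei = _place_nuclei(p, rng)
    foci = _place_foci(p, nuclei, rng)

    # retag: per nucleus, one random focus is RNA+ with ratio / fold
    tagged: list[_Focus] = []
    by_nucleus: dict[int, list[_Focus]] = {}
    for f in foci:
        by_nucleus.setdefault(f.nucleus_id, []).append(f)
    for nid in sorted(by_nucleus):
        pair = by_nucleus[nid]
        pos_idx = int(rng.integers(0, 2))
        for i, f in enumerate(pair):
            is_pos = i == pos_idx
            ratio = base_ratio / fold_difference if is_pos else base_ratio
            tagged.append(dataclasses.replace(f, true_ratio=ratio, rna_positive=is_pos))

    stack, labels = _render(p, nuclei, tagged, rng, rna_channel=True,
                            rna_amplitude=rna_amplitude,
                            rna_sigma=rna_sigma_factor * p.psf_sigma)
    truth = _truth_table(p, tagged, rna=True)
    return stack, labels, truth


# ---------------------------------------------------------------- placement

def _place_nuclei(params: SimParams, rng: np.random.Generator) -> list[_Nucleus]:
    h, w = params.image_shape
    lo, hi = params.nucleus_axes
    nuclei: list[_Nucleus] = []
    for nid in range(1, params.n_nuclei + 1):
        placed = False
        for _ in range(500):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            r = max(a, b)
            margin = r + 6  # keep nuclei fully inside the frame
            if 2 * margin >= min(h, w):
                break
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            theta = rng.uniform(0, math.pi)
            if all(
                math.hypot(cy - n.cy, cx - n.cx) > r + max(n.a, n.b) + 4
                for n in nuclei
            ):
                nuclei.append(_Nucleus(nid, cy, cx, a, b, theta))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place nucleus {nid}/{params.n_nuclei} in a "
                f"{h}x{w} frame; reduce n_nuclei or nucleus_axes"
            )
    return nuclei


def _inside_ellipse(n: _Nucleus, y: float, x: float, scale: float = 1.0) -> bool:
    dy, dx = y - n.cy, x - n.cx
    u = dy * math.cos(n.theta) + dx * math.sin(n.theta)
    v = -dy * math.sin(n.theta) + dx * math.cos(n.theta)
    return (u / (n.a * scale)) ** 2 + (v / (n.b * scale)) ** 2 <= 1.0


def _place_foci(params: SimParams, nuclei: list[_Nucleus],
                rng: np.random.Generator) -> list[_Focus]:
    lo, hi = params._foci_range()
    ratios = np.atleast_1d(np.asarray(params.true_ratio, dtype=float))
    min_sep = params.min_separation * params.psf_sigma
    # foci (plus their rims) must stay well inside the nucleus
    inner_margin = 5 + 3 * params.psf_sigma

    foci: list[_Focus] = []
    z_lo = 1 if params.n_z_slices >= 3 else 0
    z_hi = params.n_z_slices - 2 if params.n_z_slices >= 3 else params.n_z_slices - 1
    for n in nuclei:
        n_f = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        shrink = 1.0 - inner_margin / min(n.a, n.b)
        if n_f > 0 and shrink <= 0.05:
            raise ValueError(
                f"nucleus {n.nucleus_id} (axes {n.a:.0f}x{n.b:.0f}) too small "
                f"to hold foci with a {inner_margin:.0f}px interior margin"
            )
        mine: list[_Focus] = []
        for _ in range(n_f):
            placed = False
            for _ in range(500):
                y = rng.uniform(n.cy - n.a, n.cy + n.a)
                x = rng.uniform(n.cx - max(n.a, n.b), n.cx + max(n.a, n.b))
                if not _inside_ellipse(n, y, x, scale=shrink):
                    continue
                if all(math.hypot(y - f.y, x - f.x) >= min_sep for f in mine):
                    z = int(rng.integers(z_lo, z_hi + 1))
                    ratio = float(ratios[0]) if ratios.size == 1 else float(rng.choice(ratios))
                    mine.append(_Focus(n.nucleus_id, z, y, x, ratio,
                                       params.detector_amplitude))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place {n_f} separated foci in nucleus "
                    f"{n.nucleus_id}; nucleus too small for min_separation"
                )
        foci.extend(mine)
    return foci


# ---------------------------------------------------------------- rendering

def _render(params: SimParams, nuclei: list[_Nucleus], foci: list[_Focus],
            rng: np.random.Generator, rna_channel: bool = False,
            rna_amplitude: float = 0.0, rna_sigma: float = 0.0):
    h, w = params.image_shape
    nz = params.n_z_slices
    yy, xx = np.mgrid[0:h, 0:w]

    labels = np.zeros((h, w), dtype=np.int32)
    for n in nuclei:
        dy, dx = yy - n.cy, xx - n.cx
        u = dy * math.cos(n.theta) + dx * math.sin(n.theta)
        v = -dy * math.sin(n.theta) + dx * math.cos(n.theta)
        inside = (u / n.a) ** 2 + (v / n.b) ** 2 <= 1.0
        labels[inside] = n.nucleus_id

    # shared chromatin-like texture: smooth random field, unit SD
    texture = np.ones((h, w))
    if params.texture_strength > 0:
        field = ndi.gaussian_filter(rng.standard_normal((h, w)), params.texture_sigma)
        sd = field.std()
        if sd > 0:
            field /= sd
        texture = np.clip(1.0 + params.texture_strength * field, 0.2, None)

    base = params.background_level + params.background_gradient * xx
    det2d = base + params.nucleus_level[0] * texture * (labels > 0)
    sen2d = base + params.nucleus_level[1] * texture * (labels > 0)

    det = np.repeat(det2d[np.newaxis], nz, axis=0)
    sen = np.repeat(sen2d[np.newaxis], nz, axis=0)
    dy_c, dx_c = params.chromatic_shift
    for f in foci:
        _add_gaussian(det, f.z, f.y, f.x, f.amplitude, params.psf_sigma)
        _add_gaussian(sen, f.z, f.y + dy_c, f.x + dx_c,
                      f.amplitude * f.true_ratio, params.psf_sigma)

    channels = [det, sen]
    names = ["detector", "sensor"]
    if rna_channel:
        rna = np.repeat((params.background_level * 0.5 * np.ones((h, w)))[np.newaxis],
                        nz, axis=0)
        for f in foci:
            if f.rna_positive:
                _add_gaussian(rna, f.z, f.y, f.x, rna_amplitude, rna_sigma)
        channels.append(rna)
        names.append("rna")

    data = np.stack(channels)
    if params.shot_noise:
        data = rng.poisson(data).astype(float)
    if params.read_sigma > 0:
        data = data + rng.normal(0.0, params.read_sigma, size=data.shape)
    data = np.clip(data, 0.0, MAX_INTENSITY)
    return ImageStack(data, tuple(names)), labels


def _add_gaussian(vol: np.ndarray, zc: int, yc: float, xc: float,
                  amplitude: float, sigma: float) -> None:
    """Add an isotropic 3D Gaussian (2D if single slice) in place."""
    if amplitude == 0:
        return
    nz, h, w = vol.shape
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(yc) - r), min(h, int(yc) + r + 1)
    x0, x1 = max(0, int(xc) - r), min(w, int(xc) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    radial = np.exp(-((yy - yc) ** 2 + (xx - xc) ** 2) / (2 * sigma**2))
    if nz == 1:
        vol[0, y0:y1, x0:x1] += amplitude * radial
        return
    for z in range(nz):
        az = amplitude * math.exp(-((z - zc) ** 2) / (2 * sigma**2))
        if az > 1e-6 * amplitude:
            vol[z, y0:y1, x0:x1] += az * radial


def _truth_table(params: SimParams, foci: list[_Focus], rna: bool = False) -> pd.DataFrame:
    rows = [
        {
            "nucleus_id": f.nucleus_id,
            "z": f.z,
            "y": f.y,
            "x": f.x,
            "true_ratio": f.true_ratio,
            "detector_amplitude": f.amplitude,
            "condition_label": params.condition_label,
            **({"rna_positive": f.rna_positive} if rna else {}),
        }
        for f in foci
    ]
    cols = ["nucleus_id", "z", "y", "x", "true_ratio", "detector_amplitude",
            "condition_label"] + (["rna_positive"] if rna else [])
    return pd.DataFrame(rows, columns=cols)
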