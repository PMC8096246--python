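"""Inter-channel translation registration (chromatic-shift correction).

Fluorophores of different emission wavelengths are imaged with a small
lateral offset (chromatic shift).  Before any locus measurement the sensor
channel is registered to the detector channel by a single field-wide 2D
translation, estimated by normalized cross-correlation with quadratic
subpixel refinement.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .io import ImageStack

logger = logging.getLogger(__name__)

MAX_SHIFT_DEFAULT = 10.0


class Shift(NamedTuple):
    """Translation in pixels: moving ≈ reference displaced by (dy, dx)."""

    dy: float
    dx: float


def estimate_shift(reference_plane: np.ndarray, moving_plane: np.ndarray,
                   max_shift: float = MAX_SHIFT_DEFAULT) -> Shift:
    """Translation maximizing the cross-correlation of mean-subtracted planes.

    The correlation is evaluated on the full integer grid via FFT,
    constrained to |dy|,|dx| <= max_shift, then refined to subpixel
    precision by a 1D quadratic fit through the peak and its neighbors
    along each axis.
    """
    a = np.asarray(reference_plane, dtype=float)
    b = np.asarray(moving_plane, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError(f"planes must share a nonempty shape, got {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    if not a.any() or not b.any():
        raise ValueError("no registration signal: a plane has zero variance")

    # c[dy, dx] = sum_{u,v} a[u, v] * b[u+dy, v+dx]  (circular)
    c = np.fft.irfft2(np.conj(np.fft.rfft2(a)) * np.fft.rfft2(b), s=a.shape)

    m = int(np.floor(max_shift))
    window = c[np.ix_(_wrap_range(m, a.shape[0]), _wrap_range(m, a.shape[1]))]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy = float(iy - m) + _quadratic_offset(window[:, ix], iy)
    dx = float(ix - m) + _quadratic_offset(window[iy, :], ix)
    dy = float(np.clip(dy, -max_shift, max_shift))
    dx = float(np.clip(dx, -max_shift, max_shift))
    logger.debug("estimated shift dy=%.3f dx=%.3f", dy, dx)
    return Shift(dy, dx)


def _wrap_range(m: int, n: int) -> np.ndarray:
    """Indices of circular-correlation lags -m..m in an axis of length n."""
    return np.arange(-m, m + 1) % n


def _quadratic_offset(profile: np.ndarray, i: int) -> float:
    """Subpixel offset of a peak at index i from a 3-point parabola fit."""
    if i == 0 or i == len(profile) - 1:
        return 0.0
    lo, mid, hi = profile[i - 1], profile[i], profile[i + 1]
    denom = lo - 2 * mid + hi
    if denom >= 0:  # not a proper maximum
        return 0.0
    off = 0.5 * (lo - hi) / denom
    return float(np.clip(off, -0.5, 0.5))


def apply_shift(stack: ImageStack, channel: str, shift: Shift,
                max_shift: float = MAX_SHIFT_DEFAULT) -> ImageStack:
    """Resample one channel by the inverse of ``shift`` to align it.

    Fractional shifts use linear interpolation; integer shifts are exact
    array rolls with border fill.  Out-of-frame pixels are filled with the
    channel's median and flagged invalid so rims never sample them.
    """
    if not (np.isfinite(shift.dy) and np.isfinite(shift.dx)):
        raise ValueError(f"non-finite shift {shift}")
    if abs(shift.dy) > max_shift or abs(shift.dx) > max_shift:
        raise ValueError(f"shift {shift} exceeds max_shift {max_shift}")
    data = stack.channel(channel)
    if shift.dy == 0 and shift.dx == 0:
        return stack

    fill = float(np.median(data))
    out = np.empty_like(data)
    integer = float(shift.dy).is_integer() and float(shift.dx).is_integer()
    for z in range(data.shape[0]):
        if integer:
            out[z] = _roll_fill(data[z], -int(shift.dy), -int(shift.dx), fill)
        else:
            out[z] = ndi.shift(data[z], (-shift.dy, -shift.dx), order=1,
                               mode="constant", cval=fill)
    invalid = _border_invalid_mask(data.shape[1:], shift)
    return stack.with_channel(channel, out, invalid=invalid)


def _roll_fill(plane: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(plane, fill)
    ys = slice(max(dy, 0), plane.shape[0] + min(dy, 0))
    xs = slice(max(dx, 0), plane.shape[1] + min(dx, 0))
    ys_src = slice(max(-dy, 0), plane.shape[0] + min(-dy, 0))
    xs_src = slice(max(-dx, 0), plane.shape[1] + min(-dx, 0))
    out[ys, xs] = plane[ys_src, xs_src]
    return out


def _border_invalid_mask(shape: tuple[int, int], shift: Shift) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    my = int(np.ceil(abs(shift.dy)))
    mx = int(np.ceil(abs(shift.dx)))
    if my:
        if shift.dy > 0:
            mask[-my:, :] = True
        else:
            mask[:my, :] = True
    if mx:
        if shift.dx > 0:
            mask[:, -mx:] = True
        else:
            mask[:, :mx] = True
    return mask
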