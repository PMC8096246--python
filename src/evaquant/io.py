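"""Image stacks, TIFF I/O and specimen manifests.

The in-memory container is :class:`ImageStack`: named channels over an
optionally z-stacked raster, stored internally as a float array with axis
order (C, Z, Y, X).  Stacks are written to multi-page TIFF with axes
``ZCYX`` and the channel names recorded in the file's shaped metadata, so
simulator output round-trips exactly.

A :class:`SpecimenManifest` (YAML) assigns each image file a role in the
experiment — test, negative control (no antibody / no exonuclease) or a
calibration condition labeled with its mixing fraction — plus the channel
name → index mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

ROLES = ("test", "no_antibody_control", "no_exonuclease_control")


@dataclass
class ImageStack:
    """Named-channel, optionally z-stacked raster of nonnegative intensities.

    data      float array, axis order (C, Z, Y, X)
    channels  channel names, index-aligned with axis 0
    invalid   optional per-channel 2D masks of pixels made unreliable by
              resampling (e.g. border fill after registration); such pixels
              are excluded from rim background estimates
    """

    data: np.ndarray
    channels: tuple[str, ...]
    invalid: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C,Z,Y,X), got shape {self.data.shape}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None

    def channel(self, name: str) -> np.ndarray:
        """(Z, Y, X) view of one channel."""
        return self.data[self.index(name)]

    def projection(self, name: str) -> np.ndarray:
        """Maximum-intensity projection of one channel over z."""
        return self.channel(name).max(axis=0)

    def with_channel(self, name: str, data: np.ndarray,
                     invalid: np.ndarray | None = None) -> "ImageStack":
        """Copy of the stack with one channel's data replaced."""
        new = self.data.copy()
        new[self.index(name)] = data
        inv = dict(self.invalid)
        if invalid is not None:
            inv[name] = invalid
        return ImageStack(new, self.channels, inv)


def write_stack(stack: ImageStack, path) -> None:
    """Write as multi-page TIFF, axes ZCYX, channel names in metadata."""
    arr = np.ascontiguousarray(stack.data.transpose(1, 0, 2, 3)).astype(np.float32)
    tifffile.imwrite(
        str(path),
        arr,
        metadata={"axes": "ZCYX", "channels": list(stack.channels)},
    )


def read_stack(path, channel_names: tuple[str, ...] | None = None) -> ImageStack:
    """Read a 2-4 channel, optionally z-stacked TIFF into an ImageStack.

    Axis order is taken from the file's metadata when present; otherwise it
    is inferred, treating a trailing axis of length <= 4 on a large 3D array
    as interleaved channels (RGB dialect) and a leading small axis as
    channels-first.  ``channel_names`` (e.g. from the manifest) overrides
    names stored in the file and must match the channel count.
    """
    path = str(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    axes = meta.get("axes")
    stored_names = meta.get("channels")

    if axes:
        arr = _to_czyx_from_axes(arr, axes)
    else:
        arr = _to_czyx_heuristic(arr, channel_names)

    n_c = arr.shape[0]
    if not 1 <= n_c <= 4:
        raise ValueError(f"{path}: {n_c} channels outside the supported 1-4 range")
    if channel_names is not None:
        if len(channel_names) != n_c:
            raise ValueError(
                f"{path}: manifest names {len(channel_names)} channels "
                f"{tuple(channel_names)} but file has {n_c}"
            )
        names = tuple(channel_names)
    elif stored_names:
        names = tuple(stored_names)
    else:
        names = tuple(f"ch{i}" for i in range(n_c))
    return ImageStack(np.clip(arr.astype(float), 0, None), names)


def _to_czyx_from_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    axes = axes.upper()
    if arr.ndim != len(axes):
        raise ValueError(f"axes {axes!r} do not match array ndim {arr.ndim}")
    if set(axes) - set("CZYX"):
        raise ValueError(f"unsupported axes {axes!r}")
    for missing in set("CZYX") - set(axes):
        arr = arr[np.newaxis]
        axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    return arr.transpose(order)


def _to_czyx_heuristic(arr: np.ndarray, channel_names) -> np.ndarray:
    if arr.ndim == 2:  # single plane, single channel
        return arr[np.newaxis, np.newaxis]
    if arr.ndim == 3:
        if arr.shape[-1] <= 4 < arr.shape[0]:  # (Y, X, C) interleaved dialect
            return arr.transpose(2, 0, 1)[:, np.newaxis]
        if arr.shape[0] <= 4:  # (C, Y, X)
            return arr[:, np.newaxis]
        raise ValueError(f"cannot infer channel axis for shape {arr.shape}")
    if arr.ndim == 4:
        # assume (Z, C, Y, X) when the second axis is small, else (C, Z, Y, X)
        if arr.shape[1] <= 4:
            return arr.transpose(1, 0, 2, 3)
        if arr.shape[0] <= 4:
            return arr
    raise ValueError(f"cannot interpret TIFF of shape {arr.shape}")


def write_label_map(labels: np.ndarray, path) -> None:
    """Write a nucleus label map as a 16-bit single-channel TIFF."""
    tifffile.imwrite(str(path), labels.astype(np.uint16))


@dataclass(frozen=True)
class SpecimenEntry:
    path: str
    role: str  # test | no_antibody_control | no_exonuclease_control | calibration:<f>
    label: str

    @property
    def calibration_fraction(self) -> float | None:
        if self.role.startswith("calibration:"):
            return float(self.role.split(":", 1)[1])
        return None


@dataclass
class SpecimenManifest:
    """Which image plays which role, and how channels are named."""

    channels: dict[str, int]  # name -> index in file
    specimens: list[SpecimenEntry]
    pixel_size_um: float | None = None
    z_step_um: float | None = None

    def __post_init__(self):
        if "detector" not in self.channels or "sensor" not in self.channels:
            raise ValueError("channel map must name 'detector' and 'sensor'")
        for s in self.specimens:
            if s.role not in ROLES and s.calibration_fraction is None:
                raise ValueError(f"{s.path}: unknown role {s.role!r}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.channels, key=self.channels.get))

    def by_role(self, role: str) -> list[SpecimenEntry]:
        return [s for s in self.specimens if s.role == role]

    def calibration_series(self) -> dict[float, list[SpecimenEntry]]:
        out: dict[float, list[SpecimenEntry]] = {}
        for s in self.specimens:
            f = s.calibration_fraction
            if f is not None:
                out.setdefault(f, []).append(s)
        return out


def load_manifest(path) -> SpecimenManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    specimens = [
        SpecimenEntry(
            path=str((base / s["path"]).resolve()) if not Path(s["path"]).is_absolute()
            else s["path"],
            role=str(s["role"]),
            label=str(s.get("label", Path(s["path"]).stem)),
        )
        for s in raw["specimens"]
    ]
    return SpecimenManifest(
        channels={str(k): int(v) for k, v in raw["channels"].items()},
        specimens=specimens,
        pixel_size_um=raw.get("pixel_size_um"),
        z_step_um=raw.get("z_step_um"),
    )
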