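"""Image stack I/O and projection.

Multi-channel confocal z-stacks are stored as multi-page TIFF with
channel-first page order (all z of channel 0, then channel 1, ...). Physical
pixel sizes and the channel-role map travel in the TIFF ImageDescription tag
as JSON, so a written stack round-trips without a sidecar; a sidecar metadata
dict may override or supply missing fields for third-party files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: Channel roles understood by the analysis modules.
CHANNEL_ROLES = ("nuclear", "membrane", "reporter", "marker", "boundary")


class StackFormatError(ValueError):
    """Raised when a TIFF cannot be interpreted as an image stack."""


class MetadataError(ValueError):
    """Raised when pixel-size or channel-role metadata is missing/invalid."""


class ChannelRoleError(KeyError):
    """Raised when a requested channel role is absent or inconsistent."""


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack with physical calibration.

    Parameters
    ----------
    data
        Intensity array indexed ``(channel, z, y, x)``.
    pixel_size_um
        Lateral pixel size in micrometres (x and y assumed equal).
    z_step_um
        Axial step between consecutive z-slices, micrometres.
    channel_roles
        Map from role name (``nuclear``, ``membrane``, ``reporter``,
        ``marker``, ``boundary``) to channel index.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise StackFormatError(
                f"stack data must be 4D (channel, z, y, x); got {self.data.ndim}D"
            )
        if min(self.data.shape) < 1:
            raise StackFormatError(f"all dimensions must be >= 1; got {self.data.shape}")
        if not self.pixel_size_um > 0:
            raise MetadataError(f"pixel size must be > 0 um; got {self.pixel_size_um}")
        if not self.z_step_um > 0:
            raise MetadataError(f"z-step must be > 0 um; got {self.z_step_um}")
        for role, idx in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ChannelRoleError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
            if not 0 <= idx < self.data.shape[0]:
                raise ChannelRoleError(
                    f"role {role!r} maps to channel {idx}, but the stack has "
                    f"{self.data.shape[0]} channels"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a channel role."""
        if role not in self.channel_roles:
            raise ChannelRoleError(
                f"stack declares no {role!r} channel (roles: {sorted(self.channel_roles)})"
            )
        return self.data[self.channel_roles[role]]

    def depth_to_index(self, depth_um: float) -> int:
        """Convert an axial depth in micrometres to a z index (floor)."""
        return int(np.floor(depth_um / self.z_step_um))


@dataclass
class MaskSet:
    """A labeled mask aligned to one ``(z, y, x)`` or ``(y, x)`` frame.

    ``labels`` maps each positive integer label present in the array to an
    object identifier (e.g. a cell id). Background is 0.
    """

    mask: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim not in (2, 3):
            raise StackFormatError("mask must be 2D (y,x) or 3D (z,y,x)")
        present = np.unique(self.mask)
        present = present[present != 0]
        if present.size and present.min() < 0:
            raise ValueError("labels must be positive integers (background 0)")
        if not self.labels:
            self.labels = {int(v): str(int(v)) for v in present}
        else:
            missing = set(int(v) for v in present) - set(self.labels)
            if missing:
                raise ValueError(f"labels present in mask but not in table: {sorted(missing)}")

    def binary(self, label: int) -> np.ndarray:
        return self.mask == label


def write_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` to a multi-page TIFF.

    Pages are ordered channel-first; calibration and channel roles are stored
    as JSON in the ImageDescription tag.
    """
    meta = {
        "axes": "CZYX",
        "shape": list(stack.data.shape),
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channel_roles": stack.channel_roles,
    }
    c, z, y, x = stack.data.shape
    pages = stack.data.reshape(c * z, y, x)
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_stack(path, metadata: dict | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Parameters
    ----------
    path
        TIFF file path.
    metadata
        Optional sidecar dict supplying/overriding ``pixel_size_um``,
        ``z_step_um``, ``channel_roles`` and (for files written elsewhere)
        ``shape`` as ``[c, z, y, x]``. Required keys missing from both the
        embedded tag and the sidecar raise :class:`MetadataError`.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            desc = tf.pages[0].description
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise StackFormatError(f"cannot read TIFF stack {path}: {exc}") from exc

    embedded: dict = {}
    if desc:
        try:
            embedded = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            embedded = {}
    meta = {**embedded, **(metadata or {})}

    for key in ("pixel_size_um", "z_step_um"):
        if key not in meta:
            raise MetadataError(f"{key} missing from TIFF tags and sidecar metadata")
    roles = meta.get("channel_roles", {})

    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim == 4:  # tifffile reshaped from its own JSON description
        pages = pages.reshape(-1, *pages.shape[-2:])
    if pages.ndim != 3:
        raise StackFormatError(f"unexpected TIFF page array of ndim {pages.ndim}")

    if "shape" in meta:
        c, z, y, x = (int(v) for v in meta["shape"])
        if pages.shape != (c * z, y, x):
            raise StackFormatError(
                f"declared shape {meta['shape']} inconsistent with {pages.shape[0]} "
                f"pages of {pages.shape[1:]}"
            )
    else:
        # Without a declared layout, treat pages as a single-channel z-series.
        c, z = 1, pages.shape[0]
        y, x = pages.shape[1:]
    if roles and any(int(i) >= c for i in roles.values()):
        raise ChannelRoleError(
            f"channel roles {roles} reference channels beyond the {c} present"
        )

    return ImageStack(
        data=pages.reshape(c, z, y, x),
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        channel_roles={k: int(v) for k, v in roles.items()},
    )


def max_intensity_projection(
    stack: ImageStack, channel: str, z_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Maximum intensity projection (MIP) of one channel over a z-range.

    ``z_range`` is a half-open index interval ``[z0, z1)``; ``None`` projects
    the full depth. Intensity units are unchanged:
    ``out[y, x] = max_z in[z, y, x]``.
    """
    vol = stack.channel(channel)
    if z_range is None:
        z0, z1 = 0, vol.shape[0]
    else:
        z0, z1 = z_range
    if not 0 <= z0 < z1 <= vol.shape[0]:
        raise ValueError(
            f"z-range [{z0}, {z1}) empty or outside stack depth {vol.shape[0]}"
        )
    return vol[z0:z1].max(axis=0)


def substack(stack: ImageStack, z0: int, z1: int) -> ImageStack:
    """Slice a stack to z indices ``[z0, z1)``, keeping metadata."""
    if not 0 <= z0 < z1 <= stack.n_z:
        raise ValueError(f"substack [{z0}, {z1}) outside depth {stack.n_z}")
    return replace(stack, data=stack.data[:, z0:z1])
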