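"""Multichannel fluorescence image container and TIFF round-trip.

The analysis works on four-channel confocal scans of immunostained brain
slice sections: a DAPI nuclear stain, two immunofluorescence marker channels
(e.g. GFAP at 633 nm and NeuN or Iba1 at 546 nm), and the GFP reporter
carried by the viral vector (488 nm). Channels are addressed by *role*
(``dapi``, ``gfp``, ``marker_a``, ``marker_b``) rather than position so the
physical channel order on the microscope is irrelevant downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

ROLES = ("dapi", "gfp", "marker_a", "marker_b")

#: Conventional channel layout (DAPI, 633, 488, 546) used by the default
#: simulated images and by the CSV column naming.
DEFAULT_CHANNEL_ROLES = {"dapi": 0, "marker_a": 1, "gfp": 2, "marker_b": 3}

#: Emission-wavelength aliases for the stable CSV column names.
ROLE_WAVELENGTH = {"dapi": "dapi", "marker_a": "633", "gfp": "488", "marker_b": "546"}


@dataclass
class ImageStack:
    """A 2-D multichannel image with named channel roles and a pixel size.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, height, width)`` of non-negative
        intensities.
    channel_roles
        Map from role name to channel index. All four roles must be
        assigned to distinct channels.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    image_id
        Free-form identifier carried through to measurement tables.
    """

    pixels: np.ndarray
    channel_roles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )
    pixel_size_um: float = 4.0
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be (channels, height, width), got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        missing = [r for r in ROLES if r not in self.channel_roles]
        if missing:
            raise ValueError(f"channel roles not assigned: {missing}")
        idx = [self.channel_roles[r] for r in ROLES]
        if len(set(idx)) != len(idx):
            raise ValueError("channel roles must map to distinct channels")
        if max(idx) >= self.pixels.shape[0]:
            raise ValueError("channel role index out of range")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D image for a named role."""
        if role not in self.channel_roles:
            raise KeyError(f"unknown channel role {role!r}")
        return self.pixels[self.channel_roles[role]]

    def um_to_px(self, distance_um: float) -> float:
        return distance_um / self.pixel_size_um


def write_image(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF with JSON metadata."""
    meta = {
        "channel_roles": stack.channel_roles,
        "pixel_size_um": stack.pixel_size_um,
        "image_id": stack.image_id,
    }
    tifffile.imwrite(path, stack.pixels, description=json.dumps(meta))


def read_image(path) -> ImageStack:
    """Read a TIFF written by :func:`write_image`."""
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    roles = meta.get("channel_roles", dict(DEFAULT_CHANNEL_ROLES))
    return ImageStack(
        pixels=pixels,
        channel_roles={k: int(v) for k, v in roles.items()},
        pixel_size_um=float(meta.get("pixel_size_um", 4.0)),
        image_id=str(meta.get("image_id", "")),
    )
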