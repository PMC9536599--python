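"""Multi-channel 3D image stack container and OME-TIFF I/O."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "write_labels", "read_labels",
           "KNOWN_ROLES"]

KNOWN_ROLES = ("SPC", "CK7", "DNA", "LMN")


@dataclass
class ImageStack:
    """Per-channel 3D voxel data on an 8-bit intensity scale (stored float).

    ``data`` has axes (channel, z, y, x); ``voxel_size`` is (z, y, x) in um;
    ``channel_roles`` maps role name -> channel index.
    """
    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: dict[str, int] = field(default_factory=dict)
    stack_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack data must be (channel, z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size components must be positive")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < self.data.shape[0]:
                raise ValueError(f"channel index {idx} for role {role!r} out of range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in fL (1 fL = 1 um^3)."""
        return float(np.prod(self.voxel_size))

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise KeyError(f"channel role {role!r} missing; expected one of "
                           f"{sorted(self.channel_roles) or list(KNOWN_ROLES)}")
        return self.data[self.channel_roles[role]]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), tuple(self.voxel_size),
                          dict(self.channel_roles), self.stack_id)


def write_stack(stack: ImageStack, path) -> None:
    """Write as OME-TIFF preserving channel names and physical voxel size."""
    names = [None] * stack.data.shape[0]
    for role, idx in stack.channel_roles.items():
        names[idx] = role
    names = [n if n is not None else f"C{i}" for i, n in enumerate(names)]
    zs, ys, xs = stack.voxel_size
    tifffile.imwrite(
        path, stack.data.astype(np.float32), ome=True,
        metadata={
            "axes": "CZYX",
            "Name": stack.stack_id or "stack",
            "Channel": {"Name": names},
            "PhysicalSizeX": xs, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": ys, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": zs, "PhysicalSizeZUnit": "µm",
        })


def read_stack(path, require=("DNA",)) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_stack`.

    Raises if any channel role in ``require`` is absent.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        ome = tf.ome_metadata
    if data.ndim == 3:
        data = data[None]
    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    image = root.find("ome:Image", ns)
    pixels = image.find("ome:Pixels", ns)
    voxel_size = (float(pixels.get("PhysicalSizeZ", 1.0)),
                  float(pixels.get("PhysicalSizeY", 1.0)),
                  float(pixels.get("PhysicalSizeX", 1.0)))
    channels = pixels.findall("ome:Channel", ns)
    roles = {}
    for i, ch in enumerate(channels):
        name = ch.get("Name") or f"C{i}"
        roles[name] = i
    missing = [r for r in require if r not in roles]
    if missing:
        raise ValueError(f"stack at {path} is missing channel roles {missing}; "
                         f"found {sorted(roles)}, expected from {list(KNOWN_ROLES)}")
    stack_id = image.get("Name") or ""
    return ImageStack(data=data.astype(np.float32), voxel_size=voxel_size,
                      channel_roles=roles, stack_id=stack_id)


def write_labels(labels: np.ndarray, path) -> None:
    """Write a label volume as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
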