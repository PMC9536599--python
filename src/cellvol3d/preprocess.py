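"""Raw-stack corrections applied before segmentation.

Two corrections: depth-attenuation correction from a two-point reference
measurement (mean intensity of comparable bright objects near the top and
bottom of the stack), and background subtraction implemented as a
Gaussian-smoothing high-pass with a default 33.7 um filter width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import ImageStack

__all__ = ["AttenuationModel", "correct_attenuation", "subtract_background",
           "DEFAULT_BG_WIDTH_UM"]

DEFAULT_BG_WIDTH_UM = 33.7


@dataclass(frozen=True)
class AttenuationModel:
    """Two-point depth attenuation reference for one channel."""
    top_reference: float
    bottom_reference: float
    top_z: int
    bottom_z: int

    def __post_init__(self):
        if self.top_reference <= 0 or self.bottom_reference <= 0:
            raise ValueError("reference intensities must be positive")
        if self.top_z >= self.bottom_z:
            raise ValueError("top_z must be above (less than) bottom_z")

    def gain(self, n_z: int) -> np.ndarray:
        """Per-plane multiplicative gain, linear in z.

        g(top_z) = 1 and g(bottom_z) = top_reference / bottom_reference, so
        that the corrected reference means agree; extrapolated linearly
        beyond the reference planes.
        """
        g_bottom = self.top_reference / self.bottom_reference
        z = np.arange(n_z, dtype=float)
        slope = (g_bottom - 1.0) / (self.bottom_z - self.top_z)
        return 1.0 + slope * (z - self.top_z)


def correct_attenuation(stack: ImageStack, channel: str,
                        model: AttenuationModel) -> ImageStack:
    """Multiply the named channel by the model's per-plane gain."""
    out = stack.copy()
    out.data = out.data.astype(np.float64)
    idx = stack.channel_roles[channel]
    gain = model.gain(stack.shape[0])
    out.data[idx] = out.data[idx] * gain[:, None, None]
    return out


def subtract_background(stack: ImageStack, channels=None,
                        filter_width_um: float = DEFAULT_BG_WIDTH_UM) -> ImageStack:
    """High-pass each channel: subtract a Gaussian-smoothed baseline, clip at 0.

    The baseline is a Gaussian blur with sigma = filter_width/2 in physical
    units (converted per axis to voxels); constant images map to zero.
    """
    if filter_width_um <= max(stack.voxel_size):
        raise ValueError("filter width must exceed the voxel size")
    if channels is None:
        channels = list(stack.channel_roles)
    sigma_um = filter_width_um / 2.0
    sigma_vox = [sigma_um / v for v in stack.voxel_size]
    out = stack.copy()
    out.data = out.data.astype(np.float64)
    for role in channels:
        idx = stack.channel_roles[role]
        baseline = ndimage.gaussian_filter(out.data[idx], sigma=sigma_vox,
                                           mode="nearest")
        out.data[idx] = np.clip(out.data[idx] - baseline, 0.0, None)
    return out
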