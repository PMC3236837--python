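"""Median-filter background subtraction and Fourier (sinc) upsampling.

Median subtraction removes smooth background (and noise floor) while keeping
thin bright vessels: the per-slice median-filtered image is subtracted from
the original, and negative residuals are clipped to zero since the
segmentation assumes bright-vessel positivity.  Sinc interpolation resamples
lower-resolution volumes onto a finer grid by zero-padding the spectrum,
so volumes acquired at different resolutions can be compared.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .grid import ImageVolume

__all__ = ["median_subtract", "sinc_interpolate"]


def median_subtract(vol: ImageVolume, kernel: int) -> ImageVolume:
    """Subtract the per-slice 2-D median-filtered image from the original.

    The kernel is a 2-D ``kernel x kernel`` window applied within each
    transverse (x-y) slice; the result is clipped at zero.  Typical kernels
    are 5 and 11.
    """
    kernel = int(kernel)
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"median kernel must be odd and >= 3, got {kernel}")
    filtered = ndimage.median_filter(vol.data, size=(kernel, kernel, 1),
                                     mode="nearest")
    return vol.with_data(np.clip(vol.data - filtered, 0.0, None))


def sinc_interpolate(vol: ImageVolume, target_spacing) -> ImageVolume:
    """Fourier-domain (sinc) resampling to a finer grid.

    Only upsampling is supported.  The new grid size per axis is the nearest
    integer to ``n * spacing / target``; the actually achieved spacing
    (``spacing * n / new_n``) is recorded on the result, preserving the
    physical field of view.
    """
    target = np.atleast_1d(np.asarray(target_spacing, dtype=np.float64))
    if target.size == 1:
        target = np.repeat(target, 3)
    if target.size != 3 or np.any(target <= 0):
        raise ValueError("target_spacing must be three positive values")
    spacing = np.asarray(vol.spacing)
    if np.any(target > spacing * (1 + 1e-9)):
        raise ValueError(
            f"sinc interpolation only upsamples: target {tuple(target)} coarser "
            f"than source {tuple(spacing)}")
    shape = np.asarray(vol.shape)
    new_shape = np.maximum(shape, np.rint(shape * spacing / target).astype(int))
    data = vol.data
    for axis in range(3):
        if new_shape[axis] != shape[axis]:
            data = signal.resample(data, int(new_shape[axis]), axis=axis)
    actual = tuple(spacing * shape / new_shape)
    return ImageVolume(data, actual, vol.origin)
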