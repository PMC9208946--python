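"""Adaptive median filtering of intensity images prior to clustering.

The two-stage adaptive median filter: per pixel, the window grows from
``s_init`` until its median is not a local extreme (or ``s_max`` is hit);
the pixel is replaced by that median only if the pixel itself is a local
extreme.  Impulse-like pixels are removed while detail pixels pass through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FilterConfig", "adaptive_median_filter"]


@dataclass(frozen=True)
class FilterConfig:
    """Window schedule for the adaptive median filter.

    ``s_init`` and ``s_max`` are odd window edge lengths in pixels;
    ``border_policy`` maps to the scipy boundary modes ``reflect``/``nearest``.
    """

    s_init: int = 3
    s_max: int = 7
    border_policy: str = "reflect"

    def __post_init__(self) -> None:
        if self.s_init % 2 == 0 or self.s_max % 2 == 0:
            raise ValueError(
                f"window sizes must be odd, got s_init={self.s_init}, "
                f"s_max={self.s_max}"
            )
        if not 3 <= self.s_init <= self.s_max:
            raise ValueError("require 3 <= s_init <= s_max")
        if self.border_policy not in ("reflect", "nearest"):
            raise ValueError("border_policy must be 'reflect' or 'nearest'")


def _filter_nd(img: np.ndarray, config: FilterConfig) -> np.ndarray:
    out = img.copy()
    undecided = np.ones(img.shape, dtype=bool)
    med = img
    for size in range(config.s_init, config.s_max + 1, 2):
        med = ndimage.median_filter(img, size=size, mode=config.border_policy)
        mn = ndimage.minimum_filter(img, size=size, mode=config.border_policy)
        mx = ndimage.maximum_filter(img, size=size, mode=config.border_policy)
        median_ok = (med > mn) & (med < mx)
        decide = undecided & median_ok
        # Stage B: keep the pixel unless it is itself a window extreme.
        keep = (img > mn) & (img < mx)
        out[decide] = np.where(keep[decide], img[decide], med[decide])
        undecided &= ~median_ok
        if not undecided.any():
            break
    # Window capped at s_max with the median still extreme (e.g. constant
    # neighbourhoods): fall back to that median.
    out[undecided] = med[undecided]
    return out


def adaptive_median_filter(
    image: np.ndarray,
    config: FilterConfig = FilterConfig(),
    slicewise: bool = True,
) -> np.ndarray:
    """Apply the two-stage adaptive median filter.

    3D volumes are filtered slice-by-slice along the last axis by default
    (matching 2D acquisition slices); pass ``slicewise=False`` for full 3D
    windows.  The image must be at least ``s_max`` wide along every filtered
    axis.  Output has the same shape; intensities are medians of observed
    values, so no new values are invented for integer-valued input.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("expected a 2D image or 3D volume")
    if img.ndim == 3 and slicewise:
        for axis_len in img.shape[:2]:
            if axis_len < config.s_max:
                raise ValueError(
                    f"slice dimensions {img.shape[:2]} smaller than "
                    f"s_max={config.s_max}"
                )
        return np.stack(
            [_filter_nd(img[..., k], config) for k in range(img.shape[-1])],
            axis=-1,
        )
    if min(img.shape) < config.s_max:
        raise ValueError(
            f"image shape {img.shape} smaller than s_max={config.s_max}"
        )
    return _filter_nd(img, config)
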