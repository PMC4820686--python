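"""Noise reduction: square-window median filtering with reflected borders."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import as_gray_image

__all__ = ["MedianFilterParams", "median_filter"]


@dataclass(frozen=True)
class MedianFilterParams:
    """Median filter window; the default 3x3 window suits CT speckle."""

    window: int = 3

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")


def median_filter(image: np.ndarray, params: MedianFilterParams = MedianFilterParams()) -> np.ndarray:
    """Replace each pixel by the median of its window-sized neighborhood.

    Borders are reflect-padded, so the output has the input's shape and its
    values stay within the input's range.
    """
    img = as_gray_image(image)
    if params.window == 1:
        return img.copy()
    return ndimage.median_filter(img, size=params.window, mode="reflect")
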