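"""Final contour smoothing of refined masks by dilation/erosion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .io import as_binary_mask

__all__ = ["PostprocessParams", "postprocess_mask"]


@dataclass(frozen=True)
class PostprocessParams:
    """Disk radius of the final closing; 0 disables it. Closing (dilation
    then erosion) is extensive, so thin kidney poles are never eroded away."""

    radius: int = 1

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


def postprocess_mask(mask: np.ndarray, params: PostprocessParams = PostprocessParams()) -> np.ndarray:
    """Morphological closing with a disk structuring element."""
    m = as_binary_mask(mask)
    if params.radius == 0:
        return m.copy()
    return morphology.closing(m, morphology.disk(params.radius)).astype(bool)
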