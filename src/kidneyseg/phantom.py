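"""Synthetic CT-like slice sequences with ground truth.

The phantom emulates the conditions the pipeline is built for: a spatially
continuous stack of slices containing a bright convex "kidney" ellipse whose
cross-section peaks mid-stack and shrinks toward the poles, abutting a
larger neighbor structure of very similar intensity (the kidney/liver
confound), with a second, clearly darker muscle-like structure nearby (the
psoas, in real anatomy), over a darker background, corrupted by additive
Gaussian noise and a low-frequency multiplicative inhomogeneity field. Four
tissue intensities appear in a kidney crop — kidney, neighbor organ,
muscle, background — matching the four-cluster operating point of the rough
stage. It is not an anatomically realistic CT simulation: no ribs, no
Hounsfield calibration, no texture — it exists so the whole pipeline is
testable without patient data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BoundingBox, Volume
from .rough import extended_mbr

__all__ = ["PhantomSpec", "generate_phantom", "generate_two_region"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry and corruption levels.

    Intensities are on the normalized [0,1] scale: kidney 0.62 vs. neighbor
    0.58 keeps the two tissues within typical soft-tissue contrast so that
    intensity alone barely separates them, and background 0.25 is clearly
    darker. The kidney semi-axes are chosen so the kidney dominates its
    extended bounding rectangle on every slice, matching the tight manual
    crop the rough stage assumes; ``end_scale`` shrinks the ellipse toward
    the stack ends (mid-stack maximum). Twenty slices at 0.5 mm spacing span
    about 1 cm around the equator of a roughly 10 cm kidney, over which the
    cross-section changes only a few percent — hence the mild default. The
    center drifts by well under a pixel per slice, preserving the
    slice-to-slice continuity the automatic seeding relies on.
    """

    n_slices: int = 20
    shape: tuple[int, int] = (128, 128)
    kidney_center: tuple[float, float] = (64.0, 80.0)
    kidney_axes: tuple[float, float] = (26.0, 33.0)  # (row, col) semi-axes, mid-stack
    end_scale: float = 0.95
    drift_amplitude: float = 1.0  # max per-slice center displacement, px
    kidney_intensity: float = 0.62
    neighbor_center: tuple[float, float] = (60.0, 30.0)
    neighbor_axes: tuple[float, float] = (42.0, 38.0)
    neighbor_intensity: float = 0.58
    muscle_center: tuple[float, float] = (108.0, 95.0)
    muscle_axes: tuple[float, float] = (18.0, 30.0)
    muscle_intensity: float = 0.45
    background_intensity: float = 0.25
    noise_sd: float = 0.03
    inhomogeneity: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if abs(self.kidney_intensity - self.neighbor_intensity) < 0.02:
            raise ValueError("kidney and neighbor intensities must differ by >= 0.02")
        if not (0.0 < self.end_scale <= 1.0):
            raise ValueError("end_scale must be in (0, 1]")
        if self.noise_sd < 0 or not (0 <= self.inhomogeneity <= 0.05):
            raise ValueError("noise_sd >= 0 and inhomogeneity in [0, 0.05] required")
        rows, cols = self.shape
        cr, cc = self.kidney_center
        ar, ac = self.kidney_axes
        pad = self.drift_amplitude + 1
        if cr - ar - pad < 0 or cr + ar + pad > rows or cc - ac - pad < 0 or cc + ac + pad > cols:
            raise ValueError("kidney ellipse (plus drift) exits the frame")


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[Volume, list[np.ndarray], BoundingBox]:
    """Build the phantom volume, its ground-truth kidney masks, and the
    suggested starting rectangle (mid-stack truth bounding box + 10 px).

    Deterministic given ``rng_seed``. Truth masks are the noiseless kidney
    ellipses. Noisy intensities are clipped to [0, 1] (the clipped fraction
    is logged at debug level).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_slices
    slices = []
    truths: list[np.ndarray] = []
    phase = rng.uniform(0, 2 * np.pi, size=2)  # inhomogeneity field phases
    rr, cc = np.mgrid[: spec.shape[0], : spec.shape[1]]
    field = 1.0 + spec.inhomogeneity * np.sin(
        np.pi * rr / spec.shape[0] + phase[0]
    ) * np.cos(np.pi * cc / spec.shape[1] + phase[1])
    neighbor = _ellipse_mask(spec.shape, spec.neighbor_center, spec.neighbor_axes)
    muscle = _ellipse_mask(spec.shape, spec.muscle_center, spec.muscle_axes)
    clipped = 0
    for z in range(n):
        t = z / (n - 1) if n > 1 else 0.5
        scale = spec.end_scale + (1.0 - spec.end_scale) * np.sin(np.pi * t)
        # smooth sub-pixel-per-slice drift of the kidney center
        dr = spec.drift_amplitude * np.sin(2 * np.pi * z / max(n, 2))
        dc = spec.drift_amplitude * np.cos(2 * np.pi * z / max(n, 2))
        center = (spec.kidney_center[0] + dr, spec.kidney_center[1] + dc)
        axes = (spec.kidney_axes[0] * scale, spec.kidney_axes[1] * scale)
        kidney = _ellipse_mask(spec.shape, center, axes)
        img = np.full(spec.shape, spec.background_intensity)
        img[neighbor] = spec.neighbor_intensity
        img[muscle] = spec.muscle_intensity
        img[kidney] = spec.kidney_intensity
        img = img * field + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        clipped += int(np.sum((img < 0) | (img > 1)))
        slices.append(np.clip(img, 0.0, 1.0))
        truths.append(kidney)
    if clipped:
        logger.debug(
            "clipped %.4f%% of phantom intensities to [0, 1]",
            100.0 * clipped / (n * spec.shape[0] * spec.shape[1]),
        )
    mid = n // 2
    start_bbox = extended_mbr(truths[mid], margin=10, image_shape=spec.shape)
    return Volume(np.stack(slices), spacing=(0.68, 0.68, 0.5)), truths, start_bbox


def generate_two_region(
    rows: int, cols: int, intensity_a: float, intensity_b: float
) -> np.ndarray:
    """Piecewise-constant left/right image, the CA's analytic fixture.

    The left half gets ``intensity_a``; odd widths give the extra column to
    the right half.
    """
    for v in (intensity_a, intensity_b):
        if not (0.0 <= v <= 1.0):
            raise ValueError("intensities must lie in [0, 1]")
    if intensity_a == intensity_b:
        raise ValueError("intensities must be distinct")
    img = np.full((rows, cols), intensity_b)
    img[:, : cols // 2] = intensity_a
    return img
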