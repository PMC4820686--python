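"""GrowCut cellular-automaton segmentation with automatic seed generation.

The classic (user-seeded) GrowCut treats the image as a cellular automaton:
each cell carries a label l in {-1, 0, +1} (background / unlabeled /
foreground), a strength theta in [0, 1] and a feature C (the pixel
intensity). At every synchronous step each neighbor q "attacks" cell p with
force g(|C_p - C_q|) * theta_q, where g(d) = 1 - d / max||C|| is monotone
decreasing in feature distance; p is conquered (takes q's label and the
attack force as its new strength) when the force strictly exceeds theta_p.
Iteration stops when no cell changes.

The improved, automatically seeded variant exploits the spatial continuity
of CT sequences: the contour of an adjacent, already well-segmented slice
(the "seed template") generates foreground seeds just inside and background
seeds just outside the contour, so refinement needs zero user interaction.
Seed offsets follow the local contour direction: where the contour runs
horizontally (small row-coordinate change d_y along the traced chain) seeds
are placed vertically, otherwise horizontally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .io import BoundingBox, as_binary_mask, as_gray_image

__all__ = [
    "GrowCutParams",
    "SeedGenParams",
    "CellStateGrid",
    "GrowCutResult",
    "attack_g",
    "init_states",
    "growcut_step",
    "growcut_segment",
    "contour_points",
    "altitude_difference",
    "generate_seeds",
    "needs_refinement",
    "refine_slice",
]

logger = logging.getLogger(__name__)

# Neighbor offsets in fixed row-major scan order; this order is the attacker
# tie-break, so it is part of the algorithm's contract.
_MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_NEUMANN = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True)
class GrowCutParams:
    """CA parameters: neighborhood system and iteration cap.

    ``max_feature_norm`` is the normalizing constant of the attack function;
    intensities are pre-normalized to [0, 1], so it is 1.
    """

    neighborhood: str = "moore8"
    max_iter: int = 500
    max_feature_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.neighborhood not in ("moore8", "neumann4"):
            raise ValueError("neighborhood must be 'moore8' or 'neumann4'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def offsets(self):
        return _MOORE if self.neighborhood == "moore8" else _NEUMANN


@dataclass(frozen=True)
class SeedGenParams:
    """Automatic seed placement thresholds (pixels).

    ``t_h`` switches between vertical (flat contour, d_y < t_h) and
    horizontal seed offsets; ``t1``/``t2`` are the inward/outward distances
    of foreground/background seeds from the contour. The defaults (1, 3, 3)
    exceed typical contour drift between sub-millimetre-spaced slices while
    staying inside thin kidney sections. ``step`` subsamples the traced
    contour.
    """

    t_h: int = 1
    t1: int = 3
    t2: int = 3
    step: int = 1

    def __post_init__(self) -> None:
        if self.t1 < 1 or self.t2 < 1 or self.t_h < 0 or self.step < 1:
            raise ValueError("need t1 >= 1, t2 >= 1, t_h >= 0, step >= 1")


@dataclass
class CellStateGrid:
    """Per-pixel CA state: label {-1,0,+1}, strength [0,1], feature [0,1]."""

    labels: np.ndarray
    strength: np.ndarray
    feature: np.ndarray

    def copy(self) -> "CellStateGrid":
        return CellStateGrid(self.labels.copy(), self.strength.copy(), self.feature.copy())


@dataclass
class GrowCutResult:
    mask: np.ndarray
    states: CellStateGrid
    converged: bool
    n_iter: int


def attack_g(d, max_norm: float = 1.0):
    """Attack attenuation g(d) = 1 - d / max_norm, linear and decreasing."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0) or np.any(d > max_norm):
        raise ValueError(f"feature distance outside [0, {max_norm}]")
    out = 1.0 - d / max_norm
    return float(out) if out.ndim == 0 else out


def init_states(image: np.ndarray, seeds: np.ndarray) -> CellStateGrid:
    """Initial CA state: seeded cells get strength 1, all others label 0,
    strength 0; the feature is the pixel intensity everywhere."""
    img = as_gray_image(image)
    seeds = np.asarray(seeds)
    if seeds.shape != img.shape:
        raise ValueError(f"seed shape {seeds.shape} != image shape {img.shape}")
    if not np.all(np.isin(seeds, (-1, 0, 1))):
        raise ValueError("seed labels must be in {-1, 0, +1}")
    if not (seeds == 1).any() or not (seeds == -1).any():
        raise ValueError("need at least one foreground and one background seed")
    labels = seeds.astype(np.int8)
    strength = (seeds != 0).astype(np.float64)
    return CellStateGrid(labels=labels, strength=strength, feature=img.copy())


def _shift(a: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """a shifted so out[r, c] = a[r + dr, c + dc], `fill` outside the grid."""
    out = np.full_like(a, fill)
    rows, cols = a.shape
    src_r = slice(max(dr, 0), rows + min(dr, 0))
    src_c = slice(max(dc, 0), cols + min(dc, 0))
    dst_r = slice(max(-dr, 0), rows + min(-dr, 0))
    dst_c = slice(max(-dc, 0), cols + min(-dc, 0))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def growcut_step(states: CellStateGrid, params: GrowCutParams = GrowCutParams()) -> tuple[CellStateGrid, int]:
    """One synchronous CA step; returns the new state and the change count.

    All attacks read the time-t grid. Among the neighbors whose force
    strictly exceeds the cell's strength, the strongest wins; force ties are
    broken by the fixed row-major neighbor scan order.
    """
    offsets = params.offsets
    lab, theta, feat = states.labels, states.strength, states.feature
    forces = np.empty((len(offsets),) + lab.shape)
    att_labels = np.empty((len(offsets),) + lab.shape, dtype=np.int8)
    for j, (dr, dc) in enumerate(offsets):
        theta_q = _shift(theta, dr, dc, fill=-1.0)  # out-of-grid never attacks
        feat_q = _shift(feat, dr, dc, fill=0.0)
        g = 1.0 - np.abs(feat - feat_q) / params.max_feature_norm
        forces[j] = g * theta_q
        att_labels[j] = _shift(lab, dr, dc, fill=0)
    best = forces.argmax(axis=0)  # first max in scan order wins ties
    best_force = np.take_along_axis(forces, best[None], axis=0)[0]
    best_label = np.take_along_axis(att_labels, best[None], axis=0)[0]
    win = best_force > theta
    new = CellStateGrid(
        labels=np.where(win, best_label, lab).astype(np.int8),
        strength=np.where(win, best_force, theta),
        feature=feat,
    )
    return new, int(win.sum())


def growcut_segment(
    image: np.ndarray, seeds: np.ndarray, params: GrowCutParams = GrowCutParams()
) -> GrowCutResult:
    """Run the CA from seeded initial state until no cell changes.

    Returns the foreground (label +1) mask; cells still unlabeled at
    termination count as background. Hitting ``max_iter`` sets
    ``converged=False`` instead of raising.
    """
    states = init_states(image, seeds)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        states, changed = growcut_step(states, params)
        if changed == 0:
            converged = True
            break
    if not converged:
        logger.warning("GrowCut did not converge within %d iterations", params.max_iter)
    return GrowCutResult(mask=states.labels == 1, states=states, converged=converged, n_iter=it)


# clockwise Moore scan (screen orientation, row increases downward): W, NW,
# N, NE, E, SE, S, SW
_CLOCKWISE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def contour_points(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer boundary of a single-component mask.

    Moore-neighbor tracing, clockwise, starting from the top-left-most
    foreground pixel; consecutive points are 8-adjacent and the chain is
    closed. Thin structures may legitimately revisit pixels.
    """
    m = as_binary_mask(mask)
    if not m.any():
        raise ValueError("empty mask has no contour")
    if measure.label(m, connectivity=2).max() != 1:
        raise ValueError("contour tracing requires exactly one connected component")

    rows, cols = m.shape

    def fg(p):
        r, c = p
        return 0 <= r < rows and 0 <= c < cols and m[r, c]

    start_flat = int(np.argmax(m))  # first foreground pixel in raster order
    start = (start_flat // cols, start_flat % cols)
    backtrack = (start[0], start[1] - 1)  # entered scanning left-to-right

    if not any(fg((start[0] + dr, start[1] + dc)) for dr, dc in _CLOCKWISE):
        return [start]  # isolated pixel

    contour = [start]
    p, b = start, backtrack
    first_edge: tuple | None = None
    limit = 8 * int(m.sum()) + 8  # a closed chain cannot exceed this
    for _ in range(limit):
        bi = _CLOCKWISE.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            off = _CLOCKWISE[(bi + k) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if fg(q):
                nxt = q
                b = (p[0] + _CLOCKWISE[(bi + k - 1) % 8][0],
                     p[1] + _CLOCKWISE[(bi + k - 1) % 8][1])
                break
        edge = (p, nxt)
        if first_edge is None:
            first_edge = edge
        elif edge == first_edge:  # the boundary cycle closed
            break
        p = nxt
        contour.append(p)
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    return contour


def altitude_difference(contour: list[tuple[int, int]], index: int, step: int = 1) -> int:
    """Local vertical change |row(i+step) - row(i-step)| along the chain,
    with cyclic indexing."""
    n = len(contour)
    if n < 3:
        raise ValueError("contour must have at least 3 points")
    return abs(contour[(index + step) % n][0] - contour[(index - step) % n][0])


def generate_seeds(
    template_mask: np.ndarray,
    params: SeedGenParams = SeedGenParams(),
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Automatic seed labels from an adjacent-slice template contour.

    For each traced contour point (subsampled by ``step``): if the local
    altitude difference d_y is below ``t_h`` the contour is locally
    horizontal, so the foreground seed goes ``t1`` px vertically on the
    interior side and the background seed ``t2`` px on the exterior side;
    otherwise the offsets are horizontal. The interior side is found by
    testing which candidate lies inside the template (robust to concave
    contours); points whose interior test is ambiguous, or candidate seeds
    out of bounds or on the wrong side, are discarded. Foreground overrides
    background on pixel collisions (thin sections).
    """
    tmpl = as_binary_mask(template_mask)
    if image_shape is None:
        image_shape = tmpl.shape
    if tmpl.shape != tuple(image_shape):
        raise ValueError("template shape must equal image shape")
    contour = contour_points(tmpl)
    seeds = np.zeros(image_shape, dtype=np.int8)
    rows, cols = image_shape

    def inside(p):
        r, c = p
        return 0 <= r < rows and 0 <= c < cols and tmpl[r, c]

    def in_bounds(p):
        r, c = p
        return 0 <= r < rows and 0 <= c < cols

    n = len(contour)
    for i in range(0, n, params.step):
        r, c = contour[i]
        if n >= 3:
            d_y = altitude_difference(contour, i, params.step)
        else:
            d_y = 0
        axis = (1, 0) if d_y < params.t_h else (0, 1)
        plus = (r + axis[0] * params.t1, c + axis[1] * params.t1)
        minus = (r - axis[0] * params.t1, c - axis[1] * params.t1)
        plus_in, minus_in = inside(plus), inside(minus)
        if plus_in == minus_in:
            continue  # ambiguous interior side: skip this contour point
        sign = 1 if plus_in else -1
        fg = plus if plus_in else minus
        bg = (r - sign * axis[0] * params.t2, c - sign * axis[1] * params.t2)
        seeds[fg] = 1
        if in_bounds(bg) and not tmpl[bg] and seeds[bg] != 1:
            seeds[bg] = -1
    if not (seeds == 1).any():
        raise ValueError("template too thin to place foreground seeds; reduce t1")
    if not (seeds == -1).any():
        raise ValueError("no valid background seed positions; reduce t2")
    return seeds


def needs_refinement(
    prev_mask: np.ndarray,
    curr_mask: np.ndarray,
    threshold: float = 0.10,
    min_solidity: float = 0.85,
) -> bool:
    """Quality gate between adjacent rough masks.

    Flags the current slice when its area jumps by more than ``threshold``
    relative to the adjacent (toward-the-seed) mask, or when its solidity
    (area / convex hull area) drops below ``min_solidity`` — both symptoms
    of the rough stage leaking into a neighboring organ or losing a pole.
    """
    prev = as_binary_mask(prev_mask)
    curr = as_binary_mask(curr_mask)
    prev_area = int(prev.sum())
    if prev_area == 0:
        raise ValueError("previous mask is empty")
    curr_area = int(curr.sum())
    if curr_area == 0:
        return True
    if abs(curr_area - prev_area) / prev_area > threshold:
        return True
    hull_area = int(morphology.convex_hull_image(curr).sum())
    return curr_area / hull_area < min_solidity


def refine_slice(
    image: np.ndarray,
    template_mask: np.ndarray,
    seed_params: SeedGenParams = SeedGenParams(),
    growcut_params: GrowCutParams = GrowCutParams(),
    bbox: BoundingBox | None = None,
    margin: int = 10,
) -> np.ndarray:
    """Refined segmentation of one slice from an adjacent-slice template.

    Seeds are generated from the template contour and the CA runs on the
    crop window (the template's extended bounding rectangle unless a window
    is given), mirroring the pipeline's crop propagation. Returns the
    refined mask in full-slice coordinates. Consumes zero user interactions.
    """
    from .rough import extended_mbr, largest_connected_region  # avoids a module cycle

    img = as_gray_image(image)
    tmpl = as_binary_mask(template_mask, img.shape)
    # contour smoothing can leave satellite fragments; the kidney contour is
    # the template's largest component
    tmpl = largest_connected_region(tmpl)
    seeds = generate_seeds(tmpl, seed_params, img.shape)
    if bbox is None:
        bbox = extended_mbr(tmpl, margin, img.shape)
    window = img[bbox.slices()]
    seed_window = seeds[bbox.slices()]
    if not (seed_window == 1).any() or not (seed_window == -1).any():
        raise ValueError("crop window clips all seeds of one kind; enlarge the margin")
    result = growcut_segment(window, seed_window, growcut_params)
    full = np.zeros(img.shape, dtype=bool)
    full[bbox.slices()] = result.mask
    return full
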