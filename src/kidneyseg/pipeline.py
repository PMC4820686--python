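"""End-to-end orchestration: rough pass, quality gating, auto-seeded GrowCut
refinement, post-processing, and the run report.

The pipeline consumes exactly one manual input — the initial rectangle on
the slice with the largest kidney cross-section — and zero interactions
thereafter: slices whose rough mask fails the quality gate are refined with
seeds generated automatically from the nearest well-segmented neighbor
slice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np

from .growcut import GrowCutParams, SeedGenParams, needs_refinement, refine_slice
from .io import BoundingBox, Volume
from .postprocess import PostprocessParams, postprocess_mask
from .preprocess import MedianFilterParams
from .rough import RoughParams, RoughResult, rough_segment_sequence
from .skfcm import SKFCMParams

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

_PARAM_BLOCKS = {
    "median": MedianFilterParams,
    "skfcm": SKFCMParams,
    "rough": RoughParams,
    "seedgen": SeedGenParams,
    "growcut": GrowCutParams,
    "post": PostprocessParams,
}


@dataclass
class RunConfig:
    """All pipeline parameter blocks plus the refinement gate thresholds.

    Serializes to/from a YAML mapping of block name -> field dict; unknown
    keys are rejected so typos fail loudly.
    """

    median: MedianFilterParams = field(default_factory=MedianFilterParams)
    skfcm: SKFCMParams = field(default_factory=SKFCMParams)
    rough: RoughParams = field(default_factory=RoughParams)
    seedgen: SeedGenParams = field(default_factory=SeedGenParams)
    growcut: GrowCutParams = field(default_factory=GrowCutParams)
    post: PostprocessParams = field(default_factory=PostprocessParams)
    refine_area_threshold: float = 0.10
    refine_min_solidity: float = 0.85

    def __post_init__(self) -> None:
        from dataclasses import replace

        # the rough stage owns the median parameters it applies
        self.rough = replace(self.rough, median=self.median)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, block_cls in _PARAM_BLOCKS.items():
            if name in data:
                block = dict(data[name])
                block_known = {f.name for f in fields(block_cls) if f.name != "median"}
                bad = set(block) - block_known
                if bad:
                    raise ValueError(f"unknown keys in config block {name!r}: {sorted(bad)}")
                kwargs[name] = block_cls(**block)
        for scalar in ("refine_area_threshold", "refine_min_solidity"):
            if scalar in data:
                kwargs[scalar] = float(data[scalar])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in _PARAM_BLOCKS:
            block = asdict(getattr(self, name))
            block.pop("median", None)
            out[name] = block
        out["refine_area_threshold"] = self.refine_area_threshold
        out["refine_min_solidity"] = self.refine_min_solidity
        return out


@dataclass
class PipelineResult:
    """Final masks plus the structured run report."""

    masks: list[np.ndarray]
    rough_results: list[RoughResult]
    rough_masks: list[np.ndarray]
    refined: dict[int, np.ndarray]
    report: dict[str, Any]


def _quality_flags(results: list[RoughResult], start_index: int, config: RunConfig) -> dict[int, bool]:
    """Flag slices needing refinement by comparing each rough mask with its
    neighbor toward the seed slice; the seed slice itself is the manual
    reference and is never flagged (unless its rough pass failed)."""
    by_index = {r.slice_index: r for r in results}
    flags: dict[int, bool] = {}
    for r in results:
        i = r.slice_index
        if r.failed or not r.mask.any():
            flags[i] = True
            continue
        if i == start_index:
            flags[i] = False
            continue
        toward = i - 1 if i > start_index else i + 1
        prev = by_index.get(toward)
        if prev is None or not prev.mask.any():
            flags[i] = True
            continue
        flags[i] = needs_refinement(
            prev.mask, r.mask,
            threshold=config.refine_area_threshold,
            min_solidity=config.refine_min_solidity,
        )
    return flags


def _nearest_template(i: int, start_index: int, flags: dict[int, bool]) -> int | None:
    """Nearest unflagged slice index, searching toward the seed slice first."""
    toward = -1 if i > start_index else 1
    candidates = sorted(
        (j for j, fl in flags.items() if not fl and j != i),
        key=lambda j: (abs(j - i), 0 if (j - i) * toward > 0 else 1),
    )
    return candidates[0] if candidates else None


def run_pipeline(
    volume: Volume,
    start_index: int,
    start_bbox: BoundingBox,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Rough-segment the sequence, refine flagged slices, post-process.

    Refinement uses the rough mask of the nearest unflagged slice as the
    seed template and runs the CA on that template's extended rectangle. A
    flagged slice with no available template keeps its rough mask (logged).
    The whole run is deterministic: identical inputs give identical masks.
    """
    config = config or RunConfig()
    rough_results = rough_segment_sequence(
        volume, start_index, start_bbox, config.skfcm, config.rough
    )
    flags = _quality_flags(rough_results, start_index, config)
    refined: dict[int, np.ndarray] = {}
    slice_records = []
    final_masks: list[np.ndarray] = []
    for r in rough_results:
        i = r.slice_index
        mask = r.mask
        template_index = None
        if flags[i]:
            template_index = _nearest_template(i, start_index, flags)
            if template_index is None:
                logger.warning("slice %d flagged but no template available; keeping rough mask", i)
            else:
                template = next(x for x in rough_results if x.slice_index == template_index)
                try:
                    mask = refine_slice(
                        volume[i], template.mask, config.seedgen, config.growcut,
                        margin=config.rough.margin,
                    )
                    refined[i] = mask
                except ValueError as exc:
                    logger.warning("refinement of slice %d failed (%s); keeping rough mask", i, exc)
                    template_index = None
        final = postprocess_mask(mask, config.post)
        final_masks.append(final)
        slice_records.append(
            {
                "slice": i,
                "bbox": asdict(r.bbox),
                "rough_failed": bool(r.failed),
                "skfcm_converged": bool(r.converged),
                "flagged": bool(flags[i]),
                "refined": i in refined,
                "template_slice": template_index,
                "mask_area": int(final.sum()),
            }
        )
    report = {
        "n_slices": len(rough_results),
        "start_slice": start_index,
        "start_bbox": asdict(start_bbox),
        "n_flagged": int(sum(flags.values())),
        "n_refined": len(refined),
        "interactions": 0,  # one manual rectangle up front, nothing after
        "config": config.to_dict(),
        "slices": slice_records,
    }
    return PipelineResult(
        masks=final_masks,
        rough_results=rough_results,
        rough_masks=[r.mask for r in rough_results],
        refined=refined,
        report=report,
    )


def save_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
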