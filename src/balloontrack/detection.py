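"""Seven-step real-time balloon detection pipeline.

One :class:`~balloontrack.core.ImageStack` in, one
:class:`~balloontrack.core.Detection` out:

1. binarize at a mode-dependent fraction of the stack maximum, restricted
   to the shim box;
2. morphological closing (3x3 square) per slice;
3. 8-connected clustering into contiguous regions per slice;
4. size/shape filter against the balloon-radius upper bound;
5. temporal-consistency filter against the previous balloon position
   (Runtime only);
6. per-slice selection of the best remaining region;
7. cross-slice selection of the brightest candidate and lift of its
   in-plane center of mass to 3D world coordinates.

The order of the steps is fixed: a bright decoy far from the previous
position must be removed by step 5 before step 7's brightness vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    Detection,
    ImageStack,
    Mode,
    Region,
    ShimBox,
    SlicePrescription,
    TrackingParams,
)

__all__ = [
    "DetectionContext",
    "binarize_stack",
    "close_mask",
    "cluster_regions",
    "filter_size_shape",
    "filter_temporal",
    "select_in_slice",
    "select_across_slices",
    "detect_balloon",
]

_SQUARE_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionContext:
    """Everything the pipeline needs beyond the images themselves.

    ``prev_position`` may be absent only in Calibration mode or for the
    first Runtime measurement after Calibration (whose prior comes from
    the Calibration feedback).
    """

    mode: Mode
    params: TrackingParams
    shim_box: ShimBox
    prev_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        if self.prev_position is not None:
            self.prev_position = np.asarray(self.prev_position, dtype=float)

    @property
    def theta(self) -> float:
        return (
            self.params.theta_cal
            if self.mode is Mode.CALIBRATION
            else self.params.theta_run
        )


def shim_mask(stack: ImageStack, box: ShimBox) -> np.ndarray:
    """Boolean (slice, row, col) mask of pixel centers inside the shim box."""
    return np.stack([box.contains(p.pixel_grid_world()) for p in stack.prescriptions])


def binarize_stack(
    stack: ImageStack, ctx: DetectionContext
) -> tuple[np.ndarray, bool]:
    """Step 1: threshold at ``theta * max`` of the in-box stack intensities.

    Returns ``(mask, degenerate)``. A pixel is foreground iff its
    intensity is >= the threshold *and* its world position lies inside
    the shim box; pixels outside the box are always background. When the
    in-box maximum is zero the stack is degenerate: an all-background
    mask is returned with the flag set (no exception, so the controller's
    lost-counter logic handles it uniformly).
    """
    inside = shim_mask(stack, ctx.shim_box)
    if not inside.any():
        return np.zeros_like(inside), True
    m = float(stack.intensities[inside].max())
    if m <= 0.0:
        return np.zeros_like(inside), True
    threshold = ctx.theta * m
    return (stack.intensities >= threshold) & inside, False


def close_mask(mask: np.ndarray) -> np.ndarray:
    """Step 2: binary morphological closing with a 3x3 square, per slice.

    Computed on the infinite background-padded plane (pad, dilate, erode,
    crop), so the result contains the input (extensive) and the operator
    is idempotent — edge pixels are never eaten by the erosion.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("close_mask operates on a single 2D slice mask")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=_SQUARE_3X3)
    eroded = ndimage.binary_erosion(dilated, structure=_SQUARE_3X3, border_value=0)
    return eroded[1:-1, 1:-1]


def cluster_regions(
    mask: np.ndarray,
    intensities: np.ndarray,
    slice_index: int,
    prescription: SlicePrescription,
) -> list[Region]:
    """Step 3: 8-connected components within one slice.

    Each region carries its pixel set, physical area, the
    intensity-weighted in-plane center of mass computed on the ORIGINAL
    (pre-binarization) intensities, the world center of mass on the slice
    center plane, and the original peak/mean intensities.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_SQUARE_3X3)
    sp = prescription.pixel_spacing
    regions: list[Region] = []
    for lab in range(1, n + 1):
        pix = np.argwhere(labels == lab)
        vals = intensities[pix[:, 0], pix[:, 1]]
        total = float(vals.sum())
        if total > 0:
            com_r = float((vals * pix[:, 0]).sum() / total)
            com_c = float((vals * pix[:, 1]).sum() / total)
        else:  # all-zero weights: fall back to the geometric centroid
            com_r, com_c = map(float, pix.mean(axis=0))
        regions.append(
            Region(
                slice_index=slice_index,
                pixels=pix,
                area_mm2=float(len(pix)) * sp * sp,
                com_inplane=(com_r, com_c),
                com_world=prescription.pixel_to_world(com_r, com_c),
                peak_intensity=float(vals.max()),
                mean_intensity=float(vals.mean()),
            )
        )
    return regions


def filter_size_shape(
    regions: Sequence[Region], params: TrackingParams
) -> list[Region]:
    """Step 4: discard regions implausibly large for the balloon.

    A region survives iff its area is <= the area of a disc of radius
    ``r_max`` and no pixel center lies farther than ``r_max`` (in-plane
    mm) from the region's center of mass.
    """
    r = params.r_max
    max_area = np.pi * r * r
    kept = []
    for reg in regions:
        if reg.area_mm2 > max_area:
            continue
        sp = np.sqrt(reg.area_mm2 / len(reg.pixels))  # pixel spacing, mm
        d = (reg.pixels - np.array(reg.com_inplane)) * sp
        if float(np.sqrt((d * d).sum(axis=1)).max()) > r:
            continue
        kept.append(reg)
    return kept


def filter_temporal(
    regions: Sequence[Region], ctx: DetectionContext
) -> list[Region]:
    """Step 5: enforce temporal consistency of the balloon displacement.

    In Runtime mode with a previous position, regions whose world center
    of mass lies farther than ``d_disp_max`` (3D Euclidean, closed bound)
    from that position are discarded. Calibration re-localizes without a
    prior, so the filter passes everything through there, and likewise
    when no previous position exists yet.
    """
    if ctx.mode is not Mode.RUNTIME or ctx.prev_position is None:
        return list(regions)
    prev = ctx.prev_position
    return [
        reg
        for reg in regions
        if float(np.linalg.norm(reg.com_world - prev)) <= ctx.params.d_disp_max
    ]


def _row_major_key(reg: Region) -> int:
    return reg.first_pixel_rank()


def select_in_slice(
    regions: Sequence[Region], ctx: DetectionContext
) -> Optional[Region]:
    """Step 6: keep at most one region per slice.

    With a previous position: the region closest to it (ties broken by
    higher peak intensity, then lower row-major first pixel). Without one
    (Calibration): the region with the highest peak intensity, same
    residual tie-breaks.
    """
    regions = list(regions)
    if not regions:
        return None
    if len({r.slice_index for r in regions}) > 1:
        raise ValueError("select_in_slice expects regions of a single slice")
    if ctx.prev_position is not None:
        prev = ctx.prev_position
        return min(
            regions,
            key=lambda r: (
                float(np.linalg.norm(r.com_world - prev)),
                -r.peak_intensity,
                _row_major_key(r),
            ),
        )
    return min(regions, key=lambda r: (-r.peak_intensity, _row_major_key(r)))


def select_across_slices(per_slice_winners: Sequence[Region]) -> Detection:
    """Step 7: brightest candidate across slices wins; lift its COM to 3D.

    Ties are broken by larger area, then lower slice index. The reported
    position is the in-plane intensity-weighted center of mass on the
    winning slice's center plane.
    """
    winners = [w for w in per_slice_winners if w is not None]
    if not winners:
        return Detection.not_found()
    best = min(
        winners, key=lambda r: (-r.peak_intensity, -r.area_mm2, r.slice_index)
    )
    return Detection(found=True, region=best, position_world=best.com_world.copy())


def detect_balloon(stack: ImageStack, ctx: DetectionContext) -> Detection:
    """Run the full pipeline on one stack; deterministic for fixed inputs.

    The shim-box restriction is re-applied after the closing so a
    detection can never be reported outside the shim box.
    """
    if stack.mode_tag is not ctx.mode:
        raise ValueError(
            f"stack mode {stack.mode_tag} does not match context mode {ctx.mode}"
        )
    raw_mask, degenerate = binarize_stack(stack, ctx)
    if degenerate:
        return Detection.not_found(degenerate=True)
    inside = shim_mask(stack, ctx.shim_box)
    candidates: list[Region] = []
    for k in range(len(stack)):
        closed = close_mask(raw_mask[k]) & inside[k]
        regions = cluster_regions(
            closed, stack.intensities[k], k, stack.prescriptions[k]
        )
        regions = filter_size_shape(regions, ctx.params)
        regions = filter_temporal(regions, ctx)
        winner = select_in_slice(regions, ctx)
        if winner is not None:
            candidates.append(winner)
    return select_across_slices(candidates)
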