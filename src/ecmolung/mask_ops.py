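"""Lung-mask post-processing and resolution handling.

Segmentation of real scans is done upstream (any mask aligned to the CT
grid is accepted); for phantoms a simple HU threshold followed by the
standard mask clean-up — morphological closing to fill small holes and
connected-component filtering to drop isolated artifacts — is provided
here, together with nearest-neighbour resampling between grids.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, CTVolume

log = logging.getLogger(__name__)

# 26-connectivity structuring element; also the closing kernel.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_by_threshold(vol: CTVolume, hu_cutoff: float = -200.0, keep_components: int = 2) -> BinaryMask:
    """Threshold segmentation: voxels with HU below the cutoff, cleaned up.

    Intended for phantoms with a soft-tissue background; applies
    :func:`postprocess_mask` before returning.
    """
    if not np.isfinite(hu_cutoff):
        raise ValueError("hu_cutoff must be finite")
    raw = BinaryMask(vol.data < hu_cutoff, vol.spacing_mm)
    return postprocess_mask(raw, keep_components=keep_components)


def postprocess_mask(mask: BinaryMask, keep_components: int = 2) -> BinaryMask:
    """Binary closing (3x3x3) then keep the largest connected components.

    Components use 26-connectivity; by default the two largest survive
    (left and right lung).  An empty result raises, flagging a failed
    segmentation.
    """
    if mask.data.size == 0:
        raise ValueError("empty grid")
    # edge-replicated padding so closing cannot erode masks touching the
    # grid boundary (scipy treats out-of-grid voxels as background)
    padded = np.pad(mask.data, 1, mode="edge")
    closed = ndimage.binary_closing(padded, structure=_STRUCT_26)[1:-1, 1:-1, 1:-1]
    labels, n = ndimage.label(closed, structure=_STRUCT_26)
    if n > 0:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[::-1][:keep_components] + 1
        closed = np.isin(labels, keep)
    if not closed.any():
        raise ValueError("segmentation failed: mask is empty after post-processing")
    return BinaryMask(closed, mask.spacing_mm, name=mask.name)


def resample_mask(mask: BinaryMask, target_shape: tuple[int, int, int]) -> BinaryMask:
    """Nearest-neighbour resampling of a mask to a new grid shape.

    Voxel spacing is rescaled so the physical extent is preserved;
    resampling to the same shape is the identity.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n <= 0 for n in target_shape):
        raise ValueError(f"target shape must be 3 positive ints, got {target_shape}")
    src_shape = mask.shape
    if target_shape == src_shape:
        return BinaryMask(mask.data.copy(), mask.spacing_mm, name=mask.name)
    # centre-aligned nearest-neighbour index mapping per axis
    idx = [
        np.clip(((np.arange(t) + 0.5) * s / t).astype(int), 0, s - 1)
        for t, s in zip(target_shape, src_shape)
    ]
    out = mask.data[np.ix_(*idx)]
    new_spacing = tuple(sp * s / t for sp, s, t in zip(mask.spacing_mm, src_shape, target_shape))
    return BinaryMask(out, new_spacing, name=mask.name)
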