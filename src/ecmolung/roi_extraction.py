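"""Partition a lung mask into 42 spatial, functional and intersectional ROIs.

The registry comprises:

* 8 spatial ROIs — whole lung, left/right lung, a two-compartment
  ventral/dorsal split through the lung centroid, and a three-compartment
  ventral/medial/dorsal split of the lung bounding box;
* 4 functional ROIs — the aeration compartments by HU interval
  (hyperinflated, normally aerated, poorly aerated, non-aerated);
* 30 intersectional ROIs — left/right x the five ventral-dorsal
  compartments (10), left/right x the four functional compartments (8),
  and the three-compartment split x the four functional compartments (12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import AERATION_CLAMP_HU, AERATION_EDGES_HU, COMPARTMENT_NAMES
from .volumes import AXIS_SAGITTAL, AXIS_TRANSVERSAL, BinaryMask, CTVolume, check_aligned

log = logging.getLogger(__name__)

SPATIAL_NAMES = (
    "lungs", "l_lung", "r_lung",
    "lung_cs2_vent", "lung_cs2_dors",
    "lung_cs3_vent", "lung_cs3_med", "lung_cs3_dors",
)
FUNCTIONAL_NAMES = COMPARTMENT_NAMES


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    kind: str  # spatial | functional | intersection
    components: tuple[str, ...] = ()


@dataclass
class ROIRegistry:
    """Ordered ROI definitions with their materialized masks."""

    definitions: list[ROIDefinition]
    masks: dict[str, BinaryMask] = field(repr=False)

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names in registry")
        missing = set(names) - set(self.masks)
        if missing:
            raise ValueError(f"registry definitions without masks: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        for d in self.definitions:
            yield d.name, self.masks[d.name]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def counts_by_kind(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.definitions:
            out[d.kind] = out.get(d.kind, 0) + 1
        return out

    def manifest(self) -> list[dict]:
        return [
            {"name": d.name, "kind": d.kind, "components": list(d.components)}
            for d in self.definitions
        ]


def split_left_right(lung: BinaryMask, midline_fallback: bool = False) -> tuple[BinaryMask, BinaryMask]:
    """Split a lung mask into (left, right) by connected component.

    Components are labelled with 26-connectivity; the two largest are
    kept (extras dropped with a warning) and assigned left/right by
    their transversal centroid (axis 0 runs right to left).  A single
    fused component is split at the transversal centroid plane when
    ``midline_fallback`` is set, and is an error otherwise.
    """
    if lung.is_empty():
        raise ValueError("empty lung mask")
    labels, n = ndimage.label(lung.data, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 1:
        if not midline_fallback:
            raise ValueError("lung mask is a single fused component; enable midline_fallback to split")
        t_idx = np.nonzero(lung.data)[AXIS_TRANSVERSAL]
        c = t_idx.mean()
        grid_t = np.arange(lung.shape[AXIS_TRANSVERSAL]).reshape(-1, 1, 1)
        right = BinaryMask(lung.data & (grid_t < c), lung.spacing_mm, name="r_lung")
        left = BinaryMask(lung.data & (grid_t >= c), lung.spacing_mm, name="l_lung")
        return left, right
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    if n > 2:
        log.warning("lung mask has %d components; keeping the two largest", n)
    keep = order[:2]
    centroids = ndimage.center_of_mass(lung.data, labels, index=keep)
    # axis 0 runs right -> left: smaller transversal centroid = right lung
    right_label, left_label = sorted(keep, key=lambda lab: centroids[list(keep).index(lab)][AXIS_TRANSVERSAL])
    left = BinaryMask(labels == left_label, lung.spacing_mm, name="l_lung")
    right = BinaryMask(labels == right_label, lung.spacing_mm, name="r_lung")
    return left, right


def split_two_compartments(lung: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """Ventral/dorsal split at the coronal plane through the mask centroid.

    The plane sits at the unweighted voxel centroid along the sagittal
    axis; voxels strictly ventral of it go to the ventral half, the rest
    (including plane voxels) to the dorsal half.
    """
    if lung.is_empty():
        raise ValueError("empty lung mask")
    sag_idx = np.nonzero(lung.data)[AXIS_SAGITTAL]
    c = sag_idx.mean()
    grid_s = np.arange(lung.shape[AXIS_SAGITTAL]).reshape(1, -1, 1)
    ventral = BinaryMask(lung.data & (grid_s < c), lung.spacing_mm, name="lung_cs2_vent")
    dorsal = BinaryMask(lung.data & (grid_s >= c), lung.spacing_mm, name="lung_cs2_dors")
    return ventral, dorsal


def split_three_compartments(lung: BinaryMask) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Ventral/medial/dorsal thirds of the lung's tight bounding box.

    The sagittal extent of the bounding box is divided into three
    near-equal slice bins; remainder slices are assigned to the
    dorsal-most bins (depth 10 -> 3/3/4).
    """
    if lung.is_empty():
        raise ValueError("empty lung mask")
    sag_idx = np.nonzero(lung.data)[AXIS_SAGITTAL]
    lo, hi = int(sag_idx.min()), int(sag_idx.max())
    depth = hi - lo + 1
    base, rem = divmod(depth, 3)
    widths = [base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0)]
    edges = np.cumsum([lo] + widths)  # [lo, lo+w0, lo+w0+w1, hi+1]
    grid_s = np.arange(lung.shape[AXIS_SAGITTAL]).reshape(1, -1, 1)
    names = ("lung_cs3_vent", "lung_cs3_med", "lung_cs3_dors")
    out = []
    for k, name in enumerate(names):
        sel = (grid_s >= edges[k]) & (grid_s < edges[k + 1])
        out.append(BinaryMask(lung.data & sel, lung.spacing_mm, name=name))
    return tuple(out)


def functional_partition(
    vol: CTVolume,
    lung: BinaryMask,
    edges_hu: tuple[float, ...] = AERATION_EDGES_HU,
    clamp_hu: tuple[float, float] = AERATION_CLAMP_HU,
) -> dict[str, BinaryMask]:
    """Assign in-lung voxels to the four aeration compartments by HU.

    HUs are clamped to ``clamp_hu`` first; intervals are right-open
    except the last, so -900 HU is normally aerated and +100 HU is
    non-aerated.  The four masks partition the lung exactly.
    """
    check_aligned(vol, lung)
    hu = np.clip(vol.data, *clamp_hu)
    # digitize with right-open bins: index k for edges[k] <= hu < edges[k+1]
    bins = np.digitize(hu, edges_hu[1:-1], right=False)
    out = {}
    for k, name in enumerate(COMPARTMENT_NAMES):
        out[name] = BinaryMask(lung.data & (bins == k), lung.spacing_mm, name=name)
    return out


def build_registry(vol: CTVolume, lung: BinaryMask, midline_fallback: bool = True) -> ROIRegistry:
    """Materialize all 42 ROI masks for one subject.

    Empty spatial ROIs are tolerated with a warning (their features are
    emitted as zero/missing downstream); every intersection mask is the
    voxelwise AND of its two parents.
    """
    check_aligned(vol, lung)
    if lung.is_empty():
        raise ValueError("empty lung mask")

    left, right = split_left_right(lung, midline_fallback=midline_fallback)
    cs2_vent, cs2_dors = split_two_compartments(lung)
    cs3 = split_three_compartments(lung)
    functional = functional_partition(vol, lung)

    masks: dict[str, BinaryMask] = {
        "lungs": BinaryMask(lung.data.copy(), lung.spacing_mm, name="lungs"),
        "l_lung": left, "r_lung": right,
        "lung_cs2_vent": cs2_vent, "lung_cs2_dors": cs2_dors,
        "lung_cs3_vent": cs3[0], "lung_cs3_med": cs3[1], "lung_cs3_dors": cs3[2],
    }
    defs = [ROIDefinition(n, "spatial") for n in SPATIAL_NAMES]
    for name in FUNCTIONAL_NAMES:
        masks[name] = functional[name]
        defs.append(ROIDefinition(name, "functional"))

    def add_intersection(a: str, b: str) -> None:
        # l_lung x lung_cs3_med -> l_lung_cs3_med (fold the repeated "lung")
        if a in ("l_lung", "r_lung") and b.startswith("lung_"):
            name = a[:2] + b
        else:
            name = f"{a}_{b}"
        masks[name] = masks[a].intersect(masks[b], name=name)
        defs.append(ROIDefinition(name, "intersection", components=(a, b)))

    for side in ("l_lung", "r_lung"):
        for comp in ("lung_cs2_vent", "lung_cs2_dors", "lung_cs3_vent", "lung_cs3_med", "lung_cs3_dors"):
            add_intersection(side, comp)  # e.g. l_lung_cs3_med
        for fn in FUNCTIONAL_NAMES:
            add_intersection(side, fn)  # e.g. r_lung_atelectatic
    for comp in ("lung_cs3_vent", "lung_cs3_med", "lung_cs3_dors"):
        for fn in FUNCTIONAL_NAMES:
            add_intersection(comp, fn)  # e.g. lung_cs3_dors_atelectatic

    for d in defs:
        if d.kind == "spatial" and masks[d.name].is_empty():
            log.warning("spatial ROI %r is empty", d.name)
    registry = ROIRegistry(defs, masks)
    counts = registry.counts_by_kind()
    assert counts == {"spatial": 8, "functional": 4, "intersection": 30}, counts
    return registry
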