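"""First-order and geometric features per ROI: 42 x 14 + 4 = 592 values.

Per ROI (suffix in parentheses): mean / sd / excess kurtosis / skewness
of the HU distribution (``m_HU``, ``s_HU``, ``k_HU``, ``sk_HU``); gas
volume, water volume and tissue weight from the gas-water voxel mixture
model (``gasvol``, ``watervol`` in mm^3, ``weight`` in g); density-
weighted centre of gravity normalized to the lung bounding box
(``cog_t``, ``cog_s``, ``cog_l``); ROI volume (``vol``, mm^3) and
bounding-box dimensions (``dim_t``, ``dim_s``, ``dim_l``, mm).

Four global features give each aeration compartment's volume as a
fraction of the whole lung: ``hyperinflated``, ``normal_ventilated``,
``poor_ventilated``, ``atelectatic``.

The gas-water model treats every voxel as a mixture of gas and water:
the gas fraction is HU / -1000 (HU clamped to [-1000, 0] so the
decomposition stays physical), water is the remainder, and tissue weight
is water volume times the density of water at 37 degC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    COMPARTMENT_NAMES,
    GAS_FRACTION_CLAMP_HU,
    HU_AIR,
    WATER_DENSITY_G_PER_MM3,
)
from .roi_extraction import ROIRegistry
from .volumes import BinaryMask, CTVolume, check_aligned

log = logging.getLogger(__name__)

FEATURE_SUFFIXES = (
    "m_HU", "s_HU", "k_HU", "sk_HU",
    "gasvol", "watervol", "weight",
    "cog_t", "cog_s", "cog_l",
    "vol", "dim_t", "dim_s", "dim_l",
)

GLOBAL_FEATURES = COMPARTMENT_NAMES

FEATURE_UNITS = {
    "m_HU": "HU", "s_HU": "HU", "k_HU": "-", "sk_HU": "-",
    "gasvol": "mm^3", "watervol": "mm^3", "weight": "g",
    "cog_t": "-", "cog_s": "-", "cog_l": "-",
    "vol": "mm^3", "dim_t": "mm", "dim_s": "mm", "dim_l": "mm",
}


def roi_volume(mask: BinaryMask) -> float:
    """ROI volume in mm^3: voxel volume times voxel count."""
    return mask.volume_mm3


def gas_water_weight(vol: CTVolume, mask: BinaryMask) -> tuple[float, float, float]:
    """Gas volume, water volume (mm^3) and tissue weight (g) of an ROI.

    Per voxel, gas = (HU / HU_air) * V_voxel with HU clamped to
    [-1000, 0]; water is the ROI volume minus the gas volume, so the two
    sum to the ROI volume exactly; weight = water volume x 9.933e-4 g/mm^3.
    """
    check_aligned(vol, mask)
    v_roi = mask.volume_mm3
    if mask.is_empty():
        return 0.0, 0.0, 0.0
    hu = np.clip(vol.data[mask.data], *GAS_FRACTION_CLAMP_HU)
    v_gas = float((hu / HU_AIR).sum() * mask.voxel_volume_mm3)
    v_water = v_roi - v_gas
    return v_gas, v_water, v_water * WATER_DENSITY_G_PER_MM3


def hu_statistics(vol: CTVolume, mask: BinaryMask) -> tuple[float, float, float, float]:
    """Sample mean, sd, excess kurtosis and skewness of in-ROI HU values.

    Conventions: sd with ddof=1; skewness is the adjusted Fisher-Pearson
    sample coefficient; kurtosis is the bias-corrected Fisher excess
    (normal -> 0).  Degenerate cases (too few voxels, or zero variance)
    come back as NaN rather than zero.
    """
    check_aligned(vol, mask)
    x = vol.data[mask.data]
    n = x.size
    if n == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    mean = float(x.mean())
    if n < 2:
        return mean, float("nan"), float("nan"), float("nan")
    sd = float(x.std(ddof=1))
    if sd == 0.0 or n < 3:
        return mean, sd, float("nan"), float("nan")
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    skew = (np.sqrt(n * (n - 1)) / (n - 2)) * m3 / m2**1.5
    if n < 4:
        return mean, sd, float("nan"), float(skew)
    m4 = float(((x - mean) ** 4).mean())
    g2 = m4 / m2**2 - 3.0
    kurt = ((n - 1) / ((n - 2) * (n - 3))) * ((n + 1) * g2 + 6.0)
    return mean, sd, float(kurt), float(skew)


def cog_relative(vol: CTVolume, lung: BinaryMask, mask: BinaryMask) -> tuple[float, float, float]:
    """Density-weighted centre of gravity, normalized to the lung box.

    Weights are HU + 1000 clamped below at 0 (proportional to physical
    density under the gas-water model); the weighted centroid along each
    axis is mapped to [0, 1] between the lung mask's bounding-box faces.
    An all-zero weight pattern (pure air ROI) falls back to the
    unweighted centroid.
    """
    check_aligned(vol, lung)
    check_aligned(vol, mask)
    if lung.is_empty():
        raise ValueError("empty lung mask")
    if mask.is_empty():
        return float("nan"), float("nan"), float("nan")
    idx = np.nonzero(mask.data)
    w = np.clip(vol.data[mask.data] + 1000.0, 0.0, None)
    if w.sum() == 0.0:
        log.info("all-zero density weights in ROI %r; using unweighted centroid", mask.name)
        w = np.ones_like(w)
    lung_idx = np.nonzero(lung.data)
    out = []
    for ax in range(3):
        cog = float((w * idx[ax]).sum() / w.sum())
        lo, hi = float(lung_idx[ax].min()), float(lung_idx[ax].max())
        out.append(0.5 if hi == lo else float(np.clip((cog - lo) / (hi - lo), 0.0, 1.0)))
    return tuple(out)


def roi_dimensions(mask: BinaryMask) -> tuple[float, float, float]:
    """Tight bounding-box extent of the ROI along each axis, in mm."""
    if mask.is_empty():
        return 0.0, 0.0, 0.0
    idx = np.nonzero(mask.data)
    return tuple(
        float((idx[ax].max() - idx[ax].min() + 1) * mask.spacing_mm[ax]) for ax in range(3)
    )


def relative_aeration(functional_volumes: dict[str, float], lung_volume: float) -> dict[str, float]:
    """Aeration compartment volumes as fractions of the lung volume."""
    if lung_volume <= 0:
        raise ValueError("lung volume must be > 0")
    return {name: functional_volumes[name] / lung_volume for name in COMPARTMENT_NAMES}


def extract_all(vol: CTVolume, lung: BinaryMask, registry: ROIRegistry, subject_id: str = "") -> pd.Series:
    """Compute the full 592-value feature vector for one subject.

    Returns a Series indexed by feature name in a fixed order (14
    features per ROI in registry order, then the four global fractions).
    Empty ROIs yield zero volumes/dimensions and NaN distribution
    statistics.
    """
    if len(registry) != 42:
        raise ValueError(f"registry must have 42 ROIs, got {len(registry)}")
    values: dict[str, float] = {}
    for name, mask in registry:
        m, s, k, sk = hu_statistics(vol, mask)
        v_gas, v_water, weight = gas_water_weight(vol, mask)
        cog_t, cog_s, cog_l = cog_relative(vol, lung, mask)
        dim_t, dim_s, dim_l = roi_dimensions(mask)
        row = {
            "m_HU": m, "s_HU": s, "k_HU": k, "sk_HU": sk,
            "gasvol": v_gas, "watervol": v_water, "weight": weight,
            "cog_t": cog_t, "cog_s": cog_s, "cog_l": cog_l,
            "vol": roi_volume(mask), "dim_t": dim_t, "dim_s": dim_s, "dim_l": dim_l,
        }
        for suffix in FEATURE_SUFFIXES:
            values[f"{name}_{suffix}"] = row[suffix]

    functional_volumes = {name: registry.masks[name].volume_mm3 for name in COMPARTMENT_NAMES}
    values.update(relative_aeration(functional_volumes, lung.volume_mm3))
    series = pd.Series(values, name=subject_id or None)
    assert len(series) == 592, len(series)
    return series


def feature_schema(registry_names: list[str]) -> dict[str, str]:
    """Map every feature name to its unit."""
    schema = {
        f"{roi}_{suffix}": FEATURE_UNITS[suffix]
        for roi in registry_names
        for suffix in FEATURE_SUFFIXES
    }
    schema.update({name: "-" for name in GLOBAL_FEATURES})
    return schema
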