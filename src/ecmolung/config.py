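"""Package-wide physical constants and configurable conventions.

The aeration compartment boundaries follow the Gattinoni convention on
the Hounsfield scale, with right-open intervals so a voxel at exactly
-900 HU counts as normally aerated.  All of these are plain module-level
defaults; functions that use them accept overrides.
"""

from __future__ import annotations

# HU interval edges for the four aeration compartments (right-open except the last):
#   [-1000, -900) hyperinflated, [-900, -500) normally aerated,
#   [-500, -100) poorly aerated, [-100, +100] non-aerated.
AERATION_EDGES_HU: tuple[float, float, float, float, float] = (-1000.0, -900.0, -500.0, -100.0, 100.0)

# HU values are clamped to this range before compartment assignment.
AERATION_CLAMP_HU: tuple[float, float] = (-1000.0, 100.0)

COMPARTMENT_NAMES: tuple[str, str, str, str] = (
    "hyperinflated",
    "normal_ventilated",
    "poor_ventilated",
    "atelectatic",
)

# Gas/water voxel decomposition: HU of pure air, and the clamp applied
# before computing the per-voxel gas fraction so the decomposition stays
# physical (gas fraction in [0, 1]).
HU_AIR: float = -1000.0
GAS_FRACTION_CLAMP_HU: tuple[float, float] = (-1000.0, 0.0)

# Density of water at body temperature (37 degC), in g/mm^3.
WATER_DENSITY_G_PER_MM3: float = 9.933e-4

# CNN-era preprocessing resolution, kept as a config default for mask
# resampling workflows (the package itself does not require it).
DEFAULT_DOWNSCALE_SHAPE: tuple[int, int, int] = (256, 256, 128)
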