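"""Synthetic CT phantoms and patient cohorts for exercising the pipeline.

The real study data (ICU lung CTs and clinical covariates) cannot be
shared, so every downstream stage is developed and validated against
synthetic inputs with the same statistical structure:

* :func:`generate_phantom` builds a two-ellipsoid "lung" filled with a
  per-voxel mixture of the four aeration compartments (hyperinflated,
  normally aerated, poorly aerated, non-aerated) drawn from Gaussian HU
  distributions, with a ventral-to-dorsal gradient in the non-aerated
  probability that mimics gravity-dependent atelectasis.
* :func:`generate_cohort` draws clinical covariates and a normally
  aerated lung fraction, assigns each subject an ECMO probability from a
  known ground-truth logistic model, and converts it into competing-risk
  event times (ECMO initiation vs. death without ECMO) via cause-specific
  exponential hazards with administrative censoring.
* :func:`generate_planted_signal` builds a tabular feature matrix with a
  single causal feature among correlated noise blocks, for testing
  signature discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import COMPARTMENT_NAMES
from .predictive_models import LogisticModel, published_model
from .volumes import AXIS_SAGITTAL, BinaryMask, CTVolume

# Per-compartment HU distributions (mean, sd).  Component means sit
# centrally inside the aeration intervals used downstream, so compartment
# labels survive threshold-based reclassification up to tail overlap.
DEFAULT_HU_MIXTURE: dict[str, tuple[float, float]] = {
    "hyperinflated": (-950.0, 25.0),
    "normal_ventilated": (-750.0, 80.0),
    "poor_ventilated": (-300.0, 110.0),
    "atelectatic": (20.0, 40.0),
}

HU_TRUNCATION = (-1024.0, 100.0)
SOFT_TISSUE_HU = (40.0, 10.0)  # mean, sd of the background, clipped to [0, 60]


@dataclass
class PhantomSpec:
    """Parameters of a two-ellipsoid lung phantom.

    ``lung_geometry`` holds two ``(center_mm, semi_axes_mm)`` pairs (left
    and right lung).  ``compartment_fractions`` are the target volume
    fractions of (hyperinflated, normal, poor, non-aerated) and must sum
    to 1.  ``gradient_strength`` shifts the non-aerated log-odds linearly
    from the ventral to the dorsal face of the lung bounding box; the
    baseline is recalibrated so the lung-wide mean non-aerated fraction
    stays at its target.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_geometry: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] | None = None
    compartment_fractions: tuple[float, float, float, float] = (0.05, 0.45, 0.25, 0.25)
    gradient_strength: float = 2.0
    hu_mixture: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_HU_MIXTURE))
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("grid shape and voxel size must be positive")
        f = np.asarray(self.compartment_fractions, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions must lie in [0,1] and sum to 1, got {tuple(f)}")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")
        if self.lung_geometry is None:
            self.lung_geometry = self._default_geometry()
        if len(self.lung_geometry) != 2:
            raise ValueError("lung_geometry must contain exactly two ellipsoids")
        extent = np.array(self.grid_shape) * np.array(self.voxel_size_mm)
        for center, semi in self.lung_geometry:
            center, semi = np.asarray(center, float), np.asarray(semi, float)
            if np.any(semi <= 0):
                raise ValueError(f"ellipsoid semi-axes must be positive, got {tuple(semi)}")
            if np.any(center - semi < -1e-9) or np.any(center + semi > extent + 1e-9):
                raise ValueError("ellipsoid does not fit inside the grid")
        for name in COMPARTMENT_NAMES:
            mean, sd = self.hu_mixture[name]
            if not (np.isfinite(mean) and np.isfinite(sd) and sd > 0):
                raise ValueError(f"invalid HU mixture for {name!r}: ({mean}, {sd})")

    def _default_geometry(self):
        extent = np.array(self.grid_shape) * np.array(self.voxel_size_mm)
        semi = tuple(extent * np.array([0.20, 0.34, 0.39]))
        right = tuple(extent * np.array([0.30, 0.5, 0.5]))  # axis 0 runs right -> left
        left = tuple(extent * np.array([0.70, 0.5, 0.5]))
        return ((right, semi), (left, semi))


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for center, semi in spec.lung_geometry:
        cx, cy, cz = center
        ax, ay, az = semi
        mask |= ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0
    return mask


def _calibrated_nonaerated_prob(depth: np.ndarray, f4: float, strength: float) -> np.ndarray:
    """Per-voxel non-aerated probability with a dorsal gradient.

    ``depth`` is the normalized ventral->dorsal position in [0, 1] of each
    lung voxel.  The log-odds of the non-aerated class are shifted by
    ``strength * (depth - 0.5) + c`` where the offset ``c`` is solved so
    the mean probability over the actual lung voxels equals ``f4``; the
    remaining compartments share ``1 - p4`` in their target proportions,
    so every compartment keeps its lung-wide target fraction in
    expectation regardless of the gradient.
    """
    if f4 <= 0.0:
        return np.zeros_like(depth)
    if f4 >= 1.0:
        return np.ones_like(depth)
    base = np.log(f4 / (1.0 - f4))
    shift = strength * (depth - 0.5)

    def mean_p4(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(base + shift + c))))) - f4

    if strength == 0.0:
        c = 0.0
    else:
        c = optimize.brentq(mean_p4, -strength - 20.0, strength + 20.0, xtol=1e-12)
    return 1.0 / (1.0 + np.exp(-(base + shift + c)))


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, BinaryMask]:
    """Generate a phantom CT volume and its ground-truth lung mask.

    Returns the HU volume (soft-tissue background, lung interior drawn
    from the compartment mixture with dorsal bias) and the exact
    ellipsoid-union lung mask.
    """
    rng = np.random.default_rng(spec.seed)
    lung = _ellipsoid_mask(spec)
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ValueError("degenerate phantom geometry: zero-volume lung")

    # Normalized ventral->dorsal depth within the lung bounding box.
    sag_idx = np.nonzero(lung)[AXIS_SAGITTAL]
    lo, hi = sag_idx.min(), sag_idx.max()
    depth = (sag_idx - lo) / max(hi - lo, 1)

    f = np.asarray(spec.compartment_fractions, dtype=float)
    p4 = _calibrated_nonaerated_prob(depth, f[3], spec.gradient_strength)
    rest = f[:3] / f[:3].sum() if f[:3].sum() > 0 else np.zeros(3)
    probs = np.empty((n_lung, 4))
    probs[:, :3] = np.outer(1.0 - p4, rest)
    probs[:, 3] = p4

    u = rng.random(n_lung)
    labels = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
    labels = np.minimum(labels, 3)

    hu_lung = np.empty(n_lung)
    for k, name in enumerate(COMPARTMENT_NAMES):
        sel = labels == k
        if sel.any():
            mean, sd = spec.hu_mixture[name]
            hu_lung[sel] = _truncated_normal(rng, mean, sd, *HU_TRUNCATION, size=int(sel.sum()))

    data = np.clip(rng.normal(*SOFT_TISSUE_HU, size=spec.grid_shape), 0.0, 60.0)
    data[lung] = hu_lung
    vol = CTVolume(data, spec.voxel_size_mm)
    return vol, BinaryMask(lung, spec.voxel_size_mm, name="lungs")


# ---------------------------------------------------------------------------
# Cohorts


#: Covariate marginals matched to an ICU ARDS population: mean, sd and
#: truncation bounds for age (years), mean airway pressure (cmH2O),
#: lactate (mmol/L), CRP (mg/L) and the normally aerated lung fraction.
DEFAULT_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "age": (62.0, 11.0, 18.0, 95.0),
    "pmean": (13.6, 2.7, 5.0, 30.0),
    "lactate": (1.6, 1.2, 0.2, 15.0),
    "crp": (174.0, 108.0, 1.0, 600.0),
    "normal_vent": (0.492, 0.15, 0.02, 0.98),
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic competing-risk cohort.

    The ECMO outcome probability of each subject comes from
    ``true_model`` (a logistic model on age, pmean, lactate, CRP and
    normal_vent; defaults to the published combined model).  The ECMO
    cause-specific hazard is chosen so that, absent death and early
    censoring, the probability of an ECMO event by the censoring horizon
    equals the model probability exactly; death acts as an independent
    exponential competing hazard.
    """

    n_subjects: int = 200
    true_model: LogisticModel | None = None
    covariate_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    death_rate_per_day: float = 0.012
    ecmo_rate_scale: float = 1.0
    censoring_horizon_days: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.true_model is None:
            self.true_model = published_model("combined")
        if self.death_rate_per_day < 0 or self.ecmo_rate_scale < 0:
            raise ValueError("hazard rates must be >= 0")
        if self.censoring_horizon_days <= 0:
            raise ValueError("censoring horizon must be > 0")
        for name, (mean, sd, lo, hi) in self.covariate_distributions.items():
            if not all(np.isfinite(v) for v in (mean, sd, lo, hi)) or sd <= 0 or hi <= lo:
                raise ValueError(f"invalid covariate distribution for {name!r}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with covariates and competing-risk outcomes.

    Returns a DataFrame with columns ``subject_id``, the covariates,
    ``p_ecmo`` (ground-truth model probability), ``time_days`` and
    ``event_code`` (0 censored, 1 ECMO, 2 death without ECMO).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd, lo, hi) in spec.covariate_distributions.items():
        cols[name] = _truncated_normal(rng, mean, sd, lo, hi, size=n)
    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(n)])

    p = spec.true_model.predict_proba(df)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    df["p_ecmo"] = p

    horizon = spec.censoring_horizon_days
    lam_ecmo = spec.ecmo_rate_scale * (-np.log1p(-p)) / horizon
    with np.errstate(divide="ignore"):
        t_ecmo = np.where(lam_ecmo > 0, rng.exponential(1.0, size=n) / np.where(lam_ecmo > 0, lam_ecmo, 1.0), np.inf)
    if spec.death_rate_per_day > 0:
        t_death = rng.exponential(1.0 / spec.death_rate_per_day, size=n)
    else:
        t_death = np.full(n, np.inf)

    t_event = np.minimum(t_ecmo, t_death)
    event = np.where(t_event >= horizon, 0, np.where(t_ecmo <= t_death, 1, 2))
    time = np.minimum(t_event, horizon)
    # keep times strictly positive and finite
    df["time_days"] = np.maximum(time, 1e-6)
    df["event_code"] = event.astype(int)
    return df


def generate_planted_signal(
    n_subjects: int = 200,
    n_noise: int = 50,
    n_blocks: int = 5,
    block_corr: float = 0.6,
    signal_leak: float = 0.2,
    effect: float = 2.5,
    intercept: float = -0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A feature table with one causal feature among correlated noise.

    The causal feature drives a Bernoulli outcome through a logistic
    model with slope ``effect``.  The ``n_noise`` decoys fall into
    ``n_blocks`` blocks sharing a latent factor (pairwise correlation
    about ``block_corr``); each block factor carries a weak loading
    ``signal_leak`` on the causal feature, so decoys are marginally
    informative and mutually redundant — the structure that the
    clustering + MRMR + Borda pipeline is meant to see through.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_subjects)
    y = (rng.random(n_subjects) < 1.0 / (1.0 + np.exp(-(intercept + effect * z)))).astype(int)

    cols = {"causal": z}
    lam = np.sqrt(block_corr)
    for b in range(n_blocks):
        factor = signal_leak * z + np.sqrt(1 - signal_leak**2) * rng.standard_normal(n_subjects)
        for j in range(n_noise // n_blocks + (1 if b < n_noise % n_blocks else 0)):
            eps = rng.standard_normal(n_subjects)
            cols[f"noise_b{b}_{j}"] = lam * factor + np.sqrt(1 - block_corr) * eps
    return pd.DataFrame(cols), y
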