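"""Volume-to-mass conversion, density calibration, per-fish aggregation.

Fish tissue is close to neutrally buoyant, so mass is modelled as a single
density coefficient times the reconstructed volume.  The coefficient can be
calibrated from (volume, mass) pairs by least squares through the origin —
zero volume must give zero mass — or left at the default 1.05 g/cm^3
typical of teleost tissue.

Per-fish estimates aggregate many frames of the same individual: the mean,
the sample standard deviation, and a Student-t 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_DENSITY_G_CM3",
    "DensityModel",
    "MassEstimate",
    "volume_to_mass",
    "fit_density",
    "aggregate_frames",
]

#: near-neutral buoyancy of teleost tissue, g/cm^3
DEFAULT_DENSITY_G_CM3 = 1.05


@dataclass(frozen=True)
class DensityModel:
    """Mass = rho * volume; rho stored in g/cm^3 (= mg/mm^3)."""

    rho_g_cm3: float = DEFAULT_DENSITY_G_CM3
    fit_r2: float | None = None
    n_pairs: int = 0

    def __post_init__(self):
        if not self.rho_g_cm3 > 0:
            raise ValueError(f"density must be positive, got {self.rho_g_cm3}")


@dataclass(frozen=True)
class MassEstimate:
    """Aggregate of per-frame masses for one fish."""

    fish_id: str
    mean_mass: float
    sd: float
    ci95: tuple[float, float]
    n_frames: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("standard deviation cannot be negative")
        if not (self.ci95[0] <= self.mean_mass <= self.ci95[1]):
            raise ValueError("confidence interval must contain the mean")


def volume_to_mass(volume_mm3: float, model: DensityModel) -> float:
    """Convert a volume in mm^3 to a mass in grams (linear in volume)."""
    if volume_mm3 < 0:
        raise ValueError("volume cannot be negative")
    return model.rho_g_cm3 * volume_mm3 / 1000.0


def fit_density(pairs: Sequence[tuple[float, float]]) -> DensityModel:
    """Calibrate the density coefficient from (volume mm^3, mass g) pairs.

    Least-squares slope through the origin, rho = sum(m*V) / sum(V^2),
    reported in g/cm^3.  ``fit_r2`` is the conventional centered R^2 of the
    fitted line (it may be negative for a badly mis-specified fit).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (volume, mass) pairs")
    V, m = arr[:, 0], arr[:, 1]
    if np.any(V < 0):
        raise ValueError("volumes must be non-negative")
    ssv = float(np.sum(V * V))
    if ssv == 0:
        raise ValueError("degenerate calibration: all volumes are zero")
    slope = float(np.sum(m * V)) / ssv  # g per mm^3
    resid = m - slope * V
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else None
    return DensityModel(rho_g_cm3=slope * 1000.0, fit_r2=r2, n_pairs=arr.shape[0])


def aggregate_frames(per_frame_masses: Sequence[float], fish_id: str = "") -> MassEstimate:
    """Mean, sample SD, and t-based 95% CI over a fish's frames."""
    m = np.asarray(per_frame_masses, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 frames to aggregate")
    mean = float(m.mean())
    sd = float(m.std(ddof=1))
    half = float(stats.t.ppf(0.975, m.size - 1)) * sd / np.sqrt(m.size)
    return MassEstimate(
        fish_id=fish_id,
        mean_mass=mean,
        sd=sd,
        ci95=(mean - half, mean + half),
        n_frames=int(m.size),
    )
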