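"""Closed-form total-internal-reflection (TIRF) excitation physics.

An excitation beam travelling in a dense medium (glass, refractive index
``n1``) and striking the interface with a rarer medium (water or mounting
medium, ``n2``) beyond the critical angle is totally reflected.  Beyond the
interface only a non-propagating evanescent field remains, whose intensity
decays exponentially with the distance ``z`` from the interface::

    I(z) = I0 * exp(-z / d),   d = lambda / (4 pi sqrt(n1^2 sin^2(theta) - n2^2))

``d`` is the penetration depth: the distance over which the intensity falls
to ``1/e`` of its value at the interface.  All intensities in this package
are relative to ``I0 = 1``; no Fresnel transmission enhancement at ``z = 0``
is modelled (a documented simplification — the depth selectivity, not the
absolute amplitude, is the quantity of interest here).

Angles are degrees at the API boundary and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InterfaceConfig",
    "FieldProfile",
    "NoTotalInternalReflectionError",
    "PropagatingRegimeError",
    "critical_angle",
    "penetration_depth",
    "evanescent_profile",
]

#: the closed set of curve labels a FieldProfile may carry
PROFILE_LABELS = ("evanescent", "lspr", "set", "lspr_x_set")


class NoTotalInternalReflectionError(ValueError):
    """Raised when n2 >= n1: no total internal reflection exists."""


class PropagatingRegimeError(ValueError):
    """Raised when the incidence angle is at or below the critical angle,
    so the transmitted field propagates and no evanescent depth is defined."""


@dataclass(frozen=True)
class InterfaceConfig:
    """Plane-interface excitation geometry.

    Parameters
    ----------
    wavelength_nm : vacuum wavelength of the excitation light.
    n1 : refractive index on the incidence (substrate) side, e.g. 1.52 glass.
    n2 : refractive index on the transmission (sample) side, e.g. 1.33 water
        or 1.46 glycerol-based mounting medium.
    theta_deg : incidence angle measured from the interface normal.
    I0 : reference intensity at z = 0 (relative units, default 1).
    """

    wavelength_nm: float
    n1: float = 1.52
    n2: float = 1.33
    theta_deg: float = 0.0
    I0: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be positive, got {self.wavelength_nm}")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("refractive indices must be positive")
        if not 0.0 <= self.theta_deg < 90.0:
            raise ValueError(f"theta_deg must lie in [0, 90), got {self.theta_deg}")


@dataclass
class FieldProfile:
    """A relative-intensity-versus-distance curve.

    ``distance_nm`` is a strictly increasing grid; ``relative_intensity``
    holds I/I0 (dimensionless, >= 0) at each grid point; ``label`` names the
    curve (one of ``evanescent``, ``lspr``, ``set``, ``lspr_x_set``).
    """

    distance_nm: np.ndarray
    relative_intensity: np.ndarray
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance_nm = np.asarray(self.distance_nm, dtype=float)
        self.relative_intensity = np.asarray(self.relative_intensity, dtype=float)
        if self.distance_nm.shape != self.relative_intensity.shape:
            raise ValueError("distance and intensity grids must have equal shape")
        if self.distance_nm.ndim != 1 or len(self.distance_nm) < 2:
            raise ValueError("profile needs a 1-D grid of at least two points")
        if np.any(np.diff(self.distance_nm) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if not np.all(np.isfinite(self.relative_intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.relative_intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.label not in PROFILE_LABELS:
            raise ValueError(f"label must be one of {PROFILE_LABELS}, got {self.label!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_nm": self.distance_nm,
                "relative_intensity": self.relative_intensity,
                "label": self.label,
            }
        )

    def to_csv(self, path) -> None:
        """Write the shared CSV dialect: distance_nm, relative_intensity, label."""
        self.to_frame().to_csv(path, index=False)

    def interpolate(self, distance_nm) -> np.ndarray:
        """Linear interpolation on the stored grid (clamped at the ends)."""
        return np.interp(distance_nm, self.distance_nm, self.relative_intensity)


def critical_angle(n1: float, n2: float) -> float:
    """Critical angle of total internal reflection, in degrees.

    Returns ``arcsin(n2 / n1)``; requires ``n1 > n2 > 0``.
    """
    if n2 <= 0 or n1 <= 0:
        raise ValueError("refractive indices must be positive")
    if n2 >= n1:
        raise NoTotalInternalReflectionError(
            f"no total internal reflection: n2={n2} >= n1={n1}"
        )
    return float(np.degrees(np.arcsin(n2 / n1)))


def penetration_depth(config: InterfaceConfig) -> float:
    """Evanescent-field penetration depth in nm.

    ``d = lambda / (4 pi sqrt(n1^2 sin^2 theta - n2^2))``; defined only above
    the critical angle.  For glass/water at 561 nm and 65 degrees this gives
    124.4 nm.
    """
    theta_c = critical_angle(config.n1, config.n2)
    if config.theta_deg <= theta_c:
        raise PropagatingRegimeError(
            f"theta={config.theta_deg:.2f} deg is at or below the critical angle "
            f"{theta_c:.2f} deg: transmitted field propagates, depth undefined"
        )
    theta = np.radians(config.theta_deg)
    return float(
        config.wavelength_nm
        / (4.0 * np.pi * np.sqrt(config.n1**2 * np.sin(theta) ** 2 - config.n2**2))
    )


def evanescent_profile(config: InterfaceConfig, distance_grid) -> FieldProfile:
    """Evanescent intensity profile ``I(z)/I0 = exp(-z/d)`` on a z-grid (nm)."""
    z = np.asarray(distance_grid, dtype=float)
    if np.any(z < 0):
        raise ValueError("distance grid must be non-negative")
    d = penetration_depth(config)
    return FieldProfile(
        distance_nm=z,
        relative_intensity=config.I0 * np.exp(-z / d),
        label="evanescent",
        meta={"penetration_depth_nm": d, "theta_deg": config.theta_deg,
              "wavelength_nm": config.wavelength_nm},
    )
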