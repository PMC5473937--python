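"""Distance-dependent fluorescence quenching near a metal surface.

Two rate laws are supported through a single model type:

* FRET (dipole-dipole, exponent 6):  k(r) = (1/tau_D) (r0 / r)^6
* SET / NSET (dipole-to-metal-surface, exponent 4):  k(d) = (1/tau_D) (d0 / d)^4

``tau_D`` is the unquenched donor lifetime and the characteristic distance
(r0 or d0) is where the transfer rate equals the donor decay rate.  The
observable consequence for imaging is the attenuation factor

    I(d) / I_inf = 1 / (1 + (d0 / d)^exponent)

which is 1/2 at the characteristic distance and approaches 1 far from the
surface.  Multiplying the sheet near-field (LSPR) profile by this factor
gives the net excitation-to-emission profile of a fluorophore near the
nanoparticle sheet: quenched in contact, enhanced in a shell a few nm out,
unity far away.  The surface distance entering the attenuation is always
the distance to the *closest* particle surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .interface_optics import FieldProfile
from .nanosheet_field import NanoparticleSheet, ProbeLine, nearest_surface_distance

__all__ = [
    "EnergyTransferModel",
    "AttenuationCurve",
    "transfer_rate",
    "set_attenuation",
    "attenuation_curve",
    "combined_excitation_profile",
    "fit_distance_exponent",
    "ExponentFit",
]


@dataclass(frozen=True)
class EnergyTransferModel:
    """Donor lifetime, characteristic distance and distance exponent.

    exponent 4 -> surface energy transfer (default); 6 -> FRET-like d^-6.
    """

    characteristic_distance_nm: float = 5.0
    exponent: int = 4
    tau_D: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_D <= 0:
            raise ValueError("tau_D must be positive")
        if self.characteristic_distance_nm <= 0:
            raise ValueError("characteristic distance must be positive")
        if self.exponent not in (4, 6):
            raise ValueError("exponent must be 4 (SET) or 6 (FRET)")


@dataclass
class AttenuationCurve:
    """Attenuation factor I(d)/I_inf on a distance grid; values in (0, 1]."""

    distance_nm: np.ndarray
    attenuation: np.ndarray

    def __post_init__(self) -> None:
        self.distance_nm = np.asarray(self.distance_nm, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if np.any(np.diff(self.distance_nm) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if np.any((self.attenuation <= 0) | (self.attenuation > 1)):
            raise ValueError("attenuation must lie in (0, 1]")

    def as_profile(self) -> FieldProfile:
        return FieldProfile(self.distance_nm, self.attenuation, label="set")


def _check_distance(distance_nm) -> np.ndarray:
    d = np.asarray(distance_nm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    return d


def transfer_rate(model: EnergyTransferModel, distance_nm):
    """Energy-transfer rate (1/tau_D) (x0/x)^n; units of 1/tau_D."""
    d = _check_distance(distance_nm)
    out = (model.characteristic_distance_nm / d) ** model.exponent / model.tau_D
    return out if np.asarray(distance_nm).ndim else float(out)


def set_attenuation(model: EnergyTransferModel, distance_nm):
    """Fluorescence attenuation factor [1 + (d0/d)^n]^-1, in (0, 1)."""
    d = _check_distance(distance_nm)
    out = 1.0 / (1.0 + (model.characteristic_distance_nm / d) ** model.exponent)
    return out if np.asarray(distance_nm).ndim else float(out)


def attenuation_curve(model: EnergyTransferModel, distance_grid) -> AttenuationCurve:
    d = _check_distance(distance_grid)
    return AttenuationCurve(d, set_attenuation(model, d))


def combined_excitation_profile(
    lspr: FieldProfile,
    sheet: NanoparticleSheet,
    probe: ProbeLine,
    model: EnergyTransferModel,
) -> FieldProfile:
    """Pointwise product of the LSPR profile and the SET attenuation.

    The attenuation at each probe position D uses the distance to the
    closest particle surface (sqrt(D^2 + (pitch/2)^2) - r on the mid-gap
    line), not D itself.  The product is the expected relative fluorescence
    excitation of a dye sitting on the probe line.
    """
    if lspr.distance_nm.shape != probe.D_grid.shape or not np.allclose(
        lspr.distance_nm, probe.D_grid
    ):
        raise ValueError("LSPR profile and probe line must share the same D grid")
    surf = nearest_surface_distance(sheet, probe.points())
    product = lspr.relative_intensity * set_attenuation(model, surf)
    meta = dict(lspr.meta)
    meta.update(
        d0_nm=model.characteristic_distance_nm,
        exponent=model.exponent,
    )
    return FieldProfile(probe.D_grid, product, label="lspr_x_set", meta=meta)


@dataclass(frozen=True)
class ExponentFit:
    """Result of a distance-exponent regression."""

    exponent: float
    d0_nm: float
    stderr: float
    ci_low: float
    ci_high: float
    n: int


def fit_distance_exponent(distances, attenuations, confidence: float = 0.95) -> ExponentFit:
    """Estimate the distance exponent from attenuation measurements.

    Rearranging the attenuation law, ``log(1/A - 1) = n log(d0) - n log(d)``
    is linear in ``log d``; a weighted least-squares line gives the exponent
    (minus the slope) and the characteristic distance (``exp(intercept /
    n)``).  For multiplicative noise on A the variance of the transformed
    variable grows as ``1/(1 - A)^2``, so points are weighted by
    ``(1 - A)^2`` — without this, near-saturated far points dominate and
    bias the slope.  Requires at least five points spanning at least a
    factor of three in distance, with attenuations strictly inside (0, 1).
    """
    d = np.asarray(distances, dtype=float)
    a = np.asarray(attenuations, dtype=float)
    if d.shape != a.shape or d.ndim != 1:
        raise ValueError("distances and attenuations must be equal-length 1-D arrays")
    if len(d) < 5:
        raise ValueError("need at least 5 points")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    if d.max() / d.min() < 3.0:
        raise ValueError("degenerate spread: distances must span >= a factor of 3")
    if np.any((a <= 0) | (a >= 1)):
        raise ValueError("attenuations must lie strictly in (0, 1)")
    x = np.log(d)
    y = np.log(1.0 / a - 1.0)
    w = (1.0 - a) ** 2
    X = np.column_stack([x, np.ones_like(x)])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    beta = cov_unscaled @ (XtW @ y)
    resid = y - X @ beta
    dof = len(d) - 2
    sigma2 = float((w * resid**2).sum() / dof)
    slope_se = float(np.sqrt(sigma2 * cov_unscaled[0, 0]))
    exponent = -float(beta[0])
    d0 = float(np.exp(beta[1] / exponent)) if exponent > 0 else float("nan")
    tval = stats.t.ppf(0.5 + confidence / 2.0, dof)
    return ExponentFit(
        exponent=exponent,
        d0_nm=d0,
        stderr=slope_se,
        ci_low=float(exponent - tval * slope_se),
        ci_high=float(exponent + tval * slope_se),
        n=len(d),
    )
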