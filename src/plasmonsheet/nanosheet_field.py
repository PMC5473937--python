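"""Near-field model of a close-packed gold-nanoparticle monolayer.

A two-dimensional self-assembled sheet of oleylamine-capped gold cores
(diameter 12.6 nm, surface-to-surface gap 2.6 nm, hexagonal close packing)
supports a collective localized surface plasmon resonance (LSPR).  The
enhanced optical near field above the sheet is what excites interfacial
fluorophores in sheet-substrate imaging.

The solver is a quasi-static coupled-dipole approximation (CDA): each core
carries a point dipole with the Clausius-Mossotti polarizability

    alpha = r^3 (eps - eps_m) / (eps + 2 eps_m)

in a host of permittivity ``eps_m``; dipoles are coupled through the static
dipole-dipole tensor ``(3 uu - I) / d^3`` and solved self-consistently, and
the total field at a query point is the incident field plus all dipole
fields.  Retardation is neglected — the lattice pitch (15.2 nm) is far
below the wavelength — and the supporting substrate is not modelled (the
host index is the sample-side medium).  The collective red shift of the
sheet resonance emerges from the inter-particle coupling rather than being
imposed.

Gold permittivity comes from the bundled Johnson & Christy (1972)
tabulation (transcribed n, k values converted to complex epsilon) and is
used through a Drude fit, ``eps(w) = eps_inf - wp^2 / (w^2 + i g w)``,
over a fit window around the excitation lines.  The fit degrades toward the
interband edge below ~500 nm; the residual against the table is part of the
model contract (see :func:`fit_drude`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .interface_optics import FieldProfile

__all__ = [
    "MaterialModel",
    "NanoparticleSheet",
    "ProbeLine",
    "load_gold_table",
    "fit_drude",
    "gold_material",
    "single_sphere_enhancement",
    "CoupledDipoleSolver",
    "compute_near_field",
    "lspr_profile",
    "nearest_surface_distance",
    "first_unity_crossing",
]

HC_EV_NM = 1239.842  # photon energy (eV) x wavelength (nm)


class SingularCouplingError(RuntimeError):
    """The coupled-dipole system is (numerically) singular: the requested
    wavelength sits on a collective resonance pole of the lossless system."""


# ---------------------------------------------------------------------------
# material model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialModel:
    """Dispersive metal permittivity plus the surrounding host.

    ``table_wavelength_nm`` / ``table_eps`` hold the literature tabulation;
    ``eps_inf``, ``plasma_energy_ev``, ``damping_ev`` are the fitted Drude
    parameters; ``fit_window_nm`` is the wavelength range over which the fit
    was performed (and outside of which it should not be trusted);
    ``host_index`` is the refractive index of the embedding medium.
    """

    table_wavelength_nm: np.ndarray
    table_eps: np.ndarray
    eps_inf: float
    plasma_energy_ev: float
    damping_ev: float
    fit_window_nm: tuple[float, float]
    host_index: float = 1.33

    @property
    def host_eps(self) -> float:
        return self.host_index**2

    def table_permittivity(self, wavelength_nm: float) -> complex:
        """Linear interpolation of the bundled tabulation."""
        wl = float(wavelength_nm)
        tw = self.table_wavelength_nm
        if wl < tw[0] or wl > tw[-1]:
            raise ValueError(
                f"wavelength {wl} nm outside table range [{tw[0]:.0f}, {tw[-1]:.0f}] nm"
            )
        return complex(
            np.interp(wl, tw, self.table_eps.real),
            np.interp(wl, tw, self.table_eps.imag),
        )

    def permittivity(self, wavelength_nm: float) -> complex:
        """Drude-model permittivity at a vacuum wavelength inside the table range."""
        self.table_permittivity(wavelength_nm)  # range check
        E = HC_EV_NM / float(wavelength_nm)
        return self.eps_inf - self.plasma_energy_ev**2 / (
            E**2 + 1j * self.damping_ev * E
        )

    def polarizability(self, wavelength_nm: float, radius_nm: float) -> complex:
        """Quasi-static (Clausius-Mossotti) sphere polarizability, nm^3."""
        eps = self.permittivity(wavelength_nm)
        em = self.host_eps
        return radius_nm**3 * (eps - em) / (eps + 2 * em)


def load_gold_table() -> pd.DataFrame:
    """Bundled Johnson & Christy gold permittivity table.

    Columns: ``wavelength_nm``, ``eps_real``, ``eps_imag``.
    """
    with importlib.resources.files("plasmonsheet.data").joinpath(
        "au_johnson_christy.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def fit_drude(
    table: pd.DataFrame | None = None,
    fit_window_nm: tuple[float, float] = (500.0, 650.0),
    host_index: float = 1.33,
) -> MaterialModel:
    """Fit a Drude model to a permittivity table over a wavelength window.

    The residual is least squares on real and imaginary parts jointly.  With
    the bundled gold table and the default 500-650 nm window the maximum
    absolute deviation from the table is below 1.5 (dominated by the
    interband-transition tail that a free-electron model cannot capture).
    """
    if table is None:
        table = load_gold_table()
    wl = np.asarray(table["wavelength_nm"], dtype=float)
    eps = np.asarray(table["eps_real"], dtype=float) + 1j * np.asarray(
        table["eps_imag"], dtype=float
    )
    order = np.argsort(wl)
    wl, eps = wl[order], eps[order]
    lo, hi = fit_window_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"fit window {fit_window_nm} not covered by table [{wl[0]:.0f}, {wl[-1]:.0f}]"
        )
    sel = (wl >= lo) & (wl <= hi)
    E = HC_EV_NM / wl[sel]

    def residual(p):
        eps_inf, ep, g = p
        model = eps_inf - ep**2 / (E**2 + 1j * g * E)
        diff = model - eps[sel]
        return np.concatenate([diff.real, diff.imag])

    sol = least_squares(residual, x0=[9.0, 9.0, 0.1], bounds=([1, 1, 1e-4], [30, 20, 2]))
    eps_inf, ep, g = sol.x
    return MaterialModel(
        table_wavelength_nm=wl,
        table_eps=eps,
        eps_inf=float(eps_inf),
        plasma_energy_ev=float(ep),
        damping_ev=float(g),
        fit_window_nm=(float(lo), float(hi)),
        host_index=host_index,
    )


@lru_cache(maxsize=8)
def gold_material(host_index: float = 1.33) -> MaterialModel:
    """Default gold material: bundled table, Drude fit over 500-650 nm."""
    return fit_drude(host_index=host_index)


# ---------------------------------------------------------------------------
# sheet geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NanoparticleSheet:
    """Finite hexagonal patch of gold cores in the z = 0 plane.

    ``patch_size`` particles per row and ``patch_size`` rows, with the
    probed nearest-neighbour pair straddling the origin at (+-pitch/2, 0, 0)
    so that a probe line through the origin reproduces the mid-gap geometry.
    Pitch (center-to-center) = core diameter + gap = 15.2 nm by default.
    """

    core_diameter_nm: float = 12.6
    gap_nm: float = 2.6
    patch_size: int = 13
    material: MaterialModel = field(default_factory=gold_material)

    def __post_init__(self) -> None:
        if self.core_diameter_nm <= 0 or self.gap_nm < 0:
            raise ValueError("core diameter must be positive and gap non-negative")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")

    @property
    def radius_nm(self) -> float:
        return self.core_diameter_nm / 2.0

    @property
    def pitch_nm(self) -> float:
        return self.core_diameter_nm + self.gap_nm

    @property
    def n_particles(self) -> int:
        return self.patch_size**2

    def positions(self) -> np.ndarray:
        """(N, 3) particle centers of the hexagonal patch."""
        a = self.pitch_nm
        n = self.patch_size
        half = n // 2
        rows = []
        for j in range(-half, n - half):
            y = j * a * np.sqrt(3.0) / 2.0
            shift = a / 2.0 if j % 2 else 0.0
            for i in range(n):
                rows.append(((i - half) * a + shift - a / 2.0, y, 0.0))
        pos = np.array(rows, dtype=float)
        # no-overlap invariant: min center spacing equals the pitch
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            if d.min() < self.core_diameter_nm - 1e-9:
                raise ValueError("overlapping cores in lattice")
        return pos


@dataclass(frozen=True)
class ProbeLine:
    """Line normal to the sheet through the midpoint of the probed pair.

    ``D = 0`` lies in the plane of particle centers; positive D points into
    the sample.  The nearest particle surface is sqrt(D^2 + (pitch/2)^2) - r
    away from a probe point, i.e. gap/2 at D = 0.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    D_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 200.0, 2001))

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", tuple(d / np.linalg.norm(d)))
        g = np.asarray(self.D_grid, dtype=float)
        if g.ndim != 1 or np.any(np.diff(g) <= 0):
            raise ValueError("D_grid must be 1-D and strictly increasing")
        object.__setattr__(self, "D_grid", g)

    def points(self) -> np.ndarray:
        o = np.asarray(self.origin, dtype=float)
        u = np.asarray(self.direction, dtype=float)
        return o[None, :] + self.D_grid[:, None] * u[None, :]


def nearest_surface_distance(sheet: NanoparticleSheet, points) -> np.ndarray:
    """Distance from each point to the closest particle surface (nm).

    Negative would mean inside a core; that raises instead.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist = (
        np.linalg.norm(pts[:, None, :] - sheet.positions()[None, :, :], axis=2).min(axis=1)
        - sheet.radius_nm
    )
    if np.any(dist < -1e-9):
        raise ValueError("query point inside a particle core")
    return dist if np.asarray(points).ndim > 1 else float(dist[0])


# ---------------------------------------------------------------------------
# single-sphere closed form (analytic oracle)
# ---------------------------------------------------------------------------

def single_sphere_enhancement(
    material: MaterialModel, radius_nm: float, wavelength_nm: float, points
) -> np.ndarray:
    """Quasi-static intensity enhancement |E/E0|^2 around one sphere.

    The sphere sits at the origin in the host medium; the incident field is
    a unit x-polarized plane wave treated as uniform (radius << wavelength).
    The scattered field is that of the induced point dipole
    ``p = alpha E0``.  Valid only outside the sphere.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    if np.any(r < radius_nm - 1e-9):
        raise ValueError("query point inside the sphere")
    alpha = material.polarizability(wavelength_nm, radius_nm)
    u = pts / r[:, None]
    p = np.array([alpha, 0.0, 0.0], dtype=complex)
    Es = (3.0 * u * (u @ p)[:, None] - p[None, :]) / r[:, None] ** 3
    E = Es + np.array([1.0, 0.0, 0.0])
    out = np.sum(np.abs(E) ** 2, axis=1)
    return out if np.asarray(points).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# coupled-dipole solver
# ---------------------------------------------------------------------------

class CoupledDipoleSolver:
    """Self-consistent dipole solution for a sheet at one wavelength.

    Builds the 3N x 3N coupling matrix ``A = I/alpha - K`` once (LU
    factorized); solving ``A p = E0`` gives the induced dipoles for any
    incident polarization.  ``positions`` overrides the sheet lattice with
    an explicit (N, 3) array of centers (e.g. a dimer).
    """

    def __init__(
        self,
        sheet: NanoparticleSheet,
        wavelength_nm: float,
        positions: np.ndarray | None = None,
    ):
        from scipy.linalg import get_lapack_funcs, lu_factor

        self.sheet = sheet
        self.wavelength_nm = float(wavelength_nm)
        self.centers = (
            sheet.positions() if positions is None
            else np.asarray(positions, dtype=float).reshape(-1, 3)
        )
        self.alpha = sheet.material.polarizability(wavelength_nm, sheet.radius_nm)
        if not np.isfinite(self.alpha) or abs(self.alpha) < 1e-300:
            raise SingularCouplingError(
                f"polarizability not finite at {wavelength_nm} nm: dipole "
                "resonance pole (eps = -2 eps_m)"
            )
        n = len(self.centers)
        rv = self.centers[:, None, :] - self.centers[None, :, :]
        d = np.linalg.norm(rv, axis=2)
        np.fill_diagonal(d, 1.0)
        u = rv / d[:, :, None]
        K = (3.0 * u[:, :, :, None] * u[:, :, None, :] - np.eye(3)) / d[:, :, None, None] ** 3
        K[np.arange(n), np.arange(n)] = 0.0
        A = (-K.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)).astype(complex)
        A[np.arange(3 * n), np.arange(3 * n)] += 1.0 / self.alpha
        anorm = np.linalg.norm(A, 1)
        try:
            self._lu = lu_factor(A)
        except np.linalg.LinAlgError as err:  # pragma: no cover - exact singularity
            raise SingularCouplingError(str(err)) from err
        gecon = get_lapack_funcs(("gecon",), (A,))[0]
        rcond, _ = gecon(self._lu[0], anorm)
        if not np.isfinite(rcond) or rcond < 1e-13:
            raise SingularCouplingError(
                f"coupling matrix singular at {wavelength_nm} nm "
                f"(rcond={rcond:.2e}): collective resonance condition"
            )
        self._dipoles: dict[tuple, np.ndarray] = {}

    def dipoles(self, polarization) -> np.ndarray:
        """(N, 3) complex induced dipoles for a unit incident field."""
        from scipy.linalg import lu_solve

        pol = np.asarray(polarization, dtype=float)
        pol = pol / np.linalg.norm(pol)
        key = tuple(np.round(pol, 12))
        if key not in self._dipoles:
            n = len(self.centers)
            sol = lu_solve(self._lu, np.tile(pol, n).astype(complex))
            self._dipoles[key] = sol.reshape(n, 3)
        return self._dipoles[key]

    def _check_outside(self, pts: np.ndarray) -> None:
        d = np.linalg.norm(pts[:, None, :] - self.centers[None, :, :], axis=2)
        if np.any(d.min(axis=1) < self.sheet.radius_nm - 1e-9):
            raise ValueError("query point inside a particle core")

    def field(self, points, polarization, scattered_only: bool = False) -> np.ndarray:
        """Complex total (or scattered) field at query points outside all cores."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        self._check_outside(pts)
        p = self.dipoles(polarization)
        rv = pts[:, None, :] - self.centers[None, :, :]
        d = np.linalg.norm(rv, axis=2)
        u = rv / d[:, :, None]
        Es = np.sum(
            (3.0 * u * np.einsum("ijk,jk->ij", u, p)[:, :, None] - p[None, :, :])
            / d[:, :, None] ** 3,
            axis=1,
        )
        if scattered_only:
            return Es
        pol = np.asarray(polarization, dtype=float)
        return Es + pol / np.linalg.norm(pol)

    def intensity(self, points, polarization=None, scattered_only: bool = False) -> np.ndarray:
        """Relative intensity |E/E0|^2; ``polarization=None`` averages the two
        orthogonal in-plane polarizations (unpolarized epi-illumination)."""
        if polarization is not None:
            E = self.field(points, polarization, scattered_only)
            return np.sum(np.abs(E) ** 2, axis=1)
        out = None
        for pol in ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)):
            E = self.field(points, pol, scattered_only)
            term = 0.5 * np.sum(np.abs(E) ** 2, axis=1)
            out = term if out is None else out + term
        return out


def compute_near_field(
    sheet: NanoparticleSheet,
    wavelength_nm: float,
    polarization,
    query_points,
    scattered_only: bool = False,
) -> np.ndarray:
    """Relative intensity map |E/E0|^2 at query points.

    ``polarization`` is a 3-vector, or ``None`` for the in-plane unpolarized
    average.  Deterministic for fixed inputs.
    """
    solver = CoupledDipoleSolver(sheet, wavelength_nm)
    out = solver.intensity(query_points, polarization, scattered_only)
    return out if np.asarray(query_points).ndim > 1 else float(out[0])


def lspr_profile(
    sheet: NanoparticleSheet, wavelength_nm: float, probe: ProbeLine | None = None
) -> FieldProfile:
    """Near-field intensity along the mid-gap probe line (the 'LSPR' curve).

    Polarization-averaged over the two in-plane directions and normalized to
    the incident intensity in the host medium.
    """
    if probe is None:
        probe = ProbeLine()
    solver = CoupledDipoleSolver(sheet, wavelength_nm)
    intensity = solver.intensity(probe.points())
    return FieldProfile(
        distance_nm=probe.D_grid,
        relative_intensity=intensity,
        label="lspr",
        meta={
            "wavelength_nm": wavelength_nm,
            "patch_size": sheet.patch_size,
            "pitch_nm": sheet.pitch_nm,
        },
    )


def first_unity_crossing(profile: FieldProfile) -> float:
    """Distance at which the intensity first drops below the incident level
    beyond the enhancement peak, by linear interpolation between the
    bracketing grid points.  Raises if the profile never crosses unity."""
    D = profile.distance_nm
    I = profile.relative_intensity
    ipk = int(np.argmax(I))
    below = np.where((np.arange(len(D)) > ipk) & (I < 1.0))[0]
    if len(below) == 0:
        raise ValueError("profile never drops below the incident intensity")
    j = below[0]
    if j == 0 or I[j - 1] <= 1.0:
        return float(D[j])
    frac = (I[j - 1] - 1.0) / (I[j - 1] - I[j])
    return float(D[j - 1] + frac * (D[j] - D[j - 1]))
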