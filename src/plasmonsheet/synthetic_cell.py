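"""Synthetic fluorophore populations of a fixed, actin-labelled adherent cell.

The generator emulates the ground-truth geometry that interface-selective
imaging is judged against: an adherent cell whose labelled actin
cytoskeleton splits into

* a **ventral** layer hugging the substrate (z ~ 5-50 nm),
* **stress fibers** running through the lower cell body,
* **focal adhesions** — compact spots at the termini of actin bundles,
  within a few tens of nm of the substrate ("nano-contacting"), placed
  preferentially at the cell edge and under the cell center,
* a **dorsal** layer a few hundred nm up (z ~ 300-600 nm), which dominates
  widefield images and screens the interface.

z is measured from the top surface of the imaging substrate (glass, sheet
capping layer or spacer top), positive into the sample.  All randomness is
drawn from one seeded generator, so a fixed seed reproduces the population
exactly.  Structure label counts are Poisson with mean density x structure
measure (area for layers, length for fibers, per-spot mean for adhesions).

Absolute z positions of cytoskeletal layers are not well tabulated in the
literature; the defaults are plausible round numbers for a fixed adherent
cell and every one of them is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellGeometryParams",
    "FluorophorePopulation",
    "generate_cell",
    "generate_bead",
]

STRUCTURE_TAGS = ("ventral", "dorsal", "fiber", "adhesion", "bead")
#: tags counted as substrate-proximal by interface metrics
NEAR_TAGS = ("ventral", "fiber", "adhesion")

NM2_PER_UM2 = 1e6
NM_PER_UM = 1e3


@dataclass(frozen=True)
class CellGeometryParams:
    """Geometry and labelling densities of the synthetic cell.

    Densities are per um^2 (layers), per um of fiber length (fibers) or
    mean labels per spot (adhesions).  The dorsal density deliberately
    exceeds the ventral one: in widefield images of adherent cells the
    out-of-focus apical/dorsal actin dominates, which is exactly the
    background that depth-selective excitation must suppress.
    """

    footprint_radius_nm: float = 5000.0
    ventral_z_range_nm: tuple[float, float] = (5.0, 50.0)
    dorsal_z_nm: tuple[float, float] = (300.0, 600.0)
    ventral_density_um2: float = 40.0
    dorsal_density_um2: float = 120.0
    n_stress_fibers: int = 8
    fiber_width_nm: float = 150.0
    fiber_z_range_nm: tuple[float, float] = (10.0, 60.0)
    fiber_label_density_um: float = 30.0
    n_focal_adhesions: int = 12
    adhesion_radius_nm: float = 300.0
    adhesion_z_range_nm: tuple[float, float] = (5.0, 30.0)
    adhesion_labels_mean: float = 80.0
    base_brightness: float = 1.0
    brightness_cv: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ventral_z_range_nm", "dorsal_z_nm", "fiber_z_range_nm",
                     "adhesion_z_range_nm"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must be an ordered non-negative range")
        if self.footprint_radius_nm <= 0:
            raise ValueError("footprint radius must be positive")
        for name in ("ventral_density_um2", "dorsal_density_um2",
                     "fiber_label_density_um", "adhesion_labels_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.base_brightness <= 0:
            raise ValueError("base brightness must be positive")


@dataclass
class FluorophorePopulation:
    """Point emitters: positions (N, 3) in nm, brightness (expected photons
    at unit excitation and unit exposure) and a structure tag per emitter."""

    positions: np.ndarray
    brightness: np.ndarray
    tags: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.brightness = np.asarray(self.brightness, dtype=float)
        self.tags = np.asarray(self.tags, dtype=object)
        n = len(self.positions)
        if len(self.brightness) != n or len(self.tags) != n:
            raise ValueError("positions, brightness and tags must align")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.positions[:, 2] < 0):
            raise ValueError("z must be non-negative (measured from substrate top)")
        if np.any(self.brightness <= 0):
            raise ValueError("brightness must be positive")
        unknown = set(self.tags) - set(STRUCTURE_TAGS)
        if unknown:
            raise ValueError(f"unknown structure tags: {unknown}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]

    def select(self, *tags: str) -> np.ndarray:
        """Boolean mask of emitters carrying any of the given tags."""
        return np.isin(self.tags, tags)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "z_nm": self.positions[:, 2],
                "brightness": self.brightness,
                "tag": self.tags.astype(str),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def concatenate(pops: list["FluorophorePopulation"]) -> "FluorophorePopulation":
        pops = [p for p in pops if len(p)]
        if not pops:
            raise ValueError("nothing to concatenate")
        return FluorophorePopulation(
            np.vstack([p.positions for p in pops]),
            np.concatenate([p.brightness for p in pops]),
            np.concatenate([p.tags for p in pops]),
        )


def _brightness(rng, params: CellGeometryParams, n: int) -> np.ndarray:
    """Lognormal brightness with the configured coefficient of variation."""
    if n == 0:
        return np.empty(0)
    cv = params.brightness_cv
    if cv <= 0:
        return np.full(n, params.base_brightness)
    sigma = np.sqrt(np.log(1 + cv**2))
    return params.base_brightness * rng.lognormal(-sigma**2 / 2.0, sigma, n)


def _disk_layer(rng, params, density_um2, z_range, tag):
    area_um2 = np.pi * (params.footprint_radius_nm / NM_PER_UM) ** 2
    n = rng.poisson(density_um2 * area_um2)
    r = params.footprint_radius_nm * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(*z_range, n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pos, np.full(n, tag, dtype=object)


def _stress_fibers(rng, params):
    """Random chords across the footprint with Gaussian lateral spread."""
    pos_list, R = [], params.footprint_radius_nm * 0.9
    for _ in range(params.n_stress_fibers):
        phi1, phi2 = rng.uniform(0, 2 * np.pi, 2)
        a = R * np.array([np.cos(phi1), np.sin(phi1)])
        b = R * np.array([np.cos(phi2), np.sin(phi2)])
        length_um = np.linalg.norm(b - a) / NM_PER_UM
        n = rng.poisson(params.fiber_label_density_um * length_um)
        if n == 0:
            continue
        t = rng.uniform(size=n)[:, None]
        xy = a[None, :] + t * (b - a)[None, :]
        xy += rng.normal(0, params.fiber_width_nm / 2.355, size=(n, 2))
        z = rng.uniform(*params.fiber_z_range_nm, n)
        pos_list.append(np.column_stack([xy, z]))
    if not pos_list:
        return np.empty((0, 3)), np.empty(0, dtype=object)
    pos = np.vstack(pos_list)
    return pos, np.full(len(pos), "fiber", dtype=object)


def _focal_adhesions(rng, params):
    """Compact spots, two thirds near the footprint edge, one third central."""
    R = params.footprint_radius_nm
    pos_list = []
    for k in range(params.n_focal_adhesions):
        if k % 3 < 2:  # edge
            rc = rng.uniform(0.7, 0.95) * R
        else:  # center
            rc = rng.uniform(0.0, 0.3) * R
        phic = rng.uniform(0, 2 * np.pi)
        center = np.array([rc * np.cos(phic), rc * np.sin(phic)])
        n = rng.poisson(params.adhesion_labels_mean)
        if n == 0:
            continue
        rr = params.adhesion_radius_nm * np.sqrt(rng.uniform(size=n))
        aa = rng.uniform(0, 2 * np.pi, n)
        xy = center[None, :] + np.column_stack([rr * np.cos(aa), rr * np.sin(aa)])
        z = rng.uniform(*params.adhesion_z_range_nm, n)
        pos_list.append(np.column_stack([xy, z]))
    if not pos_list:
        return np.empty((0, 3)), np.empty(0, dtype=object)
    pos = np.vstack(pos_list)
    return pos, np.full(len(pos), "adhesion", dtype=object)


def generate_cell(params: CellGeometryParams | None = None) -> FluorophorePopulation:
    """Generate the labelled synthetic cell; deterministic for a fixed seed."""
    if params is None:
        params = CellGeometryParams()
    if (
        params.ventral_density_um2 == 0
        and params.dorsal_density_um2 == 0
        and params.fiber_label_density_um == 0
        and params.adhesion_labels_mean == 0
    ):
        raise ValueError("all structure densities are zero: nothing to generate")
    rng = np.random.default_rng(params.rng_seed)
    parts = [
        _disk_layer(rng, params, params.ventral_density_um2,
                    params.ventral_z_range_nm, "ventral"),
        _disk_layer(rng, params, params.dorsal_density_um2,
                    params.dorsal_z_nm, "dorsal"),
        _stress_fibers(rng, params),
        _focal_adhesions(rng, params),
    ]
    pos = np.vstack([p for p, _ in parts])
    tags = np.concatenate([t for _, t in parts])
    bright = _brightness(rng, params, len(pos))
    return FluorophorePopulation(pos, bright, tags, meta={"params": params})


def generate_bead(
    z_offset_nm: float,
    diameter_nm: float = 100.0,
    n_labels: int = 500,
    seed: int = 0,
    base_brightness: float = 1.0,
) -> FluorophorePopulation:
    """Uniformly labelled calibration bead resting at ``z_offset_nm``.

    Labels are uniform in the sphere volume; the sphere's bottom touches
    the offset plane (the bead "rests" on the substrate or spacer), so the
    minimum label z approaches ``z_offset_nm`` from above as n grows.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    if z_offset_nm < 0:
        raise ValueError("z offset must be non-negative")
    if n_labels < 1:
        raise ValueError("need at least one label")
    rng = np.random.default_rng(seed)
    r = diameter_nm / 2.0
    u = rng.normal(size=(n_labels, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    rad = r * rng.uniform(size=n_labels) ** (1.0 / 3.0)
    pos = u * rad[:, None]
    pos[:, 2] += z_offset_nm + r  # center above the resting plane
    bright = np.full(n_labels, base_brightness)
    return FluorophorePopulation(
        pos, bright, np.full(n_labels, "bead", dtype=object),
        meta={"z_offset_nm": z_offset_nm, "diameter_nm": diameter_nm, "seed": seed},
    )
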