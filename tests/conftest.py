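"""Shared fixtures: expensive solver products are session-scoped."""

import numpy as np
import pytest

from plasmonsheet import (
    CellGeometryParams,
    NanoparticleSheet,
    ProbeLine,
    generate_cell,
    gold_material,
    lspr_profile,
)


@pytest.fixture(scope="session")
def gold():
    return gold_material()


@pytest.fixture(scope="session")
def sheet(gold):
    return NanoparticleSheet(material=gold)


@pytest.fixture(scope="session")
def probe():
    return ProbeLine(D_grid=np.concatenate(
        [np.linspace(0.0, 30.0, 601), np.linspace(30.1, 400.0, 400)]
    ))


@pytest.fixture(scope="session")
def lspr561(sheet, probe):
    """Polarization-averaged sheet near-field profile at the 561 nm line."""
    return lspr_profile(sheet, 561.0, probe)


@pytest.fixture(scope="session")
def small_cell_params():
    """Reduced cell for fast rendering tests."""
    return CellGeometryParams(
        footprint_radius_nm=2000.0,
        ventral_density_um2=30.0,
        dorsal_density_um2=90.0,
        n_stress_fibers=4,
        fiber_label_density_um=20.0,
        n_focal_adhesions=6,
        adhesion_labels_mean=40.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_cell(small_cell_params):
    return generate_cell(small_cell_params)
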