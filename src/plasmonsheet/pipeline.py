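"""Reproducible orchestration of the two simulation studies.

``run_profile_study`` reconstructs the field-versus-distance picture at the
sheet: the evanescent TIRF reference curve, the coupled-dipole sheet
near-field ('LSPR') profile along the mid-gap probe line, the
surface-energy-transfer attenuation for a sweep of characteristic
distances, and their products — all on a shared distance grid, exported as
CSV plus a summary JSON (penetration depth, peak enhancement, unity
crossing).

``run_imaging_study`` renders the default synthetic cell under glass
(epi / oblique / TIRF) and nanoparticle-sheet excitation at several
incidence angles and spacer thicknesses, writing TIFF frames and a metrics
JSON containing per-image ventral fractions, signal-to-background ratios
and the qualitative ordering checks.

Both stages derive every random stream from the single configured seed and
write deterministic, byte-stable JSON; existing outputs are never
overwritten unless ``overwrite`` is set.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .interface_optics import (
    InterfaceConfig,
    critical_angle,
    evanescent_profile,
    penetration_depth,
)
from .nanosheet_field import (
    NanoparticleSheet,
    ProbeLine,
    first_unity_crossing,
    gold_material,
    lspr_profile,
)
from .energy_transfer import (
    EnergyTransferModel,
    attenuation_curve,
    combined_excitation_profile,
)
from .synthetic_cell import CellGeometryParams, generate_cell
from .image_formation import (
    ImagingSetup,
    compare_modalities,
    excitation_weights,
    render_image,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config",
           "run_profile_study", "run_imaging_study", "run_all"]

log = logging.getLogger("plasmonsheet")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["profile", "imaging"],
    "sheet": {
        "core_diameter_nm": 12.6,
        "gap_nm": 2.6,
        "patch_size": 13,
        "host_index": 1.33,
    },
    "profile": {
        "wavelengths_nm": [488.0, 561.0],
        "evanescent": {"wavelength_nm": 561.0, "n1": 1.52, "n2": 1.33,
                       "theta_deg": 65.0},
        "d0_sweep_nm": [2.0, 5.0, 7.0, 10.0],
        "exponent": 4,
        "d_max_nm": 200.0,
        "n_grid": 2001,
    },
    "cell": {},  # overrides for CellGeometryParams fields
    "imaging": {
        "excitation_wavelength_nm": 561.0,
        "emission_wavelength_nm": 609.0,
        "numerical_aperture": 1.49,
        "pixel_size_nm": 65.0,
        "field_of_view_px": 192,
        "exposure": 50.0,
        "read_noise": 1.0,
        "d0_nm": 5.0,
        # glass in water: 65 and 75 degrees are both beyond the 61 degree
        # critical angle; 488 nm at 75 degrees gives d ~ 62 nm
        "glass": {"wavelength_nm": 488.0, "emission_nm": 525.0,
                  "n1": 1.52, "n2": 1.33, "angles_deg": [0.0, 65.0, 75.0]},
        # glycerol-based mounting medium: critical angle 73.9 degrees, so 65
        # degrees is sub-critical oblique illumination and 75 is TIRF
        "mounted": {"wavelength_nm": 561.0, "emission_nm": 609.0,
                    "n1": 1.52, "n2": 1.46, "angles_deg": [65.0, 75.0]},
        "sheet_angles_deg": [0.0, 65.0, 75.0],
        "spacer_sweep_nm": [0.0, 10.0, 20.0],
        "write_tiffs": True,
    },
}

# minimal schema: section -> key -> required python types
_SCHEMA: dict = {
    "seed": int,
    "stages": list,
    "sheet": {
        "core_diameter_nm": (int, float),
        "gap_nm": (int, float),
        "patch_size": int,
        "host_index": (int, float),
    },
    "profile": {
        "wavelengths_nm": list,
        "evanescent": dict,
        "d0_sweep_nm": list,
        "exponent": int,
        "d_max_nm": (int, float),
        "n_grid": int,
    },
    "cell": dict,
    "imaging": {
        "excitation_wavelength_nm": (int, float),
        "emission_wavelength_nm": (int, float),
        "numerical_aperture": (int, float),
        "pixel_size_nm": (int, float),
        "field_of_view_px": int,
        "exposure": (int, float),
        "read_noise": (int, float),
        "d0_nm": (int, float),
        "glass": dict,
        "mounted": dict,
        "sheet_angles_deg": list,
        "spacer_sweep_nm": list,
        "write_tiffs": bool,
    },
}


class ConfigError(ValueError):
    """Invalid run configuration."""


def validate_config(config: dict) -> None:
    """Check section and key names and value types against the schema."""
    for key, val in config.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config section or key: {key!r}")
        if key == "cell":
            if not isinstance(val, dict):
                raise ConfigError("section 'cell' must be a mapping")
            unknown = set(val) - set(CellGeometryParams.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown cell parameters: {sorted(unknown)}")
            continue
        spec = _SCHEMA[key]
        if isinstance(spec, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in spec:
                    raise ConfigError(f"unknown key {key}.{k2}")
                if not isinstance(v2, spec[k2]):
                    raise ConfigError(
                        f"{key}.{k2} must be {spec[k2]}, got {type(v2).__name__}"
                    )
        else:
            if not isinstance(val, spec):
                raise ConfigError(f"{key} must be {spec}, got {type(val).__name__}")
    for stage in config.get("stages", []):
        if stage not in ("profile", "imaging"):
            raise ConfigError(f"unknown stage {stage!r}")


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}))
        else:
            out[k] = override.get(k, v)
    for k in override:
        if k not in base:
            out[k] = override[k]
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and/or a dict."""
    config = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    validate_config(config)
    return config


def _prepare_outdir(outdir, filenames, overwrite: bool) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not overwrite:
        clashes = [f for f in filenames if (outdir / f).exists()]
        if clashes:
            raise FileExistsError(
                f"outputs exist (pass overwrite=True to replace): {clashes}"
            )
    return outdir


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _build_sheet(config: dict) -> NanoparticleSheet:
    sc = config["sheet"]
    return NanoparticleSheet(
        core_diameter_nm=sc["core_diameter_nm"],
        gap_nm=sc["gap_nm"],
        patch_size=sc["patch_size"],
        material=gold_material(sc["host_index"]),
    )


def run_profile_study(config: dict, outdir, overwrite: bool = False) -> dict:
    """Write the field-profile CSV family and return the summary dict."""
    validate_config(config)
    t0 = time.perf_counter()
    pc = config["profile"]
    sheet = _build_sheet(config)
    grid = np.linspace(0.0, pc["d_max_nm"], pc["n_grid"])
    probe = ProbeLine(D_grid=grid)

    files = ["evanescent.csv", "profile_summary.json"]
    for wl in pc["wavelengths_nm"]:
        files.append(f"lspr_{wl:g}nm.csv")
    for d0 in pc["d0_sweep_nm"]:
        files.append(f"set_d0_{d0:g}nm.csv")
        for wl in pc["wavelengths_nm"]:
            files.append(f"lspr_x_set_{wl:g}nm_d0_{d0:g}nm.csv")
    outdir = _prepare_outdir(outdir, files, overwrite)

    ev_cfg = InterfaceConfig(**pc["evanescent"])
    ev = evanescent_profile(ev_cfg, grid)
    ev.to_csv(outdir / "evanescent.csv")
    depth = penetration_depth(ev_cfg)

    summary: dict = {
        "evanescent_depth_nm": round(depth, 1),
        "evanescent_depth_nm_rounded": int(round(depth)),
        "config_echo": {"profile": pc, "sheet": config["sheet"], "seed": config["seed"]},
        "lspr": {},
    }
    for wl in pc["wavelengths_nm"]:
        prof = lspr_profile(sheet, wl, probe)
        prof.to_csv(outdir / f"lspr_{wl:g}nm.csv")
        summary["lspr"][f"{wl:g}"] = {
            "peak_enhancement": round(float(prof.relative_intensity.max()), 2),
            "peak_D_nm": round(float(grid[np.argmax(prof.relative_intensity)]), 2),
            "unity_crossing_nm": round(first_unity_crossing(prof), 2),
        }
        for d0 in pc["d0_sweep_nm"]:
            model = EnergyTransferModel(characteristic_distance_nm=d0,
                                        exponent=pc["exponent"])
            if wl == pc["wavelengths_nm"][0]:
                # attenuation vs nearest-surface distance is wavelength-free
                att = attenuation_curve(model, np.maximum(grid, grid[1] / 2.0))
                att.as_profile().to_csv(outdir / f"set_d0_{d0:g}nm.csv")
            combo = combined_excitation_profile(prof, sheet, probe, model)
            combo.to_csv(outdir / f"lspr_x_set_{wl:g}nm_d0_{d0:g}nm.csv")
    _write_json(outdir / "profile_summary.json", summary)
    log.info("profile study finished in %.1f s", time.perf_counter() - t0)
    return summary


def _modality_for(theta_deg: float, n1: float, n2: float) -> str:
    """epi at normal incidence, oblique below the critical angle, else tirf."""
    if theta_deg == 0:
        return "epi"
    return "tirf" if theta_deg > critical_angle(n1, n2) else "oblique"


def _imaging_setups(config: dict, sheet: NanoparticleSheet) -> dict[str, ImagingSetup]:
    im = config["imaging"]
    common = dict(
        numerical_aperture=im["numerical_aperture"],
        pixel_size_nm=im["pixel_size_nm"],
        field_of_view_px=im["field_of_view_px"],
        exposure=im["exposure"],
        read_noise=im["read_noise"],
        rng_seed=config["seed"],
    )
    model = EnergyTransferModel(characteristic_distance_nm=im["d0_nm"])
    setups: dict[str, ImagingSetup] = {}
    for substrate in ("glass", "mounted"):
        sc = im[substrate]
        for ang in sc["angles_deg"]:
            modality = _modality_for(ang, sc["n1"], sc["n2"])
            interface = None
            if modality != "epi":
                interface = InterfaceConfig(
                    wavelength_nm=sc["wavelength_nm"], n1=sc["n1"], n2=sc["n2"],
                    theta_deg=ang,
                )
            setups[f"{substrate}_{modality}_{ang:g}"] = ImagingSetup(
                modality=modality,
                interface=interface,
                excitation_wavelength_nm=sc["wavelength_nm"],
                emission_wavelength_nm=sc["emission_nm"],
                **common,
            )
    for ang in im["sheet_angles_deg"]:
        setups[f"sheet_lspr_{ang:g}"] = ImagingSetup(
            modality="lspr_sheet", sheet=sheet, transfer_model=model,
            excitation_wavelength_nm=im["excitation_wavelength_nm"],
            emission_wavelength_nm=im["emission_wavelength_nm"],
            **common,
        )
    return setups


def run_imaging_study(config: dict, outdir, overwrite: bool = False) -> dict:
    """Render the synthetic cell under all configured setups; write metrics."""
    validate_config(config)
    t0 = time.perf_counter()
    im = config["imaging"]
    sheet = _build_sheet(config)
    params = CellGeometryParams(**{"rng_seed": config["seed"], **config["cell"]})
    pop = generate_cell(params)
    setups = _imaging_setups(config, sheet)

    files = ["imaging_metrics.json", "cell_population.csv"]
    if im["write_tiffs"]:
        files += [f"{name}.tiff" for name in setups]
    outdir = _prepare_outdir(outdir, files, overwrite)
    pop.to_csv(outdir / "cell_population.csv")

    table, checks = compare_modalities(pop, setups)
    if im["write_tiffs"]:
        for name, setup in setups.items():
            w = excitation_weights(pop, setup)
            render_image(pop, w, setup).to_tiff(outdir / f"{name}.tiff")

    model = EnergyTransferModel(characteristic_distance_nm=im["d0_nm"])
    spacer_rows = {}
    base = setups[f"sheet_lspr_{im['sheet_angles_deg'][0]:g}"]
    for t in im["spacer_sweep_nm"]:
        setup_t = ImagingSetup(
            modality="lspr_sheet", sheet=sheet, transfer_model=model,
            spacer_nm=t, emission_wavelength_nm=base.emission_wavelength_nm,
            excitation_wavelength_nm=base.excitation_wavelength_nm,
            numerical_aperture=base.numerical_aperture,
            pixel_size_nm=base.pixel_size_nm,
            field_of_view_px=base.field_of_view_px, exposure=base.exposure,
            read_noise=base.read_noise, rng_seed=config["seed"],
        )
        w = excitation_weights(pop, setup_t)
        img = render_image(pop, w, setup_t, noise=False)
        spacer_rows[f"{t:g}"] = {
            "total_photons": round(float(img.pixels.sum()), 3),
            "mean_near_weight": round(float(np.mean(w[pop.select("ventral", "adhesion", "fiber")])), 6),
        }

    def _clean(v):
        if v is None or (isinstance(v, (float, np.floating)) and np.isnan(v)):
            return None
        if isinstance(v, (int, float, np.integer, np.floating)):
            return round(float(v), 6)
        return v

    metrics = {
        "per_setup": {
            name: {k: _clean(v) for k, v in row.items()}
            for name, row in table.drop(columns="modality").to_dict("index").items()
        },
        "modality_per_setup": table["modality"].to_dict(),
        "orderings": checks,
        "spacer_sweep": spacer_rows,
        "n_fluorophores": len(pop),
        "config_echo": {"imaging": im, "cell": config["cell"],
                        "sheet": config["sheet"], "seed": config["seed"]},
    }
    _write_json(outdir / "imaging_metrics.json", metrics)
    log.info("imaging study finished in %.1f s", time.perf_counter() - t0)
    return metrics


def run_all(config: dict, outdir, overwrite: bool = False) -> dict:
    """Run the configured stages; returns {stage: result}."""
    out = {}
    if "profile" in config["stages"]:
        out["profile"] = run_profile_study(config, Path(outdir) / "profile", overwrite)
    if "imaging" in config["stages"]:
        out["imaging"] = run_imaging_study(config, Path(outdir) / "imaging", overwrite)
    return out
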