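"""Excitation weighting, rendering, and contrast metrics."""

import numpy as np
import pytest

from plasmonsheet import (
    EnergyTransferModel,
    FluorophorePopulation,
    ImagingSetup,
    InterfaceConfig,
    SyntheticImage,
    compare_modalities,
    excitation_weights,
    render_image,
    signal_to_background,
    structure_mask,
    ventral_fraction,
)

WATER = dict(n1=1.52, n2=1.33)


def setup_for(modality, sheet=None, theta=75.0, wavelength=488.0, **kw):
    interface = None
    if modality in ("tirf", "oblique"):
        interface = InterfaceConfig(wavelength, theta_deg=theta, **WATER)
    defaults = dict(
        modality=modality,
        interface=interface,
        sheet=sheet,
        field_of_view_px=64,
        exposure=20.0,
        rng_seed=3,
    )
    defaults.update(kw)
    return ImagingSetup(**defaults)


def two_layer_population(n=10, z_near=10.0, z_far=400.0):
    """Equal-count, equal-brightness near/far population."""
    rng = np.random.default_rng(0)
    xy = rng.uniform(-1200, 1200, size=(2 * n, 2))
    z = np.concatenate([np.full(n, z_near), np.full(n, z_far)])
    tags = np.array(["ventral"] * n + ["dorsal"] * n, dtype=object)
    return FluorophorePopulation(np.column_stack([xy, z]), np.ones(2 * n), tags)


class TestExcitationWeights:
    def test_epi_uniform(self, small_cell):
        w = excitation_weights(small_cell, setup_for("epi"))
        assert np.all(w == 1.0)

    def test_tirf_exponential(self):
        pop = two_layer_population(z_near=62.4459, z_far=500.0)
        setup = setup_for("tirf", theta=75.0, wavelength=488.0)  # d = 62.4 nm
        w = excitation_weights(pop, setup)
        near = w[pop.select("ventral")]
        assert near[0] == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_tirf_depth_125_dorsal_attenuation(self):
        """d = 125 nm: a dorsal fluorophore at z = 500 nm keeps e^-4 ~ 1.8%."""
        pop = two_layer_population(z_near=10.0, z_far=500.0)
        setup = setup_for("tirf", theta=65.0, wavelength=561.0)
        w = excitation_weights(pop, setup)
        # z = 4 d with d = 124.4 nm; e^-4 ~ 1.8% within the rounding of d
        assert w[pop.select("dorsal")][0] == pytest.approx(np.exp(-4.0), rel=0.03)

    def test_tirf_below_critical_raises(self):
        with pytest.raises(ValueError, match="oblique"):
            excitation_weights(two_layer_population(), setup_for("tirf", theta=55.0))

    def test_oblique_above_critical_raises(self):
        with pytest.raises(ValueError, match="tirf"):
            excitation_weights(two_layer_population(), setup_for("oblique", theta=70.0))

    def test_oblique_subcritical_uniform(self):
        w = excitation_weights(two_layer_population(), setup_for("oblique", theta=55.0))
        assert np.all(w == 1.0)

    def test_lspr_weights_nonincreasing_beyond_quench_zone(self, sheet):
        """Sheet excitation decays monotonically with height once past the
        contact-quenching zone (z > ~2 nm)."""
        z = np.geomspace(2.5, 600.0, 40)
        pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pop = FluorophorePopulation(
            pos, np.ones(len(z)), np.array(["ventral"] * len(z), dtype=object)
        )
        w = excitation_weights(pop, setup_for("lspr_sheet", sheet=sheet))
        assert np.all(np.diff(w) <= 1e-12)
        assert w[-1] < 1e-3  # substrate-bound: negligible far excitation

    def test_lspr_confinement_scale(self, sheet):
        """The confined excitation range is roughly a tenth of a typical
        evanescent depth: weight falls to 1/e of its 5 nm value well below
        65 nm."""
        z = np.array([5.0, 15.0, 65.0, 125.0])
        pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pop = FluorophorePopulation(
            pos, np.ones(4), np.array(["ventral"] * 4, dtype=object)
        )
        w = excitation_weights(pop, setup_for("lspr_sheet", sheet=sheet))
        assert w[2] < w[0] / np.e

    def test_lspr_spacer_reduces_weights(self, sheet):
        pop = two_layer_population()
        w0 = excitation_weights(pop, setup_for("lspr_sheet", sheet=sheet))
        w10 = excitation_weights(pop, setup_for("lspr_sheet", sheet=sheet, spacer_nm=10.0))
        assert np.all(w10 <= w0 + 1e-15)
        assert w10[pop.select("ventral")][0] < w0[pop.select("ventral")][0]


class TestRenderImage:
    def test_photon_conservation_noiseless(self, small_cell):
        """Without noise the frame total equals the injected photon budget."""
        setup = setup_for("epi", field_of_view_px=96)
        w = excitation_weights(small_cell, setup)
        img = render_image(small_cell, w, setup, noise=False)
        expected = (small_cell.brightness * w * setup.exposure).sum()
        assert img.pixels.sum() == pytest.approx(expected, rel=1e-6)

    def test_single_emitter_argmax_at_its_pixel(self):
        pop = FluorophorePopulation(
            np.array([[162.5, -97.5, 0.0]]), np.array([100.0]),
            np.array(["ventral"], dtype=object),
        )
        setup = setup_for("epi", field_of_view_px=64, pixel_size_nm=65.0)
        img = render_image(pop, np.ones(1), setup, noise=False)
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.shape)
        # emitter sits at the center of pixel (row 30, col 34) in a 64 px FOV
        assert (iy, ix) == (30, 34)

    def test_noisy_mean_matches_noiseless(self):
        """Poisson/read-noise frames average back to the clean image."""
        pop = two_layer_population(n=5)
        base = setup_for("epi", field_of_view_px=48, exposure=30.0)
        clean = render_image(pop, np.ones(len(pop)), base, noise=False).pixels
        acc = np.zeros_like(clean)
        n_rep = 200
        for seed in range(n_rep):
            setup = setup_for("epi", field_of_view_px=48, exposure=30.0, rng_seed=seed)
            acc += render_image(pop, np.ones(len(pop)), setup).pixels
        mean = acc / n_rep
        sigma = np.sqrt((clean + base.read_noise**2) / n_rep)
        # digitization clips negative excursions to zero, which biases empty
        # pixels upward by a fraction of a count; test the signal region
        signal = clean > 2.0
        z = (mean[signal] - clean[signal]) / sigma[signal]
        assert np.abs(z).max() < 5.0
        assert np.abs(mean[~signal] - clean[~signal]).max() < 0.7

    def test_seeded_determinism(self, small_cell):
        setup = setup_for("epi")
        w = excitation_weights(small_cell, setup)
        a = render_image(small_cell, w, setup)
        b = render_image(small_cell, w, setup)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            render_image(
                FluorophorePopulation(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=object)),
                np.empty(0), setup_for("epi"),
            )

    def test_undersampled_psf_warns(self):
        pop = two_layer_population()
        setup = setup_for("epi", pixel_size_nm=1000.0)
        with pytest.warns(UserWarning, match="undersampled"):
            render_image(pop, np.ones(len(pop)), setup, noise=False)

    def test_tiff_roundtrip(self, tmp_path, small_cell):
        import tifffile

        setup = setup_for("epi")
        w = excitation_weights(small_cell, setup)
        img = render_image(small_cell, w, setup)
        img.to_tiff(tmp_path / "frame.tiff")
        back = tifffile.imread(tmp_path / "frame.tiff")
        assert back.dtype == np.uint16
        np.testing.assert_array_equal(back, img.pixels.astype(np.uint16))

    def test_pixel_size_halving_preserves_photons_and_sharpens_fwhm(self):
        """160 -> 65 nm pixels: same photon total, FWHM estimate closer to
        the true PSF width."""
        pop = FluorophorePopulation(
            np.array([[0.0, 0.0, 0.0]]), np.array([5000.0]),
            np.array(["ventral"], dtype=object),
        )

        def fwhm_from(setup):
            img = render_image(pop, np.ones(1), setup, noise=False).pixels
            iy, ix = np.unravel_index(np.argmax(img), img.shape)
            row = img[iy]
            half = row[ix] / 2.0
            x = np.arange(len(row)) * setup.pixel_size_nm
            left = np.interp(half, row[: ix + 1], x[: ix + 1])
            right = np.interp(half, row[ix:][::-1], x[ix:][::-1])
            return right - left

        s160 = setup_for("epi", pixel_size_nm=160.0, field_of_view_px=32)
        s65 = setup_for("epi", pixel_size_nm=65.0, field_of_view_px=78)
        img160 = render_image(pop, np.ones(1), s160, noise=False).pixels
        img65 = render_image(pop, np.ones(1), s65, noise=False).pixels
        assert img160.sum() == pytest.approx(img65.sum(), rel=1e-6)
        truth = 2.3548 * s65.psf_sigma_nm
        assert abs(fwhm_from(s65) - truth) < abs(fwhm_from(s160) - truth)


class TestMetrics:
    def test_ventral_fraction_epi_equals_count_ratio(self):
        pop = two_layer_population(n=10)
        assert ventral_fraction(pop, np.ones(len(pop))) == pytest.approx(0.5)

    def test_fraction_ordering_epi_tirf_lspr(self, sheet):
        pop = two_layer_population(n=10)
        f_epi = ventral_fraction(pop, excitation_weights(pop, setup_for("epi")))
        f_tirf = ventral_fraction(pop, excitation_weights(pop, setup_for("tirf")))
        f_lspr = ventral_fraction(
            pop, excitation_weights(pop, setup_for("lspr_sheet", sheet=sheet))
        )
        assert f_epi < f_tirf < f_lspr

    def test_fraction_requires_both_groups(self):
        rng = np.random.default_rng(1)
        only_near = FluorophorePopulation(
            np.column_stack([rng.uniform(-500, 500, (5, 2)), np.full(5, 10.0)]),
            np.ones(5), np.array(["ventral"] * 5, dtype=object),
        )
        with pytest.raises(ValueError):
            ventral_fraction(only_near, np.ones(5))

    def test_sbr_constant_image_zero(self):
        img = SyntheticImage(np.full((32, 32), 7.0), {"noise": False})
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:15, 10:15] = True
        assert signal_to_background(img, mask) == 0.0

    def test_sbr_monotone_in_signal(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(10.0, (32, 32)).astype(float)
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:12, 8:12] = True
        img1 = SyntheticImage(base + 20.0 * mask)
        img2 = SyntheticImage(base + 40.0 * mask)
        assert signal_to_background(img2, mask) > signal_to_background(img1, mask)

    def test_sbr_mask_validation(self):
        img = SyntheticImage(np.ones((8, 8)))
        with pytest.raises(ValueError):
            signal_to_background(img, np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            signal_to_background(img, np.ones((8, 8), dtype=bool))

    def test_tirf_sbr_beats_oblique(self, small_cell):
        """Evanescent sectioning outperforms sub-critical inclined light on
        the same cell (mounting-medium geometry: theta_c = 73.9 deg)."""
        mounted = dict(n1=1.52, n2=1.46)
        common = dict(field_of_view_px=64, exposure=20.0, rng_seed=3)
        ob = ImagingSetup(
            modality="oblique",
            interface=InterfaceConfig(561.0, theta_deg=65.0, **mounted),
            **common,
        )
        ti = ImagingSetup(
            modality="tirf",
            interface=InterfaceConfig(561.0, theta_deg=75.0, **mounted),
            **common,
        )
        sbrs = {}
        for name, setup in [("oblique", ob), ("tirf", ti)]:
            w = excitation_weights(small_cell, setup)
            img = render_image(small_cell, w, setup)
            sbrs[name] = signal_to_background(img, structure_mask(small_cell, setup))
        assert sbrs["tirf"] > sbrs["oblique"]


class TestCompareModalities:
    def test_identical_setups_identical_rows(self, small_cell, sheet):
        s = setup_for("lspr_sheet", sheet=sheet)
        table, checks = compare_modalities(small_cell, {"a": s, "b": s})
        assert table.loc["a"].equals(table.loc["b"])
        assert checks["lspr_angle_independent"] is True

    def test_needs_two_setups(self, small_cell):
        with pytest.raises(ValueError):
            compare_modalities(small_cell, {"only": setup_for("epi")})

    def test_glass_vs_sheet_orderings(self, small_cell, sheet):
        setups = {
            "glass_epi": setup_for("epi"),
            "glass_tirf": setup_for("tirf", theta=75.0),
            "sheet_a": setup_for("lspr_sheet", sheet=sheet),
            "sheet_b": setup_for("lspr_sheet", sheet=sheet),
        }
        table, checks = compare_modalities(small_cell, setups)
        assert checks["glass_angle_dependent"] is True
        assert checks["lspr_angle_independent"] is True
        assert (
            table.loc["glass_epi", "ventral_fraction"]
            < table.loc["glass_tirf", "ventral_fraction"]
            < table.loc["sheet_a", "ventral_fraction"]
        )


class TestSetupValidation:
    def test_modality_subconfig_requirements(self):
        with pytest.raises(ValueError):
            ImagingSetup(modality="tirf")  # no interface
        with pytest.raises(ValueError):
            ImagingSetup(modality="lspr_sheet")  # no sheet
        with pytest.raises(ValueError):
            ImagingSetup(modality="widefield")

    def test_na_cannot_exceed_n1(self):
        with pytest.raises(ValueError):
            ImagingSetup(
                modality="tirf",
                interface=InterfaceConfig(488.0, n1=1.33, n2=1.0, theta_deg=60.0),
                numerical_aperture=1.49,
            )
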