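"""Band modeling, re-illumination and the annealing band fit."""

import numpy as np
import pytest

import nbisim as nb
from nbisim import fixtures as fx
from nbisim.errors import DomainError, PairingError, UsageError
from nbisim.nbi import DEFAULT_BAND_CENTERS, band_model_spd

from oracles import ciede2000_reference


def random_in_bounds_init(rng, config, grid):
    """A random band model inside the search bounds around nominal centers."""
    bands = []
    for i, c in enumerate(DEFAULT_BAND_CENTERS):
        lo = max(c - config.center_window_nm, grid.start_nm)
        hi = min(c + config.center_window_nm, grid.stop_nm)
        bands.append(
            nb.LorentzianBand(
                center_nm=rng.uniform(lo, hi),
                gamma_nm=rng.uniform(*config.gamma_bounds),
                amplitude=1.0 if i == 0 else rng.uniform(*config.amplitude_bounds),
            )
        )
    return nb.BandModel(bands=tuple(bands))


def nominal_bounds_model():
    return nb.BandModel(
        bands=tuple(nb.LorentzianBand(c, 15.0, 1.0) for c in DEFAULT_BAND_CENTERS)
    )


class TestLorentzian:
    def test_peak_hwhm_and_tail(self):
        band = nb.LorentzianBand(center_nm=540.0, gamma_nm=12.0, amplitude=0.8)
        assert nb.lorentzian_value(540.0, band) == pytest.approx(0.8)
        assert nb.lorentzian_value(552.0, band) == pytest.approx(0.4)
        assert nb.lorentzian_value(528.0, band) == pytest.approx(0.4)
        assert nb.lorentzian_value(540.0 + 120.0, band) == pytest.approx(0.8 / 101.0)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(DomainError):
            nb.LorentzianBand(center_nm=500.0, gamma_nm=0.0, amplitude=1.0)


class TestBandModelSpd:
    def test_single_band_peaks_at_center(self, grid):
        model = nb.BandModel(bands=(nb.LorentzianBand(540.0, 10.0, 1.0),))
        spd = band_model_spd(model, grid)
        assert grid.wavelengths[np.argmax(spd.power)] == 540.0

    def test_sum_of_band_spds_equals_model_spd(self, grid):
        model = nb.default_band_model()
        total = np.zeros(grid.n_samples)
        for band in model.bands:
            total += band_model_spd(nb.BandModel(bands=(band,)), grid).power
        np.testing.assert_array_equal(total, band_model_spd(model, grid).power)

    def test_far_separated_bands_locally_single(self, grid):
        model = nb.BandModel(
            bands=(nb.LorentzianBand(420.0, 5.0, 1.0), nb.LorentzianBand(740.0, 5.0, 1.0))
        )
        spd = band_model_spd(model, grid)
        alone = band_model_spd(nb.BandModel(bands=model.bands[:1]), grid)
        near = np.abs(grid.wavelengths - 420.0) <= 10.0
        np.testing.assert_allclose(spd.power[near], alone.power[near], atol=0.01)


class TestRenderPatchColor:
    def test_perfect_reflector_L100(self, grid, cmf):
        # luminance normalization pins L* at 100; a*/b* carry the band
        # illuminant's cast relative to D65 and are not constrained
        lab = nb.render_patch_color(np.ones(grid.n_samples), nb.default_band_model(), cmf)
        assert lab[0] == pytest.approx(100.0, abs=1e-9)

    def test_zero_reflectance_L0(self, grid, cmf):
        lab = nb.render_patch_color(np.zeros(grid.n_samples), nb.default_band_model(), cmf)
        assert lab[0] == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_scale_invariance(self, grid, cmf, checker_reflectances):
        model = nb.default_band_model()
        scaled = nb.BandModel(
            bands=tuple(
                nb.LorentzianBand(b.center_nm, b.gamma_nm, 3.0 * b.amplitude)
                for b in model.bands
            )
        )
        np.testing.assert_allclose(
            nb.render_patch_color(checker_reflectances, model, cmf),
            nb.render_patch_color(checker_reflectances, scaled, cmf),
            atol=1e-9,
        )

    def test_reflectance_outside_bands_tail_bounded(self, grid, cmf):
        """A reflectance zeroed within ±kγ of every band sees only the
        Lorentzian tail mass, about 2/(πk) of the power: Y is bounded
        accordingly and shrinks as the exclusion window widens."""
        model = nb.BandModel(
            bands=(
                nb.LorentzianBand(430.0, 8.0, 1.0),
                nb.LorentzianBand(550.0, 8.0, 0.8),
            )
        )
        spd = band_model_spd(model, grid)
        ys = []
        for k in (5.0, 10.0, 20.0):
            refl = np.ones(grid.n_samples)
            for band in model.bands:
                inside = np.abs(grid.wavelengths - band.center_nm) <= k * band.gamma_nm
                refl[inside] = 0.0
            y = nb.spectrum_to_xyz(refl, spd, cmf)[1]
            assert y < 100.0 * 2.0 / (np.pi * k) * 1.5  # tail bound with slack
            ys.append(y)
        assert ys[0] > ys[1] > ys[2]


class TestObjective:
    def test_zero_at_generating_model(self, cmf, checker_reflectances):
        model = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, model, cmf)
        assert nb.objective_mean_de2000(
            model, checker_reflectances, targets, cmf
        ) == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance(self, cmf, checker_reflectances):
        model = nb.default_band_model()
        other = nb.BandModel(bands=(nb.LorentzianBand(500.0, 30.0, 1.0),))
        targets = fx.generate_nbi_targets(checker_reflectances, model, cmf)
        base = nb.objective_mean_de2000(other, checker_reflectances, targets, cmf)
        rng = np.random.default_rng(7)
        perm = rng.permutation(24)
        permuted = nb.objective_mean_de2000(
            other,
            checker_reflectances[perm],
            targets,
            cmf,
            patch_ids=tuple(int(i) + 1 for i in perm),
        )
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_matches_per_patch_loop_with_reference_de(self, cmf, checker_reflectances):
        model = nb.default_band_model()
        other = nb.BandModel(
            bands=(nb.LorentzianBand(450.0, 20.0, 1.0), nb.LorentzianBand(600.0, 25.0, 0.5))
        )
        targets = fx.generate_nbi_targets(checker_reflectances, model, cmf)
        rendered = nb.render_patch_color(checker_reflectances, other, cmf)
        loop = np.mean(
            [ciede2000_reference(rendered[i], targets.ordered_lab()[i]) for i in range(24)]
        )
        assert nb.objective_mean_de2000(
            other, checker_reflectances, targets, cmf
        ) == pytest.approx(loop, abs=1e-4)

    def test_bad_pairing_rejected(self, cmf, checker_reflectances):
        model = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, model, cmf)
        with pytest.raises(PairingError):
            nb.objective_mean_de2000(
                model, checker_reflectances, targets, cmf, patch_ids=(1,) * 24
            )
        with pytest.raises(PairingError):
            nb.objective_mean_de2000(model, checker_reflectances[:10], targets, cmf)


class TestOptimizeBandModel:
    def test_init_at_optimum_returns_zero(self, cmf, checker_reflectances):
        model = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, model, cmf)
        config = nb.OptimizationConfig(seed=0, max_iterations=1, n_restarts=1)
        result = nb.optimize_band_model(
            checker_reflectances, targets, model, config, cmf=cmf
        )
        assert result.objective <= 1e-6
        assert result.objective <= nb.objective_mean_de2000(
            model, checker_reflectances, targets, cmf
        ) + 1e-12

    def test_width_amplitude_recovery(self, grid, cmf, checker_reflectances):
        """With centers fixed, γ and amplitudes of a planted model are
        recovered to better than 0.1 mean ΔE00."""
        truth = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, truth, cmf)
        rng = np.random.default_rng(7)
        config = nb.OptimizationConfig(seed=1, max_iterations=100, optimize_centers=False)
        init = nb.BandModel(
            bands=tuple(
                nb.LorentzianBand(
                    c,
                    rng.uniform(*config.gamma_bounds),
                    1.0 if i == 0 else rng.uniform(*config.amplitude_bounds),
                )
                for i, c in enumerate(DEFAULT_BAND_CENTERS)
            )
        )
        result = nb.optimize_band_model(checker_reflectances, targets, init, config, cmf=cmf)
        assert result.objective < 0.1

    def test_same_seed_reruns_identical(self, grid, cmf, checker_reflectances):
        truth = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, truth, cmf)
        config = nb.OptimizationConfig(seed=3, max_iterations=20, n_restarts=1)
        init = random_in_bounds_init(np.random.default_rng(5), config, grid)
        a = nb.optimize_band_model(
            checker_reflectances, targets, init, config, cmf=cmf,
            bounds_model=nominal_bounds_model(),
        )
        b = nb.optimize_band_model(
            checker_reflectances, targets, init, config, cmf=cmf,
            bounds_model=nominal_bounds_model(),
        )
        assert a.trace == b.trace
        assert a.objective == b.objective
        assert a.model == b.model

    def test_trace_records_monotone_improvements(self, grid, cmf, checker_reflectances):
        truth = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, truth, cmf)
        config = nb.OptimizationConfig(seed=4, max_iterations=20, n_restarts=1)
        init = random_in_bounds_init(np.random.default_rng(6), config, grid)
        result = nb.optimize_band_model(
            checker_reflectances, targets, init, config, cmf=cmf,
            bounds_model=nominal_bounds_model(),
        )
        best = [v for _, v in result.trace]
        assert np.all(np.diff(best) < 0)
        evals = [e for e, _ in result.trace]
        assert np.all(np.diff(evals) > 0)

    def test_init_outside_bounds_rejected(self, cmf, checker_reflectances):
        truth = nb.default_band_model()
        targets = fx.generate_nbi_targets(checker_reflectances, truth, cmf)
        config = nb.OptimizationConfig(seed=0, max_iterations=5)
        bad = nb.BandModel(
            bands=tuple(
                nb.LorentzianBand(b.center_nm, 200.0, b.amplitude) for b in truth.bands
            )
        )
        with pytest.raises(UsageError):
            nb.optimize_band_model(checker_reflectances, targets, bad, config, cmf=cmf)


class TestConvert:
    def test_all_black_image_stays_near_black(self, fitted_pipeline, cmf):
        # black sits outside the training patches (darkest gray 0.03), so
        # the regression extrapolates; the output must stay essentially black
        image = np.zeros((4, 4, 3), dtype=np.uint8)
        out = nb.convert_wli_to_save(
            image,
            fitted_pipeline["correction"],
            fitted_pipeline["basis"],
            fitted_pipeline["conversion"],
            nb.default_band_model(),
            cmf,
        )
        assert out.shape == (4, 4, 3) and out.dtype == np.uint8
        assert np.all(out <= 5)
        assert np.all(out[..., :] == out[0, 0])

    def test_mosaic_patches_consistent_with_scalar_path(
        self, fitted_pipeline, fixture_config, cmf
    ):
        mosaic, masks = fx.generate_checker_image(fitted_pipeline["rgbs"], fixture_config)
        bands = nb.default_band_model()
        out = nb.convert_wli_to_save(
            mosaic,
            fitted_pipeline["correction"],
            fitted_pipeline["basis"],
            fitted_pipeline["conversion"],
            bands,
            cmf,
        )
        # scalar path: reconstruct each patch color, re-render under the bands
        xyz = nb.srgb_to_xyz(nb.srgb_decode(fitted_pipeline["rgbs"].astype(float) / 255.0))
        corrected = nb.apply_correction(fitted_pipeline["correction"], xyz)
        spectra = nb.reconstruct_spectrum(
            fitted_pipeline["basis"], fitted_pipeline["conversion"], corrected
        )
        spd = band_model_spd(bands, cmf.grid)
        expected = np.round(
            nb.xyz_to_srgb(nb.spectrum_to_xyz(spectra, spd, cmf), clip=True) * 255.0
        ).astype(np.uint8)
        for idx in range(24):
            patch_pixels = out[masks[idx]]
            assert np.array_equal(patch_pixels[0], expected[idx])
            assert np.all(patch_pixels == patch_pixels[0])

    def test_lesion_contrast_narrowing_broad_blue_band(self, grid, cmf, fixture_config):
        """Narrowing an over-broad 415 nm band toward its default width
        concentrates power on the hemoglobin dip and does not decrease the
        lesion/background ΔE00 of the planted phantom spectra."""
        background, lesion = fx.lesion_reflectances(fixture_config)
        base = nb.default_band_model()
        contrasts = []
        for gamma in (45.0, 35.0, 25.0, 15.0):
            bands = (nb.LorentzianBand(415.0, gamma, 1.0),) + base.bands[1:]
            labs = nb.render_patch_color(
                np.stack([lesion, background]), nb.BandModel(bands=bands), cmf
            )
            contrasts.append(float(nb.delta_e(labs[0], labs[1], "DE2000")))
        assert np.all(np.diff(contrasts) >= 0)
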