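"""Sampling, surrogate canopy model, noise, band convolution, augmentation."""

import numpy as np
import pytest
from scipy import stats

import toatrait as tt
from toatrait.lut import (
    NonVegLibrary,
    PROV_NONVEG,
    VariableSpec,
    soil_reference,
)


@pytest.fixture(scope="module")
def draws():
    return tt.sample_parameters(tt.default_sampling_config(), 1000, seed=1)


class TestSampling:
    def test_draw_count_and_ranges(self, draws):
        assert len(draws) == 1000
        cab = np.array([t.Cab for t, _, _ in draws])
        assert cab.min() >= 5.0 and cab.max() <= 75.0
        lai = np.array([t.LAI for t, _, _ in draws])
        assert lai.min() >= 0.1 and lai.max() <= 7.0
        ths = np.array([g.theta_s for _, _, g in draws])
        assert ths.min() >= 20.0 and ths.max() <= 30.0

    def test_fixed_parameters_constant(self, draws):
        assert all(t.HotS == 0.01 and t.skyl == 0.05 for t, _, _ in draws)
        assert all(g.theta_v == 0.0 and g.phi == 0.0 for _, _, g in draws)

    def test_empty_draw(self):
        assert tt.sample_parameters(tt.default_sampling_config(), 0, seed=0) == []

    def test_lhs_stratification(self):
        """Each of n equal-width strata receives exactly one draw."""
        from toatrait.lut import _draw

        n = 100
        spec = VariableSpec("lhs", 0.05, 0.5)
        vals = _draw(spec, n, np.random.default_rng(3))
        edges = np.linspace(0.05, 0.5, n + 1)
        counts, _ = np.histogram(vals, bins=edges)
        assert np.all(counts == 1)

    def test_truncated_gaussian_distribution(self):
        """KS test of 10^4 draws against the truncated normal (alpha=0.01)."""
        cfg = tt.SamplingConfig(
            {"Cab": VariableSpec("gaussian", 5.0, 75.0, mean=35.0, sd=30.0)}
        )
        from toatrait.lut import _draw

        rng = np.random.default_rng(11)
        x = _draw(cfg["Cab"], 10_000, rng)
        a, b = (5 - 35) / 30, (75 - 35) / 30
        stat = stats.kstest(x, stats.truncnorm(a, b, loc=35, scale=30).cdf)
        assert stat.pvalue > 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            VariableSpec("triangular", 0, 1)
        with pytest.raises(ValueError):
            VariableSpec("uniform", 1.0, 1.0)
        with pytest.raises(ValueError):
            tt.sample_parameters(tt.default_sampling_config(), -1, seed=0)

    def test_config_yaml_round_trip(self):
        cfg = tt.default_sampling_config()
        back = tt.SamplingConfig.from_yaml(cfg.to_yaml())
        assert back == cfg


class TestForwardCanopy:
    def test_bare_soil_limit(self):
        """LAI=0 yields exactly the alpha_soil-scaled soil reference."""
        s = tt.TraitSample(N=1.5, Cab=40, Cm=0.005, Cw=0.02, LAI=0.0,
                           alpha_soil=0.5, ALA=50, HotS=0.01, skyl=0.05, FVC=0.05)
        sp = tt.forward_canopy(s, tt.Geometry(25.0))
        np.testing.assert_allclose(sp.values, 0.5 * soil_reference(sp.wavelengths),
                                   rtol=0, atol=1e-15)

    def test_chlorophyll_darkens_red(self):
        kw = dict(N=1.5, Cm=0.005, Cw=0.02, LAI=3.0, alpha_soil=0.5,
                  ALA=50, HotS=0.01, skyl=0.05, FVC=0.8)
        lo = tt.forward_canopy(tt.TraitSample(Cab=20, **kw), tt.Geometry(25.0))
        hi = tt.forward_canopy(tt.TraitSample(Cab=60, **kw), tt.Geometry(25.0))
        i665 = np.searchsorted(lo.wavelengths, 665.0)
        assert hi.values[i665] < lo.values[i665]

    def test_reflectance_bounds(self, draws_module=None):
        draws = tt.sample_parameters(tt.default_sampling_config(), 200, seed=9)
        for t, _, g in draws:
            v = tt.forward_canopy(t, g).values
            assert np.all((v >= 0) & (v <= 1))

    def test_outside_validity_rejected(self):
        s = tt.TraitSample(N=1.5, Cab=40, Cm=0.005, Cw=0.02, LAI=20.0,
                           alpha_soil=0.5, ALA=50, HotS=0.01, skyl=0.05, FVC=1.0)
        with pytest.raises(ValueError, match="validity"):
            tt.forward_canopy(s, tt.Geometry(25.0))

    def test_deterministic(self):
        s = tt.TraitSample(N=1.5, Cab=40, Cm=0.005, Cw=0.02, LAI=2.0,
                           alpha_soil=0.5, ALA=50, HotS=0.01, skyl=0.05, FVC=0.6)
        a = tt.forward_canopy(s, tt.Geometry(25.0)).values
        b = tt.forward_canopy(s, tt.Geometry(25.0)).values
        np.testing.assert_array_equal(a, b)


class TestNoise:
    def _spectra(self, n=3):
        grid = tt.DEFAULT_GRID
        return [tt.Spectrum(grid, np.full(grid.shape, 0.3 + 0.05 * i))
                for i in range(n)]

    def test_zero_sd_identity(self):
        sps = self._spectra()
        out = tt.add_noise(sps, tt.NoiseConfig(additive_sd=0.0), seed=1)
        for a, b in zip(sps, out):
            np.testing.assert_array_equal(a.values, b.values)

    def test_same_seed_reproducible(self):
        sps = self._spectra()
        a = tt.add_noise(sps, tt.NoiseConfig(0.01), seed=5)
        b = tt.add_noise(sps, tt.NoiseConfig(0.01), seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_empirical_sd(self):
        """Per-wavelength SD over 10^4 replicates within 5% of configured."""
        grid = np.linspace(400, 500, 6)
        sp = tt.Spectrum(grid, np.full(6, 0.5))
        out = tt.add_noise([sp] * 10_000, tt.NoiseConfig(0.01), seed=2)
        vals = np.stack([o.values for o in out])
        sd = vals.std(axis=0)
        assert np.all(np.abs(sd - 0.01) < 0.0005)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            tt.NoiseConfig(additive_sd=-0.1)

    def test_clipped_to_unit_interval(self):
        grid = np.linspace(400, 500, 50)
        sp = tt.Spectrum(grid, np.full(50, 0.999))
        out = tt.add_noise([sp], tt.NoiseConfig(0.05), seed=0)[0]
        assert out.values.max() <= 1.0 and out.values.min() >= 0.0


class TestBandConvolution:
    def test_default_band_set(self):
        bands = tt.sentinel2_bands()
        assert len(bands) == 10
        np.testing.assert_array_equal(
            bands.centers,
            [493, 560, 665, 704, 740, 783, 833, 865, 1610, 2190],
        )

    def test_flat_spectrum_identity(self):
        sp = tt.Spectrum(tt.DEFAULT_GRID, np.full(tt.DEFAULT_GRID.shape, 0.3))
        out = tt.convolve_to_bands(sp, tt.sentinel2_bands())
        assert out.shape == (10,)
        np.testing.assert_allclose(out, 0.3, rtol=1e-12)

    def test_delta_response_sifts(self):
        grid = tt.DEFAULT_GRID
        vals = np.linspace(0.1, 0.6, grid.size)
        sp = tt.Spectrum(grid, vals)
        srf = np.zeros((1, grid.size))
        srf[0, np.searchsorted(grid, 665.0)] = 1.0
        bands = tt.BandSet(ids=["B4"], centers=[665.0], srf_grid=grid, srf_values=srf)
        out = tt.convolve_to_bands(sp, bands)
        assert out[0] == pytest.approx(vals[np.searchsorted(grid, 665.0)], abs=1e-15)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        g = tt.DEFAULT_GRID
        s1, s2 = rng.uniform(0, 1, g.size), rng.uniform(0, 1, g.size)
        bands = tt.sentinel2_bands()
        lhs = tt.convolve_to_bands(tt.Spectrum(g, 0.3 * s1 + 0.6 * s2), bands)
        rhs = 0.3 * tt.convolve_to_bands(tt.Spectrum(g, s1), bands) + \
            0.6 * tt.convolve_to_bands(tt.Spectrum(g, s2), bands)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_band_support_outside_grid(self):
        grid = np.arange(400.0, 1000.0)
        sp = tt.Spectrum(grid, np.full(grid.shape, 0.3))
        with pytest.raises(ValueError, match="outside"):
            tt.convolve_to_bands(sp, tt.sentinel2_bands())


class TestAugmentation:
    def test_counts_and_zero_labels(self, small_lut):
        lib = NonVegLibrary()
        out = tt.augment_nonvegetated(small_lut, 40, lib, seed=3)
        assert len(out) == len(small_lut) + 40
        nv = out.provenance == PROV_NONVEG
        assert nv.sum() == 20 + 40
        assert np.all(out.traits.to_numpy()[nv] == 0.0)

    def test_zero_augmentation_unchanged(self, small_lut):
        out = tt.augment_nonvegetated(small_lut, 0, NonVegLibrary(), seed=3)
        assert out is small_lut

    def test_negative_rejected(self, small_lut):
        with pytest.raises(ValueError):
            tt.augment_nonvegetated(small_lut, -1, NonVegLibrary(), seed=3)


class TestTrainingSetIO:
    def test_csv_round_trip(self, small_lut, tmp_path):
        p = tmp_path / "lut.csv"
        small_lut.to_csv(p)
        back = tt.TrainingSet.from_csv(p)
        np.testing.assert_allclose(back.X, small_lut.X, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.traits.to_numpy(),
                                   small_lut.traits.to_numpy(), atol=1e-12)
        assert list(back.provenance) == list(small_lut.provenance)
        assert back.band_names == small_lut.band_names

    def test_default_pipeline_cardinalities(self, small_lut):
        assert len(small_lut) == 170
        assert small_lut.X.shape[1] == 10
        assert (small_lut.provenance == "simulated").sum() == 150
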