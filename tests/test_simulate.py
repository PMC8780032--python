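import numpy as np
import pytest

from aquakiwi import (
    CONFIGURATIONS,
    PhantomFruit,
    PolarizedSignalModel,
    SimulationDesign,
    SpectralGrid,
    make_band_profile,
    reference_values,
    simulate_measurement,
    simulate_population,
    to_absorbance,
    to_absorbance_set,
)
from aquakiwi.io import write_spectra_csv
from aquakiwi.simulate import DEFAULT_BAND_AMPLITUDES, ssc_shift_factors
from aquakiwi.wamacs import band_midpoints


def _fruit(ssc=13.75, amps=None, skin=0.0):
    return PhantomFruit(
        fruit_id="F1",
        ssc_stem=ssc,
        ssc_blossom=ssc,
        wet_weight=12.5,
        dry_weight=2.0,
        band_amplitudes=DEFAULT_BAND_AMPLITUDES if amps is None else amps,
        skin_scatter=skin,
    )


class TestBandProfile:
    def test_zero_amplitudes_zero_envelope_is_identically_zero(self, grid):
        prof = make_band_profile(np.zeros(12), grid, envelope_amplitude=0.0)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_single_band_peak_at_nearest_grid_point(self, grid):
        amps = np.zeros(12)
        amps[4] = 1.0  # C5, centre (942+955)/2 = 948.5
        prof = make_band_profile(amps, grid)
        assert np.argmax(prof.values) == grid.index_nearest(948.5)

    def test_linearity_in_amplitudes(self, grid):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0, 1, 12)
        total = make_band_profile(amps, grid).values
        parts = np.zeros(len(grid))
        for i in range(12):
            single = np.zeros(12)
            single[i] = amps[i]
            parts += make_band_profile(single, grid).values
        np.testing.assert_allclose(total, parts, atol=1e-12)

    def test_values_nonnegative(self, grid):
        prof = make_band_profile(DEFAULT_BAND_AMPLITUDES, grid,
                                 envelope_amplitude=0.8)
        assert np.all(prof.values >= 0)

    def test_negative_amplitudes_rejected(self, grid):
        with pytest.raises(ValueError):
            make_band_profile(np.r_[-1.0, np.zeros(11)], grid)


class TestReferenceValues:
    def test_equal_weights_give_100_percent(self):
        f = _fruit()
        f.dry_weight = f.wet_weight = 10.0
        assert reference_values(f)[0] == 100.0

    def test_ssc_is_mean_of_ends(self):
        f = _fruit()
        f.ssc_stem, f.ssc_blossom = 10.0, 12.0
        assert reference_values(f)[1] == 11.0

    def test_dmc_division_oracle(self):
        f = _fruit()
        f.wet_weight, f.dry_weight = 12.50, 2.05
        assert reference_values(f)[0] == pytest.approx(16.4, abs=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            PhantomFruit("F", 10, 10, 0.0, 0.0, np.zeros(12), 0.0)
        with pytest.raises(ValueError):
            PhantomFruit("F", 10, 10, 5.0, 6.0, np.zeros(12), 0.0)


class TestSimulateMeasurement:
    def test_no_effect_case_all_configurations_identical(self):
        design = SimulationDesign(noise_sd=0.0, depol_surface_weight=0.0,
                                  effect_matrix=np.ones((4, 12)),
                                  ssc_shift_rate=0.0)
        f = _fruit(skin=0.0)
        outs = {}
        for cfg in CONFIGURATIONS:
            rng = np.random.default_rng(0)
            scans, _ = simulate_measurement(f, cfg, design, rng)
            outs[cfg] = scans[0].values
        for cfg in CONFIGURATIONS[1:]:
            np.testing.assert_allclose(outs[cfg], outs["UU"], atol=1e-15)

    def test_default_effects_order_mean_absorbance(self):
        """Mean absorbance over the grid: peeled > unpeeled and
        polarized > unpolarized, as on real fruit."""
        design = SimulationDesign(noise_sd=0.0)
        f = _fruit(skin=design.skin_scatter_mean)
        means = {}
        for cfg in CONFIGURATIONS:
            rng = np.random.default_rng(0)
            scans, ref = simulate_measurement(f, cfg, design, rng)
            means[cfg] = to_absorbance(scans[0], ref).values.mean()
        assert means["PU"] > means["UU"]
        assert means["PP"] > means["UP"]
        assert means["UP"] > means["UU"]
        assert means["PP"] > means["PU"]

    def test_same_seed_bit_identical(self):
        design = SimulationDesign()
        f = _fruit()
        a, _ = simulate_measurement(f, "PP", design, np.random.default_rng(42))
        b, _ = simulate_measurement(f, "PP", design, np.random.default_rng(42))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.values, s2.values)

    def test_unknown_configuration_rejected(self):
        with pytest.raises(ValueError, match="configuration"):
            simulate_measurement(_fruit(), "XY", SimulationDesign(),
                                 np.random.default_rng(0))

    def test_copolarized_identity_holds_per_scan(self):
        """Detected = I_parallel + 0.5 * I_perp for polarized scans."""
        design = SimulationDesign(noise_sd=0.003)
        scans, _ = simulate_measurement(_fruit(), "UP", design,
                                        np.random.default_rng(1))
        for s in scans:
            model = PolarizedSignalModel(s.meta["i_parallel"], s.meta["i_perp"],
                                         s.meta["copol_fraction"])
            np.testing.assert_allclose(s.values, model.detected, atol=1e-12)

    def test_effect_matrix_increase_raises_absorbance_at_band_center(self):
        base = SimulationDesign(noise_sd=0.0)
        boosted_matrix = base.effect_matrix.copy()
        boosted_matrix[3, 6] *= 1.5  # PP row, C7
        boosted = SimulationDesign(noise_sd=0.0, effect_matrix=boosted_matrix)
        f = _fruit()
        idx = base.grid.index_nearest(band_midpoints()[6])
        scans, ref = simulate_measurement(f, "PP", base, np.random.default_rng(0))
        abs_base = to_absorbance(scans[0], ref).values[idx]
        scans, ref = simulate_measurement(f, "PP", boosted, np.random.default_rng(0))
        abs_boost = to_absorbance(scans[0], ref).values[idx]
        assert abs_boost > abs_base

    def test_depolarization_limit_polarized_equals_unpolarized(self):
        """With no surface weighting and no noise, polarized and unpolarized
        absorbance spectra coincide: fully depolarized deep light interacts
        identically regardless of incident polarization."""
        design = SimulationDesign(noise_sd=0.0, depol_surface_weight=0.0)
        f = _fruit(skin=0.04)
        spectra = {}
        for cfg in CONFIGURATIONS:
            scans, ref = simulate_measurement(f, cfg, design,
                                              np.random.default_rng(0))
            spectra[cfg] = to_absorbance(scans[0], ref).values
        assert np.abs(spectra["UP"] - spectra["UU"]).max() < 1e-12
        assert np.abs(spectra["PP"] - spectra["PU"]).max() < 1e-12


class TestSscShift:
    def test_free_decreases_bound_increases_with_ssc(self):
        design = SimulationDesign()
        sscs = np.linspace(7, 20.5, 20)
        free_tot = []
        bound_tot = []
        for ssc in sscs:
            f = DEFAULT_BAND_AMPLITUDES * ssc_shift_factors(ssc, design)
            free_tot.append(f[:5].sum())
            bound_tot.append(f[5:10].sum())
        assert np.all(np.diff(free_tot) < 0)
        assert np.all(np.diff(bound_tot) > 0)


class TestSimulatePopulation:
    def test_counts_and_ssc_bounds(self, small_population):
        spectra, truth = small_population.spectra, small_population.truth
        assert spectra.n_samples == 48 * 4
        assert len(truth) == 48
        assert truth["ssc"].min() >= 7.0
        assert truth["ssc"].max() <= 20.5

    def test_truth_invariants(self, small_population):
        truth = small_population.truth
        np.testing.assert_allclose(
            truth["ssc"], (truth["ssc_stem"] + truth["ssc_blossom"]) / 2,
            atol=1e-9)
        np.testing.assert_allclose(
            truth["dmc_pct"],
            100 * truth["dry_weight_g"] / truth["wet_weight_g"], atol=1e-9)
        amp_cols = [c for c in truth.columns if c.startswith("amp_")]
        assert (truth[amp_cols] >= 0).all().all()

    def test_bitwise_reproducible_via_csv_bytes(self, tmp_path):
        design = SimulationDesign(n_fruit=5, seed=123)
        a = simulate_population(design)
        b = simulate_population(SimulationDesign(n_fruit=5, seed=123))
        pa = write_spectra_csv(a.spectra, tmp_path / "a.csv")
        pb = write_spectra_csv(b.spectra, tmp_path / "b.csv")
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a = simulate_population(SimulationDesign(n_fruit=3, seed=1))
        b = simulate_population(SimulationDesign(n_fruit=3, seed=2))
        assert not np.array_equal(a.spectra.matrix, b.spectra.matrix)

    def test_absorbance_conversion_of_population(self, small_population):
        absorb = to_absorbance_set(small_population.spectra,
                                   small_population.references)
        assert absorb.kind == "absorbance"
        assert np.all(np.isfinite(absorb.matrix))
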