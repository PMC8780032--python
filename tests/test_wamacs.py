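import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquakiwi import (
    ActivatedWavelengthSet,
    assign_band,
    fit_pca,
    published_activated_set,
    select_activated,
    ssc_difference_spectra,
    ssc_group,
    wamacs_table,
)
from aquakiwi.spectra import SpectralGrid, Spectrum
from aquakiwi.wamacs import BAND_IDS, PUBLISHED_ACTIVATED, SSC_GROUP_REFERENCE


class TestBandTable:
    def test_twelve_bands_in_order(self):
        bands = wamacs_table()
        assert [b.band_id for b in bands] == list(BAND_IDS)
        assert len(bands) == 12
        los = [b.lo_nm for b in bands]
        assert los == sorted(los)

    def test_printed_ranges(self):
        by_id = {b.band_id: b for b in wamacs_table()}
        assert (by_id["C5"].lo_nm, by_id["C5"].hi_nm) == (942.0, 955.0)
        assert "free water" in by_id["C5"].assignment
        assert (by_id["C7"].lo_nm, by_id["C7"].hi_nm) == (965.0, 973.0)
        assert "one hydrogen bond" in by_id["C7"].assignment

    def test_species_classes(self):
        bands = wamacs_table()
        assert [b.species_class for b in bands[:5]] == ["free"] * 5
        assert [b.species_class for b in bands[5:]] == ["bound"] * 7


class TestAssignBand:
    @pytest.mark.parametrize("wl, band", [
        (946.0, "C5"),
        (998.0, "C10"),  # shared endpoint resolves to the lower band
        (899.0, None),
        (940.0, None),   # gap between C4 and C5
        (1021.0, "C12"),
        (903.0, "C1"),
    ])
    def test_examples(self, wl, band):
        assert assign_band(wl) == band

    @settings(max_examples=100, deadline=None)
    @given(wl=st.floats(min_value=800, max_value=1050))
    def test_assignment_is_consistent_with_band_ranges(self, wl):
        band = assign_band(wl)
        if band is None:
            assert not any(b.contains(wl) for b in wamacs_table())
        else:
            b = {x.band_id: x for x in wamacs_table()}[band]
            assert b.lo_nm <= wl <= b.hi_nm


class TestSscGroup:
    @pytest.mark.parametrize("ssc, group", [
        (10.4, "Low"), (12.0, "Medium"), (14.999, "Medium"),
        (15.0, "High"), (16.9, "High"), (7.0, "Low"), (11.95, "Low"),
    ])
    def test_boundaries(self, ssc, group):
        assert ssc_group(ssc) == group

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ssc_group(-1.0)

    def test_reference_table_is_internally_consistent(self):
        groups = [SSC_GROUP_REFERENCE[g] for g in ("Low", "Medium", "High")]
        assert sum(g["n"] for g in groups) == SSC_GROUP_REFERENCE["All"]["n"]
        means = [g["mean"] for g in groups]
        assert means == sorted(means)


class TestDifferenceSpectra:
    def test_low_minus_low_is_zero_and_offsets_propagate(self, small_snv2d):
        diffs = ssc_difference_spectra(small_snv2d, "UU")
        np.testing.assert_allclose(diffs["Low"].values, 0.0, atol=1e-14)
        assert diffs["High"].kind == "difference"

    def test_constant_offset_between_groups(self, grid):
        from aquakiwi.spectra import SpectraSet
        n = len(grid)
        rows = np.vstack([np.zeros(n), np.zeros(n) + 2.0, np.zeros(n) + 5.0])
        table = pd.DataFrame({
            "fruit_id": ["a", "b", "c"],
            "configuration": ["UU"] * 3,
            "ssc_group": ["Low", "Medium", "High"],
        })
        sset = SpectraSet(matrix=rows, sample_table=table, grid=grid, kind="snv2d")
        diffs = ssc_difference_spectra(sset, "UU")
        np.testing.assert_allclose(diffs["Medium"].values, -2.0, atol=1e-14)
        np.testing.assert_allclose(diffs["High"].values, -5.0, atol=1e-14)

    def test_empty_group_named_in_error(self, grid):
        from aquakiwi.spectra import SpectraSet
        table = pd.DataFrame({
            "fruit_id": ["a", "b"],
            "configuration": ["UU", "UU"],
            "ssc_group": ["Low", "High"],
        })
        sset = SpectraSet(matrix=np.zeros((2, len(grid))), sample_table=table,
                          grid=grid, kind="snv2d")
        with pytest.raises(ValueError, match="Medium"):
            ssc_difference_spectra(sset, "UU")

    def test_injected_ssc_shift_flips_sign_between_free_and_bound(self, small_snv2d):
        """The simulator moves amplitude from free (C1-C5) to bound (C6-C10)
        bands as SSC rises; the High-group difference spectrum must reflect
        that with opposite signs in the two regions."""
        diffs = ssc_difference_spectra(small_snv2d, "UU")
        high = diffs["High"]
        wl = high.grid.wavelengths
        # negated 2nd derivative ~ absorbance: Low - High positive at free bands
        free_val = -high.values[high.grid.index_nearest(946.0)]
        bound_val = -high.values[high.grid.index_nearest(994.0)]
        assert free_val > 0 > bound_val


class TestActivatedSelection:
    def test_published_pairings_roundtrip_through_assign_band(self):
        for band_id, (wl, _) in PUBLISHED_ACTIVATED.items():
            assert assign_band(wl) == band_id

    def test_published_set_is_complete_and_ordered(self):
        act = published_activated_set()
        assert act.band_ids == list(BAND_IDS)

    def test_wavelength_outside_band_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ActivatedWavelengthSet({"C5": (960.0, "pca")})

    def test_single_bump_selects_only_its_band(self, grid):
        wl = grid.wavelengths
        bump = np.exp(-0.5 * ((wl - 946.0) / 5.0) ** 2)
        matrix = np.outer(np.random.default_rng(0).normal(size=10), bump)
        model = fit_pca(matrix, n_components=1, grid=grid)
        spec = Spectrum(grid=grid, values=bump, kind="snv2d")
        diff = Spectrum(grid=grid, values=bump, kind="difference")
        with pytest.warns(UserWarning):
            act = select_activated(model, {"UU": spec}, {"High": diff})
        assert act.band_ids == ["C5"]
        assert act.entries["C5"][0] == wl[grid.index_nearest(946.0)]

    def test_equal_magnitude_tie_breaks_to_lower_wavelength(self, grid):
        wl = grid.wavelengths
        two = (np.exp(-0.5 * ((wl - 944.0) / 2.0) ** 2)
               + np.exp(-0.5 * ((wl - 953.0) / 2.0) ** 2))
        matrix = np.outer(np.random.default_rng(1).normal(size=10), two)
        model = fit_pca(matrix, n_components=1, grid=grid)
        spec = Spectrum(grid=grid, values=two, kind="snv2d")
        with pytest.warns(UserWarning):
            act = select_activated(model, {"UU": spec}, {})
        assert act.entries["C5"][0] == wl[grid.index_nearest(944.0)]

    def test_selection_invariant_to_source_rescaling(self, small_snv2d):
        from aquakiwi.spectra import CONFIGURATIONS, Spectrum as Sp
        model = fit_pca(small_snv2d, n_components=3)
        means = {}
        for cfg in CONFIGURATIONS:
            mask = (small_snv2d.sample_table["configuration"] == cfg).to_numpy()
            means[cfg] = Sp(grid=small_snv2d.grid,
                            values=small_snv2d.matrix[mask].mean(axis=0),
                            kind="snv2d")
        diffs = ssc_difference_spectra(small_snv2d, "UU")
        a = select_activated(model, means, diffs)
        scaled = {k: Sp(grid=v.grid, values=17.0 * v.values, kind="snv2d")
                  for k, v in means.items()}
        b = select_activated(model, scaled, diffs)
        assert a.entries == b.entries

    def test_every_selected_wavelength_maps_back_to_its_band(self, small_snv2d):
        from aquakiwi.spectra import CONFIGURATIONS, Spectrum as Sp
        model = fit_pca(small_snv2d, n_components=3)
        means = {cfg: Sp(grid=small_snv2d.grid,
                         values=small_snv2d.matrix[
                             (small_snv2d.sample_table["configuration"] == cfg
                              ).to_numpy()].mean(axis=0),
                         kind="snv2d")
                 for cfg in CONFIGURATIONS}
        diffs = ssc_difference_spectra(small_snv2d, "PP")
        act = select_activated(model, means, diffs)
        for band_id, (wl, source) in act.entries.items():
            assert assign_band(wl) == band_id
            assert source in ("pca", "snv2d", "ssc_diff")
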