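"""Virtual-tissue geometry, chromophore spectra and optical assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from paflux.grid import ARTERY, BACKGROUND, SKIN, VEIN, GridSpec, desk_grid
from paflux.spectra import available_chromophores, chromophore_absorption, _spectrum
from paflux.tissue import (GeometryConfig, OpticalPropertyMap, TissueLibraryEntry,
                           adjust_scattering_for_fixed_g,
                           assign_optical_properties, blood_entry,
                           load_tissue_h5, sample_forearm_geometry,
                           sample_tissue_library, save_tissue_h5)

FULL_GRID = GridSpec(128, 256, 0.15625)


class TestGeometry:
    def test_zero_vessel_case_gives_skin_band_only(self):
        config = GeometryConfig(seed=0, vessel_count=(0, 0),
                                skin_thickness_mm=(1.0, 1.0))
        label_map = sample_forearm_geometry(config, FULL_GRID)
        assert label_map.skin_rows == int(np.ceil(1.0 / 0.15625))
        assert set(np.unique(label_map.labels)) == {BACKGROUND, SKIN}
        assert np.all(label_map.labels[:label_map.skin_rows] == SKIN)

    def test_seeded_determinism_bitwise(self):
        config = GeometryConfig(seed=7)
        a = sample_forearm_geometry(config, FULL_GRID)
        b = sample_forearm_geometry(config, FULL_GRID)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.vessel_ids, b.vessel_ids)

    def test_connected_vessel_components_match_requested_range(self):
        config = GeometryConfig(seed=7, vessel_count=(2, 5))
        label_map = sample_forearm_geometry(config, FULL_GRID)
        vessel_mask = np.isin(label_map.labels, (ARTERY, VEIN))
        _, n_components = ndimage.label(vessel_mask)
        assert 2 <= n_components <= 5

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_vessels_strictly_below_skin(self, seed):
        config = GeometryConfig(seed=seed)
        label_map = sample_forearm_geometry(config, desk_grid())
        label_map.validate()
        vessel_rows = np.flatnonzero(
            np.isin(label_map.labels, (ARTERY, VEIN)).any(axis=1)
        )
        if len(vessel_rows):
            assert vessel_rows.min() >= label_map.skin_rows

    def test_geometry_statistics_within_configured_ranges(self):
        config = GeometryConfig(vessel_count=(2, 6),
                                vessel_radius_mm=(0.5, 3.0))
        counts, radii = [], []
        for seed in range(100):
            lm = sample_forearm_geometry(
                GeometryConfig(seed=seed, vessel_count=(2, 6),
                               vessel_radius_mm=(0.5, 3.0)), desk_grid()
            )
            counts.append(len(lm.vessels))
            radii.extend(v.radius for v in lm.vessels)
        assert min(counts) >= 2 and max(counts) <= 6
        assert min(radii) >= 0.5 and max(radii) <= 3.0
        # both artery and vein classes occur
        assert len({v.label for lm_seed in range(3)
                    for v in sample_forearm_geometry(
                        GeometryConfig(seed=lm_seed), desk_grid()).vessels}
                   ) == 2

    def test_oversized_vessel_rejected(self):
        config = GeometryConfig(vessel_radius_mm=(15.0, 30.0))
        with pytest.raises(ValueError):
            sample_forearm_geometry(config, desk_grid())

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            sample_forearm_geometry(
                GeometryConfig(vessel_radius_mm=(2.0, 1.0)), desk_grid()
            )

    def test_undulating_skin_stays_contiguous_per_column(self):
        config = GeometryConfig(seed=3, skin_undulation_mm=0.5,
                                skin_thickness_mm=(1.0, 2.0))
        lm = sample_forearm_geometry(config, desk_grid())
        skin = lm.labels == SKIN
        for col in range(skin.shape[1]):
            rows = np.flatnonzero(skin[:, col])
            assert rows[0] == 0 and np.all(np.diff(rows) == 1)


class TestChromophores:
    def test_knot_identity_and_midpoint_interpolation(self):
        for cid in available_chromophores():
            wl, mua = _spectrum(cid)
            assert chromophore_absorption(cid, wl[3]) == pytest.approx(mua[3])
            mid = 0.5 * (wl[3] + wl[4])
            assert chromophore_absorption(cid, mid) == pytest.approx(
                0.5 * (mua[3] + mua[4])
            )

    def test_deoxyhemoglobin_spectral_ordering(self):
        assert chromophore_absorption("hb", 700.0) > chromophore_absorption(
            "hb", 850.0
        )

    def test_all_values_positive(self):
        for cid in available_chromophores():
            for wl in np.linspace(700, 850, 31):
                assert chromophore_absorption(cid, wl) > 0

    def test_unknown_chromophore_and_range_errors(self):
        with pytest.raises(KeyError):
            chromophore_absorption("unobtainium", 800.0)
        with pytest.raises(ValueError):
            chromophore_absorption("hb", 650.0)


class TestOpticalAssignment:
    @pytest.fixture()
    def label_map(self):
        return sample_forearm_geometry(GeometryConfig(seed=11), desk_grid())

    def test_single_chromophore_mixture(self, label_map):
        f = 0.37
        library = {
            label: TissueLibraryEntry(label, (("hb", f),), 10.0, 1.2, 0.9)
            for label in (BACKGROUND, SKIN, ARTERY, VEIN)
        }
        lm = sample_forearm_geometry(
            GeometryConfig(seed=1, vessel_count=(0, 0)), desk_grid()
        )
        opt = assign_optical_properties(lm, 800.0, library)
        expected = f * chromophore_absorption("hb", 800.0)
        assert np.allclose(opt.mu_a, expected)

    def test_mixture_linearity_under_fraction_doubling(self):
        lm = sample_forearm_geometry(
            GeometryConfig(seed=2, vessel_count=(0, 0)), desk_grid()
        )

        def lib(scale):
            return {
                label: TissueLibraryEntry(
                    label, (("hb", 0.01 * scale), ("water", 0.5 * scale)),
                    10.0, 1.2, 0.9)
                for label in (BACKGROUND, SKIN)
            }

        mu1 = assign_optical_properties(lm, 750.0, lib(1.0)).mu_a
        mu2 = assign_optical_properties(lm, 750.0, lib(2.0)).mu_a
        assert np.allclose(mu2, 2.0 * mu1)

    def test_scattering_power_law_at_reference_wavelength(self, label_map):
        library = sample_tissue_library(GeometryConfig(), np.random.default_rng(0))
        opt = assign_optical_properties(label_map, 800.0, library)
        for label, entry in library.items():
            mask = (label_map.labels == label) & (label_map.vessel_ids == 0)
            if mask.any():
                assert np.allclose(opt.mu_s[mask], entry.mus_at_800)

    def test_power_law_wavelength_dependence(self):
        entry = TissueLibraryEntry(BACKGROUND, (("water", 1.0),), 10.0, 1.5, 0.9)
        assert entry.mu_s(700.0) == pytest.approx(10.0 * (700 / 800) ** -1.5)

    def test_missing_library_entry_raises(self, label_map):
        library = {BACKGROUND: blood_entry(BACKGROUND, 0.5)}
        with pytest.raises(KeyError):
            assign_optical_properties(label_map, 800.0, library)

    def test_per_vessel_oxygenation_painted(self, label_map):
        library = sample_tissue_library(GeometryConfig(), np.random.default_rng(0))
        opt = assign_optical_properties(label_map, 700.0, library)
        opt.validate()
        for vid, vessel in enumerate(label_map.vessels, start=1):
            mask = label_map.vessel_ids == vid
            if not mask.any():
                continue
            expected = blood_entry(vessel.label, vessel.oxygenation).mu_a(700.0)
            assert np.allclose(opt.mu_a[mask], expected)

    def test_invariants_hold_across_wavelengths(self, label_map):
        library = sample_tissue_library(GeometryConfig(), np.random.default_rng(1))
        for wl in (700.0, 760.0, 850.0):
            opt = assign_optical_properties(label_map, wl, library)
            opt.validate()  # mu_a > 0, mu_s >= 0, 0 <= g < 1


class TestScatteringAdjustment:
    def make_map(self, rng):
        grid = GridSpec(8, 8, 1.0)
        return OpticalPropertyMap(
            grid, 800.0,
            mu_a=rng.uniform(0.01, 1.0, grid.shape),
            mu_s=rng.uniform(0.0, 20.0, grid.shape),
            g=rng.uniform(0.0, 0.99, grid.shape),
        )

    def test_identity_when_g_unchanged(self):
        grid = GridSpec(8, 8, 1.0)
        opt = OpticalPropertyMap(grid, 800.0, np.full(grid.shape, 0.1),
                                 np.full(grid.shape, 10.0),
                                 np.full(grid.shape, 0.9))
        adj = adjust_scattering_for_fixed_g(opt, 0.9)
        assert np.allclose(adj.mu_s, opt.mu_s)

    def test_worked_example(self):
        grid = GridSpec(8, 8, 1.0)
        opt = OpticalPropertyMap(grid, 800.0, np.full(grid.shape, 0.1),
                                 np.full(grid.shape, 10.0),
                                 np.full(grid.shape, 0.9))
        adj = adjust_scattering_for_fixed_g(opt, 0.8)
        assert np.allclose(adj.mu_s, 5.0)  # 10 * 0.1 / 0.2

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_reduced_scattering_conserved(self, seed):
        rng = np.random.default_rng(seed)
        opt = self.make_map(rng)
        g_fixed = rng.uniform(0.0, 0.95)
        adj = adjust_scattering_for_fixed_g(opt, g_fixed)
        assert np.allclose(adj.mu_s * (1 - g_fixed), opt.mu_s * (1 - opt.g))
        assert np.allclose(adj.g, g_fixed)

    def test_g_of_one_rejected(self):
        opt = self.make_map(np.random.default_rng(0))
        with pytest.raises(ValueError):
            adjust_scattering_for_fixed_g(opt, 1.0)


def test_tissue_h5_round_trip(tmp_path):
    lm = sample_forearm_geometry(GeometryConfig(seed=4), desk_grid())
    library = sample_tissue_library(GeometryConfig(), np.random.default_rng(4))
    opt = assign_optical_properties(lm, 810.0, library)
    path = tmp_path / "tissue.h5"
    save_tissue_h5(path, opt, lm)
    loaded, labels = load_tissue_h5(path)
    assert np.allclose(loaded.mu_a, opt.mu_a)
    assert loaded.wavelength == 810.0
    assert loaded.grid == opt.grid
    assert np.array_equal(labels, lm.labels)
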