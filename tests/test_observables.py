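"""Radius of gyration, entropy, spectra, dipole, ESP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fullersim.observables import (
    E_A_TO_CM,
    bond_length_histogram,
    dipole_moment,
    esp_grid,
    esp_iso_points,
    power_spectrum,
    radius_of_gyration,
    shannon_entropy,
    spectral_bands,
)


class TestRadiusOfGyration:
    def test_shell_identity(self, c60_geometry):
        # equal masses all at distance R from the centroid: Rg = R
        rg = radius_of_gyration(c60_geometry.positions, c60_geometry.masses)
        assert rg == pytest.approx(c60_geometry.radii()[0], rel=1e-9)

    def test_two_point_closed_form(self):
        x = np.array([[1.5, 0, 0], [-1.5, 0, 0]])
        assert radius_of_gyration(x, np.array([1.0, 1.0])) == pytest.approx(1.5)

    def test_hand_evaluated_weighted_case(self):
        # masses {12, 12, 24} at x = 0, 1, 4:
        # com = (0 + 12 + 96)/48 = 2.25
        # Rg^2 = (12*2.25^2 + 12*1.25^2 + 24*1.75^2)/48 = 153/48 = 3.1875
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
        m = np.array([12.0, 12.0, 24.0])
        assert radius_of_gyration(x, m) == pytest.approx(np.sqrt(3.1875),
                                                         rel=1e-12)

    def test_rigid_motion_invariance(self, c60_geometry):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        moved = c60_geometry.positions @ rot.T + 3.3
        assert radius_of_gyration(moved, c60_geometry.masses) == pytest.approx(
            radius_of_gyration(c60_geometry.positions, c60_geometry.masses),
            rel=1e-12,
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


class TestShannonEntropy:
    def test_two_equal_groups_give_one_bit(self):
        values = [1.39] * 45 + [1.45] * 45
        assert shannon_entropy(values, 0.01) == pytest.approx(1.0, abs=1e-12)

    def test_single_bin_gives_zero(self):
        assert shannon_entropy([1.40] * 90, 0.01) == 0.0

    def test_four_equal_groups_give_two_bits(self):
        values = [1.31] * 10 + [1.35] * 10 + [1.41] * 10 + [1.47] * 10
        assert shannon_entropy(values, 0.01) == pytest.approx(2.0, abs=1e-12)

    @given(st.lists(st.floats(1.30, 1.55), min_size=1, max_size=200),
           st.sampled_from([0.005, 0.01, 0.02]))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, values, width):
        h = shannon_entropy(values, width)
        hist = bond_length_histogram(values, width)
        n_occupied = int((hist.counts > 0).sum())
        assert 0.0 <= h <= np.log2(max(n_occupied, 1)) + 1e-9

    def test_histogram_conserves_counts(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1.30, 1.55, 500)
        hist = bond_length_histogram(v)
        assert hist.counts.sum() == 500
        widths = np.diff(hist.bin_edges)
        assert np.allclose(widths, widths[0])


class TestPowerSpectrum:
    def test_pure_tone_recovered(self):
        t = np.arange(10000) * 1.0  # fs
        y = np.sin(2 * np.pi * 0.010 * t)  # 10 THz
        spec = power_spectrum(y, 1.0)
        assert abs(spec.fundamental_freq - 10.0) <= 0.1 + 1e-12

    def test_two_tones_both_found(self):
        t = np.arange(20000) * 1.0
        y = np.sin(2 * np.pi * 0.008 * t) + 0.5 * np.sin(2 * np.pi * 0.013 * t)
        spec = power_spectrum(y, 1.0)
        freqs = [round(f, 2) for f, _ in spec.peaks]
        assert 8.0 in freqs and 13.0 in freqs

    def test_constant_series_flat(self):
        spec = power_spectrum(np.full(256, 3.44), 10.0)
        assert np.allclose(spec.power, 0.0, atol=1e-20)
        assert spec.peaks == []

    def test_parseval(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=4096)
        spec = power_spectrum(y, 10.0)
        var = np.var(y)
        assert spec.power.sum() == pytest.approx(var, rel=1e-6)

    def test_welch_segments_reduce_variance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=8192)
        raw = power_spectrum(y, 10.0, segments=1)
        avg = power_spectrum(y, 10.0, segments=16)
        cv = lambda p: np.std(p[1:]) / np.mean(p[1:])
        assert cv(avg.power) < 0.5 * cv(raw.power)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            power_spectrum(np.ones(8), 1.0)


class TestSpectralBands:
    def test_distinct_tones_are_distinct_bands(self):
        t = np.arange(16000) * 10.0
        y = (np.sin(2 * np.pi * 3.0e-3 * t) + 0.8 * np.sin(2 * np.pi * 8.0e-3 * t)
             + 0.001 * np.random.default_rng(0).normal(size=t.size))
        spec = power_spectrum(y, 10.0, segments=8)
        bands = spectral_bands(spec)
        assert len(bands) == 2
        assert bands[0][0] == pytest.approx(3.0, abs=0.1)
        assert bands[1][0] == pytest.approx(8.0, abs=0.1)

    def test_nearby_subpeaks_merge(self):
        # two tones 0.2 THz apart (< the 0.5 THz mode separation) = one band
        t = np.arange(16000) * 10.0
        y = (np.sin(2 * np.pi * 5.0e-3 * t) + np.sin(2 * np.pi * 5.2e-3 * t)
             + 0.001 * np.random.default_rng(1).normal(size=t.size))
        spec = power_spectrum(y, 10.0, segments=8)
        assert len(spectral_bands(spec)) == 1


class TestDipoleMoment:
    def test_symmetric_pair_closed_form(self):
        x = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        q = np.array([1.0, -1.0])
        vec, mag = dipole_moment(x, q)
        assert np.allclose(vec, [2.0, 0.0, 0.0])
        assert mag == pytest.approx(2.0 * E_A_TO_CM, rel=1e-12)

    def test_zero_charges_zero_dipole(self, c60_geometry):
        _, mag = dipole_moment(c60_geometry.positions, np.zeros(60),
                               c60_geometry.masses)
        assert mag == 0.0

    def test_origin_independence_for_neutral_sets(self):
        from fullersim.synthetic import random_zero_sum_charges

        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 3))
        q = random_zero_sum_charges(20, 0.05, 3)
        _, m1 = dipole_moment(x, q)
        _, m2 = dipole_moment(x + np.array([10.0, -4.0, 2.0]), q)
        assert m1 == pytest.approx(m2, rel=1e-9)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            dipole_moment(np.zeros((3, 3)), np.zeros(4))


class TestESPGrid:
    def test_zero_charges_zero_grid(self, c60_geometry):
        grid = esp_grid(c60_geometry.positions, np.zeros(60), extent=8.0,
                        spacing=1.0)
        assert np.nanmax(np.abs(grid.values)) == 0.0

    def test_single_charge_coulomb_law(self):
        k_e = 1389.35
        grid = esp_grid(np.zeros((1, 3)), np.array([1.0]), extent=8.0,
                        spacing=1.0, k_e=k_e, center=np.zeros(3))
        # on-axis points: V = k_e / r
        ax = grid.axis(0)
        mid = len(ax) // 2
        for off in (2, 3, 4):
            v = grid.values[mid + off, mid, mid]
            assert v == pytest.approx(k_e / abs(ax[mid + off]), rel=1e-12)

    def test_sign_flip_antisymmetry(self, c60_geometry):
        from fullersim.synthetic import random_zero_sum_charges

        q = random_zero_sum_charges(60, 0.05, 9)
        g1 = esp_grid(c60_geometry.positions, q, extent=10.0, spacing=1.0)
        g2 = esp_grid(c60_geometry.positions, -q, extent=10.0, spacing=1.0)
        assert np.allclose(g1.values, -g2.values, equal_nan=True)

    def test_dipole_antisymmetric_across_bisector(self):
        x = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        q = np.array([1.0, -1.0])
        grid = esp_grid(x, q, extent=6.0, spacing=1.0, center=np.zeros(3))
        v = grid.values
        flipped = v[::-1, :, :]
        assert np.allclose(v, -flipped, equal_nan=True)

    def test_mask_near_atoms(self):
        grid = esp_grid(np.zeros((1, 3)), np.array([1.0]), extent=4.0,
                        spacing=0.5, center=np.zeros(3))
        mid = grid.values.shape[0] // 2
        assert not grid.mask[mid, mid, mid]
        assert np.isnan(grid.values[mid, mid, mid])

    def test_iso_points_split_by_sign(self):
        x = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        q = np.array([1.0, -1.0])
        grid = esp_grid(x, q, extent=6.0, spacing=0.5, center=np.zeros(3))
        pos, neg, level = esp_iso_points(grid, 0.5)
        assert level > 0
        assert len(pos) and len(neg)
        assert pos[:, 0].min() > 0 and neg[:, 0].max() < 0
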