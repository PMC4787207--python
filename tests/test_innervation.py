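"""Terminal maps: placement statistics, denervation modes, void detection."""
import numpy as np
import pytest
from scipy import stats

import striatosim as ss
from striatosim.config import ConfigError
from striatosim.innervation import coverage_counts


@pytest.fixture(scope="module")
def lattice():
    return ss.Lattice(extent=(60.0, 60.0, 60.0))


class TestMicroscale:
    def test_expected_count_poisson(self, lattice):
        tmap = ss.build_microscale(lattice, 0.1, seed=1)
        expected = 0.1 * lattice.volume
        assert abs(tmap.n_terminals - expected) < 3 * np.sqrt(expected)

    def test_zero_density_empty(self, lattice):
        assert ss.build_microscale(lattice, 0.0, seed=1).n_terminals == 0

    def test_negative_density_rejected(self, lattice):
        with pytest.raises(ConfigError):
            ss.build_microscale(lattice, -0.1, seed=1)

    def test_uniformity_chi_square_octants(self, lattice):
        tmap = ss.build_microscale(lattice, 0.1, seed=2)
        half = np.asarray(lattice.extent) / 2
        octant = (tmap.positions >= half).astype(int)
        code = octant[:, 0] * 4 + octant[:, 1] * 2 + octant[:, 2]
        counts = np.bincount(code, minlength=8)
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01


class TestUniformDenervation:
    def test_fraction_zero_is_identity(self, lattice):
        tmap = ss.build_microscale(lattice, 0.1, seed=3)
        out = ss.denervate_uniform(tmap, 0.0, seed=4)
        np.testing.assert_array_equal(out.positions, tmap.positions)

    def test_ninety_percent_removal(self, lattice):
        tmap = ss.build_microscale(lattice, 0.1, seed=3)
        out = ss.denervate_uniform(tmap, 0.9, seed=4)
        n, p = tmap.n_terminals, 0.1
        assert abs(out.n_terminals - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_fraction_one_empties_map(self, lattice):
        tmap = ss.build_microscale(lattice, 0.1, seed=3)
        assert ss.denervate_uniform(tmap, 1.0, seed=4).n_terminals == 0

    def test_remaining_distribution_stays_uniform(self, lattice):
        # the coherent regime: surviving terminals pass the same octant
        # uniformity check as the intact map
        tmap = ss.denervate_uniform(ss.build_microscale(lattice, 0.1, seed=5), 0.75, seed=6)
        half = np.asarray(lattice.extent) / 2
        octant = (tmap.positions >= half).astype(int)
        code = octant[:, 0] * 4 + octant[:, 1] * 2 + octant[:, 2]
        assert stats.chisquare(np.bincount(code, minlength=8)).pvalue > 0.01

    def test_out_of_range_fraction_rejected(self, lattice):
        tmap = ss.build_microscale(lattice, 0.01, seed=3)
        with pytest.raises(ConfigError):
            ss.denervate_uniform(tmap, 1.5, seed=0)

    def test_denervating_empty_map_is_noop(self, lattice):
        empty = ss.build_microscale(lattice, 0.0, seed=1)
        assert ss.denervate_uniform(empty, 0.5, seed=1).n_terminals == 0


class TestMesoscale:
    def test_mean_point_coverage_in_printed_range(self, lattice):
        # 5000 arbors at 2.7% coverage: expected overlap N*c = 135,
        # inside the anatomical 100-200 arbors-per-point range
        arbors, _ = ss.build_mesoscale(lattice, 5000, 0.027, 0.0, seed=7)
        rng = np.random.default_rng(0)
        pts = rng.random((2000, 3)) * np.asarray(lattice.extent)
        cover = coverage_counts(arbors, lattice, pts)
        assert 100 <= cover.mean() <= 200
        assert cover.mean() == pytest.approx(135.0, rel=0.05)

    def test_single_arbor_volume_fraction(self, lattice):
        arbors, _ = ss.build_mesoscale(lattice, 1, 0.027, 0.0, seed=8)
        sphere = 4.0 / 3.0 * np.pi * arbors.radius ** 3
        assert sphere / lattice.volume == pytest.approx(0.027, rel=1e-6)

    def test_zero_arbors_empty_map(self, lattice):
        arbors, tmap = ss.build_mesoscale(lattice, 0, 0.027, 0.1, seed=9)
        assert arbors.n_arbors == 0 and tmap.n_terminals == 0

    def test_composite_density_matches_microscale(self, lattice):
        _, tmap = ss.build_mesoscale(lattice, 500, 0.027, 0.1, seed=10)
        expected = 0.1 * lattice.volume
        assert abs(tmap.n_terminals - expected) < 4 * np.sqrt(expected)

    def test_oversized_arbor_rejected(self):
        small = ss.Lattice(extent=(20.0, 20.0, 20.0))
        with pytest.raises(ConfigError, match="diameter"):
            ss.build_mesoscale(small, 10, 0.6, 0.1, seed=0)


@pytest.fixture(scope="module")
def meso(lattice):
    return ss.build_mesoscale(lattice, 200, 0.027, 0.1, seed=11)


class TestArborDenervation:

    def test_fraction_zero_identity(self, meso):
        arbors, tmap = meso
        out = ss.denervate_arbors(arbors, tmap, 0.0, seed=12)
        assert out.n_terminals == tmap.n_terminals

    def test_zero_coverage_fraction_approximation(self, meso, lattice):
        # after removal, P(voxel uncovered) ~ (1 - c)^N_remaining
        arbors, tmap = meso
        out = ss.denervate_arbors(arbors, tmap, 0.9, seed=12)
        remaining = 200 - round(0.9 * 200)
        frac_empty = float((out.counts() == 0).mean())
        # compare with the independent-coverage prediction for *terminal-free*
        # voxels: uncovered + covered-but-empty (Poisson holes)
        uncovered = (1 - 0.027) ** remaining
        assert frac_empty >= uncovered - 0.05

    def test_void_fraction_monotone_in_loss(self, meso):
        arbors, tmap = meso
        fr = [
            float((ss.denervate_arbors(arbors, tmap, f, seed=13).counts() == 0).mean())
            for f in (0.0, 0.5, 0.9, 1.0)
        ]
        assert fr == sorted(fr)

    def test_missing_ancestry_rejected(self, lattice):
        tmap = ss.build_microscale(lattice, 0.05, seed=1)
        arbors, _ = ss.build_mesoscale(lattice, 10, 0.027, 0.0, seed=2)
        with pytest.raises(ConfigError, match="ancestry"):
            ss.denervate_arbors(arbors, tmap, 0.5, seed=3)


class TestVoids:
    def test_intact_map_has_no_large_voids(self, lattice):
        tmap = ss.build_microscale(lattice, 0.1, seed=14)
        assert ss.find_voids(tmap, min_equiv_diameter=10.0) == []

    def test_carved_sphere_recovered(self, lattice):
        tmap = ss.build_microscale(lattice, 0.3, seed=15)
        center = np.asarray(lattice.extent) / 2
        r = np.linalg.norm(tmap.positions - center, axis=1)
        carved = ss.TerminalMap(
            lattice=lattice, positions=tmap.positions[r > 15.0], intact_density=0.3
        )
        voids = ss.find_voids(carved, min_equiv_diameter=20.0)
        assert len(voids) == 1
        assert voids[0].equivalent_diameter == pytest.approx(30.0, rel=0.15)

    def test_fully_denervated_is_one_big_void(self, lattice):
        tmap = ss.build_microscale(lattice, 0.0, seed=16)
        voids = ss.find_voids(tmap)
        assert len(voids) == 1
        assert voids[0].n_voxels == lattice.n_voxels


def test_builders_are_seed_deterministic(lattice):
    a = ss.build_microscale(lattice, 0.05, seed=21)
    b = ss.build_microscale(lattice, 0.05, seed=21)
    np.testing.assert_array_equal(a.positions, b.positions)
    c1, m1 = ss.build_mesoscale(lattice, 50, 0.027, 0.05, seed=22)
    c2, m2 = ss.build_mesoscale(lattice, 50, 0.027, 0.05, seed=22)
    np.testing.assert_array_equal(c1.centers, c2.centers)
    np.testing.assert_array_equal(m1.positions, m2.positions)
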