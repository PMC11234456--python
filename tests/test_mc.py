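"""White Monte Carlo engine and reflectance LUT.

The heavier physics checks compare against a small, independent
pure-Python photon-transport oracle written directly in this file.
"""

import numpy as np
import pytest

from msiox import mc
from msiox.mc import (LutAxisSpec, PhotonRecords, apply_absorption,
                      absorption_grid, build_lut, interpolate_T, run_white_mc,
                      sample_hg_cosines)


def reference_mc_single_layer(mu_s, g, mu_a, n_photons, seed, max_path=100.0):
    """Independent single-layer absorbing MC oracle (matched boundary).

    Photons propagate in a semi-infinite homogeneous medium; absorption is
    applied *during* propagation via continuous weight attenuation, unlike
    the package's post-hoc Beer-Lambert route.
    """
    rng = np.random.default_rng(seed)
    total_weight = 0.0
    for _ in range(n_photons):
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        w = 1.0
        path = 0.0
        while True:
            step = -np.log(rng.random()) / mu_s
            if uz < 0 and z + uz * step < 0:
                d = -z / uz
                w *= np.exp(-mu_a * d)
                total_weight += w  # exits the top surface
                break
            z += uz * step
            w *= np.exp(-mu_a * step)
            path += step
            if path > max_path:
                break
            if abs(g) < 1e-12:
                cost = 2 * rng.random() - 1
            else:
                tmp = (1 - g * g) / (1 - g + 2 * g * rng.random())
                cost = (1 + g * g - tmp * tmp) / (2 * g)
            sint = np.sqrt(max(0.0, 1 - cost * cost))
            phi = 2 * np.pi * rng.random()
            if abs(uz) > 0.99999:
                ux, uy = sint * np.cos(phi), sint * np.sin(phi)
                uz = cost * np.sign(uz)
            else:
                den = np.sqrt(1 - uz * uz)
                ux, uy, uz = (
                    sint * (ux * uz * np.cos(phi) - uy * np.sin(phi)) / den + ux * cost,
                    sint * (uy * uz * np.cos(phi) + ux * np.sin(phi)) / den + uy * cost,
                    -sint * np.cos(phi) * den + uz * cost,
                )
    return total_weight / n_photons


class TestHenyeyGreenstein:
    def test_isotropic_limit(self):
        c = sample_hg_cosines(0.0, 10**6, seed=3)
        assert abs(c.mean()) < 0.004
        assert np.all((c >= -1) & (c <= 1))

    def test_mean_cosine_equals_g(self):
        c = sample_hg_cosines(0.8, 10**6, seed=3)
        assert c.mean() == pytest.approx(0.8, abs=0.003)


class TestWhiteMC:
    def test_validation(self):
        with pytest.raises(ValueError):
            run_white_mc(0.1, -1.0)
        with pytest.raises(ValueError):
            run_white_mc(0.1, 10.0, n_photons=0)

    def test_determinism(self):
        a = run_white_mc(0.1, 10.0, n_photons=500, seed=7)
        b = run_white_mc(0.1, 10.0, n_photons=500, seed=7)
        np.testing.assert_array_equal(a.path_epi, b.path_epi)
        np.testing.assert_array_equal(a.path_derm, b.path_derm)

    def test_energy_conservation_matched_boundary(self):
        # semi-infinite scattering-only medium with a matched boundary
        # returns every photon; the only loss channel is the pathlength cap
        rec = run_white_mc(0.1, 100.0, g=0.8, n_photons=100_000, seed=5,
                           n_tissue=1.0, max_path=4000.0)
        assert rec.n_detected + rec.n_capped == rec.n_launched
        p = rec.detected_fraction
        sigma = np.sqrt(p * (1 - p) / rec.n_launched)
        assert p >= 1.0 - rec.capped_fraction - 3 * sigma
        assert rec.capped_fraction < 0.02

    def test_mismatched_boundary_reflects_some_light_back(self):
        rec = run_white_mc(0.1, 25.0, n_photons=5000, seed=2)
        # specular loss at launch plus internal reflections: below unity
        assert 0.5 < rec.detected_fraction < 1.0
        assert np.all(rec.weight > 0) and np.all(rec.weight <= 1)


class TestApplyAbsorption:
    def test_zero_absorption_returns_white_fraction(self):
        rec = run_white_mc(0.1, 25.0, n_photons=2000, seed=4)
        assert apply_absorption(rec, 0.0, 0.0) == \
            pytest.approx(rec.detected_fraction)

    def test_single_record_closed_form(self):
        rec = PhotonRecords(path_epi=np.array([1.0]), path_derm=np.array([2.0]),
                            weight=np.array([1.0]), n_launched=1, n_capped=0)
        assert apply_absorption(rec, 0.1, 0.05) == pytest.approx(np.exp(-0.2))

    def test_any_absorption_strictly_attenuates(self):
        rec = run_white_mc(0.1, 25.0, n_photons=2000, seed=4)
        assert apply_absorption(rec, 0.05, 0.02) < rec.detected_fraction

    def test_grid_matches_scalar_route(self):
        rec = run_white_mc(0.1, 25.0, n_photons=1000, seed=4)
        ae = np.array([0.0, 0.1, 1.0])
        ad = np.array([0.0, 0.5])
        grid = absorption_grid(rec, ae, ad)
        for i, a in enumerate(ae):
            for j, d in enumerate(ad):
                assert grid[i, j] == pytest.approx(apply_absorption(rec, a, d))

    def test_posthoc_beer_lambert_equals_absorbing_mc_oracle(self):
        # matched boundary, single layer (epidermis collapsed to ~0)
        mu_s, g, mu_a = 10.0, 0.8, 0.2
        rec = run_white_mc(1e-9, mu_s, g=g, n_photons=6000, seed=9,
                           n_tissue=1.0, max_path=100.0)
        t_pkg = apply_absorption(rec, 0.0, mu_a)
        t_ref = reference_mc_single_layer(mu_s, g, mu_a, 6000, seed=10)
        assert t_pkg == pytest.approx(t_ref, rel=0.05)


class TestLut:
    def test_axis_validation(self):
        bad = LutAxisSpec(t_epi=np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            bad.validate()

    def test_monotone_along_absorption_axes(self, lut_small):
        v = lut_small.values
        assert np.all(np.diff(v, axis=2) <= 1e-12)
        assert np.all(np.diff(v, axis=3) <= 1e-12)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_build_determinism(self):
        spec = LutAxisSpec(t_epi=np.array([0.05, 0.2]),
                           mu_s_prime=np.array([2.0, 6.0]),
                           mu_a=np.array([0.0, 0.1, 1.0]))
        a = build_lut(spec, n_photons_per_node=400, seed=3)
        b = build_lut(spec, n_photons_per_node=400, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_node_query_returns_stored_value(self, lut_small):
        i, j, k, m = 1, 2, 3, 4
        val = interpolate_T(
            lut_small,
            float(lut_small.t_epi_axis[i]),
            np.array([lut_small.mu_s_prime_axis[j]]),
            np.array([lut_small.mu_a_epi_axis[k]]),
            np.array([lut_small.mu_a_derm_axis[m]]))
        assert val[0] == pytest.approx(lut_small.values[i, j, k, m], rel=1e-10)

    def test_out_of_hull_names_axis(self, lut_small):
        with pytest.raises(ValueError, match="mu_s_prime"):
            interpolate_T(lut_small, 0.1, np.array([500.0]),
                          np.array([0.1]), np.array([0.1]))
        with pytest.raises(ValueError, match="t_epi"):
            interpolate_T(lut_small, 5.0, np.array([2.0]),
                          np.array([0.1]), np.array([0.1]))

    def test_clip_mode_clamps_instead_of_raising(self, lut_small):
        v = interpolate_T(lut_small, 5.0, np.array([2.0]),
                          np.array([0.1]), np.array([0.1]), clip=True)
        w = interpolate_T(lut_small, float(lut_small.t_epi_axis[-1]),
                          np.array([2.0]), np.array([0.1]), np.array([0.1]))
        assert v[0] == pytest.approx(w[0], rel=1e-10)

    def test_values_bounded_for_random_in_hull_queries(self, lut_small):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.uniform(0.03, 0.3)
            musp = rng.uniform(1.0, 15.0, 5)
            ae = rng.uniform(0.0, 10.0, 5)
            ad = rng.uniform(0.0, 10.0, 5)
            v = interpolate_T(lut_small, t, musp, ae, ad)
            assert np.all((v >= 0.0) & (v <= 1.0))

    def test_hdf5_round_trip(self, lut_small, tmp_path):
        path = tmp_path / "lut.h5"
        lut_small.save(path)
        back = mc.ReflectanceLUT.load(path)
        np.testing.assert_array_equal(back.values, lut_small.values)
        assert back.meta["n_photons_per_node"] == \
            lut_small.meta["n_photons_per_node"]

    def test_midpoint_interpolation_matches_direct_simulation(self):
        # node spacing matching the compact LUT (ratio ~1.6-2 per interval)
        spec = LutAxisSpec(t_epi=np.array([0.07, 0.14]),
                           mu_s_prime=np.array([3.0, 5.2]),
                           mu_a=np.array([0.0, 0.05, 0.2, 0.8]))
        lut = build_lut(spec, n_photons_per_node=25_000, seed=21)
        t_mid = float(np.sqrt(0.07 * 0.14))
        musp_mid = float(np.sqrt(3.0 * 5.2))
        interp = interpolate_T(lut, t_mid, np.array([musp_mid]),
                               np.array([0.2]), np.array([0.2]))[0]
        rec = run_white_mc(t_mid, musp_mid / 0.2, g=0.8,
                           n_photons=50_000, seed=77)
        direct = apply_absorption(rec, 0.2, 0.2)
        assert interp == pytest.approx(direct, rel=0.02)


def test_similarity_relation_musp_invariant():
    """Reflectance depends on scattering mainly through mu_s' = mu_s(1-g):
    (mu_s=5, g=0.8) and (mu_s=1, g=0) agree to within the (loose) accuracy
    of the similarity relation."""
    rec_hg = run_white_mc(0.1, 5.0, g=0.8, n_photons=30_000, seed=11,
                          n_tissue=1.0, max_path=2000.0)
    rec_iso = run_white_mc(0.1, 1.0, g=0.0, n_photons=30_000, seed=12,
                           n_tissue=1.0, max_path=2000.0)
    t_hg = apply_absorption(rec_hg, 0.05, 0.05)
    t_iso = apply_absorption(rec_iso, 0.05, 0.05)
    assert t_hg == pytest.approx(t_iso, rel=0.05)
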