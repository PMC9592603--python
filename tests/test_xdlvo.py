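"""XDLVO energy profiles: distance laws, extraction rules, geometry limits."""

import numpy as np
import pytest

from nanoexo import (
    GENERIC_CELL,
    WATER,
    GeometryPair,
    InteractionProfile,
    MediumSpec,
    PairKind,
    SurfaceChemistry,
    VesicleRule,
    XdlvoParameters,
    barrier_height,
    energy_profile,
    interaction_summary,
    np_vesicle_energy,
)

NP_CHEM = SurfaceChemistry("coat", gamma_lw=30.0, gamma_plus=1.0, gamma_minus=40.0)
PAIR = GeometryPair(PairKind.SPHERE_SPHERE, 10.0, 10.0)


@pytest.fixture(scope="module")
def profile():
    return energy_profile(PAIR, NP_CHEM, GENERIC_CELL, MediumSpec())


class TestEnergyProfile:
    def test_additivity_exact(self, profile):
        np.testing.assert_array_equal(profile.total, profile.lw + profile.el + profile.ab)

    def test_identity_medium_uncharged_is_all_zero(self):
        p = energy_profile(PAIR, WATER, WATER, MediumSpec())
        assert np.all(p.total == 0)

    def test_ab_e_folding_over_decay_length(self):
        prm = XdlvoParameters(n_grid=4000)
        p = energy_profile(PAIR, NP_CHEM, GENERIC_CELL, MediumSpec(), prm)
        at = lambda d: np.interp(d, p.distances, p.ab)
        assert at(prm.d0 + prm.lambda_ab) == pytest.approx(
            np.exp(-1.0) * p.ab[0], rel=1e-3
        )

    def test_lw_inverse_distance_law(self, profile):
        # U_LW(2d) = U_LW(d)/2, checked against an independently coded closed form
        d = profile.distances
        u1 = np.interp(2.0, d, profile.lw)
        u2 = np.interp(4.0, d, profile.lw)
        assert u2 == pytest.approx(u1 / 2.0, rel=1e-4)
        from nanoexo.materials import contact_lw

        dg = contact_lw(NP_CHEM, GENERIC_CELL, WATER) * 1e-3
        closed = (
            2.0 * np.pi * (PAIR.r_eff * 1e-9) * (0.157e-9) ** 2 * dg / 2e-9
        ) * 6.02214076e23 / 1e3
        assert u1 == pytest.approx(closed, rel=1e-4)

    def test_el_zero_for_uncharged_pair(self):
        p = energy_profile(PAIR, NP_CHEM, GENERIC_CELL.with_psi0(0.0), MediumSpec())
        assert np.all(p.el == 0)

    def test_el_nonzero_and_decaying_for_charged_pair(self):
        charged = NP_CHEM.with_psi0(-30.0)
        p = energy_profile(PAIR, charged, GENERIC_CELL, MediumSpec())
        assert p.el[0] != 0
        assert abs(p.el[-1]) < 1e-8  # screened beyond ~25 Debye lengths

    def test_linear_scaling_in_effective_radius(self):
        small = energy_profile(
            GeometryPair(PairKind.SPHERE_SPHERE, 7.0, 7.0), NP_CHEM, GENERIC_CELL, MediumSpec()
        )
        large = energy_profile(
            GeometryPair(PairKind.SPHERE_SPHERE, 50.0, 50.0), NP_CHEM, GENERIC_CELL, MediumSpec()
        )
        np.testing.assert_allclose(large.total, small.total * (50.0 / 7.0), rtol=1e-12)

    def test_derjaguin_sphere_plate_limit(self):
        plate = energy_profile(
            GeometryPair(PairKind.SPHERE_PLATE, 10.0), NP_CHEM, GENERIC_CELL, MediumSpec()
        )
        huge = energy_profile(
            GeometryPair(PairKind.SPHERE_SPHERE, 10.0, 1e5), NP_CHEM, GENERIC_CELL, MediumSpec()
        )
        np.testing.assert_allclose(huge.total, plate.total, rtol=1e-2)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            XdlvoParameters(d0=25.0, d_max=20.0)
        with pytest.raises(ValueError):
            XdlvoParameters(n_grid=10)


def _profile_from_arrays(d, total):
    z = np.zeros_like(d)
    return InteractionProfile(distances=d, lw=total, el=z, ab=z, total=total)


class TestExtraction:
    def test_np_vesicle_energy_is_grid_maximum(self, rng):
        d = np.linspace(0.157, 20, 500)
        total = -((d - 5.0) ** 2) + 10.0  # interior maximum at d=5
        p = _profile_from_arrays(d, total)
        assert np_vesicle_energy(p) == pytest.approx(max(total[i] for i in range(len(d))))

    def test_monotone_decreasing_profile_takes_contact_value(self):
        d = np.linspace(0.157, 20, 500)
        p = _profile_from_arrays(d, 100.0 / d)
        assert np_vesicle_energy(p) == pytest.approx(100.0 / 0.157)

    def test_all_zero_profile(self):
        d = np.linspace(0.157, 20, 100)
        assert np_vesicle_energy(_profile_from_arrays(d, np.zeros_like(d))) == 0.0

    def test_barrier_matches_analytic_stationary_point(self):
        # U(d) = -A/d + B exp(-d/lam): max where A/d^2 = (B/lam) exp(-d/lam)
        A, B, lam = 50.0, 400.0, 0.6
        d = np.linspace(0.157, 20, 200000)
        total = -A / d + B * np.exp(-d / lam)
        from scipy.optimize import brentq

        # bracket the first stationary point only (U' changes sign again far out)
        d_star = brentq(
            lambda x: A / x**2 - (B / lam) * np.exp(-x / lam), 0.2, 2.0
        )
        u_star = -A / d_star + B * np.exp(-d_star / lam)
        b = barrier_height(_profile_from_arrays(d, total))
        assert b.exists
        assert b.height == pytest.approx(u_star, rel=1e-6)
        assert b.distance == pytest.approx(d_star, abs=1e-3)

    def test_barrier_bounds_every_grid_value(self, rng):
        d = np.linspace(0.157, 20, 300)
        total = rng.normal(size=d.size).cumsum()
        b = barrier_height(_profile_from_arrays(d, total))
        idx = rng.integers(0, d.size, size=20)
        assert all(b.height >= total[i] or not b.exists for i in idx)
        assert b.height >= 0.0

    def test_purely_attractive_profile_has_no_barrier(self):
        d = np.linspace(0.157, 20, 300)
        b = barrier_height(_profile_from_arrays(d, -100.0 / d))
        assert not b.exists
        assert b.height == 0.0

    def test_empty_profile_rejected(self):
        e = np.array([])
        with pytest.raises(ValueError, match="empty"):
            np_vesicle_energy(_profile_from_arrays(e, e))


class TestInteractionSummary:
    def test_energy_change_identity(self):
        s = interaction_summary(NP_CHEM, 10.0, GENERIC_CELL, MediumSpec())
        assert s.dg_change == s.dg_barrier_v_m - s.dg_np_v

    def test_all_water_phases_give_zero_summary(self):
        s = interaction_summary(WATER, 10.0, WATER, MediumSpec())
        assert s.dg_np_v == 0.0
        assert s.dg_barrier_v_m == 0.0
        assert s.dg_change == 0.0

    def test_repulsive_energies_grow_with_size(self):
        sizes = [7.0, 25.0, 50.0]
        sums = [
            interaction_summary(NP_CHEM, r, GENERIC_CELL, MediumSpec()) for r in sizes
        ]
        npv = [s.dg_np_v for s in sums]
        barriers = [s.dg_barrier_v_m for s in sums]
        assert npv == sorted(npv)
        assert barriers == sorted(barriers)
        # linear in R_eff: 50/7 ratio between extremes, as in the published
        # transferrin series (477 -> 3406 kJ/mol over 14 -> 100 nm)
        assert npv[2] / npv[0] == pytest.approx(50.0 / 7.0, rel=1e-9)

    def test_vesicle_offset_increases_barrier(self):
        base = interaction_summary(NP_CHEM, 10.0, GENERIC_CELL, MediumSpec())
        offset = interaction_summary(
            NP_CHEM, 10.0, GENERIC_CELL, MediumSpec(), vesicle_rule=VesicleRule(4.0)
        )
        assert offset.dg_barrier_v_m > base.dg_barrier_v_m

    def test_grid_refinement_stability(self):
        coarse = interaction_summary(
            NP_CHEM, 10.0, GENERIC_CELL, MediumSpec(), XdlvoParameters(n_grid=2000)
        )
        fine = interaction_summary(
            NP_CHEM, 10.0, GENERIC_CELL, MediumSpec(), XdlvoParameters(n_grid=4000)
        )
        assert fine.dg_barrier_v_m == pytest.approx(coarse.dg_barrier_v_m, rel=1e-3)
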