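"""Two-step doped release: burst, radial diffusion scheme vs analytic
series, superposition, and the mass-balance audit."""

import numpy as np
import pytest

from cuokinetics import (
    DopedKineticParams,
    MediumSpec,
    ParticleSystem,
    burst_inventory,
    check_mass_balance,
    copper_inventories,
    count_release_processes,
    paper_like_params,
    released_fraction_series,
    simulate_burst,
    simulate_doped_release,
    simulate_pure_release,
    solve_radial_diffusion,
)
from cuokinetics.doped import StabilityError
from cuokinetics.pure import WrongModelError

HOUR = 3600.0
K_SITE = 1.66e-5


class TestBurstInventory:
    def test_definition(self, doped_particle):
        inv = copper_inventories(doped_particle, K_SITE)
        assert burst_inventory(doped_particle, K_SITE) == pytest.approx(
            0.9 * inv.surface_site_molarity
        )

    def test_hand_value_and_share_of_total(self, doped_particle):
        b = burst_inventory(doped_particle, K_SITE)
        assert b / 1e3 == pytest.approx(1.8e-5, rel=0.02)  # mol/L
        assert b / doped_particle.total_cu_molarity == pytest.approx(0.13, abs=0.02)

    def test_halving_d0_doubles_inventory(self):
        big = ParticleSystem(d0=10e-9, f_fe0=0.10)
        small = ParticleSystem(d0=5e-9, f_fe0=0.10)
        assert burst_inventory(small, K_SITE) == pytest.approx(
            2 * burst_inventory(big, K_SITE), rel=1e-12
        )

    def test_decreasing_in_doping(self):
        bs = [
            burst_inventory(ParticleSystem(d0=10e-9, f_fe0=f), K_SITE)
            for f in (0.01, 0.06, 0.10)
        ]
        assert bs[0] > bs[1] > bs[2]

    def test_pure_phase_rejected(self, pure_particle):
        with pytest.raises(WrongModelError):
            burst_inventory(pure_particle, K_SITE)


class TestBurst:
    def test_surface_iron_enrichment(self, doped_particle, times):
        medium = MediumSpec(c_aa0=50.0)  # excess ligand
        t = np.concatenate(([0.0], np.geomspace(HOUR, 5000 * HOUR, 30)))
        curve, f_fe_s = simulate_burst(
            doped_particle, medium, paper_like_params(0.10), t
        )
        assert f_fe_s[0] == pytest.approx(doped_particle.f_fe0)
        assert np.all(np.diff(f_fe_s) >= -1e-12)
        assert f_fe_s[-1] == pytest.approx(1.0, abs=1e-3)
        assert curve.c_cu[-1] == pytest.approx(
            burst_inventory(doped_particle, K_SITE), rel=1e-3
        )

    def test_initial_rates_doped_vs_pure_comparable(self, medium):
        """At equal k_Cu the t=0 release rates differ only through the
        (1-f)^m factor on the surface copper."""
        k = 5e-5
        t = np.array([0.0, 1.0])
        pure = simulate_pure_release(
            ParticleSystem(d0=10e-9), medium, DopedKineticParams(k_cu=k), t
        )
        burst, _ = simulate_burst(
            ParticleSystem(d0=10e-9, f_fe0=0.10), medium, DopedKineticParams(k_cu=k), t
        )
        ratio = burst.c_cu[1] / pure.c_cu[1]
        assert ratio == pytest.approx(0.9**1.75, rel=1e-3)


class TestReleasedFractionSeries:
    def test_endpoints(self):
        assert released_fraction_series(0.0) == 0.0
        assert released_fraction_series(10.0) == pytest.approx(1.0, abs=1e-10)

    def test_value_at_tau_005(self):
        """Direct summation gives ~0.607; the short-time expansion
        6 sqrt(tau/pi) - 3 tau agrees to ~4e-11 there."""
        m = released_fraction_series(0.05)
        assert m == pytest.approx(0.607, abs=1e-3)
        short = 6 * np.sqrt(0.05 / np.pi) - 3 * 0.05
        assert m == pytest.approx(short, abs=1e-9)

    def test_representations_join_smoothly(self):
        """Series and theta-transformed branches agree across the
        internal switch at tau = 0.01."""
        taus = np.array([0.0099, 0.00999, 0.01, 0.01001, 0.02])
        m = released_fraction_series(taus)
        assert np.all(np.diff(m) > 0)
        k = np.arange(1, 4000)
        for t, got in zip(taus, m):
            direct = 1 - (6 / np.pi**2) * np.sum(np.exp(-k**2 * np.pi**2 * t) / k**2)
            assert got == pytest.approx(direct, abs=1e-9)

    def test_monotone_until_saturation(self):
        taus = np.geomspace(1e-8, 1.0, 150)
        m = released_fraction_series(taus)
        assert np.all(np.diff(m) > 0)
        assert np.all((m >= 0) & (m <= 1))


class TestRadialScheme:
    def test_oracle_equivalence(self):
        tau = np.linspace(0.0, 1.0, 101)
        _, scheme = solve_radial_diffusion(200, tau)
        series = released_fraction_series(tau)
        assert np.max(np.abs(scheme - series)) < 1e-3

    def test_second_order_grid_convergence(self):
        tau = np.linspace(0.01, 1.0, 34)
        series = released_fraction_series(tau)
        _, coarse = solve_radial_diffusion(100, tau)
        _, fine = solve_radial_diffusion(200, tau)
        e_coarse = np.max(np.abs(coarse - series))
        e_fine = np.max(np.abs(fine - series))
        assert 3.0 < e_coarse / e_fine < 5.0

    def test_stability_bound_enforced(self):
        dx2 = (1.0 / 32) ** 2
        with pytest.raises(StabilityError, match="dx\\^2/6"):
            solve_radial_diffusion(32, [0.1], dtau=dx2 / 5.9)

    def test_profile_invariants(self):
        profiles, released = solve_radial_diffusion(64, [0.0, 0.02, 0.1, 0.3])
        assert released[0] == 0.0
        for prof in profiles:
            assert prof.c[-1] == 0.0
            assert np.all((prof.c >= 0) & (prof.c <= 1))
        for early, late in zip(profiles, profiles[1:]):
            assert np.all(late.c <= early.c + 1e-12)
        assert np.all(np.diff(released) > 0)


class TestTwoStepSuperposition:
    def test_no_diffusion_stops_at_surface_inventory(self, doped_particle):
        medium = MediumSpec(c_aa0=50.0)
        p = DopedKineticParams(k_cu=5e-5, d=0.0)
        t = np.concatenate(([0.0], np.geomspace(HOUR, 5000 * HOUR, 30)))
        curve = simulate_doped_release(doped_particle, medium, p, t)
        assert np.all(curve.diffusion == 0.0)
        assert curve.total[-1] == pytest.approx(
            burst_inventory(doped_particle, K_SITE), rel=1e-3
        )

    def test_complete_release_feasible_with_diffusion(self, doped_particle):
        """With D > 0 and excess ligand, release tends to the full
        copper inventory at long times."""
        medium = MediumSpec(c_aa0=50.0)
        p = DopedKineticParams(k_cu=5e-5, d=1e-22)
        t = np.concatenate(([0.0], np.geomspace(HOUR, 50000 * HOUR, 40)))
        curve = simulate_doped_release(doped_particle, medium, p, t)
        assert curve.total[-1] == pytest.approx(
            doped_particle.total_cu_molarity, rel=1e-3
        )

    def test_diffusion_share_at_250h(self, doped_curve):
        """D = 1e-27 m^2/s, d0 = 10 nm: tau(250 h) = 3.6e-5, so the
        tail has released ~2.0 % of the bulk inventory (short-time
        expansion 6 sqrt(tau/pi) - 3 tau)."""
        tau = 1e-27 * 250 * HOUR / (5e-9) ** 2
        expected = 6 * np.sqrt(tau / np.pi) - 3 * tau
        frac = doped_curve.diffusion[-1] / doped_curve.meta["bulk_inventory"]
        assert frac == pytest.approx(expected, rel=1e-6)
        assert frac == pytest.approx(0.020, abs=0.001)

    def test_components_nonneg_monotone_bounded(self, doped_curve, doped_particle):
        for comp in (doped_curve.burst, doped_curve.diffusion, doped_curve.total):
            assert np.all(comp >= 0)
            assert np.all(np.diff(comp) >= -1e-12)
        np.testing.assert_array_equal(
            doped_curve.total, doped_curve.burst + doped_curve.diffusion
        )
        assert np.all(doped_curve.total <= doped_particle.total_cu_molarity)

    def test_burst_saturated_surface_degenerates_to_single_process(self, times):
        """If one monolayer holds the whole copper inventory the bulk
        is empty and only the fast process remains."""
        particle = ParticleSystem(d0=10e-9, f_fe0=0.10)
        k_site = particle.total_metal_molarity / particle.area_per_volume
        p = DopedKineticParams(k_cu=5e-5, k_site=k_site, d=1e-27)
        curve = simulate_doped_release(particle, MediumSpec(c_aa0=50.0), p, times)
        assert curve.meta["bulk_inventory"] == 0.0
        assert count_release_processes(curve.times, curve.total) == 1


class TestMassBalance:
    def test_simulated_conditions_pass(self, medium, times):
        for f in (0.0, 0.01, 0.06, 0.10):
            particle = ParticleSystem(d0=10e-9, f_fe0=f)
            params = paper_like_params(f)
            if f == 0:
                curve = simulate_pure_release(particle, medium, params, times)
            else:
                curve = simulate_doped_release(particle, medium, params, times)
            report = check_mass_balance(curve, particle)
            assert report.passed, str(report)
            assert report.rel_error < 1e-6

    def test_inflated_curve_fails(self, doped_curve, doped_particle):
        import copy

        tampered = copy.deepcopy(doped_curve)
        tampered.burst = tampered.burst * 1.01
        tampered.diffusion = tampered.diffusion * 1.01
        report = check_mass_balance(tampered, doped_particle)
        assert not report.passed
        released_share = doped_curve.total[-1] / doped_particle.total_cu_molarity
        assert report.rel_error == pytest.approx(0.01 * released_share, rel=1e-6)

    def test_d_zero_leaves_exactly_bulk_inventory(self, doped_particle):
        medium = MediumSpec(c_aa0=50.0)
        p = DopedKineticParams(k_cu=5e-5, d=0.0)
        t = np.concatenate(([0.0], np.geomspace(HOUR, 5000 * HOUR, 30)))
        curve = simulate_doped_release(doped_particle, medium, p, t)
        report = check_mass_balance(curve, doped_particle)
        bulk = curve.meta["bulk_inventory"]
        assert report.remaining == pytest.approx(bulk, rel=1e-3)


class TestTwoProcessSignature:
    def test_doped_show_two_processes_pure_one(self, medium, times):
        """On log time the 6 % and 10 % curves have a burst peak plus a
        rising diffusion tail; pure CuO has a single process."""
        for f, expected in ((0.0, 1), (0.06, 2), (0.10, 2)):
            particle = ParticleSystem(d0=10e-9, f_fe0=f)
            params = paper_like_params(f)
            if f == 0:
                total = simulate_pure_release(particle, medium, params, times).c_cu
            else:
                total = simulate_doped_release(particle, medium, params, times).total
            assert count_release_processes(times, total) == expected
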