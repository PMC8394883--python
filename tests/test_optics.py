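"""Forward-optics unit and property tests.

The closed-form transmittances, the effective-index formula and the
Jones-stack oracle are checked against independently written expressions
and against each other.
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lclcsense.exceptions import DomainError, UnidentifiableError
from lclcsense.optics import (
    CellOptics,
    PhiEstimator,
    effective_index,
    estimate_phi,
    jones_stack_transmittance,
    phase_retardation,
    simulate_spectrum,
    transmittance_crossed,
    transmittance_parallel,
)

from conftest import constant_dispersion


class TestEffectiveIndex:
    def test_vertical_alignment_kills_birefringence(self, dispersion):
        """At pretilt 90 deg the effective index is the ordinary one."""
        for lam in (450.0, 550.0, 800.0):
            dn = effective_index(dispersion, math.pi / 2, lam) - dispersion.n_perp(lam)
            assert abs(dn) <= 1e-15

    def test_planar_gives_parallel_index(self, dispersion):
        for lam in (450.0, 800.0):
            assert effective_index(dispersion, 0.0, lam) == pytest.approx(
                dispersion.n_parallel(lam), abs=1e-15)

    def test_midtilt_matches_independent_closed_form(self):
        # independent oracle: 1/n_eff^2 = sin^2/n_perp^2 + cos^2/n_par^2
        disp = constant_dispersion(1.50, 1.60)
        theta = math.pi / 4
        got = effective_index(disp, theta, 550.0)
        oracle = 1.0 / math.sqrt(
            math.sin(theta) ** 2 / 1.60**2 + math.cos(theta) ** 2 / 1.50**2
        )
        assert got == pytest.approx(oracle, rel=1e-14)

    def test_wavelength_outside_range_names_the_range(self, dispersion):
        with pytest.raises(DomainError, match=r"380.*820"):
            effective_index(dispersion, 0.0, 900.0)


class TestPhaseRetardation:
    def test_half_wave_condition_gives_pi(self):
        # d * dn / lambda = 0.5  =>  delta = pi
        disp = constant_dispersion(1.515, 1.500)   # dn = +0.015
        cell = CellOptics(gap_d=0.5 * 600.0 / 0.015, azimuth_phi=0.0,
                          dispersion=disp)
        assert phase_retardation(cell, 600.0) == pytest.approx(math.pi, rel=1e-12)

    def test_vertical_cell_has_zero_retardation(self, dispersion):
        cell = CellOptics(pretilt_theta=math.pi / 2, dispersion=dispersion)
        assert abs(phase_retardation(cell, 550.0)) < 1e-10

    def test_arithmetic_oracle(self):
        disp = constant_dispersion(1.518, 1.500)   # dn = +0.018
        cell = CellOptics(gap_d=15000.0, dispersion=disp)
        expected = 2.0 * math.pi * 15000.0 * 0.018 / 450.0
        assert phase_retardation(cell, 450.0) == pytest.approx(expected, rel=1e-12)

    def test_sign_of_birefringence_preserved(self, dispersion):
        # default dispersion is optically negative: delta < 0
        cell = CellOptics(dispersion=dispersion)
        assert phase_retardation(cell, 550.0) < 0


@pytest.mark.parametrize("phi, delta, i_par", [
    (0.0, 0.7, 1.0),                      # blank: maximum parallel signal
    (math.pi / 4, math.pi, 0.0),          # half-wave null at 45 deg
    (math.pi / 8, math.pi / 2, 0.75),     # hand arithmetic on the closed form
])
def test_transmittance_scalar_examples(phi, delta, i_par):
    assert transmittance_parallel(phi, delta) == pytest.approx(i_par, abs=1e-12)
    assert transmittance_crossed(phi, delta) == pytest.approx(1 - i_par, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(phi=st.floats(-10.0, 10.0), delta=st.floats(-50.0, 50.0))
def test_transmittance_properties(phi, delta):
    """Conservation, bounds, pi/2 periodicity in phi, evenness in delta."""
    ip = transmittance_parallel(phi, delta)
    ic = transmittance_crossed(phi, delta)
    assert abs(ip + ic - 1.0) < 1e-12
    assert -1e-12 <= ip <= 1 + 1e-12 and -1e-12 <= ic <= 1 + 1e-12
    assert transmittance_crossed(phi + math.pi / 2, delta) == pytest.approx(
        ic, abs=1e-9)
    assert transmittance_crossed(phi, -delta) == pytest.approx(ic, abs=1e-12)


def test_crossed_strictly_increasing_in_phi_on_first_octant():
    delta = 2.0   # sin^2(delta/2) > 0
    phis = np.linspace(0.0, math.pi / 4, 100)
    vals = transmittance_crossed(phis, delta)
    assert np.all(np.diff(vals) > 0)


class TestSimulateSpectrum:
    def test_blank_parallel_is_unity(self, planar_cell, grid400):
        spec = simulate_spectrum(planar_cell, grid400, "parallel")
        np.testing.assert_allclose(spec.values, 1.0, atol=1e-15)

    def test_schemes_sum_to_one(self, tilted_cell_factory, grid400):
        cell = tilted_cell_factory(27.0)
        sp = simulate_spectrum(cell, grid400, "parallel")
        sc = simulate_spectrum(cell, grid400, "crossed")
        np.testing.assert_allclose(sp.values + sc.values, 1.0, atol=1e-12)

    def test_birefringence_sign_flip_is_invisible(self, grid400):
        pos = constant_dispersion(1.518, 1.500)    # dn = +0.018
        neg = constant_dispersion(1.482, 1.500)    # dn = -0.018
        for scheme in ("parallel", "crossed"):
            a = simulate_spectrum(
                CellOptics(azimuth_phi=0.4, dispersion=pos), grid400, scheme)
            b = simulate_spectrum(
                CellOptics(azimuth_phi=0.4, dispersion=neg), grid400, scheme)
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_empty_grid_rejected(self, planar_cell):
        with pytest.raises(ValueError, match="empty"):
            simulate_spectrum(planar_cell, np.array([]), "parallel")


class TestJonesStack:
    def test_uniform_stack_collapses_to_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            phi = rng.uniform(0, math.pi / 2)
            delta = rng.uniform(0, 4 * math.pi)
            n = rng.integers(1, 16)
            for scheme, closed in (
                ("parallel", transmittance_parallel(phi, delta)),
                ("crossed", transmittance_crossed(phi, delta)),
            ):
                stack = jones_stack_transmittance(
                    [phi] * n, [delta / n] * n, scheme)
                assert abs(stack - closed) < 1e-10

    def test_single_planar_slab_dark_between_crossed_polarizers(self):
        assert jones_stack_transmittance([0.0], [2.3], "crossed") == pytest.approx(
            0.0, abs=1e-15)

    def test_twisted_profile_grid_refinement_converges(self):
        total_delta = 5.0
        for scheme in ("parallel", "crossed"):
            vals = []
            for n in (64, 128):
                # midpoint discretization of the continuous twist profile
                phis = (np.arange(n) + 0.5) / n * math.radians(30.0)
                vals.append(jones_stack_transmittance(
                    phis, [total_delta / n] * n, scheme))
            assert abs(vals[0] - vals[1]) < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            jones_stack_transmittance([0.1, 0.2], [1.0], "parallel")


class TestPhiEstimator:
    @pytest.mark.parametrize("phi_deg", [0.0, 5.0, 20.0, 44.0])
    def test_noiseless_recovery_to_microradians(self, tilted_cell_factory,
                                                grid400, phi_deg):
        cell = tilted_cell_factory(phi_deg)
        pair = (simulate_spectrum(cell, grid400, "parallel"),
                simulate_spectrum(cell, grid400, "crossed"))
        phi_hat, resid = estimate_phi(pair, cell)
        assert abs(phi_hat - math.radians(phi_deg)) < 1e-6
        assert resid < 1e-10

    def test_noisy_recovery_within_one_degree(self, tilted_cell_factory,
                                              grid400):
        rng = np.random.default_rng(42)
        cell = tilted_cell_factory(20.0)
        pair = []
        for scheme in ("parallel", "crossed"):
            spec = simulate_spectrum(cell, grid400, scheme)
            noisy = spec.values * (1.0 + rng.normal(0, 0.01, grid400.size))
            pair.append(replace(spec, values=noisy))
        phi_hat, _ = estimate_phi(tuple(pair), cell)
        assert abs(math.degrees(phi_hat) - 20.0) < 1.0

    def test_angle_above_45_aliases_into_first_octant(self,
                                                      tilted_cell_factory,
                                                      grid400):
        cell = tilted_cell_factory(70.0)
        pair = (simulate_spectrum(cell, grid400, "parallel"),
                simulate_spectrum(cell, grid400, "crossed"))
        phi_hat, _ = estimate_phi(pair, cell)
        # sin^2(2 phi) is symmetric about 45 deg: 70 deg reads as 20 deg
        assert math.degrees(phi_hat) == pytest.approx(20.0, abs=1e-6)

    def test_unidentifiable_when_retardation_vanishes(self, dispersion,
                                                      grid400):
        cell = CellOptics(pretilt_theta=math.pi / 2, azimuth_phi=0.3,
                          dispersion=dispersion)
        pair = (simulate_spectrum(cell, grid400, "parallel"),
                simulate_spectrum(cell, grid400, "crossed"))
        with pytest.raises(UnidentifiableError):
            PhiEstimator(cell=cell).fit(pair)
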