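"""Lineshape, prefactor and convolution against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecdkit.constants import CODATA2018, HC_EV_NM, PhysicalConstants, prefactor
from ecdkit.spectra import (
    BroadeningConfig,
    ExcitedState,
    InvalidParameterError,
    InvalidStateError,
    Spectrum,
    StickSpectrum,
    convolve,
    lineshape,
    merge_sticks,
)


def brute_force_cd(states, grid_nm, sigma, constants=CODATA2018):
    """Independent per-point double loop over Eq.-style sum; the oracle."""
    out = []
    for lam in grid_nm:
        e = HC_EV_NM / lam
        total = 0.0
        for en, rn in states:
            g = math.exp(-((e - en) ** 2) / (2.0 * sigma**2)) / (
                math.sqrt(2.0 * math.pi) * sigma
            )
            total += rn * en * g
        out.append(4.0 * constants.prefactor_a * 1e-40 * total)
    return np.array(out)


class TestLineshape:
    def test_peak_value_is_gaussian_normalization(self):
        assert lineshape(5.0, 5.0, 0.3) == pytest.approx(
            1.0 / (math.sqrt(2 * math.pi) * 0.3), rel=1e-12
        )

    def test_one_sigma_identity_and_symmetry(self):
        peak = lineshape(5.0, 5.0, 0.3)
        assert lineshape(5.3, 5.0, 0.3) == pytest.approx(peak * math.exp(-0.5), rel=1e-12)
        assert lineshape(4.7, 5.0, 0.3) == pytest.approx(lineshape(5.3, 5.0, 0.3))

    @pytest.mark.parametrize("sigma", [0.05, 0.2, 0.3, 1.0])
    def test_unit_integral_by_trapezoid_quadrature(self, sigma):
        en = 5.0
        e = np.arange(en - 8 * sigma, en + 8 * sigma, 1e-3)
        integral = np.trapezoid(lineshape(e, en, sigma), e)
        assert integral == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("sigma", [0.0, -0.3])
    def test_nonpositive_sigma_rejected(self, sigma):
        with pytest.raises(InvalidParameterError):
            lineshape(5.0, 5.0, sigma)


class TestPrefactor:
    def test_positive(self):
        assert prefactor() > 0

    def test_matches_standard_cgs_conversion_constant(self):
        # Delta_eps = E * R * g(E) / 2.296e-39 for R in full cgs units
        assert 1.0 / (4.0 * prefactor()) == pytest.approx(2.296e-39, rel=0.02)

    def test_single_state_peak_magnitude_against_literature_relation(self):
        en, sigma = 5.0, 0.3
        stick = StickSpectrum([ExcitedState(1, en, 1.0)])
        cfg = BroadeningConfig(sigma=sigma, grid_min=HC_EV_NM / en - 0.2,
                               grid_max=HC_EV_NM / en + 0.2, grid_step=0.05)
        spec = convolve(stick, cfg)
        expected = en * 1e-40 * lineshape(en, en, sigma) / 2.296e-39
        assert np.max(np.abs(spec.values)) == pytest.approx(expected, rel=0.02)

    def test_functional_dependence_on_planck(self):
        doubled = PhysicalConstants(planck=2 * CODATA2018.planck)
        assert doubled.prefactor_a == pytest.approx(CODATA2018.prefactor_a / 2, rel=1e-14)

    def test_derivation_recorded(self):
        assert "8*pi^3" in CODATA2018.derivation
        assert repr(CODATA2018.prefactor_a) in CODATA2018.derivation


class TestConvolve:
    def test_empty_stick_gives_zero_spectrum(self):
        spec = convolve(StickSpectrum([]), BroadeningConfig(sigma=0.3))
        assert np.all(spec.values == 0.0)
        assert len(spec) > 0

    def test_linearity_in_rotatory_strength(self, three_state_stick):
        cfg = BroadeningConfig(sigma=0.3)
        base = convolve(three_state_stick, cfg)
        scaled = convolve(three_state_stick.scaled(3.5), cfg)
        np.testing.assert_allclose(scaled.values, 3.5 * base.values, rtol=1e-12)

    def test_three_state_curve_matches_brute_force(self, three_state_stick):
        cfg = BroadeningConfig(sigma=0.3)
        spec = convolve(three_state_stick, cfg)
        oracle = brute_force_cd([(4.5, 8.0), (5.2, -15.0), (6.0, -10.0)],
                                spec.grid, 0.3)
        np.testing.assert_allclose(spec.values, oracle, rtol=1e-10, atol=1e-30)

    def test_sign_antisymmetry(self, three_state_stick):
        cfg = BroadeningConfig(sigma=0.3)
        pos = convolve(three_state_stick, cfg)
        neg = convolve(three_state_stick.scaled(-1.0), cfg)
        np.testing.assert_array_equal(neg.values, -pos.values)

    def test_superposition(self):
        cfg = BroadeningConfig(sigma=0.25)
        a = StickSpectrum([ExcitedState(1, 4.8, 12.0)])
        b = StickSpectrum([ExcitedState(1, 5.6, -7.0), ExcitedState(2, 6.1, 3.0)])
        combined = convolve(merge_sticks([a, b]), cfg)
        summed = convolve(a, cfg).values + convolve(b, cfg).values
        np.testing.assert_allclose(combined.values, summed, rtol=1e-12, atol=1e-30)

    def test_far_field_decay(self):
        sigma = 0.2
        stick = StickSpectrum([ExcitedState(1, 6.0, 40.0)])
        spec = convolve(stick, BroadeningConfig(sigma=sigma))
        energies = HC_EV_NM / spec.grid
        far = np.abs(energies - 6.0) >= 8 * sigma
        assert far.any()
        assert np.max(np.abs(spec.values[far])) < 1e-6 * np.max(np.abs(spec.values))

    def test_incident_energy_weighting_differs_but_agrees_at_stick(self):
        stick = StickSpectrum([ExcitedState(1, 5.0, 10.0)])
        per_state = convolve(stick, BroadeningConfig(sigma=0.3))
        incident = convolve(
            stick, BroadeningConfig(sigma=0.3, energy_weighting="incident_energy")
        )
        at_stick = np.argmin(np.abs(per_state.grid - HC_EV_NM / 5.0))
        assert incident.values[at_stick] == pytest.approx(
            per_state.values[at_stick], rel=1e-3
        )
        assert not np.allclose(incident.values, per_state.values)

    def test_invalid_states_rejected_with_index(self):
        with pytest.raises(InvalidStateError, match="state 2"):
            StickSpectrum([ExcitedState(1, 4.0, 1.0), ExcitedState(2, -0.1, 1.0)])
        with pytest.raises(InvalidStateError, match="not finite"):
            ExcitedState(3, 4.0, float("nan"))

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=3.2, max_value=7.2),
                st.floats(min_value=-80.0, max_value=80.0),
            ),
            min_size=1,
            max_size=12,
        ),
        st.floats(min_value=0.1, max_value=0.6),
    )
    def test_oracle_equivalence_on_random_sticks(self, pairs, sigma):
        stick = StickSpectrum(
            [ExcitedState(i + 1, en, rn) for i, (en, rn) in enumerate(pairs)]
        )
        cfg = BroadeningConfig(sigma=sigma, grid_min=175, grid_max=395, grid_step=5.0)
        spec = convolve(stick, cfg)
        oracle = brute_force_cd(pairs, spec.grid, sigma)
        np.testing.assert_allclose(spec.values, oracle, rtol=1e-10, atol=1e-25)


class TestDomainTypes:
    def test_states_sorted_by_energy_and_wavelength_consistent(self):
        stick = StickSpectrum([ExcitedState(2, 6.0, 1.0), ExcitedState(1, 4.0, 2.0)])
        assert [s.energy for s in stick] == [4.0, 6.0]
        assert stick.states[0].wavelength == pytest.approx(HC_EV_NM / 4.0)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(InvalidStateError, match="duplicate"):
            StickSpectrum([ExcitedState(1, 4.0, 1.0), ExcitedState(1, 5.0, 1.0)])

    def test_spectrum_requires_monotone_grid_and_finite_values(self):
        with pytest.raises(InvalidParameterError):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))
        with pytest.raises(InvalidParameterError):
            Spectrum(np.array([1.0, 2.0, 3.0]), np.array([0.0, np.inf, 0.0]))

    def test_broadening_config_validation(self):
        with pytest.raises(InvalidParameterError):
            BroadeningConfig(sigma=0.3, grid_min=300, grid_max=200)
        with pytest.raises(InvalidParameterError):
            BroadeningConfig(sigma=0.3, grid_step=0.0)
        with pytest.raises(InvalidParameterError):
            BroadeningConfig(sigma=0.3, energy_weighting="bogus")
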