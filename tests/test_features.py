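"""Peak detection, peak matching and the positive-shoulder diagnostic."""

import numpy as np
import pytest

from ecdkit.constants import HC_EV_NM
from ecdkit.features import (
    FeatureError,
    Peak,
    find_peaks,
    match_and_shift,
    positive_feature,
)
from ecdkit.spectra import BroadeningConfig, ExcitedState, Spectrum, StickSpectrum, convolve


def peak(pos, amp):
    return Peak(position=pos, amplitude=amp,
                sign="negative" if amp < 0 else "positive", prominence=abs(amp))


def two_negative_band_spectrum(centers_nm=(210.0, 275.0), r=-240.0, sigma=0.3):
    stick = StickSpectrum(
        [ExcitedState(i + 1, HC_EV_NM / c, r) for i, c in enumerate(centers_nm)]
    )
    return convolve(stick, BroadeningConfig(sigma=sigma))


class TestFindPeaks:
    def test_planted_two_negative_bands_recovered(self):
        spec = two_negative_band_spectrum()
        peaks = find_peaks(spec)
        neg = [p for p in peaks if p.sign == "negative"]
        assert len(neg) == 2
        assert abs(neg[0].position - 210.0) <= spec.grid[1] - spec.grid[0]
        assert abs(neg[1].position - 275.0) <= spec.grid[1] - spec.grid[0]

    def test_constant_spectrum_has_no_peaks(self):
        spec = Spectrum(np.linspace(200, 300, 50), np.full(50, -3.0))
        assert find_peaks(spec) == []

    def test_single_negative_band_peak_at_minimum(self):
        spec = two_negative_band_spectrum(centers_nm=(250.0,))
        peaks = find_peaks(spec)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.sign == "negative"
        assert p.amplitude == pytest.approx(spec.values.min())
        assert p.position == spec.grid[np.argmin(spec.values)]

    def test_negation_flips_signs_keeps_positions(self):
        spec = two_negative_band_spectrum()
        flipped = Spectrum(spec.grid, -spec.values)
        a = find_peaks(spec)
        b = find_peaks(flipped)
        assert [p.position for p in a] == [p.position for p in b]
        assert [p.sign for p in a] == ["negative"] * 2
        assert [p.sign for p in b] == ["positive"] * 2

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(FeatureError):
            find_peaks(Spectrum(np.array([200.0, 210.0]), np.array([0.0, 1.0])))

    def test_sub_prominence_wiggles_suppressed(self):
        grid = np.linspace(200, 300, 201)
        values = -50 * np.exp(-0.5 * ((grid - 250) / 15) ** 2)
        values += 0.3 * np.sin(grid)  # grid-scale noise below 1 M^-1 cm^-1
        peaks = find_peaks(Spectrum(grid, values), min_prominence=1.0)
        assert len([p for p in peaks if p.sign == "negative"]) == 1


class TestMatchAndShift:
    def test_reported_positions_give_20nm_verdict(self):
        report = match_and_shift(
            [peak(200, -40), peak(270, -30)],
            [peak(220, -35), peak(280, -28)],
        )
        assert sorted(report.shifts_nm) == [-20.0, -10.0]
        assert report.max_abs_shift_nm == 20.0
        assert report.within_tolerance is True

    def test_identical_peak_sets_have_zero_shifts(self):
        peaks = [peak(220, -35), peak(280, -28)]
        report = match_and_shift(peaks, peaks)
        assert report.shifts_nm == [0.0, 0.0]

    def test_larger_blue_shift_fails_20nm_verdict(self):
        report = match_and_shift(
            [peak(190, -60), peak(260, -45)],
            [peak(220, -35), peak(280, -28)],
        )
        assert sorted(report.shifts_nm) == [-30.0, -20.0]
        assert report.within_tolerance is False

    def test_swap_symmetry_up_to_shift_sign(self):
        calc = [peak(200, -40), peak(270, -30)]
        exp = [peak(220, -35), peak(280, -28)]
        fwd = match_and_shift(calc, exp)
        rev = match_and_shift(exp, calc)
        assert sorted(fwd.shifts_nm) == sorted(-s for s in rev.shifts_nm)

    def test_unmatched_peaks_listed(self):
        report = match_and_shift(
            [peak(200, -40)], [peak(205, -35), peak(280, -28)]
        )
        assert len(report.pairs) == 1
        assert [p.position for p in report.unmatched_exp] == [280]

    def test_sign_filter_empty_side_is_an_error(self):
        with pytest.raises(FeatureError, match="calculated"):
            match_and_shift([peak(230, +10)], [peak(220, -35)], sign_filter="negative")
        with pytest.raises(FeatureError, match="experimental"):
            match_and_shift([peak(220, -35)], [peak(230, +10)], sign_filter="negative")

    def test_report_serialization(self):
        report = match_and_shift(
            [peak(200, -40), peak(270, -30)], [peak(220, -35), peak(280, -28)]
        )
        text = report.to_text()
        assert "shift" in text and "tolerance_nm: 20" in text
        df = report.to_frame()
        assert list(df["shift_nm"]) == report.shifts_nm


class TestPositiveFeature:
    def test_everywhere_negative_spectrum_gives_zero(self):
        spec = two_negative_band_spectrum()
        assert positive_feature(spec) == 0.0

    def test_planted_shoulder_recovered(self):
        # R = +160 broadens to a standalone +50 shoulder at 230 nm
        shoulder = StickSpectrum([ExcitedState(1, HC_EV_NM / 230.0, +160.0)])
        amp_alone = positive_feature(
            convolve(shoulder, BroadeningConfig(sigma=0.3)), window=(220.0, 240.0)
        )
        assert amp_alone == pytest.approx(50.0, rel=0.02)
        # flanked by the two negative bands the wings eat part of it
        stick = StickSpectrum(
            [
                ExcitedState(1, HC_EV_NM / 205.0, -240.0),
                ExcitedState(2, HC_EV_NM / 230.0, +160.0),
                ExcitedState(3, HC_EV_NM / 280.0, -240.0),
            ]
        )
        amp = positive_feature(
            convolve(stick, BroadeningConfig(sigma=0.3)), window=(220.0, 240.0)
        )
        assert 0.0 < amp < amp_alone

    def test_bounded_window_propagates_bound(self):
        grid = np.linspace(200, 300, 101)
        values = np.minimum(5.0, 0.05 * (grid - 200.0)) - 0.0
        spec = Spectrum(grid, values)
        assert positive_feature(spec, window=(200.0, 260.0)) <= 5.0

    def test_monotone_under_positive_offset(self):
        spec = two_negative_band_spectrum()
        base = positive_feature(spec)
        lifted = positive_feature(Spectrum(spec.grid, spec.values + 7.0))
        assert lifted >= base
        assert lifted == pytest.approx(
            max(0.0, spec.values[(spec.grid >= 220) & (spec.grid <= 240)].max() + 7.0)
        )

    def test_disjoint_window_rejected(self):
        spec = two_negative_band_spectrum()
        with pytest.raises(FeatureError):
            positive_feature(spec, window=(500.0, 600.0))
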