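"""Peak heights, relative intensities, sigmoid fits and the filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diffcs import (
    AxisMeta,
    PeakAssignment,
    Spectrum2D,
    filter_fits,
    fit_sigmoid,
    normalized_residual,
    peak_height,
    relative_intensity,
    sigmoid,
    transition_table,
)
from diffcs.series_analysis import PeakSeries, read_peak_list, write_peak_list

TEMPS = np.arange(15.0, 44.0, 2.0)


def _spectrum(data, sw1=2700.0, sw2=1500.0):
    n1, n2 = data.shape
    return Spectrum2D(
        data, AxisMeta(n1, sw1, 118.0, 70.94), AxisMeta(n2, sw2, 8.2, 700.0)
    )


def _assignment_at(spectrum, i1, i2, label="X001N-H"):
    return PeakAssignment(label, spectrum.axis1.ppm()[i1], spectrum.axis2.ppm()[i2])


class TestPeakHeight:
    def test_unit_peak_at_assigned_point(self):
        data = np.zeros((32, 32))
        data[10, 20] = 1.0
        s = _spectrum(data)
        assert peak_height(s, _assignment_at(s, 10, 20)) == 1.0

    def test_all_zero_spectrum(self):
        s = _spectrum(np.zeros((32, 32)))
        assert peak_height(s, _assignment_at(s, 5, 5)) == 0.0

    def test_window_captures_offset_apex(self):
        data = np.zeros((32, 32))
        data[11, 21] = 2.0  # apex one point off the nominal coordinate
        data[10, 20] = 1.0
        s = _spectrum(data)
        assert peak_height(s, _assignment_at(s, 10, 20), window=1) == 2.0

    def test_out_of_window_position_rejected(self):
        s = _spectrum(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="outside"):
            peak_height(s, PeakAssignment("bad", 500.0, 8.2))


class TestRelativeIntensity:
    def test_identical_series_gives_unity(self):
        h = pd.Series(np.full(15, 5.0), index=TEMPS)
        prof = relative_intensity(h, h, noise_threshold=1.0)
        assert np.allclose(prof.i_rel, 1.0)
        assert prof.visible.all()

    def test_half_intensity_target(self):
        ref = pd.Series(np.full(15, 4.0), index=TEMPS)
        prof = relative_intensity(0.5 * ref, ref, noise_threshold=0.1)
        assert np.allclose(prof.i_rel, 0.5)

    def test_below_noise_masked(self):
        ref = pd.Series(np.full(15, 4.0), index=TEMPS)
        tgt = ref.copy()
        tgt.iloc[-3:] = 0.05
        prof = relative_intensity(tgt, ref, noise_threshold=0.5)
        assert not prof.visible[-3:].any() and prof.visible[:-3].all()
        assert np.isnan(prof.i_rel[-3:]).all()

    def test_temperature_mismatch_rejected(self):
        a = pd.Series(np.ones(5), index=np.arange(5.0))
        b = pd.Series(np.ones(5), index=np.arange(5.0) + 1)
        with pytest.raises(ValueError, match="mismatched temperature"):
            relative_intensity(a, b, 0.1)

    def test_attenuated_nterminal_block_pattern(self):
        # mirror a bound N-terminus: first 25 labels attenuated, rest ~1
        labels = [f"A{k:03d}N-H" for k in range(1, 51)]
        ref = pd.Series(np.full(15, 4.0), index=TEMPS)
        lows, highs = [], []
        for k, label in enumerate(labels):
            tgt = ref * (0.2 if k < 25 else 1.0)
            prof = relative_intensity(tgt, ref, 0.1, label=label)
            (lows if k < 25 else highs).append(np.nanmean(prof.i_rel))
        assert max(lows) < 0.3 and min(highs) > 0.9


class TestFitSigmoid:
    TRUE = dict(x_scale=0.3, x_shift=26.0, y_scale=0.8, y_shift=0.1)

    def test_noiseless_parameters_recovered(self):
        y = sigmoid(TEMPS, **self.TRUE)
        fit = fit_sigmoid(TEMPS, y)
        assert fit.status == "accepted"
        for name, value in self.TRUE.items():
            assert getattr(fit, name) == pytest.approx(value, abs=1e-3)

    def test_fitted_curve_midpoint_identity(self):
        y = sigmoid(TEMPS, **self.TRUE)
        fit = fit_sigmoid(TEMPS, y)
        assert fit.predict(fit.x_shift) == pytest.approx(fit.y_scale / 2 + fit.y_shift, rel=1e-6)

    def test_transition_temperature_robust_to_noise(self):
        # 100 noisy realizations: x_shift within +-1 degC in >= 95 of them
        y0 = sigmoid(TEMPS, **self.TRUE)
        hits = 0
        rng_seeds = range(100)
        for seed in rng_seeds:
            rng = np.random.default_rng(seed)
            fit = fit_sigmoid(TEMPS, y0 + rng.normal(0.0, 0.02, TEMPS.size))
            hits += abs(fit.x_shift - self.TRUE["x_shift"]) <= 1.0
        assert hits >= 95

    def test_too_few_points(self):
        fit = fit_sigmoid(np.array([20.0]), np.array([0.5]))
        assert fit.status == "too_few_points"


def _profile(y, label="A010N-H"):
    y = np.asarray(y, dtype=float)
    visible = np.isfinite(y)
    return PeakSeries(label, TEMPS[: y.size], np.ones(y.size), y, y, visible)


class TestFilters:
    def test_linear_profile_rejected(self):
        y = 1.0 - 0.02 * (TEMPS - 15.0)  # linear decline
        fit = fit_sigmoid(TEMPS, y, label="L001N-H")
        accepted, reasons = filter_fits([fit], [_profile(y, "L001N-H")])
        assert accepted == [] and reasons["L001N-H"] == "linear"

    def test_small_transition_rejected(self):
        # second and penultimate visible points 1.0 and 0.6: ratio 1.67 < 2
        y = sigmoid(TEMPS, 0.4, 29.0, 0.4, 0.6)
        y[1], y[-2] = 1.0, 0.6
        fit = fit_sigmoid(TEMPS, y, label="S002N-H")
        fit.x_scale = 0.4  # keep the linearity rule out of the way
        fit.relative_residual = 0.01
        accepted, reasons = filter_fits([fit], [_profile(y, "S002N-H")])
        assert reasons["S002N-H"] == "small_transition"

    def test_short_profile_rejected(self):
        y = sigmoid(TEMPS[:5], 0.3, 26.0, 0.8, 0.1)
        fit = fit_sigmoid(TEMPS[:5], y, label="F003N-H")
        accepted, reasons = filter_fits([fit], [_profile(y, "F003N-H")])
        assert reasons["F003N-H"] == "too_few_points"

    def test_ill_fitting_profile_rejected(self):
        rng = np.random.default_rng(5)
        y = sigmoid(TEMPS, 0.3, 26.0, 0.8, 0.1) + rng.normal(0, 0.15, TEMPS.size)
        fit = fit_sigmoid(TEMPS, y, label="P004N-H")
        if fit.status == "accepted" and fit.relative_residual <= 0.1:
            pytest.skip("randomized profile fitted unexpectedly well")
        accepted, reasons = filter_fits([fit], [_profile(y, "P004N-H")])
        assert reasons["P004N-H"] in ("poor_fit", "linear")

    def test_clean_sigmoid_accepted(self):
        y = sigmoid(TEMPS, 0.3, 26.0, 0.8, 0.1)
        fit = fit_sigmoid(TEMPS, y, label="G005N-H")
        accepted, reasons = filter_fits([fit], [_profile(y, "G005N-H")])
        assert len(accepted) == 1 and reasons == {}


class TestNormalizedResidual:
    def test_basic_identities(self):
        h = np.array([1.0, 2.0, 3.0])
        assert normalized_residual(h, h) == 0.0
        assert normalized_residual(np.zeros(3), h) == 1.0
        assert normalized_residual(1.1 * h, h) == pytest.approx(0.1, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero norm"):
            normalized_residual(np.ones(3), np.zeros(3))

    @settings(max_examples=50, derandomize=True)
    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_invariant_to_joint_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        h_full = rng.uniform(0.5, 2.0, 20)
        h_rec = h_full + rng.normal(0, 0.1, 20)
        base = normalized_residual(h_rec, h_full)
        assert normalized_residual(scale * h_rec, scale * h_full) == pytest.approx(base, rel=1e-9)


class TestTransitionTable:
    def test_empty_input(self):
        assert len(transition_table([])) == 0

    def test_residue_numbers_parsed_and_sorted(self):
        fits = [fit_sigmoid(TEMPS, sigmoid(TEMPS, 0.3, t, 0.8, 0.1), label=lbl)
                for lbl, t in [("A069N-H", 28.0), ("T059N-H", 25.0)]]
        table = transition_table(fits)
        assert list(table["residue"]) == [59, 69]
        assert table["transition_temp_c"].iloc[0] == pytest.approx(25.0, abs=0.1)

    def test_unparseable_label_gets_null_residue(self):
        fit = fit_sigmoid(TEMPS, sigmoid(TEMPS, 0.3, 26.0, 0.8, 0.1), label="??")
        table = transition_table([fit])
        assert np.isnan(table["residue"].iloc[0])

    def test_programmed_gradient_recovered_end_to_end(self):
        # transition temperatures rising along the sequence survive fitting
        rng = np.random.default_rng(3)
        fits = []
        for r in range(1, 31):
            true_t = 22.0 + 0.3 * r
            y = sigmoid(TEMPS, 0.35, true_t, 0.8, 0.1) + rng.normal(0, 0.01, TEMPS.size)
            fits.append(fit_sigmoid(TEMPS, y, label=f"A{r:03d}N-H"))
        table = transition_table(fits)
        fitted = table["transition_temp_c"].to_numpy()
        assert np.all(np.diff(fitted) > -0.5)  # monotone trend up to noise
        assert np.corrcoef(table["residue"], fitted)[0, 1] > 0.98


def test_peak_list_round_trip(tmp_path):
    peaks = [PeakAssignment("A069N-H", 120.0, 8.3), PeakAssignment("T059N-H", 115.0, 8.1)]
    path = tmp_path / "peaks.tsv"
    write_peak_list(peaks, path)
    assert read_peak_list(path) == peaks
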