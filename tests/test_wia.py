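"""Net wave intensity: derivatives, quadrants, peaks, suction timing."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

import corowave as cw
from corowave.errors import DegenerateSignalError, MissingWaveError, ParameterError
from corowave.wia import MMHG_TO_PA, PEAK_UNIT, WaveIntensityProfile

from conftest import make_constant_beat


def _sine_beat(phase_u=0.0, fs=200.0):
    """Pd = 100 + 10 sin(2 pi t) mmHg, U = 0.3 + 0.1 sin(2 pi t + phase) m/s."""
    t = np.arange(int(fs)) / fs
    return cw.EnsembleBeat(
        time=t,
        pa=100 + 10 * np.sin(2 * np.pi * t),
        pd=100 + 10 * np.sin(2 * np.pi * t),
        u=100.0 * (0.3 + 0.1 * np.sin(2 * np.pi * t + phase_u)),  # cm/s
        n_beats_averaged=10, fs=fs,
    )


# -- differentiation -------------------------------------------------------


def test_derivative_of_linear_ramp():
    fs = 200.0
    t = np.arange(400) / fs
    beat = cw.EnsembleBeat(time=t, pa=100 + 5 * t, pd=100 + 5 * t,
                           u=30 + 0 * t, n_beats_averaged=10, fs=fs)
    dpdt, dudt = cw.differentiate(beat)
    interior = slice(10, -10)
    np.testing.assert_allclose(dpdt[interior], 5 * MMHG_TO_PA, rtol=1e-3)
    np.testing.assert_allclose(dudt[interior], 0.0, atol=1e-10)


def test_derivative_of_sine_matches_closed_form():
    beat = _sine_beat()
    _, dudt = cw.differentiate(beat)
    assert abs(dudt.max() - 0.1 * 2 * np.pi) / (0.1 * 2 * np.pi) < 0.005


def test_derivative_of_constants_is_zero():
    dpdt, dudt = cw.differentiate(make_constant_beat())
    np.testing.assert_allclose(dpdt, 0.0, atol=1e-10)
    np.testing.assert_allclose(dudt, 0.0, atol=1e-10)


def test_nonuniform_grid_rejected():
    beat = make_constant_beat()
    t = beat.time.copy()
    t[5] += 1e-3
    with pytest.raises(ParameterError):
        cw.differentiate(replace(beat, time=t))


# -- net WI ----------------------------------------------------------------


def test_closed_form_wi_peak_and_nonnegativity():
    beat = _sine_beat()
    profile = cw.net_wave_intensity(beat)
    expected_peak = 10 * MMHG_TO_PA * 0.1 * (2 * np.pi) ** 2
    assert profile.wi.min() > -1e-8
    assert abs(profile.wi.max() / expected_peak - 1.0) < 0.01


def test_antiphase_velocity_makes_wi_nonpositive():
    profile = cw.net_wave_intensity(_sine_beat(phase_u=np.pi))
    assert profile.wi.max() <= 1e-8


def test_quadrant_partition_reconstructs_wi_exactly():
    beat = cw.process_recording(cw.synth_beat(cw.BeatParams(), 10))
    profile = cw.net_wave_intensity(beat)
    total = np.zeros_like(profile.wi)
    for q in ("FCW", "BCW", "FEW", "BEW", ""):
        total = total + profile.wi * (profile.quadrant == q)
    np.testing.assert_array_equal(total, profile.wi)


def test_flat_beat_degenerate():
    with pytest.raises(DegenerateSignalError):
        cw.net_wave_intensity(make_constant_beat())


def test_all_four_waves_present_on_synthetic_beat():
    beat = cw.process_recording(cw.synth_beat(cw.BeatParams(), 10))
    profile = cw.net_wave_intensity(beat)
    peaks = cw.extract_peaks(profile)
    for v in (peaks.fcw_peak, peaks.bcw_peak, peaks.few_peak, peaks.bew_peak):
        assert np.isfinite(v) and v > 0


# -- peak extraction -------------------------------------------------------


def test_antiphase_case_has_bew_but_no_fcw():
    profile = cw.net_wave_intensity(_sine_beat(phase_u=np.pi))
    peaks = cw.extract_peaks(profile)
    assert np.isnan(peaks.fcw_peak)
    assert np.isfinite(peaks.bew_peak) and peaks.bew_peak > 0


def test_missing_bew_raises_missing_wave():
    # in-phase sinusoids occupy only the forward quadrants (FCW, FEW)
    profile = cw.net_wave_intensity(_sine_beat(phase_u=0.0))
    with pytest.raises(MissingWaveError):
        cw.extract_peaks(profile)


def test_bew_at_expansion_start_gives_zero_tbew():
    n = 200
    t = np.arange(n) / 200.0
    wi = np.zeros(n)
    quad = np.full(n, "", dtype="U3")
    # symmetric |WI| peak exactly at the expansion-start sample
    i0 = 80
    wi[i0 - 1:i0 + 2] = [-5.0, -9.0, -5.0]
    quad[i0 - 1:i0 + 2] = "BEW"
    profile = WaveIntensityProfile(
        time=t, dpdt=-np.ones(n), dudt=np.ones(n), wi=wi, quadrant=quad,
        expansion_start=t[i0], expansion_end=1.0,
    )
    peaks = cw.extract_peaks(profile)
    assert peaks.tbew_peak == 0.0
    assert peaks.bew_peak == pytest.approx(9.0 / PEAK_UNIT)


def test_suction_delay_round_trip():
    p = cw.BeatParams(suction_delay_frac=0.25)
    beat = cw.process_recording(cw.synth_beat(p, 16))
    _, peaks = cw.analyze_beat(beat)
    assert abs(peaks.tbew_peak - 0.25) < 0.03


def test_tbew_monotone_in_suction_delay():
    rec = []
    for d in (0.10, 0.20, 0.30, 0.40, 0.50):
        beat = cw.process_recording(
            cw.synth_beat(cw.BeatParams(suction_delay_frac=d), 16))
        rec.append(cw.analyze_beat(beat)[1].tbew_peak)
    assert np.all(np.diff(rec) > 0)


def test_weaker_suction_reduces_bew_at_matched_velocity():
    """Halving suction_gain lowers the BEW peak while the mean hyperemic
    velocity is unchanged (the generator renormalizes the waveform mean)."""
    p1 = cw.BeatParams(suction_gain=1.0)
    p2 = replace(p1, suction_gain=0.5)
    b1 = cw.process_recording(cw.synth_beat(p1, 16))
    b2 = cw.process_recording(cw.synth_beat(p2, 16))
    pk1, pk2 = cw.analyze_beat(b1)[1], cw.analyze_beat(b2)[1]
    assert pk2.bew_peak < pk1.bew_peak
    u1, u2 = cw.time_average(b1, "u"), cw.time_average(b2, "u")
    assert abs(u2 / u1 - 1.0) < 0.05


# -- invariances -----------------------------------------------------------


@given(st.floats(0.2, 4.0), st.floats(0.2, 4.0))
def test_wi_bilinear_scaling(k, m):
    beat = cw.process_recording(cw.synth_beat(cw.BeatParams(), 10))
    scaled = replace(beat, pd=k * beat.pd, u=m * beat.u)
    p1 = cw.net_wave_intensity(beat)
    p2 = cw.net_wave_intensity(scaled)
    np.testing.assert_allclose(p2.wi, k * m * p1.wi, rtol=1e-9, atol=1e-6)
    pk1, pk2 = cw.extract_peaks(p1), cw.extract_peaks(p2)
    assert pk2.bew_peak == pytest.approx(k * m * pk1.bew_peak, rel=1e-6)
    assert pk2.tbew_peak == pytest.approx(pk1.tbew_peak, abs=1e-9)


def test_tbew_invariant_under_heart_rate_dilation():
    for d in (0.15, 0.35):
        vals = []
        for hr in (60.0, 90.0):
            beat = cw.process_recording(
                cw.synth_beat(cw.BeatParams(heart_rate=hr,
                                            suction_delay_frac=d), 16))
            vals.append(cw.analyze_beat(beat)[1].tbew_peak)
        assert abs(vals[0] - vals[1]) < 0.01


# -- energy fraction -------------------------------------------------------


def test_accel_fraction_half_for_inphase_sinusoid():
    profile = cw.net_wave_intensity(_sine_beat(phase_u=0.0))
    assert abs(cw.accel_energy_fraction(profile) - 0.5) < 0.01


def test_accel_fraction_one_when_only_accelerating_waves():
    profile = cw.net_wave_intensity(_sine_beat(phase_u=np.pi))
    # antiphase case: only BCW and BEW labeled; mask out the BCW to leave
    # pure accelerating energy
    profile.quadrant[profile.quadrant == "BCW"] = "BEW"
    assert cw.accel_energy_fraction(profile) == pytest.approx(1.0)


@given(st.floats(0.5, 2.0))
def test_accel_fraction_invariant_to_joint_scaling(k):
    beat = cw.process_recording(cw.synth_beat(cw.BeatParams(), 10))
    scaled = replace(beat, pd=k * beat.pd, u=k * beat.u)
    f1 = cw.accel_energy_fraction(cw.net_wave_intensity(beat))
    f2 = cw.accel_energy_fraction(cw.net_wave_intensity(scaled))
    assert f2 == pytest.approx(f1, rel=1e-9)
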