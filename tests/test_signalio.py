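"""I/O round trips, smoothing, resampling, beat detection, windows, ensembles."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

import corowave as cw
from corowave.errors import (
    FormatError,
    InsufficientBeatsError,
    InsufficientDataError,
    SegmentationError,
    SelectionError,
)
from corowave.signalio import smooth_velocity

from conftest import aligned_rms


# -- trace format ----------------------------------------------------------


@pytest.mark.parametrize("dialect", ["block", "wide"])
def test_write_read_round_trip(tmp_path, dialect):
    p = cw.BeatParams(noise_sd_p=0.5, noise_sd_u=0.5, seed=3)
    if dialect == "wide":
        p = replace(p, fs_velocity=200.0)
    rec = cw.synth_beat(p, 4, vessel_id="V42", phase="post",
                        condition="hyperemia")
    path = tmp_path / "trace.csv"
    cw.write_recording(rec, path, dialect=dialect)
    back = cw.read_recording(path)
    np.testing.assert_array_equal(back.pa, rec.pa)
    np.testing.assert_array_equal(back.pd, rec.pd)
    np.testing.assert_array_equal(back.u, rec.u)
    assert back.vessel_id == "V42" and back.phase == "post"
    assert back.fs_pressure == rec.fs_pressure
    assert back.fs_velocity == rec.fs_velocity


def test_missing_channel_raises_named_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# corowave-trace v1\n# vessel_id=X\n"
        "# channel=Pa fs=200 units=mmHg\n0,100\n0.005,101\n"
        "# channel=U fs=100 units=cm/s\n0,30\n0.01,31\n"
    )
    with pytest.raises(FormatError, match="Pd"):
        cw.read_recording(path)


def test_non_monotone_time_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# corowave-trace v1\n"
        "# channel=Pa fs=200 units=mmHg\n0,100\n0.01,101\n0.005,102\n"
        "# channel=Pd fs=200 units=mmHg\n0,90\n0.005,91\n0.01,92\n"
        "# channel=U fs=200 units=cm/s\n0,30\n0.005,31\n0.01,32\n"
    )
    with pytest.raises(FormatError, match="non-monotone"):
        cw.read_recording(path)


def test_synth_output_round_trips_through_pipeline(tmp_path):
    rec = cw.synth_beat(cw.BeatParams(heart_rate=60.0), 10)
    path = tmp_path / "t.csv"
    cw.write_recording(rec, path)
    beat = cw.process_recording(cw.read_recording(path))
    assert beat.n_beats_averaged >= 8


# -- Savitzky-Golay smoothing ---------------------------------------------


def test_smoothing_exact_on_quadratics():
    t = np.linspace(0.0, 2.0, 400)
    u = 3.0 + 2.0 * t - 1.5 * t**2
    out = smooth_velocity(u)
    np.testing.assert_allclose(out[5:-5], u[5:-5], atol=1e-10)


def test_smoothing_preserves_constants():
    out = smooth_velocity(np.full(50, 7.25))
    np.testing.assert_allclose(out, 7.25, atol=1e-12)


def test_smoothing_too_short_raises():
    with pytest.raises(InsufficientDataError):
        smooth_velocity(np.ones(10))


@given(st.floats(-3, 3), st.floats(-3, 3))
def test_smoothing_is_linear(a, b):
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=100), rng.normal(size=100)
    lhs = smooth_velocity(a * x + b * y)
    rhs = a * smooth_velocity(x) + b * smooth_velocity(y)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def sg_variance_factor(order=2, window=11):
    """Independent least-squares construction of the SG noise-variance
    reduction factor: sum of squared center-point coefficients."""
    m = window // 2
    A = np.vander(np.arange(-m, m + 1), order + 1, increasing=True)
    H = A @ np.linalg.inv(A.T @ A) @ A.T
    c = H[m]
    return float(np.sum(c**2))


def test_smoothing_noise_variance_reduction_matches_lsq_factor():
    rng = np.random.default_rng(12345)
    x = rng.normal(0.0, 1.0, 10_000)
    out = smooth_velocity(x)
    measured = out[50:-50].var()
    assert abs(measured / sg_variance_factor() - 1.0) < 0.05


# -- resampling ------------------------------------------------------------


def test_resample_identity_on_common_grid():
    p = replace(cw.BeatParams(), fs_velocity=200.0)
    rec = cw.synth_beat(p, 3)
    out = cw.resample_to_common_grid(rec)
    assert out is rec


def test_resample_sine_close_to_analytic():
    fs_u, fs_p, dur = 100.0, 200.0, 4.0
    t_u = np.arange(int(dur * fs_u)) / fs_u
    t_p = np.arange(int(dur * fs_p)) / fs_p
    rec = cw.VesselRecording("x", "pre", "rest",
                             pa=100 + 0 * t_p, pd=90 + 0 * t_p,
                             u=np.sin(2 * np.pi * t_u),
                             fs_pressure=fs_p, fs_velocity=fs_u)
    out = cw.resample_to_common_grid(rec)
    assert np.max(np.abs(out.u - np.sin(2 * np.pi * t_p))) < 1e-3


def test_resample_exact_on_linear_ramp():
    fs_u, fs_p, dur = 100.0, 200.0, 2.0
    t_u = np.arange(int(dur * fs_u)) / fs_u
    t_p = np.arange(int(dur * fs_p)) / fs_p
    rec = cw.VesselRecording("x", "pre", "rest",
                             pa=100 + 0 * t_p, pd=90 + 0 * t_p,
                             u=2.0 + 5.0 * t_u,
                             fs_pressure=fs_p, fs_velocity=fs_u)
    out = cw.resample_to_common_grid(rec)
    np.testing.assert_allclose(out.u, 2.0 + 5.0 * t_p, atol=1e-9)


# -- beat detection --------------------------------------------------------


def test_detect_beats_noiseless_60bpm():
    rec = cw.synth_beat(cw.BeatParams(heart_rate=60.0), 10)
    beats = cw.detect_beats(rec.pa, rec.fs_pressure)
    spacings = np.diff(beats.onsets) / rec.fs_pressure
    np.testing.assert_allclose(spacings, 1.0, atol=0.01)
    assert all(f == "ok" for f in beats.flags)


def test_detect_beats_constant_pressure_raises():
    with pytest.raises(SegmentationError):
        cw.detect_beats(np.full(2000, 100.0), 200.0)


def test_long_beat_flagged_rejected():
    # splice a 40%-longer beat (43 bpm) into a 60 bpm train
    a = cw.synth_beat(cw.BeatParams(heart_rate=60.0), 5)
    b = cw.synth_beat(cw.BeatParams(heart_rate=60.0 / 1.4), 1)
    c = cw.synth_beat(cw.BeatParams(heart_rate=60.0), 5)
    pa = np.concatenate([a.pa, b.pa, c.pa])
    beats = cw.detect_beats(pa, 200.0)
    spacings = np.diff(beats.onsets) / 200.0
    long_idx = int(np.argmax(spacings))
    assert spacings[long_idx] > 1.3
    assert beats.flags[long_idx] == "rejected"
    assert sum(f == "rejected" for f in beats.flags) <= 2


# -- window selection ------------------------------------------------------


def _transition_rec(seed=5, mult=2.0, **kw):
    rest = cw.BeatParams(heart_rate=60.0, noise_sd_p=0.5, noise_sd_u=0.5,
                         hr_jitter_frac=0.01, seed=seed)
    hyp = cw.hyperemic_params(rest, mult)
    return cw.synth_transition(rest, hyp, t_rest=30.0, t_ramp=5.0,
                               t_hyp=25.0, **kw)


def test_select_windows_on_step_recording():
    rec = _transition_rec()
    sel = cw.select_windows(rec)
    # plateau is reached at ~35 s; selected onset within 2 beats after it
    assert 33.0 <= sel.hyperemia_window[0] <= 37.5
    assert sel.rest_window[1] <= sel.hyperemia_window[0]
    assert "plateau" in sel.method_trace
    # downstream: both windows support an ensemble and a sane CFVR
    rest_b, hyp_b, _ = cw.process_continuous(rec)
    idx = cw.compute_indices(rest_b, hyp_b)
    assert 1.8 < idx.cfvr < 2.2


def test_select_windows_flat_recording_raises():
    rest = cw.BeatParams(heart_rate=60.0, noise_sd_p=0.5, noise_sd_u=0.5,
                         seed=2)
    rec = cw.synth_beat(rest, 60)
    rec = replace(rec, condition="continuous")
    with pytest.raises(SelectionError):
        cw.select_windows(rec)


def test_two_plateau_recording_prefers_higher_mean():
    # ramp to 1.5x, plateau, then ramp to 2.2x: second plateau must win
    rest = cw.BeatParams(heart_rate=60.0, noise_sd_p=0.3, noise_sd_u=0.3,
                         hr_jitter_frac=0.005, seed=9)
    mid = cw.hyperemic_params(rest, 1.5)
    high = cw.hyperemic_params(rest, 2.2)
    first = cw.synth_transition(rest, mid, t_rest=25.0, t_ramp=4.0, t_hyp=20.0)
    second = cw.synth_transition(mid, high, t_rest=20.0, t_ramp=4.0,
                                 t_hyp=20.0, vessel_id="x")
    rec = replace(first, pa=np.concatenate([first.pa, second.pa]),
                  pd=np.concatenate([first.pd, second.pd]),
                  u=np.concatenate([first.u, second.u]))
    sel = cw.select_windows(rec)
    assert sel.hyperemia_window[0] > 49.0  # inside the later, higher plateau


def test_window_selection_invariant_to_velocity_offset():
    rec = _transition_rec(seed=11)
    sel1 = cw.select_windows(rec)
    sel2 = cw.select_windows(replace(rec, u=rec.u + 25.0))
    assert sel1.rest_window == sel2.rest_window
    assert sel1.hyperemia_window == sel2.hyperemia_window


# -- ensemble averaging ----------------------------------------------------


def test_ensemble_of_identical_beats_is_one_beat():
    rec = cw.synth_beat(cw.BeatParams(heart_rate=60.0), 10)
    beat = cw.ensemble_average(cw.resample_to_common_grid(rec))
    assert beat.n_beats_averaged == 9
    np.testing.assert_allclose(beat.pa, rec.pa[:len(beat.pa)], atol=1e-9)
    np.testing.assert_allclose(beat.pd, rec.pd[:len(beat.pd)], atol=1e-9)


def test_ensemble_noise_reduction_mc():
    """16 noisy beats average down to <= 1.2 sigma/4 RMS residual
    (phase-aligned against the noiseless representative cycle), 12 seeds."""
    p0 = cw.BeatParams(heart_rate=70.0)
    truth = cw.process_recording(cw.synth_beat(p0, 16))
    for ch in ("pa", "pd", "u"):
        rms = [
            aligned_rms(
                cw.process_recording(
                    cw.synth_beat(replace(p0, noise_sd_p=1.0, noise_sd_u=1.0,
                                          seed=500 + s), 16)),
                truth, ch)
            for s in range(12)
        ]
        assert np.mean(rms) <= 1.2 * 1.0 / 4.0


def test_too_few_accepted_beats_reports_count():
    rec = cw.synth_beat(cw.BeatParams(heart_rate=60.0), 8)  # 7 intervals
    with pytest.raises(InsufficientBeatsError) as exc:
        cw.ensemble_average(cw.resample_to_common_grid(rec))
    assert exc.value.n_accepted == 7


@given(st.floats(0.1, 10.0))
def test_ensemble_commutes_with_channel_scaling(k):
    rec = cw.resample_to_common_grid(
        cw.synth_beat(cw.BeatParams(heart_rate=65.0), 10))
    scaled = replace(rec, pa=k * rec.pa, pd=k * rec.pd, u=k * rec.u)
    b1 = cw.ensemble_average(rec)
    b2 = cw.ensemble_average(scaled)
    np.testing.assert_allclose(b2.pa, k * b1.pa, rtol=1e-12, atol=1e-9)
    np.testing.assert_allclose(b2.u, k * b1.u, rtol=1e-12, atol=1e-9)
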