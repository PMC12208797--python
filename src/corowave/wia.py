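"""Net wave intensity analysis on the ensemble beat.

Net wave intensity is the pointwise product of the time derivatives of
distal pressure and flow velocity, ``WI(t) = (dP/dt)(dU/dt)`` in SI units
(W·m⁻²·s⁻²). Its sign separates proximally originating (forward, WI > 0)
from distally originating (backward, WI < 0) wave dominance, and the signs
of the two derivatives classify the four canonical coronary waves:

======  ========  ========  ====================================
wave    dP/dt     dU/dt     physiology
======  ========  ========  ====================================
FCW     > 0       > 0       forward compression (LV ejection)
BCW     > 0       < 0       backward compression (systolic squeeze)
FEW     < 0       < 0       forward expansion (decelerating)
BEW     < 0       > 0       backward expansion (microvascular suction)
======  ========  ========  ====================================

The expansion phase of the beat (dP/dt < 0) runs from the systolic pressure
peak of the distal trace to end-diastole. The suction-timing statistic
``tBEW_peak`` is the time from the start of the expansion phase to the BEW
peak, expressed as a fraction of the expansion-phase duration so that
patients with different heart rates are comparable.

Peak amplitudes are reported in units of 10 kW·m⁻²·s⁻² (raw value / 1e4),
the conventional magnitude scale for coronary net WI peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSignalError, MissingWaveError, ParameterError
from .signalio import SG_ORDER, SG_WINDOW, EnsembleBeat

MMHG_TO_PA = 133.322
CMS_TO_MS = 0.01
PEAK_UNIT = 1.0e4  # 1 reported unit = 10 kW.m-2.s-2

#: derivative magnitudes below this fraction of their own maximum are left
#: unlabeled: sign flips inside the dead band are noise, not waves
DEADBAND_FRAC = 0.01

WAVE_TYPES = ("FCW", "BCW", "FEW", "BEW")

_QUADRANT = {(1, 1): "FCW", (1, -1): "BCW", (-1, -1): "FEW", (-1, 1): "BEW"}


@dataclass
class WaveIntensityProfile:
    """Per-sample net wave intensity with quadrant labels."""

    time: np.ndarray  # s
    dpdt: np.ndarray  # Pa/s (distal pressure derivative)
    dudt: np.ndarray  # m/s^2
    wi: np.ndarray  # W.m-2.s-2
    quadrant: np.ndarray  # {"FCW","BCW","FEW","BEW",""} per sample
    expansion_start: float  # s, time of distal pressure maximum
    expansion_end: float  # s, end of the cycle


@dataclass
class WavePeakSet:
    """Peak amplitudes/times of the four waves plus derived statistics.

    Amplitudes are magnitudes (>= 0) in units of 10 kW·m⁻²·s⁻²; a wave
    absent from the profile is reported as NaN (the BEW is mandatory and
    raises instead).
    """

    fcw_peak: float
    bcw_peak: float
    few_peak: float
    bew_peak: float
    t_fcw: float
    t_bcw: float
    t_few: float
    t_bew: float
    tbew_peak: float  # fraction of the expansion phase, in [0, 1]
    accel_energy_fraction: float  # |WI| integral share of FCW+BEW, in [0, 1]


def differentiate(beat: EnsembleBeat) -> tuple:
    """Savitzky-Golay first derivatives of distal pressure and velocity.

    Channels are converted to SI first (mmHg -> Pa, cm/s -> m/s); the beat
    is treated as periodic (cyclic boundary handling), consistent with an
    ensemble-averaged cycle. Returns ``(dPdt, dUdt)`` in Pa/s and m/s².
    """
    dt = np.diff(beat.time)
    if len(dt) == 0 or np.ptp(dt) > 1e-9 * dt[0] + 1e-12:
        raise ParameterError("ensemble beat must be on a uniform time grid")
    delta = float(dt[0])
    dpdt = savgol_filter(beat.pd * MMHG_TO_PA, SG_WINDOW, SG_ORDER,
                         deriv=1, delta=delta, mode="wrap")
    dudt = savgol_filter(beat.u * CMS_TO_MS, SG_WINDOW, SG_ORDER,
                         deriv=1, delta=delta, mode="wrap")
    return dpdt, dudt


def _parabolic_refine(y: np.ndarray, i: int, dt: float, t0: float) -> tuple:
    """Sub-sample peak location/value by a 3-point parabola around sample i.

    The vertex offset is clamped to half a sample; returns (time, value).
    """
    if i <= 0 or i >= len(y) - 1:
        return t0 + i * dt, float(y[i])
    y0, y1, y2 = float(y[i - 1]), float(y[i]), float(y[i + 1])
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return t0 + i * dt, y1
    off = 0.5 * (y0 - y2) / denom
    off = float(np.clip(off, -0.5, 0.5))
    val = y1 - 0.25 * (y0 - y2) * off
    return t0 + (i + off) * dt, float(val)


def net_wave_intensity(beat: EnsembleBeat) -> WaveIntensityProfile:
    """Compute the net WI profile with quadrant labels and expansion phase.

    The expansion phase is anchored at the maximum of the distal pressure
    (the sensor pair WIA operates on) and extends to the end of the cycle.
    """
    if np.ptp(beat.pd) == 0 or np.ptp(beat.u) == 0:
        raise DegenerateSignalError("flat beat: wave intensity undefined")
    dpdt, dudt = differentiate(beat)
    max_dp = float(np.max(np.abs(dpdt)))
    max_du = float(np.max(np.abs(dudt)))
    if max_dp <= 0 or max_du <= 0:
        raise DegenerateSignalError("flat beat: wave intensity undefined")
    wi = dpdt * dudt

    labeled = (np.abs(dpdt) >= DEADBAND_FRAC * max_dp) & (
        np.abs(dudt) >= DEADBAND_FRAC * max_du
    )
    quadrant = np.full(len(wi), "", dtype="U3")
    sp = np.sign(dpdt).astype(int)
    su = np.sign(dudt).astype(int)
    for (qsp, qsu), name in _QUADRANT.items():
        quadrant[labeled & (sp == qsp) & (su == qsu)] = name

    dt = float(beat.time[1] - beat.time[0])
    i_max = int(np.argmax(beat.pd))
    exp_start, _ = _parabolic_refine(beat.pd, i_max, dt, float(beat.time[0]))
    exp_end = float(beat.time[0]) + len(beat.time) * dt  # full cycle length
    return WaveIntensityProfile(
        time=beat.time.copy(), dpdt=dpdt, dudt=dudt, wi=wi,
        quadrant=quadrant, expansion_start=exp_start, expansion_end=exp_end,
    )


def extract_peaks(profile: WaveIntensityProfile) -> WavePeakSet:
    """Locate the four wave peaks and the suction-timing statistic.

    Compression waves (FCW, BCW) are searched from cycle start to the
    expansion onset, expansion waves (FEW, BEW) within the expansion phase.
    Each peak is the maximum |WI| over samples carrying the wave's quadrant
    label, refined to sub-sample precision. A missing BEW raises
    :class:`MissingWaveError` (the vessel is flagged, not silently zeroed).
    """
    t = profile.time
    dt = float(t[1] - t[0])
    abs_wi = np.abs(profile.wi)
    pre_mask = t < profile.expansion_start
    exp_mask = t >= profile.expansion_start

    peaks: dict = {}
    times: dict = {}
    for wave in WAVE_TYPES:
        gate = pre_mask if wave in ("FCW", "BCW") else exp_mask
        sel = np.flatnonzero((profile.quadrant == wave) & gate)
        if len(sel) == 0:
            if wave == "BEW":
                raise MissingWaveError(
                    "no backward expansion (suction) wave found in the "
                    "expansion phase"
                )
            peaks[wave], times[wave] = np.nan, np.nan
            continue
        i = int(sel[np.argmax(abs_wi[sel])])
        t_pk, v_pk = _parabolic_refine(abs_wi, i, dt, float(t[0]))
        peaks[wave] = v_pk / PEAK_UNIT
        times[wave] = t_pk

    span = profile.expansion_end - profile.expansion_start
    tbew = (times["BEW"] - profile.expansion_start) / span
    tbew = float(np.clip(tbew, 0.0, 1.0))
    return WavePeakSet(
        fcw_peak=peaks["FCW"], bcw_peak=peaks["BCW"],
        few_peak=peaks["FEW"], bew_peak=peaks["BEW"],
        t_fcw=times["FCW"], t_bcw=times["BCW"],
        t_few=times["FEW"], t_bew=times["BEW"],
        tbew_peak=tbew,
        accel_energy_fraction=accel_energy_fraction(profile),
    )


def accel_energy_fraction(profile: WaveIntensityProfile) -> float:
    """Share of labeled wave energy carried by the accelerating waves.

    Trapezoidal integral of |WI| over samples labeled FCW or BEW divided by
    the integral over all labeled samples.
    """
    abs_wi = np.abs(profile.wi)
    lab = profile.quadrant != ""
    acc = (profile.quadrant == "FCW") | (profile.quadrant == "BEW")
    total = float(np.trapezoid(abs_wi * lab, profile.time))
    if total <= 0:
        raise DegenerateSignalError("zero total labeled wave energy")
    return float(np.trapezoid(abs_wi * acc, profile.time) / total)


def analyze_beat(beat: EnsembleBeat) -> tuple:
    """Convenience: full WIA of one ensemble beat -> (profile, peaks)."""
    profile = net_wave_intensity(beat)
    return profile, extract_peaks(profile)


def plot_wave_intensity(profile: WaveIntensityProfile, ax=None):
    """Plot the net WI trace with the expansion phase shaded (optional hook).

    Requires matplotlib; returns the axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.time, profile.wi / PEAK_UNIT, lw=1.2, color="k")
    ax.axvspan(profile.expansion_start, profile.expansion_end,
               color="tab:blue", alpha=0.12, label="expansion phase")
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("net WI (10 kW·m⁻²·s⁻²)")
    ax.legend(loc="upper right", fontsize="small")
    return ax
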