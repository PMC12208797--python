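"""Recording I/O and beat-level signal conditioning.

This module owns the raw-data side of the pipeline: the
:class:`VesselRecording` container for simultaneous aortic pressure (Pa),
distal coronary pressure (Pd) and Doppler average peak velocity (U) traces,
a plain-text trace format, Savitzky-Golay velocity smoothing, beat
segmentation on the aortic pressure trace, automatic rest/hyperemia window
selection on continuous recordings, and ensemble averaging of accepted beats
into one representative cardiac cycle.

Conventions
-----------
* Pressures are mmHg, velocity is cm/s, time is seconds.
* Pa and Pd share ``fs_pressure``; U may be on a slower ``fs_velocity`` grid
  (dual-sensor guidewire consoles record this way) and is upsampled onto the
  pressure grid before any beat-level work.
* A representative cycle requires at least ``MIN_BEATS`` (8) accepted beats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    FormatError,
    InsufficientBeatsError,
    InsufficientDataError,
    ParameterError,
    SegmentationError,
    SelectionError,
)

#: Savitzky-Golay parameters used for velocity smoothing and derivatives.
SG_WINDOW = 11
SG_ORDER = 2

#: Minimum number of consecutive accepted beats for an ensemble average.
MIN_BEATS = 8

#: Admissible beat period range, seconds (40-180 bpm).
MIN_PERIOD_S = 0.33
MAX_PERIOD_S = 1.5

#: Beats whose cycle length deviates more than this fraction from the
#: running median are rejected as arrhythmic/artefactual.
CYCLE_DEVIATION_FRAC = 0.20


@dataclass
class VesselRecording:
    """Raw multi-channel trace for one vessel, condition and phase."""

    vessel_id: str
    phase: str  # {"pre", "post"}
    condition: str  # {"rest", "hyperemia", "continuous"}
    pa: np.ndarray  # mmHg @ fs_pressure
    pd: np.ndarray  # mmHg @ fs_pressure
    u: np.ndarray  # cm/s @ fs_velocity
    fs_pressure: float
    fs_velocity: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pa = np.asarray(self.pa, dtype=float)
        self.pd = np.asarray(self.pd, dtype=float)
        self.u = np.asarray(self.u, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.pa) / self.fs_pressure

    def time_pressure(self) -> np.ndarray:
        return np.arange(len(self.pa)) / self.fs_pressure

    def time_velocity(self) -> np.ndarray:
        return np.arange(len(self.u)) / self.fs_velocity

    def validate(self) -> "VesselRecording":
        """Check structural invariants; return self for chaining."""
        if self.fs_pressure <= 0 or self.fs_velocity <= 0:
            raise FormatError("sampling frequencies must be positive")
        if len(self.pa) != len(self.pd):
            raise FormatError("Pa and Pd must share the pressure grid")
        dur_p = len(self.pa) / self.fs_pressure
        dur_u = len(self.u) / self.fs_velocity
        tol = 1.0 / min(self.fs_pressure, self.fs_velocity) + 1e-9
        if abs(dur_p - dur_u) > tol:
            raise FormatError(
                f"channel durations differ: pressure {dur_p:.3f}s vs "
                f"velocity {dur_u:.3f}s"
            )
        if np.any(self.pa < 0) or np.any(self.pd < 0):
            raise FormatError("negative pressure samples after ingest")
        return self


@dataclass
class BeatIndex:
    """Beat onsets on the pressure grid with per-beat quality flags."""

    onsets: np.ndarray  # strictly increasing sample indices
    flags: list  # one {"ok","rejected"} per beat (inter-onset interval)
    fs: float

    @property
    def n_beats(self) -> int:
        return len(self.onsets) - 1

    def accepted(self) -> np.ndarray:
        """Indices of beats flagged ok."""
        return np.array([i for i, f in enumerate(self.flags) if f == "ok"], dtype=int)


@dataclass
class EnsembleBeat:
    """Representative cardiac cycle on a common uniform grid."""

    time: np.ndarray  # s, from 0
    pa: np.ndarray  # mmHg
    pd: np.ndarray  # mmHg
    u: np.ndarray  # cm/s
    n_beats_averaged: int
    fs: float

    @property
    def cycle_length(self) -> float:
        return len(self.time) / self.fs


@dataclass
class WindowSelection:
    """Rest and hyperemia analysis windows on a continuous recording."""

    rest_window: tuple  # (start s, end s)
    hyperemia_window: tuple  # (start s, end s)
    method_trace: str


# ---------------------------------------------------------------------------
# Trace file format
# ---------------------------------------------------------------------------

_UNITS = {"Pa": "mmHg", "Pd": "mmHg", "U": "cm/s"}


def write_recording(rec: VesselRecording, path, dialect: str = "block") -> None:
    """Write a recording as UTF-8 delimited text.

    ``block`` writes one ``time,value`` block per channel (supports
    dual-rate recordings); ``wide`` writes a shared-time CSV and requires a
    common sampling rate.
    """
    lines = ["# corowave-trace v1"]
    lines.append(f"# vessel_id={rec.vessel_id}")
    lines.append(f"# phase={rec.phase}")
    lines.append(f"# condition={rec.condition}")
    for k, v in rec.metadata.items():
        lines.append(f"# meta {k}={v}")
    if dialect == "block":
        for name, data, fs in (
            ("Pa", rec.pa, rec.fs_pressure),
            ("Pd", rec.pd, rec.fs_pressure),
            ("U", rec.u, rec.fs_velocity),
        ):
            lines.append(f"# channel={name} fs={fs:g} units={_UNITS[name]}")
            t = np.arange(len(data)) / fs
            lines.extend(f"{ti:.17g},{vi:.17g}" for ti, vi in zip(t, data))
    elif dialect == "wide":
        if rec.fs_pressure != rec.fs_velocity or len(rec.pa) != len(rec.u):
            raise FormatError("wide dialect requires a common sampling grid")
        lines.append(f"# fs={rec.fs_pressure:g}")
        lines.append("time,Pa,Pd,U")
        t = rec.time_pressure()
        lines.extend(
            f"{ti:.17g},{a:.17g},{d:.17g},{u:.17g}"
            for ti, a, d, u in zip(t, rec.pa, rec.pd, rec.u)
        )
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_header_kv(line: str) -> dict:
    out = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_recording(path, dialect: str = "auto") -> VesselRecording:
    """Read a trace file written by :func:`write_recording` (either dialect).

    Raises :class:`FormatError` if a required channel (Pa, Pd, U) is absent
    or a time column is not strictly increasing.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if dialect == "auto":
        dialect = "block" if "# channel=" in text else "wide"

    meta: dict = {}
    attrs = {"vessel_id": "unknown", "phase": "pre", "condition": "rest"}
    if dialect == "block":
        channels: dict = {}
        cur_name = None
        cur_rows: list = []
        fs_by_channel: dict = {}

        def _close():
            if cur_name is not None:
                channels[cur_name] = np.array(cur_rows, dtype=float)

        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# channel="):
                    _close()
                    kv = _parse_header_kv(line)
                    cur_name = kv["channel"]
                    fs_by_channel[cur_name] = float(kv["fs"])
                    cur_rows = []
                elif line.startswith("# meta "):
                    k, _, v = line[len("# meta "):].partition("=")
                    meta[k] = v
                else:
                    kv = _parse_header_kv(line)
                    for k in attrs:
                        if k in kv:
                            attrs[k] = kv[k]
            else:
                cur_rows.append([float(x) for x in line.split(",")])
        _close()

        for name in ("Pa", "Pd", "U"):
            if name not in channels or len(channels[name]) == 0:
                raise FormatError(f"missing channel {name!r}")
            t = channels[name][:, 0]
            if np.any(np.diff(t) <= 0):
                raise FormatError(f"non-monotone time column in channel {name!r}")
        rec = VesselRecording(
            vessel_id=attrs["vessel_id"],
            phase=attrs["phase"],
            condition=attrs["condition"],
            pa=channels["Pa"][:, 1],
            pd=channels["Pd"][:, 1],
            u=channels["U"][:, 1],
            fs_pressure=fs_by_channel["Pa"],
            fs_velocity=fs_by_channel["U"],
            metadata=meta,
        )
    else:  # wide
        fs = None
        data_lines = []
        header_cols = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# meta "):
                    k, _, v = line[len("# meta "):].partition("=")
                    meta[k] = v
                else:
                    kv = _parse_header_kv(line)
                    if "fs" in kv:
                        fs = float(kv["fs"])
                    for k in attrs:
                        if k in kv:
                            attrs[k] = kv[k]
            elif header_cols is None and not line[0].isdigit():
                header_cols = [c.strip() for c in line.split(",")]
            else:
                data_lines.append(line)
        if fs is None or header_cols is None:
            raise FormatError("wide trace missing fs header or column header")
        for name in ("Pa", "Pd", "U"):
            if name not in header_cols:
                raise FormatError(f"missing channel {name!r}")
        arr = np.loadtxt(io.StringIO("\n".join(data_lines)), delimiter=",")
        arr = np.atleast_2d(arr)
        cols = {c: arr[:, i] for i, c in enumerate(header_cols)}
        if np.any(np.diff(cols["time"]) <= 0):
            raise FormatError("non-monotone time column")
        rec = VesselRecording(
            vessel_id=attrs["vessel_id"],
            phase=attrs["phase"],
            condition=attrs["condition"],
            pa=cols["Pa"],
            pd=cols["Pd"],
            u=cols["U"],
            fs_pressure=fs,
            fs_velocity=fs,
            metadata=meta,
        )
    return rec.validate()


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------


def smooth_velocity(u: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing of a Doppler velocity trace.

    Second-order polynomial, 11-sample window -- the standard conditioning
    for intracoronary Doppler envelopes before differentiation. Exact on
    locally quadratic signals; the output has the input's length.
    """
    u = np.asarray(u, dtype=float)
    if len(u) < SG_WINDOW:
        raise InsufficientDataError(
            f"velocity series of length {len(u)} shorter than the "
            f"{SG_WINDOW}-sample smoothing window"
        )
    return savgol_filter(u, SG_WINDOW, SG_ORDER, mode="interp")


def resample_to_common_grid(rec: VesselRecording) -> VesselRecording:
    """Upsample the velocity channel onto the pressure grid.

    Pressure carries the wider bandwidth used for the wave-intensity
    derivatives, so velocity is interpolated up (shape-preserving PCHIP)
    rather than pressure decimated down. Identity when the grids already
    coincide.
    """
    if rec.fs_pressure < rec.fs_velocity:
        raise ParameterError("fs_pressure must be >= fs_velocity")
    if rec.fs_pressure == rec.fs_velocity and len(rec.u) == len(rec.pa):
        return rec
    t_u = rec.time_velocity()
    t_p = rec.time_pressure()
    u_new = PchipInterpolator(t_u, rec.u, extrapolate=True)(t_p)
    return replace(rec, u=u_new, fs_velocity=rec.fs_pressure)


def detect_beats(pa: np.ndarray, fs: float) -> BeatIndex:
    """Segment beats from the aortic pressure trace.

    Onsets are placed at the diastolic pressure foot: the local minimum
    preceding each steep systolic upstroke (upstrokes found as prominent
    peaks of the smoothed dP/dt). Beats whose cycle length deviates more
    than 20% from the running median, or falls outside 0.33-1.5 s, are
    flagged ``rejected``.
    """
    pa = np.asarray(pa, dtype=float)
    if len(pa) < 2 * int(MIN_PERIOD_S * fs):
        raise SegmentationError("recording shorter than two beats")
    if np.ptp(pa) < 1e-9:
        raise SegmentationError("flat pressure trace: no beats detectable")

    if len(pa) >= SG_WINDOW:
        pa_s = savgol_filter(pa, SG_WINDOW, SG_ORDER, mode="interp")
        dp = savgol_filter(pa, SG_WINDOW, SG_ORDER, deriv=1, delta=1.0 / fs,
                           mode="interp")
    else:  # pragma: no cover - guarded by the length check above
        pa_s = pa
        dp = np.gradient(pa, 1.0 / fs)

    dp_max = dp.max()
    if dp_max <= 0:
        raise SegmentationError("no rising pressure upstroke found")
    peaks, _ = find_peaks(dp, height=0.5 * dp_max, distance=int(MIN_PERIOD_S * fs))
    if len(peaks) < 2:
        raise SegmentationError(f"found {len(peaks)} upstrokes; need at least 2")

    # Each onset is the diastolic pressure foot (the local minimum before
    # the steepest upstroke). On a noisy trace the foot region is flat and
    # a per-beat minimum wanders badly, so the onset is anchored instead to
    # a precise per-beat fiducial -- the half-height crossing of dP/dt on
    # the rising edge -- shifted by the per-recording median fiducial-to-
    # foot offset (outlier minima are voted out by the median).
    back = int(0.35 * fs)
    fiducials = []
    foot_offsets = []
    for pk in peaks:
        j = pk
        while j > 0 and dp[j - 1] > 0.5 * dp[pk]:
            j -= 1
        fiducials.append(j)
        lo = max(0, pk - back)
        coarse = lo + int(np.argmin(pa_s[lo:pk + 1]))
        a, b = max(lo, coarse - 2), min(pk + 1, coarse + 3)
        foot = a + int(np.argmin(pa[a:b]))  # un-smear the filtered corner
        foot_offsets.append(foot - j)
    offset = int(round(float(np.median(foot_offsets))))
    onsets = np.unique(np.clip(np.asarray(fiducials, dtype=int) + offset,
                               0, len(pa) - 1))
    if len(onsets) < 2:
        raise SegmentationError("fewer than 2 beat onsets")

    intervals = np.diff(onsets) / fs
    flags = []
    for i, iv in enumerate(intervals):
        lo = max(0, i - 4)
        run_med = float(np.median(intervals[lo:i + 5]))
        ok = (
            MIN_PERIOD_S <= iv <= MAX_PERIOD_S
            and abs(iv - run_med) <= CYCLE_DEVIATION_FRAC * run_med
        )
        flags.append("ok" if ok else "rejected")
    return BeatIndex(onsets=onsets, flags=flags, fs=fs)


# ---------------------------------------------------------------------------
# Window selection on continuous recordings
# ---------------------------------------------------------------------------

_ROLL = 10  # beats in the rolling mean used for plateau detection
_PLATEAU_SLOPE_FRAC = 0.02  # per-beat rolling-mean change, fraction of range
_REST_SPAN_S = 15.0


def _rolling_mean(x: np.ndarray, k: int) -> np.ndarray:
    c = np.convolve(x, np.ones(k) / k, mode="valid")
    return c


def select_windows(rec: VesselRecording) -> WindowSelection:
    """Select rest and hyperemia windows on a continuous recording.

    The hyperemia window is the contiguous run of beats on which the 10-beat
    rolling mean of the beat-mean velocity has plateaued (per-beat change
    below 2% of the overall rolling-mean range) above the stimulus midpoint;
    among plateaus the one with the highest mean velocity wins, ties broken
    by later onset. The rest window is the lowest-variance ~15 s span of
    beat-mean velocity before the stimulus onset. Both windows must contain
    at least 8 accepted beats.

    The scoring decisions are logged in ``method_trace``.
    """
    trace: list = []
    rec_c = resample_to_common_grid(rec)
    fs = rec_c.fs_pressure
    beats = detect_beats(rec_c.pa, fs)
    on = beats.onsets
    n_b = beats.n_beats
    if n_b < _ROLL + MIN_BEATS:
        raise SelectionError(
            f"only {n_b} beats; too few to scan for a hyperemic plateau",
            "\n".join(trace),
        )
    bm = np.array([rec_c.u[on[i]:on[i + 1]].mean() for i in range(n_b)])
    t_start = on[:-1] / fs
    t_end = on[1:] / fs

    roll = _rolling_mean(bm, _ROLL)
    rng = float(roll.max() - roll.min())
    noise = 1.4826 * float(np.median(np.abs(np.diff(bm)))) / np.sqrt(2.0)
    trace.append(f"beat-mean U: n={n_b}, rolling range={rng:.3f}, "
                 f"robust noise={noise:.3f}")
    if rng < max(4.0 * noise, 1e-12):
        raise SelectionError(
            "no hyperemic stimulus detected (rolling-mean velocity range "
            "indistinguishable from beat-to-beat noise)",
            "\n".join(trace),
        )

    level = roll.min() + 0.5 * rng
    slope = np.abs(np.diff(roll))
    # plateau flag for rolling positions 1..len(roll)-1
    plat = (slope < _PLATEAU_SLOPE_FRAC * rng) & (roll[1:] > level)

    # contiguous plateau runs -> candidate beat spans
    candidates = []
    j = 0
    while j < len(plat):
        if plat[j]:
            k = j
            while k + 1 < len(plat) and plat[k + 1]:
                k += 1
            b0, b1 = j + 1, min(k + 1 + _ROLL - 1, n_b - 1)
            acc = sum(1 for i in range(b0, b1 + 1) if beats.flags[i] == "ok")
            if acc >= MIN_BEATS:
                score = float(bm[b0:b1 + 1].mean())
                candidates.append((score, b0, b1, acc))
            j = k + 1
        j += 1
    if not candidates:
        raise SelectionError(
            "no hyperemic plateau with at least 8 accepted beats",
            "\n".join(trace),
        )
    best = max(candidates, key=lambda c: (round(c[0] / max(rng, 1e-12), 9), c[1]))
    score, b0, b1, acc = best
    hyp_window = (float(t_start[b0]), float(t_end[b1]))
    trace.append(
        f"hyperemia plateau: beats {b0}-{b1} ({acc} accepted), "
        f"mean U={score:.3f}, window={hyp_window[0]:.2f}-{hyp_window[1]:.2f}s "
        f"among {len(candidates)} candidate plateau(s)"
    )

    # stimulus onset = first rolling window above the midpoint level
    j_stim = int(np.argmax(roll > level))
    pre_end_beat = j_stim  # beats 0..j_stim-1 are pre-stimulus
    rest_best = None
    for a in range(0, pre_end_beat):
        b = a
        while b + 1 < pre_end_beat and t_end[b + 1] - t_start[a] <= _REST_SPAN_S:
            b += 1
        acc = sum(1 for i in range(a, b + 1) if beats.flags[i] == "ok")
        if acc >= MIN_BEATS:
            var = float(bm[a:b + 1].var())
            if rest_best is None or var < rest_best[0]:
                rest_best = (var, a, b)
    if rest_best is None:
        raise SelectionError(
            "no pre-stimulus rest span with at least 8 accepted beats",
            "\n".join(trace),
        )
    var, a, b = rest_best
    rest_window = (float(t_start[a]), float(t_end[b]))
    trace.append(
        f"rest span: beats {a}-{b}, beat-mean U variance={var:.4f}, "
        f"window={rest_window[0]:.2f}-{rest_window[1]:.2f}s"
    )
    return WindowSelection(rest_window=rest_window,
                           hyperemia_window=hyp_window,
                           method_trace="\n".join(trace))


# ---------------------------------------------------------------------------
# Ensemble averaging
# ---------------------------------------------------------------------------

_ALIGN_MAX_SHIFT = 25  # samples of cross-correlation refinement; must cover
#                        the onset jitter of a noisy, flat diastolic foot


def ensemble_average(
    rec: VesselRecording,
    beats: BeatIndex | None = None,
    window: tuple | None = None,
) -> EnsembleBeat:
    """Average accepted beats into a single representative cardiac cycle.

    Beats inside ``window`` (whole recording when None) are extracted at
    their pressure-foot onsets, alignment-refined by cross-correlation of
    the Pa segments (sub-beat onset jitter otherwise smears the systolic
    upstroke), linearly time-normalized to the median cycle length, and
    averaged samplewise per channel.

    Raises :class:`InsufficientBeatsError` when fewer than 8 accepted beats
    fall inside the window.
    """
    rec = resample_to_common_grid(rec)
    fs = rec.fs_pressure
    if beats is None:
        beats = detect_beats(rec.pa, fs)
    on = beats.onsets

    sel = []
    for i in range(beats.n_beats):
        if beats.flags[i] != "ok":
            continue
        t0, t1 = on[i] / fs, on[i + 1] / fs
        if window is not None and (t0 < window[0] or t1 > window[1] + 1e-9):
            continue
        sel.append(i)
    if len(sel) < MIN_BEATS:
        raise InsufficientBeatsError(len(sel), MIN_BEATS)

    lengths = np.array([on[i + 1] - on[i] for i in sel], dtype=float)
    l_min = int(lengths.min())

    # sub-sample alignment: detected onsets carry jitter (the diastolic
    # foot is flat), which would smear the steep systolic upstroke. Beats
    # are cross-correlated against the stack mean, with a parabolic
    # refinement for fractional lags; two passes, because the first
    # reference is itself smeared by the unaligned jitter.
    n_total = len(rec.pa)
    base = np.array([on[i] for i in sel])
    offsets = np.zeros(len(sel))
    for _ in range(2):
        ref = np.mean(
            [rec.pa[int(round(b + o)):int(round(b + o)) + l_min]
             for b, o in zip(base, offsets)
             if 0 <= int(round(b + o)) <= n_total - l_min],
            axis=0)
        ref = ref - ref.mean()
        new_offsets = []
        for i, _b in zip(sel, base):
            cc = {}
            for s in range(-_ALIGN_MAX_SHIFT, _ALIGN_MAX_SHIFT + 1):
                a = on[i] + s
                if a < 0 or a + l_min > n_total:
                    cc[s] = -np.inf
                    continue
                seg = rec.pa[a:a + l_min]
                cc[s] = float(np.dot(seg - seg.mean(), ref))
            # smallest |s| wins ties so identical beats stay untouched
            best_s = max(sorted(cc, key=abs), key=lambda s: cc[s])
            frac = 0.0
            if (cc.get(best_s - 1, -np.inf) > -np.inf
                    and cc.get(best_s + 1, -np.inf) > -np.inf):
                y0, y1, y2 = cc[best_s - 1], cc[best_s], cc[best_s + 1]
                denom = y0 - 2.0 * y1 + y2
                if abs(denom) > 1e-300:
                    frac = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            new_offsets.append(best_s + frac)
        offsets = np.asarray(new_offsets)
        offsets -= offsets.mean()  # keep the phase anchored to the onsets

    starts = np.array([on[i] for i in sel], dtype=float) + offsets
    # refined onset-to-onset spacing where beats are consecutive, so that
    # onset jitter does not masquerade as cycle-length variation
    for k in range(len(sel) - 1):
        if sel[k + 1] == sel[k] + 1:
            lengths[k] = starts[k + 1] - starts[k]
    med = float(np.median(lengths))
    # deviations within onset-quantization noise are not cycle-length
    # variation; stretching by them would inject phase noise
    lengths = np.where(np.abs(lengths - med) <= 2.0, med, lengths)
    n_grid = int(round(med))

    idx_axis = np.arange(n_total, dtype=float)
    grid = np.arange(n_grid, dtype=float)
    acc = {"pa": [], "pd": [], "u": []}
    for a, L in zip(starts, lengths):
        pos = np.clip(a + (L / n_grid) * grid, 0.0, n_total - 1.0)
        acc["pa"].append(np.interp(pos, idx_axis, rec.pa))
        acc["pd"].append(np.interp(pos, idx_axis, rec.pd))
        acc["u"].append(np.interp(pos, idx_axis, rec.u))

    return EnsembleBeat(
        time=np.arange(n_grid) / fs,
        pa=np.mean(acc["pa"], axis=0),
        pd=np.mean(acc["pd"], axis=0),
        u=np.mean(acc["u"], axis=0),
        n_beats_averaged=len(sel),
        fs=fs,
    )
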