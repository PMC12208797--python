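"""Physiologically structured synthetic coronary recordings.

Generates aortic pressure (Pa), distal coronary pressure (Pd) and Doppler
velocity (U) traces with known ground-truth hemodynamics, emulating the
statistical structure the analysis pipeline assumes: a systolic-peaked
pressure, a diastole-dominant velocity with a controllable microvascular
suction wave, a translesional pressure drop proportional to stenosis
resistance, beat-to-beat cycle-length variability and additive sensor noise.

Beat template
-------------
Each beat of period ``T = 60/heart_rate`` is a piecewise-smooth analytic
template. Pressure rises from ``p_dia`` to ``p_sys`` as a raised cosine over
the systolic fraction of the cycle and then relaxes exponentially back to
``p_dia`` at end-diastole. The velocity shape has a small systolic lobe and
a dominant diastolic lobe whose *acceleration* peak (a narrow Gaussian burst
in dU/dt, the suction wave) sits at ``suction_delay_frac`` of the interval
from the pressure peak to end-diastole.

Velocity scaling is analytic: the mean velocity is
``<U> = <Pa> / (MR + R)`` where ``MR`` is the microvascular and ``R`` the
stenosis resistance, and ``Pd = Pa - R * U`` pointwise before noise. These
choices make the ground-truth indices exact algebraic functions of the
parameters::

    FFR = MR / (MR + R)      hSR = R       hMR = MR      bMR = MR_rest

so recovery error measured against ground truth isolates pipeline error
from generation error. ``suction_gain`` rescales the diastolic lobe within
a mean-normalized shape, so it changes wave morphology without moving the
mean velocity (matched-velocity behaviour by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import GenerationError, ParameterError
from .signalio import VesselRecording

_VALID_FS = (100.0, 120.0, 200.0)

#: dimensionless velocity-shape constants
_U_BASELINE = 0.3
_U_SYS_LOBE = 0.5
_U_DIA_LOBE = 1.0
_SUCTION_WIDTH_FRAC = 0.05  # Gaussian sd of the suction burst, fraction of
#                             the expansion period
_DROP_WIDTH_FRAC = 0.20  # burst width seen by the translesional pressure
#                          drop: vessel compliance between lesion and sensor
#                          buffers fast flow transients, so the drop follows
#                          a broadened velocity waveform (same mean)
_DECAY_TAU_FRAC = 0.22  # diastolic pressure decay constant, fraction of
#                         the expansion period

_FINE_N = 8192  # samples used for analytic (noiseless) period means

REJECTION_CAP = 1000  # max draws per vessel when enforcing group membership


@dataclass(frozen=True)
class BeatParams:
    """Generator controls for one vessel x condition x phase."""

    heart_rate: float = 70.0  # beats/min
    p_sys: float = 120.0  # mmHg systolic aortic peak
    p_dia: float = 75.0  # mmHg end-diastolic aortic pressure
    systole_fraction: float = 0.35  # fraction of the cycle before decay onset
    stenosis_resistance: float = 0.25  # mmHg.cm-1.s (= target hSR)
    microvascular_resistance: float = 2.0  # mmHg.cm-1.s (= target MR)
    suction_delay_frac: float = 0.20  # BEW position within the expansion phase
    suction_gain: float = 1.0  # scales diastolic velocity acceleration
    noise_sd_p: float = 0.0  # mmHg
    noise_sd_u: float = 0.0  # cm/s
    fs_pressure: float = 200.0  # Hz
    fs_velocity: float = 100.0  # Hz
    hr_jitter_frac: float = 0.0  # sd of per-beat cycle-length variability
    seed: int = 0

    def validate(self) -> "BeatParams":
        if not (self.p_sys > self.p_dia > 0):
            raise ParameterError(
                f"require p_sys > p_dia > 0, got p_sys={self.p_sys}, "
                f"p_dia={self.p_dia}"
            )
        if not (0.0 < self.systole_fraction < 1.0):
            raise ParameterError(
                f"systole_fraction must lie in (0, 1), got {self.systole_fraction}"
            )
        if not (40.0 <= self.heart_rate <= 140.0):
            raise ParameterError(
                f"heart_rate must lie in [40, 140] bpm, got {self.heart_rate}"
            )
        if self.stenosis_resistance < 0 or self.microvascular_resistance < 0:
            raise ParameterError("resistances must be >= 0")
        if self.microvascular_resistance + self.stenosis_resistance <= 0:
            raise ParameterError("total resistance must be positive")
        if not (0.0 <= self.suction_delay_frac < 1.0):
            raise ParameterError(
                f"suction_delay_frac must lie in [0, 1), got {self.suction_delay_frac}"
            )
        if self.suction_gain < 0:
            raise ParameterError(f"suction_gain must be >= 0, got {self.suction_gain}")
        if self.noise_sd_p < 0 or self.noise_sd_u < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        for fs in (self.fs_pressure, self.fs_velocity):
            if float(fs) not in _VALID_FS:
                raise ParameterError(
                    f"sampling rate must be one of {_VALID_FS} Hz, got {fs}"
                )
        if self.fs_pressure < self.fs_velocity:
            raise ParameterError("fs_pressure must be >= fs_velocity")
        if not (0.0 <= self.hr_jitter_frac < 0.15):
            raise ParameterError("hr_jitter_frac must lie in [0, 0.15)")
        return self

    # -- analytic template -------------------------------------------------

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def t_systole(self) -> float:
        return self.systole_fraction * self.period

    def pa_template(self, tau: np.ndarray) -> np.ndarray:
        """Aortic pressure over one beat, tau in [0, T)."""
        tau = np.asarray(tau, dtype=float)
        T, ts = self.period, self.t_systole
        dp = self.p_sys - self.p_dia
        tau_d = _DECAY_TAU_FRAC * (T - ts)
        e = np.exp(-(T - ts) / tau_d)
        p_end = (self.p_dia - self.p_sys * e) / (1.0 - e)
        out = np.where(
            tau < ts,
            self.p_dia + 0.5 * dp * (1.0 - np.cos(np.pi * tau / ts)),
            p_end + (self.p_sys - p_end) * np.exp(-(tau - ts) / tau_d),
        )
        return out

    def u_shape(self, tau: np.ndarray, width_frac: float = _SUCTION_WIDTH_FRAC
                ) -> np.ndarray:
        """Unnormalized velocity shape over one beat.

        The diastolic lobe rises from exactly zero at the systolic peak (a
        truncated-renormalized Gaussian CDF) so the expansion-phase anchor
        is not perturbed by the lobe's tail.
        """
        tau = np.asarray(tau, dtype=float)
        T, ts = self.period, self.t_systole
        D = T - ts
        t_bew = ts + self.suction_delay_frac * D
        sigma = width_frac * D
        sys_lobe = np.where(
            tau < ts, _U_SYS_LOBE * np.sin(np.pi * tau / ts) ** 2, 0.0
        )
        taper = np.where(
            tau >= ts, np.cos(0.5 * np.pi * (tau - ts) / D), 0.0
        )
        cdf0 = float(ndtr((ts - t_bew) / sigma))
        lobe = np.clip((ndtr((tau - t_bew) / sigma) - cdf0) / (1.0 - cdf0),
                       0.0, None)
        dia_lobe = np.where(
            tau >= ts, self.suction_gain * _U_DIA_LOBE * lobe * taper, 0.0
        )
        return _U_BASELINE + sys_lobe + dia_lobe

    def analytic_means(self) -> tuple:
        """Noiseless period means (<Pa>, <U>, shape mean, drop-shape mean)."""
        tau = np.arange(_FINE_N) * (self.period / _FINE_N)
        pa_mean = float(self.pa_template(tau).mean())
        m_shape = float(self.u_shape(tau).mean())
        m_drop = float(self.u_shape(tau, width_frac=_DROP_WIDTH_FRAC).mean())
        u_mean = pa_mean / (
            self.microvascular_resistance + self.stenosis_resistance
        )
        return pa_mean, u_mean, m_shape, m_drop

    @property
    def velocity_scale(self) -> float:
        """Analytic mean velocity <U> = <Pa> / (MR + R), cm/s."""
        return self.analytic_means()[1]

    def u_template(self, tau: np.ndarray) -> np.ndarray:
        """Velocity over one beat, cm/s, with mean ``velocity_scale``."""
        _, u_mean, m_shape, _ = self.analytic_means()
        return (u_mean / m_shape) * self.u_shape(tau)

    def drop_template(self, tau: np.ndarray) -> np.ndarray:
        """Velocity waveform driving the translesional drop, cm/s.

        Same template with the suction burst broadened to the compliance
        width and renormalized to the same mean, so
        ``<Pd> = <Pa> - R * <U>`` holds exactly while the drop does not
        inherit the burst's sharpness.
        """
        _, u_mean, _, m_drop = self.analytic_means()
        return (u_mean / m_drop) * self.u_shape(tau, width_frac=_DROP_WIDTH_FRAC)


@dataclass
class VesselTruth:
    """Ground-truth indices implied by the generating parameters.

    Defined on the noiseless analytic template, so recovery error measured
    against these values isolates pipeline error from generation noise.
    """

    vessel_id: str
    indices: dict  # (phase,) -> {"ffr","hsr","hmr","bmr","cfvr","bapv","hapv","deltap"}
    suction_delay: dict  # (phase, condition) -> float
    suction_gain: dict  # (phase, condition) -> float
    onsets: dict  # (phase, condition) -> array of beat onset times, s
    group: str | None = None

    def as_row(self) -> dict:
        row = {"vessel_id": self.vessel_id, "true_group": self.group}
        for phase, d in self.indices.items():
            for k, v in d.items():
                row[f"true_{k}_{phase}"] = v
        for (phase, cond), v in self.suction_delay.items():
            row[f"delay_{cond}_{phase}"] = v
        return row


# ---------------------------------------------------------------------------
# Single-recording synthesis
# ---------------------------------------------------------------------------


def _beat_boundaries(params: BeatParams, n_beats: int, rng) -> np.ndarray:
    T = params.period
    if params.hr_jitter_frac > 0:
        factors = 1.0 + params.hr_jitter_frac * rng.standard_normal(n_beats)
        factors = np.clip(factors, 0.6, 1.4)
    else:
        factors = np.ones(n_beats)
    periods = T * factors
    return np.concatenate([[0.0], np.cumsum(periods)])


def _eval_train(fn, t: np.ndarray, bounds: np.ndarray, T_ref: float) -> np.ndarray:
    """Evaluate a one-beat template over a multi-beat time axis.

    Local beat time is rescaled to the reference period so jittered beats
    are uniformly time-dilated copies of the template.
    """
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(bounds) - 2)
    local = (t - bounds[idx]) / (bounds[idx + 1] - bounds[idx]) * T_ref
    return fn(np.clip(local, 0.0, np.nextafter(T_ref, 0.0)))


def synth_beat(
    params: BeatParams,
    n_beats: int,
    vessel_id: str = "synthetic",
    phase: str = "pre",
    condition: str = "rest",
) -> VesselRecording:
    """Generate a recording of ``n_beats`` beats from one parameter set.

    Pd equals ``Pa - stenosis_resistance * U`` before noise; sensor noise is
    independent Gaussian per sample and channel. Reproducible for a fixed
    ``params.seed``.
    """
    params.validate()
    if n_beats < 1:
        raise ParameterError(f"n_beats must be >= 1, got {n_beats}")
    rng = np.random.default_rng(params.seed)
    bounds = _beat_boundaries(params, n_beats, rng)
    duration = bounds[-1]
    T = params.period

    n_p = int(round(duration * params.fs_pressure))
    n_u = int(round(duration * params.fs_velocity))
    t_p = np.arange(n_p) / params.fs_pressure
    t_u = np.arange(n_u) / params.fs_velocity

    pa = _eval_train(params.pa_template, t_p, bounds, T)
    drop_on_p = _eval_train(params.drop_template, t_p, bounds, T)
    pdist = pa - params.stenosis_resistance * drop_on_p
    u = _eval_train(params.u_template, t_u, bounds, T)

    if params.noise_sd_p > 0:
        pa = pa + params.noise_sd_p * rng.standard_normal(n_p)
        pdist = pdist + params.noise_sd_p * rng.standard_normal(n_p)
    if params.noise_sd_u > 0:
        u = u + params.noise_sd_u * rng.standard_normal(n_u)

    return VesselRecording(
        vessel_id=vessel_id,
        phase=phase,
        condition=condition,
        pa=pa,
        pd=pdist,
        u=u,
        fs_pressure=params.fs_pressure,
        fs_velocity=params.fs_velocity,
        metadata={"onsets": ",".join(f"{b:.6f}" for b in bounds[:-1])},
    )


def hyperemic_params(
    rest: BeatParams,
    velocity_multiplier: float,
    suction_delay_frac: float | None = None,
    suction_gain: float | None = None,
    seed: int | None = None,
) -> BeatParams:
    """Derive hyperemic parameters giving exactly ``CFVR = velocity_multiplier``.

    Adenosine hyperemia is modeled as microvascular dilation at a fixed
    stenosis resistance: the hyperemic microvascular resistance is set to
    ``(MR_rest + R) / multiplier - R`` so the analytic mean velocity scales
    by exactly the multiplier (aortic pressure unchanged).
    """
    if velocity_multiplier <= 1.0:
        raise ParameterError(
            f"hyperemia velocity multiplier must be > 1, got {velocity_multiplier}"
        )
    R = rest.stenosis_resistance
    mr_hyp = (rest.microvascular_resistance + R) / velocity_multiplier - R
    if mr_hyp < 0:
        raise ParameterError(
            "velocity multiplier too large for this stenosis resistance: "
            "implied hyperemic microvascular resistance would be negative"
        )
    kw: dict = {"microvascular_resistance": mr_hyp}
    if suction_delay_frac is not None:
        kw["suction_delay_frac"] = suction_delay_frac
    if suction_gain is not None:
        kw["suction_gain"] = suction_gain
    if seed is not None:
        kw["seed"] = seed
    return replace(rest, **kw)


def _truth_indices(rest: BeatParams, hyp: BeatParams) -> dict:
    pa_mean_r, u_r = rest.analytic_means()[:2]
    pa_mean_h, u_h = hyp.analytic_means()[:2]
    R = hyp.stenosis_resistance
    mr_h = hyp.microvascular_resistance
    return {
        "ffr": mr_h / (mr_h + R),
        "hsr": R,
        "hmr": mr_h,
        "bmr": rest.microvascular_resistance,
        "cfvr": u_h / u_r,
        "bapv": u_r,
        "hapv": u_h,
        "deltap": R * u_h,
        "pa_rest": pa_mean_r,
        "pa_hyp": pa_mean_h,
    }


def synth_vessel(
    pre_rest: BeatParams,
    pre_hyp: BeatParams,
    post_rest: BeatParams,
    post_hyp: BeatParams,
    n_beats: int = 16,
    vessel_id: str = "V001",
) -> tuple:
    """Generate the four recordings (pre/post x rest/hyperemia) for a vessel.

    Ground truth is computed from the analytic relations on the noiseless
    templates. Hyperemic parameters must imply a higher mean velocity than
    the resting ones.
    """
    for phase, r, h in (("pre", pre_rest, pre_hyp), ("post", post_rest, post_hyp)):
        if h.velocity_scale <= r.velocity_scale:
            raise ParameterError(
                f"{phase}-PCI hyperemic velocity scale must exceed resting "
                f"(implied multiplier <= 1)"
            )
    combos = {
        ("pre", "rest"): pre_rest,
        ("pre", "hyperemia"): pre_hyp,
        ("post", "rest"): post_rest,
        ("post", "hyperemia"): post_hyp,
    }
    recordings = {}
    onsets = {}
    for (phase, cond), p in combos.items():
        rec = synth_beat(p, n_beats, vessel_id=vessel_id, phase=phase,
                         condition=cond)
        recordings[(phase, cond)] = rec
        onsets[(phase, cond)] = np.array(
            [float(x) for x in rec.metadata["onsets"].split(",")]
        )
    truth = VesselTruth(
        vessel_id=vessel_id,
        indices={
            "pre": _truth_indices(pre_rest, pre_hyp),
            "post": _truth_indices(post_rest, post_hyp),
        },
        suction_delay={k: p.suction_delay_frac for k, p in combos.items()},
        suction_gain={k: p.suction_gain for k, p in combos.items()},
        onsets=onsets,
    )
    return recordings, truth


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dist:
    """Gaussian parameter distribution (sd = 0 gives a constant)."""

    mean: float
    sd: float = 0.0

    def draw(self, rng) -> float:
        return self.mean + self.sd * rng.standard_normal()


def _default_delay(post_hyp_mean: float = 0.20, post_hyp_sd: float = 0.06) -> dict:
    return {
        ("pre", "rest"): Dist(0.22, 0.08),
        ("pre", "hyperemia"): Dist(0.28, 0.08),
        ("post", "rest"): Dist(0.17, 0.05),
        ("post", "hyperemia"): Dist(post_hyp_mean, post_hyp_sd),
    }


def _default_gain(post_hyp_mean: float = 1.0) -> dict:
    return {
        ("pre", "rest"): Dist(0.9, 0.12),
        ("pre", "hyperemia"): Dist(1.0, 0.12),
        ("post", "rest"): Dist(1.0, 0.12),
        ("post", "hyperemia"): Dist(post_hyp_mean, 0.12),
    }


@dataclass
class GroupSpec:
    """Parameter distributions for one stratum of the synthetic cohort."""

    heart_rate: Dist = Dist(70.0, 6.0)
    p_sys: Dist = Dist(122.0, 6.0)
    p_dia: Dist = Dist(72.0, 4.0)
    systole_fraction: Dist = Dist(0.35, 0.02)
    # post-PCI coronary flow velocity reserve; the basal microvascular
    # resistance is derived from it (bMR = CFVR*(hMR+hSR) - hSR) so flow
    # reserve is a stratum-independent property, as observed
    cfvr_post: Dist = Dist(2.47, 0.55)
    # hyperemic microvascular resistance pre-PCI; None derives it from the
    # cohort-level hyperemia velocity multiplier instead
    hmr_pre: Dist | None = Dist(2.43, 0.9)
    stenosis_resistance_pre: Dist = Dist(1.55, 1.0)
    stenosis_resistance_post: Dist = Dist(0.21, 0.13)
    total_hyp_resistance_post: Dist = Dist(2.05, 0.75)  # hMR + hSR, post
    # aortic pressure co-varies with total resistance (autoregulatory
    # pressure-resistance coupling); exponent 0 would make them independent
    pressure_resistance_coupling: float = 0.6
    suction_delay: dict = field(default_factory=_default_delay)
    suction_gain: dict = field(default_factory=_default_gain)
    # post-PCI FFR admissibility band for this stratum
    ffr_post_range: tuple = (0.82, 0.995)
    # when set, post-PCI FFR is drawn directly and the stenosis resistance
    # derived as (1-FFR)*(hMR+hSR); otherwise the stenosis resistance is
    # drawn and truncated to the FFR band
    ffr_post: Dist | None = None


def default_concordant_spec() -> GroupSpec:
    return GroupSpec()


def default_discordant_spec() -> GroupSpec:
    """Residual-low-FFR stratum: delayed, weaker suction at matched velocity."""
    return GroupSpec(
        stenosis_resistance_post=Dist(0.52, 0.17),
        # slightly higher total resistance: absorbs part of the hMR gap the
        # FFR band forces at equal totals, keeping both hMR and hAPV
        # contrasts within their observed null behaviour
        total_hyp_resistance_post=Dist(2.50, 0.75),
        suction_delay=_default_delay(post_hyp_mean=0.29, post_hyp_sd=0.08),
        suction_gain=_default_gain(post_hyp_mean=0.65),
        ffr_post_range=(0.40, 0.78),
        ffr_post=Dist(0.765, 0.02),
    )


@dataclass
class CohortSpec:
    """Specification of a synthetic study cohort."""

    n_concordant: int = 53
    n_discordant: int = 10
    concordant: GroupSpec = field(default_factory=default_concordant_spec)
    discordant: GroupSpec = field(default_factory=default_discordant_spec)
    hyperemia_velocity_multiplier: float = 2.5  # fallback when no hyperemic
    #                                             resistance dist is given
    n_beats: int = 16
    noise_sd_p: float = 1.0  # mmHg
    noise_sd_u: float = 1.0  # cm/s
    hr_jitter_frac: float = 0.02
    fs_pressure: float = 200.0
    fs_velocity: float = 100.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_concordant + self.n_discordant < 2:
            raise ParameterError("cohort must contain at least 2 vessels")
        if self.n_concordant < 0 or self.n_discordant < 0:
            raise ParameterError("group sizes must be nonnegative")
        if self.hyperemia_velocity_multiplier <= 1.0:
            raise ParameterError("hyperemia_velocity_multiplier must be > 1")
        return self


def _draw_positive(dist: Dist, rng, lo: float, hi: float = np.inf) -> float:
    for _ in range(REJECTION_CAP):
        x = dist.draw(rng)
        if lo <= x <= hi:
            return x
    raise GenerationError(
        f"could not draw a value in [{lo}, {hi}] from "
        f"Dist(mean={dist.mean}, sd={dist.sd}) in {REJECTION_CAP} tries"
    )


def _draw_vessel_params(spec: CohortSpec, g: GroupSpec, rng) -> dict:
    """Draw one vessel's BeatParams set, rejecting until constraints hold."""
    lo_ffr, hi_ffr = g.ffr_post_range
    for _ in range(REJECTION_CAP):
        hr = _draw_positive(g.heart_rate, rng, 45.0, 130.0)
        p_dia = _draw_positive(g.p_dia, rng, 50.0, 110.0)
        p_sys = _draw_positive(g.p_sys, rng, p_dia + 20.0, 200.0)
        sf = _draw_positive(g.systole_fraction, rng, 0.25, 0.45)
        # the total hyperemic resistance (hMR + hSR), which alone sets the
        # hyperemic velocity, is drawn from a distribution shared by both
        # strata; the stenosis share is then drawn inside the FFR band
        # implied by that total (FFR = 1 - R/total), so group membership
        # never biases the velocity scale
        total_post = _draw_positive(g.total_hyp_resistance_post, rng, 0.6, 6.0)
        # autoregulatory coupling: mean aortic pressure scales with total
        # resistance (pulse pressure preserved), keeping hyperemic
        # velocities in a physiologic band
        pa_scale = (total_post / 2.05) ** g.pressure_resistance_coupling
        pulse = p_sys - p_dia
        p_dia = float(np.clip(p_dia * pa_scale, 48.0, 115.0))
        p_sys = p_dia + pulse
        r_lo = max(0.02, (1.0 - hi_ffr) * total_post)
        r_hi = min(0.79, (1.0 - lo_ffr) * total_post, total_post - 0.3)
        if r_hi < r_lo:
            continue
        if g.ffr_post is not None:
            ffr = _draw_positive(g.ffr_post, rng, lo_ffr, hi_ffr)
            r_post = (1.0 - ffr) * total_post
            if not (r_lo <= r_post <= r_hi):
                continue
        else:
            try:
                r_post = _draw_positive(g.stenosis_resistance_post, rng,
                                        r_lo, r_hi)
            except GenerationError:
                continue  # R band unreachable at this total; redraw
        hmr_post = total_post - r_post
        r_pre = _draw_positive(g.stenosis_resistance_pre, rng, 0.15, 8.0)
        cfvr_post = _draw_positive(g.cfvr_post, rng, 1.2, 5.0)
        bmr = cfvr_post * total_post - r_post
        if not (1.5 <= bmr <= 12.0):
            continue
        # hyperemic velocity must exceed resting in both phases; the pre-PCI
        # hyperemic resistance draw is truncated below the basal one rather
        # than rejecting the vessel, to avoid biasing the shared draws
        if bmr < hmr_post + 0.3:
            continue
        if g.hmr_pre is None:
            mult = spec.hyperemia_velocity_multiplier
            hmr_pre = (bmr + r_pre) / mult - r_pre
            if hmr_pre < 0.3:
                continue
        else:
            if bmr - 0.3 < 0.5:
                continue
            hmr_pre = _draw_positive(g.hmr_pre, rng, 0.5,
                                     min(6.0, bmr - 0.3))
        delays = {k: float(np.clip(d.draw(rng), 0.03, 0.92))
                  for k, d in g.suction_delay.items()}
        gains = {k: max(0.2, float(d.draw(rng)))
                 for k, d in g.suction_gain.items()}
        # physiologic feasibility: the phasic translesional drop must not
        # push distal pressure below ~5 mmHg at any point of the cycle
        mr_map = {
            ("pre", "rest"): (bmr, r_pre),
            ("pre", "hyperemia"): (hmr_pre, r_pre),
            ("post", "rest"): (bmr, r_post),
            ("post", "hyperemia"): (hmr_post, r_post),
        }
        feasible = True
        for key, (m, r) in mr_map.items():
            probe = BeatParams(
                heart_rate=hr, p_sys=p_sys, p_dia=p_dia, systole_fraction=sf,
                microvascular_resistance=m, stenosis_resistance=r,
                suction_delay_frac=delays[key], suction_gain=gains[key],
            )
            tau = np.arange(512) * (probe.period / 512)
            pd_min = float(np.min(probe.pa_template(tau)
                                  - r * probe.drop_template(tau)))
            if pd_min < 5.0:
                feasible = False
                break
        if not feasible:
            continue
        return {
            "heart_rate": hr, "p_sys": p_sys, "p_dia": p_dia,
            "systole_fraction": sf,
            "r_pre": r_pre, "r_post": r_post,
            "hmr_pre": hmr_pre, "hmr_post": hmr_post, "bmr": bmr,
            "delays": delays, "gains": gains,
        }
    raise GenerationError(
        f"could not satisfy group constraints (post-PCI FFR in "
        f"[{lo_ffr}, {hi_ffr}], hSR < 0.8) in {REJECTION_CAP} draws"
    )


def synth_cohort(spec: CohortSpec | None = None) -> tuple:
    """Generate a full synthetic cohort.

    Returns ``(recordings, truth)`` where ``recordings`` maps vessel_id to
    the four (phase, condition) recordings and ``truth`` is a DataFrame of
    ground-truth indices with one row per vessel. Deterministic under
    ``spec.seed``.
    """
    spec = (spec or CohortSpec()).validate()
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_concordant + spec.n_discordant
    children = ss.spawn(n_total)

    recordings: dict = {}
    rows = []
    groups = (["concordant"] * spec.n_concordant
              + ["discordant"] * spec.n_discordant)
    for i, group in enumerate(groups):
        g = spec.concordant if group == "concordant" else spec.discordant
        rng = np.random.default_rng(children[i])
        draw = _draw_vessel_params(spec, g, rng)
        vessel_id = f"V{i + 1:03d}"
        base = dict(
            heart_rate=draw["heart_rate"], p_sys=draw["p_sys"],
            p_dia=draw["p_dia"], systole_fraction=draw["systole_fraction"],
            noise_sd_p=spec.noise_sd_p, noise_sd_u=spec.noise_sd_u,
            fs_pressure=spec.fs_pressure, fs_velocity=spec.fs_velocity,
            hr_jitter_frac=spec.hr_jitter_frac,
        )
        mr = {
            ("pre", "rest"): (draw["bmr"], draw["r_pre"]),
            ("pre", "hyperemia"): (draw["hmr_pre"], draw["r_pre"]),
            ("post", "rest"): (draw["bmr"], draw["r_post"]),
            ("post", "hyperemia"): (draw["hmr_post"], draw["r_post"]),
        }
        params = {}
        for j, (key, (m, r)) in enumerate(mr.items()):
            params[key] = BeatParams(
                **base,
                microvascular_resistance=m,
                stenosis_resistance=r,
                suction_delay_frac=draw["delays"][key],
                suction_gain=draw["gains"][key],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        recs, truth = synth_vessel(
            params[("pre", "rest")], params[("pre", "hyperemia")],
            params[("post", "rest")], params[("post", "hyperemia")],
            n_beats=spec.n_beats, vessel_id=vessel_id,
        )
        truth.group = group
        recordings[vessel_id] = recs
        rows.append(truth.as_row())

    truth_table = pd.DataFrame(rows).set_index("vessel_id", drop=False)
    return recordings, truth_table


def synth_transition(
    rest: BeatParams,
    hyp: BeatParams,
    t_rest: float = 30.0,
    t_ramp: float = 5.0,
    t_hyp: float = 25.0,
    vessel_id: str = "synthetic",
    phase: str = "pre",
) -> VesselRecording:
    """Continuous recording spanning an adenosine hyperemia induction.

    The velocity scale ramps linearly from the resting to the hyperemic
    level over ``t_ramp`` seconds starting at ``t_rest``; pressure keeps the
    resting template and Pd tracks the instantaneous translesional drop.
    Used to exercise automatic rest/hyperemia window selection.
    """
    rest.validate()
    hyp.validate()
    u_r, u_h = rest.velocity_scale, hyp.velocity_scale
    if u_h <= u_r:
        raise ParameterError("hyperemic velocity scale must exceed resting")
    rng = np.random.default_rng(rest.seed)
    duration = t_rest + t_ramp + t_hyp
    n_beats = int(np.ceil(duration / rest.period)) + 1
    bounds = _beat_boundaries(rest, n_beats, rng)
    duration = min(duration, bounds[-1])

    n_p = int(round(duration * rest.fs_pressure))
    n_u = int(round(duration * rest.fs_velocity))
    t_p = np.arange(n_p) / rest.fs_pressure
    t_u = np.arange(n_u) / rest.fs_velocity

    def frac(t):
        return np.clip((t - t_rest) / t_ramp, 0.0, 1.0)

    _, _, m_shape, m_drop = rest.analytic_means()

    def u_of(t):
        scale = u_r + (u_h - u_r) * frac(t)
        return (scale / m_shape) * _eval_train(rest.u_shape, t, bounds, rest.period)

    def drop_of(t):
        scale = u_r + (u_h - u_r) * frac(t)
        wide = _eval_train(
            lambda x: rest.u_shape(x, width_frac=_DROP_WIDTH_FRAC),
            t, bounds, rest.period,
        )
        return (scale / m_drop) * wide

    pa = _eval_train(rest.pa_template, t_p, bounds, rest.period)
    pdist = pa - rest.stenosis_resistance * drop_of(t_p)
    u = u_of(t_u)

    if rest.noise_sd_p > 0:
        pa = pa + rest.noise_sd_p * rng.standard_normal(n_p)
        pdist = pdist + rest.noise_sd_p * rng.standard_normal(n_p)
    if rest.noise_sd_u > 0:
        u = u + rest.noise_sd_u * rng.standard_normal(n_u)

    return VesselRecording(
        vessel_id=vessel_id, phase=phase, condition="continuous",
        pa=pa, pd=pdist, u=u,
        fs_pressure=rest.fs_pressure, fs_velocity=rest.fs_velocity,
        metadata={"t_stimulus": f"{t_rest:.3f}", "t_ramp": f"{t_ramp:.3f}"},
    )
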