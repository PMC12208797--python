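# Methods

This note documents the models, numerical choices and known limitations of
the corowave package: what the analysis pipeline assumes, what the
synthetic generator emulates, and where the design was genuinely open.

## Signal model and conditioning

A recording is three channels — aortic pressure Pa and distal coronary
pressure Pd (mmHg, shared rate `fs_pressure`) and Doppler average peak
velocity U (cm/s, rate `fs_velocity` ≤ `fs_pressure`). Supported rates are
100, 120 and 200 Hz, the rates of the dual-sensor guidewire consoles this
data comes from.

**Velocity smoothing.** The Doppler envelope is filtered with a
second-order Savitzky–Golay filter, window 11 samples, applied to velocity
only. SG filtering is exact on locally quadratic signals and has a
white-noise variance reduction factor equal to the sum of squared
center-point coefficients (~0.21 for order 2, window 11); both properties
are asserted in the tests.

**Resampling.** Velocity is upsampled onto the pressure grid with
shape-preserving PCHIP interpolation; pressure is never decimated, because
dP/dt carries the wave-intensity bandwidth. Under 1 cm/s sensor noise the
choice of PCHIP vs a cubic spline was verified to be immaterial.

**Beat detection.** Onsets sit at the diastolic pressure foot — the local
minimum preceding the steepest systolic upstroke. Because the diastolic
tail of a pressure trace is nearly flat, a per-beat minimum wanders badly
under noise; the detector therefore anchors each beat at a precise
fiducial (the half-height crossing of the smoothed dP/dt on the rising
edge, jitter ≈ 1–2 samples) and places onsets a fixed, per-recording
median fiducial-to-foot offset earlier. Beats whose cycle length deviates
more than 20% from a running median, or falls outside 0.33–1.5 s, are
flagged rejected — a surrogate for a manual signal-quality screen.

**Ensemble averaging.** At least 8 accepted beats are required. Beats are
aligned by cross-correlation of their Pa segments against the stack mean
(two passes; parabolic interpolation of the correlation peak gives
fractional-sample lags, which are centered so the ensemble phase stays
anchored to the detected onsets), linearly time-normalized to the median
cycle length, and averaged samplewise. Cycle-length deviations within ±2
samples of the median are treated as quantization noise, not physiology,
and are not stretched. With 16 beats at σ = 1 mmHg / 1 cm/s the ensemble
residual against the noiseless cycle is ≈ 0.2σ per channel (the comparison
aligns the two cycles to sub-sample phase first, since a representative
cycle is defined only up to a circular phase).

**Window selection.** On a continuous recording spanning an adenosine
induction, the hyperemia window is the contiguous run of beats whose
10-beat rolling mean of beat-mean velocity has plateaued (per-beat change
< 2% of the overall rolling-mean range) above the stimulus midpoint;
among plateaus the highest mean wins, ties resolved to the later onset.
The rest window is the lowest-variance ~15 s pre-stimulus span. A
recording whose rolling-mean range is indistinguishable from beat-to-beat
noise (< 4× a robust MAD estimate) has no stimulus and is rejected. All
scores are logged in `method_trace`. The thresholds operationalize a
"maximum mean change with visual approval" procedure that has no unique
algorithmic form; they are shift- and scale-invariant in velocity.

## Indices

All indices are trapezoidal time-averages over the ensemble cycle, so the
conventional set and the WIA describe the same representative beat.
Whether averages should be taken over the raw window instead is a
second-order choice (the ensemble is the mean of the windowed beats; the
two differ only through beat rejection and time normalization).

Two identities tie the definitions together and serve as internal
consistency checks at 1e-12: FFR = hMR/(hMR + hSR), and
MRR = RRR · (⟨Pa_rest⟩/⟨Pd_rest⟩). Stratification boundaries follow the
conventional cutoffs exactly as printed: FFR abnormal at ≤ 0.80, hSR
normal strictly below 0.80; a vessel with hSR ≥ 0.80 is its own category
regardless of FFR.

## Net wave intensity

WI(t) = (dP/dt)(dU/dt) with Pd in Pa (1 mmHg = 133.322 Pa) and U in m/s.
Derivatives are SG first derivatives (order 2, window 11) with cyclic
boundary handling — the ensemble beat is periodic. Net WI (no wave-speed
separation) is used throughout: single-point wave-speed estimation is not
part of the pipeline, and the four waves are classified by the derivative
sign quadrant, with a dead band leaving samples unlabeled when either
derivative is below 1% of its own maximum (labels only; peak amplitudes
are maxima and are unaffected above threshold).

The expansion phase is anchored at the maximum of the *distal* pressure —
the sensor pair the WIA operates on — and runs to the end of the cycle.
Compression waves (FCW, BCW) are searched before the expansion onset,
expansion waves (FEW, BEW) within it. Peak times and values are refined by
a three-point parabola (offset clamped to half a sample), which makes
tBEW_peak insensitive to grid quantization: the 60 vs 90 bpm invariance
holds within 0.01. A missing BEW raises an error rather than reporting a
silent zero; other absent waves are NaN. Peak amplitudes are reported in
units of 10 kW·m⁻²·s⁻², the conventional magnitude scale. The
accelerating-energy fraction is the |WI| integral over FCW+BEW-labeled
samples divided by the integral over all labeled samples.

## The synthetic generator

Each beat is a piecewise-smooth analytic template: a raised-cosine
systolic upstroke from `p_dia` to `p_sys` over `systole_fraction` of the
cycle, then an exponential relaxation back to `p_dia` (time constant 0.22
of the expansion period — a fairly fast decay typical of hyperemic distal
traces). The velocity shape is a baseline plus a small systolic lobe plus
a dominant diastolic lobe whose *acceleration* is a narrow Gaussian burst
(sd 5% of the expansion period) centered at `suction_delay_frac` of the
interval from the pressure peak to end-diastole — the ground truth for
tBEW_peak. `suction_gain` scales the diastolic lobe inside a
mean-normalized shape, so suction strength and mean velocity are
independent controls.

Velocity scaling is analytic: ⟨U⟩ = ⟨Pa⟩/(MR + R) with MR the
microvascular and R the stenosis resistance, and the translesional drop
has mean R·⟨U⟩, which makes the ground-truth indices exact algebraic
functions of the parameters (hSR = R, hMR = MR, FFR = MR/(MR+R), CFVR a
ratio of velocity scales). Ground truth is defined on the noiseless
template, so recovery error isolates pipeline error from generation
noise. `hyperemic_params` models adenosine as microvascular dilation at
fixed R, choosing MR_hyp so CFVR equals a requested multiplier exactly.

**The pressure drop is compliance-filtered.** The drop is R times a copy
of the velocity waveform whose suction burst is broadened to 20% of the
expansion period (same mean). A drop that followed the sharp burst
pointwise would make the distal pressure decay — and hence the BEW
amplitude — grow with stenosis resistance, so a residual stenosis would
*amplify* the suction wave; physically, the compliance of the vessel
segment between lesion and sensor buffers sub-100 ms flow transients.
With the broadened drop, BEW amplitude is governed by suction strength
and timing, which is the dissociation the cohort design needs to express.
All mean-based identities and the Pd ≤ Pa invariant are unaffected.

Beat-to-beat variability is a per-beat cycle-length jitter (uniform time
dilation of the template); sensor noise is i.i.d. Gaussian per sample and
channel. Not emulated: ECG, arrhythmia/ectopy, catheter damping, drift,
Doppler dropout, and any systolic-diastolic asymmetry of real stenosis
pressure-loss (the drop is linear in velocity, not quadratic). Passing
tests on this generator therefore demonstrate pipeline correctness under
idealized morphology, not robustness to every artefact of real
catheterization data.

## The synthetic cohort

The default cohort is 63 vessels — 53 concordant, 10 discordant — with 16
beats per recording per state (pre/post × rest/hyperemia), 2% cycle-length
jitter and 1 mmHg / 1 cm/s noise, at 200/100 Hz. Post-PCI targets follow
the lesion-level contrast the pipeline is meant to recover: concordant
stenosis resistance ≈ 0.21 ± 0.13 with FFR > 0.82, discordant FFR ~
N(0.765, 0.02) truncated at 0.78 (stenosis share derived as (1−FFR)·total,
implied hSR ≈ 0.56 ± 0.2), pre-PCI hSR ≈ 1.55 ± 1.0 and hMR ≈ 2.43 ± 0.9.
The discordant stratum gets a delayed (0.29 vs 0.20 of the expansion
phase) and weaker (gain ×0.65) suction burst; its within-group timing sd
is 0.06–0.08, chosen so a 10-vessel group mean is informative.

Three structural choices make the configured null contrasts honest nulls
rather than coin flips:

1. the total hyperemic resistance (hMR + hSR), which alone sets the
   hyperemic velocity, is drawn from a distribution shared in shape by
   both strata (2.05 vs 2.50 ± 0.75), so hyperemic velocity is matched by
   construction and the discordant offset absorbs most of the hMR gap
   that the FFR band forces at equal totals;
2. basal microvascular resistance is derived from a common CFVR
   distribution (bMR = CFVR·total − R), so flow reserve is
   stratum-independent;
3. the aortic pressure level scales with total resistance (exponent 0.6,
   pulse pressure preserved — an autoregulatory coupling), which keeps
   velocities in a narrow physiologic band without narrowing the
   resistance spread that the microvascular-resistance null comparison
   needs.

Classification margins (concordant FFR ≥ 0.82, discordant ≤ 0.78) keep
the configured labels well-posed relative to the ≤2% recovery error; a
vessel whose noiseless distal pressure would dip below 5 mmHg is redrawn
as physiologically infeasible. Rejection sampling is capped at 1000 draws
per vessel and raises a generation error for infeasible specifications.

Because the group comparisons are genuine hypothesis tests on a 53/10
split, each non-significance claim retains an irreducible ≈5% chance of a
spurious rejection in any single cohort realization (and the significance
claims have finite power). End-to-end checks of the dissociation pattern
therefore aggregate five independent cohort replicates and require each
claim to hold in the majority; measured per-claim rates across 24
independent cohorts are 0.92–1.00.

## Statistics

Normality gates use Shapiro–Wilk at α = 0.05 per group (the gate's α is a
convention; only the choice of test, not the reported p, depends on it).
Student's equal-variance t-test is the parametric default, matching common
clinical-statistics practice; Mann–Whitney U, Wilcoxon signed-rank,
chi-square (Fisher's exact when any expected cell < 5), and
Pearson/Spearman correlation complete the set, all two-sided. Constant
samples are treated as non-normal; an exactly zero paired difference
reports p = 1 and an exact constant shift p = 0, both flagged degenerate.
No multiple-testing correction is applied and the report says so; vessels
are treated as independent observations even when a patient contributes
two. The Fisher path agrees with direct hypergeometric enumeration to
1e-9 on all 2×2 tables with margins ≤ 12, and the gated two-sample
comparison's type-I error is 5% ± 1.5% under a normal null (n = 30/30,
2000 replicates).

## Known limitations

- Net-WI quadrant classification cannot separate simultaneous forward and
  backward waves; a wave-speed-based separation backend could be added
  behind `extract_peaks` without changing the interface.
- The expansion anchor (distal pressure maximum) differs from an
  aortic-anchor choice by a few milliseconds on real data; on the
  generator the two coincide by construction.
- The generator's group calibration reproduces the *pattern* of the
  residual-low-FFR contrast (which quantities differ, which do not), not
  every printed group mean; in particular its discordant total resistance
  is deliberately offset to keep the microvascular-resistance contrast a
  true null under the FFR-band constraint.
- Trace I/O covers the package's own plain-text format only; proprietary
  console exports must be converted upstream.
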