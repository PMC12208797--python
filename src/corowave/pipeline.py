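"""End-to-end analysis: raw recordings to per-vessel and cohort results."""

from __future__ import annotations

from dataclasses import replace

from .cohort import VesselResult, build_tables
from .hemodyn import classify_vessel, compute_indices
from .signalio import (
    EnsembleBeat,
    VesselRecording,
    detect_beats,
    ensemble_average,
    resample_to_common_grid,
    select_windows,
    smooth_velocity,
)
from .wia import analyze_beat


def process_recording(
    rec: VesselRecording, window: tuple | None = None
) -> EnsembleBeat:
    """Condition one recording into its representative ensemble beat.

    Velocity is Savitzky-Golay smoothed on its native grid, upsampled onto
    the pressure grid, beats are segmented on Pa, and accepted beats inside
    ``window`` (whole recording when None) are ensemble-averaged.
    """
    rec = rec.validate()
    rec = replace(rec, u=smooth_velocity(rec.u))
    rec = resample_to_common_grid(rec)
    beats = detect_beats(rec.pa, rec.fs_pressure)
    return ensemble_average(rec, beats, window)


def process_continuous(rec: VesselRecording) -> tuple:
    """Split a continuous recording at the hyperemia induction.

    Returns ``(rest_beat, hyperemia_beat, selection)`` using the automatic
    window selection.
    """
    rec = rec.validate()
    rec_s = replace(rec, u=smooth_velocity(rec.u))
    sel = select_windows(rec_s)
    rest = process_recording(rec, window=sel.rest_window)
    hyp = process_recording(rec, window=sel.hyperemia_window)
    return rest, hyp, sel


def analyze_vessel(recordings: dict, vessel_id: str | None = None) -> VesselResult:
    """Analyze the four recordings of one vessel.

    ``recordings`` maps ``(phase, condition)`` with phase in {"pre","post"}
    and condition in {"rest","hyperemia"} to :class:`VesselRecording`.
    Computes the conventional index sets per phase, net-WIA peak sets for
    all four states, and the post-PCI stratification.
    """
    beats = {key: process_recording(rec) for key, rec in recordings.items()}
    pre = compute_indices(beats[("pre", "rest")], beats[("pre", "hyperemia")])
    post = compute_indices(beats[("post", "rest")], beats[("post", "hyperemia")])
    peaks = {key: analyze_beat(b)[1] for key, b in beats.items()}
    if vessel_id is None:
        vessel_id = next(iter(recordings.values())).vessel_id
    meta = next(iter(recordings.values())).metadata
    return VesselResult(
        vessel_id=vessel_id,
        pre=pre,
        post=post,
        wia_rest_pre=peaks[("pre", "rest")],
        wia_hyp_pre=peaks[("pre", "hyperemia")],
        wia_rest_post=peaks[("post", "rest")],
        wia_hyp_post=peaks[("post", "hyperemia")],
        group=classify_vessel(post),
        metadata={k: v for k, v in meta.items() if k != "onsets"},
    )


def analyze_cohort(recordings: dict) -> list:
    """Analyze every vessel of a cohort; returns a list of VesselResult."""
    return [
        analyze_vessel(recs, vessel_id=vid)
        for vid, recs in sorted(recordings.items())
    ]


def run_study(recordings: dict):
    """Full study: per-vessel analysis plus the cohort report tables."""
    results = analyze_cohort(recordings)
    return results, build_tables(results)
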