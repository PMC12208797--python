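"""Conventional pressure/velocity indices of coronary physiology.

All indices are time-averages over the representative (ensemble) cardiac
cycle, written ``<.>``:

* ``FFR  = <Pd>/<Pa>`` during hyperemia (fractional flow reserve)
* ``CFVR = <U_hyp>/<U_rest>`` (coronary flow velocity reserve)
* ``hSR  = (<Pa>-<Pd>)/<U>`` during hyperemia (stenosis resistance)
* ``bMR, hMR = <Pd>/<U>`` at rest / hyperemia (microvascular resistance)
* ``MRR  = (CFVR/FFR) * (<Pa_rest>/<Pa_hyp>)`` (microvascular resistance
  reserve, vasodilatory capacity corrected for epicardial disease)
* ``RRR  = bMR/hMR`` (resistive reserve ratio, autoregulatory capacity)

Two algebraic identities tie the set together and are enforced by tests:
``FFR = hMR/(hMR + hSR)`` and ``MRR = RRR * (<Pa_rest>/<Pd_rest>)``.

Vessels are stratified on the conventional 0.80 cutoffs: abnormal FFR is
``<= 0.80``, normal hSR is ``< 0.80``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, ParameterError
from .signalio import EnsembleBeat

FFR_CUTOFF = 0.80
HSR_CUTOFF = 0.80


@dataclass
class HemoIndexSet:
    """All conventional indices for one vessel and phase."""

    bapv: float  # cm/s, resting mean velocity
    hapv: float  # cm/s, hyperemic mean velocity
    pa_rest_mean: float  # mmHg
    pa_hyp_mean: float  # mmHg
    pd_rest_mean: float  # mmHg
    pd_hyp_mean: float  # mmHg
    ffr: float
    cfvr: float
    hsr: float  # mmHg.cm-1.s
    deltap: float  # mmHg, hyperemic <Pa>-<Pd>
    bmr: float  # mmHg.cm-1.s
    hmr: float  # mmHg.cm-1.s
    mrr: float
    rrr: float


_CHANNELS = {"pa": "pa", "pd": "pd", "u": "u"}


def time_average(beat: EnsembleBeat, channel: str) -> float:
    """Trapezoidal time-average of a channel over the ensemble cycle."""
    key = channel.lower()
    if key not in _CHANNELS:
        raise ParameterError(f"unknown channel {channel!r}; expected Pa, Pd or U")
    y = getattr(beat, _CHANNELS[key])
    t = beat.time
    if len(y) < 2:
        raise DegenerateSignalError("empty or single-sample beat")
    span = t[-1] - t[0]
    if span <= 0:
        raise DegenerateSignalError("beat has zero duration")
    return float(np.trapezoid(y, t) / span)


def compute_indices(rest: EnsembleBeat, hyp: EnsembleBeat) -> HemoIndexSet:
    """Compute the full conventional index set from rest and hyperemia beats."""
    pa_r = time_average(rest, "pa")
    pd_r = time_average(rest, "pd")
    u_r = time_average(rest, "u")
    pa_h = time_average(hyp, "pa")
    pd_h = time_average(hyp, "pd")
    u_h = time_average(hyp, "u")

    if u_r <= 0 or u_h <= 0:
        raise DegenerateSignalError(
            f"nonpositive mean velocity (rest {u_r:.3g}, hyperemia {u_h:.3g})"
        )
    if pa_r <= 0 or pa_h <= 0:
        raise DegenerateSignalError(
            f"nonpositive mean aortic pressure (rest {pa_r:.3g}, "
            f"hyperemia {pa_h:.3g})"
        )

    ffr = pd_h / pa_h
    cfvr = u_h / u_r
    hsr = (pa_h - pd_h) / u_h
    bmr = pd_r / u_r
    hmr = pd_h / u_h
    mrr = (cfvr / ffr) * (pa_r / pa_h)
    rrr = bmr / hmr
    return HemoIndexSet(
        bapv=u_r, hapv=u_h,
        pa_rest_mean=pa_r, pa_hyp_mean=pa_h,
        pd_rest_mean=pd_r, pd_hyp_mean=pd_h,
        ffr=ffr, cfvr=cfvr, hsr=hsr, deltap=pa_h - pd_h,
        bmr=bmr, hmr=hmr, mrr=mrr, rrr=rrr,
    )


def classify_vessel(post_indices: HemoIndexSet) -> str:
    """Stratify a vessel on its post-PCI indices.

    ``concordant``: FFR > 0.80 with normal hSR (< 0.80); ``discordant``:
    residual low FFR (<= 0.80) despite normal hSR; ``abnormal_hsr``:
    hSR >= 0.80 (flow-limiting residual stenosis). The boundary conventions
    follow the printed cutoffs: abnormal FFR uses <=, normal hSR uses
    strict <.
    """
    if post_indices.hsr >= HSR_CUTOFF:
        return "abnormal_hsr"
    if post_indices.ffr > FFR_CUTOFF:
        return "concordant"
    return "discordant"
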