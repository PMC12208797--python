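from functools import lru_cache

import numpy as np
import pytest
from hypothesis import settings

import corowave as cw

settings.register_profile("ci", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def default_params():
    return cw.BeatParams()


def make_constant_beat(pa=100.0, pd=90.0, u=40.0, fs=200.0, dur=1.0):
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    return cw.EnsembleBeat(time=t, pa=np.full(n, float(pa)),
                           pd=np.full(n, float(pd)), u=np.full(n, float(u)),
                           n_beats_averaged=10, fs=fs)


@lru_cache(maxsize=8)
def cohort_results(seed: int):
    """Full default 63-vessel cohort, analyzed (cached per session)."""
    recordings, truth = cw.synth_cohort(cw.CohortSpec(seed=seed))
    results = cw.analyze_cohort(recordings)
    report = cw.build_tables(results)
    return truth, results, report


@pytest.fixture(scope="session")
def cohort_factory():
    return cohort_results


def fractional_align(x, ref, max_shift=20):
    """Circular shift (sub-sample) of x maximizing correlation with ref.

    The ensemble beat is a periodic cycle defined up to phase; comparisons
    against a reference cycle must align phases first. Returns shifted x.
    """
    x = np.asarray(x, float)
    ref = np.asarray(ref, float)
    n = len(ref)

    def fshift(sig, s):
        return np.fft.ifft(
            np.fft.fft(sig) * np.exp(-2j * np.pi * np.fft.fftfreq(n) * s)
        ).real

    best, bs = -np.inf, 0
    for s in range(-max_shift, max_shift + 1):
        c = float(np.dot(np.roll(x, s), ref))
        if c > best:
            best, bs = c, s
    best_f = float(bs)
    for f in np.linspace(bs - 1, bs + 1, 41):
        c = float(np.dot(fshift(x, f), ref))
        if c > best:
            best, best_f = c, float(f)
    return best_f


def aligned_rms(beat, truth_beat, channel):
    """RMS residual of a channel after sub-sample phase alignment on Pa."""
    n = min(len(beat.pa), len(truth_beat.pa))
    shift = fractional_align(beat.pa[:n], truth_beat.pa[:n])

    x = np.asarray(getattr(beat, channel)[:n], float)
    y = np.fft.ifft(
        np.fft.fft(x) * np.exp(-2j * np.pi * np.fft.fftfreq(n) * shift)
    ).real
    return float(np.sqrt(np.mean((y - getattr(truth_beat, channel)[:n]) ** 2)))
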