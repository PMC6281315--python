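import numpy as np
import pytest

from gammakit.io import Recording

RATE = 10_000.0


@pytest.fixture
def rate():
    return RATE


def make_sine(freq_hz, amp, dur_s, rate_hz=RATE, kind="lfp", units="V"):
    t = np.arange(int(round(dur_s * rate_hz))) / rate_hz
    return Recording(amp * np.cos(2 * np.pi * freq_hz * t), rate_hz, kind, units=units)


@pytest.fixture
def sine_40hz_60s():
    """60-s, 10 kHz, 20 uV 40 Hz cosine — the canonical band-power fixture."""
    return make_sine(40.0, 20e-6, 60.0)


def match_events(truth_times, det_times, tol_s=0.002):
    """Greedy bipartite matching of detected to true event times."""
    det = np.asarray(det_times, dtype=float)
    used = np.zeros(det.size, dtype=bool)
    hits = 0
    for t in truth_times:
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d)) if det.size else 0
        if det.size and d[j] <= tol_s:
            used[j] = True
            hits += 1
    return hits
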