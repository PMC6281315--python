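"""Oscillation rhythmicity from LFP autocorrelograms.

The coefficient of rhythmicity Cr quantifies how regular an oscillation is:
from the normalized autocorrelogram of a band-pass-filtered LFP segment,
Cr = (alpha - beta) / (alpha + beta) where alpha is the height of the second
peak and beta the depth of the first trough.  Because a signed correlation
trough would make that ratio escape [0, 1], the autocorrelation r is first
rescaled affinely to r01 = (r + 1) / 2, the minimal convention under which
Cr spans [0, 1] and a moderately damped gamma oscillation sits near 0.5.

The pre-filter is the cascade the field's acquisition software applies: a
single-pole RC high-pass (run forward-backward for zero phase) followed by a
Gaussian FIR low-pass, both specified by their -3 dB points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .io import Recording, RecordingError
from .spectral import PowerSpectrum

CR_BAND = (15.0, 60.0)
CR_THRESHOLD = 0.01  # rhythmicity gate on Cr
MAX_LAG_MS = 100.0


def bandpass_gain(f_hz, f_hp: float, f_lp: float) -> np.ndarray:
    """Analytic amplitude response of the RC + Gaussian cascade.

    The RC high-pass contributes |H|^2 (it is applied forward-backward);
    the Gaussian low-pass contributes exp(-(ln 2 / 2) (f / f_lp)^2), i.e.
    -3 dB at ``f_lp``.
    """
    f = np.asarray(f_hz, dtype=float)
    hp = (f / f_hp) ** 2 / (1.0 + (f / f_hp) ** 2)  # squared single-pole magnitude
    lp = np.exp(-0.5 * np.log(2.0) * (f / f_lp) ** 2)
    return hp * lp


def bandpass(trace: Recording, f_hp: float = CR_BAND[0], f_lp: float = CR_BAND[1]) -> Recording:
    """Zero-phase band-pass: single-pole RC high-pass (filtfilt) then
    Gaussian FIR low-pass, -3 dB points at ``f_hp`` and ``f_lp``."""
    if not 0 < f_hp < f_lp < trace.rate_hz / 2:
        raise RecordingError(
            f"invalid band ({f_hp}, {f_lp}) Hz for rate {trace.rate_hz} Hz"
        )
    x = trace.samples - np.mean(trace.samples)
    b, a = sps.butter(1, f_hp, btype="highpass", fs=trace.rate_hz)
    y = sps.filtfilt(b, a, x)
    # Gaussian kernel with -3 dB at f_lp: H(f) = exp(-2 pi^2 sigma_t^2 f^2)
    sigma_t = np.sqrt(np.log(2.0)) / (2.0 * np.pi * f_lp)
    y = gaussian_filter1d(y, sigma=sigma_t * trace.rate_hz, mode="reflect")
    return replace(trace, samples=y)


@dataclass
class Autocorrelogram:
    """Normalized autocorrelation over lags -100..+100 ms, r(0) = 1."""

    lags_ms: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        if self.lags_ms.shape != self.r.shape:
            raise RecordingError("lags and r must have equal shape")
        i0 = np.argmin(np.abs(self.lags_ms))
        if abs(self.r[i0] - 1.0) > 1e-9:
            raise RecordingError("autocorrelogram must satisfy r(0) = 1")
        if np.max(np.abs(self.r)) > 1.0 + 1e-9:
            raise RecordingError("|r| must not exceed 1")

    @property
    def r01(self) -> np.ndarray:
        """Affine rescale (r + 1) / 2 used for Cr extraction."""
        return (self.r + 1.0) / 2.0

    @property
    def dt_ms(self) -> float:
        return float(self.lags_ms[1] - self.lags_ms[0])


@dataclass
class CrResult:
    alpha: float
    beta: float
    cr: float
    trough_lag_ms: float
    peak_lag_ms: float
    implied_freq_hz: float
    rhythmic: bool


def autocorrelogram(segment: Recording, max_lag_ms: float = MAX_LAG_MS) -> Autocorrelogram:
    """Biased, lag-0-normalized autocovariance of a (filtered) segment.

    Mean-subtracted internally; symmetric by construction.
    """
    x = segment.samples - np.mean(segment.samples)
    if segment.duration_s < 1.0:
        raise RecordingError("autocorrelogram needs a segment of at least 1 s")
    var = np.dot(x, x)
    if var == 0:
        raise RecordingError("degenerate trace: zero variance")
    n = x.size
    max_lag = int(round(max_lag_ms * segment.rate_hz / 1000.0))
    nfft = next_fast_len(2 * n)
    X = np.fft.rfft(x, n=nfft)
    ac = np.fft.irfft(X * np.conj(X), n=nfft)[: max_lag + 1]
    r_pos = ac / ac[0]
    lags = np.arange(-max_lag, max_lag + 1) / segment.rate_hz * 1000.0
    r = np.concatenate([r_pos[::-1], r_pos[1:]])
    return Autocorrelogram(lags_ms=lags, r=r)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum location/value via a 3-point parabola at index i.

    Index 1 is returned as-is: the lag-0 sample (r = 1 by normalization) is
    a delta-like spike that would skew the parabola.
    """
    if i <= 1 or i >= y.size - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return i + delta, float(y1 - 0.25 * (y0 - y2) * delta)


def coefficient_of_rhythmicity(acg: Autocorrelogram,
                               threshold: float = CR_THRESHOLD,
                               smooth_ms: float = 1.0) -> CrResult:
    """Extract Cr = (alpha - beta) / (alpha + beta) from an autocorrelogram.

    beta is r01 at the first local minimum at positive lag, alpha is r01 at
    the first local maximum beyond it (one oscillation period, so
    1000 / peak_lag_ms estimates the oscillation frequency).  Extrema are
    located on a 1-ms-smoothed trace to suppress sample-level jitter, then
    value and lag are refined on the raw trace with parabolic interpolation.
    A trace with no extrema within the lag range gets cr = 0, rhythmic False.
    """
    dt = acg.dt_ms
    half = acg.lags_ms.size // 2
    lag_pos = acg.lags_ms[half:]
    y = acg.r01[half:]

    w = max(1, int(round(smooth_ms / dt)))
    s = uniform_filter1d(y, size=w, mode="nearest") if w > 1 else y

    def _first_extremum(start: int, kind: str) -> int | None:
        sign = 1.0 if kind == "min" else -1.0
        for i in range(max(start, 1), s.size - 1):
            if sign * s[i + 1] > sign * s[i]:  # turning point; ties -> smaller lag
                return i
        return None

    i_tr = _first_extremum(1, "min")
    degenerate = CrResult(alpha=float("nan"), beta=float("nan"), cr=0.0,
                          trough_lag_ms=float("nan"), peak_lag_ms=float("nan"),
                          implied_freq_hz=float("nan"), rhythmic=False)
    if i_tr is None:
        return degenerate
    i_pk = _first_extremum(i_tr + 1, "max")
    if i_pk is None:
        return degenerate

    # refine on the raw trace near the smoothed extremum
    def _refine(i: int, kind: str) -> tuple[float, float]:
        lo = max(1, i - w)
        hi = min(y.size - 1, i + w + 1)
        j = lo + (np.argmin(y[lo:hi]) if kind == "min" else np.argmax(y[lo:hi]))
        idx, val = _parabolic_refine(y, j)
        return idx * dt, val

    trough_lag, beta = _refine(i_tr, "min")
    peak_lag, alpha = _refine(i_pk, "max")
    if alpha + beta <= 0:
        cr = 0.0
    else:
        cr = float(np.clip((alpha - beta) / (alpha + beta), 0.0, 1.0))
    return CrResult(alpha=alpha, beta=beta, cr=cr,
                    trough_lag_ms=trough_lag, peak_lag_ms=peak_lag,
                    implied_freq_hz=1000.0 / peak_lag,
                    rhythmic=bool(cr >= threshold))


def confirm_frequency(cr_result: CrResult, spectrum: PowerSpectrum,
                      f_lo: float = 20.0, f_hi: float = 80.0,
                      tol_hz: float = 5.0) -> bool:
    """True iff the autocorrelogram-implied frequency matches the spectral
    peak in [f_lo, f_hi] within ``tol_hz``.  Non-rhythmic results are
    vacuously False."""
    if not cr_result.rhythmic or not np.isfinite(cr_result.implied_freq_hz):
        return False
    return abs(cr_result.implied_freq_hz - spectrum.peak_frequency(f_lo, f_hi)) <= tol_hz
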