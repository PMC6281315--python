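"""Figure helpers: power spectra, spectrograms, polar phase plots, and the
triple-cycle phase histogram (the spike-phase histogram repeated over three
gamma cycles to show firing windows).  Generated artifacts only — no
analysis happens here."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_spectrum(spectrum, ax=None, f_max=100.0):
    ax = ax or plt.gca()
    m = spectrum.freqs_hz <= f_max
    ax.plot(spectrum.freqs_hz[m], spectrum.power[m])
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power per bin (V$^2$)")
    return ax


def plot_spectrogram(sg, ax=None):
    ax = ax or plt.gca()
    ax.pcolormesh(sg.times_s, sg.freqs_hz, sg.power, shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax


def plot_polar_phases(dist, ax=None, color="k"):
    """Polar histogram of spike phases with the preferred-angle arrow."""
    if ax is None:
        ax = plt.subplot(projection="polar")
    width = 2 * np.pi / dist.n_bins
    ax.bar(dist.bin_centers, dist.hist, width=width, alpha=0.6, color=color)
    ax.annotate("", xy=(dist.preferred_angle_rad, dist.resultant_R), xytext=(0, 0),
                arrowprops=dict(arrowstyle="-|>", color=color, lw=2))
    return ax


def plot_triple_cycle(dist, ax=None, color="k"):
    """Phase histogram repeated three times (firing windows across cycles)."""
    ax = ax or plt.gca()
    theta = np.concatenate([dist.bin_centers + k * 2 * np.pi for k in range(3)])
    h = np.tile(dist.hist, 3)
    ax.bar(theta, h, width=2 * np.pi / dist.n_bins, color=color, alpha=0.6)
    ax.set_xlabel("gamma phase (rad)")
    ax.set_ylabel("normalized AP count")
    return ax
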