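"""Data model and file I/O for electrophysiology recordings.

A :class:`Recording` is a uniformly sampled trace (LFP in volts, membrane
current in pA, or membrane potential in mV) together with its sampling rate
and condition metadata.  Time is handled internally as integer sample index
plus rate; seconds appear only at the API boundary, which avoids float drift
when slicing long (minutes) windows out of 10 kHz traces.

On disk a recording is a two-column CSV ``time_s,value`` with a JSON sidecar
declaring ``rate_hz``, ``units``, ``channel_kind`` and optional ``label`` /
``condition``.  Spike trains are one-column CSVs of spike times in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CHANNEL_KINDS = ("lfp", "current", "voltage")
CONDITIONS = ("control", "abeta", "abeta_cp", "abeta_cp_cz", "other")

#: maximum tolerated relative mismatch between sidecar rate and CSV spacing
RATE_TOLERANCE = 1e-4


class RecordingError(ValueError):
    """Raised for malformed recordings or inconsistent metadata."""


@dataclass
class Recording:
    """Uniformly sampled single-channel trace.

    Parameters
    ----------
    samples
        Sample values; volts for ``lfp``, pA for ``current``, mV for
        ``voltage``.
    rate_hz
        Sampling rate in Hz (10 000 in the experiments this package models).
    channel_kind
        One of ``lfp``, ``current``, ``voltage``.
    units
        Unit string recorded in metadata; declared, never guessed.
    t0_s
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    rate_hz: float
    channel_kind: str
    units: str = "V"
    t0_s: float = 0.0
    label: str = ""
    condition: str = "other"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise RecordingError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise RecordingError("samples contain non-finite values")
        if not self.rate_hz > 0:
            raise RecordingError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.t0_s < 0:
            raise RecordingError(f"t0_s must be >= 0, got {self.t0_s}")
        if self.channel_kind not in CHANNEL_KINDS:
            raise RecordingError(
                f"channel_kind must be one of {CHANNEL_KINDS}, got {self.channel_kind!r}"
            )
        if self.condition not in CONDITIONS:
            raise RecordingError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        """Per-sample times in seconds (computed from index and rate)."""
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz

    def segment(self, start_s: float, dur_s: float) -> "Recording":
        """Extract the half-open window ``[start_s, start_s + dur_s)``.

        Returns exactly ``round(dur_s * rate_hz)`` samples.
        """
        if dur_s <= 0:
            raise RecordingError(f"segment duration must be positive, got {dur_s}")
        i0 = int(round((start_s - self.t0_s) * self.rate_hz))
        n = int(round(dur_s * self.rate_hz))
        if i0 < 0 or i0 + n > self.n_samples:
            raise RecordingError(
                f"segment [{start_s}, {start_s + dur_s}) s outside recording "
                f"[{self.t0_s}, {self.end_s}) s"
            )
        return replace(self, samples=self.samples[i0 : i0 + n], t0_s=start_s)


@dataclass
class SpikeTrain:
    """Ordered action-potential times for one cell within one epoch."""

    times_s: np.ndarray
    source: str = "whole_cell"  # whole_cell | unit
    epoch: tuple[float, float] = (0.0, np.inf)
    refractory_s: float = 0.002

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise RecordingError("spike times must be 1-D")
        if self.times_s.size:
            d = np.diff(self.times_s)
            if np.any(d <= 0):
                raise RecordingError("spike times must be strictly increasing")
            if np.any(d < self.refractory_s - 1e-12):
                raise RecordingError(
                    f"inter-spike interval below refractory period {self.refractory_s} s"
                )
            lo, hi = self.epoch
            if self.times_s[0] < lo or self.times_s[-1] > hi:
                raise RecordingError("spike times outside declared epoch")

    @property
    def n_spikes(self) -> int:
        return self.times_s.size


@dataclass
class AnalysisSegment:
    """A named analysis window on a recording (60 s for power/rhythmicity,
    300 s for spike-phase coupling by default)."""

    recording: Recording
    start_s: float
    dur_s: float

    def __post_init__(self) -> None:
        if self.dur_s <= 0:
            raise RecordingError("dur_s must be positive")
        # validates bounds
        self.recording.segment(self.start_s, self.dur_s)

    def trace(self) -> Recording:
        return self.recording.segment(self.start_s, self.dur_s)


def read_recording(path_csv, path_meta_json) -> Recording:
    """Read a two-column ``time_s,value`` CSV plus JSON sidecar.

    The sampling rate is inferred from the timestamps and cross-checked
    against the sidecar ``rate_hz``; disagreement beyond 0.01% relative is a
    hard error, as is non-uniform spacing.
    """
    df = pd.read_csv(path_csv)
    if df.shape[1] != 2:
        raise RecordingError(f"{path_csv}: expected exactly two columns, got {df.shape[1]}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise RecordingError(f"{path_csv}: need at least two samples to infer rate")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise RecordingError(f"{path_csv}: timestamps not increasing")
    if np.max(np.abs(dt - dt_med)) > RATE_TOLERANCE * dt_med:
        raise RecordingError(f"{path_csv}: non-uniform sampling beyond tolerance")
    rate_inferred = 1.0 / dt_med

    meta = json.loads(Path(path_meta_json).read_text())
    rate_meta = float(meta["rate_hz"])
    if abs(rate_meta - rate_inferred) > RATE_TOLERANCE * rate_meta:
        raise RecordingError(
            f"rate mismatch: sidecar declares {rate_meta} Hz but CSV spacing "
            f"implies {rate_inferred:.6g} Hz"
        )
    return Recording(
        samples=v,
        rate_hz=rate_meta,
        channel_kind=meta["channel_kind"],
        units=meta.get("units", "V"),
        t0_s=float(t[0]),
        label=meta.get("label", ""),
        condition=meta.get("condition", "other"),
    )


def write_recording(rec: Recording, path_csv, path_meta_json) -> None:
    """Write a recording in the CSV + JSON sidecar dialect (inverse of
    :func:`read_recording`)."""
    df = pd.DataFrame({"time_s": rec.times(), "value": rec.samples})
    df.to_csv(path_csv, index=False)
    meta = {
        "rate_hz": rec.rate_hz,
        "units": rec.units,
        "channel_kind": rec.channel_kind,
        "label": rec.label,
        "condition": rec.condition,
    }
    Path(path_meta_json).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_spike_train(path, **kwargs) -> SpikeTrain:
    times = pd.read_csv(path).iloc[:, 0].to_numpy(dtype=float)
    return SpikeTrain(times_s=times, **kwargs)


def write_spike_train(spikes: SpikeTrain, path) -> None:
    pd.DataFrame({"time_s": spikes.times_s}).to_csv(path, index=False)


RESULT_COLUMNS = ["metric", "segment_id", "condition", "value", "units"]


def write_results(records: list[dict] | pd.DataFrame, path) -> None:
    """Write flat result records as tidy CSV with a deterministic column
    order.  Floats round-trip to better than 1e-12 relative."""
    df = pd.DataFrame(records, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
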