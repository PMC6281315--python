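"""End-to-end analysis protocols over paired control/treatment datasets.

Three protocols mirror the experimental designs this package models:

* ``lfp_power_cr`` — integrated gamma power (20-80 Hz) and coefficient of
  rhythmicity from a 60-s LFP segment per epoch;
* ``spike_phase`` — concurrent LFP + spikes over 5-min epochs: gamma power,
  firing rate (1-min bins), preferred phase-angle, Gaussian half-width,
  with the Rayleigh p < 0.05 gate deciding which recordings enter the
  phase metrics (exclusions are logged, never silent);
* ``psc`` — synaptic-event frequency, amplitude, and charge transfer in
  1-min bins.

Group comparisons use the one-tailed exact Wilcoxon matched-pairs test
(Mann-Whitney for the unpaired phase-angle contrast), and reports are
deterministic: identical config + seed gives byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import events as ev
from . import rhythmicity as rh
from . import spectral as sp
from . import spike_phase as sph
from . import stats as st
from .io import RecordingError
from .synth import SimulatedRecording

log = logging.getLogger("gammakit.pipeline")

REPORT_SCHEMA_VERSION = 1

#: test direction per metric: does the treatment *reduce* or *increase* it?
METRIC_DIRECTIONS = {
    "gamma_power": "less",
    "cr": "less",
    "firing_rate": "less",
    "halfwidth": "greater",
    "psc_frequency": "less",
    "psc_amplitude": "less",
    "psc_charge": "less",
}


@dataclass
class ProtocolConfig:
    protocol: str = "lfp_power_cr"  # lfp_power_cr | spike_phase | psc
    gamma_band: tuple[float, float] = (20.0, 80.0)
    cr_band: tuple[float, float] = (15.0, 60.0)
    phase_band: tuple[float, float] = (20.0, 60.0)
    power_seg_dur_s: float = 60.0
    bin_s: float = 60.0
    rayleigh_alpha: float = 0.05
    cr_threshold: float = rh.CR_THRESHOLD
    psc_polarity: str = "inward"
    psc_threshold_pA: float = 5.0
    psc_min_iei_ms: float = 5.0
    directions: dict = field(default_factory=lambda: dict(METRIC_DIRECTIONS))
    seed: int = 0


def _epoch_metrics_lfp(epoch, cfg: ProtocolConfig) -> dict:
    lfp = epoch.lfp
    dur = min(cfg.power_seg_dur_s, lfp.duration_s)
    seg = lfp.segment(lfp.t0_s, dur)
    spec = sp.power_spectrum(seg, seg_len=min(sp.DEFAULT_SEG_LEN, seg.n_samples))
    power = sp.integrated_power(spec, *cfg.gamma_band)
    filt = rh.bandpass(seg, *cfg.cr_band)
    cr = rh.coefficient_of_rhythmicity(rh.autocorrelogram(filt),
                                       threshold=cfg.cr_threshold)
    return {
        "gamma_power": power,
        "cr": cr.cr,
        "rhythmic": cr.rhythmic,
        "implied_freq_hz": cr.implied_freq_hz,
        "freq_confirmed": rh.confirm_frequency(cr, spec, *cfg.gamma_band),
    }


def _epoch_metrics_phase(epoch, cfg: ProtocolConfig) -> dict:
    m = _epoch_metrics_lfp(epoch, cfg)
    lfp, spikes = epoch.lfp, epoch.spikes
    rate, _ = sph.firing_rate(spikes, (lfp.t0_s, lfp.end_s), bin_s=cfg.bin_s)
    m["firing_rate"] = rate
    phases, _ = sph.spike_phases(spikes, sph.instantaneous_phase(lfp, *cfg.phase_band))
    if phases.size >= 5:
        dist = sph.phase_distribution(phases, alpha=cfg.rayleigh_alpha)
        m.update(preferred_angle=dist.preferred_angle_rad,
                 halfwidth=dist.halfwidth_rad, rayleigh_p=dist.rayleigh_p,
                 included=dist.included, n_spikes=int(phases.size))
    else:
        m.update(preferred_angle=float("nan"), halfwidth=float("nan"),
                 rayleigh_p=1.0, included=False, n_spikes=int(phases.size))
    return m


def _epoch_metrics_psc(epoch, cfg: ProtocolConfig) -> dict:
    cur = epoch.current
    detected = ev.detect_psc(cur, polarity=cfg.psc_polarity,
                             amp_threshold_pA=cfg.psc_threshold_pA,
                             min_iei_ms=cfg.psc_min_iei_ms)
    summ = ev.summarize_events(detected, (cur.t0_s, cur.end_s), bin_s=cfg.bin_s)
    return {
        "psc_frequency": summ.mean_frequency_hz,
        "psc_amplitude": abs(summ.mean_amplitude_overall_pA),
        "psc_charge": abs(summ.mean_charge_per_bin_pC),
    }


_EPOCH_FNS = {
    "lfp_power_cr": _epoch_metrics_lfp,
    "spike_phase": _epoch_metrics_phase,
    "psc": _epoch_metrics_psc,
}

_PROTOCOL_METRICS = {
    "lfp_power_cr": ["gamma_power", "cr"],
    "spike_phase": ["gamma_power", "firing_rate", "halfwidth"],
    "psc": ["psc_frequency", "psc_amplitude", "psc_charge"],
}


def run_protocol(config: ProtocolConfig, dataset: list[SimulatedRecording]) -> dict:
    """Run a protocol over a paired dataset and assemble the report.

    The report holds per-recording before/after metrics, group summaries
    (mean +- SEM and per-recording percent change), one-tailed test
    statistics, and the list of recordings excluded by the Rayleigh gate
    with reasons.
    """
    if config.protocol not in _EPOCH_FNS:
        raise RecordingError(f"unknown protocol {config.protocol!r}")
    fn = _EPOCH_FNS[config.protocol]
    rows, excluded = [], []
    for rec in dataset:
        try:
            before = fn(rec.control, config)
            after = fn(rec.treatment, config)
        except RecordingError as e:
            log.warning("skipping %s: %s", rec.rec_id, e)
            excluded.append({"rec_id": rec.rec_id, "reason": str(e)})
            continue
        rows.append({"rec_id": rec.rec_id, "before": before, "after": after})

    group: dict[str, dict] = {}
    for metric in _PROTOCOL_METRICS[config.protocol]:
        use = rows
        if metric == "halfwidth":
            # Rayleigh gate: only phase-locked recordings in both epochs count
            use = [r for r in rows if r["before"].get("included")
                   and r["after"].get("included")]
            for r in rows:
                if r not in use:
                    excluded.append({"rec_id": r["rec_id"],
                                     "reason": "circular distribution uniform "
                                               "(Rayleigh p >= 0.05)"})
        b = np.array([r["before"][metric] for r in use], dtype=float)
        a = np.array([r["after"][metric] for r in use], dtype=float)
        ok = np.isfinite(b) & np.isfinite(a)
        b, a = b[ok], a[ok]
        entry = {
            "n": int(b.size),
            "before_mean": float(np.mean(b)) if b.size else float("nan"),
            "before_sem": float(np.std(b, ddof=1) / np.sqrt(b.size)) if b.size > 1 else float("nan"),
            "after_mean": float(np.mean(a)) if a.size else float("nan"),
            "after_sem": float(np.std(a, ddof=1) / np.sqrt(a.size)) if a.size > 1 else float("nan"),
        }
        direction = config.directions.get(metric, "less")
        try:
            cmp = st.paired_comparison(b, a, direction=direction)
            entry.update(test="wilcoxon_one_tailed", direction=direction,
                         statistic=cmp.statistic, p=cmp.p_one_tailed,
                         significant=cmp.significant,
                         pct_change_mean=cmp.pct_change_mean,
                         pct_change_sem=cmp.pct_change_sem,
                         pct_change_pooled=cmp.pct_change_pooled)
        except st.StatsError as e:
            entry.update(test="wilcoxon_one_tailed", direction=direction,
                         statistic=float("nan"), p=float("nan"),
                         significant=False, error=str(e))
        group[metric] = entry

    if config.protocol == "spike_phase":
        use = [r for r in rows if r["before"].get("included")
               and r["after"].get("included")]
        b = [r["before"]["preferred_angle"] for r in use]
        a = [r["after"]["preferred_angle"] for r in use]
        entry = {"n": len(b),
                 "before_mean": float(np.mean(b)) if b else float("nan"),
                 "after_mean": float(np.mean(a)) if a else float("nan")}
        try:
            u, p = st.mann_whitney_one_tailed(b, a, direction="less")
            entry.update(test="mann_whitney_one_tailed", direction="less",
                         statistic=u, p=p, significant=bool(p < st.SIGNIFICANCE))
        except st.StatsError as e:
            entry.update(test="mann_whitney_one_tailed", error=str(e),
                         p=float("nan"), significant=False)
        group["preferred_angle"] = entry

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "protocol": config.protocol,
        "seed": config.seed,
        "n_recordings": len(dataset),
        "n_analyzed": len(rows),
        "per_recording": rows,
        "group": group,
        "excluded": excluded,
    }


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, repr-exact floats)."""
    return json.dumps(report, sort_keys=True, indent=2, default=_jsonify) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def timecourse(times_s, values, bin_s: float = 60.0,
               control_window: int = 5) -> dict:
    """Normalized metric time-course over contiguous 1-min bins.

    ``times_s``/``values`` are per-bin measurements at bin start times;
    bins must tile without gaps (a missing bin is an error naming it).
    Values are normalized to the mean of the first ``control_window`` bins.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.size != values.size or times_s.size == 0:
        raise RecordingError("times and values must be equal-length and non-empty")
    idx = np.round((times_s - times_s[0]) / bin_s).astype(int)
    expected = np.arange(idx[-1] + 1)
    missing = sorted(set(expected) - set(idx))
    if missing:
        raise RecordingError(
            "gap in time-course bins; missing bin starts at "
            + ", ".join(f"{times_s[0] + m * bin_s:.0f} s" for m in missing)
        )
    normalized = st.normalize_timecourse(values, control_window=control_window)
    return {"bin_start_s": times_s, "value": values, "normalized": normalized}
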