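"""End-to-end orchestration: recording -> filtered phase -> WPLI networks ->
graph metrics -> transition dynamics -> group statistics.

The unit of work is one scored recording.  Phase is extracted once per band
over the whole (bandlimited) recording and then sliced per epoch/segment, so
wavelet edge losses are confined to the recording ends instead of every
epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .dynamics import transition_traces
from .io import EpochMask, Hypnogram, Recording
from .network import (global_efficiency, hemisphere_strengths, node_strength,
                      proportional_threshold, top_connectivity_graph)
from .preprocess import bandlimit
from .wavelet import build_wavelet_bank, connectivity_from_phase, extract_phase

log = logging.getLogger("somnet")

__all__ = ["RunConfig", "analyze_recording", "analyze_cohort", "mean_matrices"]

DEFAULT_BANDS = ("delta", "theta", "alpha", "sigma", "beta")


@dataclass
class RunConfig:
    """Analysis settings; the defaults are the study settings (density 0.30,
    3-s windows with 1-s hop, 30-s epochs, three 10-s transition segments,
    0.5-50 Hz bandpass)."""

    bands: tuple = DEFAULT_BANDS
    density: float = 0.30
    window_s: float = 3.0
    hop_s: float = 1.0
    epoch_s: float = 30.0
    segment_s: float = 10.0
    n_segments: int = 3
    fb: float = 2.0
    aggregation: str = "pooled"       # or "window-mean"
    unit: str = "epoch"               # or "subject"
    bandpass: tuple = (0.5, 50.0)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.density <= 1:
            raise ValueError("density must be in [0, 1]")

    def effective_bandpass(self, fs: float) -> tuple:
        """Clip the upper passband edge below Nyquist for low-rate inputs."""
        low, high = self.bandpass
        return (low, min(high, 0.45 * fs))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bands", "bandpass"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["bands"] = list(d["bands"])
        d["bandpass"] = list(d["bandpass"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def analyze_recording(recording: Recording, hypnogram: Hypnogram,
                      mask: EpochMask | None, subject_id: str, group: str,
                      config: RunConfig):
    """Per-epoch network metrics and per-onset transition GE for one subject.

    Returns ``(metrics_rows, onset_rows, matrix_sums)`` where
    ``matrix_sums[(band, stage)] = (sum_of_wpli_matrices, count)`` feeds the
    participant-averaged connectivity graphs.
    """
    if mask is None:
        mask = EpochMask.all_keep(len(hypnogram))
    if len(mask) != len(hypnogram):
        raise ValueError(f"mask/hypnogram length mismatch for {subject_id}")
    fs = recording.fs
    low, high = config.effective_bandpass(fs)
    filtered = bandlimit(recording, low, high)

    n_epoch = int(round(config.epoch_s * fs))
    n_seg = int(round(config.segment_s * fs))
    kept = [i for i in range(len(hypnogram)) if mask.keep[i]]
    stage_counts = pd.Series([hypnogram.labels[i] for i in kept]).value_counts()
    log.info("%s: %d kept epochs (%s)", subject_id, len(kept),
             ", ".join(f"{s}={c}" for s, c in stage_counts.items()))

    metrics_rows, onset_rows = [], []
    matrix_sums = {}
    skipped_onsets = 0
    for band in config.bands:
        bank = build_wavelet_bank(band, fs, fb=config.fb)
        ps = extract_phase(filtered.data, bank)
        for i in kept:
            s0 = i * n_epoch
            sl = ps.slice(s0, s0 + n_epoch)
            mat = connectivity_from_phase(
                sl.phase, sl.valid, fs, window_s=config.window_s,
                hop_s=config.hop_s, aggregation=config.aggregation)
            strengths = node_strength(mat)
            ge = global_efficiency(proportional_threshold(mat, config.density))
            lmean, rmean = hemisphere_strengths(strengths, recording.channels,
                                                recording.montage)
            row = {"subject": subject_id, "group": group, "band": band,
                   "stage": hypnogram.labels[i], "epoch_index": i, "ge": ge,
                   "left_strength": lmean, "right_strength": rmean}
            row.update({f"strength_{c}": strengths[k]
                        for k, c in enumerate(recording.channels)})
            metrics_rows.append(row)
            key = (band, hypnogram.labels[i])
            total, count = matrix_sums.get(key, (0.0, 0))
            matrix_sums[key] = (total + mat, count + 1)

        for stage, first, _length in hypnogram.stage_runs():
            if not mask.keep[first]:
                if band == config.bands[0]:
                    skipped_onsets += 1
                continue
            s0 = first * n_epoch
            for p in range(config.n_segments):
                sl = ps.slice(s0 + p * n_seg, s0 + (p + 1) * n_seg)
                mat = connectivity_from_phase(
                    sl.phase, sl.valid, fs, window_s=config.window_s,
                    hop_s=config.hop_s, aggregation=config.aggregation)
                ge = global_efficiency(
                    proportional_threshold(mat, config.density))
                onset_rows.append({"subject": subject_id, "group": group,
                                   "band": band, "stage": stage,
                                   "onset_epoch": first, "position": p + 1,
                                   "ge": ge})
    if skipped_onsets:
        log.info("%s: %d stage onsets skipped (masked first epoch)",
                 subject_id, skipped_onsets)
    return metrics_rows, onset_rows, matrix_sums


def analyze_cohort(subjects, config: RunConfig):
    """Run :func:`analyze_recording` over ``(subject_id, group, recording,
    hypnogram[, mask])`` tuples and assemble cohort-level tables.

    Returns a dict with the per-epoch ``metrics`` table, per-onset
    ``onsets`` table, aggregated ``traces``, and per-(group, band, stage)
    participant-mean connectivity ``matrices``.
    """
    all_metrics, all_onsets = [], []
    sums = {}
    channels = None
    for item in subjects:
        sid, group, rec, hyp = item[:4]
        mask = item[4] if len(item) > 4 else None
        channels = rec.channels
        m, o, ms = analyze_recording(rec, hyp, mask, sid, group, config)
        all_metrics.extend(m)
        all_onsets.extend(o)
        for key, (total, count) in ms.items():
            gkey = (group,) + key
            t0, c0 = sums.get(gkey, (0.0, 0))
            sums[gkey] = (t0 + total, c0 + count)
    metrics = pd.DataFrame(all_metrics)
    onsets = pd.DataFrame(all_onsets)
    traces = transition_traces(onsets) if len(onsets) else pd.DataFrame()
    matrices = {key: total / count for key, (total, count) in sums.items()}
    return {"metrics": metrics, "onsets": onsets, "traces": traces,
            "matrices": matrices, "channels": channels}


def mean_matrices(results: dict) -> dict:
    return results["matrices"]


def edge_lists(results: dict, montage: dict, fraction: float = 0.30) -> pd.DataFrame:
    """Top-connectivity edge lists of every (group, band, stage) mean matrix."""
    rows = []
    channels = results["channels"]
    for (group, band, stage), mat in sorted(results["matrices"].items()):
        for ci, cj, w, flag in top_connectivity_graph(mat, channels, montage,
                                                      fraction):
            rows.append({"group": group, "band": band, "stage": stage,
                         "chan_i": ci, "chan_j": cj, "weight": w,
                         "hemisphere": flag})
    return pd.DataFrame(rows)
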