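"""Band-limiting and segmentation of scored sleep recordings.

Segmentation follows the epoch/window scheme of the connectivity analysis:
30-s scored epochs, 3-s analysis windows advancing by 1 s (2-s overlap, so a
30-s epoch yields exactly 28 windows), and — for the stage-transition
dynamics — the first artifact-free 30-s epoch at each stage-run onset split
into three contiguous 10-s segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import EpochMask, Hypnogram, Recording

__all__ = [
    "Epoch",
    "AnalysisWindow",
    "bandlimit",
    "extract_epochs",
    "sliding_windows",
    "stage_transition_segments",
    "window_count",
]

#: Edge region (s) of a forward-backward filtered record that downstream
#: window statistics should treat as transient-contaminated.
FILTER_EDGE_S = 2.0


def bandlimit(recording: Recording, f_low: float = 0.5, f_high: float = 50.0,
              order: int = 4) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass, applied per channel.

    Band edges are the -3 dB points of the analog prototype (bilinear
    transform); the filter runs forward and backward (``sosfiltfilt``) so the
    net phase response is zero: filtering a time-reversed signal equals
    time-reversing the filtered signal.  The first and last
    :data:`FILTER_EDGE_S` seconds carry start-up transients.

    Raises if the upper edge is not strictly below Nyquist.
    """
    nyq = recording.fs / 2.0
    if f_high >= nyq:
        raise ValueError(
            f"upper passband edge {f_high} Hz must be below Nyquist "
            f"({nyq} Hz at fs={recording.fs})")
    if not 0 < f_low < f_high:
        raise ValueError("need 0 < f_low < f_high")
    sos = butter(order, [f_low, f_high], btype="bandpass", fs=recording.fs,
                 output="sos")
    # pad well past the low-edge pole ring-down (tau ~ 1/(pi*f_low)) so the
    # forward and backward passes see steady state at the record edges
    padlen = min(recording.n_samples - 1, int(round(10.0 * recording.fs / f_low)))
    filtered = sosfiltfilt(sos, recording.data, axis=1, padlen=padlen)
    return Recording(channels=list(recording.channels), fs=recording.fs,
                     data=filtered, montage=dict(recording.montage))


@dataclass
class Epoch:
    """One kept 30-s scored epoch."""

    subject_id: str
    stage: str
    index: int           # position in the hypnogram
    start_sample: int
    data: np.ndarray     # channels x samples

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class AnalysisWindow:
    """A 3-s view into an epoch, offset in whole seconds from its start."""

    epoch: Epoch
    offset_s: float
    data: np.ndarray


def extract_epochs(recording: Recording, hypnogram: Hypnogram,
                   mask: EpochMask | None = None,
                   subject_id: str = "") -> list:
    """One :class:`Epoch` per kept hypnogram entry.

    Epoch ``i`` covers samples ``[i*30*fs, (i+1)*30*fs)``; trailing epochs
    that overrun the recording are an error, as is a mask of the wrong
    length.
    """
    if mask is None:
        mask = EpochMask.all_keep(len(hypnogram))
    if len(mask) != len(hypnogram):
        raise ValueError(
            f"mask has {len(mask)} entries for {len(hypnogram)} epochs")
    if hypnogram.duration > recording.duration + 1e-9:
        raise ValueError(
            f"hypnogram covers {hypnogram.duration} s but recording is only "
            f"{recording.duration} s")
    epochs = []
    for i, stage in enumerate(hypnogram):
        if not mask.keep[i]:
            continue
        s0, s1 = hypnogram.epoch_bounds(i, recording.fs)
        epochs.append(Epoch(subject_id=subject_id, stage=stage, index=i,
                            start_sample=s0, data=recording.data[:, s0:s1]))
    return epochs


def window_count(length_s: float, window_s: float = 3.0, hop_s: float = 1.0) -> int:
    """Number of sliding windows in a block: floor((L - w)/h) + 1."""
    if length_s < window_s:
        return 0
    return int(np.floor((length_s - window_s) / hop_s + 1e-9)) + 1


def sliding_windows(epoch: Epoch, fs: float, window_s: float = 3.0,
                    hop_s: float = 1.0) -> list:
    """Tile an epoch (or 10-s segment) into 3-s windows at 1-s hop.

    A 30-s epoch yields 28 windows at offsets 0..27 s; a 10-s dynamics
    segment yields 8.
    """
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    out = []
    for k, start in enumerate(range(0, epoch.n_samples - win + 1, hop)):
        out.append(AnalysisWindow(epoch=epoch, offset_s=k * hop_s,
                                  data=epoch.data[:, start:start + win]))
    return out


def stage_transition_segments(recording: Recording, hypnogram: Hypnogram,
                              mask: EpochMask | None = None,
                              subject_id: str = "",
                              n_segments: int = 3):
    """First kept epoch of every stage-run onset, split into 10-s segments.

    For each maximal run of a constant stage label, the run's first epoch is
    taken — provided the mask keeps it, otherwise the onset is skipped — and
    divided into ``n_segments`` contiguous equal segments (three 10-s
    segments of a 30-s epoch by default).

    Returns
    -------
    segments : list of (Epoch, position, ndarray)
        ``position`` is 1-based within the onset epoch.
    skipped : int
        Number of onsets whose first epoch was masked out.
    """
    if mask is None:
        mask = EpochMask.all_keep(len(hypnogram))
    if len(mask) != len(hypnogram):
        raise ValueError(
            f"mask has {len(mask)} entries for {len(hypnogram)} epochs")
    segments = []
    skipped = 0
    for stage, first, _length in hypnogram.stage_runs():
        if not mask.keep[first]:
            skipped += 1
            continue
        s0, s1 = hypnogram.epoch_bounds(first, recording.fs)
        block = recording.data[:, s0:s1]
        seg_len = block.shape[1] // n_segments
        ep = Epoch(subject_id=subject_id, stage=stage, index=first,
                   start_sample=s0, data=block)
        for p in range(n_segments):
            segments.append((ep, p + 1, block[:, p * seg_len:(p + 1) * seg_len]))
    return segments, skipped
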