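"""Data containers and file I/O for sleep-EEG recordings.

The pipeline works on three objects: a :class:`Recording` (multichannel EEG in
microvolts with a 10-20 montage), a :class:`Hypnogram` (one AASM stage label
per 30-s epoch) and an :class:`EpochMask` (externally supplied artifact
rejection, one keep/drop flag per epoch).

Recordings travel as EDF (European Data Format): a 256-byte fixed-layout ASCII
header, one 256-byte ASCII header per signal, then 16-bit little-endian data
records.  The reader and writer below implement the continuous-EDF subset the
pipeline needs (identical sampling rate across the selected channels,
integer-second record duration).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_CHANNELS",
    "HEMISPHERE",
    "REGION",
    "STAGES",
    "Recording",
    "Hypnogram",
    "EpochMask",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_epoch_mask",
]

#: AASM stage alphabet, in conventional hypnogram order.
STAGES = ("W", "N1", "N2", "N3", "R")

#: Canonical 16-channel 10-20 montage, left/right interleaved by region.
CANONICAL_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "P3", "P4", "O1", "O2", "T3", "T4", "T5", "T6",
)

HEMISPHERE = {
    ch: ("left" if int(re.search(r"\d+", ch).group()) % 2 == 1 else "right")
    for ch in CANONICAL_CHANNELS
}

REGION = {
    "Fp1": "frontal-pole", "Fp2": "frontal-pole",
    "F3": "frontal", "F4": "frontal", "F7": "frontal", "F8": "frontal",
    "C3": "central", "C4": "central",
    "P3": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
}

#: Default stage-label synonyms accepted by :func:`read_hypnogram`.
STAGE_SYNONYMS = {
    "W": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3", "4": "N3",
    "R": "R", "REM": "R", "5": "R",
}

_REF_SUFFIX = re.compile(r"[/-](M1|M2|A1|A2|REF|AVG)$", re.IGNORECASE)


def _strip_reference(label: str) -> str:
    """'F3/M2' or 'F3-A1' -> 'F3'; EEG prefix ('EEG F3') is also dropped."""
    label = label.strip()
    if label.upper().startswith("EEG "):
        label = label[4:].strip()
    return _REF_SUFFIX.sub("", label)


def default_montage(channels) -> dict:
    """hemisphere/region tags for a channel list (canonical names only)."""
    out = {}
    for ch in channels:
        if ch in HEMISPHERE:
            out[ch] = {"hemisphere": HEMISPHERE[ch], "region": REGION[ch]}
    return out


@dataclass
class Recording:
    """Multichannel EEG block.

    Parameters
    ----------
    channels : list of str
        Channel labels, one per row of ``data``.
    fs : float
        Sampling rate in Hz (identical for all channels).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    montage : dict, optional
        ``channel -> {"hemisphere": "left"|"right", "region": ...}``.
    """

    channels: list
    fs: float
    data: np.ndarray
    montage: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not self.montage:
            self.montage = default_montage(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def hemisphere_channels(self, side: str) -> list:
        return [c for c in self.channels
                if self.montage.get(c, {}).get("hemisphere") == side]


@dataclass
class Hypnogram:
    """Ordered AASM stage labels, one per fixed-length epoch."""

    labels: list
    epoch_length_s: float = 30.0

    def __post_init__(self):
        self.labels = list(self.labels)
        bad = sorted({l for l in self.labels} - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}; expected {STAGES}")

    def __len__(self):
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_length_s

    def epoch_bounds(self, i: int, fs: float) -> tuple:
        """Half-open sample interval of epoch ``i``: [i*30*fs, (i+1)*30*fs)."""
        n = int(round(self.epoch_length_s * fs))
        return i * n, (i + 1) * n

    def stage_runs(self):
        """Maximal runs of a constant label as (stage, first_epoch, length)."""
        runs = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                runs.append((self.labels[start], start, i - start))
                start = i
        return runs


@dataclass
class EpochMask:
    """Boolean keep-flag per hypnogram epoch (True = artifact-free)."""

    keep: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 1:
            raise ValueError("mask must be 1-D")

    def __len__(self):
        return len(self.keep)

    @classmethod
    def all_keep(cls, n: int) -> "EpochMask":
        return cls(np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_PHYS_RANGE = 500.0  # default physical range +-500 uV
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(s: str, n: int) -> bytes:
    b = str(s).encode("ascii")
    if len(b) > n:
        raise ValueError(f"EDF header field too long: {s!r} (max {n})")
    return b.ljust(n)


def write_edf(recording: Recording, path, physical_range: float = _EDF_PHYS_RANGE,
              start_date: str = "01.01.00", start_time: str = "00.00.00") -> None:
    """Write a recording as 16-bit continuous EDF, one data record per second.

    Samples outside ``+-physical_range`` microvolts are clipped.  The sampling
    rate must be a positive integer (samples per 1-s record).  The start
    date/time default to a fixed value so that identical recordings produce
    byte-identical files.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))
    ns = len(recording.channels)
    n_rec = int(np.ceil(recording.n_samples / spr))
    pmin, pmax = -physical_range, physical_range

    header = b"".join([
        _pad("0", 8),                       # version
        _pad("X X X X", 80),                # patient id (anonymous)
        _pad("Startdate X X X X", 80),      # recording id
        _pad(start_date, 8),
        _pad(start_time, 8),
        _pad(str(256 * (1 + ns)), 8),       # header bytes
        _pad("", 44),                       # reserved
        _pad(str(n_rec), 8),
        _pad("1", 8),                       # record duration (s)
        _pad(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_pad(f"EEG {c}", 16) for c in recording.channels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_pad("uV", 8) for _ in range(ns)),
        b"".join(_pad(f"{pmin:g}", 8) for _ in range(ns)),
        b"".join(_pad(f"{pmax:g}", 8) for _ in range(ns)),
        b"".join(_pad(str(_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_pad(str(_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_pad("", 80) for _ in range(ns)),   # prefiltering
        b"".join(_pad(str(spr), 8) for _ in range(ns)),
        b"".join(_pad("", 32) for _ in range(ns)),   # reserved
    ])

    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    data = np.clip(recording.data, pmin, pmax)
    digital = np.round((data - pmin) / gain + _DIG_MIN).astype("<i2")
    # pad the final partial record with the digital value of 0 uV
    pad_width = n_rec * spr - recording.n_samples
    if pad_width:
        fill = np.int16(round((0.0 - pmin) / gain + _DIG_MIN))
        digital = np.concatenate(
            [digital, np.full((ns, pad_width), fill, dtype="<i2")], axis=1)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-major, then channel-major within the record
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def _parse_edf_header(fh):
    def rd(n):
        return fh.read(n).decode("ascii", errors="replace")

    rd(8); rd(80); rd(80); rd(8); rd(8)
    header_bytes = int(rd(8))
    rd(44)
    n_rec = int(rd(8))
    rec_dur = float(rd(8))
    ns = int(rd(4))
    labels = [rd(16).strip() for _ in range(ns)]
    rd(80 * ns)  # transducer
    rd(8 * ns)   # units
    pmin = [float(rd(8)) for _ in range(ns)]
    pmax = [float(rd(8)) for _ in range(ns)]
    dmin = [int(float(rd(8))) for _ in range(ns)]
    dmax = [int(float(rd(8))) for _ in range(ns)]
    rd(80 * ns)  # prefiltering
    spr = [int(rd(8)) for _ in range(ns)]
    rd(32 * ns)
    return header_bytes, n_rec, rec_dur, labels, pmin, pmax, dmin, dmax, spr


def read_edf(path, channels=CANONICAL_CHANNELS) -> Recording:
    """Read the requested channels from an EDF file into a :class:`Recording`.

    Channel labels in the file may carry reference suffixes (``F3/M2``,
    ``C4-A1``) or an ``EEG`` prefix; these are stripped before matching, so a
    contralateral-mastoid-referenced montage is read under its plain 10-20
    names.  Channels are returned in the order of ``channels`` (default: the
    canonical 16-channel montage).

    Raises
    ------
    ValueError
        If a requested channel is absent (the message names it) or if the
        selected channels disagree on sampling rate.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        (header_bytes, n_rec, rec_dur, labels, pmin, pmax,
         dmin, dmax, spr) = _parse_edf_header(fh)
        stripped = [_strip_reference(l) for l in labels]
        lut = {}
        for i, name in enumerate(stripped):
            lut.setdefault(name.upper(), i)
        missing = [c for c in channels if c.upper() not in lut]
        if missing:
            raise ValueError(
                f"channel(s) {missing} not found in {path.name}; "
                f"file contains {stripped}")
        sel = [lut[c.upper()] for c in channels]

        rates = {spr[i] / rec_dur for i in sel}
        if len(rates) != 1:
            raise ValueError(
                f"selected channels have inconsistent sampling rates: {sorted(rates)}")
        fs = rates.pop()

        fh.seek(header_bytes)
        raw = np.frombuffer(fh.read(), dtype="<i2")

    rec_len = sum(spr)
    if raw.size < n_rec * rec_len:  # tolerate a truncated final record
        n_rec = raw.size // rec_len
    raw = raw[: n_rec * rec_len].reshape(n_rec, rec_len)

    offsets = np.concatenate([[0], np.cumsum(spr)])
    data = np.empty((len(sel), n_rec * spr[sel[0]]))
    for row, i in enumerate(sel):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        chunk = raw[:, offsets[i]: offsets[i + 1]].astype(float)
        data[row] = ((chunk - dmin[i]) * gain + pmin[i]).ravel()

    return Recording(channels=list(channels), fs=fs, data=data)


# ---------------------------------------------------------------------------
# hypnogram / mask text formats
# ---------------------------------------------------------------------------

def read_hypnogram(path, epoch_length_s: float = 30.0,
                   synonyms: dict | None = None) -> Hypnogram:
    """Read a hypnogram from single-column text or 2-column CSV.

    Each non-empty, non-comment line holds one stage label (optionally
    preceded by ``epoch_index,``).  Labels are matched case-insensitively
    through a synonym map (``REM -> R``, ``Wake -> W``, numeric stage codes).
    An unknown label raises with its 1-based line number.
    """
    syn = dict(STAGE_SYNONYMS)
    if synonyms:
        syn.update({k.upper(): v for k, v in synonyms.items()})
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split(",")[-1].strip() if "," in line else line
            if lineno == 1 and token.upper() in ("LABEL", "STAGE"):
                continue
            stage = syn.get(token.upper())
            if stage is None:
                raise ValueError(
                    f"{path}: unknown stage label {token!r} on line {lineno}")
            labels.append(stage)
    return Hypnogram(labels=labels, epoch_length_s=epoch_length_s)


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index,label\n")
        for i, lab in enumerate(hypnogram.labels):
            fh.write(f"{i},{lab}\n")


def read_epoch_mask(path) -> EpochMask:
    """Single-column 0/1 text; 1 = keep the epoch."""
    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line not in ("0", "1"):
                raise ValueError(f"{path}: expected 0/1 on line {lineno}, got {line!r}")
            vals.append(line == "1")
    return EpochMask(np.array(vals, dtype=bool))
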