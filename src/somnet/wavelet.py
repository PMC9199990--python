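"""Combined-Morlet phase extraction and the weighted phase lag index (WPLI).

A single complex Morlet wavelet,

    psi(t) = (pi*fb)^(-1/2) * exp(2i*pi*fc*t) * exp(-t^2/fb),

is narrowband around its center frequency ``fc`` with bandwidth parameter
``fb`` (seconds squared; the Gaussian envelope has time SD sqrt(fb/2)).  To
cover a whole EEG band with a flat passband, wavelets at closely spaced
centers ``fM = fL + M*df`` (M = 0..N-1, df = 0.05 Hz) are superimposed and the
sum is rescaled by a correction coefficient C so the peak of the combined
amplitude-frequency response equals 1:

    psi_c(t) = (1/C) * (pi*fb)^(-1/2) * exp(-t^2/fb) * sum_M exp(2i*pi*fM*t).

Convolving a signal with psi_c yields a complex series A(tau)*exp(i*phi(tau));
phi is the instantaneous phase within the band.  For two channels i, j with
phase difference dphi = phi_i - phi_j, the WPLI is

    WPLI = |E{sin(dphi)}| / E{|sin(dphi)|}  in [0, 1],

which discounts zero-lag (volume-conduction-like) coupling: any distribution
of dphi symmetric about 0 or pi scores 0, a constant-sign lag scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "BandSpec",
    "BANDS",
    "WaveletBank",
    "PhaseSeries",
    "build_wavelet_bank",
    "extract_phase",
    "wpli",
    "connectivity_from_phase",
    "epoch_connectivity",
]

#: Default bandwidth parameter (s^2); Gaussian time SD = 1 s, per-wavelet
#: spectral SD = 1/(pi*sqrt(2*fb)) ~ 0.11 Hz, well below each band's width.
DEFAULT_FB = 2.0

#: Center-frequency spacing of the combined wavelet (Hz).
DELTA_F = 0.05


@dataclass(frozen=True)
class BandSpec:
    """A frequency band and its combined-wavelet parameterization.

    ``fL`` is the lowest wavelet center and ``n_centers`` the number of
    centers spaced ``df`` apart; every center must lie inside the band.
    """

    label: str
    f_low: float
    f_high: float
    fL: float
    n_centers: int
    df: float = DELTA_F
    fb: float = DEFAULT_FB

    def __post_init__(self):
        top = self.fL + (self.n_centers - 1) * self.df
        if self.fL < self.f_low - 1e-9 or top > self.f_high + 1e-9:
            raise ValueError(
                f"band {self.label!r}: wavelet centers {self.fL}..{top:g} Hz "
                f"exceed band edges {self.f_low}-{self.f_high} Hz")

    @property
    def centers(self) -> np.ndarray:
        return self.fL + self.df * np.arange(self.n_centers)


def _make_bands(fb: float = DEFAULT_FB) -> dict:
    return {
        "delta": BandSpec("delta", 0.5, 4.0, 0.5, 70, fb=fb),
        "theta": BandSpec("theta", 4.0, 8.0, 4.0, 80, fb=fb),
        "alpha": BandSpec("alpha", 8.0, 12.0, 8.0, 80, fb=fb),
        "sigma": BandSpec("sigma", 12.0, 16.0, 12.0, 80, fb=fb),
        "beta": BandSpec("beta", 16.0, 32.0, 16.0, 320, fb=fb),
    }


#: Canonical sleep-EEG bands: delta 0.5-4, theta 4-8, alpha 8-12,
#: sigma 12-16 and beta 16-32 Hz.
BANDS = _make_bands()

BAND_ALIASES = {"δ": "delta", "θ": "theta", "α": "alpha", "σ": "sigma", "β": "beta"}


def get_band(band) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    key = BAND_ALIASES.get(band, band)
    try:
        return BANDS[key]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


@dataclass
class WaveletBank:
    """Sampled combined-Morlet kernel for one band at one sampling rate."""

    band: BandSpec
    fs: float
    kernel: np.ndarray       # complex, odd length, centered at t=0
    correction: float        # C: peak raw magnitude response

    @property
    def half_len(self) -> int:
        return (len(self.kernel) - 1) // 2

    def frequency_response(self, freqs) -> np.ndarray:
        """|FT of the kernel| at ``freqs`` (continuous-time convention)."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        t = (np.arange(len(self.kernel)) - self.half_len) / self.fs
        ft = (self.kernel[None, :] * np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
              ).sum(axis=1) / self.fs
        return np.abs(ft)


def build_wavelet_bank(band, fs: float, fb: float | None = None,
                       truncation_sds: float = 4.0) -> WaveletBank:
    """Sample the combined Morlet wavelet for ``band`` at rate ``fs``.

    The kernel is truncated at ``truncation_sds`` Gaussian standard deviations
    (envelope below ~3e-4 of peak at the default 4).  The correction
    coefficient C is found numerically as the maximum of the discrete
    magnitude response on a grid of spacing df/10 across the band, so the
    combined passband peaks at exactly 1.

    Raises if ``fs`` does not resolve the band (f_high >= Nyquist).
    """
    spec = get_band(band)
    if fb is not None and fb != spec.fb:
        spec = BandSpec(spec.label, spec.f_low, spec.f_high, spec.fL,
                        spec.n_centers, spec.df, fb)
    if fs <= 2.0 * spec.f_high:
        raise ValueError(
            f"fs={fs} Hz cannot resolve band {spec.label!r} "
            f"(upper edge {spec.f_high} Hz requires fs > {2 * spec.f_high} Hz)")

    sd_t = np.sqrt(spec.fb / 2.0)
    half = int(np.ceil(truncation_sds * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-t ** 2 / spec.fb) / np.sqrt(np.pi * spec.fb)
    carriers = np.exp(2j * np.pi * np.outer(spec.centers, t)).sum(axis=0)
    raw = envelope * carriers

    grid = np.arange(spec.f_low, spec.f_high + spec.df / 10, spec.df / 10.0)
    ft = (raw[None, :] * np.exp(-2j * np.pi * grid[:, None] * t[None, :])
          ).sum(axis=1) / fs
    C = float(np.max(np.abs(ft)))
    return WaveletBank(band=spec, fs=float(fs), kernel=raw / C, correction=C)


@dataclass
class PhaseSeries:
    """Instantaneous phase/amplitude per channel plus an edge-validity mask.

    ``phase`` lies in (-pi, pi]; ``valid`` flags samples at least half a
    kernel length away from either end of the convolved signal, where the
    wavelet coefficient is uncontaminated by the missing data outside the
    record (no padding is ever assumed).
    """

    phase: np.ndarray        # (n_channels, n_samples)
    amplitude: np.ndarray    # (n_channels, n_samples)
    valid: np.ndarray        # (n_samples,), bool
    fs: float

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]

    def slice(self, start: int, stop: int) -> "PhaseSeries":
        return PhaseSeries(self.phase[:, start:stop], self.amplitude[:, start:stop],
                           self.valid[start:stop], self.fs)


def extract_phase(signal, bank: WaveletBank) -> PhaseSeries:
    """Complex wavelet transform of ``signal`` (1-D or channels x samples).

    The transform is the convolution integral of the signal with the
    conjugate-reflected kernel, which for this Hermitian kernel reduces to a
    plain convolution; phase = argument, amplitude = modulus of the result.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if x.shape[1] <= len(bank.kernel):
        raise ValueError(
            f"signal ({x.shape[1]} samples) must be longer than the wavelet "
            f"kernel ({len(bank.kernel)} samples); band {bank.band.label!r}")
    # WS(tau) = int S(t) conj(psi(t - tau)) dt; conj(psi(-u)) = psi(u)
    ws = fftconvolve(x, bank.kernel[None, :], mode="same", axes=1) / bank.fs
    valid = np.zeros(x.shape[1], dtype=bool)
    valid[bank.half_len: x.shape[1] - bank.half_len] = True
    return PhaseSeries(phase=np.angle(ws), amplitude=np.abs(ws),
                       valid=valid, fs=bank.fs)


def wpli(phase_a, phase_b, valid_mask=None) -> float:
    """WPLI of two equal-length phase series over the valid samples.

    Numerator and denominator are sample means of sin(dphi) and |sin(dphi)|.
    Returns 0 when the denominator vanishes (all phase differences at 0 or
    pi, i.e. pure zero-lag coupling); raises if no valid samples remain.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal length")
    if valid_mask is not None:
        m = np.asarray(valid_mask, dtype=bool)
        a, b = a[m], b[m]
    if a.size < 2:
        raise ValueError("need at least 2 valid samples for WPLI")
    s = np.sin(a - b)
    den = np.mean(np.abs(s))
    if den == 0.0:
        return 0.0
    return float(abs(np.mean(s)) / den)


def _window_starts(n_samples: int, win: int, hop: int) -> np.ndarray:
    if n_samples < win:
        return np.array([], dtype=int)
    return np.arange(0, n_samples - win + 1, hop)


def connectivity_from_phase(phase: np.ndarray, valid: np.ndarray, fs: float,
                            window_s: float = 3.0, hop_s: float = 1.0,
                            aggregation: str = "pooled") -> np.ndarray:
    """Channel x channel WPLI matrix from a block of instantaneous phase.

    The block is tiled into sliding analysis windows (default 3 s long,
    advancing by 1 s, i.e. 2 s overlap).  Two aggregation modes:

    - ``"pooled"`` (default): the expectations run over every valid sample
      covered by the windows, pooling numerator and denominator across the
      whole block.
    - ``"window-mean"``: WPLI is formed within each window and the per-window
      values averaged; windows with fewer than 2 valid samples are skipped.

    Returns a symmetric matrix with zero diagonal, entries in [0, 1].
    """
    if aggregation not in ("pooled", "window-mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    nc, T = phase.shape
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    starts = _window_starts(T, win, hop)
    if starts.size == 0:
        raise ValueError(f"block of {T} samples shorter than one "
                         f"{window_s}-s window")
    z = np.exp(1j * phase)
    # sin(phi_i - phi_j) = Im(z_i * conj(z_j)); build per-pair series lazily
    iu, ju = np.triu_indices(nc, k=1)
    sin_d = np.imag(z[iu] * np.conj(z[ju]))        # (n_pairs, T)

    mat = np.zeros((nc, nc))
    if aggregation == "pooled":
        covered = np.zeros(T, dtype=bool)
        for s in starts:
            covered[s:s + win] = True
        m = covered & valid
        if m.sum() < 2:
            raise ValueError("no valid samples inside the analysis windows")
        sel = sin_d[:, m]
        den = np.mean(np.abs(sel), axis=1)
        num = np.abs(np.mean(sel, axis=1))
        vals = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    else:
        acc = np.zeros(len(iu))
        n_win = 0
        for s in starts:
            m = valid[s:s + win]
            if m.sum() < 2:
                continue
            sel = sin_d[:, s:s + win][:, m]
            den = np.mean(np.abs(sel), axis=1)
            num = np.abs(np.mean(sel, axis=1))
            acc += np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            n_win += 1
        if n_win == 0:
            raise ValueError("no analysis window had >= 2 valid samples")
        vals = acc / n_win
    mat[iu, ju] = vals
    mat[ju, iu] = vals
    return mat


def epoch_connectivity(block, bank: WaveletBank, window_s: float = 3.0,
                       hop_s: float = 1.0, aggregation: str = "pooled") -> np.ndarray:
    """WPLI connectivity of one epoch/segment (channels x samples block).

    Convenience wrapper: wavelet phase extraction followed by
    :func:`connectivity_from_phase`.  Note that extracting phase from an
    isolated 30-s block forfeits half a kernel length at each end; pipelines
    that have the whole night available should extract phase once per
    recording and slice (see :mod:`somnet.pipeline`).
    """
    ps = extract_phase(block, bank)
    return connectivity_from_phase(ps.phase, ps.valid, ps.fs,
                                   window_s=window_s, hop_s=hop_s,
                                   aggregation=aggregation)
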