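"""Surrogate sleep-EEG with known phase-coupling ground truth.

Every channel of a simulated recording carries, per frequency band, a
narrowband oscillation

    x_i(t) = A_i * cos(2*pi*f_c*t + phi_ref(t) + eps_i(t)) ,

where ``f_c`` is the band-center carrier, ``phi_ref`` is a slowly drifting
random phase common to all channels (it cancels in every phase difference, so
it exercises the WPLI's invariance to shared phase), and ``eps_i`` is a
per-channel phase offset drawn from a von Mises distribution vM(mu_i,
kappa_i) about the common reference, redrawn independently every coherence
block (3 s by default, matching the analysis window).  Bands are summed and
white Gaussian noise added.

The phase difference of a pair (i, j) is eps_i - eps_j.  When one channel is
phase-locked to the reference (kappa = inf), the pair difference is exactly
von Mises, and :func:`wpli_ground_truth` gives the population WPLI the
downstream estimator must recover.  For two free channels the difference
follows the circular convolution of the two von Mises laws;
:func:`pair_wpli_ground_truth` integrates over that law instead.

A "cohort" scales the concentrations: patients get ``group_effect * kappa``
everywhere, plus ``delta_right_effect`` on right-hemisphere channels in the
delta band, encoding the two directional findings the pipeline must recover
(globally stronger coupling, delta-band right lateralization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, special

from .io import CANONICAL_CHANNELS, HEMISPHERE, Hypnogram, Recording, STAGES
from .wavelet import get_band

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "wpli_ground_truth",
    "pair_wpli_ground_truth",
    "simulate_recording",
    "simulate_hypnogram",
    "simulate_cohort",
]

#: Default per-band oscillation amplitudes (uV), decreasing with frequency as
#: in scalp sleep EEG, and broadband noise SD (uV).
DEFAULT_AMPLITUDE = {"delta": 40.0, "theta": 30.0, "alpha": 25.0,
                     "sigma": 15.0, "beta": 10.0}
DEFAULT_NOISE_SD = 15.0

#: Coherence block: phase offsets are redrawn at this period (s).
DEFAULT_BLOCK_S = 3.0


def _von_mises_pdf(x, mu, kappa):
    # exponentially scaled Bessel keeps this finite for large kappa
    return np.exp(kappa * (np.cos(x - mu) - 1.0)) / (2 * np.pi * special.ive(0, kappa))


def wpli_ground_truth(mu: float, kappa: float) -> float:
    """Population WPLI of a von Mises phase difference, by quadrature.

    Evaluates |E{sin d}| / E{|sin d|} for d ~ vM(mu, kappa).  Returns 0 when
    the denominator vanishes (kappa = inf with the mass at 0 or pi).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if np.isinf(kappa):
        s = np.sin(mu)
        return 0.0 if s == 0 else 1.0
    mu_w = float(np.angle(np.exp(1j * mu)))  # wrap the peak into the interval
    num, _ = integrate.quad(
        lambda x: np.sin(x) * _von_mises_pdf(x, mu_w, kappa), -np.pi, np.pi,
        limit=200, points=[mu_w])
    den, _ = integrate.quad(
        lambda x: abs(np.sin(x)) * _von_mises_pdf(x, mu_w, kappa), -np.pi, np.pi,
        limit=200, points=[mu_w, 0.0])
    if den == 0.0:
        return 0.0
    return float(abs(num) / den)


def pair_wpli_ground_truth(mu_i, kappa_i, mu_j, kappa_j, n_grid: int = 4096) -> float:
    """Population WPLI of eps_i - eps_j for two independent von Mises offsets.

    The difference law is the circular convolution of vM(mu_i, kappa_i) and
    vM(-mu_j, kappa_j), evaluated on a grid via FFT.
    """
    if np.isinf(kappa_i) and np.isinf(kappa_j):
        s = np.sin(mu_i - mu_j)
        return 0.0 if s == 0 else 1.0
    if np.isinf(kappa_i):
        return wpli_ground_truth(mu_i - mu_j, kappa_j)
    if np.isinf(kappa_j):
        return wpli_ground_truth(mu_i - mu_j, kappa_i)
    x = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    fi = _von_mises_pdf(x, mu_i, kappa_i)
    fj = _von_mises_pdf(-x, mu_j, kappa_j)  # density of -eps_j
    conv = np.real(np.fft.ifft(np.fft.fft(fi) * np.fft.fft(fj))) * (2 * np.pi / n_grid)
    s = np.sin(x)
    num = abs(np.sum(s * conv)) * (2 * np.pi / n_grid)
    den = np.sum(np.abs(s) * conv) * (2 * np.pi / n_grid)
    return 0.0 if den <= 0 else float(num / den)


@dataclass
class CouplingSpec:
    """Phase-coupling structure of one band.

    ``mu[i]``/``kappa[i]`` parameterize channel i's von Mises offset about
    the band's common reference phase; ``kappa = inf`` pins the channel to
    the reference (useful to make a chosen pair's phase difference exactly
    von Mises).  Induced pair parameters: mean lag mu_i - mu_j
    (antisymmetric), coupling strength increasing in both concentrations.
    """

    band: str
    mu: np.ndarray
    kappa: np.ndarray
    amplitude: float | np.ndarray = 30.0
    carrier: float | None = None  # Hz; default: band midpoint

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if self.mu.shape != self.kappa.shape:
            raise ValueError("mu and kappa must have the same length")
        if np.any(self.kappa < 0):
            raise ValueError(f"band {self.band!r}: kappa must be >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.mu)

    @property
    def carrier_hz(self) -> float:
        if self.carrier is not None:
            return float(self.carrier)
        spec = get_band(self.band)
        return 0.5 * (spec.f_low + spec.f_high)

    def scaled(self, factor: float, channel_mask=None) -> "CouplingSpec":
        """New spec with kappa multiplied by ``factor`` (optionally per-channel)."""
        kappa = self.kappa.copy()
        if channel_mask is None:
            kappa = kappa * factor
        else:
            kappa[np.asarray(channel_mask, dtype=bool)] *= factor
        return replace(self, kappa=kappa)

    def pair_ground_truth(self, i: int, j: int) -> float:
        return pair_wpli_ground_truth(self.mu[i], self.kappa[i],
                                      self.mu[j], self.kappa[j])


def _reference_phase(n_samples, fs, rng, drift_sd_per_sqrt_s=0.3):
    """Slow common phase drift: Gaussian random walk, SD ~0.3 rad per sqrt(s)."""
    steps = rng.normal(0.0, drift_sd_per_sqrt_s / np.sqrt(fs), size=n_samples)
    phi = np.cumsum(steps)
    return phi + rng.uniform(-np.pi, np.pi)


def _draw_offsets(spec: CouplingSpec, n_blocks: int, rng) -> np.ndarray:
    """(n_channels, n_blocks) von Mises offsets; kappa=inf -> constant mu."""
    out = np.empty((spec.n_channels, n_blocks))
    for i in range(spec.n_channels):
        if np.isinf(spec.kappa[i]):
            out[i] = spec.mu[i]
        elif spec.kappa[i] == 0.0:
            out[i] = rng.uniform(-np.pi, np.pi, size=n_blocks)
        else:
            out[i] = rng.vonmises(spec.mu[i], spec.kappa[i], size=n_blocks)
    return out


def simulate_recording(coupling_specs, hypnogram, fs: float, seed,
                       noise_sd: float = DEFAULT_NOISE_SD,
                       channels=None,
                       coherence_block_s: float = DEFAULT_BLOCK_S) -> Recording:
    """Render a multichannel surrogate recording from per-band coupling specs.

    ``coupling_specs`` is a list of :class:`CouplingSpec` (one per band);
    ``hypnogram`` (or a plain duration in seconds) sets the length.  Output
    is deterministic given ``seed`` (an int or ``numpy`` SeedSequence).
    """
    specs = list(coupling_specs)
    if not specs:
        raise ValueError("need at least one CouplingSpec")
    nc = specs[0].n_channels
    for sp in specs:
        if sp.n_channels != nc:
            raise ValueError("all coupling specs must cover the same channels")
        band = get_band(sp.band)
        if fs <= 2.0 * band.f_high:
            raise ValueError(
                f"fs={fs} Hz too low for band {sp.band!r} "
                f"(upper edge {band.f_high} Hz)")
    if channels is None:
        channels = list(CANONICAL_CHANNELS[:nc]) if nc <= 16 else \
            [f"ch{i}" for i in range(nc)]
    duration = hypnogram.duration if isinstance(hypnogram, Hypnogram) else float(hypnogram)
    n_samples = int(round(duration * fs))
    block = int(round(coherence_block_s * fs))
    n_blocks = int(np.ceil(n_samples / block))

    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    data = np.zeros((nc, n_samples))
    for sp in specs:
        phi_ref = _reference_phase(n_samples, fs, rng)
        offsets = _draw_offsets(sp, n_blocks, rng)
        eps = np.repeat(offsets, block, axis=1)[:, :n_samples]
        amp = np.broadcast_to(np.atleast_1d(sp.amplitude), (nc,))
        data += amp[:, None] * np.cos(
            2 * np.pi * sp.carrier_hz * t[None, :] + phi_ref[None, :] + eps)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return Recording(channels=channels, fs=fs, data=data)


#: Per-stage epoch-count bounds (inclusive) for one sleep cycle, in 30-s
#: epochs: brief wake and N1, long N2/N3, a REM period closing the cycle.
DEFAULT_STAGE_BOUNDS = {
    "W": (2, 8), "N1": (1, 4), "N2": (10, 30), "N3": (10, 30), "R": (5, 20),
}

#: Within-cycle stage order (descent through NREM, back to N2, then REM).
CYCLE_ORDER = ("W", "N1", "N2", "N3", "N2", "R")


def simulate_hypnogram(n_cycles: int, seed, stage_bounds=None) -> Hypnogram:
    """Plausible whole-night stage sequence: ``n_cycles`` repetitions of
    W -> N1 -> N2 -> N3 -> N2 -> R with run lengths drawn uniformly within
    ``stage_bounds`` (epochs).  Deterministic given ``seed``; every stage
    occurs at least once for any ``n_cycles >= 1``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    bounds = dict(DEFAULT_STAGE_BOUNDS)
    if stage_bounds:
        bounds.update(stage_bounds)
    rng = np.random.default_rng(seed)
    labels = []
    for _ in range(n_cycles):
        for stage in CYCLE_ORDER:
            lo, hi = bounds[stage]
            labels.extend([stage] * int(rng.integers(lo, hi + 1)))
    return Hypnogram(labels=labels)


def default_coupling(bands=("delta", "theta", "alpha", "sigma", "beta"),
                     n_channels: int = 16, base_kappa: float = 1.0,
                     lag_step: float = 0.4) -> list:
    """Baseline (control-group) coupling.

    Homologous left/right channel pairs share a mean lag (``lag_step`` times
    their anterior-posterior position), so the two hemispheres are exactly
    exchangeable at baseline — lateralization can only enter through the
    patient-group kappa scaling.  Pair lags then span a realistic mixture:
    zero within a region (suppressed by WPLI, like volume conduction) and
    increasing with region separation.
    """
    mu = lag_step * (np.arange(n_channels) // 2)
    mu = np.angle(np.exp(1j * mu))  # wrap to (-pi, pi]
    return [
        CouplingSpec(band=b, mu=mu, kappa=np.full(n_channels, base_kappa),
                     amplitude=DEFAULT_AMPLITUDE[b])
        for b in bands
    ]


@dataclass
class CohortSpec:
    """Two-group study design for the surrogate cohort.

    ``group_effect`` multiplies every patient concentration (>= 1 encodes
    "patients more strongly phase-coupled"); ``delta_right_effect``
    additionally multiplies the delta-band concentrations of right-hemisphere
    channels in patients, producing the right-lateralized delta coupling.
    """

    n_control: int = 10
    n_patient: int = 10
    group_effect: float = 1.5
    delta_right_effect: float = 1.3
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    fs: float = 100.0
    epochs_per_stage: int = 4
    base_kappa: float = 1.0
    bands: tuple = ("delta", "theta", "alpha", "sigma", "beta")
    channels: tuple = CANONICAL_CHANNELS

    def __post_init__(self):
        if self.n_control < 1 or self.n_patient < 1:
            raise ValueError("both groups need at least one subject")
        if self.group_effect < 1 or self.delta_right_effect < 1:
            raise ValueError("effect multipliers must be >= 1")

    def hypnogram(self) -> Hypnogram:
        """Fixed stage schedule: one run of each stage, ``epochs_per_stage``
        epochs long (20 epochs = 10 min at the default 4)."""
        labels = []
        for stage in STAGES:
            labels.extend([stage] * self.epochs_per_stage)
        return Hypnogram(labels=labels)

    def coupling_for(self, group: str) -> list:
        specs = default_coupling(self.bands, len(self.channels), self.base_kappa)
        if group == "control":
            return specs
        right = np.array([HEMISPHERE.get(c) == "right" for c in self.channels])
        out = []
        for sp in specs:
            sp = sp.scaled(self.group_effect)
            if sp.band == "delta":
                sp = sp.scaled(self.delta_right_effect, channel_mask=right)
            out.append(sp)
        return out


def simulate_cohort(spec: CohortSpec):
    """Yield ``(subject_id, group, Recording, Hypnogram)`` for the cohort.

    Per-subject random streams are spawned deterministically from the cohort
    seed, so any subject can be regenerated independently and the whole
    cohort is byte-reproducible.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_control + spec.n_patient
    children = ss.spawn(n_total)
    hyp = spec.hypnogram()
    out = []
    k = 0
    for group, n in (("control", spec.n_control), ("patient", spec.n_patient)):
        coupling = spec.coupling_for(group)
        for i in range(n):
            rec = simulate_recording(
                coupling, hyp, spec.fs, children[k],
                noise_sd=spec.noise_sd, channels=list(spec.channels))
            out.append((f"{group[0]}{i:02d}", group, rec, hyp))
            k += 1
    return out


def ground_truth_tables(spec: CohortSpec) -> dict:
    """Per-group, per-band mu/kappa vectors (JSON-serializable)."""
    gt = {}
    for group in ("control", "patient"):
        gt[group] = {
            sp.band: {"mu": sp.mu.tolist(), "kappa": sp.kappa.tolist(),
                      "carrier_hz": sp.carrier_hz}
            for sp in spec.coupling_for(group)
        }
    return gt
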