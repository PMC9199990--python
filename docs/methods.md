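# Methods

`somnet` estimates cortical functional networks from scored overnight EEG and
compares them between two groups.  This note documents the model, the
numerical choices, and what the surrogate-data experiments do and do not
establish.

## Connectivity model

**Instantaneous phase.**  Within each frequency band — δ 0.5–4 Hz, θ 4–8 Hz,
α 8–12 Hz, σ 12–16 Hz, β 16–32 Hz — phase is extracted with a *combined
Morlet wavelet*: a superposition of complex Morlet wavelets

ψ_c(t) = (1/C) (π f_b)^{-1/2} e^{-t²/f_b} Σ_{M=0}^{N-1} e^{2πi f_M t},
  f_M = f_L + M·Δf,

with center spacing Δf = 0.05 Hz.  The center layout is f_L = band lower
edge and N = band width / Δf (δ: f_L = 0.5, N = 70; θ: f_L = 4, N = 80;
α: 8/80; σ: 12/80; β: 16/320), so the centers tile the band and the summed
Gaussian spectra form a flat passband with a narrow transition band.  The
correction coefficient C is found numerically as the maximum of the sampled
kernel's magnitude response on a grid of Δf/10 across the band, making the
passband peak exactly 1.  Convolving a channel with ψ_c gives
A(τ)e^{iφ(τ)}; φ is the band-limited instantaneous phase.

**Bandwidth parameter.**  f_b (units s²) sets the per-wavelet envelope: time
SD √(f_b/2), spectral SD 1/(π√(2 f_b)).  Default f_b = 2 s² (time SD 1 s,
spectral SD ≈ 0.11 Hz) — narrow enough that the 0.5 Hz δ centers leak
negligibly across 0 Hz (relative response ~7·10⁻³ at DC), wide enough in
frequency that adjacent centers overlap heavily and the in-band ripple is
below 2% away from the band edges.  Configurable per run.

**Kernel truncation and edges.**  The kernel is truncated at ±4 envelope SDs
(±4√(f_b/2) s), where the Gaussian is below 3·10⁻⁴ of peak.  Convolution
uses no padding: samples within half a kernel of either end of the record
are flagged invalid and excluded from every estimate.  The pipeline
therefore extracts phase once over the whole (filtered) recording and slices
epochs out of the phase series, confining edge losses to the first and last
few seconds of the night rather than every epoch.

**WPLI.**  For channels i, j with Δφ = φ_i − φ_j, the weighted phase lag
index is

WPLI = |E{sin Δφ}| / E{|sin Δφ|} ∈ [0, 1].

Any Δφ distribution symmetric about 0 or π (in particular instantaneous
volume-conduction-like zero-lag mixing) scores 0; a constant-sign lag scores
1.  The convention WPLI = 0 when the denominator vanishes.

**Expectation windows.**  Estimates are formed over 3-s analysis windows
advancing by 1 s (a 30-s epoch holds exactly 28, a 10-s segment 8).  Two
aggregation modes are implemented:

- `pooled` (default): numerator and denominator are sample means over every
  valid sample covered by the epoch's windows;
- `window-mean`: WPLI per window, then the arithmetic mean of the 28 (or 8)
  per-window values.

Pooling is the default because the per-window ratio degenerates whenever the
phase difference is locally stationary: if Δφ barely moves within 3 s,
sin Δφ keeps one sign and *every* window reports ≈1 regardless of the
coupling strength, so the window-mean cannot converge to the population WPLI.
The pooled estimator is consistent (it converges to the population ratio as
windows accumulate) and is what all ground-truth comparisons use.  The
alternative remains available for sensitivity analyses.

## Preprocessing and segmentation

A 4th-order Butterworth bandpass (0.5–50 Hz edges, −3 dB analog prototype,
bilinear transform) is applied forward and backward (zero net phase).
Padding for the forward–backward pass extends 10/f_low seconds — well past
the low-edge pole ring-down — so the filter is effectively in steady state
at the record edges; the first/last 2 s are still treated as
transient-contaminated.  For recordings whose Nyquist frequency falls below
50 Hz the upper edge is clipped to 0.45·fs.

Epoch i of the hypnogram covers samples [i·30·fs, (i+1)·30·fs) (0-based,
half-open).  Artifact handling is an external per-epoch keep/drop mask; no
automatic detection is attempted.  For the stage-transition dynamics, every
maximal run of a constant stage contributes its first epoch — every onset in
the night, not just the first occurrence of each stage — provided the mask
keeps it; the epoch is split into three contiguous 10-s segments analyzed
with the same 3-s/1-s windowing (8 windows each).

## Graph metrics

Per epoch (or segment) and band, the 16×16 WPLI matrix is:

- **proportionally thresholded** at density 0.30: the round(0.30·120) = 36
  strongest upper-triangle edges are kept, ties broken by lexicographic
  (i, j) order for determinism;
- summarized as **global efficiency** on the thresholded graph, with edge
  length 1/weight, Dijkstra shortest paths, and 1/∞ = 0 for disconnected
  pairs — the standard weighted-efficiency convention;
- summarized as **node strength** k_i = Σ_j W_ij on the *unthresholded*
  matrix, with hemisphere means over the 8 left / 8 right channels.

Thresholding is applied per individual matrix, not to group averages; the
participant-averaged matrices feed only the top-30% edge-list exports.
A literal binary network was considered and rejected: the efficiency formula
in use is weighted, and binarizing would discard the link weights that the
strength analysis interprets.

## Statistics

Normality screening: one-sample KS against a normal with estimated mean/SD
(Lilliefors caveat: anti-conservative, used only as a screen).  Group
contrasts: two-sided Mann-Whitney U (exact enumeration when min n ≤ 8 and
tie-free, otherwise tie-corrected normal approximation with continuity
correction).  Stage contrasts within group: tie-corrected Kruskal-Wallis
with Dunn z post hoc, Bonferroni-multiplied by the number of stage pairs
within each (band, metric) family.  Hemispheric asymmetry: two-sided paired
t on per-observation (left mean, right mean) pairs.  Gender tables: Pearson
chi-squared (Yates correction by default).  Stars: *p<0.05, **p<0.005,
***p<0.001.

The default unit of analysis pools epochs across subjects (matching the
original design's very large n); because epochs within a subject are
correlated, `unit="subject"` (per-subject means, independent observations)
is provided and recommended for confirmatory inference.

## Surrogate data

Each channel carries, per band, a narrowband oscillation
A_i cos(2π f_c t + φ_ref(t) + ε_i(t)): carrier f_c at the band midpoint, a
common slowly drifting reference phase φ_ref (Gaussian random walk,
0.3 rad/√s — shared by all channels, it cancels in every phase difference
and exercises WPLI's invariance to common phase), and per-channel von Mises
offsets ε_i ~ vM(μ_i, κ_i) redrawn independently every 3-s coherence block
(matching the analysis window).  Bands are summed with amplitudes decreasing
with frequency (δ 40, θ 30, α 25, σ 15, β 10 µV) plus white Gaussian noise
(SD 15 µV).

A *star construction* is used deliberately: offsets are drawn about a common
reference rather than per pair, because no joint distribution makes every
pairwise difference exactly von Mises for arbitrary (μ_ij, κ_ij).  A pair
whose first channel is phase-locked to the reference (κ = ∞) has an exactly
von Mises difference — that is the configuration used for estimator
validation, where the population WPLI is computed by quadrature over the
von Mises density (`wpli_ground_truth`).  For two free channels the
difference law is the circular convolution of the two von Mises laws,
integrated on a grid (`pair_wpli_ground_truth`).

Baseline cohort coupling gives homologous left/right channels identical
(μ, κ) — the hemispheres are exchangeable by construction, so any detected
lateralization in the control group is a false positive.  Mean lags step by
0.4 rad per anterior-posterior region pair, yielding a realistic mixture of
zero-lag (WPLI-suppressed) and strongly lagged pairs.  Patients scale every
κ by `group_effect` (default 1.5) and additionally scale δ-band
right-hemisphere κ by `delta_right_effect` (default 1.3), encoding globally
stronger coupling and δ right-lateralization.  The default cohort is 10
control + 10 patient subjects at 100 Hz with a fixed 20-epoch (10-min)
schedule of 4 epochs per stage (W, N1, N2, N3, R); whole-night hypnograms
with randomized cycle durations are available separately
(`simulate_hypnogram`).

What the surrogate does *not* emulate: 1/f background spectra, spindles and
K-complexes, volume-conduction forward mixing, inter-subject variability in
coupling topology, or stage-dependent coupling.  Passing tests therefore
demonstrate estimator and pipeline correctness under controlled phase
statistics — not robustness to real-EEG artifacts.

## Validation experiment sizes

- **Estimator grid** (μ ∈ {π/6, π/4, π/2} × κ ∈ {0.5, 1, 2, 5}): 10 h of
  two-channel signal per cell (~12,000 independent coherence blocks,
  ~36,000 windows).  The pooled WPLI estimator's Monte-Carlo SE at κ = 0.5
  is ≈ π/√(8B) per B blocks, so this size keeps SE below ~0.01 and the
  ±0.05 comparison against the quadrature oracle probes bias, not noise.
- **Efficiency oracle**: 200 random 16-node weighted graphs (varying
  sparsity) against an exhaustive all-pairs relaxation, tolerance 1e-12.
- **Null calibration**: 200 replicates of exchangeable groups through the
  draw → WPLI → threshold → GE → Mann-Whitney chain, and 200 replicates of
  the full comparison battery on exchangeable metric tables; rejection rates
  are checked against the binomial 95% interval around α = 0.05.
- **Directional cohort**: 10+10 subjects, effects 1.5/1.3, 100 Hz, 10 min
  each — the full pipeline must find higher patient GE and strength in all
  25 band×stage cells and δ right-lateralization in patients only.

## Known limitations

- Per-window WPLI over a 3-s window contains few effective degrees of
  freedom when the underlying phase difference is slowly varying; single-
  epoch WPLI estimates (28 windows) are noisy and upward-biased under the
  null (|E{sin}| ≥ 0).  Group contrasts inherit this as a shared offset.
- The EDF writer emits the continuous 16-bit subset (integer sampling rate,
  1-s records, ±500 µV default physical range, ~0.015 µV quantization);
  EDF+ annotations and discontinuous files are out of scope.
- The KS normality screen with fitted parameters is anti-conservative; it
  gates nothing in the pipeline (nonparametric tests are used throughout).
- Pooled-epoch inference treats correlated epochs as independent; use
  `unit="subject"` when calibrated p-values matter.
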