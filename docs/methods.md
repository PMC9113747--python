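# Methods

This note documents the models, estimators, conventions and design
choices behind `socioscope`, and what the synthetic-data calibration does
and does not demonstrate about real recordings.

## Data model and conventions

A session directory holds tracking (15 Hz video positions in cm), LFP
(µV, nominally 2 kHz, low-passed at 500 Hz at acquisition), spike times
with per-unit waveform features, and an event table. All times are
seconds from session start; every event, bin and window uses half-open
semantics `[t, t + dt)` so no sample is counted twice at boundaries. The
coordinate frame puts the origin at the arena's bottom-left corner,
x rightward, y upward; the mesh cage is centered against a configurable
wall (default top). Tracking frames with optical noise are *flagged*
invalid and excluded from every downstream computation — never
interpolated — mirroring standard practice of dropping corrupted video
frames. LFP sampling must exceed twice the highest analysis frequency
(250 Hz); violations are validation errors.

Arena geometry defaults: 39.3 × 39.3 cm box; 6.5 × 10 cm cage footprint;
interaction zone (IZ) 24 cm wide × 14.5 cm deep around the cage;
9 × 9 cm avoidance squares in the two corners opposite the cage;
peripheral band 5 cm from each wall. The peripheral width is not a
published quantity; 5 cm is this package's choice (configurable) and only
affects the peripheral/center split, which feeds no headline statistic.

## Behavioral segmentation

**Speed.** Tracking is downsampled to 3 Hz by taking the first valid
frame in each 1/3 s bin (the downsampling method is underdetermined by
the nominal "3 Hz" description; first-frame selection keeps positions on
the bin grid exactly). Speed is the Euclidean displacement to the next
occupied bin divided by elapsed time. Running and stop states use strict
inequalities (> 5, < 1 cm/s); a bin at exactly 5 cm/s is neither.

**Direction and bouts.** For each 1 s bin, the moving direction is the
displacement from the bin-start position to the next bin-start position,
and θ is the unsigned angle between that vector and the line from the
bin-start position to the cage center (θ = 0° toward, 180° away). The
reference vector is anchored at the bin start; per-frame variants within
the bin are a possible alternative reading, and the anchor is therefore
isolated in one function. Candidate approach (θ < 90°) and leaving
(θ > 90°) runs require every bin inside the cage half (midline inclusive
toward the cage); θ = 90°, zero displacement, or a missing frame breaks a
run. A run must be *strictly longer* than 5 s to produce a bout (≥ 6
one-second bins), and the bout is exactly the run's first 5 s; 5-bin runs
yield nothing. These boundary rules make segmentation deterministic and
exactly testable.

**Zones and SI ratio.** Zone precedence is IZ > avoidance > peripheral >
center, one zone per occupied 1/3 s bin; occupancy is bin count × bin
width. SI ratio = IZ seconds in the target session / IZ seconds in the
no-target session; a zero denominator yields NaN with a warning, and such
mice are excluded from group tests with a logged count.

## Spectral analysis

**Morlet power.** The continuous wavelet transform is evaluated in the
frequency domain with the analytic Gaussian filter
`H(f; f0) = √2 · exp(−ω₀²(f/f0 − 1)²/2)` for f > 0 (ω₀ = 6 cycles,
configurable), equivalent to an L∞-calibrated complex Morlet: a sinusoid
of amplitude A at its center frequency yields power A²/2, its mean
power. Power therefore obeys amplitude² arithmetic, which is what the
session ratio, z-score and stimulation statistics consume. For
comparisons against spectral densities, `E|W(f0)|² = S₂(f) ∗ |H|²`
integrates to `2√π f0/ω₀ · S` for locally flat spectra, so
`|W|² · ω₀/(√π f0)` is a one-sided PSD in µV²/Hz (verified against a
Welch periodogram in the tests). The default grid is logarithmic with 60
points/decade over 1–250 Hz; squared coefficients are averaged into
10 ms bins. A unit test cross-checks the transform against PyWavelets'
`cmor` implementation.

**Band statistics.** Band power is the mean over grid frequencies in
`[lo, hi)`. The session power ratio is 100 × mean target-session band
power / mean no-target band power; with equal 150 s sessions, mean and
total power are interchangeable. Z-scoring uses the mean and SD of the
band-power series over a configurable baseline — either the concatenated
no-target + target period (used for anxiety-zone contrasts) or the target
session alone (used for approach/leaving contrasts); both conventions
appear in practice, so the baseline is an explicit parameter. State means
average z over the 10 ms bins whose centers fall in a state's intervals.

**Coherence.** Channels are low-passed at 80 Hz (4th-order Butterworth,
zero phase) and decimated to 200 Hz, then magnitude coherence
`|S_ab|/√(S_aa S_bb)` is estimated with Welch cross-spectra (2 s Hann
segments, 50% overlap). A wavelet-coherence route would need smoothing
parameters that have no canonical values; Welch with stated settings is
bit-reproducible, and the object exposes both magnitude and
magnitude-squared coherence.

**Granger causality.** A bivariate VAR is fitted at 200 Hz (statsmodels,
trend-free, order by AIC up to 20); instability (characteristic roots on
or inside the unit circle) is an error with diagnostics. Geweke's
frequency-domain causality for direction j→i is
`ln[S_ii / (S_ii − (Σ_jj − Σ_ij²/Σ_ii)|H_ij|²)]` with transfer function
`H = (I − Σ_k A_k e^{−2πifk/fs})⁻¹` and spectral matrix `S = HΣH*`. Tests
verify the estimate against the same formula evaluated at the *true*
coefficients of a simulated VAR, near-zero reverse/decoupled causality,
exact direction swapping under channel exchange, and the Geweke
consistency property that the spectral mean approximates the time-domain
causality `ln(σ²_restricted/σ²_full)`.

**Phase–amplitude coupling.** The coupling index is the
envelope-weighted mean vector `|Σ a(t)e^{iφ(t)}|/Σ a(t)` of the 30–60 Hz
Hilbert envelope over the 4–7 Hz phase, with a null from circularly
time-shifted envelopes (≥ 1 s shifts). Note that for strictly periodic
test signals this surrogate null is degenerate (shifts only rotate the
coupling phase), so calibration uses stochastic narrowband rhythms.

**Stimulation-evoked change.** Percent change is
`100 · (P_stim − P_base)/P_base` with the baseline taken as the window of
equal length immediately preceding each stimulation epoch; overlap
between any baseline and any epoch is an error.

## Spike analysis

Units are classified from baseline rate and spike width: FS if
rate > 10 Hz; RS if rate < 10 Hz and width > 0.6 ms; boundary cases stay
unclassified. Phase is extracted with a 4th-order zero-phase Butterworth
band-pass followed by the analytic signal, so filtered-trace peaks map to
0°. Phase–rate distributions use 12 bins of 30°, rates are counts divided
by LFP dwell time per phase bin, and smoothing is a circular Gaussian
with SD one bin.

The phase-locking statistic is the mean vector length (Rayleigh r). By
default it is computed from **raw spike phases**; a variant computed from
the smoothed binned distribution is available behind a flag but carries a
known attenuation — circular Gaussian smoothing with SD σ multiplies the
resultant by `exp(−σ²/2)` (≈ 0.87 for σ = 30°) — which the tests verify
explicitly. The raw-phase estimator is the statistically standard choice.

Significance uses a permutation null: spike times are redrawn uniformly
within the analysis mask (1000 shuffles by default, unconstrained
randomization, with a circular time-shift variant behind a flag), and the
observed MVL is significant when it strictly exceeds the shuffles' 95th
percentile; p is the fraction of shuffles ≥ observed. Type-I calibration
on phase-independent units recovers the nominal 5% within binomial error.
Behavior-restricted locking computes MVL and the shuffle test separately
within approach-bout and leaving-bout time; units significant in *both*
states are flagged behavior-irrelevant and excluded from the downstream
paired comparison. Units with fewer than 10 spikes in a mask are flagged
low-count.

## Synthetic cohorts

The generator's purpose is exact ground truth, not biological realism.

**Trajectories** are scripted, not sampled from an agent model: sessions
are schedules of stationary dwells, fast transits, and straight
approach/leaving runs aligned to the 1 s grid (approach runs move along
the line through the cage center, so θ = 0 on every bin; stationary
pauses separate moving segments so candidate runs never concatenate).
This makes bout boundaries, zone occupancy and SI ratios exactly
recoverable, which the segmentation tests exploit.

**LFPs** are sums of narrowband oscillators — Gaussian noise strictly
band-limited in the frequency domain, unit RMS, scaled by per-band
amplitudes (µV RMS defaults 1–4: 15, 4–7: 30, 7–10: 10, 10–30: 6,
30–60: 15, 60–100: 3) over a 10 µV white-noise floor. Session- and
state-level effects multiply a band's amplitude over the whole session or
within state intervals (e.g. target-session 4–7 Hz gain 1.10 for the
control-like group, 1.25 for the deficient group; approach-state 4–7 Hz
gain 0.8 in controls). Strict band-limiting keeps cross-band leakage into
the wavelet band means at the percent level, so recovered power ratios
follow 100·r² closely; amplitudes were chosen once for that property. A
pure-tone mode exists for analytic tests. The BLA channel is the dmPFC
band-component sum delayed by 10 ms, scaled by 0.7, plus independent
noise — a minimal construction that induces one-way Geweke causality
without a biophysical model.

**Spikes** are inhomogeneous Poisson trains (thinning) with von-Mises
phase modulation: `rate(t) = r₀ exp(κ_state cos(φ(t) − φ_pref))/I₀(κ)`,
where φ is the true phase of the generated 4–7 Hz component. FS units
draw r₀ from 12–25 Hz with widths 0.2–0.45 ms and κ 0.3 (approach) vs 1.5
(leaving); RS units draw 2–8 Hz, 0.7–1.1 ms, κ 0.3 in both states, so the
behavioral κ difference is FS-specific.

**Stimulation sessions** place pulse trains at 4/10/40 Hz with pulse
width half the inter-pulse interval (125/50/12.5 ms) in epochs recurring
every 30 s over a 10 min session (2 s epochs by default; a 10 s mode is
used where longer integration windows are needed), and multiply band
amplitudes by a response map during epochs.

**What passing tests do not show.** The generator has no 1/f background,
no movement or chewing artifacts, no volume conduction, no
nonstationarity beyond the scripted gains, and exact state labels. The
calibration therefore demonstrates estimator correctness and pipeline
integrity under the stated signal model — not robustness to the artifact
structure of in-vivo recordings, whose printed effect sizes derive from
specific animals and are not reproduction targets here.

## Group statistics

Electrode-level quantities are always averaged to one value per mouse
before any group statistic. Two-sample contrasts run an F-test on the
variance ratio as a parametric screen (α = 0.05): paired contrasts use
the paired t-test, falling back to Wilcoxon signed-rank; independent
contrasts use the two-sample t-test, falling back to Mann-Whitney U.
Bonferroni correction is `min(1, m·p)` within each family of band-wise
contrasts. Behavior-irrelevant phase-locked units are excluded before the
paired MVL comparison; undefined SI ratios are dropped with a warning.

## Calibration problem sizes

The calibration suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) uses: 50 000 von-Mises phases for the MVL
check; 500 phase-independent units × 1000 shuffles for type-I
calibration; single 150 s session pairs at 2 kHz for power-ratio and
coherence analytics; 30 000 samples at 200 Hz for causality; 10-min
stimulation sessions averaged over 7 stimulated and 4 control synthetic
mice; and 20 replicate 10-vs-10 cohorts for direction recovery, analyzed
with a coarser 20 points/decade grid restricted to the 4–7 Hz band, the
dmPFC channel only, and 200 shuffles — the contrasts under test involve
band means and MVL differences, for which these sizes give ample power.

## Known limitations

- Wavelet band means include band-edge frequencies whose response
  extends slightly beyond the nominal band; evoked-change estimates are
  diluted by a few percent when neighboring bands are unmodulated.
- The Welch coherence default trades the original wavelet-coherence
  route for reproducibility; absolute coherence levels differ between
  estimators even though contrasts are preserved.
- VAR-based causality assumes within-segment stationarity; stimulation
  transients or strong nonstationarity should be analyzed per segment.
- The binned-distribution MVL variant underestimates locking by the
  smoothing attenuation factor and is provided only for comparability.
- `shank3_ko`, `defeated`, etc. are labels parameterizing effect
  directions in synthetic cohorts; nothing about the biology of those
  models is simulated.
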