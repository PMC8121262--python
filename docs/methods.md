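# Methods

This note documents the model and procedure implemented by `gednet`, the
parameters that matter, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and the GED contrast

The data are a channels × time matrix mixing two modalities: LFP channels
(continuous voltages, regionally grouped) and multiunit (MU) channels
(binary spike trains smoothed with a 30-ms FWHM Gaussian into rate signals).
The working assumption is that a small number of narrowband networks — each
a fixed spatial pattern driven by an amplitude-modulated oscillation — are
linearly mixed into the channels over a broadband 1/f background.

At each analysis frequency the pipeline contrasts two channel covariance
matrices: **S**, from the narrowband-filtered data, and **R**, from the
broadband data. The spatial filter maximizing wᵀSw / wᵀRw is found by the
generalized eigendecomposition S W = R W Λ; each eigenvalue equals the
Rayleigh quotient of its eigenvector, so λ measures the
narrowband-to-broadband variance ratio of that component, with null
expectation 1 when S and R carry the same information. Eigenvectors are not
mutually orthogonal (R⁻¹S is not symmetric) but are R-orthogonal; they are
returned unit-norm, sign-fixed so the largest-magnitude element is positive
(correlation-based analyses downstream are sign-invariant, but fixed signs
make maps comparable across fits).

### Covariance estimation

Continuous data are cut into non-overlapping 2-s segments. Even-numbered
segments (counting from 1) feed the S pool, odd-numbered segments the R
pool, so S and R come from disjoint data. Each pool is cleaned once:
segments whose covariance lies more than 3 SDs (Frobenius distance) above
the mean distance to the pool average are excluded and the average
recomputed. A 5-minute session with 10-s edge trims yields exactly 70
segments per pool.

Masked samples (see below) are dropped listwise *within* a segment — the
segment's covariance is computed over time points at which every channel is
valid — and a segment is discarded only if fewer than half its samples
survive. An alternative rule (drop any segment containing any masked
sample) was rejected: with ~30 channels and a 4-SD mask, essentially every
segment of a realistic session contains at least one masked value, which
would empty the pools and contradict the 70-segments-per-pool bookkeeping.

R is shrunk toward a scaled identity, R̃ = (1−γ)R + γαI with γ = 0.01 and
α = trace(R)/M (the mean eigenvalue), which preserves the trace exactly and
stabilizes the decomposition of noisy or rank-reduced data.

### Preprocessing and channel normalization

LFP channels are regionally average-referenced (the mean of each region's
LFP channels is subtracted from each of them; MU channels untouched), the
first and last 10 s of each session are trimmed, every channel is
standardized, samples beyond 4 SDs are masked, and the channel is
re-standardized over the surviving samples, so valid samples have exactly
zero mean and unit variance. The ordering trim → mask → re-standardize is a
package choice; the scale divided out per channel is kept so results can be
expressed in original units. Interactive artifact screening is replaced by
a configuration hook (`exclude_channels`, `exclude_intervals`).

Two numerical interactions here required care, and both are design choices
of this package:

1. **Segment-level normalization.** All channel scalings (the z-scoring
   target and the per-frequency normalization of narrowband channels before
   S) use the *segment-level* SD — the square root of the mean
   within-segment variance — not the full-series SD. Segment mean-centering
   removes the large, slow component of 1/f broadband power but none of the
   narrowband power; scaling by full-series SDs therefore gives S a
   systematically larger diagonal than R and biases the eigenvalue scale
   (and the permutation test below) away from the null expectation of 1.
   With segment-level scales, pure-noise recordings yield top eigenvalues
   below the permutation threshold, as they should.

2. **Rank compression.** Regional referencing removes one degree of
   freedom per region; because the subsequent z-scoring is a diagonal
   transformation, the broadband covariance retains *exact* null
   directions (σ-weighted regional indicators). The per-frequency
   normalization of the narrowband data shifts S's null directions slightly
   away from R's, and with a shrinkage floor of γα those directions produce
   spurious eigenvalue ratios — measured on synthetic data, the top
   eigenvector then lies almost entirely inside the near-null regional
   subspace at every frequency. The GED is therefore solved in the
   numerically positive subspace of R (eigenvalues > 1e-8 × max; rank M−3
   for three referenced regions) and the filters mapped back to channel
   space. This is standard practice for average-referenced data.

### Narrowband filtering

Morlet wavelets are implemented as Gaussians in the frequency domain:
the spectrum is multiplied by exp(−4 ln2 (f−f_c)²/FWHM²) (unit peak gain at
f_c), negative frequencies are zeroed and positive ones doubled, returning
the complex analytic signal in one pass — magnitude is the amplitude
envelope, angle the instantaneous phase. The grid spans 2–200 Hz in 100
logarithmic steps; the spectral FWHM interpolates from 2 Hz to 5 Hz
log-linearly in frequency (the interpolation law between the stated
endpoints is a package choice). MU channels are never narrowband filtered;
they enter S and R as their smoothed rate signals, so spike–field coupling
appears as cross-modal covariance terms.

S is computed from the real part of the analytic signal (the filtered
signal's covariance), not from the envelope. Component time series values
beyond 4 SDs are masked, mirroring the channel rule.

### Component maps and their units

The map of component j is S·w_j. Because the pipeline operates on
z-scored, per-frequency-normalized channels, maps are stored both in that
normalized space (`maps`, color-comparable across frequencies) and
de-normalized into original channel units (`maps_denorm`, the normalized
map multiplied by each channel's z-score scale and narrowband scale).
Ground-truth comparisons use `maps_denorm`, since planted mixing patterns
live in original units; the correct oracle is the planted mixing *after*
regional referencing (referencing removes each region's mean from the
pattern the pipeline can see).

## Permutation-based subspace dimensionality

Each segment contributes one narrowband and one broadband covariance
matrix. Under the null that the two matrices carry the same information
they are exchangeable within a segment: each of the 200 permutations
randomly swaps, per segment, which matrix averages into S and which into R,
repeats cleaning/shrinkage/GED, and stores the largest eigenvalue. The
threshold is the maximum over permutations — the most extreme value
expected under the null, implicitly correcting for the maximum over M
components — and the dimensionality is the number of observed eigenvalues
above it. The observed decomposition here uses all segments per pool (not
the even/odd split), so observed and permuted solutions estimate the same
quantities. Pools are expressed in the rank-compressed basis for the same
reason as the main fit.

## Empirical frequency bands (gedBounds)

A frequency band is a group of grid frequencies whose top eigenvectors are
mutually correlated. The 100×100 matrix of squared Pearson correlations
between top eigenvectors is clustered with DBSCAN on its rows (each
frequency described by its full correlation profile, Euclidean distance;
eps = 0.5, min_pts = 3 — both configurable, since no canonical values
exist). Clusters become bands bounded by their lowest and highest member
frequencies; frequencies without strong intercorrelations stay unclustered,
so zero bands is a legitimate outcome. Band centre = geometric mean of the
bounds (the grid is logarithmic). Across sessions/animals, centres are
pooled in log-frequency space and summarized by k-means re-run with 100
random initializations (k defaults to the modal per-session band count);
the mean and SD of the sorted cluster centres across reseeds are reported.

A known behaviour of this construction: at low frequencies the grid spacing
(4.8% per step) is much finer than the 2-Hz FWHM floor, so adjacent filters
share most of their passband and even source-free frequencies have
correlated eigenvectors. Wide source-free regions at the low end of the
spectrum can therefore form small spurious clusters, and DBSCAN's density
chaining can bridge closely spaced sources. The cross-session modal band
count is the robust summary.

## Derived statistics

- **Region bias score**: per-region RMS of eigenvector elements, normalized
  to sum to 1, Euclidean distance to the equal-sharing profile [1,1,1]/3,
  divided by the maximum attainable distance √(2/3) so a single-region
  component scores exactly 1 and equal sharing scores 0. (The raw distance
  of the single-region case is √((n−1)/n) for n regions; the score is the
  normalized version.)
- **Region energy fractions**: the normalized per-region RMS vector itself.
- **Modality dominance**: (RMS_LFP − RMS_MU)/(RMS_LFP + RMS_MU) of the
  eigenvector elements, +1 when multiunits contribute nothing, −1 when LFP
  channels contribute nothing.
- **Channel entropy**: Shannon entropy with k = 40 equal-width bins,
  H = −Σ yᵢ log₂ yᵢ (empty bins contribute 0; a constant series scores 0;
  bounded by log₂ 40 ≈ 5.32 bits).
- **Kurtosis**: non-excess (Gaussian = 3), computed on the real part of the
  narrowband component time series and on its amplitude envelope, after the
  4-SD mask.
- **wPLI**: weighted phase-lag index between component time series,
  per 2-s epoch |mean Im c| / mean |Im c| with c = z₁·conj(z₂), epochs
  averaged, 0/0 defined as 0 (with a scale-aware numerical floor so exact
  zero-lag inputs return 0 rather than floating-point noise). The weighted
  (not debiased-squared) estimator is used. Only the imaginary
  cross-spectrum enters, so zero-lag (volume-conducted) coupling
  contributes nothing.
- **Map reproducibility**: squared Pearson correlation between two
  sessions' top-1 maps (`r2_top`) and the maximum over the four top-2 ×
  top-2 pairs (`r2_max`, tolerant of rank swaps), plus the mean of the two
  top eigenvalues for separability–reproducibility correlations.

## Multiunit extraction

Raw traces (≥ 24 kHz) are band-passed 300–6000 Hz with a zero-phase FIR
filter (odd-length `firwin` kernel, forward–backward application). The
noise SD is estimated as 1.48 × MAD, which is robust to the spikes
themselves; 1/Φ⁻¹(0.75) ≈ 1.4826 calibrates the MAD to a Gaussian SD.
Events are negative crossings of 4 SDs, aligned to the local minimum within
1 ms after the trigger, cut to [−0.7, +1.2] ms windows; detection is locked
out for one window length after each accepted event (earlier event wins),
and edge-clipped events are dropped. PCA is fitted on ≤ 5000 randomly
selected events (seeded), all events are projected to 6 dimensions, Ward
clustering produces at most 3 clusters, and remaining events join the
nearest cluster centre.

Cluster selection and fusion operationalize criteria whose exact thresholds
are not canonical; all are configurable:

- *after-hump*: the mean of the 0.15–0.8 ms post-trough window, averaged
  per event, must be significantly positive (one-sided one-sample t-test
  across events, α = 0.05);
- *pre-peak*: a significantly positive mean in the −0.7 to −0.2 ms window
  rejects the cluster;
- *size/duration*: the mean waveform's trough must be negative, its
  amplitude below a configurable cap, and its half-amplitude span at most
  1.5 ms;
- *fusion*: clusters are merged when their average waveforms correlate
  above 0.95 and their unit-normalized averages lie within Euclidean
  distance 1.0.

Accepted units are exported as event tables and can be regenerated as
binary trains at the LFP sampling rate for matrix assembly.

## Synthetic-data generator

`generate_ground_truth` draws n networks with log-spaced centre frequencies
and random unit-norm mixing over the LFP channels (optionally confined to
one region); each source's spectral FWHM defaults to 0.15 × its centre
frequency (constant-Q oscillations). `generate_recording` synthesizes each
source as frequency-domain-shaped Gaussian noise at (f_c, FWHM) multiplied
by a slowly varying positive envelope |1 + 0.5·g|, where g is a 1-s-smoothed
standardized Gaussian random walk — waxing/waning amplitude with a
coefficient of variation ≈ 0.5 that is never pinned at zero for long
stretches, giving leptokurtic narrowband statistics. LFP channel i is
snr · Σ_k m_ik a_k s_k(t) plus independent unit-variance 1/f^1.0 Gaussian
noise (synthesized in the frequency domain; exponent configurable), so
`snr` is the planted-source amplitude relative to the broadband background
and snr = 0 yields pure noise. MU channels are inhomogeneous Bernoulli
trains with rate base_rate·(1 + depth·cos φ(t)) driven by a source's
instantaneous phase (defaults: 13.2 spikes/s, depth 0.6 — the base rate
matches the grand-average multiunit rate the pipeline is designed around),
smoothed with the 30-ms Gaussian and assigned to the region carrying most
of the source's mixing energy. A synthetic *animal* is a fixed ground truth
reused across sessions with fresh noise seeds, so map reproducibility is
high within and low across animals by construction.

What the generator does **not** emulate: volume conduction and electrode
geometry (mixing weights are abstract, not a biophysical forward model),
cross-frequency coupling, non-stationary band shifts, behavioural state
changes, shared noise between channels, and line noise. Passing tests
therefore demonstrate correct recovery of linearly mixed narrowband
networks under realistic 1/f background — not robustness to every property
of real recordings.

### The snr regime, and why "more" is not "better"

Because a narrowband source contributes to the broadband reference R as
well as to S, the GED contrast is strongest when each rhythm is a modest
fraction of per-channel broadband variance — the regime of real LFP
rhythms. At snr where a planted source dominates total channel variance
(per-channel source fraction ≳ 50%), z-scoring shrinks the noise in
source-carrying channels, the per-frequency normalization re-inflates it at
off-source frequencies, and the eigenvalue profile flattens or inverts.
The recovery tests therefore run at snr 1.5–4 depending on the property
(per-channel source fractions of roughly 5–30%), 60–300 s sessions, 20–40
channels; the three-source dimensionality check uses 300-s sessions (70
segments per pool) with orthonormal mixing patterns, and the seven-band
check plants sources at canonical rodent band centres (3, 6, 10, 16, 28,
60, 130 Hz), whose spacing — denser at low frequencies, like physiological
bands — avoids wide source-free gaps at the grid's coarsest spectral
resolution.

## Degenerate inputs and tie-breaks

Constant channels raise an error naming the channel; a constant eigenvector
has similarity 0 by convention; entropy of a constant series is 0; wPLI
0/0 epochs are 0; an empty waveform set is legal (no events); clustering
fewer events than the cluster cap falls back to a single shape-checked
cluster; `clean_covariance_pool` refuses to exclude every segment; zero
discovered bands is a valid `BandStructure`.

## Known limitations

- The permutation dimensionality test inherits a mild anticonservativeness
  from the different effective degrees of freedom of narrowband vs
  broadband segment covariances (a 2-s segment holds far fewer independent
  narrowband samples); the segment-level normalization removes the
  first-order bias but sampling-spread asymmetry remains at small segment
  counts.
- Band discovery depends on DBSCAN parameters for which no canonical values
  exist; the defaults (eps 0.5, min_pts 3) are documented, exposed in the
  configuration, and summarized across sessions by the modal band count.
- Eigenvalue magnitudes depend on the normalization convention; they are
  comparable within a fit and against that fit's permutation null, not
  across pipelines with different conventions.
- The spike-sorting chain targets multiunits; no single-unit isolation
  quality metrics are computed.
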