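# gednet

Frequency-resolved multivariate source separation for combined local field
potential (LFP) and multiunit recordings.

Multichannel electrophysiology mixes many narrowband rhythms — each a
coordinated network spanning electrodes and brain regions — on top of a
broadband 1/f background, and every electrode sees a different blend of them.
`gednet` separates these rhythms with **generalized eigendecomposition (GED)**
of two channel covariance matrices: **S**, estimated from narrowband-filtered
data at one frequency, and **R**, estimated from the broadband data.  The
spatial filter **w** that best isolates narrowband activity maximizes the
Rayleigh quotient

```
w* = argmax_w  (wᵀ S w) / (wᵀ R w)      ⇔      S W = R W Λ
```

Each eigenvalue λ is the narrowband-to-broadband variance ratio achieved by
its filter (null expectation 1); the component time series is wᵀX and its
anatomically interpretable map is S·w.  Repeating the decomposition over 100
log-spaced frequencies (2–200 Hz, Morlet wavelets defined as frequency-domain
Gaussians with 2–5 Hz FWHM) yields an eigenspectrum per frequency, from which
the package derives:

- **Empirical frequency bands** (gedBounds): DBSCAN clustering of the matrix
  of squared correlations between per-frequency top eigenvectors, with
  k-means (100 reseeds) summarizing band centres across sessions and animals.
- **Subspace dimensionality**: a 200-iteration permutation test that swaps
  each 2-s segment's narrowband/broadband covariance between the S and R
  pools and counts observed eigenvalues above the most extreme null maximum.
- **Network statistics**: region bias score, per-region energy fractions,
  LFP-vs-multiunit modality dominance, channel entropy (40 bins), kurtosis of
  narrowband signal and envelope, weighted phase-lag index between
  components, and cross-session spatial-map reproducibility.

The package is aimed at systems neuroscientists analysing continuous
multi-region recordings (tens of LFP channels plus extracted multiunits), and
it ships a first-class synthetic-data generator that plants known
multiregional narrowband networks — so every stage of the pipeline can be
validated against ground truth.  A multiunit extraction chain (zero-phase
300–6000 Hz FIR filtering, robust 4-SD detection via 1.48×MAD, PCA + Ward
clustering with waveform-shape selection and fusion) turns raw high-rate
traces into the smoothed rate channels that join the LFP data matrix.

## Worked example

Plant three networks (6, 19 and 60 Hz) in 30 LFP channels across three
regions plus three phase-coupled multiunits, then fit:

```python
import numpy as np
from gednet import FrequencyGED, synthetic

truth = synthetic.generate_ground_truth(3, freq_range=(6.0, 60.0), seed=1)
rec = synthetic.generate_recording(truth, duration=120.0, fs=1000.0,
                                   snr=1.5, seed=2)
res = FrequencyGED(rec).fit()
print(res.summary())
```

```
Frequency-resolved GED source separation
============================================
animal/session        animal1/session0
channels              33 (30 LFP, 3 MU; regions: PFC, PAR, HIP)
duration analysed     100.0 s (fs 1000 Hz, trim 10 s/end)
frequencies           100 (2-200 Hz)
segments per pool     S~25, R=25 (2-s, even/odd split)
excluded segments     31 (3-SD Frobenius rule)
shrinkage gamma       0.01
top eigenvalue        7.691 at 17.80 Hz (null expectation 1)
```

The eigenspectrum peaks near the planted 19-Hz network — λ≈7.7 means its
spatial filter carries 7.7× more narrowband than broadband variance, against
a null expectation of 1.  Band discovery and the permutation test recover the
planted structure:

```python
bands = res.band_structure()
for b in bands.bands:
    print(f"band {b.f_low:6.2f}-{b.f_high:6.2f} Hz  (centre {b.center:6.2f} Hz)")
k = int(np.argmax(res.top_eigenvalues))
d = res.dimensionality(k, n_perm=200, seed=0)
print(f"dimensionality at {res.freqs[k]:.1f} Hz: {d['dimensionality']}")
```

```
band   2.00-  2.90 Hz  (centre   2.41 Hz)
band   4.02-  4.41 Hz  (centre   4.21 Hz)
band   4.84-  7.71 Hz  (centre   6.11 Hz)
band  12.86- 14.11 Hz  (centre  13.47 Hz)
band  17.00- 21.45 Hz  (centre  19.09 Hz)
band  54.37- 65.49 Hz  (centre  59.67 Hz)
dimensionality at 17.8 Hz: 1 (threshold 3.13)
```

The three planted networks appear as the bands around 6, 19 and 60 Hz; one
genuine component at 17.8 Hz survives the permutation threshold.  The small
clusters below 4.5 Hz are a known artifact of the grid's spectral overlap at
low frequencies (adjacent narrowband filters share most of their passband
there, so even source-free frequencies have correlated eigenvectors; see
`docs/methods.md`).  `res.metric_table()` returns the per-frequency network
statistics as a DataFrame, `res.plot_eigenspectrum()` /
`res.plot_band_matrix()` plot the eigenspectra and the clustered r² matrix,
and `gednet.compare_sessions(res_a, res_b)` quantifies map reproducibility
between two fitted sessions.

The same pipeline is scriptable from the shell:

```bash
gednet simulate --n-networks 3 --duration 120 --seed 1 --out rec.h5
gednet run --input rec.h5 --out-dir out/
gednet report out/
gednet bands out_session1/ out_session2/   # cross-session band centres
```

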