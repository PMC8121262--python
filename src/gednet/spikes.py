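"""Automatic multiunit extraction from high-sample-rate voltage traces.

Pipeline: zero-phase 300–6000 Hz FIR band-pass; detection of negative
threshold crossings at 4 SDs of the background noise (robustly estimated as
1.48 x the median absolute deviation); alignment of each event to its
post-trigger minimum and extraction of a [-0.7, +1.2] ms window; PCA on a
random subset of events to a 6-D score space; Ward hierarchical clustering
with at most 3 clusters; and post hoc cluster selection (waveform-shape
criteria) and fusion (similar average waveforms merged).

The aim is multiunit activity — thresholded spiking possibly mixing nearby
neurons — not isolated single units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as ssig
from scipy import stats as sps
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

__all__ = ["WaveformSet", "bandpass_spike_filter", "estimate_noise_sd",
           "detect_and_align", "sort_multiunits", "binary_train"]

WINDOW_PRE_MS = 0.7      # window before the alignment trough
WINDOW_POST_MS = 1.2     # window after the alignment trough
MAD_TO_SD = 1.48         # calibrates the MAD to the SD of a Gaussian


@dataclass
class WaveformSet:
    """Detected spike events cut to a common window around the trough.

    The alignment sample (index ``align_index``) holds each waveform's
    minimum.  ``cluster_labels`` of -1 mark rejected events.
    """

    waveforms: np.ndarray                  # events x window samples
    event_times: np.ndarray                # alignment sample indices
    fs: float
    cluster_labels: np.ndarray | None = None

    def __post_init__(self):
        expected = window_length(self.fs)
        if self.waveforms.size and self.waveforms.shape[1] != expected:
            raise ValueError(f"window length {self.waveforms.shape[1]} != {expected}")

    @property
    def n_events(self) -> int:
        return self.waveforms.shape[0]

    @property
    def align_index(self) -> int:
        return int(round(WINDOW_PRE_MS * 1e-3 * self.fs))

    def accepted_units(self) -> list:
        """Sorted labels of accepted (non-rejected) clusters."""
        if self.cluster_labels is None:
            return []
        return sorted(set(self.cluster_labels[self.cluster_labels >= 0]))


def window_length(fs: float) -> int:
    return int(round((WINDOW_PRE_MS + WINDOW_POST_MS) * 1e-3 * fs)) + 1


def bandpass_spike_filter(raw: np.ndarray, fs: float,
                          f_lo: float = 300.0, f_hi: float = 6000.0) -> np.ndarray:
    """Zero-phase FIR band-pass isolating the spike band (300–6000 Hz)."""
    if fs <= 2 * f_hi:
        raise ValueError(f"fs={fs} too low for a {f_hi}-Hz passband edge")
    numtaps = int(3 * fs / f_lo) | 1        # odd length, ~3 cycles of the low edge
    kern = ssig.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs)
    return ssig.filtfilt(kern, [1.0], np.asarray(raw, dtype=float),
                         padlen=min(3 * numtaps, len(raw) - 1))


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD: 1.48 x median absolute deviation.

    Unlike the sample SD, the MAD is insensitive to the spikes themselves and
    to large artifacts; the 1.48 factor makes it consistent with the SD of a
    Gaussian.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(MAD_TO_SD * np.median(np.abs(x - np.median(x))))


def detect_and_align(x: np.ndarray, fs: float, threshold_sd: float = 4.0) -> WaveformSet:
    """Detect negative threshold crossings and cut trough-aligned windows.

    Crossings of ``-threshold_sd x noise SD`` trigger events; each event is
    aligned to the local minimum within 1 ms after the trigger.  After an
    accepted event, detection is locked out for one window length (earlier
    event wins on overlap); events whose window would cross the recording
    edges are dropped.
    """
    x = np.asarray(x, dtype=float)
    n_w = window_length(fs)
    if x.size <= n_w:
        raise ValueError("series shorter than the waveform window")
    thr = -threshold_sd * estimate_noise_sd(x)
    below = x < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    pre = int(round(WINDOW_PRE_MS * 1e-3 * fs))
    post = int(round(WINDOW_POST_MS * 1e-3 * fs))
    search = int(round(1.0e-3 * fs))
    waveforms, times = [], []
    last_end = -1
    for c in crossings:
        if c <= last_end:
            continue
        seg = x[c:min(c + search + 1, x.size)]
        t_min = c + int(np.argmin(seg))
        if t_min - pre < 0 or t_min + post >= x.size:
            continue
        waveforms.append(x[t_min - pre:t_min + post + 1])
        times.append(t_min)
        last_end = t_min + post
    waveforms = np.asarray(waveforms, dtype=float).reshape(len(times), n_w)
    return WaveformSet(waveforms=waveforms, event_times=np.asarray(times, dtype=int),
                       fs=fs)


def _shape_ok(mean_wf: np.ndarray, wfs: np.ndarray, align: int, fs: float,
              alpha: float = 0.05, max_amplitude: float | None = None,
              max_duration_ms: float = 1.5) -> bool:
    """Waveform-shape acceptance test for one cluster.

    Requires a significantly positive after-hump following the trough (mean
    of the 0.15–0.8 ms post-trough window tested against 0 across events),
    rejects clusters with a significantly positive pre-trough peak, and
    rejects waveforms larger or longer than expected for an extracellular
    spike.
    """
    post0 = align + int(round(0.15e-3 * fs))
    post1 = align + int(round(0.80e-3 * fs)) + 1
    pre0 = max(align - int(round(0.70e-3 * fs)), 0)
    pre1 = max(align - int(round(0.20e-3 * fs)), 1)
    post_means = wfs[:, post0:post1].mean(axis=1)
    pre_means = wfs[:, pre0:pre1].mean(axis=1)
    if post_means.std() == 0:
        hump_ok = post_means.mean() > 0
    else:
        t, p = sps.ttest_1samp(post_means, 0.0)
        hump_ok = (t > 0) and (p / 2 < alpha)
    if not hump_ok:
        return False
    if pre_means.std() > 0:
        t, p = sps.ttest_1samp(pre_means, 0.0)
        if t > 0 and p / 2 < alpha:       # significantly positive pre-peak
            return False
    elif pre_means.mean() > 0:
        return False
    if mean_wf[align] >= 0:               # trough must be negative-going
        return False
    if max_amplitude is not None and np.abs(mean_wf).max() > max_amplitude:
        return False
    # duration: span where |mean waveform| exceeds half the trough depth
    half = np.abs(mean_wf[align]) / 2.0
    over = np.flatnonzero(np.abs(mean_wf) > half)
    if over.size and (over[-1] - over[0]) / fs * 1e3 > max_duration_ms:
        return False
    return True


def sort_multiunits(ws: WaveformSet, n_subset: int = 5000, n_pcs: int = 6,
                    max_clusters: int = 3, fuse_corr: float = 0.95,
                    fuse_dist: float = 1.0, seed: int = 0,
                    max_amplitude: float | None = None,
                    max_duration_ms: float = 1.5) -> WaveformSet:
    """Cluster detected events into 0+ accepted multiunits.

    PCA is fitted on a random subset of at most ``n_subset`` events and
    projects every event to ``n_pcs`` dimensions; Ward clustering on the
    subset scores yields at most ``max_clusters`` clusters; remaining events
    are assigned to the nearest cluster centre (Euclidean).  Clusters failing
    the waveform-shape criteria are rejected (label -1); cluster pairs whose
    unit-normalized average waveforms correlate above ``fuse_corr`` and lie
    within ``fuse_dist`` are fused.
    """
    n = ws.n_events
    if n == 0:
        return WaveformSet(ws.waveforms, ws.event_times, ws.fs,
                           cluster_labels=np.empty(0, dtype=int))
    rng = np.random.default_rng(seed)
    wfs = ws.waveforms
    align = ws.align_index
    if n < max_clusters:
        labels = np.zeros(n, dtype=int)
    else:
        sub = rng.choice(n, size=min(n_subset, n), replace=False)
        pca = PCA(n_components=min(n_pcs, wfs.shape[1], sub.size))
        scores_sub = pca.fit_transform(wfs[sub])
        k = min(max_clusters, sub.size)
        ward = AgglomerativeClustering(n_clusters=k, linkage="ward")
        sub_labels = ward.fit_predict(scores_sub)
        centers = np.stack([scores_sub[sub_labels == c].mean(axis=0)
                            for c in range(k)])
        scores_all = pca.transform(wfs)
        d = np.linalg.norm(scores_all[:, None, :] - centers[None, :, :], axis=2)
        labels = np.argmin(d, axis=1)

    # fuse clusters with nearly identical average waveforms
    def _avg(lab):
        return wfs[labels == lab].mean(axis=0)

    changed = True
    while changed:
        changed = False
        labs = sorted(set(labels))
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                a, b = _avg(labs[i]), _avg(labs[j])
                an = a / np.linalg.norm(a)
                bn = b / np.linalg.norm(b)
                corr = np.corrcoef(a, b)[0, 1]
                if corr > fuse_corr and np.linalg.norm(an - bn) < fuse_dist:
                    labels[labels == labs[j]] = labs[i]
                    changed = True
                    break
            if changed:
                break

    # shape-based selection; relabel accepted clusters 0..n_units-1
    out = np.full(n, -1, dtype=int)
    next_label = 0
    for lab in sorted(set(labels)):
        members = labels == lab
        if _shape_ok(_avg(lab), wfs[members], align, ws.fs,
                     max_amplitude=max_amplitude, max_duration_ms=max_duration_ms):
            out[members] = next_label
            next_label += 1
    return WaveformSet(wfs, ws.event_times, ws.fs, cluster_labels=out)


def binary_train(ws: WaveformSet, unit: int, n_samples: int, fs_out: float) -> np.ndarray:
    """Regenerate a unit's 0/1 spike train at the LFP sampling rate."""
    if ws.cluster_labels is None:
        raise ValueError("waveform set is unsorted")
    train = np.zeros(n_samples)
    t = ws.event_times[ws.cluster_labels == unit] / ws.fs
    idx = np.round(t * fs_out).astype(int)
    idx = idx[idx < n_samples]
    train[idx] = 1.0
    return train
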