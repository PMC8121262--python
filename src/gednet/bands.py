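"""Empirical frequency-band discovery (gedBounds).

A frequency band is defined as a contiguous-in-structure group of grid
frequencies whose top GED eigenvectors are mutually correlated.  The matrix
of squared Pearson correlations between the per-frequency top eigenvectors is
clustered with DBSCAN (which, unlike k-means, may leave uncorrelated
frequencies unassigned); band centres pooled over sessions and animals are
then summarized by repeated k-means in log-frequency space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN, KMeans

from .spectral import FrequencyGrid

__all__ = ["Band", "BandStructure", "eigenvector_similarity_matrix",
           "detect_frequency_bands", "summarize_band_centers"]


@dataclass(frozen=True)
class Band:
    f_low: float
    f_high: float
    member_freq_indices: tuple

    @property
    def center(self) -> float:
        """Geometric-mean centre frequency (grid is logarithmic)."""
        return float(np.sqrt(self.f_low * self.f_high))


@dataclass
class BandStructure:
    r2_matrix: np.ndarray
    bands: list = field(default_factory=list)
    unclustered: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    grid: FrequencyGrid | None = None

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])


def eigenvector_similarity_matrix(top_eigenvectors: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between every pair of top eigenvectors.

    ``top_eigenvectors``: n_freqs x M (one sign-fixed eigenvector per grid
    frequency).  The result is symmetric with unit diagonal; correlation with
    a constant vector is defined as 0.
    """
    V = np.asarray(top_eigenvectors, dtype=float)
    sd = V.std(axis=1)
    r2 = np.zeros((V.shape[0], V.shape[0]))
    ok = sd > 0
    if ok.any():
        C = np.corrcoef(V[ok])
        r2[np.ix_(ok, ok)] = np.atleast_2d(C) ** 2
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def detect_frequency_bands(r2: np.ndarray, grid: FrequencyGrid,
                           eps: float = 0.5, min_pts: int = 3) -> BandStructure:
    """Density-cluster the r2 matrix rows into empirical frequency bands.

    Each frequency is described by its full correlation profile (its row of
    the r2 matrix); DBSCAN with Euclidean distance groups frequencies with
    similar profiles.  Clusters with at least ``min_pts`` members become
    bands whose bounds are the lowest and highest member frequencies; noise
    frequencies stay unclustered.  Zero bands is a legitimate outcome.
    """
    r2 = np.asarray(r2, dtype=float)
    if r2.shape[0] != r2.shape[1] or r2.shape[0] != len(grid):
        raise ValueError("r2 must be square and match the frequency grid")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(r2)
    bands = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        f = grid.freqs[idx]
        bands.append(Band(float(f.min()), float(f.max()), tuple(int(i) for i in idx)))
    bands.sort(key=lambda b: b.f_low)
    return BandStructure(r2_matrix=r2, bands=bands,
                         unclustered=np.flatnonzero(labels == -1), grid=grid)


def summarize_band_centers(band_sets, k: int | None = None, reseeds: int = 100,
                           rng: np.random.Generator | int | None = None) -> dict:
    """Consensus band-centre frequencies across sessions/animals via k-means.

    ``band_sets`` is a collection of per-session band lists (``Band`` objects
    or (f_low, f_high) pairs).  Centres are pooled in log-frequency space and
    clustered ``reseeds`` times with fresh random initializations; the sorted
    cluster centres of each run are collected and their across-run mean and
    SD reported in Hz.  ``k`` defaults to the modal band count per session.
    """
    rng = np.random.default_rng(rng)
    per_session_counts = []
    centers = []
    for bands in band_sets:
        per_session_counts.append(len(bands))
        for b in bands:
            if isinstance(b, Band):
                centers.append(b.center)
            else:
                lo, hi = b
                centers.append(float(np.sqrt(lo * hi)))
    centers = np.asarray(centers, dtype=float)
    if k is None:
        if not per_session_counts:
            raise ValueError("no band sets supplied")
        counts, vals = np.histogram(per_session_counts,
                                    bins=np.arange(0.5, max(per_session_counts) + 1.5))
        k = int(np.argmax(counts) + 1)
    if centers.size < k:
        raise ValueError(f"fewer pooled band centres ({centers.size}) than k={k}")
    log_c = np.log10(centers).reshape(-1, 1)
    runs = np.empty((reseeds, k))
    for r in range(reseeds):
        km = KMeans(n_clusters=k, n_init=1, init="random",
                    random_state=int(rng.integers(2**31 - 1)))
        km.fit(log_c)
        runs[r] = 10.0 ** np.sort(km.cluster_centers_.ravel())
    return {"centers": runs.mean(axis=0), "sd": runs.std(axis=0),
            "k": k, "runs": runs}
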