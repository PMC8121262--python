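"""Derived per-frequency network statistics.

Covers the inferential and descriptive quantities computed from the GED
components: permutation-based subspace dimensionality, region bias score and
regional energy fractions, LFP-vs-multiunit modality dominance, channel
entropy, kurtosis of the narrowband signal and its amplitude envelope, the
weighted phase-lag index (wPLI) between components, and cross-session spatial
map reproducibility.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .ged import clean_covariance_pool, ged_decompose, shrink_regularize

__all__ = [
    "permutation_dimensionality", "region_bias_score", "region_energy_fractions",
    "modality_dominance", "channel_entropy", "distribution_kurtosis", "wpli",
    "map_reproducibility",
]


def permutation_dimensionality(seg_covs_narrow: np.ndarray,
                               seg_covs_broad: np.ndarray,
                               n_perm: int = 200, gamma: float = 0.01,
                               clean_sd: float = 3.0,
                               rng: np.random.Generator | int | None = None) -> dict:
    """Number of GED eigenvalues exceeding a permutation-derived null maximum.

    Each data segment contributes two covariance matrices — one narrowband,
    one broadband.  The observed decomposition averages the narrowband pool
    into S and the broadband pool into R (each cleaned with the 3-SD
    Frobenius rule, R shrunk by ``gamma``).  Under the null that S and R
    carry the same information the two matrices of a segment are
    exchangeable: each permutation randomly swaps, per segment, which of its
    two covariance matrices averages into S and which into R, then repeats
    cleaning/shrinkage/GED and stores the largest eigenvalue.  The threshold
    is the maximum of the ``n_perm`` largest eigenvalues — the most extreme
    value expected under the null, which also controls for the implicit
    maximum over the M components.

    ``seg_covs_narrow`` and ``seg_covs_broad`` must be aligned by segment
    (equal counts).  Returns ``{"dimensionality", "threshold",
    "eigenvalues", "null_max"}``.
    """
    rng = np.random.default_rng(rng)
    seg_covs_narrow = np.asarray(seg_covs_narrow)
    seg_covs_broad = np.asarray(seg_covs_broad)
    if seg_covs_narrow.shape != seg_covs_broad.shape:
        raise ValueError("narrow/broad segment covariances must be aligned by segment")
    n_seg = seg_covs_narrow.shape[0]
    if n_seg < 4:
        raise ValueError("need at least 4 segments per pool")

    def _solve(pool_S, pool_R):
        S, _, _ = clean_covariance_pool(pool_S, clean_sd)
        R, _, _ = clean_covariance_pool(pool_R, clean_sd)
        S = 0.5 * (S + S.T)
        R = shrink_regularize(0.5 * (R + R.T), gamma)
        return ged_decompose(S, R).lambdas

    observed = _solve(seg_covs_narrow, seg_covs_broad)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        swap = rng.random(n_seg) < 0.5
        pool_S = np.where(swap[:, None, None], seg_covs_broad, seg_covs_narrow)
        pool_R = np.where(swap[:, None, None], seg_covs_narrow, seg_covs_broad)
        null_max[p] = _solve(pool_S, pool_R)[0]
    threshold = null_max.max()
    return {"dimensionality": int((observed > threshold).sum()),
            "threshold": float(threshold),
            "eigenvalues": observed,
            "null_max": null_max}


def _region_rms(w: np.ndarray, region_labels) -> tuple:
    w = np.asarray(w, dtype=float)
    labels = np.asarray(region_labels)
    regions = list(dict.fromkeys(labels))
    rms = np.array([np.sqrt(np.mean(w[labels == r] ** 2)) for r in regions])
    return rms, regions


def region_bias_score(w: np.ndarray, region_labels) -> float:
    """How strongly one region dominates a spatial filter, in [0, 1].

    Per-region RMS of the eigenvector elements is normalized to sum to 1 and
    compared (Euclidean distance) with the perfectly shared profile
    ``[1, 1, 1]/3``; the distance is divided by its maximum attainable value
    (the single-region profile, sqrt((n-1)/n)) so that 0 means exactly equal
    regional contributions and 1 means a single region carries everything.
    """
    rms, regions = _region_rms(w, region_labels)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    total = rms.sum()
    if total == 0:
        raise ValueError("zero eigenvector")
    v = rms / total
    n = len(regions)
    ideal = np.full(n, 1.0 / n)
    d_max = np.sqrt((n - 1) / n)
    return float(np.linalg.norm(v - ideal) / d_max)


def region_energy_fractions(w: np.ndarray, region_labels) -> np.ndarray:
    """Per-region RMS of eigenvector elements, normalized to sum to 1."""
    rms, _ = _region_rms(w, region_labels)
    total = rms.sum()
    if total == 0:
        return np.full(rms.size, 1.0 / rms.size)
    return rms / total


def modality_dominance(w: np.ndarray, modality_labels) -> float:
    """Normalized RMS difference of LFP vs. multiunit filter weights, in [-1, 1].

    +1 means the multiunits contribute nothing; -1 means the LFP channels
    contribute nothing.
    """
    w = np.asarray(w, dtype=float)
    labels = np.asarray(modality_labels)
    lfp = w[labels == "LFP"]
    mu = w[labels == "MU"]
    if lfp.size == 0 or mu.size == 0:
        raise ValueError("both LFP and MU channels required")
    rms_lfp = np.sqrt(np.mean(lfp ** 2))
    rms_mu = np.sqrt(np.mean(mu ** 2))
    denom = rms_lfp + rms_mu
    if denom == 0:
        raise ValueError("zero eigenvector on both modalities")
    return float((rms_lfp - rms_mu) / denom)


def channel_entropy(x: np.ndarray, k: int = 40) -> float:
    """Shannon entropy (bits) of a series discretized into k equal-width bins.

    Empty bins contribute zero; a constant series has zero entropy by
    convention.  Bounded by log2(k).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=k)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def distribution_kurtosis(z: np.ndarray, valid: np.ndarray | None = None) -> dict:
    """Non-excess kurtosis of the real part and of the amplitude envelope.

    A Gaussian signal scores 3; leptokurtic (heavy-tailed) signals score
    above 3.  ``z`` is the complex analytic narrowband series.
    """
    z = np.asarray(z)
    if valid is not None:
        z = z[valid]
    if z.size < 4:
        raise ValueError("need at least 4 samples")
    re = np.real(z)
    env = np.abs(z)
    if re.std() == 0 or env.std() == 0:
        raise ValueError("zero-variance series")
    return {"kurt_real": float(sps.kurtosis(re, fisher=False)),
            "kurt_envelope": float(sps.kurtosis(env, fisher=False))}


def wpli(z1: np.ndarray, z2: np.ndarray, fs: float, epoch_s: float = 2.0) -> float:
    """Weighted phase-lag index between two analytic signals, in [0, 1].

    Uses only the imaginary part of the cross-spectrum c = z1 * conj(z2), so
    zero-lag (volume-conducted) coupling contributes nothing.  Per epoch:
    |mean(imag c)| / mean(|imag c|); epochs are averaged and 0/0 is 0.
    """
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError("series must have equal length")
    cross = z1 * np.conj(z2)
    c = np.imag(cross)
    scale = np.abs(cross).mean()         # sets the numerical floor for 0/0
    seg_len = max(int(round(epoch_s * fs)), 1)
    n_ep = max(c.size // seg_len, 1)
    vals = []
    for k in range(n_ep):
        seg = c[k * seg_len:(k + 1) * seg_len] if c.size >= seg_len else c
        denom = np.abs(seg).mean()
        vals.append(0.0 if denom <= 1e-12 * scale else np.abs(seg.mean()) / denom)
    return float(np.mean(vals))


def _corr2(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def map_reproducibility(maps_a: np.ndarray, maps_b: np.ndarray) -> dict:
    """Squared spatial correlations between two sessions' top-2 component maps.

    ``r2_top`` correlates the two rank-1 maps; ``r2_max`` takes the largest of
    the four correlations across the top-2 x top-2 pairs, accommodating rank
    swaps of the same underlying network between sessions.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.shape[0] != maps_b.shape[0]:
        raise ValueError("maps must share the channel set")
    r2_top = _corr2(maps_a[:, 0], maps_b[:, 0])
    ka = min(2, maps_a.shape[1])
    kb = min(2, maps_b.shape[1])
    r2_max = max(_corr2(maps_a[:, i], maps_b[:, j])
                 for i in range(ka) for j in range(kb))
    return {"r2_top": r2_top, "r2_max": r2_max}
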