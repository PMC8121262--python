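"""Generalized eigendecomposition (GED) of narrowband vs. broadband covariance.

The contrast maximizes the Rayleigh quotient w'Sw / w'Rw where S is the
channel covariance of narrowband-filtered data and R the covariance of the
broadband data.  Solving S W = R W L yields spatial filters (columns of W)
sorted by eigenvalue; each eigenvalue is the narrowband-to-broadband variance
ratio achieved by its filter, with null expectation 1.

Covariance estimation follows a segment-and-clean scheme: the continuous data
are cut into non-overlapping segments (2 s by default), even-numbered segments
feed the S pool and odd-numbered segments the R pool, and segments whose
covariance lies more than 3 SDs (Frobenius distance) from the pool mean are
excluded once before re-averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "CovariancePair", "ComponentSet", "segment_slices", "segment_covariances",
    "clean_covariance_pool", "build_covariance_pair", "shrink_regularize",
    "ged_decompose", "project_components",
]


@dataclass
class CovariancePair:
    """Averaged narrowband (S) and broadband (R) covariance matrices.

    ``n_segments_S`` / ``n_segments_R`` count the segments assigned to each
    pool by the even/odd split (before outlier cleaning); ``n_excluded`` is
    the total number of segments removed by the 3-SD Frobenius rule.
    """

    S: np.ndarray
    R: np.ndarray
    n_segments_S: int
    n_segments_R: int
    n_excluded: int = 0
    frequency: float | str = "broadband"

    def __post_init__(self):
        for name, C in (("S", self.S), ("R", self.R)):
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
        if self.S.shape != self.R.shape:
            raise ValueError("S and R must have equal shapes")


@dataclass
class ComponentSet:
    """Eigenvectors, eigenvalues and projections of one GED solution.

    Columns of ``W`` are spatial filters sorted by descending eigenvalue.
    ``maps`` column j is S @ w_j (the anatomically interpretable projection);
    ``timeseries`` row j is w_j' @ X.
    """

    W: np.ndarray
    lambdas: np.ndarray
    maps: np.ndarray | None = None
    timeseries: np.ndarray | None = None
    timeseries_valid: np.ndarray | None = None
    frequency: float | str = "broadband"


def segment_slices(n_samples: int, fs: float, seg_s: float = 2.0) -> list:
    """Non-overlapping full-length segment slices covering the recording."""
    seg_len = int(round(seg_s * fs))
    n_seg = n_samples // seg_len
    return [slice(k * seg_len, (k + 1) * seg_len) for k in range(n_seg)]


def segment_covariances(X: np.ndarray, slices, valid: np.ndarray | None = None,
                        min_valid_frac: float = 0.5):
    """Per-segment channel covariance matrices of mean-centred data.

    Complex input is reduced to its real part (covariance of the filtered
    signal, not of the envelope).  If ``valid`` is given, time points where
    any channel is masked are dropped listwise inside each segment; segments
    with fewer than ``min_valid_frac`` valid samples are discarded.

    Returns ``(covs, kept)`` where ``covs`` has shape (n_kept, M, M) and
    ``kept`` indexes the surviving slices.
    """
    X = np.real(X)
    M = X.shape[0]
    covs, kept = [], []
    for k, sl in enumerate(slices):
        seg = X[:, sl]
        if valid is not None:
            ok = valid[:, sl].all(axis=0)
            if ok.mean() < min_valid_frac:
                continue
            seg = seg[:, ok]
        if seg.shape[1] < 2:
            continue
        seg = seg - seg.mean(axis=1, keepdims=True)
        covs.append(seg @ seg.T / (seg.shape[1] - 1))
        kept.append(k)
    if covs:
        covs = np.stack(covs)
    else:
        covs = np.empty((0, M, M))
    return covs, np.asarray(kept, dtype=int)


def clean_covariance_pool(covs: np.ndarray, clean_sd: float = 3.0):
    """Average a pool of segment covariances after one outlier-exclusion pass.

    Frobenius distance of each segment covariance to the pool mean is
    computed; segments farther than ``clean_sd`` SDs above the mean distance
    are excluded and the average recomputed once.

    Returns ``(mean_cov, n_excluded, kept_mask)``.
    """
    if covs.shape[0] == 0:
        raise ValueError("empty covariance pool")
    mean_cov = covs.mean(axis=0)
    dists = np.linalg.norm(covs - mean_cov, axis=(1, 2))
    sd = dists.std()
    if sd == 0:
        return mean_cov, 0, np.ones(covs.shape[0], dtype=bool)
    keep = dists <= dists.mean() + clean_sd * sd
    if not keep.any():       # pathological; refuse to drop everything
        keep[:] = True
    return covs[keep].mean(axis=0), int((~keep).sum()), keep


def build_covariance_pair(X_narrow: np.ndarray, X_broad: np.ndarray, fs: float,
                          seg_s: float = 2.0, clean_sd: float = 3.0,
                          valid: np.ndarray | None = None,
                          frequency: float | str = "narrowband") -> CovariancePair:
    """Build the averaged S (narrowband) / R (broadband) covariance pair.

    Segments are numbered from 1; even-numbered segments contribute to S and
    odd-numbered segments to R, so the two matrices are estimated from
    disjoint data.  Each pool is cleaned with the 3-SD Frobenius rule.
    """
    if X_narrow.shape[-1] != X_broad.shape[-1]:
        raise ValueError("narrowband and broadband matrices must share sample count")
    slices = segment_slices(X_narrow.shape[-1], fs, seg_s)
    if len(slices) < 4:
        raise ValueError(f"need at least 4 segments of {seg_s} s; got {len(slices)}")
    # 1-based parity: slices[0] is segment 1 -> odd -> R pool
    even = slices[1::2]
    odd = slices[0::2]
    covs_S, _ = segment_covariances(X_narrow, even, valid)
    covs_R, _ = segment_covariances(X_broad, odd, valid)
    S, excl_S, _ = clean_covariance_pool(covs_S, clean_sd)
    R, excl_R, _ = clean_covariance_pool(covs_R, clean_sd)
    return CovariancePair(S=0.5 * (S + S.T), R=0.5 * (R + R.T),
                          n_segments_S=covs_S.shape[0], n_segments_R=covs_R.shape[0],
                          n_excluded=excl_S + excl_R, frequency=frequency)


def shrink_regularize(R: np.ndarray, gamma: float = 0.01) -> np.ndarray:
    """Shrink R toward a scaled identity: (1-g) R + g a I with a = mean eigenvalue.

    The mean eigenvalue equals trace(R)/M, so the trace is preserved exactly.
    """
    if not (0 <= gamma < 1):
        raise ValueError("gamma must be in [0, 1)")
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    M = R.shape[0]
    alpha = np.trace(R) / M
    return (1.0 - gamma) * R + gamma * alpha * np.eye(M)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def ged_decompose(S: np.ndarray, R: np.ndarray) -> ComponentSet:
    """Solve S W = R W L, sorted by descending eigenvalue.

    R must be positive definite (apply :func:`shrink_regularize` first for
    noisy or rank-deficient data).  Each returned eigenvalue equals the
    Rayleigh quotient w'Sw / w'Rw of its (unit-norm, sign-fixed) eigenvector.
    Eigenvectors are not mutually orthogonal in general, but are R-orthogonal.
    """
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    try:
        evals, evecs = linalg.eigh(S, R)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "generalized eigendecomposition failed; R may be singular — "
            "apply shrink_regularize to R first") from err
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evecs = evecs / np.linalg.norm(evecs, axis=0, keepdims=True)
    evecs = _fix_signs(evecs)
    return ComponentSet(W=evecs, lambdas=evals)


def project_components(W: np.ndarray, S: np.ndarray, X: np.ndarray,
                       z_outlier: float = 4.0):
    """Component maps (S @ w_j) and time series (w_j' @ X) with 4-SD masking.

    Time-series samples whose real part deviates more than ``z_outlier`` SDs
    from the component mean are flagged invalid (mirroring the channel-level
    exclusion rule).  Returns ``(maps, timeseries, ts_valid)``.
    """
    maps = S @ W
    ts = W.T @ X
    re = np.real(ts)
    mu = re.mean(axis=1, keepdims=True)
    sd = re.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    ts_valid = np.abs(re - mu) <= z_outlier * sd
    return maps, ts, ts_valid
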