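"""Assembly of the joint LFP + multiunit data matrix.

Steps: regional average referencing of the LFP channels, Gaussian smoothing
of binary spike trains into continuous rate signals, trimming of the first
and last seconds of a session, per-channel z-scoring, and masking of 4-SD
outlier samples.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .recording import PreparedMatrix, Recording

__all__ = ["regional_average_reference", "smooth_spike_train", "prepare_matrix",
           "apply_exclusions"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def regional_average_reference(rec: Recording) -> Recording:
    """Subtract, per region, the mean of that region's LFP channels.

    Removes long-range volume-conducted fields so components reflect the
    coordination of local dipoles.  Multiunit channels are untouched.  A
    region with a single LFP channel cannot be referenced and is left as-is
    with a warning.  The operation is idempotent.
    """
    out = rec.copy()
    modality = rec.channel_meta["modality"].to_numpy()
    region = rec.channel_meta["region"].to_numpy()
    for r in rec.regions:
        idx = np.flatnonzero((modality == "LFP") & (region == r))
        if idx.size == 0:
            continue
        if idx.size == 1:
            warnings.warn(f"region {r!r} has a single LFP channel; left unreferenced")
            continue
        out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    return out


def smooth_spike_train(train: np.ndarray, fs: float, fwhm_ms: float = 30.0) -> np.ndarray:
    """Convolve a binary spike train with a unit-area Gaussian (30-ms FWHM).

    Produces the continuous multiunit rate signal entered into the data
    matrix.  Reflective edge handling preserves the total mass, so the output
    sums to the spike count regardless of spike placement.
    """
    train = np.asarray(train, dtype=float)
    if fwhm_ms <= 0:
        raise ValueError("fwhm_ms must be positive")
    if train.size == 0:
        return train.copy()
    sigma = fwhm_ms * 1e-3 * fs * _FWHM_TO_SIGMA
    return gaussian_filter1d(train, sigma, mode="reflect")


def apply_exclusions(rec: Recording, exclude_channels=(), exclude_intervals=()) -> Recording:
    """Drop listed channels and zero-weight listed time intervals.

    Config-level stand-in for interactive artifact screening: channels are
    removed by name; ``exclude_intervals`` is a list of (t_start, t_stop)
    pairs in seconds whose samples will be masked by :func:`prepare_matrix`
    (they are flagged by setting them to NaN here).
    """
    keep = ~rec.channel_meta["name"].isin(list(exclude_channels)).to_numpy()
    data = rec.data[keep].copy()
    meta = rec.channel_meta.loc[keep].reset_index(drop=True)
    for t0, t1 in exclude_intervals:
        a, b = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
        data[:, a:b] = np.nan
    return Recording(data, rec.fs, meta, rec.session_id, rec.animal_id)


def prepare_matrix(rec: Recording, trim_s: float = 10.0,
                   z_outlier: float = 4.0) -> PreparedMatrix:
    """Trim, z-score and outlier-mask every channel.

    The first and last ``trim_s`` seconds are removed (handling artifacts at
    session boundaries).  Each channel is normalized to mean 0 / variance 1,
    samples deviating more than ``z_outlier`` SDs are masked, and the channel
    is re-standardized over the surviving samples in one pass, so valid
    samples have exactly zero mean and unit variance.
    """
    n_trim = int(round(trim_s * rec.fs))
    if rec.n_samples <= 2 * n_trim:
        raise ValueError(f"recording ({rec.duration:.1f} s) shorter than twice "
                         f"the trim ({trim_s} s)")
    data = rec.data[:, n_trim:rec.n_samples - n_trim].astype(float).copy()
    valid = np.isfinite(data)
    data[~valid] = 0.0
    names = rec.channel_meta["name"].tolist()
    scale = np.empty(data.shape[0])
    for i in range(data.shape[0]):
        v = valid[i]
        x = data[i]
        sd = x[v].std()
        if sd == 0 or not v.any():
            raise ValueError(f"channel {names[i]!r} is constant after trimming")
        z = (x - x[v].mean()) / sd
        v &= np.abs(z) <= z_outlier
        if not v.any() or x[v].std() == 0:
            raise ValueError(f"channel {names[i]!r} degenerate after outlier masking")
        scale[i] = x[v].std()
        data[i] = (x - x[v].mean()) / scale[i]
        valid[i] = v
    return PreparedMatrix(data=data, valid=valid, fs=rec.fs,
                          channel_meta=rec.channel_meta.copy(), trim_s=trim_s,
                          session_id=rec.session_id, animal_id=rec.animal_id,
                          channel_scale=scale)
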