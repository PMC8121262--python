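"""Core in-memory containers for multichannel electrophysiology data.

A :class:`Recording` holds a channels-by-samples matrix together with
per-channel metadata (modality — local field potential ``LFP`` or multiunit
``MU`` — and anatomical region label).  All downstream analyses consume this
container or the z-scored/masked :class:`PreparedMatrix` produced by
:mod:`gednet.preprocessing`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODALITIES = ("LFP", "MU")


def make_channel_meta(names, modalities, regions) -> pd.DataFrame:
    """Assemble a channel-metadata table.

    Parameters
    ----------
    names, modalities, regions : sequences of str, equal length
        ``modalities`` entries must be ``"LFP"`` or ``"MU"``.
    """
    meta = pd.DataFrame({"name": list(names),
                         "modality": list(modalities),
                         "region": list(regions)})
    bad = set(meta["modality"]) - set(MODALITIES)
    if bad:
        raise ValueError(f"unknown modalities {sorted(bad)}; expected {MODALITIES}")
    return meta


@dataclass
class Recording:
    """Continuous multichannel recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in arbitrary units.  LFP channels are voltages; MU channels
        are Gaussian-smoothed spike-rate signals.
    fs : float
        Sampling rate in samples/s.
    channel_meta : DataFrame with columns ``name``, ``modality``, ``region``
    session_id : str
    animal_id : str
    """

    data: np.ndarray
    fs: float
    channel_meta: pd.DataFrame
    session_id: str = "session0"
    animal_id: str = "animal0"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_meta) != self.data.shape[0]:
            raise ValueError("channel_meta length does not match channel count")
        if self.channel_meta["region"].nunique() < 1:
            raise ValueError("at least one region label required")
        bad = set(self.channel_meta["modality"]) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def lfp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.channel_meta["modality"].to_numpy() == "LFP")

    @property
    def mu_indices(self) -> np.ndarray:
        return np.flatnonzero(self.channel_meta["modality"].to_numpy() == "MU")

    @property
    def regions(self) -> list:
        """Region labels in order of first appearance."""
        return list(dict.fromkeys(self.channel_meta["region"]))

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, self.channel_meta.copy(),
                         self.session_id, self.animal_id)


@dataclass
class PreparedMatrix:
    """Trimmed, z-scored, outlier-masked data matrix ready for covariance work.

    ``valid`` marks samples retained after the 4-SD exclusion; masked samples
    are excluded from all downstream moments and covariances.
    """

    data: np.ndarray            # channels x samples, z-scored on valid samples
    valid: np.ndarray           # boolean, same shape
    fs: float
    channel_meta: pd.DataFrame
    trim_s: float = 0.0
    session_id: str = "session0"
    animal_id: str = "animal0"
    channel_scale: np.ndarray | None = None   # SD divided out per channel (orig units)

    def __post_init__(self):
        if self.data.shape != self.valid.shape:
            raise ValueError("data and valid mask must have equal shapes")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def lfp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.channel_meta["modality"].to_numpy() == "LFP")

    @property
    def mu_indices(self) -> np.ndarray:
        return np.flatnonzero(self.channel_meta["modality"].to_numpy() == "MU")

    @property
    def regions(self) -> list:
        return list(dict.fromkeys(self.channel_meta["region"]))
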