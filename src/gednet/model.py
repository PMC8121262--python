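"""Model/results interface for the frequency-resolved GED analysis.

:class:`FrequencyGED` is constructed from a :class:`~gednet.recording.Recording`
(or raw arrays) and holds the preprocessed joint LFP+multiunit matrix together
with the analysis parameters; :meth:`FrequencyGED.fit` runs the per-frequency
generalized eigendecomposition over the whole grid and returns a
:class:`FrequencyGEDResults` carrying eigenvalues, spatial filters, component
maps and bookkeeping, with methods for band discovery, permutation-based
dimensionality, derived network statistics, summary tables and plots.

Typical use::

    truth = synthetic.generate_ground_truth(3, seed=1)
    rec = synthetic.generate_recording(truth, duration=120, snr=1.5, seed=2)
    res = FrequencyGED(rec).fit()
    print(res.summary())
    bands = res.band_structure()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import netstats
from .bands import BandStructure, detect_frequency_bands, eigenvector_similarity_matrix
from .ged import (CovariancePair, clean_covariance_pool, ged_decompose,
                  project_components, segment_covariances, segment_slices,
                  shrink_regularize)
from .preprocessing import apply_exclusions, prepare_matrix, regional_average_reference
from .recording import PreparedMatrix, Recording
from .spectral import FrequencyGrid, make_frequency_grid, narrowband_filter

__all__ = ["FrequencyGED", "FrequencyGEDResults", "compare_sessions"]


class FrequencyGED:
    """Frequency-resolved GED source separation of an LFP+multiunit recording.

    Parameters
    ----------
    recording : Recording
        Continuous channels-by-samples data with modality and region labels.
    grid : FrequencyGrid, optional
        Analysis frequencies; defaults to 2–200 Hz in 100 log steps with
        spectral FWHMs 2–5 Hz.
    seg_s : float
        Covariance segment length in seconds (default 2).
    clean_sd : float
        Frobenius-distance outlier threshold for segment covariances
        (default 3 SDs).
    gamma : float
        Shrinkage applied to the broadband covariance R (default 0.01).
    trim_s, z_outlier :
        Session-edge trim (s) and sample-outlier threshold (SDs) used by
        preprocessing (defaults 10 s and 4 SDs).
    per_freq_norm : bool
        Rescale each channel's narrowband series to unit variance before
        building S (makes maps comparable across frequencies).  The
        de-normalized maps remain available on the results object.
    reference : bool
        Apply regional average referencing to LFP channels first.
    """

    def __init__(self, recording: Recording, grid: FrequencyGrid | None = None, *,
                 seg_s: float = 2.0, clean_sd: float = 3.0, gamma: float = 0.01,
                 trim_s: float = 10.0, z_outlier: float = 4.0,
                 per_freq_norm: bool = True, reference: bool = True,
                 exclude_channels=(), exclude_intervals=()):
        if exclude_channels or exclude_intervals:
            recording = apply_exclusions(recording, exclude_channels, exclude_intervals)
        if reference:
            recording = regional_average_reference(recording)
        self.recording = recording
        self.grid = grid if grid is not None else make_frequency_grid()
        nyq = recording.fs / 2
        if self.grid.freqs.max() >= nyq:
            raise ValueError(f"grid extends to {self.grid.freqs.max()} Hz, "
                             f"at or above Nyquist ({nyq} Hz)")
        self.seg_s = seg_s
        self.clean_sd = clean_sd
        self.gamma = gamma
        self.per_freq_norm = per_freq_norm
        self.prepared: PreparedMatrix = prepare_matrix(recording, trim_s, z_outlier)
        self._slices = segment_slices(self.prepared.n_samples, recording.fs, seg_s)
        if len(self._slices) < 4:
            raise ValueError("recording too short: fewer than 4 covariance segments")
        self._rank_basis = None
        self._broadband_scale = None

    # ------------------------------------------------------------------ #
    @property
    def fs(self) -> float:
        return self.recording.fs

    @property
    def n_channels(self) -> int:
        return self.prepared.n_channels

    def _segment_sd(self, X: np.ndarray) -> np.ndarray:
        """Per-channel SD at the segment level (sqrt of the mean
        within-segment variance over valid samples).

        All channel normalizations use this segment-level scale — the scale
        at which the covariance matrices are actually estimated — so that
        narrowband (S) and broadband (R) matrices share a unit-diagonal
        convention and the null eigenvalue expectation of 1 is preserved.
        """
        X = np.real(X)
        valid = self.prepared.valid
        var_sum = np.zeros(X.shape[0])
        n_used = 0
        for sl in self._slices:
            v = valid[:, sl].all(axis=0)
            if v.sum() < 2:
                continue
            seg = X[:, sl][:, v]
            var_sum += seg.var(axis=1)
            n_used += 1
        sd = np.sqrt(var_sum / max(n_used, 1))
        sd[sd == 0] = 1.0
        return sd

    def narrowband_matrix(self, freq_index: int):
        """Joint analytic matrix at one grid frequency.

        LFP channels are Morlet-filtered to complex analytic series; MU
        channels pass through unfiltered (already 30-ms-smoothed rates).
        Returns ``(X_narrow, scales)`` where ``scales`` are the per-channel
        segment-level SDs divided out when ``per_freq_norm`` is on (ones
        otherwise).
        """
        f_c = self.grid.freqs[freq_index]
        fwhm = self.grid.fwhms[freq_index]
        prep = self.prepared
        X = prep.data.astype(complex).copy()
        lfp = prep.lfp_indices
        X[lfp] = narrowband_filter(prep.data[lfp], self.fs, f_c, fwhm)
        scales = np.ones(prep.n_channels)
        if self.per_freq_norm:
            scales = self._segment_sd(X)
            X /= scales[:, None]
        return X, scales

    def broadband_matrix(self):
        """Broadband data on the segment-level unit-variance scale."""
        prep = self.prepared
        if not self.per_freq_norm:
            return prep.data, np.ones(prep.n_channels)
        if self._broadband_scale is None:
            self._broadband_scale = self._segment_sd(prep.data)
        sc = self._broadband_scale
        return prep.data / sc[:, None], sc

    def broadband_covariances(self):
        """Per-segment broadband covariance matrices (all segments)."""
        covs, kept = segment_covariances(self.prepared.data, self._slices,
                                         self.prepared.valid)
        return covs, kept

    def rank_basis(self, R_raw: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
        """Orthonormal basis of R's numerically positive subspace.

        Regional average referencing removes one degree of freedom per
        region, leaving exact null directions in the broadband covariance;
        the GED is solved in the complementary subspace so those directions
        cannot produce spurious eigenvalue ratios.  Without referencing this
        is the identity basis.
        """
        if self._rank_basis is None:
            e, U = np.linalg.eigh(R_raw)
            keep = e > rel_tol * e.max()
            self._rank_basis = U[:, keep]
        return self._rank_basis

    def segment_covariance_pools(self, freq_index: int):
        """Aligned per-segment (narrowband, broadband) covariance pairs.

        Used by the permutation dimensionality test: every segment
        contributes one narrowband and one broadband covariance matrix.
        Both are expressed in the rank-compressed basis of the broadband
        covariance (see :meth:`rank_basis`).
        """
        X_narrow, _ = self.narrowband_matrix(freq_index)
        X_broad, _ = self.broadband_matrix()
        covs_n, kept_n = segment_covariances(X_narrow, self._slices,
                                             self.prepared.valid)
        covs_b, kept_b = segment_covariances(X_broad, self._slices,
                                             self.prepared.valid)
        common = np.intersect1d(kept_n, kept_b)
        covs_n = covs_n[np.isin(kept_n, common)]
        covs_b = covs_b[np.isin(kept_b, common)]
        if self._rank_basis is None:
            R_raw, _, _ = clean_covariance_pool(
                segment_covariances(X_broad, self._slices[0::2],
                                    self.prepared.valid)[0], self.clean_sd)
            self.rank_basis(0.5 * (R_raw + R_raw.T))
        T = self._rank_basis
        return (np.einsum("ij,njk,kl->nil", T.T, covs_n, T),
                np.einsum("ij,njk,kl->nil", T.T, covs_b, T))

    def fit(self, freq_indices=None) -> "FrequencyGEDResults":
        """Run the GED at every grid frequency (or a subset of indices)."""
        if freq_indices is None:
            freq_indices = np.arange(len(self.grid))
        freq_indices = np.asarray(freq_indices, dtype=int)
        prep = self.prepared
        M = prep.n_channels

        X_broad, _ = self.broadband_matrix()
        covs_b, _ = segment_covariances(X_broad, self._slices[0::2], prep.valid)
        R_raw, excl_R, _ = clean_covariance_pool(covs_b, self.clean_sd)
        R_raw = 0.5 * (R_raw + R_raw.T)
        T = self.rank_basis(R_raw)
        K = T.shape[1]
        R_c = shrink_regularize(T.T @ R_raw @ T, self.gamma)

        n_f = freq_indices.size
        lambdas = np.empty((n_f, K))
        W = np.empty((n_f, M, K))
        maps = np.empty((n_f, M, K))
        maps_denorm = np.empty((n_f, M, K))
        scales = np.empty((n_f, M))
        S_all = np.empty((n_f, M, M))
        n_seg_S = np.empty(n_f, dtype=int)
        n_excl = np.empty(n_f, dtype=int)
        for k, fi in enumerate(freq_indices):
            X_narrow, sc = self.narrowband_matrix(fi)
            covs_n, _ = segment_covariances(X_narrow, self._slices[1::2], prep.valid)
            S, excl_S, _ = clean_covariance_pool(covs_n, self.clean_sd)
            S = 0.5 * (S + S.T)
            cs = ged_decompose(T.T @ S @ T, R_c)
            Wk = T @ cs.W                       # back to channel space
            Wk /= np.linalg.norm(Wk, axis=0, keepdims=True)
            idx = np.argmax(np.abs(Wk), axis=0)
            sign = np.sign(Wk[idx, np.arange(K)])
            sign[sign == 0] = 1.0
            Wk *= sign
            lambdas[k] = cs.lambdas
            W[k] = Wk
            maps[k] = S @ Wk
            # undo per-frequency narrowband scaling and the z-score scaling so
            # this map lives in the raw input channel units
            maps_denorm[k] = (prep.channel_scale * sc)[:, None] * maps[k]
            scales[k] = sc
            S_all[k] = S
            n_seg_S[k] = covs_n.shape[0]
            n_excl[k] = excl_S
        return FrequencyGEDResults(
            model=self, freq_indices=freq_indices, lambdas=lambdas, W=W,
            maps=maps, maps_denorm=maps_denorm, scales=scales, S=S_all,
            R_raw=R_raw, n_segments_S=n_seg_S, n_segments_R=covs_b.shape[0],
            n_excluded_S=n_excl, n_excluded_R=excl_R)


class FrequencyGEDResults:
    """Estimates and diagnostics from :meth:`FrequencyGED.fit`.

    Attributes
    ----------
    lambdas : ndarray (n_freqs, M)
        Generalized eigenvalues, sorted descending per frequency; the
        narrowband/broadband variance ratio with null expectation 1.
    W : ndarray (n_freqs, M, M)
        Spatial filters (columns), unit norm, sign-fixed.
    maps, maps_denorm : ndarray (n_freqs, M, M)
        Component maps S @ w in the per-frequency-normalized space and
        re-expressed in original channel units.
    """

    def __init__(self, model, freq_indices, lambdas, W, maps, maps_denorm,
                 scales, S, R_raw, n_segments_S, n_segments_R,
                 n_excluded_S, n_excluded_R):
        self.model = model
        self.freq_indices = freq_indices
        self.freqs = model.grid.freqs[freq_indices]
        self.lambdas = lambdas
        self.W = W
        self.maps = maps
        self.maps_denorm = maps_denorm
        self.scales = scales
        self.S = S
        self.R_raw = R_raw
        self.n_segments_S = n_segments_S
        self.n_segments_R = n_segments_R
        self.n_excluded_S = n_excluded_S
        self.n_excluded_R = n_excluded_R

    # ----------------------------------------------------------------- #
    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    @property
    def top_eigenvalues(self) -> np.ndarray:
        return self.lambdas[:, 0]

    def top_eigenvectors(self) -> np.ndarray:
        """(n_freqs, M) matrix of the top spatial filter per frequency."""
        return self.W[:, :, 0]

    def covariance_pair(self, k: int) -> CovariancePair:
        return CovariancePair(S=self.S[k], R=self.R_raw,
                              n_segments_S=int(self.n_segments_S[k]),
                              n_segments_R=int(self.n_segments_R),
                              n_excluded=int(self.n_excluded_S[k] + self.n_excluded_R),
                              frequency=float(self.freqs[k]))

    def component_timeseries(self, k: int, n_components: int | None = None):
        """Complex component time series at result row ``k`` with 4-SD mask."""
        fi = self.freq_indices[k]
        X, _ = self.model.narrowband_matrix(fi)
        n_components = n_components or X.shape[0]
        Wk = self.W[k][:, :n_components]
        _, ts, ts_valid = project_components(Wk, self.S[k], X)
        return ts, ts_valid

    # ----------------------------------------------------------------- #
    def eigenvalue_table(self, top_k: int = 3) -> pd.DataFrame:
        cols = {"frequency_hz": self.freqs}
        for j in range(min(top_k, self.lambdas.shape[1])):
            cols[f"lambda{j + 1}"] = self.lambdas[:, j]
        cols["n_segments_S"] = self.n_segments_S
        cols["n_segments_R"] = self.n_segments_R
        cols["n_excluded"] = self.n_excluded_S + self.n_excluded_R
        return pd.DataFrame(cols)

    def band_structure(self, eps: float = 0.5, min_pts: int = 3) -> BandStructure:
        """Empirical frequency bands from the top-eigenvector r2 matrix."""
        r2 = eigenvector_similarity_matrix(self.top_eigenvectors())
        grid = FrequencyGrid(self.freqs, self.model.grid.fwhms[self.freq_indices])
        return detect_frequency_bands(r2, grid, eps=eps, min_pts=min_pts)

    def dimensionality(self, k: int, n_perm: int = 200, seed: int = 0) -> dict:
        """Permutation-test subspace dimensionality at result row ``k``."""
        covs_n, covs_b = self.model.segment_covariance_pools(self.freq_indices[k])
        return netstats.permutation_dimensionality(
            covs_n, covs_b, n_perm=n_perm, gamma=self.model.gamma,
            clean_sd=self.model.clean_sd, rng=seed)

    def metric_table(self, n_perm: int = 0, seed: int = 0,
                     entropy_bins: int = 40) -> pd.DataFrame:
        """Per-frequency derived network statistics.

        One row per analysed frequency: top eigenvalues, region bias and
        energy fractions of the top filter, LFP-vs-MU modality dominance,
        kurtosis (real part and envelope) of the top component, wPLI between
        the top two components, and — if ``n_perm > 0`` — permutation
        dimensionality.  Channel-entropy summaries (mean over LFP and MU
        channels) are frequency-independent and repeated on each row.
        """
        prep = self.model.prepared
        meta = prep.channel_meta
        region_labels = meta["region"].to_numpy()
        modality_labels = meta["modality"].to_numpy()
        have_mu = (modality_labels == "MU").any()
        regions = list(dict.fromkeys(region_labels))

        ent = np.array([netstats.channel_entropy(prep.data[i][prep.valid[i]],
                                                 k=entropy_bins)
                        for i in range(prep.n_channels)])
        ent_lfp = float(ent[modality_labels == "LFP"].mean())
        ent_mu = float(ent[modality_labels == "MU"].mean()) if have_mu else np.nan

        rows = []
        for k in range(self.n_freqs):
            w = self.W[k][:, 0]
            row = {
                "animal": prep.animal_id, "session": prep.session_id,
                "frequency_hz": self.freqs[k],
                "lambda1": self.lambdas[k, 0],
                "lambda2": self.lambdas[k, 1] if self.lambdas.shape[1] > 1 else np.nan,
                "lambda3": self.lambdas[k, 2] if self.lambdas.shape[1] > 2 else np.nan,
                "region_bias": netstats.region_bias_score(w, region_labels),
                "modality_dominance": (netstats.modality_dominance(w, modality_labels)
                                       if have_mu else np.nan),
                "entropy_lfp_bits": ent_lfp, "entropy_mu_bits": ent_mu,
            }
            for r, frac in zip(regions,
                               netstats.region_energy_fractions(w, region_labels)):
                row[f"frac_{r}"] = frac
            ts, ts_valid = self.component_timeseries(k, n_components=2)
            kt = netstats.distribution_kurtosis(ts[0], ts_valid[0])
            row["kurt_real"] = kt["kurt_real"]
            row["kurt_envelope"] = kt["kurt_envelope"]
            row["wpli_top2"] = (netstats.wpli(ts[0], ts[1], self.model.fs,
                                              epoch_s=self.model.seg_s)
                                if ts.shape[0] > 1 else np.nan)
            if n_perm > 0:
                row["dimensionality"] = self.dimensionality(
                    k, n_perm=n_perm, seed=seed + k)["dimensionality"]
            rows.append(row)
        return pd.DataFrame(rows)

    # ----------------------------------------------------------------- #
    def summary(self, top_k: int = 3) -> str:
        """Human-readable overview of the fit."""
        lam = self.top_eigenvalues
        peak = int(np.argmax(lam))
        prep = self.model.prepared
        lines = [
            "Frequency-resolved GED source separation",
            "=" * 44,
            f"animal/session        {prep.animal_id}/{prep.session_id}",
            f"channels              {prep.n_channels} "
            f"({prep.lfp_indices.size} LFP, {prep.mu_indices.size} MU; "
            f"regions: {', '.join(prep.regions)})",
            f"duration analysed     {prep.n_samples / self.model.fs:.1f} s "
            f"(fs {self.model.fs:g} Hz, trim {self.model.prepared.trim_s:g} s/end)",
            f"frequencies           {self.n_freqs} "
            f"({self.freqs.min():.3g}-{self.freqs.max():.3g} Hz)",
            f"segments per pool     S~{int(np.median(self.n_segments_S))}, "
            f"R={self.n_segments_R} ({self.model.seg_s:g}-s, even/odd split)",
            f"excluded segments     {int(self.n_excluded_S.sum() + self.n_excluded_R)} "
            f"(3-SD Frobenius rule)",
            f"shrinkage gamma       {self.model.gamma:g}",
            f"top eigenvalue        {lam[peak]:.3f} at {self.freqs[peak]:.2f} Hz "
            "(null expectation 1)",
        ]
        head = self.eigenvalue_table(top_k).head(8)
        lines += ["", "eigenvalue table (first rows):",
                  head.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<FrequencyGEDResults: {self.n_freqs} frequencies x "
                f"{self.model.n_channels} channels>")

    # ----------------------------------------------------------------- #
    def plot_eigenspectrum(self, top_k: int = 3, ax=None):
        """Eigenvalues of the largest components across frequencies."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for j in range(min(top_k, self.lambdas.shape[1])):
            ax.plot(self.freqs, self.lambdas[:, j], label=f"component {j + 1}")
        ax.axhline(1.0, color="k", ls="--", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("eigenvalue (narrowband/broadband ratio)")
        ax.legend(frameon=False)
        return ax

    def plot_band_matrix(self, band_structure: BandStructure | None = None, ax=None):
        """Top-eigenvector r2 matrix with discovered band boundaries."""
        import matplotlib.pyplot as plt
        bs = band_structure or self.band_structure()
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(bs.r2_matrix, origin="lower", cmap="magma",
                       vmin=0, vmax=1, interpolation="nearest")
        for b in bs.bands:
            lo, hi = min(b.member_freq_indices), max(b.member_freq_indices)
            ax.add_patch(plt.Rectangle((lo - 0.5, lo - 0.5), hi - lo + 1, hi - lo + 1,
                                       fill=False, edgecolor="deeppink", lw=1.2))
        ax.set_xlabel("frequency index")
        ax.set_ylabel("frequency index")
        plt.colorbar(im, ax=ax, label="r$^2$")
        return ax


def compare_sessions(res_a: FrequencyGEDResults, res_b: FrequencyGEDResults,
                     use_denormalized: bool = False) -> pd.DataFrame:
    """Cross-session spatial-map reproducibility, per shared frequency.

    For each frequency present in both results, correlates the top-1 maps
    (``r2_top``) and takes the best of the four top-2 x top-2 correlations
    (``r2_max``).  Also reports the mean of the two sessions' top eigenvalues,
    enabling the separability-vs-reproducibility correlation.
    """
    if res_a.model.n_channels != res_b.model.n_channels:
        raise ValueError("sessions must share the channel set")
    common, ia, ib = np.intersect1d(res_a.freq_indices, res_b.freq_indices,
                                    return_indices=True)
    maps_a = res_a.maps_denorm if use_denormalized else res_a.maps
    maps_b = res_b.maps_denorm if use_denormalized else res_b.maps
    rows = []
    for fi, ka, kb in zip(common, ia, ib):
        rep = netstats.map_reproducibility(maps_a[ka][:, :2], maps_b[kb][:, :2])
        rows.append({"frequency_hz": res_a.model.grid.freqs[fi],
                     "r2_top": rep["r2_top"], "r2_max": rep["r2_max"],
                     "mean_lambda1": 0.5 * (res_a.lambdas[ka, 0]
                                            + res_b.lambdas[kb, 0])})
    return pd.DataFrame(rows)
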