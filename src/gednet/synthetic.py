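"""Synthetic multiregional recordings with known narrowband networks.

The generator plants narrowband oscillatory sources — each a fixed per-channel
mixing pattern driven by an amplitude-modulated band-limited oscillation —
into region-grouped LFP channels over a 1/f broadband background, and can add
multiunit channels whose spike probability is phase-coupled to a source.
Because the mixing patterns, centre frequencies and coupling parameters are
known, every pipeline stage has a ground-truth oracle.

A synthetic "animal" is a fixed :class:`GroundTruth` (mixing patterns) reused
across sessions with fresh noise seeds, so component maps are reproducible
within an animal and idiosyncratic across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.ndimage import gaussian_filter1d

from .preprocessing import smooth_spike_train
from .recording import Recording, make_channel_meta

__all__ = ["SourceSpec", "SpikeCoupling", "GroundTruth", "generate_ground_truth",
           "generate_recording", "generate_coupled_spikes", "one_over_f_noise"]


@dataclass(frozen=True)
class SourceSpec:
    """One planted narrowband network."""
    center_freq: float          # Hz
    spectral_fwhm: float        # Hz
    mixing: np.ndarray          # unit-norm weight per LFP channel
    amplitude: float = 1.0      # a.u.


@dataclass(frozen=True)
class SpikeCoupling:
    """A multiunit channel phase-coupled to one planted source."""
    source_index: int
    base_rate: float = 13.2         # spikes/s, the grand-average multiunit rate
    modulation_depth: float = 0.6   # in [0, 1]


@dataclass
class GroundTruth:
    """Planted sources, noise model and spike couplings for one synthetic animal."""
    sources: list
    regions: list
    channels_per_region: list
    noise_exponent: float = 1.0
    spike_coupling: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        n_ch = sum(self.channels_per_region)
        for s in self.sources:
            if s.mixing.shape != (n_ch,):
                raise ValueError("mixing length must equal total LFP channel count")
            if not np.isclose(np.linalg.norm(s.mixing), 1.0):
                raise ValueError("mixing vectors must have unit Euclidean norm")
        for c in self.spike_coupling:
            if not 0 <= c.modulation_depth <= 1:
                raise ValueError("modulation_depth must lie in [0, 1]")
            if not 0 <= c.source_index < len(self.sources):
                raise ValueError("spike coupling references a missing source")

    @property
    def n_lfp_channels(self) -> int:
        return sum(self.channels_per_region)

    @property
    def region_labels(self) -> np.ndarray:
        return np.repeat(self.regions, self.channels_per_region)

    @property
    def center_freqs(self) -> np.ndarray:
        return np.array([s.center_freq for s in self.sources])

    def referenced_mixing(self, source_index: int) -> np.ndarray:
        """Mixing pattern as it appears after regional average referencing.

        Referencing subtracts each region's channel mean, so the planted
        pattern visible to the pipeline is the mixing with per-region means
        removed.  This is the correct oracle for recovered component maps.
        """
        m = self.sources[source_index].mixing.copy()
        labels = self.region_labels
        for r in self.regions:
            idx = labels == r
            m[idx] -= m[idx].mean()
        return m

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "channels_per_region": [int(c) for c in self.channels_per_region],
            "noise_exponent": self.noise_exponent,
            "seed": int(self.seed),
            "sources": [{"center_freq": s.center_freq, "spectral_fwhm": s.spectral_fwhm,
                         "amplitude": s.amplitude, "mixing": s.mixing.tolist()}
                        for s in self.sources],
            "spike_coupling": [{"source_index": c.source_index, "base_rate": c.base_rate,
                                "modulation_depth": c.modulation_depth}
                               for c in self.spike_coupling],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            sources=[SourceSpec(s["center_freq"], s["spectral_fwhm"],
                                np.asarray(s["mixing"], dtype=float), s["amplitude"])
                     for s in d["sources"]],
            regions=list(d["regions"]),
            channels_per_region=list(d["channels_per_region"]),
            noise_exponent=d.get("noise_exponent", 1.0),
            spike_coupling=[SpikeCoupling(c["source_index"], c["base_rate"],
                                          c["modulation_depth"])
                            for c in d.get("spike_coupling", [])],
            seed=d.get("seed", 0),
        )


def generate_ground_truth(n_networks: int, freq_range=(3.0, 150.0),
                          regions=("PFC", "PAR", "HIP"),
                          channels_per_region=(10, 10, 10),
                          seed: int = 0,
                          region_concentration: str = "uniform",
                          spectral_fwhm_frac: float = 0.15,
                          n_mu_per_source: int = 1,
                          base_rate: float = 13.2,
                          modulation_depth: float = 0.6) -> GroundTruth:
    """Draw a ground truth with log-spaced source frequencies and random mixing.

    Parameters
    ----------
    n_networks : int
        Number of planted sources; their centre frequencies are strictly
        increasing and log-spaced over ``freq_range``.
    region_concentration : "uniform" or a region label
        "uniform" draws mixing weights across all regions; a region label
        confines every source's weights to that region's channels.
    spectral_fwhm_frac : float
        Spectral FWHM of each source as a fraction of its centre frequency
        (constant-Q oscillations).
    n_mu_per_source : int
        Number of phase-coupled multiunit channels attached to each source.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    regions = list(regions)
    if not regions:
        raise ValueError("empty region list")
    if len(regions) != len(channels_per_region):
        raise ValueError("regions and channels_per_region must align")
    if region_concentration != "uniform" and region_concentration not in regions:
        raise ValueError(f"unknown region {region_concentration!r}")
    rng = np.random.default_rng(seed)
    n_ch = int(sum(channels_per_region))
    if n_networks == 1:
        freqs = np.array([np.sqrt(freq_range[0] * freq_range[1])])
    else:
        freqs = np.geomspace(freq_range[0], freq_range[1], n_networks)
    labels = np.repeat(regions, channels_per_region)
    sources = []
    for f in freqs:
        w = rng.standard_normal(n_ch)
        if region_concentration != "uniform":
            w[labels != region_concentration] = 0.0
        w /= np.linalg.norm(w)
        sources.append(SourceSpec(center_freq=float(f),
                                  spectral_fwhm=float(spectral_fwhm_frac * f),
                                  mixing=w))
    coupling = [SpikeCoupling(k, base_rate, modulation_depth)
                for k in range(len(sources)) for _ in range(n_mu_per_source)]
    return GroundTruth(sources=sources, regions=regions,
                       channels_per_region=list(channels_per_region),
                       spike_coupling=coupling, seed=seed)


def one_over_f_noise(n_samples: int, fs: float, exponent: float = 1.0,
                     rng: np.random.Generator | int | None = None,
                     size: int = 1) -> np.ndarray:
    """Gaussian noise with power spectrum 1/f^exponent, unit variance per row.

    Synthesized in the frequency domain: white Gaussian Fourier coefficients
    scaled by f^(-exponent/2), DC removed.
    """
    rng = np.random.default_rng(rng)
    freqs = sfft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    coeff = (rng.standard_normal((size, freqs.size))
             + 1j * rng.standard_normal((size, freqs.size))) * scale
    x = sfft.irfft(coeff, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _narrowband_source(n_samples: int, fs: float, f_c: float, fwhm: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Complex band-limited oscillation with a smoothed-random-walk envelope.

    White noise is shaped by a frequency-domain Gaussian at (f_c, fwhm); a
    slowly varying strictly positive envelope (|smoothed Gaussian random
    walk|, ~1-s smoothing) multiplies it, giving non-Gaussian (leptokurtic)
    narrowband dynamics.  Unit variance of the real part.
    """
    freqs = sfft.fftfreq(n_samples, d=1.0 / fs)
    gain = np.exp(-4.0 * np.log(2.0) * (freqs - f_c) ** 2 / fwhm ** 2)
    gain[freqs <= 0] = 0.0
    coeff = (rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples)) * gain
    z = sfft.ifft(2.0 * coeff)
    walk = gaussian_filter1d(np.cumsum(rng.standard_normal(n_samples)), sigma=1.0 * fs,
                             mode="reflect")
    sd = walk.std()
    if sd == 0:
        sd = 1.0
    # waxing/waning amplitude with coefficient of variation ~0.5, never pinned
    # at zero for long stretches (leptokurtic narrowband statistics)
    env = np.abs(1.0 + 0.5 * (walk - walk.mean()) / sd)
    z = z * env
    return z / np.real(z).std()


def generate_coupled_spikes(source_phase: np.ndarray, base_rate: float,
                            modulation_depth: float, fs: float,
                            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Bernoulli spike train with rate base_rate * (1 + depth * cos(phase)).

    The long-run mean rate converges to ``base_rate``; with depth 1 no spikes
    occur at phase pi.  Returns a 0/1 array at the sampling rate.
    """
    if not 0 <= modulation_depth <= 1:
        raise ValueError("modulation_depth must lie in [0, 1]")
    if base_rate * (1 + modulation_depth) >= fs:
        raise ValueError("peak rate exceeds the sampling rate")
    rng = np.random.default_rng(rng)
    rate = base_rate * (1.0 + modulation_depth * np.cos(source_phase))
    p = np.clip(rate / fs, 0.0, 1.0)
    return (rng.random(p.size) < p).astype(float)


def generate_recording(truth: GroundTruth, duration: float = 300.0,
                       fs: float = 1000.0, snr: float = 1.0,
                       seed: int = 0, session_id: str = "session0",
                       animal_id: str | None = None) -> Recording:
    """Mix the planted sources into channels over 1/f noise; add MU channels.

    Each LFP channel is ``snr * sum_k mixing_k * amplitude_k * s_k(t)`` plus
    independent unit-variance 1/f noise, so ``snr`` sets the planted-source
    amplitude relative to the broadband background (snr=0 gives pure noise).
    Multiunit channels are Bernoulli spike trains phase-coupled to their
    source, smoothed with a 30-ms FWHM Gaussian, and assigned to the region
    where their source's mixing energy is largest.
    """
    if duration < 20:
        raise ValueError("duration must be at least 20 s (10-s trims at both ends)")
    if truth.sources and fs < 4 * truth.center_freqs.max():
        raise ValueError("fs must be at least 4x the highest planted frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_lfp = truth.n_lfp_channels
    region_labels = truth.region_labels

    data = one_over_f_noise(n, fs, truth.noise_exponent, rng, size=n_lfp)
    analytic = []
    for s in truth.sources:
        z = _narrowband_source(n, fs, s.center_freq, s.spectral_fwhm, rng)
        analytic.append(z)
        data += snr * s.amplitude * np.outer(s.mixing, np.real(z))

    rows = [data]
    names = [f"{r}_lfp{i}" for r, c in zip(truth.regions, truth.channels_per_region)
             for i in range(c)]
    modalities = ["LFP"] * n_lfp
    regions_out = list(region_labels)
    for j, c in enumerate(truth.spike_coupling):
        phase = np.angle(analytic[c.source_index]) if snr > 0 and analytic else \
            rng.uniform(-np.pi, np.pi, n)
        train = generate_coupled_spikes(phase, c.base_rate, c.modulation_depth, fs, rng)
        rows.append(smooth_spike_train(train, fs)[None, :])
        src = truth.sources[c.source_index]
        energies = [np.sum(src.mixing[region_labels == r] ** 2) for r in truth.regions]
        mu_region = truth.regions[int(np.argmax(energies))]
        names.append(f"{mu_region}_mu{j}")
        modalities.append("MU")
        regions_out.append(mu_region)

    meta = make_channel_meta(names, modalities, regions_out)
    return Recording(np.vstack(rows), fs, meta, session_id=session_id,
                     animal_id=animal_id or f"animal{truth.seed}")
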