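"""Narrowband filtering with Morlet wavelets defined as frequency-domain Gaussians.

The filter multiplies the signal spectrum by a Gaussian of unit peak gain
centred on the target frequency, zeroes the negative frequencies and doubles
the positive ones, returning the complex analytic narrowband signal in one
pass: its magnitude is the amplitude envelope and its angle the instantaneous
phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

__all__ = ["FrequencyGrid", "make_frequency_grid", "narrowband_filter"]

_LN2x4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmic grid of analysis frequencies with per-frequency FWHMs."""

    freqs: np.ndarray   # Hz, geometrically spaced
    fwhms: np.ndarray   # Hz, spectral full width at half maximum

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "fwhms", np.asarray(self.fwhms, dtype=float))
        if self.freqs.shape != self.fwhms.shape:
            raise ValueError("freqs and fwhms must have equal length")

    def __len__(self) -> int:
        return self.freqs.size

    def nearest_index(self, f: float) -> int:
        """Index of the grid frequency closest to ``f`` on a log axis."""
        return int(np.argmin(np.abs(np.log(self.freqs) - np.log(f))))


def make_frequency_grid(f_min: float = 2.0, f_max: float = 200.0, n: int = 100,
                        fwhm_min: float = 2.0, fwhm_max: float = 5.0) -> FrequencyGrid:
    """Geometrically spaced frequency grid, 2–200 Hz in 100 steps by default.

    The spectral FWHM interpolates log-linearly in frequency between
    ``fwhm_min`` at ``f_min`` and ``fwhm_max`` at ``f_max``.
    """
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need at least two grid frequencies")
    freqs = np.geomspace(f_min, f_max, n)
    t = (np.log(freqs) - np.log(f_min)) / (np.log(f_max) - np.log(f_min))
    fwhms = fwhm_min + (fwhm_max - fwhm_min) * t
    return FrequencyGrid(freqs, fwhms)


def narrowband_filter(x: np.ndarray, fs: float, f_c: float, fwhm: float) -> np.ndarray:
    """Filter ``x`` around ``f_c`` and return the complex analytic signal.

    Works on a 1-D series or a channels-by-samples matrix (filtering along the
    last axis).  The spectrum is multiplied by
    ``exp(-4 ln2 (f - f_c)^2 / fwhm^2)`` (peak gain 1 at ``f_c``); negative
    frequencies are zeroed and positive ones doubled, so ``abs`` of the output
    is the amplitude envelope and ``angle`` the instantaneous phase.
    """
    x = np.asarray(x, dtype=float)
    if f_c >= fs / 2:
        raise ValueError(f"centre frequency {f_c} Hz is at or above Nyquist ({fs/2} Hz)")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    n = x.shape[-1]
    freqs = sfft.fftfreq(n, d=1.0 / fs)
    gain = np.exp(-_LN2x4 * (freqs - f_c) ** 2 / fwhm ** 2)
    # analytic-signal construction: keep positive frequencies only, doubled
    analytic = np.zeros(n)
    analytic[freqs > 0] = 2.0
    X = sfft.fft(x, axis=-1)
    return sfft.ifft(X * (gain * analytic), axis=-1)
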