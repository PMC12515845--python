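"""Power spectra of IMFs and selection of the primary modes.

After VMD splits a window into K modes, the highest-frequency mode carries
mostly broadband/noise content whose frequency distribution is unlike the
rest; feature extraction keeps only the primary (lowest-frequency) modes.
The ranking statistic is the spectral centroid — the power-weighted mean
frequency of each mode's Welch spectrum — and the default configuration
decomposes into K = 5 and keeps the 4 lowest-centroid modes, giving
3 channels x 4 IMFs = 12 features per window downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .vmd import ModeDecomposition

#: Welch defaults sized for 250-sample (1-s) windows: two 50%-overlapping
#: Hamming segments of 125 samples, a variance/resolution compromise.
DEFAULT_SEGMENT = 125
DEFAULT_OVERLAP = 0.5
DEFAULT_WINDOW = "hamming"
MIN_LENGTH = 16


@dataclass(frozen=True)
class PowerSpectrum:
    """Welch power spectral density estimate.

    ``power`` is in input-units^2 per Hz on the ``freqs`` grid, so the
    integral over frequency approximates the signal variance.
    """

    freqs: np.ndarray
    power: np.ndarray
    segment: int
    overlap: float
    window: str

    def integrated_power(self) -> float:
        """Total power, via trapezoidal integration of the density."""
        return float(np.trapezoid(self.power, self.freqs))

    def centroid(self) -> float:
        """Power-weighted mean frequency (0 for an all-zero spectrum)."""
        total = self.power.sum()
        if total <= 0:
            return 0.0
        return float((self.freqs * self.power).sum() / total)


def power_spectrum(
    series: np.ndarray,
    fs: float,
    segment: int = DEFAULT_SEGMENT,
    overlap: float = DEFAULT_OVERLAP,
    window: str = DEFAULT_WINDOW,
) -> PowerSpectrum:
    """Welch-averaged periodogram of one series (deterministic)."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(series) < MIN_LENGTH:
        raise ValueError(f"series of length {len(series)} is too short "
                         f"(need >= {MIN_LENGTH})")
    nperseg = min(segment, len(series))
    noverlap = int(nperseg * overlap)
    freqs, power = sps.welch(series, fs=fs, window=window, nperseg=nperseg,
                             noverlap=noverlap, detrend="constant")
    return PowerSpectrum(freqs=freqs, power=power, segment=nperseg,
                         overlap=overlap, window=window)


def mode_centroids(
    dec: ModeDecomposition,
    fs: float,
    segment: int = DEFAULT_SEGMENT,
    overlap: float = DEFAULT_OVERLAP,
) -> np.ndarray:
    """Spectral centroid of each mode, in Hz."""
    return np.array([
        power_spectrum(m, fs, segment=segment, overlap=overlap).centroid()
        for m in dec.modes
    ])


def select_primary_modes(
    dec: ModeDecomposition,
    fs: float,
    n_keep: int = 4,
    rule: str = "centroid",
    min_energy_frac: float = 0.01,
    segment: int = DEFAULT_SEGMENT,
    overlap: float = DEFAULT_OVERLAP,
) -> ModeDecomposition:
    """Retain the primary IMFs of a decomposition.

    ``rule="centroid"`` (default) keeps the ``n_keep`` modes with the
    lowest spectral centroids, in ascending-centroid order.  The
    alternative ``rule="energy"`` drops modes carrying less than
    ``min_energy_frac`` of the total mode power (still capped at
    ``n_keep``).  Dropped modes are folded into the residual so the
    additive reconstruction stays exact.
    """
    if not 1 <= n_keep <= dec.K:
        raise ValueError(f"n_keep={n_keep} out of range [1, {dec.K}]")
    if rule not in ("centroid", "energy"):
        raise ValueError("rule must be 'centroid' or 'energy'")

    centroids = mode_centroids(dec, fs, segment=segment, overlap=overlap)
    order = np.argsort(centroids, kind="stable")
    if rule == "centroid":
        keep = order[:n_keep]
    else:
        energy = (dec.modes ** 2).sum(axis=1)
        total = energy.sum()
        frac_ok = energy >= min_energy_frac * total if total > 0 else np.ones(dec.K, bool)
        keep = np.array([i for i in order if frac_ok[i]][:n_keep], dtype=int)
        if keep.size == 0:  # degenerate: keep at least the lowest-centroid mode
            keep = order[:1]

    dropped = np.setdiff1d(np.arange(dec.K), keep)
    residual = dec.residual + dec.modes[dropped].sum(axis=0)
    return ModeDecomposition(
        modes=dec.modes[keep],
        center_freqs=dec.center_freqs[keep],
        residual=residual,
        fs=dec.fs,
        n_iter=dec.n_iter,
        converged=dec.converged,
    )
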