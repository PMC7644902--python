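"""Welch spectra, individual frequency landmarks, and band powers.

Band edges are individualized per subject from two spectral landmarks in
the Klimesch tradition: the transition frequency TF (the power minimum
between the delta and alpha peaks, searched in 3-8 Hz) and the individual
alpha frequency peak IAF (the power maximum in 6-14 Hz). Delta, theta and
alpha are anchored to TF/IAF; beta (14-30 Hz) and gamma (30-40 Hz) are
fixed. With 2-s epochs the spectral resolution is 0.5 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import CHANNELS_1020, Epoch, Recording

logger = logging.getLogger(__name__)

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class PowerSpectrum:
    """Per-channel one-sided power density on a 0.5 Hz grid (µV²/Hz)."""

    freqs: np.ndarray            # Hz, 0.5 spacing, 0.5..Nyquist
    power: np.ndarray            # channels x freqs
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        df = np.diff(self.freqs)
        if len(df) and not np.allclose(df, 0.5):
            raise ValueError("frequency grid spacing must be exactly 0.5 Hz")
        if np.any(self.power < -1e-12):
            raise ValueError("power density must be non-negative")

    def mean_power(self) -> np.ndarray:
        return self.power.mean(axis=0)


@dataclass(frozen=True)
class FrequencyLandmarks:
    """Per-subject transition frequency and alpha peak (Hz)."""

    tf: float
    iaf: float
    tf_fallback: bool = False
    iaf_fallback: bool = False

    def __post_init__(self) -> None:
        if not 3.0 <= self.tf <= 8.0:
            raise ValueError(f"TF {self.tf} outside [3, 8] Hz")
        if not 6.0 <= self.iaf <= 14.0:
            raise ValueError(f"IAF {self.iaf} outside [6, 14] Hz")
        if self.tf >= self.iaf:
            raise ValueError("TF must be below IAF")


@dataclass(frozen=True)
class BandScheme:
    """Half-open frequency ranges [low, high) per band, Hz."""

    bands: dict[str, tuple[float, float]]

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def items(self):
        return self.bands.items()


def welch_psd(recording: Recording, epochs: list[Epoch],
              channels: tuple[str, ...] = CHANNELS_1020) -> PowerSpectrum:
    """Average of Hann-windowed periodograms over the given 2-s epochs.

    Each epoch is one Welch segment (no sub-windowing, no overlap); density
    scaling compensates the window power, so integrating the PSD of white
    noise over the band recovers its variance.
    """
    if not epochs:
        raise ValueError("welch_psd requires at least one epoch")
    idx = [recording.index(ch) for ch in channels]
    data = recording.data[idx]
    acc = None
    for ep in epochs:
        seg = data[:, ep.sl()]
        f, p = sps.periodogram(seg, fs=recording.fs, window="hann",
                               detrend="constant", scaling="density")
        acc = p if acc is None else acc + p
    power = acc / len(epochs)
    keep = f >= 0.5 - 1e-9
    return PowerSpectrum(freqs=f[keep], power=power[:, keep],
                         labels=tuple(channels))


def find_transition_frequency(freqs: np.ndarray, mean_power: np.ndarray
                              ) -> tuple[float, bool]:
    """Minimum of the channel-averaged PSD on [3, 8] Hz.

    Ties resolve to the lowest frequency; a minimum sitting on the search
    boundary is returned with a fallback flag.
    """
    mask = (freqs >= 3.0 - 1e-9) & (freqs <= 8.0 + 1e-9)
    if not mask.any():
        raise ValueError("PSD does not cover the 3-8 Hz search interval")
    sub_f, sub_p = freqs[mask], mean_power[mask]
    i = int(np.argmin(sub_p))
    fallback = i == 0 or i == len(sub_f) - 1
    return float(sub_f[i]), fallback


def find_iaf(freqs: np.ndarray, mean_power: np.ndarray) -> tuple[float, bool]:
    """Highest local power peak of the channel-averaged PSD on [6, 14] Hz.

    Ties resolve to the lowest frequency. If the interval contains no
    interior local maximum (flat or monotone spectrum), the global maximum
    on the interval is returned with a fallback flag.
    """
    mask = (freqs >= 6.0 - 1e-9) & (freqs <= 14.0 + 1e-9)
    if not mask.any():
        raise ValueError("PSD does not cover the 6-14 Hz search interval")
    sub_f, sub_p = freqs[mask], mean_power[mask]
    peaks = [i for i in range(1, len(sub_p) - 1)
             if sub_p[i] > sub_p[i - 1] and sub_p[i] >= sub_p[i + 1]]
    if peaks:
        best = max(sub_p[i] for i in peaks)
        i = next(i for i in peaks if sub_p[i] == best)
        return float(sub_f[i]), False
    return float(sub_f[int(np.argmax(sub_p))]), True


def estimate_landmarks(psd: PowerSpectrum) -> FrequencyLandmarks:
    """TF and IAF from a subject's spectrum (all channels averaged)."""
    mp = psd.mean_power()
    tf, tf_fb = find_transition_frequency(psd.freqs, mp)
    iaf, iaf_fb = find_iaf(psd.freqs, mp)
    if tf >= iaf:  # degenerate spectrum: fall back to canonical landmarks
        logger.warning("TF %.1f >= IAF %.1f; falling back to TF=6, IAF=10",
                       tf, iaf)
        return FrequencyLandmarks(6.0, 10.0, True, True)
    return FrequencyLandmarks(tf, iaf, tf_fb, iaf_fb)


def define_bands(tf: float, iaf: float) -> BandScheme:
    """Individual band scheme from the two landmarks.

    delta = [TF-4, TF-2), theta = [TF-2, TF), alpha = [TF, min(IAF+2, 14)),
    beta = [14, 30), gamma = [30, 40). The alpha upper edge is clipped at
    14 Hz (with a warning) so that alpha never overlaps the fixed beta
    band.
    """
    FrequencyLandmarks(tf, iaf)  # validates ranges and TF < IAF
    alpha_hi = iaf + 2.0
    if alpha_hi > 14.0:
        logger.warning("alpha upper edge %.1f clipped to 14 Hz", alpha_hi)
        alpha_hi = 14.0
    return BandScheme(bands={
        "delta": (max(tf - 4.0, 0.0), tf - 2.0),
        "theta": (tf - 2.0, tf),
        "alpha": (tf, alpha_hi),
        "beta": (14.0, 30.0),
        "gamma": (30.0, 40.0),
    })


def band_power(psd: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Per-channel power in µV²: sum of density x 0.5 Hz over the bins
    whose center lies in [low, high)."""
    low, high = band
    mask = (psd.freqs >= low - 1e-9) & (psd.freqs < high - 1e-9)
    if not mask.any():
        raise ValueError(f"band [{low}, {high}) contains no spectral bins")
    return psd.power[:, mask].sum(axis=1) * 0.5
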