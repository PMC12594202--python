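"""Spectral and rate analysis of population spike trains.

Population rates are built by binning spike times into 1-ms intervals and
averaging across the population; power spectra use Welch's method
(1024-sample Hann windows, 50% overlap at the 1-kHz rate sampling) over 60-s
segments, and the integral beta power is the 13-30 Hz integral of the PSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PopulationRate",
    "PowerSpectrum",
    "population_rate",
    "welch_psd",
    "integral_beta",
    "beta_peak_ratio",
    "beta_time_course",
    "BETA_BAND",
]

BIN_MS = 1.0
FS_HZ = 1000.0
BETA_BAND = (13.0, 30.0)
WELCH_NPERSEG = 1024
SEGMENT_S = 60.0


@dataclass
class PopulationRate:
    """1-ms-binned population firing rate (spikes per neuron per second)."""

    rate: np.ndarray
    label: str = ""
    bin_ms: float = BIN_MS

    @property
    def fs(self) -> float:
        return 1000.0 / self.bin_ms

    @property
    def duration_s(self) -> float:
        return self.rate.size * self.bin_ms / 1000.0


@dataclass
class PowerSpectrum:
    """One-sided Welch PSD of a population rate (power density per Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    nperseg: int = WELCH_NPERSEG
    overlap: float = 0.5
    label: str = ""
    window: str = field(default="hann")


def population_rate(spike_times_ms, n_neurons: int, duration_ms: float,
                    label: str = "") -> PopulationRate:
    """Bin spike times (ms) into the 1-ms population rate series (Hz).

    ``spike_times_ms`` is a flat array of spike times pooled over the
    population.  Counts per bin are divided by the population size and the
    bin width, giving spikes per neuron per second.
    """
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size and (t.min() < 0 or t.max() >= duration_ms):
        raise ValueError("spike times outside [0, duration)")
    n_bins = int(round(duration_ms / BIN_MS))
    counts = np.bincount((t / BIN_MS).astype(np.int64), minlength=n_bins)[:n_bins]
    rate = counts / (n_neurons * BIN_MS * 1e-3)
    return PopulationRate(rate=rate, label=label)


def welch_psd(rate: PopulationRate, nperseg: int = WELCH_NPERSEG,
              window: str = "hann", detrend: str = "constant") -> PowerSpectrum:
    """Welch power spectral density of a population-rate series.

    1024-sample windows with 50% overlap at 1-kHz sampling give a ~0.977-Hz
    frequency resolution.  Series shorter than one window are rejected.
    """
    x = rate.rate
    if x.size < nperseg:
        raise ValueError(f"series too short for Welch ({x.size} < {nperseg} samples)")
    f, p = signal.welch(x, fs=rate.fs, window=window, nperseg=nperseg,
                        noverlap=nperseg // 2, detrend=detrend,
                        scaling="density")
    return PowerSpectrum(freqs=f, psd=p, nperseg=nperseg, label=rate.label,
                         window=window)


def integral_beta(ps: PowerSpectrum, band: tuple[float, float] = BETA_BAND) -> float:
    """Trapezoidal integral of the PSD over the beta band (13-30 Hz)."""
    lo, hi = band
    if ps.freqs[0] > lo or ps.freqs[-1] < hi:
        raise ValueError("spectrum does not cover the requested band")
    mask = (ps.freqs >= lo) & (ps.freqs <= hi)
    return float(np.trapezoid(ps.psd[mask], ps.freqs[mask]))


def beta_peak_ratio(ps: PowerSpectrum, band: tuple[float, float] = BETA_BAND,
                    full_range: tuple[float, float] = (0.0, 100.0)) -> float:
    """Peak beta PSD divided by the mean PSD over 0-100 Hz."""
    if ps.freqs[-1] < full_range[1]:
        raise ValueError("spectrum does not cover 0-100 Hz")
    beta = (ps.freqs >= band[0]) & (ps.freqs <= band[1])
    full = (ps.freqs >= full_range[0]) & (ps.freqs <= full_range[1])
    mean_power = float(np.mean(ps.psd[full]))
    if mean_power <= 0:
        raise ValueError("zero mean power over the reference range")
    return float(np.max(ps.psd[beta])) / mean_power


def beta_time_course(rate: PopulationRate, window_s: float = SEGMENT_S,
                     step_s: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integral beta power over sliding windows (centre times, power)."""
    step_s = window_s if step_s is None else step_s
    w = int(round(window_s * rate.fs))
    s = int(round(step_s * rate.fs))
    centres, power = [], []
    for start in range(0, rate.rate.size - w + 1, s):
        seg = PopulationRate(rate.rate[start:start + w], label=rate.label)
        power.append(integral_beta(welch_psd(seg)))
        centres.append((start + w / 2) / rate.fs)
    return np.asarray(centres), np.asarray(power)
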