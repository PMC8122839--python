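"""Auditory steady-state response (ASSR) analysis chain.

The recording is band-pass filtered (zero-phase FIR), segmented into a
fixed number of contiguous sweeps, averaged pointwise in the time domain,
and transformed with an FFT (rectangular window) into a one-sided power
spectrum. Detection is quantified as the SNR in dB at the modulation
frequency: power in the target bin over the mean power of its spectral
neighborhood (guard bins around the target excluded).

Because the steady-state response is periodic and the epoch length holds
an integer number of modulation cycles, sweeps need no stimulus trigger:
contiguous segmentation leaves the response coherent across sweeps while
background EEG averages down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import design_fir, filt_zero_phase
from .synth import EEGRecording


@dataclass(frozen=True)
class SweepConfig:
    """Sweep segmentation: ``n_sweeps`` blocks of ``epochs_per_sweep``
    contiguous epochs of ``points_per_epoch`` samples each."""

    n_sweeps: int = 6
    epochs_per_sweep: int = 16
    points_per_epoch: int = 1000

    def __post_init__(self) -> None:
        if min(self.n_sweeps, self.epochs_per_sweep, self.points_per_epoch) < 1:
            raise ValueError("all sweep-configuration counts must be >= 1")

    @property
    def sweep_length(self) -> int:
        return self.epochs_per_sweep * self.points_per_epoch

    @property
    def total_samples(self) -> int:
        return self.n_sweeps * self.sweep_length


@dataclass
class SweepSet:
    """Sweeps x channels x samples array with its sampling rate."""

    data: np.ndarray
    fs: float

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]


@dataclass
class PowerSpectrum:
    """One-sided power spectrum per channel (uV^2), uniform bins to Nyquist."""

    freqs: np.ndarray
    power: np.ndarray  # channels x bins
    resolution: float


@dataclass
class SNRResult:
    f_target: float
    snr_db: float
    signal_power: float
    noise_power: float
    neighbor_bins_used: int


def bandpass_fir(rec: EEGRecording, low_hz: float = 0.1, high_hz: float = 500.0,
                 order: int = 500) -> EEGRecording:
    """Zero-phase FIR band-pass.

    A high edge at or above Nyquist reduces the design to a pure high-pass
    (a low-pass at Nyquist is a no-op given anti-aliased acquisition); a
    low edge of 0 reduces it to a low-pass.
    """
    nyq = rec.fs / 2
    if not 0 <= low_hz < high_hz or high_hz > nyq:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz invalid for fs={rec.fs} Hz")
    kernel = design_fir(order, rec.fs,
                        low_hz if low_hz > 0 else None,
                        high_hz if high_hz < nyq else None)
    data = rec.data
    if low_hz > 0:
        # a practical-order FIR cannot realize a 0.1 Hz stopband; the DC
        # term is removed exactly by demeaning, the kernel shapes the rest
        data = data - data.mean(axis=-1, keepdims=True)
    return rec.copy_with(filt_zero_phase(data, kernel))


def extract_sweeps(rec: EEGRecording, cfg: SweepConfig,
                   settle: int = 0) -> SweepSet:
    """Cut the stream into contiguous non-overlapping sweeps.

    ``settle`` samples are discarded at each end first (filter transient
    guard). Raises if the recording is too short rather than silently
    truncating.
    """
    available = rec.n_samples - 2 * settle
    required = cfg.total_samples
    if available < required:
        raise ValueError(
            f"recording too short: need {required} samples after discarding "
            f"{settle} settle samples per end, have {max(available, 0)}")
    seg = rec.data[:, settle:settle + required]
    sweeps = seg.reshape(rec.n_channels, cfg.n_sweeps, cfg.sweep_length)
    return SweepSet(np.transpose(sweeps, (1, 0, 2)), rec.fs)


def average_and_spectrum(sweeps: SweepSet) -> PowerSpectrum:
    """Average sweeps in the time domain, then FFT the mean sweep.

    Power is one-sided and scaled so a sinusoid of peak amplitude A that
    falls on a bin contributes A^2/2 (its mean-square value) to that bin.
    """
    if sweeps.data.size == 0 or sweeps.n_sweeps < 1:
        raise ValueError("sweep set is empty")
    mean = sweeps.data.mean(axis=0)  # channels x samples
    n = mean.shape[-1]
    spec = np.fft.rfft(mean, axis=-1)
    power = (np.abs(spec) ** 2) / n ** 2
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / sweeps.fs)
    return PowerSpectrum(freqs, power, resolution=sweeps.fs / n)


def compute_snr(spectrum: PowerSpectrum, f_target: float,
                neighbor_halfwidth_bins: int = 60, guard_bins: int = 2,
                channel: int = 0) -> SNRResult:
    """SNR (dB) at ``f_target``: target-bin power over mean neighbor power.

    The noise floor is the mean power over the ``+/- neighbor_halfwidth_bins``
    around the target bin, excluding the target and ``+/- guard_bins``.
    A zero noise floor yields +inf dB rather than an exception.
    """
    if not spectrum.freqs[0] <= f_target <= spectrum.freqs[-1]:
        raise ValueError(f"target {f_target} Hz outside spectrum range")
    if not neighbor_halfwidth_bins > guard_bins >= 0:
        raise ValueError("need neighbor_halfwidth_bins > guard_bins >= 0")
    k = int(np.argmin(np.abs(spectrum.freqs - f_target)))
    lo, hi = k - neighbor_halfwidth_bins, k + neighbor_halfwidth_bins
    if lo < 0 or hi >= len(spectrum.freqs):
        raise ValueError("neighbor window exceeds spectrum bounds")
    p = spectrum.power[channel]
    idx = np.arange(lo, hi + 1)
    keep = np.abs(idx - k) > guard_bins
    noise = float(p[idx[keep]].mean())
    signal = float(p[k])
    if noise > 0:
        snr_db = 10 * np.log10(signal / noise)
    else:
        snr_db = np.inf if signal > 0 else 0.0
    return SNRResult(float(spectrum.freqs[k]), snr_db, signal, noise,
                     int(keep.sum()))


def run_assr(rec: EEGRecording, fm: float = 41.0, cfg: SweepConfig | None = None,
             low_hz: float = 0.1, high_hz: float = 500.0, order: int = 500,
             neighbor_halfwidth_bins: int = 60, guard_bins: int = 2,
             ) -> tuple[PowerSpectrum, list[SNRResult]]:
    """Full chain: filter, settle-trim, sweep, average, FFT, per-channel SNR.

    Settle trim is max(order, fs) samples per end, removing the zero-phase
    filter's edge transients deterministically.
    """
    cfg = cfg or SweepConfig()
    filtered = bandpass_fir(rec, low_hz, high_hz, order)
    settle = int(max(order, rec.fs))
    sweeps = extract_sweeps(filtered, cfg, settle=settle)
    spectrum = average_and_spectrum(sweeps)
    results = [compute_snr(spectrum, fm, neighbor_halfwidth_bins, guard_bins, ch)
               for ch in range(rec.n_channels)]
    return spectrum, results
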