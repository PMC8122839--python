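"""Synthetic ear-EEG generator.

Produces multichannel recordings with the statistical structure the
downstream analyses assume, so each pipeline stage can be validated with
known ground truth:

* background EEG: 1/f ("pink") broadband activity synthesized by spectral
  shaping of white noise, plus a narrowband alpha rhythm and a power-line
  sinusoid; channels share a configurable common-source fraction,
* a steady-state component phase-locked at the modulation frequency of an
  AM stimulus (with optional harmonics),
* stimulus-locked event-related deflections (Gaussian in time), e.g. a
  P300-like positivity after target tones only,
* eye-blink and muscle-burst artifacts at configurable Poisson rates, with
  a log of every inserted artifact for sensitivity/specificity scoring.

All component-adding operations are additive, so they commute and scale
linearly — the properties the recovery tests rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stimuli import EventSchedule, OddballSpec, generate_oddball_schedule

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Channels x samples EEG matrix in microvolts with its sampling rate."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default=None)  # type: ignore[assignment]
    schedule: EventSchedule | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data, self.fs, list(self.channel_labels), self.schedule)


@dataclass(frozen=True)
class NoiseSpec:
    """Background EEG model: 1/f^a broadband + alpha rhythm + line hum.

    RMS values are per channel in microvolts. ``common_fraction`` is the
    variance fraction of the broadband component shared across channels
    (volume-conduction stand-in).
    """

    one_over_f_exponent: float = 1.0
    broadband_rms: float = 20.0
    alpha_freq: float = 10.0
    alpha_rms: float = 3.0
    line_freq: float = 60.0
    line_rms: float = 1.0
    common_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ValueError("1/f exponent must be >= 0")
        for name in ("broadband_rms", "alpha_rms", "line_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.common_fraction <= 1:
            raise ValueError("common_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ERPTemplate:
    """A Gaussian-in-time evoked deflection tied to one event label.

    ``latency_ms`` is the peak time after stimulus onset, ``width_ms`` the
    Gaussian standard deviation, ``amplitude_uv`` the signed peak.
    """

    label: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    def waveform(self, fs: float, support_sigmas: float = 5.0) -> tuple[np.ndarray, int]:
        """Sampled template and the offset (samples) of its first sample
        relative to the event onset."""
        sigma = self.width_ms / 1000 * fs
        center = self.latency_ms / 1000 * fs
        lo = int(np.floor(center - support_sigmas * sigma))
        hi = int(np.ceil(center + support_sigmas * sigma))
        n = np.arange(lo, hi + 1)
        return self.amplitude_uv * np.exp(-0.5 * ((n - center) / sigma) ** 2), lo


@dataclass(frozen=True)
class ArtifactSpec:
    """Eye-blink and muscle-burst contamination model.

    Blinks are large low-frequency Gaussian transients projected onto all
    channels through a fixed mixing vector; muscle bursts are band-limited
    noise segments. Occurrence times are Poisson with the given per-minute
    rates.
    """

    blink_rate_per_min: float = 2.0
    blink_amplitude_uv: float = 200.0
    blink_width_ms: float = 80.0
    blink_mixing: tuple[float, ...] = (1.0, -0.5, 0.2)
    muscle_burst_rate_per_min: float = 1.0
    muscle_band: tuple[float, float] = (20.0, 100.0)
    muscle_rms_uv: float = 30.0
    muscle_burst_ms: float = 300.0

    def __post_init__(self) -> None:
        for name in ("blink_rate_per_min", "blink_amplitude_uv",
                     "muscle_burst_rate_per_min", "muscle_rms_uv"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def _pink_noise(n: int, exponent: float, fs: float, rng: np.random.Generator,
                f_floor: float = 0.5, ref_band: tuple[float, float] = (0.5, 500.0),
                ) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of seeded white noise.

    Below ``f_floor`` the amplitude is held flat to keep the variance
    finite for exponents >= 1. Normalized to unit RMS *within the fixed
    reference band* (clipped to Nyquist), so the spectral density near any
    analysis frequency is independent of the simulation sampling rate —
    resampling the same continuous process, not redistributing its power.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    above = f >= f_floor
    shape[above] = (f_floor / f[above]) ** (exponent / 2.0)
    spec *= shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    band = (f >= ref_band[0]) & (f <= min(ref_band[1], fs / 2))
    band_spec = np.where(band, spec, 0.0)
    x_band = np.fft.irfft(band_spec, n=n)
    rms = np.sqrt(np.mean(x_band ** 2))
    return x / rms if rms > 0 else x


def _narrowband(n: int, center: float, bw: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to center +/- bw/2."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = np.abs(f - center) <= bw / 2
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def simulate_background(noise: NoiseSpec, duration_s: float, fs: float,
                        n_channels: int, seed: int) -> EEGRecording:
    """Generate multichannel background EEG.

    Each channel mixes a common broadband source (variance fraction
    ``noise.common_fraction``) with an independent one; alpha and line
    components get independent/random phases per channel.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    common = _pink_noise(n, noise.one_over_f_exponent, fs, rng)
    c = noise.common_fraction
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        indep = _pink_noise(n, noise.one_over_f_exponent, fs, rng)
        broad = np.sqrt(c) * common + np.sqrt(1 - c) * indep
        x = noise.broadband_rms * broad
        if noise.alpha_rms > 0:
            x = x + noise.alpha_rms * _narrowband(n, noise.alpha_freq, 2.0, fs, rng)
        if noise.line_rms > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + noise.line_rms * np.sqrt(2) * np.sin(
                2 * np.pi * noise.line_freq * t + phase)
        data[ch] = x
    return EEGRecording(data, fs)


def add_assr_component(rec: EEGRecording, fm: float, amplitude_uv: float,
                       harmonic_amplitudes: Sequence[float] = (),
                       phase: float = 0.0) -> EEGRecording:
    """Add a steady-state sinusoid at ``fm`` (plus harmonics) to every channel.

    ``harmonic_amplitudes[k]`` is the peak amplitude of the (k+2)-th
    harmonic, i.e. the component at (k+2)*fm.
    """
    if fm >= rec.fs / 2:
        raise ValueError(f"fm={fm} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    freqs = [fm] + [(k + 2) * fm for k in range(len(harmonic_amplitudes))]
    amps = [amplitude_uv] + list(harmonic_amplitudes)
    if freqs and max(freqs) >= rec.fs / 2:
        raise ValueError("harmonic frequency at or above Nyquist")
    t = rec.t
    comp = np.zeros(rec.n_samples)
    for f, a in zip(freqs, amps):
        comp += a * np.sin(2 * np.pi * f * t + phase)
    return rec.copy_with(rec.data + comp[None, :])


def add_erp_components(rec: EEGRecording, schedule: EventSchedule,
                       templates: Sequence[ERPTemplate],
                       jitter_ms: float = 0.0, seed: int = 0) -> EEGRecording:
    """Add stimulus-locked Gaussian deflections after matching events.

    Every event whose label matches a template's label receives that
    template, its latency perturbed by a seeded uniform jitter of
    +/- ``jitter_ms``. Events whose template support would extend past the
    recording end are skipped with a logged warning.
    """
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n = rec.n_samples
    by_label: dict[str, list[ERPTemplate]] = {}
    for tpl in templates:
        by_label.setdefault(tpl.label, []).append(tpl)
    for onset, label in zip(schedule.onsets, schedule.labels):
        onset_idx = int(np.floor(onset * rec.fs + 0.5))
        for tpl in by_label.get(label, []):
            dj = rng.uniform(-jitter_ms, jitter_ms) if jitter_ms > 0 else 0.0
            wave, lo = replace(tpl, latency_ms=tpl.latency_ms + dj).waveform(rec.fs)
            start = onset_idx + lo
            stop = start + len(wave)
            if stop > n or start < 0:
                logger.warning(
                    "event at %.3f s: template %r extends beyond recording; skipped",
                    onset, tpl.label)
                continue
            data[:, start:stop] += wave[None, :]
    return rec.copy_with(data)


def add_artifacts(rec: EEGRecording, spec: ArtifactSpec,
                  seed: int) -> tuple[EEGRecording, list[dict]]:
    """Insert blink and muscle artifacts; return the recording and a log.

    The log lists one dict per inserted artifact:
    ``{"kind": "blink"|"muscle", "time_s": center, "duration_s": ...}``.
    """
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n, fs = rec.n_samples, rec.fs
    log: list[dict] = []

    mix = np.asarray(spec.blink_mixing[:rec.n_channels], dtype=float)
    if len(mix) < rec.n_channels:
        mix = np.resize(mix, rec.n_channels)

    n_blinks = rng.poisson(spec.blink_rate_per_min * rec.duration / 60.0)
    sigma = spec.blink_width_ms / 1000 * fs
    half = int(np.ceil(4 * sigma))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    for center in np.sort(rng.uniform(0, rec.duration, n_blinks)):
        ci = int(round(center * fs))
        lo, hi = ci - half, ci + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if hi <= lo:
            continue
        data[:, lo:hi] += spec.blink_amplitude_uv * np.outer(mix, kernel[klo:khi])
        log.append({"kind": "blink", "time_s": float(center),
                    "duration_s": 2 * half / fs})

    n_bursts = rng.poisson(spec.muscle_burst_rate_per_min * rec.duration / 60.0)
    burst_len = int(round(spec.muscle_burst_ms / 1000 * fs))
    lo_f, hi_f = spec.muscle_band
    hi_f = min(hi_f, fs / 2 * 0.99)
    for center in np.sort(rng.uniform(0, rec.duration, n_bursts)):
        ci = int(round(center * fs))
        lo, hi = ci - burst_len // 2, ci - burst_len // 2 + burst_len
        lo, hi = max(lo, 0), min(hi, n)
        if hi - lo < 8:
            continue
        for ch in range(rec.n_channels):
            burst = _narrowband(hi - lo, (lo_f + hi_f) / 2, hi_f - lo_f, fs, rng)
            win = np.hanning(hi - lo)
            data[ch, lo:hi] += spec.muscle_rms_uv * burst * win
        log.append({"kind": "muscle", "time_s": float(center),
                    "duration_s": burst_len / fs})

    return rec.copy_with(data), log


# --- default study-matched scenario ------------------------------------

DEFAULT_TEMPLATES = (
    ERPTemplate(label="target", latency_ms=400.0, width_ms=60.0, amplitude_uv=24.0),
    ERPTemplate(label="target", latency_ms=100.0, width_ms=25.0, amplitude_uv=-8.0),
    ERPTemplate(label="standard", latency_ms=100.0, width_ms=25.0, amplitude_uv=-8.0),
)


def simulate_oddball_recording(
    seed: int,
    n_channels: int = 3,
    fs: float = 1000.0,
    oddball: OddballSpec | None = None,
    noise: NoiseSpec | None = None,
    templates: Sequence[ERPTemplate] = DEFAULT_TEMPLATES,
    jitter_ms: float = 20.0,
    artifacts: ArtifactSpec | None = None,
    pad_s: float = 2.0,
) -> tuple[EEGRecording, list[dict]]:
    """One participant's oddball session: background + ERPs (+ artifacts).

    Defaults mirror the validated study setup: 3 exploring channels at
    1000 Hz, a 40-sequence oddball schedule, a P300-like positivity
    (400 ms, 24 uV) on targets and an N1-like negativity on every tone.
    Pass ``artifacts=None`` for a clean recording; an :class:`ArtifactSpec`
    adds contamination and a ground-truth log.
    """
    from .stimuli import schedule_span

    oddball = oddball or OddballSpec()
    noise = noise or NoiseSpec()
    ss = np.random.SeedSequence(seed)
    s_sched, s_bg, s_erp, s_art = [int(s.generate_state(1)[0] % (2 ** 31))
                                   for s in ss.spawn(4)]
    schedule = generate_oddball_schedule(oddball, s_sched)
    duration = schedule_span(oddball) + 2 * pad_s
    schedule = EventSchedule(schedule.onsets + pad_s, schedule.labels,
                             schedule.sequence_indices)
    rec = simulate_background(noise, duration, fs, n_channels, s_bg)
    rec = add_erp_components(rec, schedule, templates, jitter_ms, s_erp)
    rec.schedule = schedule
    log: list[dict] = []
    if artifacts is not None:
        rec, log = add_artifacts(rec, artifacts, s_art)
        rec.schedule = schedule
    return rec, log


def simulate_assr_recording(
    seed: int,
    fm: float = 41.0,
    amplitude_uv: float = 1.0,
    harmonic_amplitudes: Sequence[float] = (),
    duration_s: float = 100.0,
    fs: float = 1000.0,
    n_channels: int = 1,
    noise: NoiseSpec | None = None,
) -> EEGRecording:
    """Background EEG plus a steady-state component at ``fm``.

    Long enough by default for six 16-epoch sweeps after filter settle.
    """
    noise = noise or NoiseSpec()
    rec = simulate_background(noise, duration_s, fs, n_channels, seed)
    return add_assr_component(rec, fm, amplitude_uv, harmonic_amplitudes)
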