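"""Auditory stimulus synthesis for ear-EEG paradigms.

Two stimulus families are generated here:

* an amplitude-modulated (AM) tone for auditory steady-state response
  (ASSR) testing — a carrier sinusoid at ``fc`` whose envelope oscillates
  at the modulation frequency ``fm``, 100 % modulation depth:

      y(t) = sin(2*pi*fc*t) * (sin(2*pi*fm*t) + 1) / 2

* short gated sinusoidal tones (raised-cosine rise/fall around a flat
  plateau) arranged into an auditory oddball sequence: trains of frequent
  "standard" tones with one rare "target" tone per sequence, whose onset
  times and labels form an :class:`EventSchedule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class Waveform:
    """A single-channel stimulus signal normalized to [-1, 1]."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds, t[n] = n / fs."""
        return np.arange(len(self.samples)) / self.fs

    def to_txt(self, path: str | Path) -> None:
        np.savetxt(path, self.samples, header=f"fs={self.fs}")

    def to_wav(self, path: str | Path) -> None:
        from scipy.io import wavfile

        wavfile.write(path, int(round(self.fs)), self.samples.astype(np.float32))


@dataclass(frozen=True)
class AMToneSpec:
    """Parameters of the AM (ASSR) stimulus.

    fc : carrier frequency, Hz (the audiometric test frequency)
    fm : modulation frequency, Hz (the envelope frequency the brain
         phase-locks to); fm = 0 degenerates to a pure tone at half scale
    """

    fc: float = 1000.0
    fm: float = 41.0
    duration: float = 1.0
    fs: float = 16000.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.fc > self.fm >= 0):
            raise ValueError(f"need fc > fm >= 0, got fc={self.fc}, fm={self.fm}")
        if self.fs <= 2 * self.fc:
            raise ValueError(
                f"sampling rate {self.fs} Hz violates Nyquist for carrier {self.fc} Hz"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must lie in [0, 1]")


@dataclass(frozen=True)
class GatingSpec:
    """Parameters of a gated oddball tone.

    The tone lasts ``2*rise_ms + plateau_ms`` milliseconds: a raised-cosine
    (Hann) onset ramp, a flat plateau, and a mirror-image offset ramp.
    """

    tone_freq: float = 1000.0
    rise_ms: float = 9.9
    plateau_ms: float = 50.0
    fs: float = 16000.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_ms < 0 or self.plateau_ms < 0:
            raise ValueError("rise_ms and plateau_ms must be non-negative")

    @property
    def duration_ms(self) -> float:
        return 2 * self.rise_ms + self.plateau_ms


@dataclass(frozen=True)
class OddballSpec:
    """Structure of the auditory oddball paradigm.

    Each of ``n_sequences`` sequences holds ``tones_per_sequence`` tones:
    all standards except a single target placed at a random position drawn
    from ``target_position_choices`` (1-based). Tones within a sequence are
    separated by ``isi_s`` seconds (offset-to-onset); sequences by
    ``inter_sequence_s`` seconds.
    """

    n_sequences: int = 40
    tones_per_sequence: int = 10
    standard_freq: float = 1000.0
    target_freq: float = 2000.0
    target_position_choices: tuple[int, ...] = (7, 8, 9, 10)
    isi_s: float = 2.0
    inter_sequence_s: float = 4.0
    tone_duration_s: float = 0.0698

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.tones_per_sequence < 1:
            raise ValueError("need at least one sequence and one tone per sequence")
        if not self.target_position_choices:
            raise ValueError("target_position_choices must be non-empty")
        bad = [p for p in self.target_position_choices
               if not 1 <= p <= self.tones_per_sequence]
        if bad:
            raise ValueError(
                f"target positions {bad} outside 1..{self.tones_per_sequence}"
            )


@dataclass
class EventSchedule:
    """Stimulus events: onset (s from recording start), label, 1-based sequence."""

    onsets: np.ndarray
    labels: list[str]
    sequence_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.sequence_indices is None:
            self.sequence_indices = np.ones(len(self.onsets), dtype=int)
        self.sequence_indices = np.asarray(self.sequence_indices, dtype=int)
        if not (len(self.onsets) == len(self.labels) == len(self.sequence_indices)):
            raise ValueError("onsets, labels, sequence_indices must align")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("onset_s\tlabel\tsequence\n")
            for t, lab, seq in zip(self.onsets, self.labels, self.sequence_indices):
                fh.write(f"{t:.6f}\t{lab}\t{seq}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventSchedule":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        for col in ("onset_s", "label", "sequence"):
            if col not in df.columns:
                raise ValueError(f"schedule file missing column {col!r}")
        return cls(df["onset_s"].to_numpy(),
                   df["label"].astype(str).tolist(),
                   df["sequence"].to_numpy())


def generate_am_tone(spec: AMToneSpec) -> Waveform:
    """Synthesize the 100 %-amplitude-modulated ASSR stimulus.

    The spectrum of the product form is three lines: the carrier at fc at
    half amplitude and two sidebands at fc +/- fm at quarter amplitude.
    """
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    y = np.sin(2 * np.pi * spec.fc * t) * (np.sin(2 * np.pi * spec.fm * t) + 1) / 2
    return Waveform(spec.amplitude * y, spec.fs)


def generate_gated_tone(spec: GatingSpec) -> Waveform:
    """Synthesize a gated sinusoid with Hann rise/fall ramps."""
    n_rise = int(round(spec.rise_ms / 1000 * spec.fs))
    n_plateau = int(round(spec.plateau_ms / 1000 * spec.fs))
    n = 2 * n_rise + n_plateau
    t = np.arange(n) / spec.fs
    env = np.ones(n)
    if n_rise > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise))
        env[:n_rise] = ramp
        env[n - n_rise:] = ramp[::-1]
    y = spec.amplitude * env * np.sin(2 * np.pi * spec.tone_freq * t)
    return Waveform(y, spec.fs)


def generate_oddball_schedule(spec: OddballSpec, seed: int) -> EventSchedule:
    """Draw a seeded oddball event schedule.

    One target per sequence at a position drawn uniformly from
    ``spec.target_position_choices``; every other tone is a standard.
    Intervals are offset-to-onset: consecutive onsets within a sequence are
    ``tone_duration_s + isi_s`` apart, and a new sequence starts
    ``inter_sequence_s`` after the previous tone's offset.
    """
    rng = np.random.default_rng(seed)
    onsets, labels, seqs = [], [], []
    t = 0.0
    step = spec.tone_duration_s + spec.isi_s
    for s in range(1, spec.n_sequences + 1):
        target_pos = int(rng.choice(spec.target_position_choices))
        for k in range(1, spec.tones_per_sequence + 1):
            onsets.append(t)
            labels.append("target" if k == target_pos else "standard")
            seqs.append(s)
            t += step
        # replace the last ISI with the inter-sequence gap
        t += spec.inter_sequence_s - spec.isi_s
    return EventSchedule(np.array(onsets), labels, np.array(seqs))


def schedule_span(spec: OddballSpec) -> float:
    """Closed-form time from first onset to last tone offset, seconds."""
    per_seq = (spec.tones_per_sequence * spec.tone_duration_s
               + (spec.tones_per_sequence - 1) * spec.isi_s)
    return (spec.n_sequences * per_seq
            + (spec.n_sequences - 1) * spec.inter_sequence_s)
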