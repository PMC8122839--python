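#!/usr/bin/env python
"""Synthesize the auditory stimuli and characterize them.

Generates the 41 Hz amplitude-modulated ASSR tone and the gated oddball
tones, verifies their spectral/temporal structure (three spectral lines
at fc and fc +/- fm; 69.8 ms gated duration), and writes an oddball event
schedule. Outputs land in results/stimuli/.
"""

import json
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from earpipe.stimuli import (AMToneSpec, GatingSpec, OddballSpec,
                             generate_am_tone, generate_gated_tone,
                             generate_oddball_schedule)

OUT = Path(__file__).resolve().parents[1] / "results" / "stimuli"
OUT.mkdir(parents=True, exist_ok=True)

am = generate_am_tone(AMToneSpec(fc=1000, fm=41, duration=1.0))
env = np.abs(hilbert(am.samples))
p = np.abs(np.fft.rfft(env - env.mean())) ** 2
f = np.fft.rfftfreq(len(env), 1 / am.fs)
env_peak = float(f[1:][np.argmax(p[1:])])

amp = np.abs(np.fft.rfft(am.samples)) / len(am.samples)
lines = [float(x) for x in f[amp > 1e-3]]

gated = generate_gated_tone(GatingSpec(tone_freq=1000, rise_ms=9.9,
                                       plateau_ms=50.0))
sched = generate_oddball_schedule(OddballSpec(), seed=1)

am.to_txt(OUT / "am_tone_41hz.txt")
gated.to_txt(OUT / "gated_tone_standard.txt")
sched.to_tsv(OUT / "oddball_schedule_seed1.tsv")

summary = {
    "am_envelope_dominant_hz": env_peak,
    "am_spectral_lines_hz": lines,
    "gated_tone_duration_ms": len(gated.samples) / gated.fs * 1000,
    "oddball_events": len(sched),
    "oddball_targets": sum(lab == "target" for lab in sched.labels),
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
print("Stimulus synthesis summary")
print(f"  AM envelope dominant frequency : {env_peak:g} Hz")
print(f"  AM spectral lines              : {lines} Hz")
print(f"  gated tone duration            : {summary['gated_tone_duration_ms']:.2f} ms")
print(f"  oddball schedule               : {len(sched)} events, "
      f"{summary['oddball_targets']} targets")
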