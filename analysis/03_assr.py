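#!/usr/bin/env python
"""ASSR detection study: SNR at 41 Hz versus stimulus level and sampling rate.

Runs the band-pass -> sweep-average -> FFT -> SNR chain on simulated
steady-state recordings: (a) SNR as a function of injected response
amplitude (detection monotonicity), (b) SNR at 1 kHz versus 4 kHz
acquisition with matched spectral resolution (sampling-rate invariance),
and (c) the second harmonic at 82 Hz. Tables land in results/assr/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from earpipe.study import assr_snr_study

OUT = Path(__file__).resolve().parents[1] / "results" / "assr"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for amp in (0.3, 0.6, 1.0, 2.0):
    snrs = assr_snr_study(seed=10, n_seeds=10, amplitude_uv=amp)
    rows.append({"amplitude_uv": amp, "mean_snr_db": np.mean(snrs),
                 "sd_snr_db": np.std(snrs, ddof=1)})
amp_table = pd.DataFrame(rows)
amp_table.to_csv(OUT / "snr_vs_amplitude.tsv", sep="\t", index=False)

fs_rows = []
for fs in (1000.0, 4000.0):
    snrs = assr_snr_study(seed=20, n_seeds=20, fs=fs)
    fs_rows.append({"fs_hz": fs, "mean_snr_db": np.mean(snrs),
                    "sd_snr_db": np.std(snrs, ddof=1)})
fs_table = pd.DataFrame(fs_rows)
fs_table.to_csv(OUT / "snr_vs_sampling_rate.tsv", sep="\t", index=False)

h2 = np.mean(assr_snr_study(seed=30, n_seeds=10,
                            harmonic_amplitudes=(0.6,), snr_at=82.0))
h0 = np.mean(assr_snr_study(seed=30, n_seeds=10, snr_at=82.0))

summary = {
    "snr_vs_amplitude": rows,
    "snr_fs_1000_vs_4000_diff_db":
        float(abs(fs_rows[0]["mean_snr_db"] - fs_rows[1]["mean_snr_db"])),
    "second_harmonic_snr_gain_db": float(h2 - h0),
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2, default=float))

print("ASSR detection study")
print(amp_table.to_string(index=False, float_format="%.2f"))
print(fs_table.to_string(index=False, float_format="%.2f"))
print(f"  |SNR(1 kHz) - SNR(4 kHz)| = "
      f"{summary['snr_fs_1000_vs_4000_diff_db']:.2f} dB")
print(f"  82 Hz SNR gain with second harmonic injected = {h2 - h0:.1f} dB")
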