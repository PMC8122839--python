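# earpipe

Analysis chain for validating in-ear / around-ear EEG ("ear-EEG")
recording hardware against two canonical auditory paradigms, plus the
wearability statistics that go with such a validation:

* **ASSR detection** — an auditory steady-state response is the EEG's
  phase-locked following of the envelope of an amplitude-modulated tone
  `y(t) = sin(2π f_c t) · (sin(2π f_m t) + 1)/2` (carrier f_c = 1000 Hz,
  modulation f_m = 41 Hz). Detection: zero-phase FIR band-pass
  (0.1–500 Hz), segmentation into 6 sweeps of 16 × 1000-point epochs,
  time-domain sweep averaging, FFT, and the SNR in dB at 41 Hz
  (target-bin power over the mean of ±60 neighboring bins, ±2 guard bins
  excluded).
* **P300 oddball ERP** — 40 sequences of 10 gated tones (69.8 ms;
  9.9 ms raised-cosine rise/fall, 50 ms plateau), one 2 kHz target per
  sequence at position 7–10 among 1 kHz standards. Pipeline: 0.1 Hz
  high-pass (order 500), resample to 128 Hz, 30 Hz low-pass (order 100),
  ICA eye-blink component removal, epoching −500…1000 ms with
  [−500, 0) ms baseline, joint-probability + kurtosis epoch rejection at
  |z| > 3, 9-tap moving-average smoothing, per-condition grand average
  over participants (≥ 2 channels required), and the peak of the
  target−standard difference wave in a 250–600 ms window.
* **Comfort statistics** — seven bipolar 7-point scales with alternating
  direction (lines 1, 3, 5, 7 reversed: mark m → 8−m) summed into a
  comfort index in [7, 49]; compared between earpiece designs with
  noninferiority / nonsuperiority two-sample t-tests at margin
  ε = ±1 pooled SD, the tie-corrected Friedman rank sum test, and the
  classical unpaired t-test.

Because no recordings from such validation studies are typically
released, the package includes a first-class **synthetic ear-EEG
generator**: 1/f background with alpha and power-line components,
steady-state components with harmonics, Gaussian ERP templates locked to
the event schedule (P300: 24 μV at 400 ms on targets), and logged
blink/muscle artifacts — so every pipeline stage is testable against
ground truth.

## Layout

```
src/earpipe/      library: stimuli, synth, assr, erp, comfort, io, study, cli
analysis/         numbered narrative drivers writing tables to results/
scripts/          acceptance.py (headline-number reproduction)
tests/            pytest suite
docs/methods.md   model, parameter and design documentation
```

## Worked example

Run the P300 study driver:

```
$ python analysis/04_erp.py
P300 oddball study (one replicate)
  participants in grand average : 8
  difference-wave peak          : 19.3 uV at 398 ms
  rejected epochs per subject   : [7.0, 7.0, 7.2, 5.5, 6.2, 5.8, 6.8, 5.2] %
```

Eight simulated participants carry a 24 μV / 400 ms P300 template on
target tones; the full chain recovers a 19.3 μV peak at 398 ms. The
~20 % amplitude shortfall is the measured cost of the chain itself
(smoothing, ICA component removal, rejection selection; see
`docs/methods.md`), and the per-subject rejected fractions sit in the
plausible 3–10 % band for statistical artifact rejection. The other
drivers print, e.g., SNR growing monotonically from 5.7 dB to 21.4 dB as
the injected 41 Hz amplitude rises from 0.3 to 2 μV, and a 1 kHz-vs-4 kHz
SNR difference of 0.7 dB (sampling-rate invariance of the detection
chain).

The same functionality is scriptable through the `earpipe` CLI
(`earpipe simulate`, `earpipe stim assr`, `earpipe assr`, `earpipe erp`,
`earpipe comfort`) for file-based workflows (EDF or tab-separated text).

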