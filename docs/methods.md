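# Methods

This note documents the models, parameter choices and numerical
conventions behind `earpipe`, and what the synthetic-data tests do and do
not establish about real recordings.

## Stimuli

The ASSR stimulus is the product form
`y(t) = A · sin(2π f_c t) · (sin(2π f_m t) + 1)/2`, i.e. a carrier at
f_c whose envelope swings fully between 0 and 1 at f_m (100 % modulation
depth). Its exact spectrum is three lines: f_c at A/2 and f_c ± f_m at
A/4 — the identity the Parseval test asserts. Defaults: f_c = 1000 Hz,
f_m = 41 Hz, stimulus sampling rate 16 kHz (a convention; any rate above
2·f_c is accepted). Sample count is `round(duration · fs)` with the time
axis starting at 0.

Oddball tones are gated sinusoids with raised-cosine (Hann) onset/offset
ramps — the standard audiological gating shape for a stated "rise/fall"
— 9.9 ms ramps around a 50 ms plateau (69.8 ms total), 1 kHz standards
and 2 kHz targets. The schedule places one target per 10-tone sequence
uniformly at positions 7–10; interstimulus gaps are offset-to-next-onset
(2 s within sequences, 4 s between), a convention the run configuration
records so it can be switched.

## Synthetic ear-EEG

The generator produces the statistical structure the analyses assume,
not a biophysical head model:

* **Background**: spectrally shaped white noise with a 1/f^a amplitude
  profile (a = 1, held flat below 0.5 Hz so variance stays finite), an
  alpha band (2 Hz-wide Gaussian noise at 10 Hz, 3 μV RMS) and a line
  sinusoid (60 Hz, 1 μV RMS). The broadband component is normalized to
  20 μV RMS *within a fixed 0.5–500 Hz reference band*, so the spectral
  density near any analysis frequency is independent of the simulation
  sampling rate — simulating the same continuous process at 1 kHz and
  4 kHz, which is what the sampling-rate-invariance test requires.
  Channels mix a common broadband source (50 % variance fraction) with
  independent ones. The 20 μV level matters: it keeps single-trial
  evoked deflections below the ongoing-activity floor, as in real EEG;
  with a much quieter background the statistical rejection stage would
  "see" and preferentially discard the largest single-trial responses,
  which no real recording licenses.
* **Evoked components**: Gaussian-in-time deflections per event label
  (two parameters suffice for amplitude/latency-recovery tests). The
  default scenario attaches a P300-like positivity (24 μV peak, 400 ms
  latency, 60 ms SD) to targets and an N1-like negativity (−8 μV,
  100 ms, 25 ms SD) to every tone; per-event latency jitter is uniform
  ±20 ms. Deflections add uniformly across channels.
* **Artifacts**: blinks are 200 μV Gaussian transients (80 ms SD) at
  2/min (Poisson), projected through a fixed cross-channel mixing vector
  (1.0, −0.5, 0.2) — around-ear contacts view the ocular dipole from
  different sides, so gains differ in magnitude and sign. (A mixing
  vector nearly collinear with the uniform evoked topography would make
  blink-component removal strip the ERP itself; the default geometry
  avoids that degeneracy.) Muscle bursts are Hann-windowed 20–100 Hz
  noise, 300 ms, 30 μV RMS, 1/min. Every insertion is logged, making
  rejection sensitivity/specificity computable exactly. The default
  rates were set so the statistical-rejection stage discards a fraction
  of epochs in the 3–10 % range reported for such recordings.

All component-adding operations are additive, hence order-independent
and linear — the basis of the linearity and commutation property tests.

What passing these tests does *not* show: robustness to non-Gaussian
ERP shapes, correlated artifact/evoked timing, electrode drift,
impedance variation, or real volume conduction.

## ASSR analysis

Band-pass: linear-phase FIR (`firwin`, order 500 → 501 taps), applied as
a single centered convolution, which is exactly zero-phase for a
symmetric kernel; edges are reflection-padded. At 1 kHz sampling the
stated 500 Hz upper edge sits at Nyquist, so the design reduces to a
high-pass (a low-pass at Nyquist is a no-op given anti-aliased
acquisition). A 501-tap kernel cannot realize a true 0.1 Hz stopband
(transition width ≈ 6.6 Hz at 1 kHz), so the DC term is removed exactly
by per-channel demeaning before convolution; this is what "0.1 Hz
high-pass at order 500" can honestly deliver.

Sweeps are contiguous and trigger-free — valid because the steady-state
response is periodic and 41 Hz is an integer number of cycles per
1000 ms epoch, so it stays coherent across sweeps while background
averages down. `max(order, fs)` samples are trimmed at each end first
(filter settle). The six 16,000-sample sweeps are averaged pointwise and
the *mean sweep* is FFT'd (rectangular window; resolution fs/16,000 =
1/16 Hz, on which 41 Hz falls exactly).

SNR definition (the conventional neighborhood form): power in the bin
nearest f_m over the mean power of ±60 neighboring bins excluding the
target and ±2 guard bins. A zero noise floor reports +inf rather than
raising. Both the half-width and guard count are arguments.

## ERP analysis

Order of operations: exact demeaning + 0.1 Hz zero-phase high-pass
(order 500) at the acquisition rate (default 1 kHz) → polyphase resample
to 128 Hz → 30 Hz zero-phase low-pass (order 100) → ICA blink removal on
the continuous record → epoching −500…1000 ms (192 samples at 128 Hz;
onset sample belongs to the post-stimulus segment; baseline window
[−500, 0) ms) → statistical rejection → 9-tap moving-average smoothing
("order 8"; read as an order-8 FIR, i.e. 9 taps) → averaging.

**Rejection.** Two criteria, each computed per channel and channel-
pooled, z-scored across epochs, rejecting any epoch with |z| > 3:
(a) joint probability — the mean log-likelihood of an epoch's samples
under the empirical amplitude distribution (100-bin histogram over all
epochs); (b) excess kurtosis. The z-scoring is single-pass and
non-robust: when gross artifacts occupy more than ~10 % of epochs they
inflate the score spread and mask each other (sensitivity to inserted
blinks collapses from ~100 % toward ~30 % in heavy-contamination
simulations). This is a property of the method, not a bug; the default
scenario stays in the regime where it works.

**ICA.** FastICA (negentropy fixed-point, fixed random state, unit-
variance whitening) on the continuous preprocessed record, one component
per channel. The blink component is selected automatically as the source
maximizing the 0.5–4 Hz-to-total power ratio among sources with excess
kurtosis above 2 (blinks are sparse, heavy-tailed and slow); if none
qualifies the data pass through unchanged, and an explicit component
index can override the rule. The component's projection is subtracted.
Removal is not free: a small fraction of evoked variance rides on the
removed component (~4 % linear bleed at the default geometry).

**Amplitude budget.** The chain attenuates the injected 24 μV peak to a
recovered ≈ 19–20 μV: ≈ 2 % latency jitter, ≈ 5 % boxcar smoothing
(70 ms window on a 60 ms-SD peak), ≈ 4 % ICA bleed, and ≈ 5 % from the
rejection stage still preferentially trimming the largest single-trial
targets. Latency is essentially unbiased (grid resolution 7.8 ms). The
recovery tests therefore assert a ±20 % amplitude band and ±40 ms
latency band around the injected values.

Participants contribute to the grand average only with ≥ 2 channels;
per-participant condition averages (kept epochs, then channels) enter an
unweighted mean; the difference wave is target − standard and the P300
is its maximum in 250–600 ms, ties resolved to the earliest sample.

## Comfort statistics

Scale conversion: lines 2, 4, 6 map mark m → m; lines 1, 3, 5, 7 map
m → 8 − m (an involution). Index = sum of the seven converted values.

Noninferiority of A vs B at margin ε tests H0: μ_A − μ_B ≤ −ε with
t = (x̄_A − x̄_B + ε)/SE (pooled SE by default, Welch switchable),
one-sided upper p; nonsuperiority mirrors at +ε with the lower tail.
ε defaults to one pooled SD of the two groups (the margin is config-
exposed because "one σ" admits per-group variants). The implementation
matches `statsmodels.stats.weightstats.ttost_ind` to 1e-10 in tests.

The Friedman statistic uses within-subject midranks with the standard
tie correction `1 − Σ(t³−t)/(n k (k²−1))` and a χ²(k−1) reference; it
is implemented here (rather than delegated) because the installed SciPy
refuses k = 2 treatments, which the paired two-device comparisons need;
it agrees with SciPy exactly for k ≥ 3. Note a discreteness fact the
calibration tests expose: at n = 10, k = 2 the statistic is a function
of a Binomial(10, ½) count, so the attainable test sizes at nominal
α = 0.05 are 0.0215 or 0.1094 — a rejection rate in, say, [0.04, 0.06]
is not achievable by any valid Friedman test at those dimensions, and
the measured rate sits at the conservative 0.021–0.023 level.

## I/O and determinism

Recordings read/write as EDF (16-bit; physical range ±3200 μV declared
in the header, out-of-range amplitudes raise rather than clip; reading
goes through MNE and is the round-trip oracle for the writer) or as
tab-separated text with `# fs=` / `# channels=` headers (lossless,
diffable). Schedules are TSV (`onset_s  label  sequence`). Event onsets
map to the nearest sample (round half up); windows are in ms, schedules
in s. Every stochastic operation takes one integer seed; study-level
runners derive sub-seeds via `numpy.random.SeedSequence.spawn`, and the
batch runner records a config hash, seed and library versions with every
run.

## Problem sizes

The replicated ERP recovery study uses 20 replicates × 8 participants ×
40 sequences (the study-scale scenario); ASSR studies use 10–20 seeds of
~100 s single-channel recordings; calibration simulations use 10,000
replicates. These sizes give stable means (SE of the recovered P300
amplitude across replicates ≈ 0.1 μV) at a few minutes of single-core
compute.

## Known limitations

* The rejection operator's masking behavior under heavy contamination
  (above) limits the generator's valid artifact-rate range.
* FastICA at 3 channels with more latent sources than channels is
  necessarily approximate; the blink-selection heuristic can in
  principle pick an evoked-dominated component on pathological data —
  the explicit `component_index` override exists for that case.
* The EDF writer emits one-second records and requires integer sampling
  rates; trailing sub-second samples are dropped with a warning.
* The noninferiority margin uses the unpaired pooled-SD form; a paired
  design (each participant wearing both devices) would warrant a
  paired-margin variant that is not implemented.
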