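"""P300 oddball event-related-potential (ERP) pipeline.

Chain, in order: zero-phase high-pass (0.1 Hz), resample to 128 Hz,
zero-phase low-pass (30 Hz); independent component analysis on the
continuous record to remove the eye-blink component; epoching from -500
to 1000 ms around stimulus onsets with baseline correction over
[-500, 0) ms; statistical epoch rejection by joint-probability and
kurtosis criteria (|z| > 3); moving-average smoothing; per-condition
averaging; grand average across participants; target-minus-standard
difference wave; and P300 peak measurement in a 250-600 ms window.

Participants with fewer than two acquisition channels are excluded from
the grand average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly
from scipy.stats import kurtosis as _kurtosis

from ._filters import design_fir, filt_zero_phase, moving_average_kernel
from .stimuli import EventSchedule
from .synth import EEGRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ERPFilterConfig:
    """Preprocessing parameters (defaults follow the validated chain)."""

    hp_cutoff: float = 0.1
    hp_order: int = 500
    resample_fs: float = 128.0
    lp_cutoff: float = 30.0
    lp_order: int = 100
    smooth_order: int = 8

    def __post_init__(self) -> None:
        if self.hp_cutoff <= 0 or self.lp_cutoff >= self.resample_fs / 2:
            raise ValueError("cutoffs must lie inside (0, Nyquist)")
        if min(self.hp_order, self.lp_order, self.smooth_order) < 1:
            raise ValueError("filter orders must be >= 1")


@dataclass
class EpochSet:
    """Epochs x channels x samples (uV) with labels, time axis and keep mask."""

    data: np.ndarray
    labels: list[str]
    times_ms: np.ndarray
    fs: float
    keep_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.data.shape[0], dtype=bool)
        if not (self.data.shape[0] == len(self.labels) == len(self.keep_mask)):
            raise ValueError("epochs, labels and keep_mask must align")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis must match epoch length")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def kept(self, label: str | None = None) -> np.ndarray:
        """Kept epochs, optionally restricted to one condition label."""
        sel = self.keep_mask.copy()
        if label is not None:
            sel &= np.array([l == label for l in self.labels])
        return self.data[sel]


@dataclass
class RejectionReport:
    prob_z: np.ndarray        # epochs x (channels + 1); last column pooled
    kurtosis_z: np.ndarray    # epochs x (channels + 1)
    rejected_indices: np.ndarray
    rejected_fraction: float  # percent


@dataclass
class ERPResult:
    times_ms: np.ndarray
    target_avg: np.ndarray
    standard_avg: np.ndarray
    difference: np.ndarray
    n_participants: int
    p300_amplitude_uv: float | None = None
    p300_latency_ms: float | None = None


def preprocess(rec: EEGRecording, cfg: ERPFilterConfig | None = None) -> EEGRecording:
    """High-pass -> resample -> low-pass, all zero-phase; output at 128 Hz."""
    cfg = cfg or ERPFilterConfig()
    if rec.fs <= 2 * cfg.lp_cutoff:
        raise ValueError("input sampling rate too low for the low-pass cutoff")
    if cfg.resample_fs > rec.fs:
        raise ValueError("resample target above input sampling rate")
    hp = design_fir(cfg.hp_order, rec.fs, cfg.hp_cutoff, None)
    # exact DC removal first; the stated-order kernel handles the rest
    data = rec.data - rec.data.mean(axis=-1, keepdims=True)
    data = filt_zero_phase(data, hp)
    frac = Fraction(cfg.resample_fs / rec.fs).limit_denominator(10000)
    data = resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    lp = design_fir(cfg.lp_order, cfg.resample_fs, None, cfg.lp_cutoff)
    data = filt_zero_phase(data, lp)
    out = EEGRecording(data, cfg.resample_fs, list(rec.channel_labels), rec.schedule)
    return out


def epoch_and_baseline(rec: EEGRecording, schedule: EventSchedule | None = None,
                       window_ms: tuple[float, float] = (-500.0, 1000.0),
                       baseline_ms: tuple[float, float] = (-500.0, 0.0)) -> EpochSet:
    """Cut epochs around event onsets and subtract the baseline mean.

    The baseline window is closed-open [start, 0): the onset sample belongs
    to the post-stimulus segment. Events whose window falls outside the
    recording are dropped with a logged warning.
    """
    schedule = schedule if schedule is not None else rec.schedule
    if schedule is None or len(schedule) == 0:
        raise ValueError("no event schedule supplied")
    fs = rec.fs
    n_pre = int(round(-window_ms[0] / 1000 * fs))
    n_post = int(round(window_ms[1] / 1000 * fs))
    n_len = n_pre + n_post
    times_ms = (np.arange(n_len) - n_pre) / fs * 1000.0
    b_lo = int(round((baseline_ms[0] - window_ms[0]) / 1000 * fs))
    b_hi = int(round((baseline_ms[1] - window_ms[0]) / 1000 * fs))

    epochs, labels = [], []
    for onset, label in zip(schedule.onsets, schedule.labels):
        ci = int(np.floor(onset * fs + 0.5))
        lo, hi = ci - n_pre, ci + n_post
        if lo < 0 or hi > rec.n_samples:
            logger.warning("event at %.3f s outside recording; dropped", onset)
            continue
        seg = rec.data[:, lo:hi]
        seg = seg - seg[:, b_lo:b_hi].mean(axis=1, keepdims=True)
        epochs.append(seg)
        labels.append(label)
    if not epochs:
        raise ValueError("all events fall outside the recording")
    return EpochSet(np.stack(epochs), labels, times_ms, fs)


def _prob_z(data: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Joint-probability z-scores, epochs x (channels + 1).

    Per channel, an empirical density (histogram over all epochs' values)
    scores each epoch by the mean log-likelihood of its samples; the scores
    are z-scored across epochs. The last column repeats the computation
    with all channels pooled.
    """
    n_ep, n_ch, _ = data.shape
    out = np.empty((n_ep, n_ch + 1))
    pools = [data[:, c, :] for c in range(n_ch)] + [data.reshape(n_ep, -1)]
    for j, pool in enumerate(pools):
        counts, edges = np.histogram(pool, bins=n_bins)
        density = counts / counts.sum()
        idx = np.clip(np.digitize(pool, edges[1:-1]), 0, n_bins - 1)
        logp = np.log(density[idx] + 1e-12)
        score = logp.mean(axis=1)
        sd = score.std()
        out[:, j] = (score - score.mean()) / sd if sd > 0 else 0.0
    return out


def _kurt_z(data: np.ndarray) -> np.ndarray:
    """Excess-kurtosis z-scores, epochs x (channels + 1), pooled last."""
    n_ep, n_ch, _ = data.shape
    per_ch = _kurtosis(data, axis=2, fisher=True, bias=True)   # epochs x ch
    pooled = _kurtosis(data.reshape(n_ep, -1), axis=1, fisher=True, bias=True)
    k = np.column_stack([per_ch, pooled])
    sd = k.std(axis=0)
    z = np.zeros_like(k)
    nz = sd > 0
    z[:, nz] = (k[:, nz] - k[:, nz].mean(axis=0)) / sd[nz]
    return z


def reject_epochs(epochs: EpochSet,
                  sd_threshold: float = 3.0) -> tuple[EpochSet, RejectionReport]:
    """Flag improbable/artifactual epochs by probability and kurtosis criteria.

    An epoch is rejected when any single-channel or channel-pooled measure
    exceeds ``sd_threshold`` standard deviations (|z|). Returns a new
    EpochSet whose keep_mask has the rejected epochs cleared, plus a report.
    """
    if epochs.n_epochs < 8:
        raise ValueError("need at least 8 epochs for meaningful z-scores")
    pz = _prob_z(epochs.data)
    kz = _kurt_z(epochs.data)
    bad = (np.abs(pz) > sd_threshold).any(axis=1) | \
          (np.abs(kz) > sd_threshold).any(axis=1)
    keep = epochs.keep_mask & ~bad
    rejected = np.flatnonzero(bad)
    report = RejectionReport(pz, kz, rejected,
                             100.0 * len(rejected) / epochs.n_epochs)
    out = EpochSet(epochs.data, list(epochs.labels), epochs.times_ms,
                   epochs.fs, keep)
    return out, report


def ica_blink_removal(rec: EEGRecording, n_components: int | None = None,
                      low_freq_band: tuple[float, float] = (0.5, 4.0),
                      kurtosis_floor: float = 2.0,
                      component_index: int | None = None,
                      random_state: int = 0,
                      ) -> tuple[EEGRecording, dict]:
    """Unmix with FastICA, remove the eye-blink component, remix.

    The blink component is chosen automatically as the source with the
    largest ratio of 0.5-4 Hz power to total power among sources whose
    excess kurtosis exceeds ``kurtosis_floor`` (blinks are sparse, heavy
    tailed, low frequency). If no source qualifies, the data pass through
    unchanged. ``component_index`` overrides the automatic choice.
    """
    from sklearn.decomposition import FastICA

    if rec.n_channels < 2:
        raise ValueError("ICA needs at least 2 channels")
    n_components = n_components or rec.n_channels
    X = rec.data.T  # samples x channels
    if np.linalg.matrix_rank(np.cov(rec.data)) < n_components:
        raise np.linalg.LinAlgError(
            "rank-deficient data: reduce n_components or check for "
            "duplicated/flat channels")
    ica = FastICA(n_components=n_components, random_state=random_state,
                  whiten="unit-variance", max_iter=1000)
    S = ica.fit_transform(X)  # samples x components

    n = S.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    band = (freqs >= low_freq_band[0]) & (freqs <= low_freq_band[1])
    ratios, kurts = [], []
    for j in range(n_components):
        p = np.abs(np.fft.rfft(S[:, j])) ** 2
        tot = p[1:].sum()
        ratios.append(p[band].sum() / tot if tot > 0 else 0.0)
        kurts.append(float(_kurtosis(S[:, j], fisher=True, bias=True)))
    ratios = np.array(ratios)
    kurts = np.array(kurts)

    if component_index is not None:
        blink = component_index
    else:
        ok = kurts > kurtosis_floor
        blink = int(np.argmax(np.where(ok, ratios, -np.inf))) if ok.any() else None

    record = {"removed_index": blink, "low_freq_ratio": ratios.tolist(),
              "kurtosis": kurts.tolist(),
              "sources": S, "mixing": ica.mixing_}
    if blink is None:
        return rec.copy_with(rec.data.copy()), record
    contrib = np.outer(S[:, blink], ica.mixing_[:, blink])  # samples x channels
    cleaned = (X - contrib).T
    return rec.copy_with(cleaned), record


def smooth_moving_average(series: np.ndarray, order: int = 8) -> np.ndarray:
    """Zero-phase boxcar smoother with ``order + 1`` taps, length preserved.

    Works along the last axis with symmetric edge padding.
    """
    series = np.asarray(series, dtype=float)
    kernel = moving_average_kernel(order)
    if series.shape[-1] <= len(kernel):
        raise ValueError("series shorter than the smoothing kernel")
    return filt_zero_phase(series, kernel)


def grand_average_and_difference(participant_epochs: list[EpochSet],
                                 min_channels: int = 2) -> ERPResult:
    """Per-participant condition averages, then unweighted grand average.

    Participants whose data carry fewer than ``min_channels`` channels are
    excluded. Per participant, kept epochs are averaged within condition
    and across channels; the grand average is the unweighted mean of those
    participant waveforms; the difference wave is target minus standard.
    """
    admissible = [e for e in participant_epochs if e.n_channels >= min_channels]
    if not admissible:
        raise ValueError("no participant meets the minimum channel count")
    times = admissible[0].times_ms
    tgt, std = [], []
    for ep in admissible:
        t = ep.kept("target")
        s = ep.kept("standard")
        if len(t) == 0 or len(s) == 0:
            logger.warning("participant without kept epochs in one condition; "
                           "excluded from grand average")
            continue
        tgt.append(t.mean(axis=0).mean(axis=0))
        std.append(s.mean(axis=0).mean(axis=0))
    if not tgt:
        raise ValueError("no participant contributed both conditions")
    target_avg = np.mean(tgt, axis=0)
    standard_avg = np.mean(std, axis=0)
    return ERPResult(times, target_avg, standard_avg,
                     target_avg - standard_avg, n_participants=len(tgt))


def measure_p300(result: ERPResult,
                 search_window_ms: tuple[float, float] = (250.0, 600.0),
                 ) -> tuple[float, float]:
    """Peak amplitude (uV) and latency (ms) of the difference wave.

    The maximum within the search window; ties resolve to the earliest
    sample. The result is also written back onto ``result``.
    """
    t = result.times_ms
    sel = (t >= search_window_ms[0]) & (t <= search_window_ms[1])
    if not sel.any():
        raise ValueError("search window outside the epoch span")
    seg = result.difference[sel]
    i = int(np.argmax(seg))  # argmax returns the first maximum
    amp = float(seg[i])
    lat = float(t[sel][i])
    result.p300_amplitude_uv = amp
    result.p300_latency_ms = lat
    return amp, lat


def run_erp_participant(rec: EEGRecording,
                        cfg: ERPFilterConfig | None = None,
                        apply_ica: bool = True,
                        apply_rejection: bool = True,
                        sd_threshold: float = 3.0,
                        ) -> tuple[EpochSet, RejectionReport | None]:
    """One participant through the full single-subject chain.

    preprocess -> (ICA blink removal) -> epoch+baseline -> (rejection) ->
    moving-average smoothing. ICA runs only with >= 2 channels, mirroring
    the all-channels-active condition of the validated chain.
    """
    cfg = cfg or ERPFilterConfig()
    pp = preprocess(rec, cfg)
    if apply_ica and pp.n_channels >= 2:
        pp, _ = ica_blink_removal(pp)
    epochs = epoch_and_baseline(pp)
    report = None
    if apply_rejection:
        epochs, report = reject_epochs(epochs, sd_threshold)
    smoothed = smooth_moving_average(epochs.data, cfg.smooth_order)
    epochs = EpochSet(smoothed, list(epochs.labels), epochs.times_ms,
                      epochs.fs, epochs.keep_mask)
    return epochs, report


def run_erp_study(recordings: list[EEGRecording],
                  cfg: ERPFilterConfig | None = None,
                  min_channels: int = 2,
                  **participant_kwargs) -> tuple[ERPResult, list[RejectionReport | None]]:
    """Full multi-participant analysis ending in the measured P300."""
    epochsets, reports = [], []
    for rec in recordings:
        ep, rep = run_erp_participant(rec, cfg, **participant_kwargs)
        epochsets.append(ep)
        reports.append(rep)
    result = grand_average_and_difference(epochsets, min_channels)
    measure_p300(result)
    return result, reports
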