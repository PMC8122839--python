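"""Study-level scenario runners on the default synthetic conditions.

These functions tie the simulator to the analysis chains at the study's
scale — an 8-participant, 40-sequence oddball ERP session and a
six-sweep ASSR session — and are shared by the analysis drivers, the
test suite and the acceptance script. All randomness descends from one
integer seed through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assr import SweepConfig, run_assr
from .erp import grand_average_and_difference, measure_p300, run_erp_participant
from .synth import ArtifactSpec, NoiseSpec, simulate_assr_recording, \
    simulate_oddball_recording


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2**31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ERPStudyResult:
    amplitudes_uv: list[float]
    latencies_ms: list[float]
    rejected_fractions: list[float]

    @property
    def mean_amplitude_uv(self) -> float:
        return float(np.mean(self.amplitudes_uv))

    @property
    def mean_latency_ms(self) -> float:
        return float(np.mean(self.latencies_ms))


def erp_recovery_study(seed: int, n_seeds: int = 20, n_participants: int = 8,
                       with_artifacts: bool = True) -> ERPStudyResult:
    """Replicated 8-participant oddball studies on the default scenario.

    Each replicate simulates ``n_participants`` contaminated recordings,
    runs the full single-subject chain (preprocess, ICA blink removal,
    epoching, statistical rejection, smoothing), grand-averages, and
    measures the difference-wave peak. Returns per-replicate P300
    amplitude and latency plus all per-participant rejected fractions.
    """
    artifacts = ArtifactSpec() if with_artifacts else None
    amps, lats, rejfracs = [], [], []
    for rep_seed in child_seeds(seed, n_seeds):
        epochsets = []
        for p_seed in child_seeds(rep_seed, n_participants):
            rec, _ = simulate_oddball_recording(p_seed, artifacts=artifacts)
            ep, report = run_erp_participant(rec)
            epochsets.append(ep)
            if report is not None:
                rejfracs.append(report.rejected_fraction)
        result = grand_average_and_difference(epochsets)
        amp, lat = measure_p300(result)
        amps.append(amp)
        lats.append(lat)
    return ERPStudyResult(amps, lats, rejfracs)


def assr_snr_study(seed: int, n_seeds: int = 10, fm: float = 41.0,
                   amplitude_uv: float = 1.0, fs: float = 1000.0,
                   points_per_epoch: int | None = None,
                   harmonic_amplitudes: tuple[float, ...] = (),
                   noise: NoiseSpec | None = None,
                   snr_at: float | None = None) -> list[float]:
    """Per-seed SNR (dB) at ``snr_at`` (default: fm) on the default scenario.

    ``points_per_epoch`` defaults to one epoch per second (fs samples), so
    the spectral resolution is sampling-rate invariant.
    """
    from .assr import compute_snr

    cfg = SweepConfig(points_per_epoch=int(points_per_epoch or fs))
    target = fm if snr_at is None else snr_at
    out = []
    for s in child_seeds(seed, n_seeds):
        rec = simulate_assr_recording(s, fm=fm, amplitude_uv=amplitude_uv,
                                      harmonic_amplitudes=harmonic_amplitudes,
                                      duration_s=cfg.total_samples / fs + 2.5,
                                      fs=fs, noise=noise)
        spectrum, _ = run_assr(rec, fm=fm, cfg=cfg)
        out.append(compute_snr(spectrum, target).snr_db)
    return out
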