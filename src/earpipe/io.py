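"""Recording I/O, configuration, and the batch pipeline runner.

Two on-disk recording formats:

* delimited text — a ``# fs=<Hz>`` header line, a ``# channels=...`` line,
  then one tab-separated column per channel; lossless and diffable,
* EDF (European Data Format) — the standard 16-bit biosignal container.
  Reading goes through :func:`mne.io.read_raw_edf`; writing uses the
  compact single-record writer below (samples are mapped onto the 16-bit
  digital range declared in the header, so amplitudes must fit the stated
  physical range).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .stimuli import EventSchedule
from .synth import EEGRecording

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Unknown or malformed file format."""


# --- delimited text -----------------------------------------------------

def write_recording_txt(rec: EEGRecording, path: str | Path) -> None:
    if rec.n_samples == 0:
        raise ValueError("refusing to write a 0-sample recording")
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:.10g}\n")
        fh.write("# channels=" + "\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter="\t", fmt="%.10g")


def read_recording_txt(path: str | Path) -> EEGRecording:
    fs = None
    labels = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("channels="):
                labels = body[len("channels="):].split("\t")
    if fs is None:
        raise FormatError(f"{path}: missing required '# fs=<Hz>' header field")
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2).T
    if labels is not None and len(labels) != data.shape[0]:
        raise FormatError(f"{path}: channel label count does not match columns")
    return EEGRecording(data, fs, labels)


# --- EDF ----------------------------------------------------------------

def write_recording_edf(rec: EEGRecording, path: str | Path,
                        physical_range: tuple[float, float] = (-3200.0, 3200.0),
                        ) -> None:
    """Write a minimal EDF file (one data record per second, 16-bit).

    ``physical_range`` is the declared physical min/max in microvolts;
    amplitudes outside it raise rather than clip silently.
    """
    if rec.n_samples == 0:
        raise ValueError("refusing to write a 0-sample recording")
    pmin, pmax = physical_range
    if rec.data.min() < pmin or rec.data.max() > pmax:
        raise ValueError(
            f"amplitudes outside the declared EDF physical range {physical_range}")
    fs_int = int(round(rec.fs))
    if abs(fs_int - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // fs_int
    if n_rec * fs_int != rec.n_samples:
        logger.warning("EDF write: trailing %d samples do not fill a 1 s "
                       "record and are dropped", rec.n_samples - n_rec * fs_int)
    ns = rec.n_channels
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(ns), 4),
    ])
    hdr += b"".join(pad(lab, 16) for lab in rec.channel_labels)
    hdr += b"".join(pad("EEG", 80) for _ in range(ns))
    hdr += b"".join(pad("uV", 8) for _ in range(ns))
    hdr += b"".join(pad(f"{pmin:.1f}", 8) for _ in range(ns))
    hdr += b"".join(pad(f"{pmax:.1f}", 8) for _ in range(ns))
    hdr += b"".join(pad(str(dmin), 8) for _ in range(ns))
    hdr += b"".join(pad(str(dmax), 8) for _ in range(ns))
    hdr += b"".join(pad("", 80) for _ in range(ns))
    hdr += b"".join(pad(str(fs_int), 8) for _ in range(ns))
    hdr += b"".join(pad("", 32) for _ in range(ns))

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            seg = rec.data[:, r * fs_int:(r + 1) * fs_int]
            dig = np.round((seg - pmin) * scale + dmin).astype("<i2")
            fh.write(dig.tobytes())


def read_recording_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file via MNE; channels returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_recording(rec: EEGRecording, path: str | Path,
                    format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "edf":
        write_recording_edf(rec, path)
    elif fmt == "txt":
        write_recording_txt(rec, path)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return read_recording_edf(path)
    if fmt == "txt":
        return read_recording_txt(path)
    raise FormatError(f"unknown recording format {fmt!r}")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".txt", ".tsv", ".csv"):
        return "txt"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


# --- comfort sheets -----------------------------------------------------

def read_comfort_sheet(path: str | Path):
    """Read a delimited comfort-response sheet.

    One row per participant per device: seven integer marks then a device
    label. Returns a pandas DataFrame with columns m1..m7 and device.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    needed = [f"m{i}" for i in range(1, 8)] + ["device"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: comfort sheet missing columns {missing}")
    return df


# --- configuration and pipeline runner ---------------------------------

@dataclass
class PipelineConfig:
    """Validated run description for the batch runner."""

    paradigm: str
    seed: int
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "results"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.paradigm not in ("assr", "erp", "comfort", "simulate"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        out = Path(self.output_dir).resolve()
        for p in self.inputs:
            if Path(p).resolve() == out:
                raise ValueError("input and output paths must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def provenance(self) -> dict:
        import scipy

        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "seed": self.seed,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Dispatch a configured run; returns a summary dict and writes files.

    Deterministic given config + seed: every stochastic stage derives its
    seed from ``config.seed``. Outputs land under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"paradigm": config.paradigm,
                     "provenance": config.provenance()}
    try:
        if config.paradigm == "simulate":
            summary.update(_run_simulate(config, out))
        elif config.paradigm == "assr":
            summary.update(_run_assr(config, out))
        elif config.paradigm == "erp":
            summary.update(_run_erp(config, out))
        elif config.paradigm == "comfort":
            summary.update(_run_comfort(config, out))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{config.paradigm}' failed on inputs "
            f"{config.inputs}: {exc}") from exc
    with open(out / f"{config.paradigm}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _run_simulate(config: PipelineConfig, out: Path) -> dict:
    from .synth import ArtifactSpec, simulate_oddball_recording

    p = config.params
    artifacts = ArtifactSpec(**p["artifacts"]) if "artifacts" in p else None
    rec, log = simulate_oddball_recording(config.seed, artifacts=artifacts)
    fmt = p.get("format", "edf")
    path = out / f"simulated_oddball_seed{config.seed}.{fmt}"
    write_recording(rec, path, fmt)
    rec.schedule.to_tsv(out / f"schedule_seed{config.seed}.tsv")
    logger.info("simulate: %d channels x %d samples at %g Hz -> %s",
                rec.n_channels, rec.n_samples, rec.fs, path)
    return {"recording": str(path), "n_events": len(rec.schedule),
            "n_artifacts": len(log)}


def _run_assr(config: PipelineConfig, out: Path) -> dict:
    from .assr import SweepConfig, run_assr

    p = config.params
    cfg = SweepConfig(**p.get("sweeps", {}))
    rows = []
    for path in config.inputs:
        rec = read_recording(path)
        _, snrs = run_assr(rec, fm=p.get("fm", 41.0), cfg=cfg,
                           order=p.get("order", 500))
        for ch, r in zip(rec.channel_labels, snrs):
            rows.append((path, ch, r.f_target, r.signal_power,
                         r.noise_power, r.snr_db))
    report = out / "assr_report.tsv"
    with open(report, "w") as fh:
        fh.write("file\tchannel\tf_target\tsignal_power\tnoise_power\tsnr_db\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    logger.info("assr: %d recordings -> %s", len(config.inputs), report)
    return {"report": str(report),
            "mean_snr_db": float(np.mean([r[-1] for r in rows])) if rows else None}


def _run_erp(config: PipelineConfig, out: Path) -> dict:
    from .erp import run_erp_study

    recs = []
    for path in config.inputs:
        rec = read_recording(path)
        sched = Path(path).with_suffix(".events.tsv")
        if sched.exists():
            rec.schedule = EventSchedule.from_tsv(sched)
        recs.append(rec)
    result, reports = run_erp_study(recs)
    np.savetxt(out / "difference_wave.tsv",
               np.column_stack([result.times_ms, result.difference]),
               delimiter="\t", header="time_ms\tamplitude_uv")
    for cond in ("target", "standard"):
        np.savetxt(out / f"grand_average_{cond}.tsv",
                   np.column_stack([result.times_ms,
                                    getattr(result, f"{cond}_avg")]),
                   delimiter="\t", header="time_ms\tamplitude_uv")
    rejected = [r.rejected_fraction for r in reports if r is not None]
    logger.info("erp: N=%d, P300 %.2f uV @ %.0f ms", result.n_participants,
                result.p300_amplitude_uv, result.p300_latency_ms)
    return {"n_participants": result.n_participants,
            "p300_amplitude_uv": result.p300_amplitude_uv,
            "p300_latency_ms": result.p300_latency_ms,
            "rejected_fraction_pct": rejected}


def _run_comfort(config: PipelineConfig, out: Path) -> dict:
    from .comfort import (ComfortResponse, NoninferiorityConfig,
                          noninferiority_t_test)

    df = read_comfort_sheet(config.inputs[0])
    marks = df[[f"m{i}" for i in range(1, 8)]].to_numpy()
    df = df.assign(index=[ComfortResponse.from_marks(row).index for row in marks])
    devices = sorted(df["device"].unique())
    results = {}
    if len(devices) == 2:
        a = df.loc[df.device == devices[0], "index"].to_numpy(float)
        b = df.loc[df.device == devices[1], "index"].to_numpy(float)
        for direction in ("noninferiority", "nonsuperiority"):
            r = noninferiority_t_test(
                a, b, NoninferiorityConfig(direction=direction,
                                           **config.params.get("margin", {})))
            results[direction] = {"t": r.statistic, "df": r.degrees_of_freedom,
                                  "p": r.p_value}
    df.to_csv(out / "comfort_indices.tsv", sep="\t", index=False)
    return {"devices": devices,
            "mean_index": df.groupby("device")["index"].mean().to_dict(),
            "tests": results}
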