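"""Plain-text containers: delimited matrices with JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .mem import FitReport, MEMParams
from .preprocessing import BinaryPatternSeries

__all__ = [
    "save_recording",
    "load_recording",
    "save_series",
    "load_series",
    "save_model",
    "load_model",
]


def save_recording(path, recording, truth_summary: dict | None = None) -> None:
    """Signals as TSV plus a JSON sidecar (fs, channel map, latent states)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "signals.tsv", recording.signals, delimiter="\t", fmt="%.6g")
    np.savetxt(path / "latent_patterns.tsv", recording.latent_patterns, fmt="%d")
    meta = {
        "fs": recording.fs,
        "channel_map": {str(k): [v[0], list(v[1])] for k, v in recording.channel_map.items()},
    }
    if truth_summary:
        meta["truth"] = truth_summary
    (path / "recording.json").write_text(json.dumps(meta, indent=1))


def load_recording(path):
    from .synthetic import SyntheticRecording

    path = Path(path)
    meta = json.loads((path / "recording.json").read_text())
    signals = np.loadtxt(path / "signals.tsv", delimiter="\t")
    latent = np.loadtxt(path / "latent_patterns.tsv", dtype=np.int64)
    cmap = {int(k): (v[0], list(v[1])) for k, v in meta["channel_map"].items()}
    return SyntheticRecording(
        signals=signals,
        fs=meta["fs"],
        latent_states=np.full(len(latent), -1, dtype=np.int8),
        latent_patterns=latent,
        channel_map=cmap,
    )


def save_series(path, series: BinaryPatternSeries) -> None:
    path = Path(path)
    np.savetxt(path, series.values, fmt="%d", delimiter="\t",
               header=json.dumps({"fs": series.fs}), comments="# ")


def load_series(path) -> BinaryPatternSeries:
    path = Path(path)
    first = path.open().readline()
    fs = json.loads(first.lstrip("# ").strip())["fs"] if first.startswith("#") else 300.0
    values = np.loadtxt(path, dtype=np.int8, delimiter="\t")
    return BinaryPatternSeries(values=values, fs=fs)


def save_model(path, params: MEMParams, report: FitReport | None = None,
               provenance: str | None = None) -> None:
    d = params.to_dict()
    if report is not None:
        d["fit_report"] = {
            "pearson_r": float(report.pearson_r),
            "kl_ratio": float(report.kl_ratio),
            "n_iterations": int(report.n_iterations),
            "converged": bool(report.converged),
            "max_moment_gap": float(report.max_moment_gap),
        }
    if provenance is not None:
        d["input_sha256"] = provenance
    Path(path).write_text(json.dumps(d, indent=1))


def load_model(path) -> MEMParams:
    return MEMParams.from_dict(json.loads(Path(path).read_text()))


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
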