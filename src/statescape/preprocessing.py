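"""Offline preprocessing: from raw multichannel signals to binary patterns.

The chain mirrors standard practice for envelope-based state tracking:
average re-reference, downsampling, broadband filtering, artifact-epoch
rejection on global field power, narrow-band filtering (gamma, 30-80 Hz
for the state pipeline), Hilbert envelope, spatial Hjorth derivation
per region (3 x centre electrode minus its three surrounding
electrodes) and binarisation of each region's envelope against its
temporal mean.  All filters are zero-phase (forward-backward), so
envelope timing is not delayed.

Independent component analysis is treated as an optional upstream
cleaning step outside this package; the chain ingests either raw or
pre-cleaned matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EnvelopeSeries",
    "BinaryPatternSeries",
    "PreprocessConfig",
    "rereference_and_filter",
    "artifact_epoch_mask",
    "bandpass",
    "hilbert_envelope",
    "hjorth_derive",
    "binarise",
    "preprocess_recording",
]

GAMMA_BAND = (30.0, 80.0)

#: named frequency bands computable with the same operations
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": GAMMA_BAND,
}


@dataclass
class EnvelopeSeries:
    """Non-negative amplitude envelopes, samples x regions."""

    values: np.ndarray
    fs: float
    band: tuple = GAMMA_BAND

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if (self.values < 0).any():
            raise ValueError("envelope amplitudes must be non-negative")


@dataclass
class BinaryPatternSeries:
    """Samples x regions matrix of +-1 activity with its thresholds."""

    values: np.ndarray
    fs: float
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("binary series must contain only +1 / -1")

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]

    def pattern_indices(self) -> np.ndarray:
        bits = ((self.values + 1) // 2).astype(np.int64)
        return bits @ (1 << np.arange(self.n_roi))


@dataclass
class PreprocessConfig:
    """Keys of the offline chain; defaults follow the study protocol."""

    target_fs: float = 300.0
    broad_band: tuple = (1.0, 80.0)
    band: tuple = GAMMA_BAND
    artifact_z: float = 5.0
    epoch_len: float = 1.0
    prewhiten: bool = False  # optional first-difference step before Hjorth


def _sos_bandpass(band: tuple, fs: float, order: int = 4):
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist of fs={fs}")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def rereference_and_filter(
    raw: np.ndarray,
    fs: float,
    target_fs: float = 300.0,
    band: tuple = (1.0, 80.0),
) -> tuple[np.ndarray, float]:
    """Average re-reference, resample to ``target_fs``, zero-phase band-pass.

    Each output channel is the input channel minus the per-sample mean
    across channels.  Returns ``(signals, target_fs)``.
    """
    x = np.asarray(raw, float)
    if target_fs > fs:
        raise ValueError("target_fs must not exceed the input rate")
    x = x - x.mean(axis=1, keepdims=True)
    if target_fs != fs:
        # rational resampling with an anti-aliasing FIR
        from fractions import Fraction

        frac = Fraction(target_fs / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=0)
    sos = _sos_bandpass(band, target_fs)
    x = sps.sosfiltfilt(sos, x, axis=0)
    return x, target_fs


def bandpass(signals: np.ndarray, fs: float, band: tuple = GAMMA_BAND) -> np.ndarray:
    """Zero-phase Butterworth band-pass of every channel."""
    sos = _sos_bandpass(band, fs)
    return sps.sosfiltfilt(sos, np.asarray(signals, float), axis=0)


def artifact_epoch_mask(
    signals: np.ndarray,
    fs: float,
    epoch_len: float = 1.0,
    z_thresh: float = 5.0,
) -> np.ndarray:
    """Per-epoch keep-mask from mean global field power.

    Epochs whose mean global field power exceeds
    ``mean + z_thresh * SD`` of the epoch powers are excluded.  Returns
    a boolean array with one entry per epoch (True = keep).
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    x = np.asarray(signals, float)
    n_ep = int(x.shape[0] // round(epoch_len * fs))
    if n_ep == 0:
        raise ValueError("recording shorter than one epoch")
    step = int(round(epoch_len * fs))
    gfp = np.array([
        np.mean(x[i * step:(i + 1) * step] ** 2) for i in range(n_ep)
    ])
    keep = gfp <= gfp.mean() + z_thresh * gfp.std()
    if not keep.any():
        raise ValueError("all epochs excluded by the artifact criterion")
    return keep


def expand_epoch_mask(keep: np.ndarray, fs: float, epoch_len: float, n_samples: int) -> np.ndarray:
    """Per-sample boolean mask from a per-epoch keep-mask."""
    step = int(round(epoch_len * fs))
    mask = np.ones(n_samples, bool)
    for i, k in enumerate(keep):
        if not k:
            mask[i * step:(i + 1) * step] = False
    # samples beyond the last full epoch inherit the last epoch's verdict
    if len(keep) * step < n_samples:
        mask[len(keep) * step:] = bool(keep[-1])
    return mask


def hilbert_envelope(band_signals: np.ndarray, fs: float, band: tuple = GAMMA_BAND) -> EnvelopeSeries:
    """Analytic-signal magnitude of already band-limited channels."""
    x = np.asarray(band_signals, float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    env = np.abs(sps.hilbert(x, axis=0))
    return EnvelopeSeries(values=env, fs=fs, band=band)


def hjorth_derive(centre: np.ndarray, neighbours: np.ndarray) -> np.ndarray:
    """Sum-of-difference spatial filter: ``3*centre - (n1 + n2 + n3)``.

    ``neighbours`` has the three surrounding-electrode series as
    columns (or rows of equal length).
    """
    c = np.asarray(centre, float)
    nb = np.asarray(neighbours, float)
    if nb.ndim != 2 or 3 not in nb.shape:
        raise ValueError("neighbours must hold exactly three series")
    if nb.shape[0] == 3 and nb.shape[1] != 3:
        nb = nb.T
    if nb.shape[0] != c.shape[0]:
        raise ValueError("centre and neighbour series differ in length")
    return 3.0 * c - nb.sum(axis=1)


def binarise(
    env: EnvelopeSeries | np.ndarray,
    thresholds: np.ndarray | None = None,
    fs: float | None = None,
) -> BinaryPatternSeries:
    """Per-region +-1 series: +1 where the envelope strictly exceeds its threshold.

    Without explicit thresholds each region's temporal mean is used
    (offline mode); online tracking supplies control-run means instead.
    A value exactly at threshold maps to -1, so constant signals map to
    all -1.
    """
    if isinstance(env, EnvelopeSeries):
        values, fs_ = env.values, env.fs
    else:
        values, fs_ = np.asarray(env, float), fs
        if fs_ is None:
            raise ValueError("fs required for plain arrays")
    if thresholds is None:
        thresholds = values.mean(axis=0)
    thresholds = np.asarray(thresholds, float)
    if not np.isfinite(thresholds).all():
        raise ValueError("non-finite thresholds")
    if thresholds.shape[0] != values.shape[1]:
        raise ValueError("one threshold per region required")
    # strict ">" with a relative guard so exact-threshold values (e.g. a
    # constant series against its own float-accumulated mean) map to -1
    margin = 1e-9 * np.maximum(1.0, np.abs(thresholds))
    binary = np.where(values - thresholds > margin, 1, -1).astype(np.int8)
    return BinaryPatternSeries(values=binary, fs=fs_, thresholds=thresholds)


def preprocess_recording(
    signals: np.ndarray,
    fs: float,
    channel_map: dict,
    config: PreprocessConfig | None = None,
    thresholds: np.ndarray | None = None,
) -> tuple[BinaryPatternSeries, EnvelopeSeries, np.ndarray]:
    """Full offline chain from a raw matrix to the binary pattern series.

    ``channel_map`` maps region index -> (centre_channel, [n1, n2, n3]).
    Returns the binary series, the per-region Hjorth envelopes and the
    per-sample artifact keep-mask (already applied to the outputs).
    """
    cfg = config or PreprocessConfig()
    x, fs2 = rereference_and_filter(signals, fs, cfg.target_fs, cfg.broad_band)
    keep_ep = artifact_epoch_mask(x, fs2, cfg.epoch_len, cfg.artifact_z)
    mask = expand_epoch_mask(keep_ep, fs2, cfg.epoch_len, x.shape[0])
    g = bandpass(x, fs2, cfg.band)
    env_all = hilbert_envelope(g, fs2, cfg.band).values
    if cfg.prewhiten:
        env_all = np.vstack([env_all[:1] * 0, np.diff(env_all, axis=0)])
    n_roi = len(channel_map)
    roi_env = np.empty((env_all.shape[0], n_roi))
    for r in range(n_roi):
        centre, nbs = channel_map[r]
        h = hjorth_derive(env_all[:, centre], env_all[:, list(nbs)])
        roi_env[:, r] = h
    # Hjorth of envelopes can dip below zero; amplitudes are rectified
    roi_env = np.clip(roi_env, 0.0, None)
    roi_env = roi_env[mask]
    env = EnvelopeSeries(values=roi_env, fs=fs2, band=cfg.band)
    series = binarise(env, thresholds=thresholds)
    return series, env, mask
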