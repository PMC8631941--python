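"""Deterministic simulator of the closed-loop state-dependent trigger.

The online pipeline re-implements, sample for sample, the real-time
analysis that drives state-dependent stimulation: the 28-channel input
is collapsed to seven Hjorth signals; a sliding 1000 ms window (2000
points at 2 kHz) is gamma-masked in the frequency domain; the Hilbert
envelope is computed and 100 ms trimmed at both edges; a Yule-Walker
autoregressive model (order 30) forecasts 280 ms of envelope beyond the
trimmed edge, covering T = -100 ... +180 ms around the true recording
end; the forecast is binarised against control-run thresholds,
classified through the offline major-state map, and temporally
smoothed, leaving states for T = -95 ... +175 ms.  A trigger fires when
the target state dominates the forthcoming T = 25 ... 175 ms span
(> 90 % of samples); history-dependent conditions additionally require
the preceding T = -95 ... 25 ms span to be dominated by the specified
prior state.  Honoured triggers are timestamped at window end + 21 ms
buffer and suppressed for 9 s after the previous one.

Hardware latencies and TTL signalling are not modelled; only their
timing bookkeeping is, so simulated trigger latency is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .dynamics import StateSequence, smooth_states
from .landscape import STATE_F, STATE_INT, STATE_V, MajorStateMap
from .preprocessing import binarise, hjorth_derive

__all__ = [
    "TrackerConfig",
    "TriggerEvent",
    "TriggerLog",
    "CONDITIONS",
    "window_envelope",
    "ar_forecast",
    "classify_forecast",
    "trigger_decision",
    "run_closed_loop",
    "evaluate_online",
    "control_thresholds",
]

#: trigger conditions: plain state-dependent and state-history-dependent
CONDITIONS = {
    "F": (STATE_F, None),
    "Int": (STATE_INT, None),
    "V": (STATE_V, None),
    "PostF_Int": (STATE_INT, STATE_F),
    "PostV_Int": (STATE_INT, STATE_V),
}


@dataclass
class TrackerConfig:
    """Timing and decision constants of the closed-loop tracker."""

    window_len: float = 1.0
    fs_online: float = 2000.0
    edge_trim: float = 0.100
    ar_order: int = 30
    forecast_len: float = 0.280
    decision_span: tuple = (0.025, 0.175)
    history_span: tuple = (-0.095, 0.025)
    dominance: float = 0.90
    trigger_buffer: float = 0.021
    refractory: float = 9.0
    burst_len: float = 0.150
    band: tuple = (30.0, 80.0)
    stride: float = 0.005
    smooth_window: float = 0.010
    smooth_fwhm: float = 0.010

    def __post_init__(self) -> None:
        if not 0.5 < self.dominance <= 1.0:
            raise ValueError("dominance must be in (0.5, 1]")
        # -100 ... +180 ms coverage: the forecast must reach the decision-span
        # end plus half the smoothing window, beyond the trimmed edge
        expected = self.edge_trim + self.decision_span[1] + self.smooth_window / 2
        if abs(self.forecast_len - expected) > 1e-9:
            raise ValueError(
                "forecast_len must equal edge_trim + decision span end + half "
                f"smoothing window ({expected:.3f} s)"
            )

    @property
    def n_window(self) -> int:
        return int(round(self.window_len * self.fs_online))

    @property
    def n_trim(self) -> int:
        return int(round(self.edge_trim * self.fs_online))

    @property
    def n_forecast(self) -> int:
        return int(round(self.forecast_len * self.fs_online))


@dataclass
class TriggerEvent:
    time: float
    condition: str
    evidence: float
    honoured: bool
    history_evidence: float | None = None


@dataclass
class TriggerLog:
    events: list = field(default_factory=list)
    refractory: float = 9.0

    def honoured_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events if e.honoured])

    def append(self, event: TriggerEvent) -> None:
        self.events.append(event)


def window_envelope(window: np.ndarray, cfg: TrackerConfig) -> np.ndarray:
    """Gamma envelope of one analysis window, edges trimmed.

    ``window`` is ``(n_window, n_roi)`` of Hjorth signals.  The
    frequency-domain mask keeps 30-80 Hz of the windowed transform; the
    analytic signal is built directly in the frequency domain and the
    envelope trimmed by ``edge_trim`` on both sides (1000 ms -> 800 ms).
    """
    x = np.asarray(window, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != cfg.n_window:
        raise ValueError(f"window must have exactly {cfg.n_window} samples")
    n = x.shape[0]
    freqs = np.fft.fftfreq(n, 1.0 / cfg.fs_online)
    spec = np.fft.fft(x, axis=0)
    lo, hi = cfg.band
    keep = (freqs >= lo) & (freqs <= hi)   # positive band only -> analytic
    spec[~keep] = 0.0
    analytic = 2.0 * np.fft.ifft(spec, axis=0)
    env = np.abs(analytic)
    t = cfg.n_trim
    return env[t:n - t]


def _yule_walker(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients from sample autocovariances (Levinson via Toeplitz solve).

    ``x`` must already be demeaned.  Raises ``numpy.linalg.LinAlgError``
    on a singular (e.g. constant-signal) autocovariance sequence.
    """
    n = len(x)
    r = np.array([x[: n - k] @ x[k:] for k in range(order + 1)]) / n
    if r[0] <= 0:
        raise np.linalg.LinAlgError("zero-variance signal")
    try:
        return solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        raise
    except Exception as exc:  # scipy raises its own error type on singularity
        raise np.linalg.LinAlgError(str(exc))


def ar_forecast(envelope: np.ndarray, cfg: TrackerConfig) -> np.ndarray:
    """Yule-Walker AR forward prediction of each region's envelope.

    Coefficients come from the autocovariances of the trimmed 800 ms
    envelope (order 30); the recursion is run ``forecast_len`` ahead.
    A singular autocovariance matrix falls back to mean prediction with
    a warning.
    """
    x = np.asarray(envelope, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < cfg.ar_order + 1:
        raise ValueError("envelope shorter than the AR order")
    horizon = cfg.n_forecast
    out = np.empty((horizon, x.shape[1]))
    for r in range(x.shape[1]):
        series = x[:, r]
        mean = series.mean()
        centred = series - mean
        try:
            rho = _yule_walker(centred, cfg.ar_order)
            if not np.isfinite(rho).all():
                raise np.linalg.LinAlgError("non-finite AR coefficients")
            a_poly = np.concatenate(([1.0], -rho))
            zi = sps.lfiltic([1.0], a_poly, centred[::-1][: cfg.ar_order])
            pred, _ = sps.lfilter([1.0], a_poly, np.zeros(horizon), zi=zi)
            out[:, r] = pred + mean
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular autocovariance for region {r}; using mean prediction",
                RuntimeWarning,
                stacklevel=2,
            )
            out[:, r] = mean
    return out


def classify_forecast(
    forecast: np.ndarray,
    thresholds: np.ndarray,
    major_map: MajorStateMap,
    cfg: TrackerConfig,
) -> tuple[StateSequence, float]:
    """Binarise, classify and smooth a forecast envelope block.

    Returns the smoothed predicted state sequence and the time of its
    first sample relative to the true recording end of the window
    (``-forecast_len + edge_trim + smooth_window/2``; -95 ms with the
    defaults, the sequence then extends to +175 ms).
    """
    series = binarise(np.clip(forecast, 0.0, None), thresholds=thresholds, fs=cfg.fs_online)
    from .dynamics import label_states  # local import avoids a cycle at module load

    seq = label_states(series.pattern_indices(), major_map, dt=1.0 / cfg.fs_online,
                       origin="online_predicted")
    sm = smooth_states(seq, window=cfg.smooth_window, fwhm=cfg.smooth_fwhm)
    half = int(round(cfg.smooth_window / 2 * cfg.fs_online))
    labels = sm.labels[half:len(sm) - half]
    # the forecast starts at the trimmed-data edge (T = -edge_trim) and the
    # smoothing trim advances the first valid sample by half a window
    t0 = -cfg.edge_trim + half / cfg.fs_online
    return (
        StateSequence(labels=labels, dt=sm.dt, origin="online_predicted", smoothed=True),
        t0,
    )


def trigger_decision(
    pred: StateSequence,
    t0: float,
    condition: str,
    last_trigger_time: float | None,
    window_end_time: float,
    cfg: TrackerConfig,
) -> TriggerEvent | None:
    """Dominance + history + refractory logic for one window.

    ``pred`` spans ``t0 ... t0 + len*dt`` relative to the window end.
    Returns an event when the dominance rule is satisfied (honoured or
    suppressed by the refractory period), else None.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    target, history = CONDITIONS[condition]
    times = t0 + np.arange(len(pred)) * pred.dt
    dec = (times >= cfg.decision_span[0]) & (times < cfg.decision_span[1])
    if not dec.any():
        raise ValueError("prediction does not cover the decision span")
    evidence = float(np.mean(pred.labels[dec] == target))
    hist_evidence = None
    fire = evidence > cfg.dominance
    if history is not None:
        his = (times >= cfg.history_span[0]) & (times < cfg.history_span[1])
        hist_evidence = float(np.mean(pred.labels[his] == history))
        fire = fire and hist_evidence > cfg.dominance
    if not fire:
        return None
    t_trigger = window_end_time + cfg.trigger_buffer
    honoured = last_trigger_time is None or (t_trigger - last_trigger_time) >= cfg.refractory
    return TriggerEvent(
        time=t_trigger,
        condition=condition,
        evidence=evidence,
        honoured=honoured,
        history_evidence=hist_evidence,
    )


def control_thresholds(hjorth: np.ndarray, cfg: TrackerConfig) -> np.ndarray:
    """Per-region mean gamma envelope of a control run (binarisation thresholds)."""
    n = cfg.n_window
    step = max(1, int(round(cfg.stride * cfg.fs_online)))
    sums = np.zeros(hjorth.shape[1])
    count = 0
    for start in range(0, hjorth.shape[0] - n + 1, step):
        env = window_envelope(hjorth[start:start + n], cfg)
        sums += env.mean(axis=0)
        count += 1
    if count == 0:
        raise ValueError("control recording shorter than one window")
    return sums / count


def hjorth_channels(signals: np.ndarray, channel_map: dict) -> np.ndarray:
    """Collapse raw channels to one Hjorth signal per region."""
    n_roi = len(channel_map)
    out = np.empty((signals.shape[0], n_roi))
    for r in range(n_roi):
        centre, nbs = channel_map[r]
        out[:, r] = hjorth_derive(signals[:, centre], signals[:, list(nbs)])
    return out


def run_closed_loop(
    recording,
    condition: str,
    cfg: TrackerConfig,
    major_map: MajorStateMap,
    thresholds: np.ndarray,
) -> tuple[TriggerLog, StateSequence, int]:
    """Slide the tracker across a recording; returns log + online labels.

    ``recording`` is a :class:`~statescape.synthetic.SyntheticRecording`
    or any object with ``signals``, ``fs`` and ``channel_map``.  The
    window advances by ``cfg.stride``; each position contributes its
    predicted label at T = +25 ms ... +25 ms + stride to the online
    state stream (the start of the actionable decision span), so the
    stream is aligned with the recording's own time base.  Returns the
    trigger log, the online state sequence and the index of its first
    sample in the recording.
    """
    if recording.fs != cfg.fs_online:
        raise ValueError("recording must be sampled at cfg.fs_online")
    x = np.asarray(recording.signals, float)
    n = cfg.n_window
    if x.shape[0] < n:
        raise ValueError("recording shorter than one analysis window")
    hj = hjorth_channels(x, recording.channel_map)
    step = max(1, int(round(cfg.stride * cfg.fs_online)))
    lead = int(round(cfg.decision_span[0] * cfg.fs_online))  # +25 ms
    log = TriggerLog(refractory=cfg.refractory)
    last_time = None
    online = []
    first_idx = n - 1 + lead
    for start in range(0, x.shape[0] - n + 1, step):
        end = start + n
        env = window_envelope(hj[start:end], cfg)
        pred = ar_forecast(env, cfg)
        seq, t0 = classify_forecast(pred, thresholds, major_map, cfg)
        end_time = end / cfg.fs_online
        ev = trigger_decision(seq, t0, condition, last_time, end_time, cfg)
        if ev is not None:
            log.append(ev)
            if ev.honoured:
                last_time = ev.time
        # labels for the stride-length segment just entering the actionable
        # span; consecutive windows tile a contiguous stream at fs_online
        k0 = int(round((cfg.decision_span[0] - t0) * cfg.fs_online))
        online.extend(seq.labels[k0:k0 + step])
    seq_online = StateSequence(
        labels=np.array(online, dtype=np.int8),
        dt=1.0 / cfg.fs_online,
        origin="online_predicted",
        smoothed=True,
    )
    return log, seq_online, first_idx


def evaluate_online(
    online: StateSequence,
    offline: StateSequence,
    log: TriggerLog | None = None,
    cfg: TrackerConfig | None = None,
) -> dict:
    """Agreement, trigger accuracy and latency of an online run.

    ``online`` and ``offline`` must share a time base (the caller
    aligns them; see :func:`run_closed_loop` for the online stream's
    start index).  Per-state agreement is the fraction of
    offline-labelled samples of each state that the online stream
    labels identically.  Trigger accuracy is the fraction of honoured
    triggers whose target state holds throughout the burst according to
    the offline labels.  In simulation the trigger latency error is
    exactly zero and reported as such.
    """
    if len(online) != len(offline):
        raise ValueError("sequences must be aligned to the same length")
    agreement = {}
    for s, name in ((STATE_F, "F"), (STATE_INT, "Int"), (STATE_V, "V")):
        mask = offline.labels == s
        agreement[name] = float(np.mean(online.labels[mask] == s)) if mask.any() else float("nan")
    out = {"agreement": agreement, "overall_agreement": float(np.mean(online.labels == offline.labels))}
    if log is not None and cfg is not None:
        honoured = [e for e in log.events if e.honoured]
        correct = 0
        for e in honoured:
            target, _ = CONDITIONS[e.condition]
            a = int(round(e.time / offline.dt))
            b = int(round((e.time + cfg.burst_len) / offline.dt))
            b = min(b, len(offline))
            if a >= len(offline):
                continue
            if (offline.labels[a:b] == target).all():
                correct += 1
        out["trigger_accuracy"] = correct / len(honoured) if honoured else float("nan")
        out["n_triggers"] = len(honoured)
        out["latency_error"] = 0.0
    return out
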