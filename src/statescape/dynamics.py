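"""Brain-state dynamics: Metropolis walks, labelling, smoothing, statistics.

The random walk moves on the hypercube of activity patterns: at each
step one of the ``N`` single-flip neighbours is proposed uniformly and
accepted with probability ``min(1, exp(E_current - E_proposed))``
(Metropolis rule); a rejected proposal repeats the current pattern for
one step.  The stationary distribution is the Boltzmann distribution of
the underlying MEM, so dwelling times and transition frequencies of the
walk characterise the model-implied state dynamics.

Walk trajectories are expressed in steps.  One step is treated as one
sample of the offline recording (300 Hz), so the 10 ms temporal
smoothing of empirical state sequences translates to a 3-step window on
simulated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .landscape import (
    STATE_F,
    STATE_INT,
    STATE_OTHER,
    STATE_V,
    EnergyLandscape,
    MajorStateMap,
    enumerate_landscape,
)
from .mem import MEMParams

__all__ = [
    "StateSequence",
    "DynamicsSummary",
    "TravelResult",
    "WALK_DT",
    "metropolis_walk",
    "label_states",
    "smooth_states",
    "dynamics_summary",
    "travel_length",
]

#: seconds per walk step: one step emulates one offline sample at 300 Hz
WALK_DT = 1.0 / 300.0

#: FWHM -> standard deviation for a Gaussian
_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class StateSequence:
    """Time series of major-state codes (0=F, 1=Int, 2=V, 3=Other)."""

    labels: np.ndarray
    dt: float
    origin: str = "offline"  # offline | online_predicted | random_walk
    smoothed: bool = False

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.dt


@dataclass
class DynamicsSummary:
    """Dwelling times and between-state transition statistics."""

    dwell: dict                 # state code -> mean dwelling time (seconds)
    transitions: np.ndarray     # 3x3 counts between distinct major states
    transition_freq: np.ndarray  # row-normalised, diagonal excluded
    n_transitions: int
    direct_fv_share: float      # fraction of transitions that are F<->V


@dataclass
class TravelResult:
    mean_steps: float
    n_cycles: int
    defined: bool


def metropolis_walk(
    model: MEMParams | EnergyLandscape,
    n_steps: int = 100_000,
    burn_in: int = 100,
    seed: int | None = None,
    start: int | None = None,
) -> np.ndarray:
    """Metropolis random walk; returns full-space pattern indices.

    The first ``burn_in`` steps are discarded to wash out the random
    initial pattern.  On a restricted landscape, proposals towards
    removed patterns are invalid moves and repeat the current pattern.
    """
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    ls = model if isinstance(model, EnergyLandscape) else enumerate_landscape(model)
    e = ls.energies
    nb = ls.neighbors
    n = ls.n_roi
    rng = np.random.default_rng(seed)
    # acceptance probability for every (node, flip) pair, 0 for removed
    with np.errstate(over="ignore"):
        acc = np.exp(np.clip(e[:, None] - np.where(nb >= 0, e[np.clip(nb, 0, None)], np.inf), None, 0.0))
    acc[nb < 0] = 0.0
    choices = rng.integers(0, n, size=n_steps)
    uniforms = rng.random(n_steps)
    cur = int(rng.integers(0, len(e))) if start is None else int(start)
    traj = np.empty(n_steps, dtype=np.int64)
    acc_l = acc  # local bindings for speed
    nb_l = nb
    for t in range(n_steps):
        c = choices[t]
        if uniforms[t] < acc_l[cur, c]:
            cur = int(nb_l[cur, c])
        traj[t] = cur
    return ls.patterns[traj[burn_in:]]


def label_states(
    patterns,
    major_map: MajorStateMap,
    dt: float = WALK_DT,
    origin: str = "random_walk",
) -> StateSequence:
    """Classify a pattern trajectory or binary series into major states."""
    if hasattr(patterns, "values"):  # BinaryPatternSeries
        series = patterns
        v = np.asarray(series.values)
        n = v.shape[1]
        idx = ((v + 1) // 2).astype(np.int64) @ (1 << np.arange(n))
        dt = 1.0 / series.fs
        origin = "offline"
    else:
        idx = np.asarray(patterns, dtype=np.int64)
    labels = major_map.labels_for(idx)
    return StateSequence(labels=labels, dt=dt, origin=origin)


def smooth_states(
    seq: StateSequence,
    window: float = 0.010,
    fwhm: float = 0.010,
) -> StateSequence:
    """Sliding-window appearance frequency + Gaussian smoothing + argmax.

    For each of F, Int and V, the appearance frequency in a centred
    sliding window (Other counts in the denominator only) is smoothed
    with a Gaussian of the given FWHM; the most frequent state is then
    assigned per sample, so the output never contains Other.  Argmax
    ties resolve to the earlier state in the fixed order (F, Int, V).
    """
    n_win = max(1, int(round(window / seq.dt)))
    if len(seq) < n_win:
        raise ValueError("sequence shorter than the smoothing window")
    sd = (fwhm / seq.dt) / _FWHM_TO_SD
    kernel = np.ones(n_win) / n_win
    curves = np.empty((3, len(seq)))
    for s in (STATE_F, STATE_INT, STATE_V):
        freq = np.convolve((seq.labels == s).astype(float), kernel, mode="same")
        curves[s] = gaussian_filter1d(freq, sd, mode="nearest") if sd > 0 else freq
    labels = np.argmax(curves, axis=0).astype(np.int8)  # ties -> F < Int < V
    return StateSequence(labels=labels, dt=seq.dt, origin=seq.origin, smoothed=True)


def _runs(labels: np.ndarray):
    """Run-length encoding: (state, length) pairs."""
    change = np.where(labels[1:] != labels[:-1])[0] + 1
    bounds = np.concatenate(([0], change, [len(labels)]))
    return [(int(labels[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


def dynamics_summary(
    seq: StateSequence,
    analysis_window: tuple[float, float] | None = None,
) -> DynamicsSummary:
    """Dwelling times and transition counts of a smoothed state sequence.

    ``analysis_window`` restricts the sequence to ``[start, end)``
    seconds from its first sample (used e.g. for post-stimulation
    windows).
    """
    labels = seq.labels
    if analysis_window is not None:
        a = int(round(analysis_window[0] / seq.dt))
        b = int(round(analysis_window[1] / seq.dt))
        labels = labels[a:b]
        if len(labels) == 0:
            raise ValueError("empty analysis window")
    if (labels == STATE_OTHER).any():
        raise ValueError("dynamics_summary expects a smoothed sequence without Other")
    runs = _runs(labels)
    dwell_acc: dict[int, list[int]] = {STATE_F: [], STATE_INT: [], STATE_V: []}
    for s, length in runs:
        dwell_acc[s].append(length)
    dwell = {
        s: (float(np.mean(v)) * seq.dt if v else float("nan"))
        for s, v in dwell_acc.items()
    }
    trans = np.zeros((3, 3), dtype=np.int64)
    for (s1, _), (s2, _) in zip(runs[:-1], runs[1:]):
        trans[s1, s2] += 1
    row = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(row > 0, trans / row, 0.0)
    n_tr = int(trans.sum())
    direct = (trans[STATE_F, STATE_V] + trans[STATE_V, STATE_F]) / n_tr if n_tr else 0.0
    return DynamicsSummary(
        dwell=dwell,
        transitions=trans,
        transition_freq=freq,
        n_transitions=n_tr,
        direct_fv_share=float(direct),
    )


def travel_length(seq: StateSequence) -> TravelResult:
    """Mean number of steps per completed F -> Int -> V -> Int -> F cycle.

    A cycle starts when the sequence enters F and completes at the first
    return to F after V has been visited; its length is the number of
    steps between start and completion (back-and-forth moves included).
    With no completed cycle the result is flagged undefined.
    """
    labels = seq.labels
    lengths = []
    start = None
    seen_v = False
    for t, s in enumerate(labels):
        if s == STATE_F:
            if start is None:
                start = t
            elif seen_v:
                lengths.append(t - start)
                start, seen_v = t, False
        elif s == STATE_V:
            seen_v = True
    if not lengths:
        return TravelResult(mean_steps=float("nan"), n_cycles=0, defined=False)
    return TravelResult(mean_steps=float(np.mean(lengths)), n_cycles=len(lengths), defined=True)
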