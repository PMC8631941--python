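"""Behavioural metrics and the landscape-dynamics-behaviour linkage chain.

Perceptual stability is summarised by the median duration of clear
(non-mixed) percepts; stimulation effects as the proportional change
``(stimulated - control) / control``; prediction quality as the mean
absolute percentage error (MAPE).  The causal chain — landscape change
X affects state dynamics M which affects behaviour Y — is tested with a
standard product-of-coefficients mediation analysis: alpha from
``M ~ X``, beta and gamma' from ``Y ~ X + M``, gamma from ``Y ~ X``,
indirect effect ``alpha * beta`` with a percentile bootstrap CI.  The
time course of an effect is profiled with the absolute Fisher-z
transformed correlation per sliding analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PerceptEvent",
    "PerceptRecord",
    "MediationResult",
    "median_percept_duration",
    "proportional_change",
    "mape",
    "decay_profile",
    "mediate",
    "cohens_d",
]


@dataclass
class PerceptEvent:
    onset: float
    offset: float
    percept: str  # up | down | mixed

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PerceptRecord:
    run_id: str
    events: list

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(ev[:-1], ev[1:]):
            if a.offset > b.onset + 1e-12:
                raise ValueError("percept events overlap")
        self.events = ev


@dataclass
class MediationResult:
    alpha: float
    beta: float
    gamma: float
    gamma_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int


def median_percept_duration(record: PerceptRecord) -> float:
    """Median duration of clear percepts; mixed periods are excluded."""
    durations = [e.duration for e in record.events if e.percept != "mixed"]
    if not durations:
        raise ValueError("no clear-percept events")
    return float(np.median(durations))


def proportional_change(stimulated: float, control: float) -> float:
    """(stimulated - control) / control."""
    if control <= 0:
        raise ValueError("control duration must be positive")
    return (stimulated - control) / control


def mape(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean absolute percentage error, in percent."""
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have equal length")
    if (o == 0).any():
        raise ValueError("observations must be non-zero")
    return float(np.mean(np.abs(p - o) / np.abs(o)) * 100.0)


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with an intercept column prepended."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("collinear design in mediation regression")
    return coef


def mediate(
    X: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 5000,
    seed: int | None = None,
    ci: float = 95.0,
) -> MediationResult:
    """OLS product-of-coefficients mediation with percentile bootstrap.

    alpha: X -> M; beta: M -> Y adjusted for X; gamma: total X -> Y;
    gamma_prime: direct X -> Y adjusted for M.  For linear models
    ``gamma = gamma_prime + alpha * beta`` exactly.
    """
    X, M, Y = (np.asarray(v, float) for v in (X, M, Y))
    if not (len(X) == len(M) == len(Y)) or len(X) < 10:
        raise ValueError("X, M, Y must share a length of at least 10")

    def paths(x, m, y):
        alpha = _ols(m, x[:, None])[1]
        b = _ols(y, np.column_stack([x, m]))
        gamma_prime, beta = b[1], b[2]
        gamma = _ols(y, x[:, None])[1]
        return alpha, beta, gamma, gamma_prime

    alpha, beta, gamma, gamma_prime = paths(X, M, Y)
    rng = np.random.default_rng(seed)
    idxs = rng.integers(0, len(X), size=(n_boot, len(X)))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        k = idxs[i]
        try:
            a, b, _, _ = paths(X[k], M[k], Y[k])
            boots[i] = a * b
        except ValueError:
            boots[i] = np.nan
    lo, hi = np.nanpercentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return MediationResult(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        gamma_prime=float(gamma_prime),
        indirect=float(alpha * beta),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def decay_profile(
    effect_by_window: np.ndarray,
    barrier_deltas: np.ndarray,
    window_starts: np.ndarray | None = None,
) -> np.ndarray:
    """|Fisher z| of the across-participant correlation per window start.

    ``effect_by_window`` is ``(n_windows, n_participants)``; each row is
    correlated with the per-participant barrier changes and the absolute
    Fisher-transformed coefficient returned per window.
    """
    eff = np.asarray(effect_by_window, float)
    bd = np.asarray(barrier_deltas, float)
    if eff.ndim != 2 or eff.shape[1] != len(bd):
        raise ValueError("effect matrix must be (n_windows, n_participants)")
    if len(bd) < 3:
        raise ValueError("at least 3 participants required")
    if np.std(bd) == 0:
        raise ValueError("degenerate barrier-change variance")
    out = np.empty(eff.shape[0])
    for i, row in enumerate(eff):
        if np.std(row) == 0:
            raise ValueError(f"degenerate effect variance in window {i}")
        r = float(np.corrcoef(row, bd)[0, 1])
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        out[i] = abs(np.arctanh(r))
    return out


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with a pooled standard deviation (convenience utility)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp)
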