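"""Pairwise maximum-entropy (Ising) modelling of binary activity patterns.

An activity pattern of ``N`` regions is a vector ``V = (s_1, ..., s_N)``
with ``s_i = +1`` (active) or ``-1`` (inactive).  The pairwise
maximum-entropy model (MEM) assigns each pattern the energy

    E(V) = - sum_i h_i s_i - 1/2 sum_ij J_ij s_i s_j

and the Boltzmann appearance probability ``P(V) = exp(-E(V)) / Z``.
``h_i`` is the basal activity of region *i* and ``J_ij`` the pairwise
coupling between regions *i* and *j* (``J`` symmetric, zero diagonal).
The parameters are fitted by moment matching: gradient ascent on the
log-likelihood until the model means ``<s_i>_m`` and correlations
``<s_i s_j>_m`` match their empirical counterparts.

Pattern indexing convention, shared by every module in this package:
pattern -> integer with bits ``b_i = (s_i + 1) / 2`` and region 0 as the
least-significant bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MEMParams",
    "PatternDistribution",
    "FitReport",
    "all_patterns",
    "pattern_index",
    "pattern_from_index",
    "pattern_energy",
    "boltzmann_distribution",
    "empirical_moments",
    "fit_pairwise_mem",
    "fit_quality",
    "independent_fit",
]

#: exact enumeration guard: 2**20 patterns is the largest space we enumerate
MAX_ENUM_N = 20

#: clip for atanh of degenerate empirical means
_ATANH_CLIP = 1.0 - 1e-9


@dataclass
class MEMParams:
    """Basal activities ``h`` (length N) and couplings ``J`` (N x N)."""

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError(f"J must be {n}x{n}, got {self.J.shape}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have a zero diagonal")

    @property
    def n_roi(self) -> int:
        return self.h.shape[0]

    def to_dict(self) -> dict:
        return {"h": self.h.tolist(), "J": self.J.tolist(), "n_roi": self.n_roi}

    @classmethod
    def from_dict(cls, d: dict) -> "MEMParams":
        return cls(h=np.array(d["h"], float), J=np.array(d["J"], float))


@dataclass
class PatternDistribution:
    """Energies and Boltzmann probabilities over all ``2**N`` patterns."""

    probs: np.ndarray
    energies: np.ndarray


@dataclass
class FitReport:
    """Goodness-of-fit summary for a fitted pairwise MEM.

    ``kl_ratio`` is ``(D1 - D2) / D1`` where ``D1``/``D2`` are the KL
    divergences of the empirical pattern distribution from the
    independent (first-order) and pairwise (second-order) models.
    ``pearson_r`` correlates model probabilities with empirical pattern
    frequencies.
    """

    pearson_r: float
    kl_ratio: float
    n_iterations: int
    converged: bool
    max_moment_gap: float
    d1: float = float("nan")
    d2: float = float("nan")
    degenerate_first_order: bool = False


_PATTERN_CACHE: dict[int, np.ndarray] = {}


def all_patterns(n_roi: int) -> np.ndarray:
    """All ``2**n_roi`` patterns as a ``(2**N, N)`` array of +-1.

    Row ``k`` is the pattern whose index is ``k`` under the package's
    bit convention (region 0 = least-significant bit).
    """
    if n_roi > MAX_ENUM_N:
        raise ValueError(f"refusing to enumerate 2**{n_roi} patterns")
    if n_roi not in _PATTERN_CACHE:
        k = np.arange(2**n_roi)
        bits = (k[:, None] >> np.arange(n_roi)) & 1
        pats = (2 * bits - 1).astype(np.int8)
        pats.setflags(write=False)
        _PATTERN_CACHE[n_roi] = pats
    return _PATTERN_CACHE[n_roi]

def pattern_index(pattern: np.ndarray) -> int:
    """Integer index of a single +-1 pattern."""
    bits = (np.asarray(pattern) + 1) // 2
    return int(np.sum(bits * (1 << np.arange(len(bits)))))


def pattern_from_index(k: int, n_roi: int) -> np.ndarray:
    bits = (k >> np.arange(n_roi)) & 1
    return (2 * bits - 1).astype(np.int8)


def _check_patterns(x: np.ndarray, n_roi: int | None = None) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 1:
        x = x[None, :]
    if n_roi is not None and x.shape[1] != n_roi:
        raise ValueError(f"pattern length {x.shape[1]} != N={n_roi}")
    if not np.isin(x, (-1, 1)).all():
        raise ValueError("patterns must contain only +1 / -1")
    return x


def pattern_energy(params: MEMParams, pattern: np.ndarray) -> float | np.ndarray:
    """Energy ``-h.s - 1/2 s.J.s`` of one pattern or a stack of patterns."""
    p = np.asarray(pattern)
    single = p.ndim == 1
    s = _check_patterns(p, params.n_roi).astype(float)
    e = -(s @ params.h) - 0.5 * np.einsum("ki,ij,kj->k", s, params.J, s)
    return float(e[0]) if single else e


def boltzmann_distribution(params: MEMParams) -> PatternDistribution:
    """Exact Boltzmann distribution over all ``2**N`` patterns."""
    s = all_patterns(params.n_roi).astype(float)
    e = -(s @ params.h) - 0.5 * np.einsum("ki,ij,kj->k", s, params.J, s)
    if not np.isfinite(e).all():
        raise FloatingPointError("non-finite energies")
    logz = logsumexp(-e)
    return PatternDistribution(probs=np.exp(-e - logz), energies=e)


def empirical_moments(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-averaged ``<s_i>``, ``<s_i s_j>`` and pattern frequencies.

    ``series`` is a ``BinaryPatternSeries`` or a plain ``(T, N)`` +-1
    array.  Frequencies cover all ``2**N`` patterns (zeros allowed).
    """
    values = getattr(series, "values", series)
    v = _check_patterns(values).astype(float)
    if v.shape[0] == 0:
        raise ValueError("empty series")
    n = v.shape[1]
    means = v.mean(axis=0)
    corr = (v.T @ v) / v.shape[0]
    idx = ((v + 1) / 2).astype(np.int64) @ (1 << np.arange(n))
    freqs = np.bincount(idx, minlength=2**n) / v.shape[0]
    return means, corr, freqs


def _model_moments(params: MEMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = all_patterns(params.n_roi).astype(float)
    p = boltzmann_distribution(params).probs
    return p @ s, (s * p[:, None]).T @ s, p


def independent_fit(means: np.ndarray) -> MEMParams:
    """Closed-form first-order model: ``J = 0``, ``h_i = atanh(<s_i>)``."""
    h = np.arctanh(np.clip(means, -_ATANH_CLIP, _ATANH_CLIP))
    n = len(h)
    return MEMParams(h=h, J=np.zeros((n, n)))


def fit_pairwise_mem(
    series,
    learning_rate: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 100_000,
    strict: bool = False,
) -> tuple[MEMParams, FitReport]:
    """Fit ``h``, ``J`` by gradient ascent with exact-enumeration moments.

    Updates ``h_i += eta (<s_i> - <s_i>_m)`` and
    ``J_ij += eta (<s_i s_j> - <s_i s_j>_m)`` until the largest moment
    gap falls below ``tol``.  The step size decays geometrically when
    the gradient starts oscillating, which keeps plain ascent stable.
    """
    emp_m, emp_c, freqs = empirical_moments(series)
    if (freqs > 0).sum() < 2:
        raise ValueError("series is degenerate: fewer than 2 distinct patterns")
    n = len(emp_m)
    h = np.zeros(n)
    J = np.zeros((n, n))
    eta = learning_rate
    prev_gh = None
    gap = np.inf
    it = 0
    s = all_patterns(n).astype(float)
    for it in range(1, max_iter + 1):
        e = -(s @ h) - 0.5 * np.einsum("ki,ij,kj->k", s, J, s)
        w = np.exp(-(e - e.min()))
        p = w / w.sum()
        mod_m = p @ s
        mod_c = (s * p[:, None]).T @ s
        gh = emp_m - mod_m
        gJ = emp_c - mod_c
        np.fill_diagonal(gJ, 0.0)
        gap = max(np.abs(gh).max(), np.abs(gJ).max())
        if gap < tol:
            break
        if prev_gh is not None and float(gh @ prev_gh) < 0:
            eta = max(eta * 0.9, 1e-3)
        prev_gh = gh
        h = h + eta * gh
        J = J + eta * gJ
    converged = gap < tol
    if strict and not converged:
        raise RuntimeError(f"moment matching did not converge (gap={gap:.2e})")
    params = MEMParams(h=h, J=J)
    report = fit_quality(params, series)
    report.n_iterations = it
    report.converged = converged
    report.max_moment_gap = float(gap)
    return params, report


def fit_quality(params: MEMParams, series) -> FitReport:
    """KL-ratio ``(D1 - D2)/D1`` and probability correlation of a fit.

    ``D1`` / ``D2`` are KL divergences of the empirical distribution
    from the first-order (independent) and the given pairwise model,
    with empirical zeros contributing zero (``0 log 0 = 0``).
    """
    emp_m, _, freqs = empirical_moments(series)
    p2 = boltzmann_distribution(params).probs
    p1 = boltzmann_distribution(independent_fit(emp_m)).probs
    nz = freqs > 0
    d1 = float(np.sum(freqs[nz] * np.log(freqs[nz] / p1[nz])))
    d2 = float(np.sum(freqs[nz] * np.log(freqs[nz] / p2[nz])))
    degenerate = d1 <= 0.0
    kl_ratio = 0.0 if degenerate else (d1 - d2) / d1
    r = float(np.corrcoef(p2, freqs)[0, 1])
    return FitReport(
        pearson_r=r,
        kl_ratio=float(kl_ratio),
        n_iterations=0,
        converged=True,
        max_moment_gap=float("nan"),
        d1=d1,
        d2=d2,
        degenerate_first_order=degenerate,
    )
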