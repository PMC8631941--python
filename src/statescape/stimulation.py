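"""Virtual inhibitory stimulation as state-space restriction.

Inhibiting a region is modelled as complete silencing: every pattern in
which the target region is active (sigma = +1) is removed from the
state space, and the landscape machinery is re-run on the remaining
``2**(N-1)`` patterns with the *same* ``h`` and ``J``.  A removed major
minimum is represented by its surviving neighbour (the pattern
differing only at the target region); the restricted basin containing
that neighbour inherits the major-state label.  The change in the four
directional barriers between F, Int and V (F->Int, Int->F, Int->V,
V->Int) and in the ratio of the Int->F to the Int->V barrier summarise
how the stimulation reshapes the landscape, and hence the expected
state dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import (
    STATE_F,
    STATE_INT,
    STATE_V,
    EnergyLandscape,
    MajorStateMap,
    analyze_landscape,
    assign_basins,
    build_disconnectivity,
    coarse_grain,
    enumerate_landscape,
    major_barriers,
)
from .mem import MEMParams

__all__ = ["RestrictionResult", "restrict_landscape", "remap_major_states",
           "barrier_change_stats", "virtual_stimulation", "graded_inhibition"]


@dataclass
class RestrictionResult:
    target_roi: int
    restricted_landscape: EnergyLandscape
    remapped_majors: MajorStateMap
    barrier_deltas: dict          # (state_a, state_b) -> post - pre, None if undefined
    barrier_ratio_delta: float    # change in (Int->F)/(Int->V)
    pre_barriers: dict
    post_barriers: dict


def restrict_landscape(params: MEMParams, target_roi: int) -> EnergyLandscape:
    """Landscape over the patterns with the target region silenced.

    The kept set is the ``2**(N-1)`` patterns with sigma_target = -1;
    their energies are identical to the full-landscape energies (same
    ``h``, ``J``), and adjacency is single-flip among the remaining
    regions.
    """
    n = params.n_roi
    if not 0 <= target_roi < n:
        raise ValueError(f"invalid region index {target_roi}")
    full = np.arange(2**n)
    keep = (full >> target_roi) & 1 == 0
    ls = enumerate_landscape(params, keep=keep)
    assign_basins(ls)
    build_disconnectivity(ls)
    return ls


def remap_major_states(
    pre_map: MajorStateMap,
    restricted: EnergyLandscape,
    target_roi: int,
    barrier_threshold: float = 1.0,
) -> MajorStateMap:
    """Carry the pre-stimulation F/Int/V labels onto the restricted space.

    The restricted landscape is coarse-grained with the same rule; each
    major state's label then attaches to the restricted basin that
    contains its representative minimum, or — if that minimum was
    removed (it had sigma_target = +1) — the basin containing the
    neighbouring pattern that differs from it only at the target
    region.  Raises if two major labels collapse onto one restricted
    basin.
    """
    mm = coarse_grain(restricted, barrier_threshold=barrier_threshold)
    # positions of restricted basins: use basin roots after coarse-graining as
    # group identity; simplest faithful route: label per node already in mm,
    # but we override names using the pre-map representatives.
    pos = np.full(int(restricted.patterns.max()) + 1, -1, dtype=np.int64)
    pos[restricted.patterns] = np.arange(len(restricted.patterns))
    # group id per node: representative of its merged basin
    # (re-derive from mm: group = label where named, else basin root)
    label = np.full(restricted.n_patterns, 3, dtype=np.int8)
    merged_into = {a: b for a, b in mm.merge_trace}

    def resolve(full_index: int) -> int:
        seen = set()
        while full_index in merged_into and full_index not in seen:
            seen.add(full_index)
            full_index = merged_into[full_index]
        return full_index

    anchor_group: dict[int, int] = {}   # surviving-group rep (full idx) -> code
    reps: dict[int, int] = {}           # code -> anchor basin root (full idx)
    for code, full_idx in pre_map.representative_minima.items():
        anchor = full_idx
        if (anchor >> target_roi) & 1 == 1:
            anchor = full_idx ^ (1 << target_roi)  # surviving neighbour
        p = int(pos[anchor]) if anchor <= restricted.patterns.max() else -1
        if p < 0:
            raise RuntimeError(f"anchor pattern {anchor} missing from the restricted space")
        root = int(restricted.basin_of[p])
        group = resolve(int(restricted.patterns[root]))
        if group in anchor_group:
            raise RuntimeError(
                "two major states collapse onto one restricted basin "
                f"(codes {anchor_group[group]} and {code})"
            )
        anchor_group[group] = code
        reps[code] = int(restricted.patterns[root])
    for i in range(restricted.n_patterns):
        root_full = resolve(int(restricted.patterns[int(restricted.basin_of[i])]))
        label[i] = anchor_group.get(root_full, 3)
    return MajorStateMap(
        label_of=label,
        representative_minima={c: reps[c] for c in sorted(reps)},
        merge_trace=mm.merge_trace,
        patterns=restricted.patterns,
    )


_BARRIER_KEYS = (
    (STATE_F, STATE_INT),
    (STATE_INT, STATE_F),
    (STATE_INT, STATE_V),
    (STATE_V, STATE_INT),
)


def barrier_change_stats(
    pre_landscape: EnergyLandscape,
    pre_map: MajorStateMap,
    restricted: EnergyLandscape,
    post_map: MajorStateMap,
) -> tuple[dict, float]:
    """Directional barrier differences (post - pre) and the ratio change.

    Barriers undefined after the restriction (merged or missing states)
    are reported as ``None``, never silently zero.  The ratio is
    ``barrier(Int->F) / barrier(Int->V)``.
    """
    pre = major_barriers(pre_landscape, pre_map)
    post = major_barriers(restricted, post_map)
    deltas = {}
    for key in _BARRIER_KEYS:
        if key in pre and key in post:
            deltas[key] = float(post[key] - pre[key])
        else:
            deltas[key] = None

    def ratio(b):
        a, c = b.get((STATE_INT, STATE_F)), b.get((STATE_INT, STATE_V))
        return a / c if (a is not None and c is not None and c != 0) else np.nan

    ratio_delta = float(ratio(post) - ratio(pre))
    return deltas, ratio_delta


def graded_inhibition(params: MEMParams, target_roi: int, shift: float) -> MEMParams:
    """Extension: model partial inhibition as a basal-activity shift.

    Lowers ``h`` of the target region by ``shift`` (complete silencing,
    the default model of this module, corresponds to the limit of
    removing the active half-space instead).  Returned parameters feed
    the ordinary landscape pipeline.
    """
    if not 0 <= target_roi < params.n_roi:
        raise ValueError(f"invalid region index {target_roi}")
    if shift < 0:
        raise ValueError("shift must be non-negative")
    h = params.h.copy()
    h[target_roi] -= shift
    return MEMParams(h=h, J=params.J.copy())


def virtual_stimulation(
    params: MEMParams,
    target_roi: int,
    barrier_threshold: float = 1.0,
) -> RestrictionResult:
    """Full virtual-stimulation analysis of one target region."""
    pre_ls, pre_map = analyze_landscape(params, barrier_threshold=barrier_threshold)
    restricted = restrict_landscape(params, target_roi)
    post_map = remap_major_states(pre_map, restricted, target_roi, barrier_threshold)
    deltas, ratio_delta = barrier_change_stats(pre_ls, pre_map, restricted, post_map)
    return RestrictionResult(
        target_roi=target_roi,
        restricted_landscape=restricted,
        remapped_majors=post_map,
        barrier_deltas=deltas,
        barrier_ratio_delta=ratio_delta,
        pre_barriers=major_barriers(pre_ls, pre_map),
        post_barriers=major_barriers(restricted, post_map),
    )
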