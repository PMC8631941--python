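"""Energy-landscape construction: minima, basins, barriers, major states.

The landscape is the hypercube graph over all activity patterns (two
patterns are adjacent when they differ in exactly one region) with the
MEM energy attached to every node.  Local minima are patterns strictly
below all ``N`` single-flip neighbours.  For every pair of minima
``(l, m)`` the saddle level ``E*_{lm}`` is the lowest threshold at
which the two remain connected when all nodes with energy at or above
the threshold are removed; the directional barrier is
``barrier(l -> m) = E*_{lm} - E(min l)``.  Coarse-graining repeatedly
absorbs a minimum into a deeper one whenever the connecting barrier is
below a threshold (1 energy unit by default), which condenses the
landscape into a small number of major states.  For the 7-region
recordings these are a frontal-dominant (F), a visual-dominant (V) and
an intermediate (Int) state; patterns left in minor basins are "Other".

All operations accept an optional pattern subset so that the same
machinery runs on restricted state spaces (see
:mod:`statescape.stimulation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mem import MEMParams, all_patterns, boltzmann_distribution

__all__ = [
    "EnergyLandscape",
    "MajorStateMap",
    "STATE_F",
    "STATE_INT",
    "STATE_V",
    "STATE_OTHER",
    "STATE_NAMES",
    "FRONTAL_ROIS",
    "VISUAL_ROIS",
    "ROI_NAMES",
    "enumerate_landscape",
    "build_disconnectivity",
    "assign_basins",
    "coarse_grain",
    "analyze_landscape",
]

# integer state codes used across the package
STATE_F, STATE_INT, STATE_V, STATE_OTHER = 0, 1, 2, 3
STATE_NAMES = ("F", "Int", "V", "Other")

# the seven-region montage of the study: frontal eye field, dorsolateral
# prefrontal, inferior frontal, anterior/posterior superior parietal,
# lateral occipital, MT/V5
ROI_NAMES = ("FEF", "DLPFC", "IFC", "aSPL", "pSPL", "LOC", "V5")
FRONTAL_ROIS = (0, 1, 2)
VISUAL_ROIS = (5, 6)


@dataclass
class EnergyLandscape:
    """Energies, minima, basins and barriers over a pattern space.

    ``patterns`` holds the full-space integer indices of the nodes in
    this landscape (the whole hypercube, or a subset after a
    state-space restriction).  ``neighbors[i, j]`` is the position (in
    ``patterns``) of the node obtained by flipping free region ``j`` of
    node ``i``; ``-1`` marks a neighbour that was removed.
    """

    n_roi: int
    patterns: np.ndarray
    energies: np.ndarray
    neighbors: np.ndarray
    minima: np.ndarray = field(default=None)
    basin_of: np.ndarray = field(default=None)
    basin_sizes: dict = field(default=None)
    saddle: np.ndarray = field(default=None)       # E*_{lm}, (n_min, n_min)
    barriers: np.ndarray = field(default=None)     # barrier(l->m)
    tree: list = field(default=None)               # merge events of the disconnectivity tree

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def minimum_position(self, full_index: int) -> int:
        """Position in ``self.minima`` of a minimum given its full-space index."""
        pos = np.where(self.patterns[self.minima] == full_index)[0]
        if len(pos) == 0:
            raise KeyError(f"pattern {full_index} is not a minimum")
        return int(pos[0])


@dataclass
class MajorStateMap:
    """Coarse-grained classification of every pattern into F/Int/V/Other.

    ``label_of[i]`` is the state code of node ``i`` of the landscape it
    was built from; ``representative_minima`` maps state code to the
    full-space pattern index of the surviving minimum.
    """

    label_of: np.ndarray
    representative_minima: dict
    merge_trace: list
    patterns: np.ndarray

    def labels_for(self, pattern_indices: np.ndarray) -> np.ndarray:
        """State codes for full-space pattern indices (unknown -> Other)."""
        lookup = np.full(int(self.patterns.max()) + 1, STATE_OTHER, dtype=np.int8)
        lookup[self.patterns] = self.label_of
        idx = np.asarray(pattern_indices)
        out = np.full(idx.shape, STATE_OTHER, dtype=np.int8)
        ok = idx <= self.patterns.max()
        out[ok] = lookup[idx[ok]]
        return out


def enumerate_landscape(params: MEMParams, keep: np.ndarray | None = None) -> EnergyLandscape:
    """Energies and strict local minima over the (possibly masked) hypercube.

    ``keep`` is an optional boolean mask over the ``2**N`` full-space
    patterns; adjacency is the single-flip relation restricted to the
    kept set.
    """
    n = params.n_roi
    dist = boltzmann_distribution(params)
    full_idx = np.arange(2**n)
    if keep is None:
        kept = full_idx
    else:
        keep = np.asarray(keep, bool)
        kept = full_idx[keep]
        if len(kept) == 0:
            raise ValueError("empty pattern subset")
    pos = np.full(2**n, -1, dtype=np.int64)
    pos[kept] = np.arange(len(kept))
    nbr_full = kept[:, None] ^ (1 << np.arange(n))
    neighbors = pos[nbr_full]  # -1 where the flipped pattern was removed
    energies = dist.energies[kept]
    # strict minima among surviving neighbours
    nb_e = np.where(neighbors >= 0, energies[np.clip(neighbors, 0, None)], np.inf)
    minima = np.where((energies[:, None] < nb_e).all(axis=1))[0]
    return EnergyLandscape(
        n_roi=n,
        patterns=kept,
        energies=energies,
        neighbors=neighbors,
        minima=minima,
    )


def assign_basins(landscape: EnergyLandscape) -> EnergyLandscape:
    """Steepest-descent basin of every node (ties -> lowest pattern index).

    From each node, move to the neighbour with the smallest energy while
    one is strictly lower; the reached minimum defines the basin.  Basin
    sizes are fractions of the number of nodes in the landscape.  Nodes
    on exact plateaus (no strictly lower neighbour, not a strict
    minimum) terminate where they stand and are kept in their own
    degenerate basin; generic landscapes do not produce them.
    """
    if landscape.minima is None or len(landscape.minima) == 0:
        raise ValueError("landscape has no minima")
    e = landscape.energies
    nb = landscape.neighbors
    n_nodes = len(e)
    # descent target per node: lowest-energy neighbour, ties broken by the
    # lowest full-space pattern index among the tied neighbours
    nb_e = np.where(nb >= 0, e[np.clip(nb, 0, None)], np.inf)
    target = np.empty(n_nodes, dtype=np.int64)
    for i in range(n_nodes):
        row = nb_e[i]
        best = row.min()
        if best >= e[i]:
            target[i] = i
            continue
        tied = np.where(row == best)[0]
        cand = nb[i, tied]
        target[i] = cand[np.argmin(landscape.patterns[cand])]
    basin = np.full(n_nodes, -1, dtype=np.int64)
    for start in range(n_nodes):
        if basin[start] >= 0:
            continue
        path = []
        k = start
        while basin[k] < 0 and target[k] != k:
            path.append(k)
            k = target[k]
            if len(path) > n_nodes:
                raise RuntimeError("descent cycle detected")
        root = basin[k] if basin[k] >= 0 else k
        basin[path] = root
        basin[k] = root
    landscape.basin_of = basin
    counts = {int(m): int(np.sum(basin == m)) for m in np.unique(basin)}
    landscape.basin_sizes = {m: c / n_nodes for m, c in counts.items()}
    return landscape


def build_disconnectivity(landscape: EnergyLandscape) -> EnergyLandscape:
    """Saddle levels ``E*`` and directional barriers between all minima.

    Nodes are re-inserted in ascending energy order with a union-find
    over the adjacency; the level at which two minima first share a
    component is their connecting threshold.  Equal-energy nodes enter
    together, which realises threshold stepping over the sorted multiset
    of distinct energy values.  The resulting ``E*`` is a single-linkage
    ultrametric; the merge events form the disconnectivity tree.
    """
    mins = landscape.minima
    if mins is None or len(mins) == 0:
        raise ValueError("landscape has no minima")
    e = landscape.energies
    nb = landscape.neighbors
    order = np.argsort(e, kind="stable")
    parent = np.arange(len(e))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_min = len(mins)
    min_pos = {int(m): i for i, m in enumerate(mins)}
    saddle = np.full((n_min, n_min), np.nan)
    np.fill_diagonal(saddle, -np.inf)
    tree: list = []
    added = np.zeros(len(e), bool)
    i = 0
    while i < len(order):
        j = i
        level = e[order[i]]
        while j < len(order) and e[order[j]] == level:
            j += 1
        group = order[i:j]
        added[group] = True
        for k in group:
            for nbk in nb[k]:
                if nbk >= 0 and added[nbk]:
                    parent[find(nbk)] = find(k)
        roots: dict[int, list[int]] = {}
        for m in mins:
            roots.setdefault(find(m), []).append(min_pos[int(m)])
        for members in roots.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    pa, pb = members[a], members[b]
                    if np.isnan(saddle[pa, pb]):
                        saddle[pa, pb] = saddle[pb, pa] = level
                        tree.append((float(level), int(mins[pa]), int(mins[pb])))
        i = j
    landscape.saddle = saddle
    landscape.barriers = saddle - e[mins][:, None]
    landscape.tree = tree
    return landscape


def _group_saddle(saddle, groups, pos, a, b):
    return min(saddle[pos[x], pos[y]] for x in groups[a] for y in groups[b])


def coarse_grain(
    landscape: EnergyLandscape,
    barrier_threshold: float = 1.0,
    frontal: tuple = FRONTAL_ROIS,
    visual: tuple = VISUAL_ROIS,
    strict_three: bool = False,
) -> MajorStateMap:
    """Merge shallow minima and label every pattern F / Int / V / Other.

    A minimum ``l`` is absorbed into ``m`` when ``barrier(l -> m)`` is
    below ``barrier_threshold`` and ``E(l) > E(m)``; the lowest
    qualifying barrier merges first and barriers are re-evaluated after
    each merge (single-linkage between groups).  Surviving minima are
    named by their activity profiles: F has the frontal trio active and
    the visual pair silent, V the reverse, Int is the third.  Patterns
    of surviving minor basins are labelled Other.
    """
    if landscape.basin_of is None:
        assign_basins(landscape)
    if landscape.saddle is None:
        build_disconnectivity(landscape)
    mins = landscape.minima
    e = landscape.energies
    pos = {int(m): i for i, m in enumerate(mins)}
    groups = {int(m): [int(m)] for m in mins}
    reps = [int(m) for m in mins]
    trace: list = []
    while True:
        best = None
        for a in reps:
            for b in reps:
                if a == b:
                    continue
                bar = _group_saddle(landscape.saddle, groups, pos, a, b) - e[a]
                if bar < barrier_threshold and e[a] > e[b]:
                    if best is None or bar < best[0]:
                        best = (bar, a, b)
        if best is None:
            break
        _, a, b = best
        groups[b].extend(groups.pop(a))
        reps.remove(a)
        trace.append((int(landscape.patterns[a]), int(landscape.patterns[b])))
    # map every basin root to its surviving representative
    rep_of = {}
    for r, members in groups.items():
        for m in members:
            rep_of[m] = r
    # name survivors by ROI profile
    s = all_patterns(landscape.n_roi)
    fr = list(frontal)
    vi = list(visual)

    def profile(r: int) -> float:
        sig = s[landscape.patterns[r]]
        return float(sig[fr].mean() - sig[vi].mean())

    code_of_rep = {}
    if len(reps) >= 3:
        scored = sorted(reps, key=profile)
        v_rep, f_rep = scored[0], scored[-1]
        sig_f, sig_v = s[landscape.patterns[f_rep]], s[landscape.patterns[v_rep]]
        ok = (sig_f[fr] == 1).all() and (sig_f[vi] == -1).all() and \
             (sig_v[vi] == 1).all() and (sig_v[fr] == -1).all()
        if ok:
            # Int: among the remaining survivors, the one whose saddle to F
            # and V is lowest (the state between them in the tree)
            rest = [r for r in reps if r not in (f_rep, v_rep)]
            int_rep = min(
                rest,
                key=lambda r: max(
                    _group_saddle(landscape.saddle, groups, pos, r, f_rep),
                    _group_saddle(landscape.saddle, groups, pos, r, v_rep),
                ),
            )
            code_of_rep = {f_rep: STATE_F, int_rep: STATE_INT, v_rep: STATE_V}
    if strict_three and (len(reps) != 3 or not code_of_rep):
        raise RuntimeError(
            f"coarse-graining left {len(reps)} major states; expected exactly "
            "three with frontal/visual-dominant profiles"
        )
    label = np.full(landscape.n_patterns, STATE_OTHER, dtype=np.int8)
    for i in range(landscape.n_patterns):
        r = rep_of[int(landscape.basin_of[i])]
        label[i] = code_of_rep.get(r, STATE_OTHER)
    rep_minima = {code: int(landscape.patterns[r]) for r, code in code_of_rep.items()}
    return MajorStateMap(
        label_of=label,
        representative_minima={c: rep_minima[c] for c in sorted(rep_minima)},
        merge_trace=trace,
        patterns=landscape.patterns,
    )


def analyze_landscape(
    params: MEMParams,
    barrier_threshold: float = 1.0,
    keep: np.ndarray | None = None,
    strict_three: bool = False,
) -> tuple[EnergyLandscape, MajorStateMap]:
    """Full pipeline: enumerate, basins, disconnectivity, coarse-grain."""
    ls = enumerate_landscape(params, keep=keep)
    assign_basins(ls)
    build_disconnectivity(ls)
    mm = coarse_grain(ls, barrier_threshold=barrier_threshold, strict_three=strict_three)
    return ls, mm


def major_barriers(landscape: EnergyLandscape, major_map: MajorStateMap) -> dict:
    """Directional barriers between the three major states.

    Group saddles are single-linkage over the members merged into each
    major state; the barrier from state ``a`` to ``b`` is the group
    saddle minus the energy of ``a``'s representative minimum.  Missing
    states yield no entry.
    """
    mins = landscape.minima
    pos = {int(m): i for i, m in enumerate(mins)}
    # members of each code: minima whose basin label equals the code
    members = {c: [] for c in (STATE_F, STATE_INT, STATE_V)}
    for m in mins:
        c = int(major_map.label_of[m])
        if c in members:
            members[c].append(int(m))
    out = {}
    e = landscape.energies
    for a, ma in members.items():
        for b, mb in members.items():
            if a == b or not ma or not mb:
                continue
            sad = min(landscape.saddle[pos[x], pos[y]] for x in ma for y in mb)
            rep_a = major_map.representative_minima.get(a)
            ra = int(np.where(landscape.patterns == rep_a)[0][0])
            out[(a, b)] = float(sad - e[ra])
    return out


__all__.append("major_barriers")
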