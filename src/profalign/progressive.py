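"""Guide-tree construction and progressive multiple alignment of lanes.

All pairwise global costs feed single-linkage agglomeration; merges then
run in guide-tree order, aligning alignments to alignments.  Gaps chosen
at a merge are propagated to every member of each side, and a gap is
realized by repeating the preceding slice of that sample.

Determinism: linkage ties are broken by the smallest member index; at each
merge the side holding the lowest original sample index is the first DTW
argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .mdtw import dtw_align, dtw_align_alignments
from .profile_io import ProfileSet


@dataclass(frozen=True)
class GuideTree:
    """Binary merge order over samples.

    Leaves are numbered 0..n-1 in sample order; internal node n+k is
    created by merge k.  In each merge the first node is the side holding
    the smallest leaf index.
    """

    sample_ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def members(self, node: int) -> tuple[int, ...]:
        """Sorted leaf indices under a node."""
        n = self.n_leaves
        if node < n:
            return (node,)
        left, right, _ = self.merges[node - n]
        return tuple(sorted(self.members(left) + self.members(right)))

    def newick(self) -> str:
        n = self.n_leaves

        def render(node: int) -> str:
            if node < n:
                return self.sample_ids[node]
            left, right, cost = self.merges[node - n]
            return f"({render(left)},{render(right)}){cost:g}"

        return render(n + len(self.merges) - 1) + ";"


@dataclass(frozen=True)
class Alignment:
    """Multiple alignment of samples onto a common slice axis.

    ``maps[s]`` sends each aligned position to the source slice of sample
    ``s``; a position whose source repeats the previous one is an inserted
    gap (the preceding slice's values are repeated there).
    """

    sample_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    matrices: Mapping[str, np.ndarray]
    maps: Mapping[str, np.ndarray]
    cost_matrix: np.ndarray | None = None
    tree: GuideTree | None = None

    @property
    def length(self) -> int:
        return next(iter(self.matrices.values())).shape[1]

    def insertions(self, sample_id: str) -> np.ndarray:
        """0-based aligned positions where this sample has an inserted slice."""
        m = self.maps[sample_id]
        return np.flatnonzero(np.diff(m) == 0) + 1

    def dewarp(self, sample_id: str) -> np.ndarray:
        """Remove this sample's inserted positions, recovering its input matrix."""
        keep = np.ones(self.length, dtype=bool)
        keep[self.insertions(sample_id)] = False
        return self.matrices[sample_id][:, keep]


def pairwise_cost_matrix(profile_set: ProfileSet) -> np.ndarray:
    """Symmetric matrix of DTW global costs between all sample pairs."""
    n = profile_set.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    costs = np.zeros((n, n), dtype=float)
    mats = [p.intensities for p in profile_set]
    for i, j in combinations(range(n), 2):
        c = dtw_align(mats[i], mats[j]).global_cost
        costs[i, j] = costs[j, i] = c
    return costs


def build_guide_tree(costs: np.ndarray, sample_ids: tuple[str, ...] | list[str]) -> GuideTree:
    """Single-linkage agglomeration of the pairwise cost matrix."""
    costs = np.asarray(costs, dtype=float)
    n = costs.shape[0]
    if costs.shape != (n, n) or n != len(sample_ids):
        raise ValueError("cost matrix shape does not match sample ids")
    if np.any(np.isnan(costs)):
        raise ValueError("NaN in cost matrix")
    if np.any(costs < 0):
        raise ValueError("negative cost in cost matrix")
    if not np.allclose(costs, costs.T, rtol=1e-12, atol=0.0):
        raise ValueError("cost matrix is not symmetric")

    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(members) > 1:
        best_key = None
        best_pair = None
        for a, b in combinations(sorted(members), 2):
            d = min(costs[i, j] for i in members[a] for j in members[b])
            la, lb = members[a][0], members[b][0]
            key = (d, min(la, lb), max(la, lb))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (a, b, d)
        assert best_pair is not None
        a, b, d = best_pair
        left, right = (a, b) if members[a][0] < members[b][0] else (b, a)
        merges.append((left, right, float(d)))
        members[next_id] = tuple(sorted(members[a] + members[b]))
        del members[a], members[b]
        next_id += 1
    return GuideTree(sample_ids=tuple(sample_ids), merges=tuple(merges))


def progressive_align(
    profile_set: ProfileSet,
    tree: GuideTree | None = None,
    costs: np.ndarray | None = None,
) -> Alignment:
    """Merge all samples into one multiple alignment following the guide tree."""
    if costs is None:
        costs = pairwise_cost_matrix(profile_set)
    if tree is None:
        tree = build_guide_tree(costs, profile_set.sample_ids)
    if tree.sample_ids != profile_set.sample_ids:
        raise ValueError("guide tree leaves do not match the profile set")

    profiles = list(profile_set)
    n = len(profiles)
    # node -> (sorted member leaf indices, {leaf: aligned->source map})
    states: dict[int, tuple[tuple[int, ...], dict[int, np.ndarray]]] = {
        i: ((i,), {i: np.arange(profiles[i].n_slices)}) for i in range(n)
    }
    for k, (left, right, _) in enumerate(tree.merges):
        l_members, l_maps = states.pop(left)
        r_members, r_maps = states.pop(right)
        # tree construction guarantees left holds the smaller leaf index
        first_mats = [profiles[i].intensities[:, l_maps[i]] for i in l_members]
        second_mats = [profiles[i].intensities[:, r_maps[i]] for i in r_members]
        res = dtw_align_alignments(first_mats, second_mats)
        xs = res.path.x_indices
        ys = res.path.y_indices
        new_maps = {i: l_maps[i][xs] for i in l_members}
        new_maps.update({i: r_maps[i][ys] for i in r_members})
        states[n + k] = (tuple(sorted(l_members + r_members)), new_maps)

    (_, final_maps), = states.values()
    matrices = {
        profiles[i].sample_id: profiles[i].intensities[:, final_maps[i]] for i in range(n)
    }
    maps = {profiles[i].sample_id: final_maps[i] for i in range(n)}
    return Alignment(
        sample_ids=profile_set.sample_ids,
        protein_ids=profile_set.protein_ids,
        matrices=matrices,
        maps=maps,
        cost_matrix=costs,
        tree=tree,
    )


def insertion_report(alignment: Alignment) -> pd.DataFrame:
    """Per-sample table of 1-based aligned positions of inserted slices."""
    rows = []
    L = alignment.length
    for sid in alignment.sample_ids:
        ins = alignment.insertions(sid)
        rows.append(
            {
                "sample_id": sid,
                "original_n_slices": L - len(ins),
                "aligned_length": L,
                "n_insertions": len(ins),
                "positions": ";".join(str(int(p) + 1) for p in ins),
            }
        )
    return pd.DataFrame(rows)
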