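"""Pairwise multi-dimensional dynamic time warping of gel lanes.

The local cost between slice x of one lane and slice y of another pools
all proteins: it is the sum over proteins of the absolute intensity
difference (cityblock distance between slice columns).  The accumulated
cost follows the classic three-move recursion (diagonal, gap in one lane,
gap in the other); the global cost is the accumulated cost of the optimal
full path and carries no gap penalty term.

Tie-breaking is deterministic: during traceback the diagonal predecessor
is preferred, then the predecessor along the first argument's axis, then
the second's.  Costs are compared exactly in double precision.

Aligning two multiple alignments uses the same recursion with the local
cost replaced by the average local cost over all cross sample pairs; with
one sample on each side this reduces bit-exactly to the pairwise case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class CostMatrix:
    """Local and accumulated cost matrices of one DTW run."""

    local: np.ndarray
    accumulated: np.ndarray


@dataclass(frozen=True)
class WarpPath:
    """Monotone, continuous path of (x, y) index pairs."""

    steps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        steps = tuple((int(x), int(y)) for x, y in self.steps)
        if not steps:
            raise ValueError("empty warp path")
        if steps[0] != (0, 0):
            raise ValueError(f"warp path must start at (0, 0), got {steps[0]}")
        for (x0, y0), (x1, y1) in zip(steps, steps[1:]):
            if (x1 - x0, y1 - y0) not in ((1, 0), (0, 1), (1, 1)):
                raise ValueError(f"illegal warp move {(x0, y0)} -> {(x1, y1)}")
        object.__setattr__(self, "steps", steps)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def x_indices(self) -> np.ndarray:
        return np.fromiter((s[0] for s in self.steps), dtype=int, count=len(self.steps))

    @property
    def y_indices(self) -> np.ndarray:
        return np.fromiter((s[1] for s in self.steps), dtype=int, count=len(self.steps))


@dataclass(frozen=True)
class PairwiseAlignment:
    """Warp path with its global cost and the resulting gap positions.

    ``gaps_x`` are aligned-axis indices (0-based) where the x side repeats
    a slice, i.e. where a slice was inserted into x; analogously ``gaps_y``.
    """

    path: WarpPath
    global_cost: float
    gaps_x: tuple[int, ...]
    gaps_y: tuple[int, ...]
    cost: CostMatrix | None = None

    @property
    def aligned_length(self) -> int:
        return len(self.path)


def local_cost(slice_x: np.ndarray, slice_y: np.ndarray) -> float:
    """Sum over proteins of absolute intensity differences at one slice pair."""
    x = np.asarray(slice_x, dtype=float)
    y = np.asarray(slice_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"protein roster mismatch: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


def local_cost_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-pairs slice local costs for two (n_proteins, n_slices) matrices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"protein roster mismatch: {x.shape[0]} vs {y.shape[0]} proteins")
    return cdist(x.T, y.T, metric="cityblock")


def _accumulate(local: np.ndarray) -> np.ndarray:
    n_x, n_y = local.shape
    acc = np.empty_like(local)
    acc[0, :] = np.cumsum(local[0, :])
    acc[:, 0] = np.cumsum(local[:, 0])
    for i in range(1, n_x):
        prev = acc[i - 1]
        row = acc[i]
        loc = local[i]
        for j in range(1, n_y):
            row[j] = loc[j] + min(prev[j - 1], prev[j], row[j - 1])
    return acc


def _traceback(acc: np.ndarray) -> tuple[tuple[int, int], ...]:
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    steps = [(i, j)]
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = acc[i - 1, j - 1]
            along_x = acc[i - 1, j]
            along_y = acc[i, j - 1]
            best = min(diag, along_x, along_y)
            if diag == best:
                i, j = i - 1, j - 1
            elif along_x == best:
                i -= 1
            else:
                j -= 1
        steps.append((i, j))
    steps.reverse()
    return tuple(steps)


def _finish(local: np.ndarray, keep_matrices: bool) -> PairwiseAlignment:
    acc = _accumulate(local)
    steps = _traceback(acc)
    xs = np.fromiter((s[0] for s in steps), dtype=int, count=len(steps))
    ys = np.fromiter((s[1] for s in steps), dtype=int, count=len(steps))
    gaps_x = tuple(int(k) for k in (np.flatnonzero(np.diff(xs) == 0) + 1))
    gaps_y = tuple(int(k) for k in (np.flatnonzero(np.diff(ys) == 0) + 1))
    return PairwiseAlignment(
        path=WarpPath(steps=steps),
        global_cost=float(acc[-1, -1]),
        gaps_x=gaps_x,
        gaps_y=gaps_y,
        cost=CostMatrix(local=local, accumulated=acc) if keep_matrices else None,
    )


def dtw_align(x: np.ndarray, y: np.ndarray, *, keep_matrices: bool = False) -> PairwiseAlignment:
    """Align two (n_proteins, n_slices) matrices; full-sequence boundary."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0 or x.shape[1] == 0 or y.shape[1] == 0:
        raise ValueError("cannot align an empty slice sequence")
    return _finish(local_cost_matrix(x, y), keep_matrices)


def dtw_align_alignments(
    a_matrices: Sequence[np.ndarray],
    b_matrices: Sequence[np.ndarray],
    *,
    keep_matrices: bool = False,
) -> PairwiseAlignment:
    """Align two groups of already co-warped matrices (alignment vs alignment).

    Local cost at (x, y) = average over all cross pairs (one sample from
    each side) of the pairwise local cost.  Repeated (gap-extended) slices
    contribute their repeated values as-is.
    """
    a_mats = [np.asarray(m, dtype=float) for m in a_matrices]
    b_mats = [np.asarray(m, dtype=float) for m in b_matrices]
    if not a_mats or not b_mats:
        raise ValueError("each side needs at least one sample")
    n_prot = a_mats[0].shape[0]
    for m in a_mats + b_mats:
        if m.shape[0] != n_prot:
            raise ValueError("protein roster mismatch between alignment members")
    for mats in (a_mats, b_mats):
        lengths = {m.shape[1] for m in mats}
        if len(lengths) != 1:
            raise ValueError("members of one alignment must share an aligned length")
    total = None
    for a in a_mats:
        for b in b_mats:
            lc = local_cost_matrix(a, b)
            total = lc if total is None else total + lc
    local = total / (len(a_mats) * len(b_mats))
    return _finish(local, keep_matrices)
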