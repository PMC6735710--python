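"""Per-protein Hausdorff distances between aligned migration curves.

Each protein's aligned curve in one sample is a discrete point set
{(position, intensity)} with one point per aligned position.  Before the
distance is taken, intensities are rescaled per protein so that the
maximum over all samples compared equals ``weight * aligned_length`` —
with weight 1 this puts the curves on a square plane; smaller weights
up-weight migration (x-axis) shifts relative to abundance changes.

The symmetric Hausdorff distance max(h(A,B), h(B,A)) is used, where
h(A,B) is the largest Euclidean distance from a point of A to its nearest
point of B.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff


@dataclass(frozen=True)
class ScalingScheme:
    """Intensity rescaling weight; 1.0 gives a square plane, 0.25 weighs
    migration shifts 4-fold over abundance shifts."""

    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError(f"weight must be positive, got {self.weight}")


@dataclass(frozen=True)
class DistanceTable:
    """Per-protein Hausdorff distances for every sample pair."""

    frame: pd.DataFrame  # index: protein_id; columns: "a|b" pair labels
    pairs: tuple[tuple[str, str], ...]
    sample_ids: tuple[str, ...]
    weight: float = 1.0

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def rescale_protein(
    curves: np.ndarray | Sequence[Sequence[float]], length: int, weight: float = 1.0
) -> np.ndarray:
    """Rescale one protein's per-sample curves so max over samples = weight*length.

    All-zero proteins are returned unchanged.
    """
    if not (weight > 0):
        raise ValueError("weight must be positive")
    curves = np.asarray(curves, dtype=float)
    m = curves.max() if curves.size else 0.0
    if m == 0:
        return curves.copy()
    # divide by the max first so the maximum lands on weight*length exactly
    return (curves / m) * (weight * length)


def curve_points(curve: np.ndarray) -> np.ndarray:
    """Point set of a curve: one (position, intensity) row per aligned position."""
    curve = np.asarray(curve, dtype=float)
    return np.column_stack([np.arange(curve.shape[0], dtype=float), curve])


def hausdorff_distance(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two 2-D point sets."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty curve")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("curves must be (n, 2) point sets")
    return float(max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0]))


def distance_table(alignment, scheme: ScalingScheme | float = ScalingScheme()) -> DistanceTable:
    """Hausdorff distances for every protein and every sample pair of an alignment.

    ``alignment`` is any object exposing ``sample_ids``, ``protein_ids``,
    ``matrices`` (sample -> (n_proteins, L) array) and ``length``.
    """
    if not isinstance(scheme, ScalingScheme):
        scheme = ScalingScheme(weight=float(scheme))
    sids = tuple(alignment.sample_ids)
    pids = tuple(alignment.protein_ids)
    L = alignment.length
    n = len(sids)
    pair_list = list(combinations(range(n), 2))
    data = np.zeros((len(pids), len(pair_list)), dtype=float)
    stack = np.stack([np.asarray(alignment.matrices[s], dtype=float) for s in sids])
    for pi in range(len(pids)):
        curves = rescale_protein(stack[:, pi, :], L, scheme.weight)
        if curves.max() == 0:
            continue  # identical all-zero curves: every distance is 0
        points = [curve_points(curves[s]) for s in range(n)]
        for k, (i, j) in enumerate(pair_list):
            data[pi, k] = hausdorff_distance(points[i], points[j])
    pairs = tuple((sids[i], sids[j]) for i, j in pair_list)
    frame = pd.DataFrame(
        data, index=list(pids), columns=[f"{a}|{b}" for a, b in pairs]
    )
    frame.index.name = "protein_id"
    return DistanceTable(frame=frame, pairs=pairs, sample_ids=sids, weight=scheme.weight)
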