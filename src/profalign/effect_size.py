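"""Per-protein Hausdorff effect sizes and rank-ordered exports.

For each protein the effect size is the mean Hausdorff distance over
between-group sample pairs divided by the mean over within-group pairs.
Proteins are ranked descending; a zero within-group mean with a positive
between-group mean yields +inf (ranked top, flagged), and a protein whose
distances are all zero is undefined (ranked bottom, flagged, excluded
from the .rnk export).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hausdorff import DistanceTable
from .profile_io import GeneSetCollection, GroupAssignment

log = logging.getLogger(__name__)

FLAG_WITHIN_ZERO = "within_zero"
FLAG_UNDEFINED = "undefined"


@dataclass(frozen=True)
class EffectSizeTable:
    """Ranked per-protein effect sizes.

    ``frame`` columns: protein_id, hes, mean_between, mean_within,
    n_between, n_within, rank, flag — sorted by rank.
    """

    frame: pd.DataFrame
    n_between: int
    n_within: int


def hes(distances: DistanceTable, groups: GroupAssignment) -> EffectSizeTable:
    """Effect size per protein: mean between-group / mean within-group distance."""
    groups.validate_against(distances.sample_ids)
    case = groups.case_ids
    between_idx = []
    within_idx = []
    for k, (a, b) in enumerate(distances.pairs):
        if (a in case) != (b in case):
            between_idx.append(k)
        else:
            within_idx.append(k)
    n_between = len(between_idx)
    n_within = len(within_idx)
    if n_within == 0:
        raise ValueError(
            "no within-group sample pairs (both groups are singletons); "
            "at least one group needs two samples"
        )
    assert n_between == len(case) * len(groups.control_ids)

    values = distances.values()
    mean_between = values[:, between_idx].mean(axis=1)
    mean_within = values[:, within_idx].mean(axis=1)

    scores = np.empty(len(mean_between), dtype=float)
    flags = []
    for i, (mb, mw) in enumerate(zip(mean_between, mean_within)):
        if mw > 0:
            scores[i] = mb / mw
            flags.append("")
        elif mb > 0:
            scores[i] = np.inf
            flags.append(FLAG_WITHIN_ZERO)
        else:
            scores[i] = np.nan
            flags.append(FLAG_UNDEFINED)

    frame = pd.DataFrame(
        {
            "protein_id": list(distances.protein_ids),
            "hes": scores,
            "mean_between": mean_between,
            "mean_within": mean_within,
            "n_between": n_between,
            "n_within": n_within,
            "flag": flags,
        }
    )
    # descending score, undefined last, ties by protein id
    frame["_key"] = np.where(np.isnan(scores), -np.inf, scores)
    frame = frame.sort_values(["_key", "protein_id"], ascending=[False, True], kind="stable")
    frame = frame.drop(columns="_key").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame = frame[
        ["protein_id", "hes", "mean_between", "mean_within", "n_between", "n_within",
         "rank", "flag"]
    ]
    return EffectSizeTable(frame=frame, n_between=n_between, n_within=n_within)


def export_ranked(table: EffectSizeTable, path: str | Path) -> Path:
    """Write a two-column tab-separated .rnk file (descending score).

    Infinite scores are replaced by 10x the largest finite score so the
    file stays usable by preranked enrichment tools; undefined proteins
    are omitted and listed in a sidecar ``*_excluded.txt`` file.
    """
    path = Path(path)
    frame = table.frame
    defined = frame[frame["flag"] != FLAG_UNDEFINED]
    scores = defined["hes"].to_numpy(dtype=float)
    finite = scores[np.isfinite(scores)]
    if np.any(np.isinf(scores)):
        cap = (float(finite.max()) if finite.size and finite.max() > 0 else 1.0) * 10.0
        log.warning(
            "%d proteins with zero within-group distance written with score %g",
            int(np.isinf(scores).sum()), cap,
        )
        scores = np.where(np.isinf(scores), cap, scores)
    lines = [
        f"{pid}\t{float(score)!r}" for pid, score in zip(defined["protein_id"], scores)
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))

    excluded = frame.loc[frame["flag"] == FLAG_UNDEFINED, "protein_id"]
    sidecar = path.with_name(path.stem + "_excluded.txt")
    sidecar.write_text("".join(f"{pid}\n" for pid in excluded))
    return path


def leading_edge_summary(
    table: EffectSizeTable, sets: GeneSetCollection, top_k: int = 50
) -> pd.DataFrame:
    """Per set: member ranks (1-based, sorted) and how many fall in the top k."""
    n = len(table.frame)
    if top_k > n:
        raise ValueError(f"top_k={top_k} exceeds table size {n}")
    rank_of = dict(zip(table.frame["protein_id"], table.frame["rank"]))
    rows = []
    for name, members in sets.items():
        ranks = sorted(int(rank_of[m]) for m in members if m in rank_of)
        rows.append(
            {
                "set": name,
                "n_members": len(members),
                "n_in_table": len(ranks),
                "n_in_top_k": sum(r <= top_k for r in ranks),
                "top_k": top_k,
                "member_ranks": ";".join(str(r) for r in ranks),
            }
        )
    return pd.DataFrame(rows)
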