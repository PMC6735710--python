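"""Sum-equalization across samples.

Each sample's matrix is multiplied by a single scalar so that total
intensity over the analysis roster is identical across samples.  The
default target is the mean of the raw totals, which keeps values in the
input's order of magnitude; a fixed numeric target can be given instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile_io import Profile, ProfileSet


@dataclass(frozen=True)
class NormalizationReport:
    sample_ids: tuple[str, ...]
    raw_sums: tuple[float, ...]
    scale_factors: tuple[float, ...]
    target_sum: float

    def __post_init__(self) -> None:
        for sid, raw, f in zip(self.sample_ids, self.raw_sums, self.scale_factors):
            if not np.isclose(raw * f, self.target_sum, rtol=1e-9):
                raise ValueError(f"inconsistent report for sample {sid!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "raw_sum": list(self.raw_sums),
                "scale_factor": list(self.scale_factors),
                "target_sum": self.target_sum,
            }
        )


def normalize_sum(
    profile_set: ProfileSet, target: str | float = "mean"
) -> tuple[ProfileSet, NormalizationReport]:
    """Scale every sample so its roster total equals the common target.

    ``target`` is ``"mean"`` (mean of raw totals) or a positive number.
    """
    sums = np.array([p.total_intensity() for p in profile_set], dtype=float)
    for p, s in zip(profile_set, sums):
        if s <= 0:
            raise ValueError(f"sample {p.sample_id!r} has zero total intensity over the roster")
    if isinstance(target, str):
        if target not in ("mean", "mean-of-sums"):
            raise ValueError(f"unknown normalization target {target!r}")
        target_sum = float(np.mean(sums))
    else:
        target_sum = float(target)
        if target_sum <= 0:
            raise ValueError("fixed normalization target must be positive")
    factors = target_sum / sums
    scaled = tuple(
        Profile(
            sample_id=p.sample_id,
            protein_ids=p.protein_ids,
            intensities=p.intensities * f,
        )
        for p, f in zip(profile_set, factors)
    )
    report = NormalizationReport(
        sample_ids=profile_set.sample_ids,
        raw_sums=tuple(float(s) for s in sums),
        scale_factors=tuple(float(f) for f in factors),
        target_sum=target_sum,
    )
    return ProfileSet(profiles=scaled), report
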