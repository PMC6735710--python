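"""Synthetic complexome profiles with known ground truth.

Profiles are Gaussian peak mixtures over the slice axis with optional
multiplicative lognormal noise and random dropout.  Gel-specific warps
duplicate slices at known positions (mimicking migration shifts between
gel runs) and a case-group effect shifts and scales a chosen protein
subset, so aligner and effect-size recovery can be tested end to end.

The default study geometry is 4 cases + 5 controls over 3 gels with 60
slices, 100 proteins, and 10 affected proteins shifted by 4 slices and
scaled 3-fold in the cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profile_io import GroupAssignment, Profile, ProfileSet, build_profile_set


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian migration peak of one protein."""

    protein_id: str
    center: float  # slice index
    width: float  # Gaussian sigma, in slices
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("peak width must be positive")
        if not (self.height > 0):
            raise ValueError("peak height must be positive")


@dataclass(frozen=True)
class GelWarpSpec:
    """Slice duplications and a whole-lane intensity factor for one gel."""

    positions: tuple[int, ...] = ()
    intensity_factor: float = 1.0

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        if list(pos) != sorted(set(pos)):
            raise ValueError("warp positions must be strictly increasing")
        if not (self.intensity_factor > 0):
            raise ValueError("intensity factor must be positive")
        object.__setattr__(self, "positions", pos)

    def duplicate_input_indices(self) -> tuple[int, ...]:
        """Input-axis (post-warp) indices of the duplicated (extra) slices."""
        return tuple(p + 1 + i for i, p in enumerate(self.positions))


@dataclass(frozen=True)
class EffectSpec:
    """Migration shift and abundance change applied to case samples."""

    protein_ids: tuple[str, ...] = ()
    shift: int = 0
    abundance_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.abundance_factor > 0):
            raise ValueError("abundance factor must be positive")
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_profile(
    roster: Sequence[str],
    n_slices: int,
    peaks: Sequence[PeakSpec],
    noise_cv: float = 0.1,
    dropout_p: float = 0.02,
    seed=0,
    sample_id: str = "sample",
) -> Profile:
    """Noisy Gaussian-mixture profile; deterministic for a given seed.

    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` (mean 1); each cell is independently zeroed with
    probability ``dropout_p``.
    """
    if not (0 <= dropout_p < 1):
        raise ValueError("dropout_p must be in [0, 1)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = _as_rng(seed)
    roster = [str(r) for r in roster]
    index = {pid: i for i, pid in enumerate(roster)}
    grid = np.arange(n_slices, dtype=float)
    base = np.zeros((len(roster), n_slices), dtype=float)
    for pk in peaks:
        i = index.get(pk.protein_id)
        if i is None:
            raise ValueError(f"peak for unknown protein {pk.protein_id!r}")
        base[i, :] += pk.height * np.exp(-((grid - pk.center) ** 2) / (2 * pk.width**2))
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        base = base * np.exp(rng.normal(0.0, sigma, size=base.shape) - sigma**2 / 2)
    if dropout_p > 0:
        base[rng.random(size=base.shape) < dropout_p] = 0.0
    return Profile(sample_id=sample_id, protein_ids=tuple(roster), intensities=base)


def apply_warp(profile: Profile, warp: GelWarpSpec) -> Profile:
    """Duplicate slices at the warp positions and scale the whole lane."""
    counts = np.ones(profile.n_slices, dtype=int)
    for p in warp.positions:
        if not (0 <= p < profile.n_slices):
            raise ValueError(f"warp position {p} out of range for {profile.n_slices} slices")
        counts[p] += 1
    mat = np.repeat(profile.intensities, counts, axis=1) * warp.intensity_factor
    return Profile(
        sample_id=profile.sample_id, protein_ids=profile.protein_ids, intensities=mat
    )


def default_gel_warps(n_slices: int = 60) -> tuple[GelWarpSpec, ...]:
    """Three gels: one unwarped, two with slice duplications at distinct
    sites (positions scale with lane length; at 60 slices: 14/38 and 22/47)."""

    def at(fraction: float) -> int:
        return int(round(fraction * n_slices))

    return (
        GelWarpSpec(positions=(), intensity_factor=1.0),
        GelWarpSpec(positions=(at(14 / 60), at(38 / 60)), intensity_factor=1.6),
        GelWarpSpec(positions=(at(22 / 60), at(47 / 60)), intensity_factor=0.7),
    )


def generate_study(
    n_case: int = 4,
    n_control: int = 5,
    n_proteins: int = 100,
    n_slices: int = 60,
    effect: EffectSpec | None = None,
    gel_warps: Sequence[GelWarpSpec] | None = None,
    noise_cv: float = 0.1,
    dropout_p: float = 0.02,
    seed: int = 0,
) -> tuple[ProfileSet, GroupAssignment, dict[str, pd.DataFrame]]:
    """Full labeled synthetic study plus machine-readable ground truth.

    Samples are assigned round-robin to gels so gel warps do not confound
    the case/control contrast.  ``effect=None`` draws 10 affected proteins
    (shift +4 slices, 3-fold abundance in cases); pass
    ``EffectSpec()`` for a null study.

    Truth tables: ``effects`` (affected proteins), ``gaps`` (per-sample
    duplicated slice positions, original and input-axis), ``samples``
    (group, gel, intensity factor).
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng(seed)
    roster = tuple(f"P{i:03d}" for i in range(n_proteins))
    if gel_warps is None:
        gel_warps = default_gel_warps(n_slices)

    base_peaks: dict[str, list[PeakSpec]] = {}
    for pid in roster:
        n_peaks = int(rng.integers(1, 3))
        specs = []
        for _ in range(n_peaks):
            specs.append(
                PeakSpec(
                    protein_id=pid,
                    center=float(rng.uniform(6, n_slices - 6)),
                    width=float(rng.uniform(1.2, 2.8)),
                    height=float(10 ** rng.uniform(2.5, 3.5)),
                )
            )
        base_peaks[pid] = specs

    if effect is None:
        affected = sorted(rng.choice(n_proteins, size=min(10, n_proteins), replace=False))
        effect = EffectSpec(
            protein_ids=tuple(roster[i] for i in affected),
            shift=4,
            abundance_factor=3.0,
        )
    unknown = set(effect.protein_ids) - set(roster)
    if unknown:
        raise ValueError(f"effect names proteins outside the roster: {sorted(unknown)}")
    affected_set = set(effect.protein_ids)

    sample_ids = [f"case_{i + 1}" for i in range(n_case)] + [
        f"ctrl_{i + 1}" for i in range(n_control)
    ]
    n_gels = len(gel_warps)
    gels = [k % n_gels for k in range(len(sample_ids))]

    profiles = []
    gap_rows = []
    sample_rows = []
    for k, sid in enumerate(sample_ids):
        is_case = k < n_case
        peaks: list[PeakSpec] = []
        for pid in roster:
            for pk in base_peaks[pid]:
                if is_case and pid in affected_set:
                    center = float(np.clip(pk.center + effect.shift, 0, n_slices - 1))
                    peaks.append(
                        PeakSpec(
                            protein_id=pid,
                            center=center,
                            width=pk.width,
                            height=pk.height * effect.abundance_factor,
                        )
                    )
                else:
                    peaks.append(pk)
        sample_rng = np.random.default_rng(rng.integers(2**63))
        prof = generate_profile(
            roster, n_slices, peaks, noise_cv=noise_cv, dropout_p=dropout_p,
            seed=sample_rng, sample_id=sid,
        )
        warp = gel_warps[gels[k]]
        profiles.append(apply_warp(prof, warp))
        gap_rows.append(
            {
                "sample_id": sid,
                "gel": gels[k],
                "duplicated_positions": ";".join(str(p) for p in warp.positions),
                "duplicate_input_indices": ";".join(
                    str(i) for i in warp.duplicate_input_indices()
                ),
            }
        )
        sample_rows.append(
            {
                "sample_id": sid,
                "group": "case" if is_case else "control",
                "gel": gels[k],
                "intensity_factor": warp.intensity_factor,
            }
        )

    pset = build_profile_set(profiles)
    groups = GroupAssignment(
        case_ids=frozenset(sample_ids[:n_case]),
        control_ids=frozenset(sample_ids[n_case:]),
    )
    truth = {
        "effects": pd.DataFrame(
            {
                "protein_id": list(effect.protein_ids),
                "shift": effect.shift,
                "abundance_factor": effect.abundance_factor,
            }
        ),
        "gaps": pd.DataFrame(gap_rows),
        "samples": pd.DataFrame(sample_rows),
    }
    return pset, groups, truth
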