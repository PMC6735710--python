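from __future__ import annotations

import numpy as np
import pytest

from profalign import Profile, build_profile_set, normalize_sum


def make_profile(sample_id: str, mat, ids=None) -> Profile:
    mat = np.asarray(mat, dtype=float)
    if ids is None:
        ids = tuple(f"P{i:03d}" for i in range(mat.shape[0]))
    return Profile(sample_id=sample_id, protein_ids=tuple(ids), intensities=mat)


@pytest.fixture
def small_profiles():
    """Two 3-protein x 4-slice profiles over the same roster."""
    rng = np.random.default_rng(42)
    a = make_profile("a", rng.random((3, 4)) * 10)
    b = make_profile("b", rng.random((3, 4)) * 10)
    return a, b


@pytest.fixture
def normalized_pair(small_profiles):
    pset = build_profile_set(small_profiles)
    pset, _ = normalize_sum(pset)
    return pset
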