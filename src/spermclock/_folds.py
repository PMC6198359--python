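"""Deterministic k-fold partitioning shared by lambda selection and CV."""

from __future__ import annotations

import numpy as np

from .exceptions import InputError


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition ``range(n)`` into k shuffled folds with sizes differing by <= 1."""
    if k < 2:
        raise InputError(f"need at least 2 folds, got k={k}")
    if k > n:
        raise InputError(f"k={k} folds exceed n={n} samples")
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k)]
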