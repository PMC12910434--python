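"""Inference on monolayer roughness: a seeded two-sample permutation test
(difference of group means, two-sided, add-one rule) plus a thin
Mann-Whitney U pass-through."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["PermutationResult", "permutation_test", "rank_test_passthrough"]


@dataclass
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int


def permutation_test(
    group_a, group_b, n_perm: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Two-sample permutation test on the difference of means.

    The null distribution is built by reshuffling group labels; the
    two-sided p-value uses the add-one rule
    p = (1 + #{|T*| >= |T|}) / (n_perm + 1), so p is never exactly zero.
    Deterministic for a given seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs at least 2 values")
    if n_perm < 999:
        raise InvalidParameterError("n_perm must be at least 999")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = len(a)
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of uniform draws
    order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    shuffled = pooled[order]
    t_null = shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
    p = (1.0 + np.sum(np.abs(t_null) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    return PermutationResult(
        observed_diff=observed, p_value=float(p), n_permutations=n_perm, seed=seed
    )


def rank_test_passthrough(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (standard library routine)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("empty sample")
    return float(spstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
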