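"""Distribution-free contrast between land-abandonment stages.

The field (site) is the unit of replication: replicate bottles within a
field are pseudo-replicates and move with their field.  The test permutes
stage labels across fields and compares the observed difference of stage
means against the permutation distribution, two-sided:

    p = (1 + #{ |diff_perm| >= |diff_obs| }) / (1 + n_permutations).

With 3 + 3 fields the label assignment space is tiny (C(6,3) = 20 distinct
assignments, 19 besides the observed one), so exhaustive enumeration is
available and is the default there; because the complement of any assignment
yields the same |difference|, the smallest attainable two-sided p is
2/20 = 1/10.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientUnitsError


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float  # mean(stage B) - mean(stage A), labels sorted
    p_value: float
    n_permutations: int   # permutations actually compared against
    method: str           # "exhaustive" or "sampled"
    stages: tuple


def _check_inputs(values: np.ndarray, labels: np.ndarray) -> tuple:
    stages = tuple(sorted(set(labels.tolist())))
    if len(stages) != 2:
        raise InsufficientUnitsError(
            f"need exactly 2 stages, got {stages}"
        )
    for s in stages:
        if int((labels == s).sum()) < 2:
            raise InsufficientUnitsError(
                f"stage {s!r} has fewer than 2 fields: no valid permutation contrast"
            )
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    return stages


def _mean_diff(values: np.ndarray, mask_b: np.ndarray) -> float:
    return float(values[mask_b].mean() - values[~mask_b].mean())


def permutation_stage_test(
    values: Sequence[float],
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
    exhaustive: Optional[bool] = None,
) -> PermutationResult:
    """Two-sided permutation test of a stage effect on per-field values.

    ``values`` holds one number per field (e.g. the field mean of a
    response); ``labels`` the stage of each field.  ``exhaustive=None``
    enumerates all distinct label assignments when there are at most
    ``n_permutations`` of them, otherwise samples ``n_permutations`` random
    relabelings with the given seed.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    stages = _check_inputs(values, labels)
    mask_obs = labels == stages[1]
    observed = _mean_diff(values, mask_obs)
    n_b = int(mask_obs.sum())
    n = len(values)

    from math import comb

    n_distinct = comb(n, n_b)
    if exhaustive is None:
        exhaustive = n_distinct - 1 <= n_permutations

    if exhaustive:
        obs_set = frozenset(np.flatnonzero(mask_obs).tolist())
        count = 0
        n_done = 0
        for idx in combinations(range(n), n_b):
            if frozenset(idx) == obs_set:
                continue  # the identity assignment is the observed statistic
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if abs(_mean_diff(values, mask)) >= abs(observed):
                count += 1
            n_done += 1
        p = (1 + count) / (1 + n_done)
        return PermutationResult(observed, p, n_done, "exhaustive", stages)

    rng = np.random.default_rng(seed)
    # vectorized: each row of `order` is one random relabeling
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    masks = np.take(mask_obs, order)
    diffs = (values * masks).sum(axis=1) / n_b - (values * ~masks).sum(axis=1) / (n - n_b)
    count = int((np.abs(diffs) >= abs(observed)).sum())
    p = (1 + count) / (1 + n_permutations)
    return PermutationResult(observed, p, n_permutations, "sampled", stages)


def min_attainable_p(n_fields: int, n_stage_b: int) -> float:
    """Smallest p the exhaustive two-sided test can return for a design.

    Assignments come in complementary pairs with identical |difference|
    whenever the two stages have equal size, so the floor is one over the
    number of distinct unordered partitions: with 3 + 3 fields,
    C(6,3)/2 = 10 partitions and p_min = 1/10.
    """
    from math import comb

    n_assignments = comb(n_fields, n_stage_b)
    if 2 * n_stage_b == n_fields:
        return 2.0 / n_assignments
    return 1.0 / n_assignments
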