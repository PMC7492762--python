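"""Permutation test for overlap between two class assignments of the same
patients.

The observed statistic is the alignment-maximized agreement: the maximum,
over one-to-one matchings of the classes of one labelling to the classes of
the other, of the number of co-assigned patients (an assignment problem on
the cross-tabulation).  Because the matching is optimized, the statistic is
invariant to relabelling classes in either input, which lets a 2-class
structure be compared with a 3-class one.

The null distribution is generated by uniformly permuting the second
labelling, which preserves both sets of class proportions exactly
(fixed-marginal resampling).  The one-sided p-value uses the add-one
convention p = (#{null >= observed} + 1) / (N + 1), so p is never zero and
its minimum 1/(N+1) corresponds to "less than 1 in N" evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._rng import substream

__all__ = ["PermutationResult", "overlap_test", "matched_agreement"]


@dataclass
class PermutationResult:
    observed_statistic: int
    n_permutations: int
    n_null_ge_observed: int
    p_value: float
    seed: int


def matched_agreement(table: np.ndarray) -> int:
    """Maximum co-assignment count over class matchings (Hungarian)."""
    table = np.asarray(table)
    rows, cols = linear_sum_assignment(-table)
    return int(table[rows, cols].sum())


def _encode(labels) -> tuple[np.ndarray, int]:
    arr = np.asarray(labels)
    _, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1


def overlap_test(labels_a, labels_b, n_permutations: int = 100_000,
                 seed: int = 0, chunk: int = 2048) -> PermutationResult:
    """Fixed-marginal permutation test of class-membership overlap."""
    a, ka = _encode(labels_a)
    b, kb = _encode(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two patients")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    n = a.size
    obs_table = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(obs_table, (a, b), 1)
    observed = matched_agreement(obs_table)

    rng = substream(seed, "overlap")
    # enumerate injective column matchings once when the table is small
    small = max(ka, kb) <= 6
    if small:
        if ka <= kb:
            matchings = [(tuple(range(ka)), perm)
                         for perm in permutations(range(kb), ka)]
        else:
            matchings = [(perm, tuple(range(kb)))
                         for perm in permutations(range(ka), kb)]
        flat_idx = np.array([[r * kb + c for r, c in zip(rows, cols)]
                             for rows, cols in matchings])

    n_ge = 0
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm_b = rng.permuted(np.broadcast_to(b, (m, n)), axis=1)
        codes = a[None, :] * kb + perm_b
        codes = codes + (np.arange(m) * ka * kb)[:, None]
        tables = np.bincount(codes.ravel(), minlength=m * ka * kb)
        tables = tables.reshape(m, ka * kb)
        if small:
            stats = tables[:, flat_idx].sum(axis=2).max(axis=1)
        else:
            stats = np.fromiter(
                (matched_agreement(tb.reshape(ka, kb)) for tb in tables),
                dtype=np.int64, count=m)
        n_ge += int((stats >= observed).sum())
        done += m

    p = (n_ge + 1) / (n_permutations + 1)
    return PermutationResult(observed_statistic=observed,
                             n_permutations=int(n_permutations),
                             n_null_ge_observed=n_ge, p_value=float(p),
                             seed=int(seed))
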