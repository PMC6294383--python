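"""Congruence C between two partitions of the same species set.

C is the maximum proportion of species co-assigned by the two partitions
over all one-to-one matchings of group labels: group labels are arbitrary,
so the cluster labels are "rotated" against the module labels and the
highest agreement is kept.  The optimum is a maximum-weight assignment on
the k_a x k_b contingency table (weights = shared-species counts); an
exhaustive enumeration over label matchings gives the identical optimum and
is used for small k, reporting how many matchings were examined (3 x 3
groups need 6).

Significance comes from a permutation test: species are shuffled across the
second partition's groups holding group sizes fixed, C is recomputed, and
p = (#{C_perm >= C_obs} + 1) / (n_perm + 1); the raw proportion is also
reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .partition import Partition


@dataclass(frozen=True)
class CongruenceResult:
    c: float
    n_matched: int
    n_total: int
    matching: dict[int, int]  # label of `a` -> matched label of `b`
    n_matchings_examined: int | None = None
    p: float | None = None
    p_raw: float | None = None
    n_perm: int | None = None


def _label_arrays(a: Partition, b: Partition) -> tuple[np.ndarray, np.ndarray, list[str]]:
    shared = [s for s in a.species if s in b.assignment]
    if not shared:
        raise ValueError("partitions share no species")
    la = np.array([a.assignment[s] - 1 for s in shared])
    lb = np.array([b.assignment[s] - 1 for s in shared])
    return la, lb, shared


def _contingency(la: np.ndarray, lb: np.ndarray, ka: int, kb: int) -> np.ndarray:
    M = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(M, (la, lb), 1)
    return M


def _match_assignment(M: np.ndarray) -> tuple[int, dict[int, int]]:
    rows, cols = linear_sum_assignment(M, maximize=True)
    return int(M[rows, cols].sum()), {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


def _match_exhaustive(M: np.ndarray) -> tuple[int, dict[int, int], int]:
    """Enumerate all injective matchings of the smaller label set into the larger."""
    ka, kb = M.shape
    best, best_map, examined = -1, {}, 0
    if ka <= kb:
        for perm in permutations(range(kb), ka):
            examined += 1
            total = int(M[np.arange(ka), perm].sum())
            if total > best:
                best, best_map = total, {i + 1: p + 1 for i, p in enumerate(perm)}
    else:
        for perm in permutations(range(ka), kb):
            examined += 1
            total = int(M[perm, np.arange(kb)].sum())
            if total > best:
                best, best_map = total, {p + 1: j + 1 for j, p in enumerate(perm)}
    return best, best_map, examined


def congruence_C(a: Partition, b: Partition, method: str = "auto") -> CongruenceResult:
    """Maximum congruence between partitions a and b.

    ``method``: ``"assignment"`` (Hungarian algorithm), ``"exhaustive"``
    (all label matchings, counts them), or ``"auto"`` (exhaustive when the
    smaller group count is <= 6, assignment otherwise).  When group counts
    differ, the matching is injective from the smaller label set into the
    larger and unmatched groups contribute nothing — an extension of the
    equal-k definition, flagged by consumers.
    """
    la, lb, shared = _label_arrays(a, b)
    M = _contingency(la, lb, a.k, b.k)
    if method == "auto":
        method = "exhaustive" if min(a.k, b.k) <= 6 else "assignment"
    if method == "exhaustive":
        n_matched, matching, examined = _match_exhaustive(M)
    elif method == "assignment":
        n_matched, matching = _match_assignment(M)
        examined = None
    else:
        raise ValueError(f"unknown method {method!r}")
    n_total = len(shared)
    return CongruenceResult(
        c=n_matched / n_total,
        n_matched=n_matched,
        n_total=n_total,
        matching=matching,
        n_matchings_examined=examined,
    )


def congruence_permutation_test(
    a: Partition, b: Partition, n_perm: int = 999, seed: int = 0
) -> CongruenceResult:
    """Permutation test of C: shuffle species across b's groups, sizes fixed.

    p uses the add-one convention (never exactly 0); ``p_raw`` is the plain
    proportion of permutations with C_perm >= C_obs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    la, lb, shared = _label_arrays(a, b)
    ka, kb = a.k, b.k
    obs = congruence_C(a, b)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm_lb = rng.permutation(lb)
        M = _contingency(la, perm_lb, ka, kb)
        n_matched, _ = _match_assignment(M)
        if n_matched >= obs.n_matched:
            n_ge += 1
    return CongruenceResult(
        c=obs.c,
        n_matched=obs.n_matched,
        n_total=obs.n_total,
        matching=obs.matching,
        n_matchings_examined=obs.n_matchings_examined,
        p=(n_ge + 1) / (n_perm + 1),
        p_raw=n_ge / n_perm,
        n_perm=n_perm,
    )
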