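"""Partitioning around medoids (PAM) and gap-statistic k selection.

PAM clusters species on the Jaccard dissimilarity matrix by choosing k
medoid species minimizing the summed dissimilarity of every species to its
nearest medoid: a greedy BUILD phase seeds the medoids, then a SWAP phase
exchanges medoid / non-medoid pairs until no single swap lowers the cost.
Both phases break ties toward the lower species index, which makes the
procedure fully deterministic.

The number of clusters is either imposed (k = number of network modules) or
selected by the gap statistic of Tibshirani, Walther & Hastie: the observed
log within-cluster dispersion is compared with that of reference data drawn
from a structureless null.  The classical null needs feature vectors, so the
dissimilarity matrix is embedded by classical multidimensional scaling
(components covering >= 95% of the positive eigenvalue mass), reference
points are sampled uniformly within the embedding's bounding box, and
reference dissimilarities are Euclidean.  k_opt follows the 1-SE rule:
the smallest k with gap(k) >= gap(k+1) - se(k+1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .occurrence import DissimilarityMatrix
from .partition import Partition

_EPS = 1e-12


@dataclass(frozen=True)
class PAMResult:
    partition: Partition
    medoids: tuple[str, ...]
    total_cost: float


@dataclass(frozen=True)
class GapResult:
    k_values: tuple[int, ...]
    gap: tuple[float, ...]
    se: tuple[float, ...]
    k_opt: int
    b_refs: int
    seed: int


def _pam_core(D: np.ndarray, k: int) -> tuple[list[int], float]:
    """BUILD + SWAP on a square dissimilarity array; returns medoid indices."""
    n = D.shape[0]
    # BUILD: first medoid minimizes the summed dissimilarity; subsequent
    # medoids maximize the reduction in cost (argmin/argmax take the lowest
    # index on ties).
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, D[c])

    def cost(meds: list[int]) -> float:
        return float(D[np.sort(meds)].min(axis=0).sum())

    current = cost(medoids)
    # SWAP: best-improvement passes until a local optimum.  Exact cost ties
    # create plateaus on which different medoid sets have identical cost but
    # different neighbourhoods; deterministic sideways moves (lexicographically
    # smallest unvisited set, bounded) cross them instead of stalling.
    visited = {frozenset(medoids)}
    sideways_left = 50
    while True:
        best_delta, best_swap = _EPS, None
        tie_sets: list[tuple[tuple[int, ...], tuple[int, int]]] = []
        for mi, m_idx in enumerate(medoids):
            others = [m for j, m in enumerate(medoids) if j != mi]
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = cost(others + [h])
                delta = current - new_cost
                if delta > best_delta:
                    best_delta, best_swap = delta, (mi, h)
                elif abs(delta) <= _EPS:
                    tie_sets.append((tuple(sorted(others + [h])), (mi, h)))
        if best_swap is None:
            move = None
            for key, swap in sorted(tie_sets):
                if frozenset(key) not in visited:
                    move = swap
                    break
            if move is None or sideways_left == 0:
                break
            sideways_left -= 1
            best_swap = move
        mi, h = best_swap
        medoids[mi] = h
        current = cost(medoids)
        visited.add(frozenset(medoids))
    return sorted(medoids), current


def pam_cluster(d: DissimilarityMatrix, k: int, seed: int = 0) -> PAMResult:
    """PAM clustering of species into k groups.

    ``seed`` is accepted for interface symmetry with the stochastic stages
    but unused: BUILD/SWAP with lowest-index tie-breaking is deterministic.
    Assignment ties (equal dissimilarity to two medoids) go to the medoid
    with the lower species index.
    """
    n = len(d.species_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} species")
    D = np.asarray(d.d, dtype=float)
    medoids, total_cost = _pam_core(D, k)
    labels = np.argmin(D[medoids], axis=0)  # ties -> first (lower) medoid
    part = Partition.from_labels(
        list(d.species_ids), [int(l) + 1 for l in labels], source="cluster"
    )
    return PAMResult(
        partition=part,
        medoids=tuple(d.species_ids[m] for m in medoids),
        total_cost=total_cost,
    )


def _pam_cost(D: np.ndarray, k: int) -> float:
    return _pam_core(D, k)[1]


def cmds_embed(D: np.ndarray, var_frac: float = 0.95) -> np.ndarray:
    """Classical MDS embedding of a dissimilarity matrix.

    Keeps the leading components covering ``var_frac`` of the positive
    eigenvalue mass (at least one).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > _EPS
    w, V = w[pos], V[:, pos]
    if w.size == 0:  # all species identical
        return np.zeros((n, 1))
    frac = np.cumsum(w) / w.sum()
    keep = int(np.searchsorted(frac, var_frac) + 1)
    return V[:, :keep] * np.sqrt(w[:keep])


def gap_statistic(
    d: DissimilarityMatrix,
    k_max: int,
    b_refs: int = 50,
    seed: int = 0,
    rule: str = "1se",
) -> GapResult:
    """Gap-statistic selection of the number of PAM clusters.

    Dispersion W_k is PAM's own objective (summed dissimilarity to medoids).
    ``rule`` is ``"1se"`` (default, smallest k passing the 1-SE criterion)
    or ``"max"`` (global gap maximum).  k_opt = 1 is a legal outcome.
    """
    n = len(d.species_ids)
    if not 1 <= k_max <= n:
        raise ValueError(f"k_max={k_max} out of range for {n} species")
    if b_refs < 1:
        raise ValueError("b_refs must be >= 1")
    if rule not in ("1se", "max"):
        raise ValueError(f"unknown rule {rule!r}")
    D = np.asarray(d.d, dtype=float)
    ks = list(range(1, k_max + 1))
    log_w = np.array([np.log(max(_pam_cost(D, k), _EPS)) for k in ks])

    X = cmds_embed(D)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(seed)
    log_w_ref = np.empty((b_refs, len(ks)))
    for b in range(b_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        Dref = squareform(pdist(ref))
        log_w_ref[b] = [np.log(max(_pam_cost(Dref, k), _EPS)) for k in ks]

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1 + 1 / b_refs)

    if rule == "max":
        k_opt = ks[int(np.argmax(gap))]
    else:
        k_opt = ks[-1]
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                k_opt = ks[i]
                break
    return GapResult(
        k_values=tuple(ks),
        gap=tuple(float(g) for g in gap),
        se=tuple(float(s) for s in se),
        k_opt=k_opt,
        b_refs=b_refs,
        seed=seed,
    )
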