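"""Range centroids and the spatial-clustering permutation test.

A species' range centroid is the unweighted mean of the planar (equal-area,
km) centroids of the occupancy units it occupies.  Given a partition of the
species, the spatial-clustering statistic is the ratio of the mean pairwise
Euclidean distance between centroids of same-group species (MD_within,
pooled over all within-group pairs) to the mean over different-group pairs
(MD_among).  A ratio < 1 indicates spatially aggregated groups, the
signature of environmental filtering.

Significance follows the multi-response permutation procedure (MRPP)
convention: species are shuffled among groups holding group sizes fixed,
the statistic is recomputed, and p is the probability of clustering at
least as strong as observed — p = (#{stat_perm <= stat_obs} + 1)/(n_perm + 1).
Two alternative statistics are provided: the MRPP weighted within-group
delta, and a "literal" rule that counts permutations with
MD_within >= MD_among (reported for audit; it is not a calibrated test).
Species ranges are never re-simulated in the null.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import AmongGroupsImpossibleError, NoWithinPairsError
from .partition import Partition

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnitCentroidTable:
    """Planar centroids (km) of the occupancy units, e.g. watershed units."""

    unit_ids: tuple[str, ...]
    coords: np.ndarray  # (n_units, 2)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.unit_ids), 2):
            raise ValueError("coords must be (n_units, 2)")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids")
        if not np.isfinite(c).all():
            raise ValueError("coordinates must be finite")

    def lookup(self, unit_ids: list[str]) -> np.ndarray:
        index = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            rows = [index[u] for u in unit_ids]
        except KeyError as exc:
            raise KeyError(f"unknown unit id: {exc.args[0]!r}") from None
        return self.coords[rows]

    @staticmethod
    def read_csv(path: str | Path) -> "UnitCentroidTable":
        """CSV with columns unit_id, x_km, y_km."""
        df = pd.read_csv(path, dtype={"unit_id": str})
        return UnitCentroidTable(
            unit_ids=tuple(df["unit_id"]),
            coords=df[["x_km", "y_km"]].to_numpy(dtype=float),
        )

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"unit_id": self.unit_ids,
             "x_km": self.coords[:, 0],
             "y_km": self.coords[:, 1]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CentroidTable:
    """One planar range centroid (km) per species."""

    species_ids: tuple[str, ...]
    coords: np.ndarray  # (n_species, 2)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.species_ids), 2):
            raise ValueError("coords must be (n_species, 2)")
        if not np.isfinite(c).all():
            raise ValueError("coordinates must be finite")

    def subset(self, species: list[str]) -> "CentroidTable":
        index = {s: i for i, s in enumerate(self.species_ids)}
        rows = [index[s] for s in species]
        return CentroidTable(tuple(species), self.coords[rows])

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species": self.species_ids,
             "x_km": self.coords[:, 0],
             "y_km": self.coords[:, 1]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SpatialClusterResult:
    md_within: float
    md_among: float
    ratio: float
    p: float | None = None
    p_raw: float | None = None
    n_perm: int | None = None
    statistic: str = "ratio"


def interpolate_centroid(
    units: UnitCentroidTable, occupied: list[str]
) -> tuple[float, float]:
    """Unweighted mean coordinate of the occupied units."""
    if not occupied:
        raise ValueError("empty occupancy: no units to average")
    xy = units.lookup(occupied).mean(axis=0)
    return float(xy[0]), float(xy[1])


def species_centroids(
    units: UnitCentroidTable, occupancy: pd.DataFrame
) -> CentroidTable:
    """Range centroid of every species in a species-by-unit 0/1 table.

    ``occupancy`` has species ids as index and unit ids as columns.  Species
    occupying no unit are excluded and logged ("missing centroid").
    """
    kept, coords, missing = [], [], []
    for sp in occupancy.index:
        occ = [str(u) for u in occupancy.columns[occupancy.loc[sp].to_numpy() > 0]]
        if not occ:
            missing.append(str(sp))
            continue
        kept.append(str(sp))
        coords.append(interpolate_centroid(units, occ))
    if missing:
        log.warning("missing centroid (no occupied units) for %d species: %s",
                    len(missing), missing)
    return CentroidTable(tuple(kept), np.asarray(coords, dtype=float))


def _masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    same = labels[:, None] == labels[None, :]
    iu = np.triu(np.ones_like(same, dtype=bool), k=1)
    return same & iu, ~same & iu


def _md(D: np.ndarray, within_mask: np.ndarray, among_mask: np.ndarray) -> tuple[float, float]:
    return float(D[within_mask].mean()), float(D[among_mask].mean())


def _mrpp_delta(D: np.ndarray, labels: np.ndarray) -> float:
    """Group-size-weighted mean within-group distance (classical MRPP delta)."""
    total = 0.0
    n = len(labels)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        total += (len(idx) / n) * sub[np.triu_indices(len(idx), k=1)].mean()
    return total


def _prepare(c: CentroidTable, p: Partition) -> tuple[np.ndarray, np.ndarray]:
    shared = [s for s in c.species_ids if s in p.assignment]
    missing = [s for s in p.species if s not in set(c.species_ids)]
    if missing:
        log.warning("%d partitioned species lack centroids and are excluded: %s",
                    len(missing), missing)
    sub = c.subset(shared)
    labels = np.array([p.assignment[s] for s in shared])
    if len(np.unique(labels)) < 2:
        raise AmongGroupsImpossibleError(
            "k = 1: among-group comparison impossible"
        )
    D = squareform(pdist(sub.coords))
    within_mask, _ = _masks(labels)
    if not within_mask.any():
        raise NoWithinPairsError("all groups are singletons: no within-group pairs")
    return D, labels


def mean_distance_ratio(c: CentroidTable, p: Partition) -> SpatialClusterResult:
    """MD_within, MD_among (km) and their ratio for a partition of species."""
    D, labels = _prepare(c, p)
    w_mask, a_mask = _masks(labels)
    md_w, md_a = _md(D, w_mask, a_mask)
    return SpatialClusterResult(md_within=md_w, md_among=md_a, ratio=md_w / md_a)


def spatial_permutation_test(
    c: CentroidTable,
    p: Partition,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "ratio",
) -> SpatialClusterResult:
    """MRPP-style permutation test of spatial clustering.

    ``statistic``: ``"ratio"`` (MD_within / MD_among, default), ``"delta"``
    (size-weighted within-group mean distance, classical MRPP), or
    ``"literal"`` (p = proportion of permutations with MD_within >= MD_among,
    audit only — not a calibrated test).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("ratio", "delta", "literal"):
        raise ValueError(f"unknown statistic {statistic!r}")
    D, labels = _prepare(c, p)
    w_mask, a_mask = _masks(labels)
    md_w, md_a = _md(D, w_mask, a_mask)
    rng = np.random.default_rng(seed)

    if statistic == "literal":
        n_hit = 0
        for _ in range(n_perm):
            lab = rng.permutation(labels)
            wm, am = _masks(lab)
            pw, pa = _md(D, wm, am)
            if pw >= pa:
                n_hit += 1
        return SpatialClusterResult(
            md_within=md_w, md_among=md_a, ratio=md_w / md_a,
            p=(n_hit + 1) / (n_perm + 1), p_raw=n_hit / n_perm,
            n_perm=n_perm, statistic=statistic,
        )

    if statistic == "ratio":
        def stat(lab: np.ndarray) -> float:
            wm, am = _masks(lab)
            pw, pa = _md(D, wm, am)
            return pw / pa
    else:
        def stat(lab: np.ndarray) -> float:
            return _mrpp_delta(D, lab)

    obs = stat(labels)
    n_le = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) <= obs:
            n_le += 1
    return SpatialClusterResult(
        md_within=md_w, md_among=md_a, ratio=md_w / md_a,
        p=(n_le + 1) / (n_perm + 1), p_raw=n_le / n_perm,
        n_perm=n_perm, statistic=statistic,
    )
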