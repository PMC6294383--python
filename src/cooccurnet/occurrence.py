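"""Presence-absence matrices and the two structures the pipeline branches on.

A site x species incidence matrix is converted either to a co-occurrence
edge list (species pairs sharing at least one site, the input to network
construction) or to a species x species Jaccard dissimilarity matrix (the
input to medoid clustering).  Species are the objects being grouped, so
Jaccard is computed between species profiles across sites.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateMatrixError, InsufficientSamplesError, ParseError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Validated binary site x species incidence.

    Every retained species occurs at >= 1 site and every retained site hosts
    >= 1 species; ids are unique.  ``incidence[i, j]`` is 1 iff species
    ``species_ids[j]`` was recorded at site ``site_ids[i]``.
    """

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    incidence: np.ndarray  # (n_sites, n_species) of 0/1, int8

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError("incidence shape does not match id lists")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence cells must be 0 or 1")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def occurrence_counts(self) -> pd.Series:
        """Per-species number of occupied sites (N1, N2, ... of the model)."""
        return pd.Series(
            self.incidence.sum(axis=0), index=list(self.species_ids), name="n_sites_occupied"
        )

    def column(self, species: str) -> np.ndarray:
        try:
            j = self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"unknown species id: {species!r}") from None
        return self.incidence[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=list(self.site_ids), columns=list(self.species_ids)
        )

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "OccurrenceMatrix":
        """Validate a sites-by-species 0/1 DataFrame, dropping empty rows/columns."""
        return _validate(df)


@dataclass(frozen=True)
class EdgeList:
    """Unordered species pairs sharing >= 1 site, with shared-site counts.

    Pairs are stored with species ordered as in the source matrix, each pair
    once.  Counts are retained even though downstream networks are unweighted:
    the effect-size module reuses them.
    """

    pairs: tuple[tuple[str, str], ...]
    co_counts: tuple[int, ...]

    def as_dict(self) -> dict[tuple[str, str], int]:
        return dict(zip(self.pairs, self.co_counts))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_a": [a for a, _ in self.pairs],
                "species_b": [b for _, b in self.pairs],
                "n_shared_sites": list(self.co_counts),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric species x species dissimilarity in [0, 1], zero diagonal."""

    species_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValueError("dissimilarity must be square over species_ids")
        if not np.allclose(d, d.T):
            raise ValueError("dissimilarity must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.species_ids)
        return pd.DataFrame(self.d, index=ids, columns=ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def _validate(df: pd.DataFrame) -> OccurrenceMatrix:
    arr = df.to_numpy()
    empty_species = df.columns[arr.sum(axis=0) == 0]
    if len(empty_species):
        log.warning("dropping %d species with zero occurrences: %s",
                    len(empty_species), list(empty_species))
        df = df.drop(columns=empty_species)
    empty_sites = df.index[df.to_numpy().sum(axis=1) == 0]
    if len(empty_sites):
        log.warning("dropping %d sites with no species", len(empty_sites))
        df = df.drop(index=empty_sites)
    return OccurrenceMatrix(
        site_ids=tuple(str(s) for s in df.index),
        species_ids=tuple(str(s) for s in df.columns),
        incidence=df.to_numpy(dtype=np.int8),
    )


def read_occurrence_matrix(path: str | Path, min_sites: int = 1) -> OccurrenceMatrix:
    """Read and validate a presence-absence CSV.

    Format: comma-separated, first row = species ids, first column = site
    ids, every cell strictly ``0`` or ``1``.  Species with zero occurrences
    and all-zero sites are dropped (logged).  If the retained site count is
    below ``min_sites`` the basin is rejected with
    :class:`InsufficientSamplesError` — a distinct signal from a parse error.
    """
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot read occurrence CSV {path}: {exc}") from exc
    for col in df.columns:
        bad = ~df[col].isin(("0", "1"))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-binary cell at site {row!r}, species {col!r} in {path}"
            )
    m = _validate(df.astype(np.int8))
    if m.n_sites < min_sites:
        raise InsufficientSamplesError(
            f"{m.n_sites} sites retained, minimum is {min_sites}"
        )
    return m


def build_edge_list(m: OccurrenceMatrix) -> EdgeList:
    """All unordered species pairs co-occurring at >= 1 site.

    The co-count for a pair is the dot product of the two 0/1 columns.
    """
    if m.n_species < 2:
        raise DegenerateMatrixError("need >= 2 species to build an edge list")
    co = m.incidence.T.astype(np.int64) @ m.incidence.astype(np.int64)
    iu = np.triu_indices(m.n_species, k=1)
    counts = co[iu]
    keep = counts >= 1
    pairs = tuple(
        (m.species_ids[i], m.species_ids[j])
        for i, j in zip(iu[0][keep], iu[1][keep])
    )
    return EdgeList(pairs=pairs, co_counts=tuple(int(c) for c in counts[keep]))


def jaccard_dissimilarity(m: OccurrenceMatrix) -> DissimilarityMatrix:
    """Species x species Jaccard dissimilarity, d = 1 - |A∩B| / |A∪B|.

    Computed between species occurrence profiles across sites (the matrix is
    transposed relative to a site-wise dissimilarity) because the pipeline
    partitions species, not sites.
    """
    if m.n_species < 2:
        raise DegenerateMatrixError("need >= 2 species for a dissimilarity matrix")
    d = squareform(pdist(m.incidence.T.astype(bool), metric="jaccard"))
    return DissimilarityMatrix(species_ids=m.species_ids, d=d)
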