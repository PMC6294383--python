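"""Synthetic communities with planted structure.

The generator emulates the two confounded signals the analysis is meant to
separate: *environmental filtering* (habitat groups — each species occurs
with high probability p_in at sites of its own habitat group and low
probability p_out elsewhere) and *positive association* (a host-conditional
nest complex — each associate's occurrence probability at a site depends
only on whether the host is present there).  Range centroids come in two
spatial modes: "clustered" (each group's species ranges drawn around a
group-specific mean, means separated by ``group_sep_km``) and "common"
(all species from one distribution), mirroring the filtering vs interaction
scenarios the spatial test is designed to distinguish.

Occurrences are independent Bernoulli draws given habitat / host presence;
this is the simplest mechanism producing both signals in controllable
doses.  Everything is reproducible bit-for-bit given ``seed``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nests import NestComplexSpec
from .occurrence import OccurrenceMatrix
from .partition import Partition
from .spatial import UnitCentroidTable


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a planted community.

    Defaults are the planted-structure regime the package's validation runs
    use: 3 habitat groups of 20 species over 100 sites with p_in = 0.9 /
    p_out = 0.05, clustered ranges with 50 km group separation and 10 km
    within-group spread (a 5-sigma separation), and — when a complex is
    planted — 6 associates at p(occur | host) = 0.8 vs 0.05 otherwise.
    """

    n_sites: int = 100
    n_groups: int = 3
    species_per_group: int = 20
    p_in: float = 0.9
    p_out: float = 0.05
    site_group_mix: tuple[float, ...] | None = None  # None -> balanced
    spatial_mode: str = "clustered"  # clustered | common
    group_sep_km: float = 50.0
    sigma_km: float = 10.0
    n_units_per_species: int = 30
    host_group: int | None = None
    n_associates: int = 6
    p_assoc_given_host: float = 0.8
    p_assoc_no_host: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "p_assoc_given_host", "p_assoc_no_host"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.n_sites < 1 or self.species_per_group < 1:
            raise ValueError("n_sites and species_per_group must be >= 1")
        if self.spatial_mode not in ("clustered", "common"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        if self.site_group_mix is not None:
            mix = self.site_group_mix
            if len(mix) != self.n_groups or any(w < 0 for w in mix) or sum(mix) <= 0:
                raise ValueError("site_group_mix must be n_groups non-negative weights")
        if self.host_group is not None and not 1 <= self.host_group <= self.n_groups:
            raise ValueError("host_group out of range")
        if self.n_associates < 1:
            raise ValueError("n_associates must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside the data."""

    partition: Partition  # source = "planted"
    group_centroid_means: tuple[tuple[float, float], ...]
    complex: NestComplexSpec | None = None


def _site_group_counts(cfg: SyntheticConfig) -> np.ndarray:
    mix = np.asarray(
        cfg.site_group_mix
        if cfg.site_group_mix is not None
        else [1.0] * cfg.n_groups,
        dtype=float,
    )
    mix = mix / mix.sum()
    counts = np.floor(mix * cfg.n_sites).astype(int)
    # largest-remainder distribution of the leftover sites
    rem = cfg.n_sites - counts.sum()
    order = np.argsort(-(mix * cfg.n_sites - counts))
    counts[order[:rem]] += 1
    return counts


def generate_occurrences(cfg: SyntheticConfig) -> tuple[OccurrenceMatrix, SyntheticTruth]:
    """Draw a planted occurrence matrix and its ground truth.

    Species ids are ``g{group}_s{idx}``; a planted host is ``g{group}_host``
    and associates ``g{group}_a{idx}``.  Host and associates are extra
    species on top of ``species_per_group``; associates occur conditionally
    on host presence only.  Zero-occurrence species (possible at extreme
    p_out) are dropped by validation, and the truth partition is restricted
    to the retained species.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _site_group_counts(cfg)
    site_groups = np.repeat(np.arange(1, cfg.n_groups + 1), counts)
    site_ids = [f"site{i:04d}" for i in range(cfg.n_sites)]

    species, labels, cols = [], [], []
    for g in range(1, cfg.n_groups + 1):
        p_site = np.where(site_groups == g, cfg.p_in, cfg.p_out)
        for s in range(cfg.species_per_group):
            species.append(f"g{g}_s{s:02d}")
            labels.append(g)
            cols.append((rng.random(cfg.n_sites) < p_site).astype(np.int8))

    complex_spec = None
    if cfg.host_group is not None:
        g = cfg.host_group
        host_id = f"g{g}_host"
        p_site = np.where(site_groups == g, cfg.p_in, cfg.p_out)
        host_col = (rng.random(cfg.n_sites) < p_site).astype(np.int8)
        species.append(host_id)
        labels.append(g)
        cols.append(host_col)
        assoc_ids = []
        for a in range(cfg.n_associates):
            aid = f"g{g}_a{a:02d}"
            p_site = np.where(host_col == 1, cfg.p_assoc_given_host, cfg.p_assoc_no_host)
            species.append(aid)
            labels.append(g)
            cols.append((rng.random(cfg.n_sites) < p_site).astype(np.int8))
            assoc_ids.append(aid)
        complex_spec = NestComplexSpec(host=host_id, associates=tuple(assoc_ids))

    df = pd.DataFrame(np.column_stack(cols), index=site_ids, columns=species)
    matrix = OccurrenceMatrix.from_dataframe(df)

    retained = set(matrix.species_ids)
    planted = Partition.from_labels(
        [s for s in species if s in retained],
        [l for s, l in zip(species, labels) if s in retained],
        source="planted",
    )
    means = _group_means(cfg)
    return matrix, SyntheticTruth(
        partition=planted,
        group_centroid_means=tuple((float(x), float(y)) for x, y in means),
        complex=complex_spec,
    )


def _group_means(cfg: SyntheticConfig) -> np.ndarray:
    # group centroid means on a line at group_sep_km spacing; "common" mode
    # collapses every mean to the origin (sep = 0 is the same distribution)
    if cfg.spatial_mode == "common":
        return np.zeros((cfg.n_groups, 2))
    x = np.arange(cfg.n_groups) * cfg.group_sep_km
    return np.column_stack([x, np.zeros(cfg.n_groups)])


def generate_planted_network(
    n_species: int = 60,
    n_groups: int = 3,
    p_in: float = 0.9,
    p_out: float = 0.05,
    seed: int = 0,
) -> tuple["Network", Partition]:
    """Planted-partition random graph (stochastic block model).

    Each within-group species pair is linked with probability ``p_in`` and
    each cross-group pair with ``p_out``.  This generates network-level
    planted structure directly — the regime module-detection validation
    uses — as opposed to :func:`generate_occurrences`, whose binarized
    co-occurrence graph saturates (any pair sharing >= 1 of many sites is
    linked) and is intentionally a much harder target.
    """
    from .network import Network  # local import to avoid a cycle

    if n_species % n_groups:
        raise ValueError("n_species must divide evenly into n_groups")
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    per = n_species // n_groups
    labels = np.repeat(np.arange(1, n_groups + 1), per)
    ids = [f"g{g}_s{i:02d}" for g, i in zip(labels, range(n_species))]
    edges = []
    for i in range(n_species):
        for j in range(i + 1, n_species):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                edges.append((ids[i], ids[j]))
    connected = {v for e in edges for v in e}
    net = Network(
        nodes=tuple(v for v in ids if v in connected),
        edges=tuple(edges),
        isolated=tuple(v for v in ids if v not in connected),
    )
    truth = Partition.from_labels(
        [v for v in ids if v in connected],
        [int(l) for v, l in zip(ids, labels) if v in connected],
        source="planted",
    )
    return net, truth


def generate_centroid_tables(
    cfg: SyntheticConfig, truth: SyntheticTruth
) -> tuple[UnitCentroidTable, pd.DataFrame]:
    """Occupancy-unit centroids and a species-by-unit occupancy table.

    Each species gets ``n_units_per_species`` units drawn from an isotropic
    bivariate normal around its group's mean (clustered) or around a common
    origin (common mode); units are species-specific with unique ids.  The
    derived range centroid of a species is therefore a sample mean around
    its group mean.  Uses a seed offset so occurrence and centroid draws are
    independent streams of the same master seed.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    means = np.asarray(truth.group_centroid_means, dtype=float)
    unit_ids, coords, occ_rows = [], [], {}
    for sp in truth.partition.species:
        g = truth.partition.assignment[sp]
        mu = means[g - 1]
        pts = rng.normal(mu, cfg.sigma_km, size=(cfg.n_units_per_species, 2))
        ids = [f"{sp}_u{j:03d}" for j in range(cfg.n_units_per_species)]
        unit_ids.extend(ids)
        coords.append(pts)
        occ_rows[sp] = ids
    units = UnitCentroidTable(tuple(unit_ids), np.vstack(coords))
    occupancy = pd.DataFrame(
        0, index=list(occ_rows), columns=list(unit_ids), dtype=np.int8
    )
    for sp, ids in occ_rows.items():
        occupancy.loc[sp, ids] = 1
    return units, occupancy


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Persist the ground truth as JSON."""
    payload = {
        "partition": dict(truth.partition.assignment),
        "group_centroid_means": list(map(list, truth.group_centroid_means)),
        "complex": (
            {"host": truth.complex.host, "associates": list(truth.complex.associates)}
            if truth.complex
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    part = Partition.from_labels(
        list(payload["partition"]), list(payload["partition"].values()), "planted"
    )
    cx = payload.get("complex")
    return SyntheticTruth(
        partition=part,
        group_centroid_means=tuple(
            (float(x), float(y)) for x, y in payload["group_centroid_means"]
        ),
        complex=NestComplexSpec(cx["host"], tuple(cx["associates"])) if cx else None,
    )
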