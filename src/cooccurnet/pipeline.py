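"""Per-basin orchestration of the full analysis.

One basin = one occurrence matrix.  The run follows the workflow: matrix →
{edge list → network → annealing modules} and {Jaccard → PAM clusters}, then
module-vs-cluster congruence with a permutation test, spatial-clustering
tests on range centroids for each grouping, gap-statistic selection of an
optimal cluster number, and (optionally) nest-complex evaluation.  Analyses
that are impossible for a basin (k_opt = 1, or k_opt equal to the module
count making the optimal-k spatial test redundant) are reported with an
explicit skip reason rather than omitted.

A single master seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` derivation, so any stage can be re-run in
isolation with the same stream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .congruence import CongruenceResult, congruence_permutation_test
from .cooccur import effect_size_table
from .errors import AmongGroupsImpossibleError, InsufficientSamplesError
from .medoids import GapResult, gap_statistic, pam_cluster
from .nests import NestComplexResult, NestComplexSpec, effect_contrast
from .network import ModularityResult, build_network, detect_modules_sa
from .occurrence import (OccurrenceMatrix, build_edge_list, jaccard_dissimilarity,
                         read_occurrence_matrix)
from .partition import Partition
from .spatial import (CentroidTable, SpatialClusterResult, UnitCentroidTable,
                      spatial_permutation_test, species_centroids)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide knobs; defaults follow the analysis' standard settings."""

    min_sites: int = 1
    n_perm: int = 999
    spins: int = 100
    start_temp: float = 1.0
    stop_temp: float = 0.01
    cooling: float = 0.99
    restarts: int = 1
    k_max: int = 10
    b_refs: int = 50
    seed: int = 0

    def sa_params(self) -> dict:
        return {
            "spins": self.spins,
            "start_temp": self.start_temp,
            "stop_temp": self.stop_temp,
            "cooling": self.cooling,
        }


def stage_seeds(master: int, n: int = 8) -> list[int]:
    """Fixed fan-out of a master seed into per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class BasinReport:
    """Everything computed (or explicitly skipped) for one basin."""

    basin: str
    scale: str
    n_sites: int = 0
    n_species: int = 0
    n_modules: int = 0
    q: float = float("nan")
    modules: Partition | None = None
    clusters_k_modules: Partition | None = None
    clusters_k_opt: Partition | None = None
    congruence: CongruenceResult | None = None
    gap: GapResult | None = None
    spatial_modules: SpatialClusterResult | None = None
    spatial_clusters: SpatialClusterResult | None = None
    spatial_clusters_opt: SpatialClusterResult | None = None
    nest_by_grouping: dict[str, NestComplexResult] = field(default_factory=dict)
    isolated_species: tuple[str, ...] = ()
    skipped: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def summary_row(self) -> dict:
        """Flat row mirroring the per-basin report table."""
        row = {
            "scale": self.scale,
            "basin": self.basin,
            "n_sites": self.n_sites,
            "n_species": self.n_species,
            "modules": self.n_modules,
            "q": self.q,
            "C": self.congruence.c if self.congruence else None,
            "C_p": self.congruence.p if self.congruence else None,
            "md_ratio_modules": self.spatial_modules.ratio if self.spatial_modules else None,
            "md_p_modules": self.spatial_modules.p if self.spatial_modules else None,
            "md_ratio_clusters": self.spatial_clusters.ratio if self.spatial_clusters else None,
            "md_p_clusters": self.spatial_clusters.p if self.spatial_clusters else None,
            "gap_k_opt": self.gap.k_opt if self.gap else None,
            "md_ratio_clusters_opt": (
                self.spatial_clusters_opt.ratio if self.spatial_clusters_opt else None
            ),
            "md_p_clusters_opt": (
                self.spatial_clusters_opt.p if self.spatial_clusters_opt else None
            ),
        }
        for key, reason in self.skipped.items():
            row[f"skipped_{key}"] = reason
        return row


def _spatial(centroids, partition, n_perm, seed, report, key):
    try:
        return spatial_permutation_test(centroids, partition, n_perm=n_perm, seed=seed)
    except AmongGroupsImpossibleError:
        report.skipped[key] = "among-group comparison impossible (k = 1)"
        return None


def run_basin_analysis(
    occurrence: str | Path | OccurrenceMatrix,
    unit_centroids: str | Path | UnitCentroidTable | None,
    occupancy: str | Path | pd.DataFrame | None,
    config: PipelineConfig = PipelineConfig(),
    nest_spec: NestComplexSpec | None = None,
    basin: str = "basin",
    scale: str = "",
) -> BasinReport:
    """Run the full workflow for one basin and return its report."""
    report = BasinReport(basin=basin, scale=scale)
    seeds = stage_seeds(config.seed)
    report.seeds = {
        "modules": seeds[0], "gap": seeds[1], "congruence": seeds[2],
        "spatial_modules": seeds[3], "spatial_clusters": seeds[4],
        "spatial_clusters_opt": seeds[5],
    }

    if isinstance(occurrence, OccurrenceMatrix):
        m = occurrence
        if m.n_sites < config.min_sites:
            raise InsufficientSamplesError(
                f"basin {basin}: {m.n_sites} sites < minimum {config.min_sites}"
            )
    else:
        m = read_occurrence_matrix(occurrence, min_sites=config.min_sites)
    report.n_sites, report.n_species = m.n_sites, m.n_species

    edges = build_edge_list(m)
    net = build_network(edges, all_species=list(m.species_ids))
    report.isolated_species = net.isolated

    mod = detect_modules_sa(
        net, params=config.sa_params(), seed=seeds[0], restarts=config.restarts
    )
    report.modules = mod.partition
    report.n_modules = mod.partition.k
    report.q = mod.q

    diss = jaccard_dissimilarity(m)
    pam = pam_cluster(diss, k=report.n_modules)
    report.clusters_k_modules = pam.partition

    report.congruence = congruence_permutation_test(
        mod.partition, pam.partition, n_perm=config.n_perm, seed=seeds[2]
    )

    k_max = min(config.k_max, m.n_species - 1)
    report.gap = gap_statistic(diss, k_max=k_max, b_refs=config.b_refs, seed=seeds[1])
    k_opt = report.gap.k_opt
    if k_opt == report.n_modules:
        report.clusters_k_opt = pam.partition
        report.skipped["spatial_clusters_opt"] = (
            "optimal cluster number equals module count; results identical to k = modules"
        )
    else:
        report.clusters_k_opt = pam_cluster(diss, k=k_opt).partition
        report.skipped["congruence_opt"] = (
            "cluster and module counts differ; congruence not calculated"
        )

    centroids: CentroidTable | None = None
    if unit_centroids is not None and occupancy is not None:
        units = (
            unit_centroids
            if isinstance(unit_centroids, UnitCentroidTable)
            else UnitCentroidTable.read_csv(unit_centroids)
        )
        occ = (
            occupancy
            if isinstance(occupancy, pd.DataFrame)
            else pd.read_csv(occupancy, index_col=0)
        )
        centroids = species_centroids(units, occ)
        report.spatial_modules = _spatial(
            centroids, mod.partition, config.n_perm, seeds[3], report, "spatial_modules"
        )
        report.spatial_clusters = _spatial(
            centroids, pam.partition, config.n_perm, seeds[4], report, "spatial_clusters"
        )
        if "spatial_clusters_opt" not in report.skipped:
            report.spatial_clusters_opt = _spatial(
                centroids, report.clusters_k_opt, config.n_perm, seeds[5],
                report, "spatial_clusters_opt",
            )

    if nest_spec is not None:
        effects = effect_size_table(m)
        for key, part in (
            ("modules", mod.partition),
            ("clusters_k_modules", pam.partition),
            ("clusters_k_opt", report.clusters_k_opt),
        ):
            if part is None or nest_spec.host not in part.assignment:
                report.skipped[f"nest_{key}"] = "host absent from grouping"
                continue
            report.nest_by_grouping[key] = effect_contrast(effects, net, part, nest_spec)

    return report


@dataclass(frozen=True)
class BasinInput:
    """Paths and thresholds for one basin in a multi-scale run."""

    basin: str
    scale: str
    occurrence: str | Path
    unit_centroids: str | Path | None = None
    occupancy: str | Path | None = None
    min_sites: int = 1


def run_nested_scales(
    basins: Sequence[BasinInput],
    config: PipelineConfig = PipelineConfig(),
    nest_spec: NestComplexSpec | None = None,
) -> list[BasinReport]:
    """Run every basin passing its scale's site threshold.

    Basins are analyzed independently (a species occurring in several
    sub-basins appears once per sub-basin network).  Basins below their
    ``min_sites`` are excluded with a logged reason.  Basin ids must be
    unique.
    """
    ids = [b.basin for b in basins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate basin ids in nested-scale run")
    reports = []
    for i, b in enumerate(basins):
        cfg_b = PipelineConfig(
            **{**config.__dict__, "min_sites": b.min_sites,
               "seed": stage_seeds(config.seed, len(basins) + 8)[8 + i]},
        )
        try:
            reports.append(
                run_basin_analysis(
                    b.occurrence, b.unit_centroids, b.occupancy, cfg_b,
                    nest_spec=nest_spec, basin=b.basin, scale=b.scale,
                )
            )
        except InsufficientSamplesError as exc:
            log.warning("basin %s excluded: %s", b.basin, exc)
    return reports


def reports_to_table(reports: Sequence[BasinReport]) -> pd.DataFrame:
    """Flatten basin reports into the summary table."""
    return pd.DataFrame([r.summary_row() for r in reports])
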