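"""Nest-associate complex evaluation.

Nest association is a reproductive strategy in which smaller associate
fishes deposit eggs in the gravel-mound nest of a host (e.g. minnows in a
chub's nest).  If a grouping method captures positive biotic interactions,
the host and its associates should land in the same group.  Two checks are
provided: *completeness* — the proportion of associates sharing the host's
group under a given partition — and an *effect contrast* — mean/s.d. of the
pairwise co-occurrence effect sizes of host-associate pairs versus the
whole network (and its within-/among-module split).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Network
from .partition import Partition

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NestComplexSpec:
    """A declared host species and its known associates."""

    host: str
    associates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.associates:
            raise ValueError("at least one associate required")
        if self.host in self.associates:
            raise ValueError("host cannot be its own associate")
        if len(set(self.associates)) != len(self.associates):
            raise ValueError("duplicate associate ids")


@dataclass(frozen=True)
class NestComplexResult:
    completeness: float
    n_present: int
    n_associates: int
    effect_mean_complex: float
    effect_sd_complex: float
    effect_mean_all: float
    effect_sd_all: float
    effect_mean_within: float
    effect_sd_within: float
    effect_mean_among: float
    effect_sd_among: float


def completeness(p: Partition, spec: NestComplexSpec) -> float:
    """Proportion of associates sharing the host's group label.

    Associates absent from the partition count as not co-grouped (logged);
    the denominator is the declared associate list.
    """
    if spec.host not in p.assignment:
        raise KeyError(f"host {spec.host!r} not in partition")
    host_group = p.assignment[spec.host]
    absent = [a for a in spec.associates if a not in p.assignment]
    if absent:
        log.warning("associates absent from partition, counted as not co-grouped: %s",
                    absent)
    n_present = sum(
        1 for a in spec.associates if p.assignment.get(a) == host_group
    )
    return n_present / len(spec.associates)


def _summary(effects: np.ndarray) -> tuple[float, float]:
    # sample (n-1) standard deviation; 0 for a single pair
    if effects.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(effects, ddof=1)) if effects.size > 1 else 0.0
    return float(np.mean(effects)), sd


def effect_contrast(
    effects: pd.DataFrame,
    g: Network,
    p: Partition,
    spec: NestComplexSpec,
) -> NestComplexResult:
    """Contrast host-associate effect sizes with the network-wide pattern.

    ``effects`` is the pairwise effect-size table (columns species_a,
    species_b, effect) and must cover every pair of g's nodes.  Summaries:
    host-associate pairs; all node pairs; within-module pairs; among-module
    pairs (the latter two partition the all-pairs set).
    """
    nodes = set(g.nodes)
    key = {frozenset((a, b)): e for a, b, e in
           zip(effects["species_a"], effects["species_b"], effects["effect"])}
    all_eff, within_eff, among_eff = [], [], []
    node_list = list(g.nodes)
    for i, a in enumerate(node_list):
        for b in node_list[i + 1:]:
            fs = frozenset((a, b))
            if fs not in key:
                raise ValueError(f"effect table missing pair {a!r}-{b!r}")
            e = key[fs]
            all_eff.append(e)
            if p.assignment.get(a) == p.assignment.get(b):
                within_eff.append(e)
            else:
                among_eff.append(e)
    complex_eff = [
        key[frozenset((spec.host, a))]
        for a in spec.associates
        if a in nodes and frozenset((spec.host, a)) in key
    ]
    comp = completeness(p, spec)
    m_c, s_c = _summary(np.asarray(complex_eff))
    m_all, s_all = _summary(np.asarray(all_eff))
    m_w, s_w = _summary(np.asarray(within_eff))
    m_a, s_a = _summary(np.asarray(among_eff))
    return NestComplexResult(
        completeness=comp,
        n_present=round(comp * len(spec.associates)),
        n_associates=len(spec.associates),
        effect_mean_complex=m_c, effect_sd_complex=s_c,
        effect_mean_all=m_all, effect_sd_all=s_all,
        effect_mean_within=m_w, effect_sd_within=s_w,
        effect_mean_among=m_a, effect_sd_among=s_a,
    )
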