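"""Probabilistic model of pairwise co-occurrence.

For two species occupying N1 and N2 of N sites, the number of shared sites j
under random, independent placement follows the hypergeometric law

    P(j) = C(N1, j) * C(N - N1, N2 - j) / C(N, N2),

with expectation N1*N2/N.  The effect size for a pair is the standardized
difference (observed - expected) / N, which lies in [-1, 1]; the raw
difference is also reported.  Tail probabilities p_le / p_ge quantify how
surprising the observed sharing is in either direction.  Probabilities are
evaluated through scipy's hypergeometric distribution, which works in
log-space and stays finite for thousands of sites.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DegenerateMatrixError
from .occurrence import OccurrenceMatrix


@dataclass(frozen=True)
class PairStats:
    """Observed vs expected co-occurrence for one species pair."""

    species_a: str
    species_b: str
    n_sites: int
    n_a: int
    n_b: int
    observed: int
    expected: float
    p_le: float
    p_ge: float
    effect: float       # (observed - expected) / n_sites
    effect_raw: float   # observed - expected


def cooccurrence_probability(n_sites: int, n_a: int, n_b: int, j: int) -> float:
    """P(two species share exactly j sites) under random placement.

    Returns 0 for j outside the feasible range
    [max(0, n_a + n_b - n_sites), min(n_a, n_b)]; raises for arguments that
    are negative or exceed the site count.
    """
    if n_sites < 0 or not (0 <= n_a <= n_sites) or not (0 <= n_b <= n_sites):
        raise ValueError(
            f"occurrence counts must lie in [0, n_sites]: N={n_sites}, N1={n_a}, N2={n_b}"
        )
    if j < 0 or j > n_sites:
        raise ValueError(f"j={j} out of range for N={n_sites}")
    return float(hypergeom.pmf(j, n_sites, n_a, n_b))


def pair_stats(m: OccurrenceMatrix, a: str, b: str) -> PairStats:
    """Full co-occurrence statistics for one species pair of the matrix."""
    col_a, col_b = m.column(a), m.column(b)
    n = m.n_sites
    n_a, n_b = int(col_a.sum()), int(col_b.sum())
    obs = int(col_a @ col_b)
    return _stats_from_counts(a, b, n, n_a, n_b, obs)


def _stats_from_counts(a: str, b: str, n: int, n_a: int, n_b: int, obs: int) -> PairStats:
    rv = hypergeom(n, n_a, n_b)
    expected = n_a * n_b / n
    return PairStats(
        species_a=a,
        species_b=b,
        n_sites=n,
        n_a=n_a,
        n_b=n_b,
        observed=obs,
        expected=expected,
        p_le=float(rv.cdf(obs)),
        p_ge=float(rv.sf(obs - 1)),
        effect=(obs - expected) / n,
        effect_raw=obs - expected,
    )


def effect_size_table(m: OccurrenceMatrix) -> pd.DataFrame:
    """PairStats for every unordered species pair, one row each.

    Non-co-occurring pairs (observed = 0) are included so that among-group
    summaries over all node pairs are complete.  Columns: species_a,
    species_b, n_sites, n_a, n_b, observed, expected, effect, effect_raw,
    p_le, p_ge.
    """
    if m.n_species < 2:
        raise DegenerateMatrixError("need >= 2 species for an effect-size table")
    inc = m.incidence.astype(np.int64)
    counts = inc.sum(axis=0)
    co = inc.T @ inc
    n = m.n_sites
    rows = []
    for i, j in combinations(range(m.n_species), 2):
        n_a, n_b, obs = int(counts[i]), int(counts[j]), int(co[i, j])
        rv = hypergeom(n, n_a, n_b)
        expected = n_a * n_b / n
        rows.append(
            (
                m.species_ids[i], m.species_ids[j], n, n_a, n_b, obs, expected,
                (obs - expected) / n, obs - expected,
                float(rv.cdf(obs)), float(rv.sf(obs - 1)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a", "species_b", "n_sites", "n_a", "n_b", "observed",
            "expected", "effect", "effect_raw", "p_le", "p_ge",
        ],
    )


def write_effect_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
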