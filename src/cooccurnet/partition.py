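"""Partitions of a species set into labelled groups.

A :class:`Partition` is the shared currency of the pipeline: network modules,
medoid clusters and planted (synthetic-truth) groupings are all partitions,
and every downstream comparison (congruence, spatial clustering, nest
completeness) is required to be invariant to relabelling of the groups.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class Partition:
    """Mapping species id -> group label in ``1..k``.

    Labels are normalised so that every label in ``1..k`` is non-empty;
    construction through :meth:`from_labels` guarantees this.
    """

    assignment: Mapping[str, int]
    source: str = "module"  # module | cluster | planted

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if not self.assignment:
            raise ValueError("empty partition")
        k = max(labels)
        if labels != set(range(1, k + 1)):
            raise ValueError(
                f"labels must be exactly 1..k with no empty group, got {sorted(labels)}"
            )

    @property
    def k(self) -> int:
        return max(self.assignment.values())

    @property
    def species(self) -> list[str]:
        return list(self.assignment)

    def group(self, label: int) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def sizes(self) -> list[int]:
        out = [0] * self.k
        for g in self.assignment.values():
            out[g - 1] += 1
        return out

    def restrict(self, species: Iterable[str]) -> "Partition":
        """Restriction to a species subset, with labels re-compacted."""
        keep = {s: self.assignment[s] for s in species if s in self.assignment}
        return Partition.from_labels(list(keep), [keep[s] for s in keep], self.source)

    @staticmethod
    def from_labels(
        species_ids: Sequence[str], labels: Sequence[int], source: str = "module"
    ) -> "Partition":
        """Build a partition from parallel id/label sequences.

        Arbitrary hashable labels are accepted and compacted to ``1..k`` in
        order of first appearance.
        """
        if len(species_ids) != len(labels):
            raise ValueError("species_ids and labels length mismatch")
        if len(set(species_ids)) != len(species_ids):
            raise ValueError("duplicate species ids")
        remap: dict = {}
        assignment: dict[str, int] = {}
        for s, lab in zip(species_ids, labels):
            if lab not in remap:
                remap[lab] = len(remap) + 1
            assignment[s] = remap[lab]
        return Partition(assignment, source)
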