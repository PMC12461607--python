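"""Set algebra over the binder matrix.

Partitions probe binders into the diamine-exclusive subset A (bound to
probes 2 and/or 3 but none of 4-6), the higher-polyamine-exclusive subset B
(bound to 4, 5 and/or 6 but neither 2 nor 3), and the shared remainder;
computes UpSet-style exclusive intersections (each protein counted once,
under its full bound set); and overlaps binder sets with external
interactor lists.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .binder_enrichment import BinderMatrix, PROBE_COLUMNS

__all__ = ["SubsetPartition", "IntersectionCounts", "OverlapResult",
           "partition_subsets", "intersection_counts", "overlap_external",
           "DIAMINE_PROBES", "POLYAMINE_PROBES"]

DIAMINE_PROBES = (2, 3)
POLYAMINE_PROBES = (4, 5, 6)


@dataclass
class SubsetPartition:
    """Per-protein label in {A, B, shared, none}; labels are exclusive and exhaustive."""

    labels: pd.Series  # index accession, values str

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("A", "B", "shared", "none")}

    def accessions(self, label: str) -> set[str]:
        return set(self.labels.index[self.labels == label])

    def to_tsv(self, path) -> None:
        self.labels.rename("subset").to_csv(path, sep="\t", index_label="accession")


def partition_subsets(bm: BinderMatrix) -> SubsetPartition:
    """Label every protein in the binder matrix as A / B / shared / none."""
    missing = set(PROBE_COLUMNS) - set(bm.frame.columns)
    if missing:
        raise ValueError(f"binder matrix missing probe columns {sorted(missing)}")
    frame = bm.frame
    bound_di = frame[list(DIAMINE_PROBES)].any(axis=1)
    bound_poly = frame[list(POLYAMINE_PROBES)].any(axis=1)
    labels = pd.Series("none", index=frame.index, dtype=object)
    labels[bound_di & ~bound_poly] = "A"
    labels[bound_poly & ~bound_di] = "B"
    labels[bound_di & bound_poly] = "shared"
    return SubsetPartition(labels)


@dataclass
class IntersectionCounts:
    """Exclusive (UpSet-semantics) intersection sizes plus marginal set sizes."""

    table: pd.DataFrame  # columns: probes (str like "4+5"), size
    set_sizes: pd.Series  # marginal binder count per probe


def intersection_counts(bm: BinderMatrix) -> IntersectionCounts:
    """Count proteins by their full bound probe set, sorted by size descending.

    Each protein with at least one bound probe contributes to exactly one
    intersection, so sizes sum to the number of bound proteins.
    """
    frame = bm.frame
    probes = list(frame.columns)
    combos: Counter = Counter()
    for _, row in frame.iterrows():
        bound = tuple(p for p in probes if row[p])
        if bound:
            combos[bound] += 1
    rows = [("+".join(str(p) for p in combo), len(combo), n) for combo, n in combos.items()]
    table = pd.DataFrame(rows, columns=["probes", "degree", "size"])
    table = table.sort_values(["size", "probes"], ascending=[False, True], ignore_index=True)
    set_sizes = frame.sum(axis=0)
    set_sizes.name = "set_size"
    return IntersectionCounts(table, set_sizes)


@dataclass(frozen=True)
class OverlapResult:
    n_overlap: int
    n_union: int
    jaccard: float


def overlap_external(members: Iterable[str], external: Iterable[str],
                     mapping: Mapping[str, str] | None = None) -> OverlapResult:
    """Overlap and Jaccard index between a binder set and an external list.

    Matching is accession-level; an optional ``mapping`` (external ID ->
    accession) can be supplied instead of any online ID-mapping service.
    """
    a = set(members)
    b = set(external)
    if mapping is not None:
        b = {mapping.get(x, x) for x in b}
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    inter = a & b
    union = a | b
    return OverlapResult(len(inter), len(union), len(inter) / len(union))
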