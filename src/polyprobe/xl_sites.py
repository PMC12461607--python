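"""Crosslink-site mapping and modified-peptide acidity profiling.

Probe-modified peptides are mapped back onto proteins by exact substring
search (1-based inclusive coordinates). Candidate crosslink sites are the
D/E residues of the peptide (or the single known modified offset); each
observed Δmass is assigned a probe class via the adduct ladder. Peptides
are profiled by their D/E fraction (>=50%, >=1/3, below) and partitioned by
adduct-class exclusivity — the readout that exposes the intracellular
truncation of the spermine probe to a spermidine-mass adduct.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percent
from .binder_enrichment import BinderMatrix
from .chem_adducts import ProbeAdduct, assign_adduct, builtin_adducts
from .proteome_io import ProteinEntry

logger = logging.getLogger(__name__)

__all__ = ["ModifiedPeptideRecord", "SiteAssignment", "AcidityProfile",
           "PeptideMappingError", "PeptideNotFound", "AmbiguousPeptide",
           "map_peptide_to_protein", "candidate_sites", "acidity_profile",
           "classify_exclusive_adducts", "tally_sites",
           "read_peptide_table", "DEFAULT_SITE_RESIDUES"]

DEFAULT_SITE_RESIDUES = frozenset("DE")


class PeptideMappingError(ValueError):
    pass


class PeptideNotFound(PeptideMappingError):
    def __init__(self, peptide: str, accession: str):
        super().__init__(f"peptide {peptide!r} not found in {accession}")


class AmbiguousPeptide(PeptideMappingError):
    def __init__(self, peptide: str, accession: str, starts: list[int]):
        super().__init__(f"peptide {peptide!r} occurs at multiple starts {starts} in {accession}")
        self.starts = starts


@dataclass(frozen=True)
class ModifiedPeptideRecord:
    """One probe-modified peptide observation."""

    peptide: str
    protein_accession: str
    observed_delta_da: float
    source_probe_id: int
    modified_offset: int | None = None  # 1-based within peptide, None = unlocalised

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("empty peptide")
        if self.modified_offset is not None and not (1 <= self.modified_offset <= len(self.peptide)):
            raise ValueError("modified_offset outside peptide")


@dataclass(frozen=True)
class SiteAssignment:
    """A candidate crosslink site in protein coordinates."""

    protein_accession: str
    position: int  # 1-based
    residue: str
    adduct_class: str | None
    source_probe_id: int
    peptide: str


@dataclass(frozen=True)
class AcidityProfile:
    peptide: str
    de_fraction: float
    acidity_class: str  # ge50 | ge33 | lt33


def _occurrences(peptide: str, sequence: str) -> list[int]:
    starts, pos = [], sequence.find(peptide)
    while pos != -1:
        starts.append(pos + 1)
        pos = sequence.find(peptide, pos + 1)
    return starts


def map_peptide_to_protein(peptide: str, entry: ProteinEntry) -> tuple[int, int]:
    """Locate a peptide in a protein by exact substring search.

    Returns 1-based inclusive (start, end); raises :class:`PeptideNotFound`
    or :class:`AmbiguousPeptide` (listing all starts) otherwise.
    """
    if not peptide:
        raise ValueError("empty peptide")
    starts = _occurrences(peptide, entry.sequence)
    if not starts:
        raise PeptideNotFound(peptide, entry.accession)
    if len(starts) > 1:
        raise AmbiguousPeptide(peptide, entry.accession, starts)
    start = starts[0]
    return start, start + len(peptide) - 1


def candidate_sites(record: ModifiedPeptideRecord, entry: ProteinEntry,
                    adducts: Sequence[ProbeAdduct] | None = None,
                    tolerance_ppm: float = 10.0,
                    site_residues: frozenset = DEFAULT_SITE_RESIDUES) -> list[SiteAssignment]:
    """Enumerate candidate crosslink sites for one record, in protein coordinates.

    A known modified offset yields a single assignment; otherwise one
    candidate per site residue (default D/E) in the peptide. The adduct
    class comes from matching the observed Δmass at ``tolerance_ppm``.
    """
    start, _ = map_peptide_to_protein(record.peptide, entry)
    assignment = assign_adduct(record.observed_delta_da, adducts or builtin_adducts(),
                               tolerance_ppm)
    if record.modified_offset is not None:
        offsets = [record.modified_offset]
    else:
        offsets = [i + 1 for i, ch in enumerate(record.peptide) if ch in site_residues]
        if not offsets:
            logger.warning("peptide %r has no %s residue; no candidate sites",
                           record.peptide, "/".join(sorted(site_residues)))
            return []
    out = []
    for off in offsets:
        pos = start + off - 1
        out.append(SiteAssignment(entry.accession, pos, entry.sequence[pos - 1],
                                  assignment.matched_class, record.source_probe_id,
                                  record.peptide))
    return out


def acidity_profile(peptide: str) -> AcidityProfile:
    """D/E fraction of a peptide, classed at the closed thresholds 1/2 and 1/3."""
    if not peptide:
        raise ValueError("empty peptide")
    de = peptide.count("D") + peptide.count("E")
    frac = de / len(peptide)
    if frac >= 0.5:
        cls = "ge50"
    elif frac >= 1.0 / 3.0:
        cls = "ge33"
    else:
        cls = "lt33"
    return AcidityProfile(peptide, frac, cls)


@dataclass
class ExclusivitySummary:
    """Unique peptides grouped by adduct-class exclusivity, with acidity fractions."""

    peptide_classes: dict[str, frozenset]  # peptide -> set of matched classes
    groups: dict[str, list[str]]  # e.g. exclusive_spermidine -> peptides
    table: pd.DataFrame
    n_unresolved: int = 0


def classify_exclusive_adducts(records: Iterable[ModifiedPeptideRecord],
                               adducts: Sequence[ProbeAdduct] | None = None,
                               tolerance_ppm: float = 10.0) -> ExclusivitySummary:
    """Partition unique peptides by the set of adduct classes they carry.

    Peptides matching exactly one class across all their observations go to
    ``exclusive_<class>``; peptides seen with two or more classes go to
    ``both``. Records whose Δmass resolves to no class are excluded (logged).
    For each group the summary reports the fraction of peptides with >=50%
    D/E and with >=1/3 D/E (percent, rounded half-up).
    """
    adducts = list(adducts) if adducts is not None else builtin_adducts()
    classes: dict[str, set] = {}
    n_unresolved = 0
    for rec in records:
        a = assign_adduct(rec.observed_delta_da, adducts, tolerance_ppm)
        if a.matched_class is None:
            n_unresolved += 1
            logger.info("Δmass %.5f of peptide %r matches no adduct at %.1f ppm; excluded",
                        rec.observed_delta_da, rec.peptide, tolerance_ppm)
            continue
        classes.setdefault(rec.peptide, set()).add(a.matched_class)
    groups: dict[str, list[str]] = {}
    for pep in sorted(classes):
        cset = classes[pep]
        label = f"exclusive_{next(iter(cset))}" if len(cset) == 1 else "both"
        groups.setdefault(label, []).append(pep)
    rows = []
    for label in sorted(groups):
        peps = groups[label]
        profiles = [acidity_profile(p) for p in peps]
        n = len(peps)
        n_ge50 = sum(1 for pr in profiles if pr.acidity_class == "ge50")
        n_ge33 = sum(1 for pr in profiles if pr.acidity_class in ("ge50", "ge33"))
        rows.append({"group": label, "n_peptides": n,
                     "n_ge50": n_ge50, "pct_ge50": percent(n_ge50, n),
                     "n_ge33": n_ge33, "pct_ge33": percent(n_ge33, n)})
    table = pd.DataFrame(rows, columns=["group", "n_peptides", "n_ge50", "pct_ge50",
                                        "n_ge33", "pct_ge33"])
    return ExclusivitySummary({p: frozenset(s) for p, s in classes.items()},
                              groups, table, n_unresolved)


@dataclass
class SiteTally:
    per_group: dict[str, dict]  # group label -> {n_sites, n_targets, ...}
    table: pd.DataFrame  # per (protein, group): n_sites, is_binder


def tally_sites(assignments: Iterable[SiteAssignment],
                binder_matrix: BinderMatrix | None = None,
                probe_groups: Mapping[str, tuple] | None = None) -> SiteTally:
    """Count distinct crosslink sites per protein within probe groups.

    A site is a distinct (protein, position) pair; repeated observations
    collapse. Default groups mirror the diamine (2-3) vs higher-polyamine
    (4-6) probe split. When a binder matrix is given, per-protein rows carry
    whether the protein was called a binder of any probe in the group.
    """
    if probe_groups is None:
        probe_groups = {"probes_2_3": (2, 3), "probes_4_6": (4, 5, 6)}
    sites: dict[str, set] = {g: set() for g in probe_groups}
    for a in assignments:
        for g, probes in probe_groups.items():
            if a.source_probe_id in probes:
                sites[g].add((a.protein_accession, a.position))
    rows = []
    per_group = {}
    for g, pairs in sites.items():
        by_protein: dict[str, int] = {}
        for acc, _pos in pairs:
            by_protein[acc] = by_protein.get(acc, 0) + 1
        per_group[g] = {"n_sites": len(pairs), "n_targets": len(by_protein)}
        for acc in sorted(by_protein):
            is_binder = None
            if binder_matrix is not None:
                cols = [p for p in probe_groups[g] if p in binder_matrix.frame.columns]
                is_binder = bool(acc in binder_matrix.frame.index
                                 and binder_matrix.frame.loc[acc, cols].any())
            rows.append({"group": g, "accession": acc, "n_sites": by_protein[acc],
                         "is_binder": is_binder})
    table = pd.DataFrame(rows, columns=["group", "accession", "n_sites", "is_binder"])
    return SiteTally(per_group, table)


def read_peptide_table(path: str | Path) -> list[ModifiedPeptideRecord]:
    """Read a modified-peptide TSV (peptide, protein_accession, observed_delta_da,
    source_probe_id, optional modified_offset)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"peptide", "protein_accession", "observed_delta_da", "source_probe_id"}
    if not required <= set(df.columns):
        raise ValueError(f"peptide table must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        off = row.get("modified_offset")
        off = None if off is None or pd.isna(off) else int(off)
        records.append(ModifiedPeptideRecord(str(row["peptide"]), str(row["protein_accession"]),
                                             float(row["observed_delta_da"]),
                                             int(row["source_probe_id"]), off))
    return records


def site_assignment_table(assignments: Iterable[SiteAssignment]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in assignments],
                        columns=["protein_accession", "position", "residue",
                                 "adduct_class", "source_probe_id", "peptide"])
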