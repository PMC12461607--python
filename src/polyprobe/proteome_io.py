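"""Protein sequence I/O and residue-composition utilities.

Reads Swiss-Prot-style FASTA into an ordered, accession-indexed
:class:`Proteome`. Sequences are validated against the 20 canonical amino
acids plus the tolerated ambiguity codes B, Z, X, U, O; ambiguity codes are
accepted but never counted as acidic residues downstream, and entries
containing them are flagged in the log. Coordinates throughout the package
are 1-based inclusive (residue E208 is ``sequence[207]``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY = set("BZXUO")
ALLOWED = CANONICAL | AMBIGUITY

__all__ = ["ProteinEntry", "Proteome", "FastaError", "read_fasta", "write_fasta",
           "composition", "composition_table", "CANONICAL", "AMBIGUITY", "ALLOWED"]


class FastaError(ValueError):
    pass


def _accession_from_id(record_id: str) -> str:
    parts = record_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return record_id


@dataclass(frozen=True)
class ProteinEntry:
    """One protein: accession, original header text, validated sequence."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.accession:
            raise FastaError("empty accession")
        if not self.sequence:
            raise FastaError(f"empty sequence for {self.accession}")
        for i, ch in enumerate(self.sequence):
            if ch not in ALLOWED:
                raise FastaError(
                    f"illegal character {ch!r} at position {i + 1} in record {self.accession}")

    def __len__(self):
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered protein collection with unique accessions."""

    entries: list[ProteinEntry]
    source_tag: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {}
        for e in self.entries:
            if e.accession in self._index:
                raise FastaError(f"duplicate accession {e.accession!r}")
            self._index[e.accession] = e

    def __iter__(self) -> Iterator[ProteinEntry]:
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def get(self, accession: str) -> ProteinEntry:
        return self._index[accession]

    @property
    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]


def read_fasta(path: str | Path, source_tag: str | None = None) -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    UniProt-style headers ``sp|ACC|NAME desc`` yield ``accession = ACC``;
    plain headers yield the first whitespace-delimited token. Multi-line
    sequences are concatenated and uppercased. Rejects empty files,
    duplicate accessions, and illegal sequence characters.
    """
    path = Path(path)
    entries = []
    n_ambiguous = 0
    # fasta-pearson tolerates ';' comment lines (used for seed/config preambles)
    for record in SeqIO.parse(str(path), "fasta-pearson"):
        acc = _accession_from_id(record.id)
        seq = str(record.seq).upper().replace(" ", "")
        entry = ProteinEntry(acc, record.description, seq)
        if set(seq) & AMBIGUITY:
            n_ambiguous += 1
            logger.debug("entry %s contains ambiguity codes", acc)
        entries.append(entry)
    if not entries:
        raise FastaError(f"no FASTA records in {path}")
    if n_ambiguous:
        logger.info("%d/%d entries contain ambiguity codes (B/Z/X/U/O)", n_ambiguous, len(entries))
    return Proteome(entries, source_tag=source_tag if source_tag is not None else path.name)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60,
                preamble: str | None = None) -> Path:
    """Write a proteome as wrapped FASTA; round-trips accessions and sequences.

    ``preamble`` (e.g. a seed/config tag) is written as a leading ``;`` comment
    line, which FASTA parsers skip.
    """
    if not proteome.entries:
        raise FastaError("refusing to write an empty proteome")
    if width < 1:
        raise ValueError("width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        if preamble:
            fh.write(f"; {preamble}\n")
        for e in proteome:
            header = e.description if e.description else e.accession
            fh.write(f">{header}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i:i + width] + "\n")
    return path


def composition(entry: ProteinEntry | str, residues: Iterable[str]) -> tuple[int, float]:
    """Count and fraction of positions whose letter is in ``residues``.

    Ambiguity codes only count if explicitly listed, so B/Z/X/U/O never
    inflate a D/E count.
    """
    residues = set(residues)
    if not residues:
        raise ValueError("residues set must be nonempty")
    seq = entry.sequence if isinstance(entry, ProteinEntry) else entry
    count = sum(seq.count(r) for r in residues)
    return count, count / len(seq)


def composition_table(proteome: Proteome, residues: Iterable[str] = ("D", "E")) -> pd.DataFrame:
    """Per-protein residue composition as a DataFrame (TSV-exportable)."""
    rows = []
    for e in proteome:
        c, f = composition(e, residues)
        rows.append((e.accession, len(e), c, f))
    return pd.DataFrame(rows, columns=["accession", "length", "count", "fraction"])
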