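"""Probe-adduct mass arithmetic.

Polyamine photoaffinity probes leave a characteristic neutral mass shift
(Δmass) on the peptides they crosslink: the probe-derived photoadduct plus
the click-conjugated azide-PEG3-biotin handle. The three probe classes form
an arithmetic ladder spaced by one aminopropyl unit (C3H7N, ~57.058 Da):

    putrescine-type  C29H52O5N8S   +624.37814 Da   (probe 3)
    spermidine-type  C32H59O5N9S   +681.43599 Da   (probes 4, 5)
    spermine-type    C35H66O5N10S  +738.49384 Da   (probe 6)

This module parses Hill-style elemental formulas, computes monoisotopic
masses from a pinned atomic-mass table, and assigns observed Δmasses to a
probe class within a ppm tolerance. Masses are neutral monoisotopic shifts;
isotope patterns and charge states are out of scope.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Sequence

from ._util import round_half_up

__all__ = [
    "AtomicMassTable",
    "ElementalFormula",
    "ProbeAdduct",
    "AdductAssignment",
    "FormulaError",
    "DEFAULT_MASS_TABLE",
    "parse_formula",
    "monoisotopic_mass",
    "builtin_adducts",
    "assign_adduct",
    "adduct_table_tsv",
]


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


# Monoisotopic masses of the most abundant isotope, Da (IUPAC/CODATA).
_DEFAULT_MASSES = {
    "C": 12.0,  # exact by definition
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}


@dataclass(frozen=True)
class AtomicMassTable:
    """Immutable element -> monoisotopic mass (Da) lookup.

    The default table pins H/C/N/O/S/P to >=9 significant digits; the printed
    5-dp adduct Δmasses are only reproducible at this precision.
    """

    masses: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MASSES))
    version: str = "monoisotopic-iupac-v1"

    def __post_init__(self):
        for sym, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for element {sym!r}")
        object.__setattr__(self, "masses", MappingProxyType(dict(self.masses)))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.masses

    def __getitem__(self, symbol: str) -> float:
        return self.masses[symbol]

    def with_elements(self, extra: Mapping[str, float]) -> "AtomicMassTable":
        """Return an extended copy (the base table is never mutated)."""
        merged = dict(self.masses)
        merged.update(extra)
        return AtomicMassTable(merged, version=self.version + "+user")


DEFAULT_MASS_TABLE = AtomicMassTable()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """A bag of atoms; equality is count-map equality, order-free."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for sym, n in self.counts.items():
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym!r} must be a positive integer, got {n!r}")
            clean[sym] = n
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __eq__(self, other):
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self):
        return hash(frozenset(self.counts.items()))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def to_hill(self) -> str:
        """Canonical Hill order: C, H, then alphabetical (all alphabetical if no C)."""
        syms = set(self.counts)
        if "C" in syms:
            order = ["C"] + (["H"] if "H" in syms else []) + sorted(syms - {"C", "H"})
        else:
            order = sorted(syms)
        return "".join(f"{s}{self.counts[s] if self.counts[s] != 1 else ''}" for s in order)

    def __str__(self):
        return self.to_hill()


def parse_formula(text: str, table: AtomicMassTable = DEFAULT_MASS_TABLE) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C29H52O5N8S"``.

    Each token is an element symbol followed by an optional integer count
    (absent = 1). Repeated symbols accumulate. Rejects unknown elements,
    zero counts, and malformed tokens with the offending position.
    """
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula token at position {pos}: {text[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {sym!r} at position {pos} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int] | str,
                      table: AtomicMassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic mass in Da: sum over elements of count * isotope mass."""
    if isinstance(formula, str):
        formula = parse_formula(formula, table)
    counts = formula.counts if isinstance(formula, ElementalFormula) else formula
    total = 0.0
    for sym, n in counts.items():
        if sym not in table:
            raise FormulaError(f"element {sym!r} missing from mass table")
        total += n * table[sym]
    return total


@dataclass(frozen=True)
class ProbeAdduct:
    """One probe class with its photoadduct formula and Δmass."""

    probe_ids: frozenset[int]
    polyamine_class: str
    formula: ElementalFormula
    delta_mass_da: float

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", frozenset(self.probe_ids))


_BUILTIN = [
    # (probe ids, class, photoadduct + biotin-handle formula)
    ((3,), "putrescine", "C29H52O5N8S"),
    ((4, 5), "spermidine", "C32H59O5N9S"),
    ((6,), "spermine", "C35H66O5N10S"),
]


def builtin_adducts(table: AtomicMassTable = DEFAULT_MASS_TABLE) -> list[ProbeAdduct]:
    """The three built-in probe adducts; Δmasses recomputed from the table."""
    out = []
    for ids, cls, ftext in _BUILTIN:
        f = parse_formula(ftext, table)
        out.append(ProbeAdduct(frozenset(ids), cls, f, monoisotopic_mass(f, table)))
    return out


@dataclass(frozen=True)
class AdductAssignment:
    """Result of matching an observed Δmass against candidate adducts."""

    observed_delta_da: float
    matched_class: str | None
    ppm_error: float  # NaN when no adduct is within tolerance
    ambiguous: bool


def assign_adduct(observed_delta_da: float,
                  adducts: Sequence[ProbeAdduct] | None = None,
                  tolerance_ppm: float = 10.0) -> AdductAssignment:
    """Assign an observed Δmass to the nearest adduct class within tolerance.

    ppm error is 1e6 * (observed - theoretical) / theoretical. ``ambiguous``
    is set when two or more adducts fall within tolerance (impossible for the
    built-in ladder at any sane tolerance: spacing is ~57 Da).
    """
    if adducts is None:
        adducts = builtin_adducts()
    if not adducts:
        raise ValueError("empty adduct list")
    if observed_delta_da <= 0:
        raise ValueError("observed Δmass must be positive")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    errors = [(1e6 * (observed_delta_da - a.delta_mass_da) / a.delta_mass_da, a) for a in adducts]
    within = [(e, a) for e, a in errors if abs(e) <= tolerance_ppm]
    if not within:
        return AdductAssignment(observed_delta_da, None, math.nan, False)
    best_err, best = min(within, key=lambda ea: abs(ea[0]))
    return AdductAssignment(observed_delta_da, best.polyamine_class, best_err, len(within) >= 2)


def adduct_table_tsv(adducts: Sequence[ProbeAdduct] | None = None,
                     path: str | Path | None = None) -> str:
    """Render the adduct table as TSV (Δmass at 5 dp); optionally write it."""
    if adducts is None:
        adducts = builtin_adducts()
    lines = ["probe_ids\tclass\tformula\tdelta_mass_da"]
    for a in adducts:
        ids = ",".join(str(i) for i in sorted(a.probe_ids))
        lines.append(f"{ids}\t{a.polyamine_class}\t{a.formula.to_hill()}\t{round_half_up(a.delta_mass_da, 5):.5f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
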