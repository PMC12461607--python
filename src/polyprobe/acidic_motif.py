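"""Acidic-stretch motif scanning and fold-enrichment statistics.

The motif is a fixed-length sliding window (default 20 residues) containing
at least K acidic residues (default 10 of D/E) — the signature of
multivalent electrostatic polyamine binding, typically inside intrinsically
disordered regions. A protein "has the motif" if at least one window
qualifies. Subset-level overrepresentation is summarised as fold enrichment

    FE = (k/n) / (K_bg/N_bg)

of motif prevalence in a protein subset over a background proteome, with a
hypergeometric tail probability (upper tail when FE >= 1, lower otherwise).
Reported percentages are rounded half-up to integers and FE to one decimal;
full precision is retained in the objects.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent, round_half_up
from .binder_sets import SubsetPartition
from .proteome_io import Proteome

__all__ = ["MotifParams", "MotifScanResult", "EnrichmentStat", "Prevalence",
           "scan_acidic_windows", "scan_proteome", "motif_prevalence",
           "fold_enrichment", "subset_motif_report"]


@dataclass(frozen=True)
class MotifParams:
    """Window length W, minimum acidic count K, and the acidic residue set."""

    window: int = 20
    min_acidic: int = 10
    residues: frozenset = frozenset("DE")

    def __post_init__(self):
        if not (1 <= self.min_acidic <= self.window):
            raise ValueError("require 1 <= min_acidic <= window")
        if not self.residues:
            raise ValueError("residue set must be nonempty")


@dataclass
class MotifScanResult:
    accession: str
    has_motif: bool
    windows: list[tuple[int, int]]  # (1-based start, acidic count), count >= K


def scan_acidic_windows(seq: str, params: MotifParams = MotifParams()) -> list[tuple[int, int]]:
    """All qualifying windows of ``seq`` as (1-based start, acidic count).

    Rolling-count scan over the L - W + 1 windows; sequences shorter than
    the window yield no hits. Ambiguity codes are not acidic.
    """
    w, k = params.window, params.min_acidic
    L = len(seq)
    if L < w:
        return []
    mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    acidic = np.zeros(L, dtype=np.int32)
    for r in params.residues:
        acidic |= mask == ord(r)
    cum = np.concatenate(([0], np.cumsum(acidic)))
    counts = cum[w:] - cum[:-w]  # counts[i] = acidic in window starting at 0-based i
    starts = np.nonzero(counts >= k)[0]
    return [(int(s) + 1, int(counts[s])) for s in starts]


def scan_proteome(proteome: Proteome, params: MotifParams = MotifParams()) -> list[MotifScanResult]:
    out = []
    for entry in proteome:
        windows = scan_acidic_windows(entry.sequence, params)
        out.append(MotifScanResult(entry.accession, bool(windows), windows))
    return out


@dataclass
class Prevalence:
    n_with_motif: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_with_motif / self.n_total

    @property
    def percent(self) -> int:
        return percent(self.n_with_motif, self.n_total)


def motif_prevalence(proteome: Proteome, params: MotifParams = MotifParams()) -> Prevalence:
    """Fraction of proteins with at least one qualifying window."""
    if not len(proteome):
        raise ValueError("empty proteome")
    n_with = sum(1 for r in scan_proteome(proteome, params) if r.has_motif)
    return Prevalence(n_with, len(proteome))


@dataclass
class EnrichmentStat:
    """Fold enrichment of a binary protein property in a subset vs background."""

    k: int
    n: int
    K_bg: int
    N_bg: int
    fe: float = field(init=False)
    p_hyper: float = field(init=False)
    tail: str = field(init=False)

    def __post_init__(self):
        if not (0 <= self.k <= self.n <= self.N_bg):
            raise ValueError("require 0 <= k <= n <= N_bg")
        if not (0 <= self.K_bg <= self.N_bg):
            raise ValueError("require 0 <= K_bg <= N_bg")
        if self.n < 1:
            raise ValueError("subset must be nonempty")
        if self.K_bg == 0:
            raise ValueError("fold enrichment undefined: no background hits (K_bg = 0)")
        self.fe = (self.k / self.n) / (self.K_bg / self.N_bg)
        hg = stats.hypergeom(self.N_bg, self.K_bg, self.n)
        if self.fe >= 1:
            self.tail = "upper"
            self.p_hyper = float(hg.sf(self.k - 1))
        else:
            self.tail = "lower"
            self.p_hyper = float(hg.cdf(self.k))

    @property
    def fe_rounded(self) -> float:
        return round_half_up(self.fe, 1)

    @property
    def subset_percent(self) -> int:
        return percent(self.k, self.n)


def fold_enrichment(k: int, n: int, K_bg: int, N_bg: int) -> EnrichmentStat:
    """FE = (k/n)/(K_bg/N_bg) with a hypergeometric tail p-value."""
    return EnrichmentStat(k, n, K_bg, N_bg)


def subset_motif_report(partition: SubsetPartition, proteome: Proteome,
                        params: MotifParams, background: Proteome) -> pd.DataFrame:
    """Per-subset motif prevalence and fold enrichment against a background.

    Every accession labelled A/B/shared must be present in ``proteome``.
    Returns one row per nonempty subset with k, n, percent, FE (full and
    1-dp) and the hypergeometric tail p.
    """
    labelled = [a for a in partition.labels.index if partition.labels[a] != "none"]
    missing = [a for a in labelled if a not in proteome]
    if missing:
        raise ValueError(f"subset accessions missing from proteome: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    bg = motif_prevalence(background, params)
    rows = []
    for label in ("A", "B", "shared"):
        accs = sorted(partition.accessions(label))
        if not accs:
            continue
        k = sum(1 for a in accs
                if scan_acidic_windows(proteome.get(a).sequence, params))
        stat = fold_enrichment(k, len(accs), bg.n_with_motif, bg.n_total)
        rows.append({"subset": label, "k": k, "n": len(accs),
                     "percent": stat.subset_percent, "fe": stat.fe,
                     "fe_1dp": stat.fe_rounded, "p_hyper": stat.p_hyper,
                     "tail": stat.tail,
                     "K_bg": bg.n_with_motif, "N_bg": bg.n_total})
    return pd.DataFrame(rows)
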