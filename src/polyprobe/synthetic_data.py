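"""Synthetic photoaffinity-study generator with planted ground truth.

Emits a complete miniature study — proteome FASTA, replicate log2 quant
matrix with a control probe, and a probe-modified peptide table — together
with the planted truth (binder sets, motif positions, crosslink sites), so
every pipeline stage can be validated without any deposited data.

What it emulates, and how the defaults were chosen:

- Proteome: i.i.d. residues at a background D/E frequency of 0.12, lengths
  log-normal (median ~400, sigma 0.5). Two disjoint binder pools are
  designated: an "A-like" pool (diamine probes 2-3) and a "B-like" pool
  (higher-polyamine probes 4-6). One 20-residue acidic stretch is planted
  (overwriting, so lengths are preserved) with class-dependent probability
  0.06 / 0.57 / 0.11 for A-like / B-like / background proteins — the
  prevalences the motif statistic should recover.
- Pool sizes: 200 binders per probe drawn from disjoint pools of 300 in a
  2000-protein proteome. Binder prevalence is deliberately higher than the
  study's (~1%) so that Benjamini-Hochberg calling retains power at the
  planted effect size with triplicates; at 1% prevalence and m = 2000 the
  q-values of genuine ~3-log2 effects sit above any usable threshold. The
  planted fold enrichment is defined against background-class proteins
  (``truth.classes == "background"``), whose motif rate is the 11% target;
  the binder pools themselves are too large a slice of this proteome for
  whole-proteome prevalence to stay at 11%, unlike in a full-size proteome.
- Quant matrix: per-protein baseline ~ N(25, 2) log2 units; each probe's
  binders are drawn from its pool and receive an enrichment effect
  ~ N(3.0, 0.5) in that probe's samples only; i.i.d. N(0, 0.3) noise;
  3 replicates per condition including the monoamine control (probe 1).
- Modified peptides: tryptic digestion (cleave after K/R unless before P,
  up to 1 missed cleavage, emitted length 6-40), peptides with >=1 D/E
  sampled per binder of probes 3-6 (D/E-rich peptides oversampled for the
  spermidine-class probes), a true site drawn uniformly among the peptide's
  D/E, and an observed Δmass equal to the class mass with ~3 ppm
  multiplicative Gaussian error. With ``spermine_truncation`` (default on,
  as observed in cells) probe-6 records carry the spermidine-class mass.

Everything is driven by one ``numpy.random.default_rng(seed)``; the same
seed reproduces byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import config_hash
from .chem_adducts import builtin_adducts
from .proteome_io import Proteome, ProteinEntry, write_fasta

logger = logging.getLogger(__name__)

__all__ = ["SyntheticStudyConfig", "SyntheticTruth", "SyntheticStudy",
           "generate_proteome", "generate_quant_table", "generate_modified_peptides",
           "digest_tryptic", "generate_study", "write_study"]

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
_NON_ACIDIC = [a for a in _AMINO if a not in "DE"]


@dataclass
class SyntheticStudyConfig:
    """All knobs of a synthetic study; defaults define the emulated conditions."""

    seed: int = 0
    n_proteins: int = 2000
    length_median: float = 400.0
    length_sigma: float = 0.5
    background_de_freq: float = 0.12
    motif_fraction_a: float = 0.06
    motif_fraction_b: float = 0.57
    motif_fraction_background: float = 0.11
    probes: tuple = (2, 3, 4, 5, 6)
    control_probe: int = 1
    n_binders_per_probe: int = 200
    binder_pool_factor: float = 1.5
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    effect_log2_mean: float = 3.0
    effect_log2_sd: float = 0.5
    noise_sd: float = 0.3
    n_replicates: int = 3
    spermine_truncation: bool = True
    mass_error_ppm_sd: float = 3.0
    missed_cleavages: int = 1
    peptide_min_len: int = 6
    peptide_max_len: int = 40
    peptides_per_binder: int = 2
    acidity_weight: float = 1.0

    def __post_init__(self):
        for name in ("background_de_freq", "motif_fraction_a", "motif_fraction_b",
                     "motif_fraction_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_binders_per_probe > self.n_proteins:
            raise ValueError("n_binders_per_probe cannot exceed n_proteins")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probes"] = list(self.probes)
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every synthetic study."""

    classes: dict[str, str] = field(default_factory=dict)  # accession -> A/B/background
    motifs: dict[str, list] = field(default_factory=dict)  # accession -> [[start, n_acidic]]
    binders: dict[int, list] = field(default_factory=dict)  # probe -> accessions
    peptides: list[dict] = field(default_factory=list)  # planted modified peptides/sites

    def to_json(self, extra: dict | None = None) -> str:
        payload = {"classes": self.classes, "motifs": self.motifs,
                   "binders": {str(k): v for k, v in self.binders.items()},
                   "peptides": self.peptides}
        if extra:
            payload = {**extra, **payload}
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(d["classes"], d["motifs"],
                   {int(k): v for k, v in d["binders"].items()}, d["peptides"])


def _pool_size(cfg: SyntheticStudyConfig) -> int:
    return int(round(cfg.n_binders_per_probe * cfg.binder_pool_factor))


def generate_proteome(cfg: SyntheticStudyConfig,
                      rng: np.random.Generator | None = None) -> tuple[Proteome, SyntheticTruth]:
    """Generate the synthetic proteome with planted acidic stretches.

    Assigns disjoint A-like and B-like binder pools, then draws i.i.d.
    sequences and overwrites one 20-residue window (10-16 acidic residues,
    uniform position) with class-dependent probability.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    pool = _pool_size(cfg)
    if 2 * pool > n:
        raise ValueError("binder pools exceed proteome size")
    picked = rng.choice(n, size=2 * pool, replace=False)
    a_pool, b_pool = set(picked[:pool].tolist()), set(picked[pool:].tolist())

    de = cfg.background_de_freq
    letters = np.array(list(_AMINO))
    probs = np.array([de / 2 if a in "DE" else (1 - de) / len(_NON_ACIDIC) for a in _AMINO])
    probs = probs / probs.sum()
    motif_p = {"A": cfg.motif_fraction_a, "B": cfg.motif_fraction_b,
               "background": cfg.motif_fraction_background}

    entries, truth = [], SyntheticTruth()
    width = len(str(n))
    mu = np.log(cfg.length_median)
    for i in range(n):
        acc = f"SYN{i + 1:0{width}d}"
        cls = "A" if i in a_pool else "B" if i in b_pool else "background"
        length = 0
        while length < 20:  # resample sub-window lengths
            length = int(round(rng.lognormal(mu, cfg.length_sigma)))
        seq = rng.choice(letters, size=length, p=probs)
        motifs = []
        if rng.random() < motif_p[cls]:
            start = int(rng.integers(0, length - 20 + 1))
            n_acidic = int(rng.integers(10, 17))
            window = rng.choice(np.array(_NON_ACIDIC), size=20)
            acidic_pos = rng.choice(20, size=n_acidic, replace=False)
            window[acidic_pos] = rng.choice(np.array(["D", "E"]), size=n_acidic)
            seq[start:start + 20] = window
            motifs.append([start + 1, n_acidic])
        truth.classes[acc] = cls
        if motifs:
            truth.motifs[acc] = motifs
        entries.append(ProteinEntry(acc, f"{acc} synthetic protein", "".join(seq)))
    return Proteome(entries, source_tag="synthetic"), truth


from .binder_enrichment import QuantMatrix  # noqa: E402  (avoids cycle at import time)


def generate_quant_table(cfg: SyntheticStudyConfig, proteome: Proteome,
                         truth: SyntheticTruth,
                         rng: np.random.Generator | None = None) -> QuantMatrix:
    """Plant per-probe binder enrichment effects on a noisy log2 matrix.

    Binders of diamine probes come from the A-like pool, binders of the
    higher-polyamine probes from the B-like pool; the planted sets are
    recorded in ``truth.binders``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    accs = proteome.accessions
    a_pool = [a for a in accs if truth.classes.get(a) == "A"]
    b_pool = [a for a in accs if truth.classes.get(a) == "B"]
    conditions = (cfg.control_probe,) + tuple(cfg.probes)
    samples = [f"probe{p}_rep{r + 1}" for p in conditions for r in range(cfg.n_replicates)]
    meta = pd.DataFrame({"sample": samples,
                         "probe_id": [p for p in conditions for _ in range(cfg.n_replicates)],
                         "replicate": [r + 1 for _ in conditions for r in range(cfg.n_replicates)]
                         }).set_index("sample")

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(accs))
    values = np.tile(baseline[:, None], (1, len(samples)))
    acc_index = {a: i for i, a in enumerate(accs)}
    for p in cfg.probes:
        pool = a_pool if p in (2, 3) else b_pool
        chosen = sorted(rng.choice(np.array(pool), size=min(cfg.n_binders_per_probe, len(pool)),
                                   replace=False).tolist())
        truth.binders[p] = chosen
        cols = [j for j, s in enumerate(samples) if meta.iloc[j]["probe_id"] == p]
        for a in chosen:
            effect = rng.normal(cfg.effect_log2_mean, cfg.effect_log2_sd)
            values[acc_index[a], cols] += effect
    values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    frame = pd.DataFrame(values, index=pd.Index(accs, name="accession"), columns=samples)
    return QuantMatrix(frame, meta)


def digest_tryptic(seq: str, missed_cleavages: int = 1,
                   length_range: tuple[int, int] | None = None) -> list[tuple[str, int]]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Returns (peptide, 1-based start) for all peptides with 0 to
    ``missed_cleavages`` missed sites, optionally filtered to
    ``length_range`` (inclusive).
    """
    cut_after = [i for i in range(len(seq) - 1)
                 if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = seq[bounds[i]:bounds[j]]
            if length_range is not None and not (length_range[0] <= len(pep) <= length_range[1]):
                continue
            out.append((pep, bounds[i] + 1))
    return out


def _probe_class(cfg: SyntheticStudyConfig, probe: int) -> str | None:
    if probe == 3:
        return "putrescine"
    if probe in (4, 5):
        return "spermidine"
    if probe == 6:
        return "spermidine" if cfg.spermine_truncation else "spermine"
    return None  # diamine probe 2 has no defined adduct


def generate_modified_peptides(cfg: SyntheticStudyConfig, proteome: Proteome,
                               truth: SyntheticTruth,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample probe-modified tryptic peptides for planted binders of probes 3-6.

    Each record carries the class Δmass with ppm-scale multiplicative error;
    the true site (a peptide D/E, in protein coordinates) goes to
    ``truth.peptides``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    class_mass = {a.polyamine_class: a.delta_mass_da for a in builtin_adducts()}
    rows = []
    for probe in sorted(truth.binders):
        cls = _probe_class(cfg, probe)
        if cls is None:
            continue
        for acc in truth.binders[probe]:
            seq = proteome.get(acc).sequence
            peps = [(p, s) for p, s in
                    digest_tryptic(seq, cfg.missed_cleavages,
                                   (cfg.peptide_min_len, cfg.peptide_max_len))
                    if ("D" in p or "E" in p) and len(_occurrence_starts(p, seq)) == 1]
            if not peps:
                logger.info("binder %s has no unique D/E tryptic peptide; skipped", acc)
                continue
            if probe in (4, 5, 6):
                w = np.array([1.0 + cfg.acidity_weight * (p.count("D") + p.count("E"))
                              for p, _ in peps])
            else:
                w = np.ones(len(peps))
            w = w / w.sum()
            k = min(cfg.peptides_per_binder, len(peps))
            idx = rng.choice(len(peps), size=k, replace=False, p=w)
            for i in sorted(idx.tolist()):
                pep, start = peps[i]
                de_offsets = [j + 1 for j, ch in enumerate(pep) if ch in "DE"]
                off = int(rng.choice(de_offsets))
                theo = class_mass[cls]
                observed = theo * (1.0 + rng.normal(0.0, cfg.mass_error_ppm_sd) * 1e-6)
                rows.append({"peptide": pep, "protein_accession": acc,
                             "observed_delta_da": observed, "source_probe_id": probe,
                             "modified_offset": off})
                truth.peptides.append({"peptide": pep, "accession": acc,
                                       "peptide_start": start,
                                       "site_position": start + off - 1,
                                       "residue": seq[start + off - 2],
                                       "probe": probe, "adduct_class": cls,
                                       "delta_true_da": theo})
    return pd.DataFrame(rows, columns=["peptide", "protein_accession", "observed_delta_da",
                                       "source_probe_id", "modified_offset"])


def _occurrence_starts(pep: str, seq: str) -> list[int]:
    starts, pos = [], seq.find(pep)
    while pos != -1:
        starts.append(pos)
        pos = seq.find(pep, pos + 1)
    return starts


def background_proteome(proteome: Proteome, truth: SyntheticTruth) -> Proteome:
    """The background-class slice of a synthetic proteome.

    This is the population whose planted motif rate is the configured
    background prevalence; use it as the enrichment background when
    checking recovery of the planted fold enrichment.
    """
    entries = [e for e in proteome if truth.classes.get(e.accession) == "background"]
    return Proteome(entries, source_tag=proteome.source_tag + ":background")


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    proteome: Proteome
    quant: QuantMatrix
    peptides: pd.DataFrame
    truth: SyntheticTruth


def generate_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a full synthetic study (proteome, quant matrix, peptides, truth)."""
    proteome, truth = generate_proteome(cfg)
    quant = generate_quant_table(cfg, proteome, truth)
    peptides = generate_modified_peptides(cfg, proteome, truth)
    return SyntheticStudy(cfg, proteome, quant, peptides, truth)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the five study files; every header carries the seed and config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    tag = f"polyprobe synthetic study seed={cfg.seed} config={cfg.hash}"
    paths = {"fasta": outdir / "proteome.fasta",
             "quant": outdir / "quant.tsv",
             "sample_meta": outdir / "sample_meta.tsv",
             "peptides": outdir / "modified_peptides.tsv",
             "truth": outdir / "truth.json"}
    write_fasta(study.proteome, paths["fasta"], preamble=tag)
    with open(paths["quant"], "w") as fh:
        fh.write(f"# {tag}\n")
        study.quant.values.to_csv(fh, sep="\t", index_label="accession",
                                  float_format="%.6f", lineterminator="\n")
    with open(paths["sample_meta"], "w") as fh:
        fh.write(f"# {tag}\n")
        study.quant.sample_meta.reset_index().to_csv(fh, sep="\t", index=False,
                                                     lineterminator="\n")
    with open(paths["peptides"], "w") as fh:
        fh.write(f"# {tag}\n")
        study.peptides.to_csv(fh, sep="\t", index=False, float_format="%.6f",
                              lineterminator="\n")
    paths["truth"].write_text(study.truth.to_json(
        extra={"seed": cfg.seed, "config_hash": cfg.hash, "config": cfg.to_dict()}) + "\n")
    return paths
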