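"""Pipeline orchestration: config handling, stage sequencing, summary report.

``run_analyze`` executes the full downstream analysis in order —
normalize -> test -> call -> partition -> motif -> sites -> report — from a
FASTA proteome, a quant matrix with sample metadata, and (optionally) a
modified-peptide table. Missing optional inputs run a partial pipeline with
a logged notice. Every number in the summary report is re-derivable from
the stage TSVs written next to it.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import config_hash, percent, round_half_up
from .acidic_motif import MotifParams, fold_enrichment, scan_proteome, subset_motif_report
from .binder_enrichment import (call_binders, median_normalize, read_quant,
                                test_enrichment)
from .binder_sets import intersection_counts, partition_subsets
from .chem_adducts import assign_adduct, builtin_adducts, monoisotopic_mass, parse_formula
from .proteome_io import read_fasta
from .synthetic_data import SyntheticStudyConfig, generate_study, write_study
from .xl_sites import (AmbiguousPeptide, PeptideNotFound, acidity_profile,
                       candidate_sites, classify_exclusive_adducts,
                       read_peptide_table, site_assignment_table, tally_sites)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "run_simulate", "run_analyze",
           "worked_examples", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters; unknown keys are rejected on load."""

    fasta: str | None = None
    quant: str | None = None
    sample_meta: str | None = None
    peptides: str | None = None
    output_dir: str = "polyprobe_out"
    seed: int = 0
    # enrichment
    alpha: float = 0.05
    min_lfc: float = 1.0
    control_probe: int = 1
    # motif
    window: int = 20
    min_acidic: int = 10
    # adduct matching
    tolerance_ppm: float = 10.0
    # simulation overrides (forwarded to SyntheticStudyConfig)
    simulate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; reject unknown keys by name."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" in data and data["simulate"]:
        sim_known = {f.name for f in dataclasses.fields(SyntheticStudyConfig)}
        sim_unknown = set(data["simulate"]) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(sim_unknown)}")
    return PipelineConfig(**data)


def _echo_config(config: PipelineConfig, outdir: Path) -> None:
    (outdir / "effective_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic study into the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dict(config.simulate)
    sim.setdefault("seed", config.seed)
    try:
        cfg = SyntheticStudyConfig(**sim)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate config: {exc}") from exc
    study = generate_study(cfg)
    paths = write_study(study, outdir)
    _echo_config(config, outdir)
    logger.info("simulated study: %d proteins, %d samples, %d modified peptides",
                len(study.proteome), study.quant.values.shape[1], len(study.peptides))
    return paths


def run_analyze(config: PipelineConfig) -> dict:
    """Run the staged analysis and write stage TSVs plus ``summary.json``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir)
    if config.fasta is None or config.quant is None or config.sample_meta is None:
        raise ConfigError("analyze requires fasta, quant and sample_meta paths")

    proteome = read_fasta(config.fasta)
    logger.info("proteome: %d entries", len(proteome))
    quant = read_quant(config.quant, config.sample_meta)
    logger.info("quant matrix: %d proteins x %d samples", *quant.values.shape)

    # --- enrichment ---
    quant = median_normalize(quant)
    probes = [p for p in quant.probes if p != config.control_probe]
    results = {p: test_enrichment(quant, p, config.control_probe) for p in probes}
    calls, bm = call_binders(results, alpha=config.alpha, min_lfc=config.min_lfc)
    calls.to_csv(outdir / "binder_calls.tsv", sep="\t", index=False)
    bm.to_tsv(outdir / "binder_matrix.tsv")
    binder_counts = {int(p): int(bm.frame[p].sum()) for p in bm.frame.columns}
    logger.info("binder counts per probe: %s", binder_counts)

    # --- set algebra ---
    partition = partition_subsets(bm)
    partition.to_tsv(outdir / "subset_partition.tsv")
    inter = intersection_counts(bm)
    inter.table.to_csv(outdir / "intersections.tsv", sep="\t", index=False)

    # --- acidic motif ---
    params = MotifParams(config.window, config.min_acidic)
    scan = scan_proteome(proteome, params)
    pd.DataFrame(
        [{"accession": r.accession, "has_motif": r.has_motif,
          "n_windows": len(r.windows),
          "best_window_start": max(r.windows, key=lambda w: w[1])[0] if r.windows else "",
          "best_count": max(w[1] for w in r.windows) if r.windows else ""}
         for r in scan]).to_csv(outdir / "motif_scan.tsv", sep="\t", index=False)
    motif_report = subset_motif_report(partition, proteome, params, background=proteome)
    motif_report.to_csv(outdir / "subset_motif_report.tsv", sep="\t", index=False)

    summary = {
        "provenance": {"polyprobe_version": __version__, "config_hash": config.hash,
                       "parameters": config.to_dict()},
        "binder_counts_per_probe": binder_counts,
        "n_binders_total": int(bm.frame.any(axis=1).sum()),
        "subset_sizes": partition.counts,
        "subset_motif": motif_report.to_dict(orient="records"),
    }

    # --- crosslink sites (optional stage) ---
    if config.peptides is not None:
        records = read_peptide_table(config.peptides)
        logger.info("modified peptides: %d records", len(records))
        adducts = builtin_adducts()
        assignments, skipped = [], {"not_found": 0, "ambiguous": 0, "unmapped_protein": 0}
        for rec in records:
            if rec.protein_accession not in proteome:
                skipped["unmapped_protein"] += 1
                continue
            try:
                assignments.extend(candidate_sites(rec, proteome.get(rec.protein_accession),
                                                   adducts, config.tolerance_ppm))
            except PeptideNotFound:
                skipped["not_found"] += 1
            except AmbiguousPeptide:
                skipped["ambiguous"] += 1
        if any(skipped.values()):
            logger.warning("peptide mapping skipped records: %s", skipped)
        site_assignment_table(assignments).to_csv(outdir / "site_assignments.tsv",
                                                  sep="\t", index=False)
        pd.DataFrame([vars(acidity_profile(p)) for p in
                      sorted({r.peptide for r in records})]).to_csv(
            outdir / "acidity_profiles.tsv", sep="\t", index=False)
        excl = classify_exclusive_adducts(records, adducts, config.tolerance_ppm)
        excl.table.to_csv(outdir / "exclusivity_summary.tsv", sep="\t", index=False)
        tally = tally_sites(assignments, bm)
        tally.table.to_csv(outdir / "site_tally.tsv", sep="\t", index=False)
        class_counts = pd.Series(
            [assign_adduct(r.observed_delta_da, adducts, config.tolerance_ppm).matched_class
             or "unmatched" for r in records]).value_counts().to_dict()
        summary["adduct_class_counts"] = {str(k): int(v) for k, v in class_counts.items()}
        summary["exclusivity"] = excl.table.to_dict(orient="records")
        summary["site_tallies"] = tally.per_group
        summary["peptide_mapping_skipped"] = skipped
    else:
        logger.info("no modified-peptide table supplied; site stages skipped")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary


# Inputs for the worked examples: the published headline quantities this
# package's arithmetic must reproduce (formulas, count pairs, peptides).
_WORKED = {
    "formulas": [("putrescine", "C29H52O5N8S", 624.37814),
                 ("spermidine", "C32H59O5N9S", 681.43599),
                 ("spermine", "C35H66O5N10S", 738.49384)],
    "ladder": ("C3H7N", 57.05785),
    "fe": [("subset_B", 111, 195, 2206, 20399, 5.3, 57),
           ("subset_A", 11, 171, 2206, 20399, 0.6, 6)],
    "background_pct": (2206, 20399, 11),
    "acidity_pcts": [("spermidine_exclusive_ge50", 24, 198, 12),
                     ("spermidine_exclusive_ge33", 75, 198, 38),
                     ("putrescine_exclusive_ge33", 6, 47, 13)],
    "peptides": [("DYEEVGADSADGEDEGEEY", "ge50"),
                 ("YQDEVFGGFVTEPQEESEEEVEEPEER", "ge33")],
}


def worked_examples() -> pd.DataFrame:
    """Recompute the headline published quantities from their inputs.

    Returns a table with one row per check: the computed value, the expected
    published value, and pass/fail at the printed precision.
    """
    rows = []

    def add(name, computed, expected):
        rows.append({"check": name, "computed": computed, "expected": expected,
                     "pass": computed == expected})

    for cls, ftext, expected in _WORKED["formulas"]:
        add(f"delta_mass_{cls}", round_half_up(monoisotopic_mass(parse_formula(ftext)), 5),
            expected)
    ladder_f, ladder_expected = _WORKED["ladder"]
    masses = sorted(monoisotopic_mass(parse_formula(f)) for _, f, _ in _WORKED["formulas"])
    add("ladder_spacing_low", round_half_up(masses[1] - masses[0], 5),
        round_half_up(monoisotopic_mass(parse_formula(ladder_f)), 5))
    add("ladder_spacing_high", round_half_up(masses[2] - masses[1], 5), ladder_expected)
    for name, k, n, K, N, fe_exp, pct_exp in _WORKED["fe"]:
        stat = fold_enrichment(k, n, K, N)
        add(f"fe_{name}", stat.fe_rounded, fe_exp)
        add(f"pct_motif_{name}", stat.subset_percent, pct_exp)
    k, n, pct_exp = _WORKED["background_pct"]
    add("pct_motif_background", percent(k, n), pct_exp)
    for name, k, n, pct_exp in _WORKED["acidity_pcts"]:
        add(f"pct_{name}", percent(k, n), pct_exp)
    for pep, cls_exp in _WORKED["peptides"]:
        add(f"acidity_class_{pep[:8]}", acidity_profile(pep).acidity_class, cls_exp)
    return pd.DataFrame(rows)
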