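# polyprobe

Downstream analysis for **polyamine photoaffinity-labeling chemoproteomics**:
the computational workflow that turns probe-enrichment proteomics and
probe-modified peptide tables into a polyamine–protein interaction profile.

Polyamines (putrescine, spermidine, spermine) are polycations that engage
proteins mainly through multivalent electrostatic contacts with acidic
residues. Photoaffinity analogs of the polyamines — a minimalist alkynyl
diazirine on a terminal amine — crosslink to nearby proteins in live cells
on 365 nm irradiation; click chemistry then attaches a biotin handle for
enrichment and quantitative LC-MS/MS. `polyprobe` implements everything
downstream of the search engine:

- **`chem_adducts`** — elemental-formula parsing and monoisotopic Δmass
  arithmetic for the probe photoadducts. The three probe classes form an
  arithmetic ladder spaced by one aminopropyl unit (C₃H₇N, 57.05785 Da):
  putrescine-type C₂₉H₅₂O₅N₈S (+624.37814 Da), spermidine-type C₃₂H₅₉O₅N₉S
  (+681.43599 Da), spermine-type C₃₅H₆₆O₅N₁₀S (+738.49384 Da). Observed
  peptide Δmasses are assigned to a class within a ppm tolerance — which is
  how the intracellular truncation of a spermine probe to a spermidine-mass
  adduct is detected.
- **`binder_enrichment`** — per-protein Welch *t* of each probe condition
  against the monoamine control on a replicate log₂-intensity matrix,
  Benjamini–Hochberg within condition, binder at *q* ≤ α and log₂FC ≥ 1.
- **`binder_sets`** — UpSet-style exclusive intersections and the subset
  partition: **A** = bound by diamine probes only, **B** = bound by
  spermidine/spermine probes only; overlap with external interactor lists.
- **`acidic_motif`** — the acidic-stretch statistic: a protein "has the
  motif" if some 20-residue window contains ≥ 10 D/E. Subset-level fold
  enrichment FE = (k/n)/(K_bg/N_bg) with a hypergeometric tail *p*.
- **`xl_sites`** — crosslink-site mapping (exact peptide→protein search,
  1-based coordinates), D/E candidate-site enumeration, peptide acidity
  classes (≥ 50 %, ≥ 1/3 D/E), and adduct-class exclusivity summaries.
- **`synthetic_data`** — a seeded generator that emits a complete synthetic
  study (proteome FASTA, quant + sample-meta TSVs, modified-peptide TSV)
  with planted ground truth, so the whole pipeline is testable end to end.
- **`pipeline` / `cli`** — orchestration with YAML config, structured
  logging, and a machine-readable `summary.json`.

## Worked example

`polyprobe worked-examples` recomputes the headline published quantities
from their primary inputs (formulas, count pairs, peptide sequences):

```
                        check   computed   expected  pass
        delta_mass_putrescine  624.37814  624.37814  True
        delta_mass_spermidine  681.43599  681.43599  True
          delta_mass_spermine  738.49384  738.49384  True
           ladder_spacing_low   57.05785   57.05785  True
          ladder_spacing_high   57.05785   57.05785  True
                  fe_subset_B        5.3        5.3  True
           pct_motif_subset_B         57         57  True
                  fe_subset_A        0.6        0.6  True
           pct_motif_subset_A          6          6  True
         pct_motif_background         11         11  True
pct_spermidine_exclusive_ge50         12         12  True
pct_spermidine_exclusive_ge33         38         38  True
pct_putrescine_exclusive_ge33         13         13  True
       acidity_class_DYEEVGAD       ge50       ge50  True
       acidity_class_YQDEVFGG       ge33       ge33  True
```

Reading the table: the three Δmasses are the monoisotopic masses of the
probe-adduct formulas at 5 dp, and their ladder spacing is exactly the
aminopropyl mass. FE 5.3 means acidic stretches are 5.3-fold
overrepresented among proteins bound only by spermidine/spermine probes
(111/195 = 57 % vs 2206/20399 = 11 % background), while diamine-only
binders are depleted (FE 0.6, 6 %). The two peptides are known acidic-IDR
regions of TUBA1C and G3BP1; their D/E fractions (10/19 and 12/27) put them
in the ≥ 50 % and ≥ 1/3 classes.

A full synthetic study runs in seconds:

```sh
polyprobe simulate --output-dir demo --seed 1
polyprobe analyze --fasta demo/proteome.fasta --quant demo/quant.tsv \
    --sample-meta demo/sample_meta.tsv --peptides demo/modified_peptides.tsv \
    --output-dir demo/out
```

which prints (seed 1):

```
binders per probe: {2: 166, 3: 155, 4: 164, 5: 169, 6: 157}
subset sizes: {'A': 227, 'B': 264, 'shared': 0, 'none': 1509}
summary written to demo/out/summary.json
```

— about 80 % of the 200 planted binders per probe are recovered with no
false calls, subset B is strongly motif-enriched in `summary.json`, and
every probe-6 peptide record carries a spermidine-class mass (the planted
truncation scenario).

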