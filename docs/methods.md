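# Methods

## Adduct mass arithmetic

Probe-modified peptides carry a neutral monoisotopic mass shift equal to the
probe-derived photoadduct plus the click-conjugated azide-PEG3-biotin
handle. Masses are computed as Σ count(e)·m(e) over a pinned atomic-mass
table (monoisotopic, most abundant isotope): C = 12 exactly,
H = 1.00782503207, N = 14.0030740048, O = 15.9949146196, S = 31.97207100,
P = 30.97376163 Da. At least 9 significant digits are needed for the 5-dp
adduct masses to be exact; the table is immutable at run time and its
version string travels with exported tables. Formula strings are Hill-style
(`C29H52O5N8S`); the canonical writer emits C, H, then alphabetical.

The three built-in adducts differ by aminopropyl units (C3H7N,
57.05785 Da), so class assignment of an observed Δmass is unambiguous at
any realistic tolerance. Assignment minimises |ppm error| with
ppm = 1e6·(obs − theo)/theo and a default tolerance of 10 ppm — a typical
high-resolution accuracy; the generator's simulated errors are 3 ppm (1 σ),
so ~0.1 % of simulated records fall outside 10 ppm (3.3 σ) and are excluded
with a log entry, which is the intended behaviour for outliers. Isotope
patterns, charge states and spectrum scoring are out of scope: the package
consumes search-result-like tables.

Reported values follow the source conventions: round-half-up at the printed
precision (masses 5 dp, fold enrichment 1 dp, percentages integer), with
full precision retained in the objects. Half-up is applied to the shortest
decimal representation of the float, so 10.81 % → 11 % and 5.26 → 5.3.

## Binder calling

Input is a protein × sample log₂-intensity matrix with a sample → (probe,
replicate) map. The isobaric-label workflow upstream is reduced to median
centring (each column shifted so its median equals the median of column
medians); calls are invariant to global shifts. Each probe condition is
tested against the monoamine control with a per-protein two-sided Welch
*t*-test, BH-adjusted within the condition; a binder requires q ≤ α (0.05)
and log₂FC ≥ 1. The test choice is recorded in the output provenance so it
can be swapped.

Degenerate cases: zero-variance rows get p = 1 (rather than an infinite
statistic); rows with any missing intensity in a tested condition are
excluded from that test and logged — no imputation. Welch with estimated
degrees of freedom is conservative at 3 + 3 replicates (empirical null
rejection ≈ 0.03 at nominal 0.05), which costs a little power but never
inflates the false-positive rate; the test suite asserts level control and
≥ 95 % power at the reference effect (3 log₂ units, σ 0.5, triplicates).

## Set algebra and acidic-stretch enrichment

Subset A = bound to a diamine probe (2/3) and none of 4–6; subset B = bound
to 4/5/6 and neither diamine; "shared" otherwise. Intersections use
UpSet-exclusive semantics: each bound protein is counted once, under its
full bound set, so intersection sizes partition the bound proteins;
marginal per-probe set sizes are reported separately. External-list overlap
is accession-level with an optional user-supplied mapping table — no online
ID-mapping.

The acidic-stretch motif is a sliding window of W = 20 residues containing
K ≥ 10 of {D, E}, scanned with a rolling count over all L − W + 1 windows;
a protein has the motif if at least one window qualifies (all qualifying
windows are still reported). Ambiguity codes B/Z/X/U/O are tolerated in
sequences but never counted as acidic — silently counting them would bias
the statistic. Note the monotonicity caveat: lowering K can only add
motifs, but shortening W at fixed K is *not* monotone (shortening W by d is
monotone when K also drops by ≥ d).

Fold enrichment of a subset against a background proteome is
FE = (k/n)/(K_bg/N_bg), with a hypergeometric tail probability — upper tail
when FE ≥ 1, lower when FE < 1, labelled accordingly (the tail p is
additive information; the headline statistic is FE itself). Backgrounds are
user-supplied; the pipeline report uses the full input proteome, mirroring
the use of the whole Swiss-Prot human proteome as background.

## Crosslink sites and peptide acidity

Peptides map to proteins by exact substring search; zero or multiple
occurrences raise distinct signals and multi-mapping peptides are excluded
from site tallies (site coordinates must be unique). With a known modified
offset, one site is assigned; otherwise every D/E of the peptide is
enumerated as a candidate (site residues configurable; probabilistic
localisation is out of scope). Peptide acidity classes use closed
thresholds: ge50 ⇔ D/E fraction ≥ 1/2, ge33 ⇔ ≥ 1/3 — "≥ 33 %" is read as
one-third of the length, which only differs from 0.33 at exact thirds.
Exclusivity is computed per unique peptide sequence: peptides observed with
exactly one adduct class are "exclusive" to it, peptides observed with two
or more go to a separate "both" bucket, making the handling of shared
peptides explicit. Sites are tallied as distinct (protein, position) pairs
within probe groups (diamine 2–3 vs higher-polyamine 4–6) and joined to
binder status.

## Synthetic-study generator

The generator emulates the data *structure* of a live-cell photoaffinity
study at a scale where every stage is testable in seconds:

- **Proteome** — 2000 proteins, i.i.d. residues, background D/E frequency
  0.12, lengths log-normal (median 400, σ 0.5, resampled below 20). Two
  disjoint binder pools of 300 are designated (A-like for diamine probes,
  B-like for the higher polyamines). One 20-residue acidic stretch (10–16
  D/E at a uniform position, overwriting so lengths are preserved) is
  planted with probability 0.06 / 0.57 / 0.11 for A-like / B-like /
  background proteins — the prevalences the motif analysis should recover.
- **Quant matrix** — baseline ~ N(25, 2) log₂ units per protein; each
  probe's 200 binders (drawn from its pool) receive an enrichment effect
  ~ N(3.0, 0.5) in that probe's 3 replicates; i.i.d. N(0, 0.3) noise
  everywhere; a control condition (probe 1) carries no effects.
- **Modified peptides** — tryptic digestion (cleave after K/R unless before
  P, ≤ 1 missed cleavage, emitted length 6–40), two D/E-containing,
  uniquely mapping peptides sampled per binder of probes 3–6 (D/E-rich
  peptides oversampled for spermidine-class probes, weight 1 + de_count),
  a true site uniform among the peptide's D/E, and an observed Δmass equal
  to the class mass with 3 ppm (1 σ) multiplicative Gaussian error. With
  `spermine_truncation` (default on, the behaviour observed in cells),
  probe-6 records carry the spermidine-class mass.

Two scale choices deliberately depart from the real study's proportions.
First, binder prevalence is ~10 % per probe rather than ~1 %: at the
reference effect size and triplicates, BH across 2000 proteins with only
~20 true signals would leave all q-values above any usable threshold, so a
1 %-prevalence emulation at this proteome size cannot exercise the calling
stage at all. Second, because the 300-protein pools are a substantial slice
of a 2000-protein proteome, whole-proteome motif prevalence (~17 %) exceeds
the planted background rate; the planted fold enrichment (0.57/0.11 ≈ 5.18)
is therefore defined against the background-class proteins
(`background_proteome()`), whose rate is 0.11 by construction. In a
full-size proteome, where binders are a few percent, the two backgrounds
coincide to within a percent.

All randomness flows from one `numpy.random.default_rng(seed)`
(sub-generators at seed + 1 and seed + 2 for the quant and peptide stages);
the same seed reproduces byte-identical files, and every output header
carries the seed and a config hash (the FASTA as a `;` preamble line, which
FASTA parsers skip).

What the generator does *not* model — realistic residue correlations,
protein-abundance/peptide-detectability coupling, missing values, batch
effects, PSM-level FDR — bounds what green tests mean: they validate the
statistical machinery and its calibration under the stated model, not
performance on real LC-MS/MS data.

## Recovery checks and their problem sizes

The end-to-end checks run the full pipeline on default 2000-protein
studies. Subset B holds ~290 proteins, so its motif fraction carries ~10 %
binomial noise per study; the fold-enrichment recovery check (within 15 %
of the planted 5.18) is therefore evaluated on the mean of three replicate
studies (standard error ~5 %), with replication rather than a wider band
providing the power. The probe-6 truncation check (100 % spermidine-class
assignments at 10 ppm) and binder precision are pooled over the same
studies. The motif scanner and intersection counter are checked exactly
against brute-force oracles (1000 random sequences up to length 2000; 5-probe
boolean matrices), and the hypergeometric tail against exhaustive
enumeration for backgrounds up to 60.

## Known limitations

- The quantitative workflow is a reduction: no isobaric reporter-ion
  modelling, no peptide-to-protein roll-up, no batch correction.
- Exact substring mapping cannot place peptides across sequence variants or
  isoforms; multi-mapping peptides are set aside rather than apportioned.
- FE is undefined for backgrounds with zero motif proteins (rejected).
- The published dataset-level counts (total binders, subset sizes, site
  tallies) depend on the deposited raw data and unstated search settings;
  the pipeline reproduces their *structure* on synthetic studies, and the
  worked examples reproduce the published derived quantities from their
  printed inputs.
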