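"""Generator determinism, tryptic digestion, and planted-truth consistency."""
import filecmp

import numpy as np
import pytest

from polyprobe.acidic_motif import MotifParams, scan_acidic_windows
from polyprobe.chem_adducts import assign_adduct
from polyprobe.synthetic_data import (SyntheticStudyConfig, SyntheticTruth, digest_tryptic,
                                      generate_modified_peptides, generate_proteome,
                                      generate_quant_table, generate_study, write_study)


class TestDigest:
    def test_basic_cleavage(self):
        assert digest_tryptic("AAAKBBBRCCC", missed_cleavages=0) == \
            [("AAAK", 1), ("BBBR", 5), ("CCC", 9)]

    def test_proline_suppression(self):
        assert digest_tryptic("AAKPAA", missed_cleavages=0) == [("AAKPAA", 1)]

    def test_missed_cleavage_adds_joined_peptide(self):
        peps = digest_tryptic("AAAKBBBR", missed_cleavages=1)
        assert ("AAAKBBBR", 1) in peps
        assert ("AAAK", 1) in peps and ("BBBR", 5) in peps

    def test_length_filter(self):
        peps = digest_tryptic("AAAKBBBRCCC", missed_cleavages=0, length_range=(4, 40))
        assert [p for p, _ in peps] == ["AAAK", "BBBR"]

    def test_matches_pyteomics_cleave(self, rng):
        """Independent oracle: pyteomics' cleave with the same K/R-not-P rule."""
        parser = pytest.importorskip("pyteomics.parser")
        rule = r"[KR](?=[^P])"
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=int(rng.integers(5, 200))))
            for mc in (0, 1, 2):
                ours = {p for p, _ in digest_tryptic(seq, missed_cleavages=mc)}
                theirs = parser.cleave(seq, rule, missed_cleavages=mc, min_length=1)
                assert ours == set(theirs)

    def test_starts_index_into_sequence(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seq = "".join(rng.choice(letters, size=300))
        for pep, start in digest_tryptic(seq, missed_cleavages=1):
            assert seq[start - 1:start - 1 + len(pep)] == pep


class TestProteome:
    def test_motif_fraction_one_plants_everywhere(self):
        cfg = SyntheticStudyConfig(seed=3, n_proteins=60, n_binders_per_probe=10,
                                   motif_fraction_a=1.0, motif_fraction_b=1.0,
                                   motif_fraction_background=1.0)
        proteome, truth = generate_proteome(cfg)
        for e in proteome:
            assert scan_acidic_windows(e.sequence, MotifParams())

    def test_motif_fraction_zero_near_background_rate(self):
        # with no planting, a qualifying window needs >=10 D/E of Binom(20, 0.12): rare
        cfg = SyntheticStudyConfig(seed=3, n_proteins=500, n_binders_per_probe=10,
                                   motif_fraction_a=0.0, motif_fraction_b=0.0,
                                   motif_fraction_background=0.0)
        proteome, _ = generate_proteome(cfg)
        n_with = sum(bool(scan_acidic_windows(e.sequence, MotifParams())) for e in proteome)
        assert n_with / len(proteome) < 0.02

    def test_truth_motifs_verify_in_sequences(self, default_study):
        for acc, windows in default_study.truth.motifs.items():
            seq = default_study.proteome.get(acc).sequence
            for start, n_acidic in windows:
                window = seq[start - 1:start + 19]
                assert window.count("D") + window.count("E") == n_acidic >= 10

    def test_class_pools_sized_and_disjoint(self, default_study):
        classes = default_study.truth.classes
        cfg = default_study.config
        pool = int(round(cfg.n_binders_per_probe * cfg.binder_pool_factor))
        counts = {c: sum(1 for v in classes.values() if v == c)
                  for c in ("A", "B", "background")}
        assert counts["A"] == counts["B"] == pool
        assert sum(counts.values()) == cfg.n_proteins

    def test_min_length_respected(self, default_study):
        assert min(len(e) for e in default_study.proteome) >= 20


class TestQuant:
    def test_binders_come_from_matching_pools(self, default_study):
        truth = default_study.truth
        for p in (2, 3):
            assert all(truth.classes[a] == "A" for a in truth.binders[p])
        for p in (4, 5, 6):
            assert all(truth.classes[a] == "B" for a in truth.binders[p])

    def test_zero_effect_gives_null_matrix(self):
        cfg = SyntheticStudyConfig(seed=5, n_proteins=400, n_binders_per_probe=40,
                                   effect_log2_mean=0.0, effect_log2_sd=0.0)
        proteome, truth = generate_proteome(cfg)
        quant = generate_quant_table(cfg, proteome, truth)
        from polyprobe.binder_enrichment import call_binders, test_enrichment
        res = {p: test_enrichment(quant, p, 1) for p in (2, 3, 4, 5, 6)}
        frac_small_p = np.mean([(df["p"] < 0.05).mean() for df in res.values()])
        assert abs(frac_small_p - 0.05) < 0.03
        _, bm = call_binders(res)
        assert bm.frame.to_numpy().sum() <= 5  # BH keeps the null clean


class TestModifiedPeptides:
    def test_truncation_on_all_probe6_spermidine(self, default_study):
        assert default_study.config.spermine_truncation
        probe6 = default_study.peptides.query("source_probe_id == 6")
        assert len(probe6) > 0
        classes = {assign_adduct(d).matched_class for d in probe6["observed_delta_da"]}
        assert classes == {"spermidine"}

    def test_truncation_off_probe6_spermine(self):
        cfg = SyntheticStudyConfig(seed=5, n_proteins=300, n_binders_per_probe=20,
                                   spermine_truncation=False)
        study = generate_study(cfg)
        probe6 = study.peptides.query("source_probe_id == 6")
        classes = {assign_adduct(d).matched_class for d in probe6["observed_delta_da"]}
        assert classes == {"spermine"}

    def test_mass_error_is_ppm_scale(self, default_study):
        truth_by_key = {}
        for t in default_study.truth.peptides:
            truth_by_key.setdefault((t["peptide"], t["probe"]), t["delta_true_da"])
        for _, row in default_study.peptides.iterrows():
            theo = truth_by_key[(row["peptide"], row["source_probe_id"])]
            ppm = 1e6 * (row["observed_delta_da"] - theo) / theo
            assert abs(ppm) < 20  # ~6 sd at the 3 ppm default


class TestDeterminismAndIO:
    def test_same_seed_identical_files(self, tmp_path):
        cfg = SyntheticStudyConfig(seed=42, n_proteins=150, n_binders_per_probe=15)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(generate_study(cfg), d1)
        write_study(generate_study(cfg), d2)
        names = ["proteome.fasta", "quant.tsv", "sample_meta.tsv",
                 "modified_peptides.tsv", "truth.json"]
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert match == names and not mismatch and not errors

    def test_different_seed_differs(self, tmp_path):
        small = dict(n_proteins=150, n_binders_per_probe=15)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(generate_study(SyntheticStudyConfig(seed=1, **small)), d1)
        write_study(generate_study(SyntheticStudyConfig(seed=2, **small)), d2)
        assert (d1 / "proteome.fasta").read_text() != (d2 / "proteome.fasta").read_text()

    def test_truth_json_roundtrip(self, tmp_path, default_study):
        text = default_study.truth.to_json()
        back = SyntheticTruth.from_json(text)
        assert back.binders == default_study.truth.binders
        assert back.classes == default_study.truth.classes
        assert back.peptides == default_study.truth.peptides

    def test_headers_carry_seed_and_hash(self, tmp_path):
        cfg = SyntheticStudyConfig(seed=9, n_proteins=60, n_binders_per_probe=5)
        paths = write_study(generate_study(cfg), tmp_path)
        tag = f"seed={cfg.seed} config={cfg.hash}"
        for name in ("fasta", "quant", "sample_meta", "peptides"):
            assert tag in paths[name].read_text().splitlines()[0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(n_proteins=0)
        with pytest.raises(ValueError):
            SyntheticStudyConfig(background_de_freq=1.5)
        with pytest.raises(ValueError):
            SyntheticStudyConfig(n_proteins=10, n_binders_per_probe=20)
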