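"""Enrichment testing against the control probe and binder calling."""
import numpy as np
import pandas as pd
import pytest

from polyprobe.binder_enrichment import (BinderMatrix, QuantMatrix, call_binders,
                                         median_normalize, read_quant)
from polyprobe.binder_enrichment import test_enrichment as welch_test


def make_matrix(values, probes, n_rep=3, accessions=None):
    """values: protein x sample ndarray; probes: condition id per sample block."""
    samples = [f"probe{p}_rep{r + 1}" for p in probes for r in range(n_rep)]
    meta = pd.DataFrame({"probe_id": [p for p in probes for _ in range(n_rep)],
                         "replicate": [r + 1 for _ in probes for r in range(n_rep)]},
                        index=pd.Index(samples, name="sample"))
    accessions = accessions or [f"P{i}" for i in range(values.shape[0])]
    return QuantMatrix(pd.DataFrame(values, index=accessions, columns=samples), meta)


class TestMedianNormalize:
    def test_fixed_point(self, rng):
        vals = rng.normal(25, 1, size=(50, 6))
        vals -= np.median(vals, axis=0, keepdims=True)  # all medians 0
        m = make_matrix(vals, [1, 2])
        out = median_normalize(m)
        assert np.allclose(out.values.to_numpy(), vals)

    def test_shift_removed(self, rng):
        # a +2 shift of one column is removed up to a global constant
        # (the grand median target itself moves with the shifted column)
        vals = rng.normal(25, 1, size=(50, 6))
        m0 = median_normalize(make_matrix(vals, [1, 2]))
        shifted = vals.copy()
        shifted[:, 0] += 2.0
        m1 = median_normalize(make_matrix(shifted, [1, 2]))
        diff = m1.values.to_numpy() - m0.values.to_numpy()
        assert np.allclose(diff, diff[0, 0], atol=1e-12)

    def test_all_medians_equal_after(self, rng):
        m = make_matrix(rng.normal(20, 3, size=(101, 9)), [1, 2, 3])
        out = median_normalize(m)
        medians = out.values.median(axis=0).to_numpy()
        assert np.allclose(medians, medians[0])


class TestEnrichmentTest:
    def test_no_signal_gives_p_one(self):
        vals = np.full((3, 6), 25.0)
        res = welch_test(make_matrix(vals, [1, 2]), probe_id=2)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_planted_four_log2_units(self, rng):
        # effect +4, sigma 0.2, 3 vs 3 -> overwhelming evidence
        n = 200
        vals = rng.normal(25, 0.2, size=(n, 6))
        vals[:, 3:] += 4.0
        res = welch_test(make_matrix(vals, [1, 2]), probe_id=2)
        assert (res["p"] < 0.01).all()
        assert res["log2fc"].mean() == pytest.approx(4.0, abs=0.1)

    def test_global_null_level_controlled(self, rng):
        # Welch with estimated df is conservative at n=3 per group (observed
        # rejection ~0.03 at nominal 0.05), so assert level control rather
        # than exact calibration, plus a floor that catches a broken test.
        n = 5000
        vals = rng.normal(0, 1, size=(n, 6))
        res = welch_test(make_matrix(vals, [1, 2]), probe_id=2)
        frac = (res["p"] < 0.05).mean()
        assert frac <= 0.05 + 3.3 * np.sqrt(0.05 * 0.95 / n)
        assert frac >= 0.01

    def test_too_few_replicates_rejected(self, rng):
        m = make_matrix(rng.normal(size=(5, 2)), [1, 2], n_rep=1)
        with pytest.raises(ValueError, match="replicates"):
            welch_test(m, probe_id=2)

    def test_missing_rows_excluded(self, rng):
        vals = rng.normal(25, 1, size=(10, 6))
        vals[3, 1] = np.nan
        res = welch_test(make_matrix(vals, [1, 2]), probe_id=2)
        assert len(res) == 9 and "P3" not in res.index


class TestCallBinders:
    def test_all_p_one_gives_no_binders(self):
        df = pd.DataFrame({"log2fc": [5.0] * 4, "p": [1.0] * 4},
                          index=[f"P{i}" for i in range(4)])
        calls, bm = call_binders({2: df})
        assert not calls["is_binder"].any()
        assert not bm.frame.to_numpy().any()

    def test_bh_stepup_hand_example(self):
        df = pd.DataFrame({"log2fc": [2.0] * 4, "p": [0.01, 0.02, 0.03, 0.04]},
                          index=list("abcd"))
        calls, _ = call_binders({2: df})
        assert np.allclose(calls["q"], 0.04)

    def test_q_monotone_in_p_rank(self, rng):
        df = pd.DataFrame({"log2fc": rng.normal(size=100),
                           "p": rng.uniform(size=100)}, index=[f"P{i}" for i in range(100)])
        calls, _ = call_binders({2: df})
        calls = calls.sort_values("p")
        assert (np.diff(calls["q"]) >= -1e-12).all()
        assert (calls["q"] <= 1).all() and (calls["q"] >= calls["p"] - 1e-12).all()

    def test_binder_requires_both_thresholds(self):
        df = pd.DataFrame({"log2fc": [3.0, 0.5], "p": [1e-6, 1e-6]}, index=["hit", "low_fc"])
        calls, _ = call_binders({2: df}, min_lfc=1.0)
        calls = calls.set_index("accession")
        assert bool(calls.loc["hit", "is_binder"])
        assert not bool(calls.loc["low_fc", "is_binder"])

    def test_constant_shift_changes_no_call(self, rng):
        vals = rng.normal(25, 0.5, size=(300, 6))
        vals[:30, 3:] += 3.0
        m = make_matrix(vals, [1, 2])
        m_shift = make_matrix(vals + 7.5, [1, 2])
        res = {2: welch_test(median_normalize(m), 2)}
        res_shift = {2: welch_test(median_normalize(m_shift), 2)}
        _, bm = call_binders(res)
        _, bm_shift = call_binders(res_shift)
        assert bm.frame.equals(bm_shift.frame)


def test_power_at_planted_effect(rng):
    """Effect 3 log2 units, sigma 0.5, n=3: the per-protein test detects >=95%."""
    n = 1000
    vals = rng.normal(0, 0.5, size=(n, 6))
    vals[:, 3:] += 3.0
    res = welch_test(make_matrix(vals, [1, 2]), probe_id=2)
    power = ((res["p"] < 0.05) & (res["log2fc"] >= 1.0)).mean()
    assert power >= 0.95


def test_false_discovery_proportion_on_synthetic_study(default_study):
    """BH keeps the observed false-discovery proportion near alpha against truth."""
    q = median_normalize(default_study.quant)
    results = {p: welch_test(q, p, 1) for p in (2, 3, 4, 5, 6)}
    calls, bm = call_binders(results, alpha=0.05, min_lfc=1.0)
    n_false = n_called = 0
    for p in (2, 3, 4, 5, 6):
        called = bm.accessions_bound(p)
        truth = set(default_study.truth.binders[p])
        n_called += len(called)
        n_false += len(called - truth)
    assert n_called > 0
    fdp = n_false / n_called
    assert fdp <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_called)


def test_quant_round_trip_via_tsv(tmp_path, rng):
    vals = rng.normal(25, 1, size=(5, 6))
    m = make_matrix(vals, [1, 2])
    qp, mp = tmp_path / "q.tsv", tmp_path / "m.tsv"
    m.values.to_csv(qp, sep="\t", index_label="accession")
    m.sample_meta.reset_index().to_csv(mp, sep="\t", index=False)
    back = read_quant(qp, mp)
    assert np.allclose(back.values.to_numpy(), vals)
    assert back.samples_for(2) == m.samples_for(2)


def test_binder_matrix_tsv_roundtrip(tmp_path, default_study):
    q = median_normalize(default_study.quant)
    _, bm = call_binders({2: welch_test(q, 2, 1)})
    path = bm.to_tsv(tmp_path / "bm.tsv")
    back = BinderMatrix.from_tsv(path)
    assert back.frame.equals(bm.frame)
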