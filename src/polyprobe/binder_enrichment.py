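"""Binder calling from replicate quantitative proteomics.

Each photoaffinity probe condition is tested protein-by-protein against the
monoamine control probe (compound 1) on a log2-intensity matrix: per-protein
two-sided Welch t-test, Benjamini-Hochberg adjustment within each probe
condition, and a binder call at q <= alpha AND log2 fold change >= min_lfc.
The isobaric-label workflow upstream is reduced to median centering here.

Conventions:
- zero-variance rows (identical values in both conditions) get p = 1 rather
  than an infinite t statistic;
- rows with any missing intensity in a tested condition are excluded from
  that test (no imputation) and logged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["QuantMatrix", "BinderMatrix", "read_quant", "median_normalize",
           "test_enrichment", "call_binders", "PROBE_COLUMNS"]

#: probe conditions tested against the control (compound 1)
PROBE_COLUMNS = (2, 3, 4, 5, 6)


@dataclass
class QuantMatrix:
    """Protein x sample log2-intensity matrix with sample metadata.

    ``values``: DataFrame indexed by accession, columns are sample IDs.
    ``sample_meta``: DataFrame indexed by sample ID with columns
    ``probe_id`` (int) and ``replicate`` (int).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    def samples_for(self, probe_id: int) -> list[str]:
        mask = self.sample_meta["probe_id"] == probe_id
        return list(self.sample_meta.index[mask])

    @property
    def probes(self) -> list[int]:
        return sorted(self.sample_meta["probe_id"].unique())


def read_quant(quant_path: str | Path, meta_path: str | Path) -> QuantMatrix:
    """Read a quant TSV (first column accession) and its sample-meta sidecar."""
    values = pd.read_csv(quant_path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    required = {"sample", "probe_id", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample meta must have columns {sorted(required)}, got {list(meta.columns)}")
    meta = meta.set_index("sample")
    return QuantMatrix(values, meta)


def median_normalize(m: QuantMatrix) -> QuantMatrix:
    """Shift each sample column so its median equals the grand median of column medians."""
    if m.values.empty:
        raise ValueError("empty quant matrix")
    col_medians = m.values.median(axis=0)
    target = float(np.median(col_medians.to_numpy()))
    shifted = m.values + (target - col_medians)
    return QuantMatrix(shifted, m.sample_meta.copy())


def test_enrichment(m: QuantMatrix, probe_id: int, control_id: int = 1) -> pd.DataFrame:
    """Per-protein Welch t-test of one probe condition against the control.

    Returns a DataFrame indexed by accession with columns ``log2fc``
    (mean(probe) - mean(control)) and ``p`` (two-sided). Rows with missing
    values in either condition are dropped (and counted in the log).
    """
    probe_cols = m.samples_for(probe_id)
    ctrl_cols = m.samples_for(control_id)
    if len(probe_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >=2 replicates per condition (probe {probe_id}: {len(probe_cols)}, "
            f"control {control_id}: {len(ctrl_cols)})")
    a = m.values[probe_cols].to_numpy(float)
    b = m.values[ctrl_cols].to_numpy(float)
    complete = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("probe %d vs %d: excluded %d proteins with missing intensities",
                    probe_id, control_id, n_dropped)
    a, b = a[complete], b[complete]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    zero_var = np.isnan(p)
    if zero_var.any():
        logger.warning("probe %d vs %d: %d zero-variance rows set to p=1",
                       probe_id, control_id, int(zero_var.sum()))
        p = np.where(zero_var, 1.0, p)
    idx = m.values.index[complete]
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=idx)


@dataclass
class BinderMatrix:
    """Boolean protein x probe matrix of called binders, with provenance."""

    frame: pd.DataFrame  # bool, columns are int probe ids
    provenance: dict = field(default_factory=dict)

    def accessions_bound(self, probe_id: int) -> set[str]:
        return set(self.frame.index[self.frame[probe_id]])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.astype(int).to_csv(path, sep="\t", index_label="accession")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinderMatrix":
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        frame.columns = [int(c) for c in frame.columns]
        return cls(frame.astype(bool))


def call_binders(results: Mapping[int, pd.DataFrame],
                 alpha: float = 0.05,
                 min_lfc: float = 1.0) -> tuple[pd.DataFrame, BinderMatrix]:
    """BH-adjust per probe condition and call binders.

    ``results`` maps probe_id -> output of :func:`test_enrichment`. Returns
    a long-format call table (accession, probe_id, log2fc, p, q, is_binder)
    and the assembled :class:`BinderMatrix`. Proteins untested for a probe
    are not binders of that probe.
    """
    if not results:
        raise ValueError("no test results supplied")
    frames = []
    for probe_id, df in sorted(results.items()):
        out = df.copy()
        if len(out):
            _, q, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        else:
            q = np.array([])
        out["q"] = np.maximum(q, out["p"])  # guard q >= p at the boundary
        out["probe_id"] = probe_id
        out["is_binder"] = (out["q"] <= alpha) & (out["log2fc"] >= min_lfc)
        frames.append(out.reset_index(names="accession"))
    calls = pd.concat(frames, ignore_index=True)[
        ["accession", "probe_id", "log2fc", "p", "q", "is_binder"]]

    proteins = sorted(calls["accession"].unique())
    probes = sorted(results.keys())
    matrix = pd.DataFrame(False, index=proteins, columns=probes)
    hits = calls[calls["is_binder"]]
    for probe_id, sub in hits.groupby("probe_id"):
        matrix.loc[sub["accession"], probe_id] = True
    prov = {"test": "welch-t two-sided", "adjust": "benjamini-hochberg per probe",
            "alpha": alpha, "min_lfc": min_lfc}
    return calls, BinderMatrix(matrix, prov)
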