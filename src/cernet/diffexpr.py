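"""Differential expression of pooled read counts between two sample groups.

Replicates are pooled within each group (counts and library sizes summed) and
each molecule is tested with a two-proportion z-test on its pooled relative
abundance: with p1 = c1/n1, p2 = c2/n2 and pooled p = (c1+c2)/(n1+n2),

    z = (p1 - p2) / sqrt(p * (1-p) * (1/n1 + 1/n2))

with a two-sided normal p-value. The fold change is computed on
pseudocounted proportions, log2((c1+0.5)/n1) - log2((c2+0.5)/n2), so it is
always finite; the pseudocount enters the fold change only, never the test.

A molecule is called differentially expressed (DE) when p < p_threshold AND
|log2FC| > lfc_threshold, both strict (defaults 0.01 and 2). Raw p-values
drive the call; Benjamini-Hochberg adjusted values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CountMatrix, DesignTable

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_LFC_THRESHOLD = 2.0

#: Columns of a contrast table, one row per molecule.
CONTRAST_COLUMNS = [
    "id",
    "rna_class",
    "c1",
    "n1",
    "c2",
    "n2",
    "log2fc",
    "z",
    "pvalue",
    "padj_bh",
    "is_de",
]


@dataclass
class ContrastTable:
    """Per-molecule DE results for one group1-vs-group2 comparison."""

    label: str
    records: pd.DataFrame

    def de_ids(self) -> set[str]:
        return set(self.records.loc[self.records["is_de"], "id"])

    def de_summary(self) -> pd.DataFrame:
        """Up/down DE counts per RNA class."""
        de = self.records[self.records["is_de"]]
        out = (
            de.assign(direction=np.where(de["log2fc"] > 0, "up", "down"))
            .groupby(["rna_class", "direction"])
            .size()
            .rename("n")
            .reset_index()
        )
        return out


def pool_counts(counts: CountMatrix, design: DesignTable, group: str) -> tuple[pd.Series, int]:
    """Sum counts and library sizes over the samples of one group."""
    design.validate_against(counts)
    samples = [s for s in design.samples_in(group) if s in counts.counts.columns]
    if not samples:
        raise ValueError(f"group {group!r} has no samples in the count matrix")
    pooled = counts.counts[samples].sum(axis=1)
    lib = int(counts.library_size[samples].sum())
    return pooled, lib


def test_molecule(c1: int, n1: int, c2: int, n2: int) -> tuple[float, float, float]:
    """Two-proportion z-test and pseudocounted log2 fold change for one molecule."""
    lfc, z, p = _ztest(np.array([c1]), n1, np.array([c2]), n2)
    return float(lfc[0]), float(z[0]), float(p[0])


def _ztest(c1: np.ndarray, n1: float, c2: np.ndarray, n2: float):
    if n1 <= 0 or n2 <= 0:
        raise ValueError("pooled library sizes must be positive")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("counts must be non-negative")
    if (c1 > n1).any() or (c2 > n2).any():
        raise ValueError("counts cannot exceed their library size")
    p1 = c1 / n1
    p2 = c2 / n2
    pooled = (c1 + c2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.log2((c1 + 0.5) / n1) - np.log2((c2 + 0.5) / n2)
    return log2fc, z, pvalue


def apply_de_filter(
    table: ContrastTable,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> ContrastTable:
    """Set the DE flag: p < p_threshold AND |log2FC| > lfc_threshold (strict)."""
    rec = table.records.copy()
    rec["is_de"] = (rec["pvalue"] < p_threshold) & (rec["log2fc"].abs() > lfc_threshold)
    return replace(table, records=rec)


def run_contrast(
    counts: CountMatrix,
    design: DesignTable,
    group1: str,
    group2: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    label: str | None = None,
) -> ContrastTable:
    """Pool, test and filter one comparison (group1 over group2)."""
    pooled1, n1 = pool_counts(counts, design, group1)
    pooled2, n2 = pool_counts(counts, design, group2)
    log2fc, z, pvalue = _ztest(pooled1.to_numpy(), n1, pooled2.to_numpy(), n2)
    padj = multipletests(pvalue, method="fdr_bh")[1] if len(pvalue) else pvalue
    rec = pd.DataFrame(
        {
            "id": counts.molecules,
            "rna_class": counts.rna_class,
            "c1": pooled1.to_numpy(),
            "n1": n1,
            "c2": pooled2.to_numpy(),
            "n2": n2,
            "log2fc": log2fc,
            "z": z,
            "pvalue": pvalue,
            "padj_bh": padj,
            "is_de": False,
        }
    )
    table = ContrastTable(label or f"{group1}_vs_{group2}", rec)
    return apply_de_filter(table, p_threshold, lfc_threshold)


def concat_contrasts(tables: list[ContrastTable]) -> ContrastTable:
    """Stack per-class tables of the same comparison into one table."""
    labels = {t.label for t in tables}
    if len(labels) != 1:
        raise ValueError(f"cannot concatenate different contrasts: {sorted(labels)}")
    rec = pd.concat([t.records for t in tables], ignore_index=True)
    return ContrastTable(tables[0].label, rec)


def write_contrast(table: ContrastTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_contrast(path, label: str) -> ContrastTable:
    rec = pd.read_csv(path, sep="\t")
    return ContrastTable(label, rec)
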