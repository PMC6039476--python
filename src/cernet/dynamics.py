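"""Cross-contrast dynamics: shared DE molecules and key miRNA-target pairs.

A molecule is *shared* when it is DE in both the tumorigenesis contrast
(primary vs control) and the metastasis contrast (metastatic vs primary).
Its direction pattern is *reversed* when the two log2 fold changes have
opposite signs, *concordant* otherwise. A *key pair* is a predicted
(miRNA, target) relation whose two members are shared and whose relation
itself appears in the DE-restricted pair sets of both contrasts. Reversal
is reported for every key-pair member but is not required for membership
(an optional strict-reversal filter is exposed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import ContrastTable

SHARED_COLUMNS = ["id", "rna_class", "log2fc_a", "log2fc_b", "pattern"]
KEY_PAIR_COLUMNS = [
    "mirna",
    "target",
    "target_class",
    "mirna_pattern",
    "target_pattern",
]


def _pattern(lfc_a: pd.Series, lfc_b: pd.Series) -> pd.Series:
    reversed_mask = (lfc_a * lfc_b) < 0
    return pd.Series(["reversed" if r else "concordant" for r in reversed_mask],
                     index=lfc_a.index)


def shared_molecules(contrast_a: ContrastTable, contrast_b: ContrastTable) -> pd.DataFrame:
    """Per-class intersection of the two contrasts' DE sets, with patterns."""
    a = contrast_a.records
    b = contrast_b.records
    merged = a[a["is_de"]][["id", "rna_class", "log2fc"]].merge(
        b[b["is_de"]][["id", "rna_class", "log2fc"]],
        on=["id", "rna_class"],
        suffixes=("_a", "_b"),
    )
    merged["pattern"] = _pattern(merged["log2fc_a"], merged["log2fc_b"])
    return merged[SHARED_COLUMNS].sort_values(["rna_class", "id"], ignore_index=True)


def extract_key_pairs(
    shared: pd.DataFrame,
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    require_reversed: bool = False,
) -> pd.DataFrame:
    """Pairs present in both contrasts' DE-restricted pair sets whose miRNA
    and target are both shared molecules."""
    cols = ["mirna", "target", "target_class"]
    both = pairs_a[cols].merge(pairs_b[cols], on=cols).drop_duplicates()
    pat = dict(zip(shared["id"], shared["pattern"]))
    shared_mirnas = set(shared.loc[shared["rna_class"] == "miRNA", "id"])
    shared_targets = {
        (r.id, r.rna_class) for r in shared.itertuples() if r.rna_class != "miRNA"
    }
    target_ok = np.array(
        [(t, c) in shared_targets for t, c in zip(both["target"], both["target_class"])],
        dtype=bool,
    )
    keep = both["mirna"].isin(shared_mirnas).to_numpy() & target_ok
    out = both[keep].copy()
    out["mirna_pattern"] = out["mirna"].map(pat)
    out["target_pattern"] = out["target"].map(pat)
    if require_reversed:
        out = out[(out["mirna_pattern"] == "reversed") & (out["target_pattern"] == "reversed")]
    out = out[KEY_PAIR_COLUMNS].sort_values(["mirna", "target"], ignore_index=True)
    return out


def dynamics_report(
    shared: pd.DataFrame, key_pairs: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Summary tables: shared counts, pattern breakdown, per-miRNA target
    counts, and the per-pair fold-change trend table."""
    shared_counts = (
        shared.groupby("rna_class").size().rename("n_shared").reset_index()
        if len(shared)
        else pd.DataFrame(columns=["rna_class", "n_shared"])
    )
    pattern_counts = (
        shared.groupby(["rna_class", "pattern"]).size().rename("n").reset_index()
        if len(shared)
        else pd.DataFrame(columns=["rna_class", "pattern", "n"])
    )
    per_mirna = (
        key_pairs.groupby("mirna").size().rename("n_targets").reset_index()
        if len(key_pairs)
        else pd.DataFrame(columns=["mirna", "n_targets"])
    )
    lfc = shared.set_index("id")[["log2fc_a", "log2fc_b"]] if len(shared) else None
    trend_rows = []
    for row in key_pairs.itertuples():
        trend_rows.append(
            {
                "mirna": row.mirna,
                "target": row.target,
                "mirna_log2fc_a": float(lfc.loc[row.mirna, "log2fc_a"]),
                "mirna_log2fc_b": float(lfc.loc[row.mirna, "log2fc_b"]),
                "target_log2fc_a": float(lfc.loc[row.target, "log2fc_a"]),
                "target_log2fc_b": float(lfc.loc[row.target, "log2fc_b"]),
                "mirna_pattern": row.mirna_pattern,
                "target_pattern": row.target_pattern,
            }
        )
    trend = pd.DataFrame(
        trend_rows,
        columns=[
            "mirna",
            "target",
            "mirna_log2fc_a",
            "mirna_log2fc_b",
            "target_log2fc_a",
            "target_log2fc_b",
            "mirna_pattern",
            "target_pattern",
        ],
    )
    return {
        "shared_counts": shared_counts,
        "pattern_counts": pattern_counts,
        "per_mirna_targets": per_mirna,
        "trend": trend,
    }
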