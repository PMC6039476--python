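"""Canonical seed-match miRNA target prediction.

The seed is miRNA nucleotides 2-8 (5'->3'). A canonical site on a target
transcript (DNA alphabet, read 5'->3') is an occurrence of the Watson-Crick
reverse complement of the seed region, classified by the standard site
taxonomy:

* ``8mer``    - reverse complement of positions 2-8 followed by an A,
* ``7mer-m8`` - reverse complement of positions 2-8 (no A requirement),
* ``7mer-A1`` - reverse complement of positions 2-7 followed by an A,
* ``6mer``    - reverse complement of positions 2-7 only.

Each locus (each occurrence of the 6-nt core) is assigned its single most
stringent achievable type; overlapping core occurrences are each counted.
Whole transcripts are scanned (lncRNAs carry no UTR annotation, and both
target classes flow through the same rule). Site coordinates are 1-based
positions of the first base of the full site pattern, so the reported
pattern always re-extracts from the target at ``[start, start+len-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import ContrastTable

#: Site types ordered from least to most stringent.
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

#: Complement from the miRNA (RNA) alphabet into the target (DNA) alphabet.
_RNA_TO_DNA_COMPLEMENT = {"A": "T", "U": "A", "G": "C", "C": "G"}

PAIR_COLUMNS = [
    "mirna",
    "target",
    "target_class",
    "n_8mer",
    "n_7mer_m8",
    "n_7mer_a1",
    "n_6mer",
    "best_type",
]


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site on a target transcript."""

    site_type: str
    start: int  # 1-based position of the site pattern's first base
    pattern: str  # the matched substring of the target


def seed_of(mirna_seq: str) -> str:
    """Seed heptamer: miRNA positions 2-8, 5'->3' (RNA alphabet)."""
    seq = mirna_seq.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(f"miRNA sequence too short for a seed (length {len(seq)} < 8)")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid miRNA letters {sorted(bad)}")
    return seq[1:8]


def _core_and_m8(seed7: str) -> tuple[str, str]:
    """DNA-alphabet reverse complement of seed positions 2-7, and the
    complement of position 8 (the base that extends the core on its 5' side
    on the target)."""
    core = "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(seed7[:6]))
    m8c = _RNA_TO_DNA_COMPLEMENT[seed7[6]]
    return core, m8c


def site_pattern(mirna_seq: str, site_type: str) -> str:
    """The exact target substring a site of ``site_type`` must contain.

    For the two A1-anchored types the trailing A is part of the pattern;
    for 7mer-m8 and 6mer the pattern is the seed complement alone.
    """
    core, m8c = _core_and_m8(seed_of(mirna_seq))
    if site_type == "8mer":
        return m8c + core + "A"
    if site_type == "7mer-m8":
        return m8c + core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "6mer":
        return core
    raise ValueError(f"unknown site type {site_type!r}")


def find_seed_sites(mirna_seq: str, target_seq: str) -> list[SeedSite]:
    """All canonical seed sites of one miRNA on one target transcript."""
    core, m8c = _core_and_m8(seed_of(mirna_seq))
    t = target_seq.upper().replace("U", "T")
    sites: list[SeedSite] = []
    j = t.find(core)
    while j != -1:
        has_m8 = j > 0 and t[j - 1] == m8c
        has_a1 = j + 6 < len(t) and t[j + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite("8mer", j, t[j - 1 : j + 7]))
        elif has_m8:
            sites.append(SeedSite("7mer-m8", j, t[j - 1 : j + 6]))
        elif has_a1:
            sites.append(SeedSite("7mer-A1", j + 1, t[j : j + 7]))
        else:
            sites.append(SeedSite("6mer", j + 1, t[j : j + 6]))
        j = t.find(core, j + 1)  # overlapping occurrences each counted
    return sites


def predict_pairs(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    target_classes: Mapping[str, str],
    min_best_type: str = "7mer-A1",
    min_sites: int = 1,
) -> pd.DataFrame:
    """Scan all miRNA x target combinations and keep pairs meeting stringency.

    A pair is retained when its best site type is at least ``min_best_type``
    and its total site count is at least ``min_sites``. Output is sorted by
    (mirna, target) for determinism.
    """
    if min_best_type not in SITE_RANK:
        raise ValueError(f"unknown site type {min_best_type!r}")
    min_rank = SITE_RANK[min_best_type]
    rows = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            sites = find_seed_sites(mirnas[mid], targets[tid])
            if not sites:
                continue
            n_by_type = {t: 0 for t in SITE_TYPES}
            for s in sites:
                n_by_type[s.site_type] += 1
            best = max((s.site_type for s in sites), key=lambda t: SITE_RANK[t])
            if SITE_RANK[best] < min_rank or len(sites) < min_sites:
                continue
            if tid not in target_classes:
                raise ValueError(f"target {tid!r} has no class annotation")
            tclass = target_classes[tid]
            if tclass not in ("mRNA", "lncRNA"):
                raise ValueError(f"target {tid!r} has non-target class {tclass!r}")
            rows.append(
                {
                    "mirna": mid,
                    "target": tid,
                    "target_class": tclass,
                    "n_8mer": n_by_type["8mer"],
                    "n_7mer_m8": n_by_type["7mer-m8"],
                    "n_7mer_a1": n_by_type["7mer-A1"],
                    "n_6mer": n_by_type["6mer"],
                    "best_type": best,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def restrict_to_de(pairs: pd.DataFrame, contrast: ContrastTable) -> pd.DataFrame:
    """Keep pairs whose miRNA and target are both DE in the contrast."""
    de = contrast.de_ids()
    keep = pairs["mirna"].isin(de) & pairs["target"].isin(de)
    return pairs[keep].reset_index(drop=True)
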