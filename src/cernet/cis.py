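"""Cis-acting lncRNA-gene annotation: coding genes within a +/-100-kb window.

The genomic gap between two loci on the same chromosome is the number of
bases strictly between them (0 when they overlap or are adjacent). A lncRNA
and a coding gene form a cis pair when their gap is at most the window,
inclusive at exactly the window edge. Membership ignores strand (divergent
transcription makes both orientations biologically relevant); strand enters
only the descriptive relative-position label.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .diffexpr import ContrastTable
from .model import MoleculeRecord

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 100_000

CIS_COLUMNS = ["lncrna", "gene", "chrom", "gap", "relative_position"]


def genomic_gap(a: MoleculeRecord, b: MoleculeRecord) -> int:
    """Bases strictly between two same-chromosome loci (0 if they intersect)."""
    if not (a.has_coordinates and b.has_coordinates):
        raise ValueError("both molecules need coordinates")
    if a.chrom != b.chrom:
        raise ValueError(f"{a.id!r} and {b.id!r} are on different chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)  # type: ignore[arg-type]


def _relative_position(lnc: MoleculeRecord, gene: MoleculeRecord) -> str:
    """Position of the gene relative to the lncRNA in + orientation."""
    if gene.end < lnc.start:  # type: ignore[operator]
        return "upstream"
    if gene.start > lnc.end:  # type: ignore[operator]
        return "downstream"
    return "overlapping"


def cis_pairs(
    annotation: Sequence[MoleculeRecord],
    lncrna_ids: Iterable[str] | None = None,
    gene_ids: Iterable[str] | None = None,
    window: int = DEFAULT_CIS_WINDOW,
) -> pd.DataFrame:
    """All (lncRNA, coding gene) pairs with genomic gap <= window, inclusive.

    By default lncRNAs and genes are taken from the annotation by RNA class.
    Molecules lacking coordinates are skipped with a logged warning.
    """
    by_id = {r.id: r for r in annotation}
    if lncrna_ids is None:
        lncrna_ids = [r.id for r in annotation if r.rna_class == "lncRNA"]
    if gene_ids is None:
        gene_ids = [r.id for r in annotation if r.rna_class == "mRNA"]

    def usable(ids: Iterable[str]) -> list[MoleculeRecord]:
        out = []
        for i in ids:
            r = by_id.get(i)
            if r is None or not r.has_coordinates:
                logger.warning("skipping %r: no coordinates in annotation", i)
                continue
            out.append(r)
        return out

    lncs = usable(lncrna_ids)
    genes = usable(gene_ids)
    genes_by_chrom: dict[str, list[MoleculeRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)  # type: ignore[arg-type]

    rows = []
    for lnc in lncs:
        for gene in genes_by_chrom.get(lnc.chrom, []):  # type: ignore[arg-type]
            gap = genomic_gap(lnc, gene)
            if gap <= window:
                rows.append(
                    {
                        "lncrna": lnc.id,
                        "gene": gene.id,
                        "chrom": lnc.chrom,
                        "gap": gap,
                        "relative_position": _relative_position(lnc, gene),
                    }
                )
    df = pd.DataFrame(rows, columns=CIS_COLUMNS)
    return df.sort_values(["lncrna", "gene"], ignore_index=True)


def restrict_cis_to_de(pairs: pd.DataFrame, contrast: ContrastTable) -> pd.DataFrame:
    """Keep cis pairs whose lncRNA and gene are both DE in the contrast."""
    de = contrast.de_ids()
    keep = pairs["lncrna"].isin(de) & pairs["gene"].isin(de)
    return pairs[keep].reset_index(drop=True)
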