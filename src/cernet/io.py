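"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: count TSV (molecules x samples, optional ``library_size`` row),
annotation TSV (id / class / chrom / start / end / strand, 1-based inclusive),
FASTA (via Biopython), and GMT gene-set files. All readers reject duplicate
primary ids; all writers round-trip losslessly on valid inputs.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CountMatrix,
    DesignTable,
    FormatError,
    GeneSet,
    GeneSetCollection,
    MoleculeRecord,
)

LIBRARY_SIZE_ROW = "library_size"
_MISSING = {"", "."}

RNA_LETTERS = set("ACGU")
DNA_LETTERS = set("ACGT")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | os.PathLike, rna_class: str) -> CountMatrix:
    """Read a count TSV: first column molecule id, remaining columns samples.

    A row whose id is ``library_size`` supplies per-sample library sizes;
    absent that row, library sizes default to column sums.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate molecule id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric count {df.iat[i, j]!r} at molecule "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    frac = numeric != np.floor(numeric)
    if frac.any().any():
        i, j = np.argwhere(frac.to_numpy())[0]
        raise FormatError(
            f"{path}: non-integer count {df.iat[i, j]!r} at molecule "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    neg = numeric < 0
    if neg.any().any():
        i, j = np.argwhere(neg.to_numpy())[0]
        raise FormatError(
            f"{path}: negative count {df.iat[i, j]!r} at molecule "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    numeric = numeric.astype(np.int64)
    library_size = None
    if LIBRARY_SIZE_ROW in numeric.index:
        library_size = numeric.loc[LIBRARY_SIZE_ROW]
        numeric = numeric.drop(index=LIBRARY_SIZE_ROW)
    return CountMatrix.from_counts(rna_class, numeric, library_size)


def write_counts(cm: CountMatrix, path: str | os.PathLike, include_library_size: bool = True) -> None:
    df = cm.counts.copy()
    if include_library_size:
        df.loc[LIBRARY_SIZE_ROW] = cm.library_size
    df.index.name = "id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def read_design(path: str | os.PathLike) -> DesignTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise FormatError(f"{path}: expected columns 'sample' and 'group'")
    return DesignTable(pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy()))


def write_design(design: DesignTable, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample": design.groups.index, "group": design.groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["id", "class", "chrom", "start", "end", "strand"]


def read_annotation(path: str | os.PathLike) -> list[MoleculeRecord]:
    """Read the 6-column annotation TSV ('.' marks an absent field)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    if list(df.columns) != _ANN_COLUMNS:
        raise FormatError(f"{path}: expected columns {_ANN_COLUMNS}, got {list(df.columns)}")
    df.columns = ["id", "rna_class", "chrom", "start", "end", "strand"]
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    for row in df.itertuples(index=False):
        if row.id in seen:
            raise FormatError(f"{path}: duplicate molecule id {row.id!r}")
        seen.add(row.id)
        chrom = None if row.chrom in _MISSING else row.chrom
        start = None if row.start in _MISSING else int(row.start)
        end = None if row.end in _MISSING else int(row.end)
        strand = None if row.strand in _MISSING else row.strand
        records.append(MoleculeRecord(row.id, row.rna_class, chrom, start, end, strand))
    return records


def write_annotation(records: Sequence[MoleculeRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "class": r.rna_class,
                "chrom": r.chrom if r.chrom is not None else ".",
                "start": r.start if r.start is not None else ".",
                "end": r.end if r.end is not None else ".",
                "strand": r.strand if r.strand is not None else ".",
            }
        )
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def annotation_index(records: Iterable[MoleculeRecord]) -> dict[str, MoleculeRecord]:
    out: dict[str, MoleculeRecord] = {}
    for r in records:
        if r.id in out:
            raise FormatError(f"duplicate molecule id {r.id!r}")
        out[r.id] = r
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: str | None = None) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping.

    ``alphabet='rna'`` normalizes T->U (miRNAs); ``alphabet='dna'`` normalizes
    U->T (target transcripts); ``None`` keeps letters as read (uppercased).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        if alphabet == "rna":
            seq = seq.replace("T", "U")
            letters = RNA_LETTERS
        elif alphabet == "dna":
            seq = seq.replace("U", "T")
            letters = DNA_LETTERS
        elif alphabet is None:
            letters = RNA_LETTERS | DNA_LETTERS
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        bad = set(seq) - letters
        if bad:
            raise FormatError(f"{path}: invalid letter(s) {sorted(bad)} in sequence {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line as name <TAB> description <TAB> members..."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and >=1 member"
                )
            sid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {sid!r} is empty")
            if sid in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate gene set id {sid!r}")
            try:
                sets[sid] = GeneSet(sid, desc, tuple(members))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return GeneSetCollection(sets, tuple(universe) if universe is not None else None)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets.values():
            fh.write("\t".join([gs.id, gs.name, *gs.members]) + "\n")
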