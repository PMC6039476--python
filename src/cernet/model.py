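"""Core domain types shared by every pipeline stage.

The pipeline studies three RNA classes (miRNA, lncRNA, mRNA) measured as
read counts in three sample groups (normal control tissue, primary tumor,
pulmonary metastasis). Types here carry the validated in-memory form of the
external inputs: per-class count matrices, the sample->group design, genomic
annotation records, and gene-set collections for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RNA_CLASSES = ("miRNA", "lncRNA", "mRNA")
GROUPS = ("control", "primary", "metastatic")

#: The two comparisons the pipeline runs: tumorigenesis and metastasis.
CONTRAST_A = "primary_vs_control"
CONTRAST_B = "metastatic_vs_primary"
CONTRASTS = {
    CONTRAST_A: ("primary", "control"),
    CONTRAST_B: ("metastatic", "primary"),
}


class FormatError(ValueError):
    """An external input violated the expected format or an invariant."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One annotated molecule: identifier, RNA class, optional genomic locus.

    Coordinates are 1-based and inclusive (GTF convention). Identifiers are
    treated as opaque strings; gene symbols and Ensembl-style ids are never
    resolved against each other.
    """

    id: str
    rna_class: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("molecule id must be non-empty")
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(
                f"unknown RNA class {self.rna_class!r} for molecule {self.id!r}; "
                f"expected one of {RNA_CLASSES}"
            )
        coords = (self.chrom is not None, self.start is not None, self.end is not None)
        if any(coords) and not all(coords):
            raise FormatError(f"molecule {self.id!r}: chrom/start/end must be given together")
        if self.start is not None:
            if self.start < 1:
                raise FormatError(f"molecule {self.id!r}: start must be >= 1 (1-based)")
            if self.start > self.end:  # type: ignore[operator]
                raise FormatError(f"molecule {self.id!r}: start {self.start} > end {self.end}")
        if self.strand not in (None, "+", "-"):
            raise FormatError(f"molecule {self.id!r}: strand must be '+' or '-'")

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None

    @property
    def span(self) -> int:
        """Locus length in bp (1-based inclusive, so end - start + 1)."""
        if not self.has_coordinates:
            raise ValueError(f"molecule {self.id!r} has no coordinates")
        return self.end - self.start + 1  # type: ignore[operator]


@dataclass
class CountMatrix:
    """Integer read counts for one RNA class: molecules (rows) x samples (cols).

    ``library_size`` may exceed the per-sample column sum (a library can
    contain reads not assigned to any catalogued molecule) but never be
    smaller.
    """

    rna_class: str
    counts: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(f"unknown RNA class {self.rna_class!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate molecule id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at molecule {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.library_size.isna().any():
            missing = self.library_size.index[self.library_size.isna()][0]
            raise FormatError(f"missing library size for sample {missing!r}")
        colsums = self.counts.sum(axis=0)
        too_small = self.library_size < colsums
        if too_small.any():
            s = too_small.index[too_small][0]
            raise FormatError(
                f"library size for sample {s!r} ({self.library_size[s]}) is smaller "
                f"than its column sum ({colsums[s]})"
            )
        if (self.library_size <= 0).any():
            s = self.library_size.index[self.library_size <= 0][0]
            raise FormatError(f"library size for sample {s!r} must be positive")

    @classmethod
    def from_counts(
        cls,
        rna_class: str,
        counts: pd.DataFrame,
        library_size: pd.Series | None = None,
    ) -> "CountMatrix":
        """Build a matrix; library sizes default to per-sample column sums."""
        counts = counts.astype(np.int64, copy=True)
        if library_size is None:
            library_size = counts.sum(axis=0)
        return cls(rna_class, counts, pd.Series(library_size, dtype=np.int64))

    @property
    def molecules(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DesignTable:
    """Sample -> group assignment for the three study groups."""

    groups: pd.Series  # index: sample id, values: group label

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups, dtype=str)
        if self.groups.index.duplicated().any():
            dup = self.groups.index[self.groups.index.duplicated()][0]
            raise FormatError(f"sample {dup!r} assigned more than once")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group label(s) {sorted(bad)}; expected {GROUPS}")

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    def validate_against(self, counts: CountMatrix) -> None:
        """Every count-matrix column must appear exactly once in the design."""
        missing = set(counts.samples) - set(self.groups.index)
        if missing:
            raise FormatError(f"samples missing from design: {sorted(missing)}")


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.id!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.id!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """A named collection of gene sets with an optional explicit universe."""

    sets: dict[str, GeneSet]
    universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if sid != gs.id:
                raise FormatError(f"gene set key {sid!r} != id {gs.id!r}")

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Sequence[str]],
        names: Mapping[str, str] | None = None,
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        sets = {
            sid: GeneSet(sid, (names or {}).get(sid, sid), tuple(members))
            for sid, members in mapping.items()
        }
        return cls(sets, tuple(universe) if universe is not None else None)

    def effective_universe(self) -> set[str]:
        """Explicit universe when given, otherwise the union of all members."""
        if self.universe is not None:
            return set(self.universe)
        out: set[str] = set()
        for gs in self.sets.values():
            out.update(gs.members)
        return out
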