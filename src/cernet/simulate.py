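"""Synthetic three-group, three-class RNA-seq datasets with planted truth.

The generator emulates the study design the pipeline targets: three sample
groups (control, primary tumor, pulmonary metastasis) with a small number of
replicates each, and read counts for miRNAs, lncRNAs and mRNAs. Counts are
negative-binomial (gamma-Poisson) around a per-molecule baseline mean, with
multiplicative planted group effects of +/- ``planted_lfc`` log2 units:

    mean(m, s) = mu_m * 2**(effect(m, group(s))) * L_s

where ``effect`` is 0 for the control group, the contrast-A effect for the
primary group, and the cumulative A+B effect for the metastatic group, so a
molecule planted DE in both contrasts with opposite signs ("reversed")
returns to baseline in the metastasis group.

Planted structure, all recorded in a :class:`TruthSet`:

* DE molecules per contrast and class, with signs; a configurable fraction
  of contrast-A DE molecules is also planted DE in contrast B with the
  opposite sign (reversed molecules).
* ceRNA triplets (lncRNA, miRNA, mRNA): the miRNA's two targets each carry
  exactly one planted seed site of the configured type; all other
  (decoy) transcripts are rejection-sampled to contain no occurrence of any
  simulated miRNA's 6-nt seed core, so target prediction on the synthetic
  data has exactly computable recall and precision.
* "Key" triplets are built entirely from reversed molecules, so their pairs
  survive the cross-contrast dynamics stage; ordinary triplets use
  contrast-A-only DE molecules.
* cis pairs: a fraction of lncRNAs is placed on the same chromosome as a
  partner gene with a gap uniform on [0, cis_window]; every other molecule
  sits in its own 1-Mb slot, far outside any window.
* gene sets: one set per contrast holding that contrast's planted DE mRNAs,
  plus random decoy sets, over the all-mRNA universe.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as cio
from .model import (
    CONTRAST_A,
    CONTRAST_B,
    CountMatrix,
    DesignTable,
    GeneSetCollection,
    MoleculeRecord,
    RNA_CLASSES,
)
from .targets import SITE_TYPES, site_pattern

_GROUP_PREFIX = {"control": "N", "primary": "P", "metastatic": "M"}
_SLOT_SPACING = 1_000_000  # bp between independent loci; >> cis window


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a desk-scale version of the target design: 3 replicates
    per group, overdispersed counts (dispersion 0.1, biological replicates
    from different donors), planted |log2FC| of 4 (comfortably above the
    DE threshold of 2), a quarter of miRNAs and 15% of the transcript
    classes DE per contrast, half of the contrast-A effects reversing in
    contrast B, and eight planted triplets of which three are key triplets —
    mirroring the three shared miRNAs the dual-contrast design is built to
    expose.
    """

    n_mirna: int = 24
    n_lncrna: int = 120
    n_mrna: int = 360
    n_per_group: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    de_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"miRNA": 0.25, "lncRNA": 0.15, "mRNA": 0.15}
    )
    planted_lfc: float = 4.0
    reversal_fraction: float = 0.5
    n_planted_triplets: int = 8
    n_key_triplets: int = 3
    site_type: str = "8mer"
    cis_fraction: float = 0.2
    cis_window: int = 100_000
    mirna_length: int = 22
    target_length: int = 200
    library_scale_low: float = 0.7
    library_scale_high: float = 1.3
    #: library size = depth_factor x (baseline expected class total) per
    #: sample: the catalogued molecules are a subset of the library, and
    #: sequencing depth does not depend on which molecules are perturbed
    depth_factor: float = 5.0
    n_decoy_gene_sets: int = 18
    decoy_gene_set_size: int = 30
    rng_seed: int = 0

    def de_fraction_of(self, rna_class: str) -> float:
        if isinstance(self.de_fraction, Mapping):
            return float(self.de_fraction.get(rna_class, 0.0))
        return float(self.de_fraction)

    def validate(self) -> None:
        for cls in RNA_CLASSES:
            f = self.de_fraction_of(cls)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"DE fraction for {cls} must be in [0, 1], got {f}")
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise ValueError("reversal_fraction must be in [0, 1]")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.n_key_triplets > self.n_planted_triplets:
            raise ValueError("n_key_triplets cannot exceed n_planted_triplets")
        if self.mirna_length < 8:
            raise ValueError("miRNAs must be at least 8 nt for a seed")
        if self.target_length < 10:
            raise ValueError("target transcripts must be at least 10 nt")
        if self.n_planted_triplets > 0 and self.n_mirna == 0:
            raise ValueError("cannot plant triplets without miRNAs")
        if self.n_planted_triplets > min(self.n_lncrna, self.n_mrna):
            raise ValueError(
                f"{self.n_planted_triplets} triplets need {self.n_planted_triplets} "
                f"distinct lncRNAs and mRNAs, only "
                f"{min(self.n_lncrna, self.n_mrna)} available"
            )


@dataclass
class TruthSet:
    """Planted ground truth of one simulated dataset."""

    #: contrast -> rna_class -> molecule id -> effect sign (+1 / -1)
    de: dict[str, dict[str, dict[str, int]]]
    #: planted (mirna, target, target_class)
    target_pairs: list[tuple[str, str, str]]
    #: planted (lncrna, gene, gap)
    cis_pairs: list[tuple[str, str, int]]
    #: planted (lncrna, mirna, mrna)
    triplets: list[tuple[str, str, str]]
    #: rna_class -> ids planted DE in both contrasts with opposite signs
    reversed_molecules: dict[str, list[str]]
    #: planted (mirna, target, target_class) surviving the dynamics filter
    key_pairs: list[tuple[str, str, str]]

    @classmethod
    def empty(cls) -> "TruthSet":
        return cls(
            de={c: {k: {} for k in RNA_CLASSES} for c in (CONTRAST_A, CONTRAST_B)},
            target_pairs=[],
            cis_pairs=[],
            triplets=[],
            reversed_molecules={k: [] for k in RNA_CLASSES},
            key_pairs=[],
        )

    def de_ids(self, contrast: str) -> set[str]:
        return {m for cls in RNA_CLASSES for m in self.de[contrast][cls]}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de=d["de"],
            target_pairs=[tuple(t) for t in d["target_pairs"]],
            cis_pairs=[tuple(t) for t in d["cis_pairs"]],
            triplets=[tuple(t) for t in d["triplets"]],
            reversed_molecules=d["reversed_molecules"],
            key_pairs=[tuple(t) for t in d["key_pairs"]],
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    counts: dict[str, CountMatrix]
    design: DesignTable
    mirna_seqs: dict[str, str]
    target_seqs: dict[str, str]
    annotation: list[MoleculeRecord]
    gene_sets: GeneSetCollection
    truth: TruthSet

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write all inputs as plain-text files; returns name -> path."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}
        for cls in RNA_CLASSES:
            p = os.path.join(outdir, f"counts_{cls}.tsv")
            cio.write_counts(self.counts[cls], p)
            paths[f"counts_{cls}"] = p
        paths["design"] = os.path.join(outdir, "design.tsv")
        cio.write_design(self.design, paths["design"])
        paths["mirna_fasta"] = os.path.join(outdir, "mirna.fa")
        cio.write_fasta(self.mirna_seqs, paths["mirna_fasta"])
        paths["target_fasta"] = os.path.join(outdir, "targets.fa")
        cio.write_fasta(self.target_seqs, paths["target_fasta"])
        paths["annotation"] = os.path.join(outdir, "annotation.tsv")
        cio.write_annotation(self.annotation, paths["annotation"])
        paths["gene_sets"] = os.path.join(outdir, "gene_sets.gmt")
        cio.write_gmt(self.gene_sets, paths["gene_sets"])
        paths["truth"] = os.path.join(outdir, "truth.json")
        self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def sample_counts(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts via gamma-Poisson mixing (Poisson when
    dispersion is 0). ``means`` is molecules x samples."""
    means = np.asarray(means, dtype=float)
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    else:
        lam = means
    return rng.poisson(lam).astype(np.int64)


def simulate_null_counts(
    n_molecules: int,
    n_per_group: int = 3,
    baseline_mean: float = 100.0,
    dispersion: float = 0.0,
    rng: np.random.Generator | int | None = None,
    rna_class: str = "mRNA",
) -> tuple[CountMatrix, DesignTable]:
    """A no-effect two-group dataset (control vs primary) for calibration
    studies of the DE statistic."""
    rng = np.random.default_rng(rng)
    mu = baseline_mean * rng.uniform(0.5, 1.5, size=n_molecules)
    scale = rng.uniform(0.7, 1.3, size=2 * n_per_group)
    means = mu[:, None] * scale[None, :]
    counts = sample_counts(means, dispersion, rng)
    samples = [f"N{i+1}" for i in range(n_per_group)] + [
        f"P{i+1}" for i in range(n_per_group)
    ]
    ids = [f"NULL{i:05d}" for i in range(n_molecules)]
    depth = np.ceil(5.0 * mu.sum() * scale).astype(np.int64)
    lib = np.maximum(counts.sum(axis=0), depth)
    cm = CountMatrix.from_counts(
        rna_class,
        pd.DataFrame(counts, index=ids, columns=samples),
        pd.Series(lib, index=samples),
    )
    design = DesignTable(
        pd.Series(
            ["control"] * n_per_group + ["primary"] * n_per_group, index=samples
        )
    )
    return cm, design


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> str:
    return "".join(alphabet[rng.integers(0, 4, size=length)])


def _simulate_mirnas(
    rng: np.random.Generator, ids: list[str], length: int
) -> dict[str, str]:
    """Random miRNA sequences with pairwise-compatible 6-nt seed cores.

    Besides distinctness, no core may coincide with the two fixed windows of
    another miRNA's planted site pattern (m8-complement + core[:5] and
    core[1:] + A); otherwise planting a site for one miRNA would
    systematically create a site for another, and decoy rejection sampling
    could never terminate.
    """
    from .targets import _core_and_m8, seed_of  # local: avoid polluting module API

    seqs: dict[str, str] = {}
    drawn: list[tuple[str, str]] = []  # (core, m8 complement)

    def fixed_windows(core: str, m8c: str) -> set[str]:
        return {m8c + core[:5], core[1:] + "A"}

    for mid in ids:
        for _ in range(1000):
            s = _random_seq(rng, length, _RNA)
            core, m8c = _core_and_m8(seed_of(s))
            conflict = any(
                core == ec
                or core in fixed_windows(ec, em8c)
                or ec in fixed_windows(core, m8c)
                for ec, em8c in drawn
            )
            if not conflict:
                drawn.append((core, m8c))
                seqs[mid] = s
                break
        else:  # pragma: no cover - 4^6 >> plausible n_mirna
            raise RuntimeError("could not draw a compatible miRNA seed core")
    return seqs


def _site_free_seq(
    rng: np.random.Generator, length: int, cores: list[str], max_tries: int = 10_000
) -> str:
    """Rejection-sample a DNA sequence containing no miRNA seed core."""
    for _ in range(max_tries):
        s = _random_seq(rng, length, _DNA)
        if not any(c in s for c in cores):
            return s
    raise RuntimeError(
        "rejection sampling failed; shorten targets or reduce the miRNA count"
    )


def _planted_target_seq(
    rng: np.random.Generator,
    mirna_seq: str,
    site_type: str,
    length: int,
    all_cores: list[str],
    own_core: str,
    max_tries: int = 1000,
) -> str:
    """A transcript carrying exactly one site of ``site_type`` for one miRNA
    and no other canonical site for any simulated miRNA.

    The planted pattern is padded with explicit flanking bases so the
    realized site type is exactly the configured one (e.g. a 7mer-m8 is
    followed by a non-A base, a 7mer-A1 preceded by a base that does not
    complete the m8 match).
    """
    pat = site_pattern(mirna_seq, site_type)
    from .targets import _core_and_m8, seed_of

    m8c = _core_and_m8(seed_of(mirna_seq))[1]
    non_a = "CGT"
    not_m8c = [b for b in "ACGT" if b != m8c]
    if site_type == "7mer-m8":
        pat = pat + non_a[rng.integers(0, len(non_a))]
    elif site_type == "7mer-A1":
        pat = not_m8c[rng.integers(0, len(not_m8c))] + pat
    elif site_type == "6mer":
        pat = (
            not_m8c[rng.integers(0, len(not_m8c))]
            + pat
            + non_a[rng.integers(0, len(non_a))]
        )
    for _ in range(max_tries):
        background = _site_free_seq(rng, length, all_cores)
        pos = int(rng.integers(0, length - len(pat) + 1))
        seq = background[:pos] + pat + background[pos + len(pat) :]
        if seq.count(own_core) != 1:
            continue
        if any(c in seq for c in all_cores if c != own_core):
            continue
        return seq
    raise RuntimeError("could not plant a clean seed site")  # pragma: no cover


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _round(x: float) -> int:
    return int(round(x))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset plus its planted :class:`TruthSet`."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    ids = {
        "miRNA": [f"sim-miR-{i:03d}" for i in range(1, config.n_mirna + 1)],
        "lncRNA": [f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)],
        "mRNA": [f"GENE{i:04d}" for i in range(1, config.n_mrna + 1)],
    }

    truth = TruthSet.empty()

    # --- plant DE molecules per class -------------------------------------
    pools: dict[str, dict[str, list[str]]] = {}
    for cls in RNA_CLASSES:
        perm = list(rng.permutation(ids[cls]))
        n_a = _round(config.de_fraction_of(cls) * len(perm))
        n_rev = _round(config.reversal_fraction * n_a)
        n_b = _round(config.de_fraction_of(cls) * len(perm))
        n_b_only = max(n_b - n_rev, 0)
        rev = perm[:n_rev]
        a_only = perm[n_rev:n_a]
        b_only = perm[n_a : n_a + n_b_only]
        non_de = perm[n_a + n_b_only :]
        pools[cls] = {
            "reversed": rev,
            "a_only": a_only,
            "b_only": b_only,
            "non_de": non_de,
        }
        truth.reversed_molecules[cls] = sorted(rev)
        for m in rev:
            s = int(rng.choice([-1, 1]))
            truth.de[CONTRAST_A][cls][m] = s
            truth.de[CONTRAST_B][cls][m] = -s
        for m in a_only:
            truth.de[CONTRAST_A][cls][m] = int(rng.choice([-1, 1]))
        for m in b_only:
            truth.de[CONTRAST_B][cls][m] = int(rng.choice([-1, 1]))

    # --- plant triplets ----------------------------------------------------
    n_key = min(
        config.n_key_triplets,
        len(pools["lncRNA"]["reversed"]),
        len(pools["mRNA"]["reversed"]),
        config.n_planted_triplets if pools["miRNA"]["reversed"] else 0,
    )
    n_plain = config.n_planted_triplets - n_key
    plain_mirna_pool = pools["miRNA"]["a_only"] or pools["miRNA"]["non_de"]
    plain_lnc_pool = pools["lncRNA"]["a_only"] + pools["lncRNA"]["non_de"]
    plain_mrna_pool = pools["mRNA"]["a_only"] + pools["mRNA"]["non_de"]
    if n_plain > 0 and (
        not plain_mirna_pool
        or len(plain_lnc_pool) < n_plain
        or len(plain_mrna_pool) < n_plain
    ):
        raise ValueError(
            f"cannot plant {config.n_planted_triplets} triplets: not enough "
            "molecules outside the reversed pools"
        )

    triplets: list[tuple[str, str, str]] = []
    key_triplets: list[tuple[str, str, str]] = []
    for i in range(n_key):
        m = pools["miRNA"]["reversed"][i % len(pools["miRNA"]["reversed"])]
        t = (pools["lncRNA"]["reversed"][i], m, pools["mRNA"]["reversed"][i])
        triplets.append(t)
        key_triplets.append(t)
    for i in range(n_plain):
        m = plain_mirna_pool[i % len(plain_mirna_pool)]
        triplets.append((plain_lnc_pool[i], m, plain_mrna_pool[i]))

    truth.triplets = sorted(triplets)
    pair_set: set[tuple[str, str, str]] = set()
    for lnc, m, gene in triplets:
        pair_set.add((m, lnc, "lncRNA"))
        pair_set.add((m, gene, "mRNA"))
    truth.target_pairs = sorted(pair_set)
    key_pairs: set[tuple[str, str, str]] = set()
    for lnc, m, gene in key_triplets:
        key_pairs.add((m, lnc, "lncRNA"))
        key_pairs.add((m, gene, "mRNA"))
    truth.key_pairs = sorted(key_pairs)

    # --- design and counts -------------------------------------------------
    samples: list[str] = []
    groups: list[str] = []
    for group in ("control", "primary", "metastatic"):
        for i in range(config.n_per_group):
            samples.append(f"{_GROUP_PREFIX[group]}{i + 1}")
            groups.append(group)
    design = DesignTable(pd.Series(groups, index=samples))

    counts: dict[str, CountMatrix] = {}
    for cls in RNA_CLASSES:
        mols = ids[cls]
        mu = config.baseline_mean * rng.uniform(0.5, 1.5, size=len(mols))
        lib_scale = rng.uniform(
            config.library_scale_low, config.library_scale_high, size=len(samples)
        )
        effect = np.zeros((len(mols), 3))  # columns: control, primary, metastatic
        for j, m in enumerate(mols):
            sa = truth.de[CONTRAST_A][cls].get(m, 0)
            sb = truth.de[CONTRAST_B][cls].get(m, 0)
            effect[j, 1] = sa * config.planted_lfc
            effect[j, 2] = effect[j, 1] + sb * config.planted_lfc
        group_idx = np.array(
            [("control", "primary", "metastatic").index(g) for g in groups]
        )
        means = (
            mu[:, None] * np.power(2.0, effect[:, group_idx]) * lib_scale[None, :]
        )
        arr = sample_counts(means, config.dispersion, rng)
        # library size = modeled per-sample sequencing depth, independent of
        # the planted effects; supplying it keeps pooled proportions free of
        # compositional distortion when planted signal dominates a small class
        depth = np.ceil(config.depth_factor * mu.sum() * lib_scale).astype(np.int64)
        lib = np.maximum(arr.sum(axis=0), depth)
        counts[cls] = CountMatrix.from_counts(
            cls,
            pd.DataFrame(arr, index=mols, columns=samples),
            pd.Series(lib, index=samples),
        )

    # --- sequences ----------------------------------------------------------
    from .targets import _core_and_m8, seed_of

    mirna_seqs = _simulate_mirnas(rng, ids["miRNA"], config.mirna_length)
    core_of = {m: _core_and_m8(seed_of(s))[0] for m, s in mirna_seqs.items()}
    all_cores = sorted(core_of.values())
    planted_mirna_of: dict[str, str] = {}
    for m, t, _cls in truth.target_pairs:
        planted_mirna_of[t] = m
    target_seqs: dict[str, str] = {}
    for cls in ("lncRNA", "mRNA"):
        for t in ids[cls]:
            if t in planted_mirna_of:
                m = planted_mirna_of[t]
                target_seqs[t] = _planted_target_seq(
                    rng,
                    mirna_seqs[m],
                    config.site_type,
                    config.target_length,
                    all_cores,
                    core_of[m],
                )
            else:
                target_seqs[t] = _site_free_seq(rng, config.target_length, all_cores)

    # --- annotation and cis pairs -------------------------------------------
    n_cis = _round(config.cis_fraction * config.n_lncrna)
    cis_lncs = list(rng.choice(ids["lncRNA"], size=n_cis, replace=False)) if n_cis else []
    cis_genes = list(rng.choice(ids["mRNA"], size=n_cis, replace=False)) if n_cis else []
    cis_partner = dict(zip(cis_lncs, cis_genes))

    chroms = [f"chr{i}" for i in range(1, 6)]
    slot_counter = {c: 0 for c in chroms}
    annotation: list[MoleculeRecord] = []
    placed: dict[str, MoleculeRecord] = {}

    def place(mol: str, cls: str, length: int) -> None:
        k = len(placed) % len(chroms)
        chrom = chroms[k]
        start = 1 + slot_counter[chrom] * _SLOT_SPACING
        slot_counter[chrom] += 1
        rec = MoleculeRecord(
            mol, cls, chrom, start, start + length - 1, "+" if rng.random() < 0.5 else "-"
        )
        placed[mol] = rec
        annotation.append(rec)

    for m in ids["miRNA"]:
        place(m, "miRNA", 80)
    for g in ids["mRNA"]:
        place(g, "mRNA", int(rng.integers(1000, 5001)))
    cis_records: list[tuple[str, str, int]] = []
    for lnc in ids["lncRNA"]:
        length = int(rng.integers(500, 2001))
        if lnc in cis_partner:
            gene_rec = placed[cis_partner[lnc]]
            gap = int(rng.integers(0, config.cis_window + 1))
            start = gene_rec.end + gap + 1  # type: ignore[operator]
            rec = MoleculeRecord(
                lnc,
                "lncRNA",
                gene_rec.chrom,
                start,
                start + length - 1,
                "+" if rng.random() < 0.5 else "-",
            )
            placed[lnc] = rec
            annotation.append(rec)
            cis_records.append((lnc, gene_rec.id, gap))
        else:
            place(lnc, "lncRNA", length)
    truth.cis_pairs = sorted(cis_records)

    # --- gene sets ------------------------------------------------------------
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    a_mrnas = sorted(truth.de[CONTRAST_A]["mRNA"])
    b_mrnas = sorted(truth.de[CONTRAST_B]["mRNA"])
    if a_mrnas:
        sets["PLANTED_A_MRNA"] = a_mrnas
        names["PLANTED_A_MRNA"] = "planted DE mRNAs, primary vs control"
    if b_mrnas:
        sets["PLANTED_B_MRNA"] = b_mrnas
        names["PLANTED_B_MRNA"] = "planted DE mRNAs, metastatic vs primary"
    set_size = min(config.decoy_gene_set_size, config.n_mrna)
    for i in range(config.n_decoy_gene_sets):
        sid = f"RANDOM_{i + 1:02d}"
        sets[sid] = sorted(rng.choice(ids["mRNA"], size=set_size, replace=False))
        names[sid] = "random gene set"
    gene_sets = GeneSetCollection.from_mapping(sets, names, universe=ids["mRNA"])

    return SimulatedDataset(
        config=config,
        counts=counts,
        design=design,
        mirna_seqs=mirna_seqs,
        target_seqs=target_seqs,
        annotation=annotation,
        gene_sets=gene_sets,
        truth=truth,
    )


def truth_report(truth: TruthSet) -> pd.Series:
    """Counts of planted entities per category."""
    out = {}
    for contrast in (CONTRAST_A, CONTRAST_B):
        for cls in RNA_CLASSES:
            out[f"de_{contrast}_{cls}"] = len(truth.de[contrast][cls])
    for cls in RNA_CLASSES:
        out[f"reversed_{cls}"] = len(truth.reversed_molecules[cls])
    out["target_pairs"] = len(truth.target_pairs)
    out["cis_pairs"] = len(truth.cis_pairs)
    out["triplets"] = len(truth.triplets)
    out["key_pairs"] = len(truth.key_pairs)
    return pd.Series(out, dtype=int)
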