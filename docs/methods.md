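# Methods

## Scope and design

`cernet` implements a dual-contrast ceRNA discovery analysis for a
three-group design (control, primary tumor, pulmonary metastasis; small
numbers of biological replicates per group) over three RNA classes. The two
comparisons are fixed: contrast A = primary vs control (tumorigenesis),
contrast B = metastatic vs primary (metastasis). All molecule identifiers
are opaque strings — gene symbols and Ensembl-style ids are never resolved
against each other. Genomic coordinates are 1-based and inclusive
throughout (GTF convention), since the annotation input is GTF-like.

## Differential expression

Replicates are pooled within groups (counts and library sizes summed)
before testing. With only three donors per group, per-gene dispersion
cannot be estimated stably, so the pipeline deliberately uses one fully
specified statistic for all three RNA classes: a two-proportion z-test on
pooled relative abundances with a two-sided normal p-value. The log2 fold
change is computed on pseudocounted proportions
(`log2((c1+0.5)/n1) − log2((c2+0.5)/n2)`); the pseudocount of 0.5 keeps
fold changes finite and enters the fold change only, never the test. When
both pooled counts are zero the statistic is defined as `z = 0`,
`p = 1`. A molecule is DE when `p < 0.01` **and** `|log2FC| > 2`, both
strict inequalities. Raw p-values drive the call, mirroring the stated
cut-off convention of this analysis family; BH-adjusted values are reported
as an additional column.

**Calibration.** The test is exact-level only under binomial sampling of
counts given library sizes. On Poisson (technical-replicate) null
simulations the empirical `p < 0.01` rate is ≈ 0.009, within the
[0.003, 0.03] band expected from the normal approximation at moderate
counts. Under the generator's default biological overdispersion
(negative-binomial, dispersion 0.1) the raw p-values are strongly
anticonservative (null rate ≈ 0.4 at baseline mean 100) — a real and
documented property of pooled proportion tests on overdispersed replicates.
The fold-change filter restores practical specificity: the joint DE-flag
rate on overdispersed null data is ≈ 0. The test suite asserts both facts;
the calibration acceptance check therefore simulates its null at
dispersion 0, where the only error source is the normal approximation.

## Target prediction

The seed is miRNA positions 2–8 (5'→3'). Sites on a target (DNA alphabet)
are occurrences of the reverse complement of the seed region, classified by
the canonical taxonomy: 8mer (rc of 2–8 followed by A), 7mer-m8 (rc of
2–8), 7mer-A1 (rc of 2–7 followed by A), 6mer (rc of 2–7 alone). Each
occurrence of the 6-nt core is one locus assigned its single most stringent
achievable type; overlapping cores are each counted. Reported site starts
are the 1-based first base of the full site pattern, so every site
re-extracts from the target — a self-verifying output checked by property
tests. Whole transcripts are scanned (lncRNAs carry no UTR annotation and
both target classes flow through one rule). No conservation, context score
or free-energy term is used: the matcher replaces external database lookups
with a closed, testable rule. Pair stringency defaults to "7mer-A1 or
better, ≥ 1 site" and is config-exposed.

## Cis annotation

The genomic gap between two same-chromosome loci is the number of bases
strictly between them (0 for overlap or adjacency):
`max(0, max(starts) − min(ends) − 1)`. A lncRNA–gene cis pair requires gap
≤ 100 kb, inclusive at exactly the window edge (the window bounds the
flanking interval). Distance is measured span-to-span, not TSS-to-TSS, and
strand is ignored for membership — divergent transcription makes both
orientations biologically relevant — entering only the descriptive
upstream/downstream/overlapping label.

## Networks, dynamics, enrichment

Per-contrast networks are typed tripartite graphs over DE molecules; edge
multiplicity is collapsed (site counts are edge attributes) so degree
counts distinct partners, and hub ties break lexicographically for
determinism. A ceRNA triplet (lncRNA, miRNA, mRNA) exists iff the miRNA has
edges to both transcripts; the classical sponge pattern (targets
co-directional, opposite to the miRNA) is computed as an annotation, never
a membership filter, because real networks of this kind contain both
directions. Key pairs require the predicted relation itself in both
contrasts' DE-restricted pair sets, not merely both endpoints shared;
reversal of members is reported but not required (a strict-reversal flag
exists, default off — reversal is an observed outcome, not a selection
criterion). Enrichment is the hypergeometric upper tail P(X ≥ x) (computed
via `scipy.stats.hypergeom.sf`) with BH adjustment; the universe defaults
to the union of set members unless given explicitly, and query ids outside
the universe are dropped with a warning, since DE lists routinely contain
unannotated non-coding transcripts.

## Synthetic data generator

The generator emulates the target study design, not its scale: desk-sized
classes (24 miRNAs, 120 lncRNAs, 360 mRNAs by default), 3 replicates per
group. Counts are gamma-Poisson (negative binomial) with dispersion 0.1 —
biological replicates from different donors are overdispersed — around
per-molecule baselines drawn uniformly in [0.5, 1.5] × `baseline_mean`
(default 100). Planted effects are multiplicative, ±`planted_lfc` (default
4) log2 units, applied cumulatively across groups so a molecule planted DE
in both contrasts with opposite signs returns to baseline in the
metastasis group. Effects are symmetric in sign (up and down both occur).
Default DE fractions are 0.25 (miRNA) and 0.15 (lncRNA, mRNA) per
contrast, with half of contrast-A effects reversing in contrast B.

**Library sizes are supplied, not inferred.** Each sample's library size is
a modeled sequencing depth — `depth_factor` (default 5) × the class's
baseline expected total × a per-sample scale drawn in [0.7, 1.3] — floor-ed
at the realized column sum. The catalogued molecules are a subset of a real
library, and depth does not depend on which molecules are perturbed;
deriving library sizes from column sums instead would compositionally
shrink every estimated fold change whenever planted signal dominates a
small class.

Eight triplets are planted by default, of which three "key" triplets are
built entirely from reversed molecules (emulating a small set of shared
miRNAs driving both transitions); planted targets carry exactly one seed
site of the configured type (default 8mer) with controlled flanks, all
other transcripts are rejection-sampled to contain no 6-nt seed core of any
simulated miRNA, and miRNA seed cores are drawn pairwise-compatible so one
miRNA's planted site can never embed another's core. This makes target
prediction recall and precision on the truth exactly computable. A fifth
of lncRNAs are placed with a gap uniform on [0, 100 kb] from a partner
gene; every other molecule sits in its own 1-Mb slot, so the planted cis
pairs are exactly the pairs the window query should return. Gene sets
comprise the planted DE mRNA sets per contrast plus 18 random decoy sets
over the all-mRNA universe. Everything is deterministic given `rng_seed`;
identical configs produce byte-identical output files.

**What passing tests do and do not show.** The generator has no batch
effects, no sample outliers, no isoforms, no read-level noise, no
correlation between expression and sequence, and decoys are perfectly
site-free — so perfect recall/precision on synthetic data demonstrates
correctness of the implemented rules, not performance on real libraries,
where seed matching alone has well-known false-positive rates and pooled
proportion tests are anticonservative (above).

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `p_threshold` / `lfc_threshold` | 0.01 / 2 | strict DE cut-offs |
| `cis_window` | 100 000 bp | inclusive cis window |
| `min_best_type` / `min_sites` | 7mer-A1 / 1 | pair stringency |
| `fdr` | 0.05 | BH threshold for enrichment |
| `planted_lfc` | 4 | planted |log2FC|, comfortably above the cut-off |
| `dispersion` | 0.1 | NB overdispersion of replicates |
| `baseline_mean` | 100 | expected null count per molecule |
| `depth_factor` | 5 | library size / catalogued expected total |

The acceptance script uses 20 null simulations of 2000 molecules for
calibration and one default-size planted dataset for the end-to-end run;
these sizes keep the full recomputation in the order of seconds while the
calibration estimate still averages 40 000 null tests.

## Known limitations

- The pooled z-test ignores replicate-level variability; with biological
  overdispersion its raw p-values are anticonservative and only the joint
  p + fold-change criterion is practically specific.
- Seed matching has no conservation/context model; stringency is the only
  specificity control.
- Co-expression filtering of miRNA–lncRNA pairs is not implemented (no
  computable definition available for it in this analysis family).
- Printed headline DE counts from the motivating study design (e.g.
  65/233/1405 molecules) are not reproducible without the raw libraries and
  are not a target of this package.
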