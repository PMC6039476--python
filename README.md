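# cernet

Dual-contrast **competing endogenous RNA (ceRNA) network discovery** from
miRNA / lncRNA / mRNA read counts.

The package is built for the study design used in osteosarcoma progression
profiling: three sample groups — normal control tissue, primary tumor, and
pulmonary metastasis — sequenced for three RNA classes, analysed through two
comparisons (primary vs control: *tumorigenesis*; metastatic vs primary:
*metastasis*). It answers the question that design exists for: **which
miRNA–target regulations are active in both transitions, and do they flip
direction between them?**

## The method

1. **Differential expression.** Replicates are pooled per group; each
   molecule is tested with a two-proportion z-test on pooled relative
   abundances. With `p1 = c1/n1`, `p2 = c2/n2`, pooled `p = (c1+c2)/(n1+n2)`:

   `z = (p1 − p2) / sqrt(p (1−p) (1/n1 + 1/n2))`,

   two-sided normal p-value, and `log2FC = log2((c1+0.5)/n1) − log2((c2+0.5)/n2)`.
   A molecule is DE when `p < 0.01` and `|log2FC| > 2` (strict).
2. **miRNA target prediction.** Canonical seed matching: the reverse
   complement of miRNA positions 2–8 scanned over whole target transcripts,
   with the standard site taxonomy (8mer > 7mer-m8 > 7mer-A1 > 6mer);
   default stringency 7mer-A1 or better.
3. **Cis annotation.** A lncRNA and a coding gene are a cis pair when
   their loci lie within ±100 kb on the same chromosome (gap inclusive at
   the boundary, strand-agnostic membership).
4. **ceRNA networks.** Per contrast, a typed tripartite graph over DE
   molecules: miRNA–mRNA and miRNA–lncRNA target edges plus lncRNA–gene cis
   edges; ceRNA triplets (lncRNA, miRNA, mRNA) are miRNAs with edges to both
   transcripts; hubs are ranked by degree.
5. **Dynamics.** Molecules DE in *both* contrasts are intersected (Venn
   stage) and direction-classified (*reversed* when the fold changes have
   opposite signs); **key pairs** are predicted relations present in both
   contrasts' DE-restricted pair sets whose two members are shared.
6. **Enrichment.** Hypergeometric over-representation of DE mRNAs against
   GMT gene sets with Benjamini–Hochberg FDR (< 0.05).

A synthetic-data generator (`cernet.simulate`) produces complete inputs —
negative-binomial counts with planted group effects, transcript sequences
with planted seed sites and site-free decoys, annotation with planted cis
neighborhoods, gene sets — together with the planted `TruthSet`, so the
whole pipeline is testable end to end without any external data.

## Worked example

```python
from cernet import SimulationConfig, simulate_dataset
from cernet.pipeline import PipelineInputs, run_pipeline, score_against_truth

ds = simulate_dataset(SimulationConfig(rng_seed=42))
result = run_pipeline(PipelineInputs(
    counts=ds.counts, design=ds.design,
    mirna_seqs=ds.mirna_seqs, target_seqs=ds.target_seqs,
    annotation=ds.annotation, gene_sets=ds.gene_sets,
))
print(result.key_pairs[["mirna", "target", "target_class"]].to_string(index=False))
print({k: round(v, 3) for k, v in score_against_truth(result, ds.truth).items()
       if k in ("de_recall_overall", "target_pair_recall", "key_pairs_exact")})
```

prints

```
      mirna   target target_class
sim-miR-016 GENE0193         mRNA
sim-miR-016  LNC0052       lncRNA
sim-miR-017 GENE0246         mRNA
sim-miR-017  LNC0004       lncRNA
sim-miR-019 GENE0196         mRNA
sim-miR-019  LNC0034       lncRNA
{'de_recall_overall': 1.0, 'target_pair_recall': 1.0, 'key_pairs_exact': 1.0}
```

— the six key pairs are exactly the planted ones (three reversed miRNAs,
each sponged by one lncRNA and regulating one mRNA), every planted DE
molecule was recovered, and every planted seed-site pair was predicted.

The same analysis runs from the shell:

```bash
cernet run-all --simulate-seed 42 --outdir runs/demo   # or --config run.yaml
```

which writes per-stage TSVs (DE tables, pair sets, networks as edge-TSV and
GraphML, shared molecules, key pairs, enrichment) plus `manifest.json`
recording the analysis funnel (counts in/out of every filter) and file
checksums.

The package also ships a small worked example of the dynamics stage: the
eight key miRNA–target relations reported for osteosarcoma (miR-223-5p →
CLSTN2 / AC009951.1 / LINC01705 / AC090673.1, miR-378b → ALX4 / IGSF3 /
SULF1, miR-323b-3p → TGFBR3) mixed with twelve decoy relations; see
`cernet.fixtures.load_key_pair_fixture`.

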