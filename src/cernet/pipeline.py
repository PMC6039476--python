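"""End-to-end orchestration: DE -> targets -> cis -> networks -> dynamics -> enrichment.

``run_pipeline`` executes the whole analysis in memory on validated inputs;
``run_all`` is the disk-facing wrapper that reads the input files named in a
:class:`PipelineConfig`, writes every stage output as TSV, and returns a run
manifest (config echo, per-stage row counts, file checksums). The manifest
makes the analysis funnel auditable: molecule counts in and out of every
filter are recorded per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import cis as cis_mod
from . import io as cio
from .diffexpr import (
    ContrastTable,
    concat_contrasts,
    run_contrast,
    write_contrast,
)
from .dynamics import dynamics_report, extract_key_pairs, shared_molecules
from .enrichment import enrich
from .model import (
    CONTRASTS,
    CountMatrix,
    DesignTable,
    GeneSetCollection,
    MoleculeRecord,
    RNA_CLASSES,
)
from .network import CeRNANetwork, build_network, hub_report, triplets, write_network
from .simulate import TruthSet
from .targets import predict_pairs, restrict_to_de

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunable thresholds with the pipeline's default cut-offs."""

    p_threshold: float = 0.01
    lfc_threshold: float = 2.0
    cis_window: int = 100_000
    min_best_type: str = "7mer-A1"
    min_sites: int = 1
    fdr: float = 0.05
    require_reversed: bool = False

    def validate(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.cis_window <= 0 or self.fdr <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineInputs:
    counts: dict[str, CountMatrix]
    design: DesignTable
    mirna_seqs: dict[str, str]
    target_seqs: dict[str, str]
    annotation: list[MoleculeRecord]
    gene_sets: GeneSetCollection


@dataclass
class PipelineResult:
    params: PipelineParams
    contrasts: dict[str, ContrastTable]  # combined across classes, per label
    contrasts_by_class: dict[tuple[str, str], ContrastTable]
    all_pairs: pd.DataFrame
    pairs_by_contrast: dict[str, pd.DataFrame]
    all_cis: pd.DataFrame
    cis_by_contrast: dict[str, pd.DataFrame]
    networks: dict[str, CeRNANetwork]
    hubs: dict[str, dict]
    triplets: dict[str, pd.DataFrame]
    shared: pd.DataFrame
    key_pairs: pd.DataFrame
    report: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    funnel: dict[str, int] = field(default_factory=dict)


def run_pipeline(inputs: PipelineInputs, params: PipelineParams | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs; deterministic for fixed inputs."""
    params = params or PipelineParams()
    params.validate()
    funnel: dict[str, int] = {}

    ann_classes = {r.id: r.rna_class for r in inputs.annotation}

    # 1. differential expression: two contrasts x three classes
    by_class: dict[tuple[str, str], ContrastTable] = {}
    combined: dict[str, ContrastTable] = {}
    for label, (g1, g2) in CONTRASTS.items():
        tables = []
        for cls in RNA_CLASSES:
            t = run_contrast(
                inputs.counts[cls],
                inputs.design,
                g1,
                g2,
                p_threshold=params.p_threshold,
                lfc_threshold=params.lfc_threshold,
                label=label,
            )
            by_class[(label, cls)] = t
            tables.append(t)
            funnel[f"de_{label}_{cls}"] = int(t.records["is_de"].sum())
        combined[label] = concat_contrasts(tables)

    # 2. seed-match target prediction over all sequences, then DE restriction
    target_classes = {
        t: ann_classes[t] for t in inputs.target_seqs if t in ann_classes
    }
    missing = set(inputs.target_seqs) - set(target_classes)
    if missing:
        raise ValueError(f"targets missing from annotation: {sorted(missing)[:5]}")
    all_pairs = predict_pairs(
        inputs.mirna_seqs,
        inputs.target_seqs,
        target_classes,
        min_best_type=params.min_best_type,
        min_sites=params.min_sites,
    )
    funnel["predicted_pairs"] = len(all_pairs)
    pairs_by_contrast = {
        label: restrict_to_de(all_pairs, combined[label]) for label in CONTRASTS
    }
    for label, p in pairs_by_contrast.items():
        funnel[f"de_pairs_{label}"] = len(p)

    # 3. cis annotation, then DE restriction
    all_cis = cis_mod.cis_pairs(inputs.annotation, window=params.cis_window)
    funnel["cis_pairs"] = len(all_cis)
    cis_by_contrast = {
        label: cis_mod.restrict_cis_to_de(all_cis, combined[label])
        for label in CONTRASTS
    }
    for label, c in cis_by_contrast.items():
        funnel[f"de_cis_{label}"] = len(c)

    # 4. per-contrast ceRNA networks
    networks = {
        label: build_network(combined[label], pairs_by_contrast[label], cis_by_contrast[label])
        for label in CONTRASTS
    }
    hubs = {label: hub_report(net) for label, net in networks.items()}
    trips = {label: triplets(net) for label, net in networks.items()}
    for label, net in networks.items():
        funnel[f"network_nodes_{label}"] = net.n_nodes
        funnel[f"network_edges_{label}"] = net.n_edges
        funnel[f"triplets_{label}"] = len(trips[label])

    # 5. cross-contrast dynamics
    label_a, label_b = list(CONTRASTS)
    shared = shared_molecules(combined[label_a], combined[label_b])
    key_pairs = extract_key_pairs(
        shared,
        pairs_by_contrast[label_a],
        pairs_by_contrast[label_b],
        require_reversed=params.require_reversed,
    )
    report = dynamics_report(shared, key_pairs)
    funnel["shared_molecules"] = len(shared)
    funnel["key_pairs"] = len(key_pairs)

    # 6. enrichment of each contrast's DE mRNAs
    enrich_results: dict[str, pd.DataFrame] = {}
    for label in CONTRASTS:
        rec = by_class[(label, "mRNA")].records
        query = sorted(rec.loc[rec["is_de"], "id"])
        enrich_results[label] = (
            enrich(query, inputs.gene_sets, fdr=params.fdr)
            if query
            else pd.DataFrame()
        )
        funnel[f"enriched_sets_{label}"] = (
            int(enrich_results[label]["enriched"].sum())
            if len(enrich_results[label])
            else 0
        )

    return PipelineResult(
        params=params,
        contrasts=combined,
        contrasts_by_class=by_class,
        all_pairs=all_pairs,
        pairs_by_contrast=pairs_by_contrast,
        all_cis=all_cis,
        cis_by_contrast=cis_by_contrast,
        networks=networks,
        hubs=hubs,
        triplets=trips,
        shared=shared,
        key_pairs=key_pairs,
        report=report,
        enrichment=enrich_results,
        funnel=funnel,
    )


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def score_against_truth(result: PipelineResult, truth: TruthSet) -> dict[str, float]:
    """Compare a pipeline run with the planted truth of a synthetic dataset.

    DE recall/false-positive rates are computed per contrast over all
    classes; pair metrics compare the DE-restricted predicted pairs with the
    planted pairs restricted to the same called-DE molecules, so a missed DE
    call does not doubly penalize prediction.
    """
    out: dict[str, float] = {}
    total_planted = total_recovered = 0
    for label in CONTRASTS:
        planted = truth.de_ids(label)
        called = result.contrasts[label].de_ids()
        universe = set(result.contrasts[label].records["id"])
        nulls = universe - planted
        recovered = planted & called
        out[f"de_recall_{label}"] = len(recovered) / len(planted) if planted else 1.0
        out[f"de_false_rate_{label}"] = (
            len(called - planted) / len(nulls) if nulls else 0.0
        )
        total_planted += len(planted)
        total_recovered += len(recovered)
    out["de_recall_overall"] = (
        total_recovered / total_planted if total_planted else 1.0
    )

    planted_pairs = {(m, t) for m, t, _c in truth.target_pairs}
    predicted_pairs = set(zip(result.all_pairs["mirna"], result.all_pairs["target"]))
    out["target_pair_recall"] = (
        len(planted_pairs & predicted_pairs) / len(planted_pairs)
        if planted_pairs
        else 1.0
    )
    out["target_pair_precision"] = (
        len(planted_pairs & predicted_pairs) / len(predicted_pairs)
        if predicted_pairs
        else 1.0
    )

    label_a = list(CONTRASTS)[0]
    called_a = result.contrasts[label_a].de_ids()
    planted_de_pairs = {
        (m, t) for m, t in planted_pairs if m in called_a and t in called_a
    }
    de_pred = set(
        zip(
            result.pairs_by_contrast[label_a]["mirna"],
            result.pairs_by_contrast[label_a]["target"],
        )
    )
    out["de_pair_recall"] = (
        len(planted_de_pairs & de_pred) / len(planted_de_pairs)
        if planted_de_pairs
        else 1.0
    )

    planted_cis = {(l, g) for l, g, _gap in truth.cis_pairs}
    found_cis = set(zip(result.all_cis["lncrna"], result.all_cis["gene"]))
    out["cis_recall"] = (
        len(planted_cis & found_cis) / len(planted_cis) if planted_cis else 1.0
    )
    out["cis_precision"] = (
        len(planted_cis & found_cis) / len(found_cis) if found_cis else 1.0
    )

    planted_key = {(m, t) for m, t, _c in truth.key_pairs}
    found_key = set(zip(result.key_pairs["mirna"], result.key_pairs["target"]))
    out["key_pairs_planted"] = float(len(planted_key))
    out["key_pairs_found"] = float(len(found_key))
    out["key_pairs_exact"] = float(planted_key == found_key)
    return out


# ---------------------------------------------------------------------------
# disk orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """File-level configuration for a full run."""

    counts_mirna: str
    counts_lncrna: str
    counts_mrna: str
    design: str
    mirna_fasta: str
    target_fasta: str
    annotation: str
    gene_sets: str
    outdir: str
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        param_fields = {f.name for f in dataclasses.fields(PipelineParams)}
        params = PipelineParams(**{k: v for k, v in raw.items() if k in param_fields})
        kwargs = {
            k: v for k, v in raw.items() if k not in param_fields and k != "params"
        }
        return cls(params=params, **kwargs)


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    counts = {
        "miRNA": cio.read_counts(config.counts_mirna, "miRNA"),
        "lncRNA": cio.read_counts(config.counts_lncrna, "lncRNA"),
        "mRNA": cio.read_counts(config.counts_mrna, "mRNA"),
    }
    return PipelineInputs(
        counts=counts,
        design=cio.read_design(config.design),
        mirna_seqs=cio.read_fasta(config.mirna_fasta, alphabet="rna"),
        target_seqs=cio.read_fasta(config.target_fasta, alphabet="dna"),
        annotation=cio.read_annotation(config.annotation),
        gene_sets=cio.read_gmt(config.gene_sets),
    )


def run_all(config: PipelineConfig) -> dict:
    """Read inputs, run the pipeline, write all stage outputs and a manifest."""
    stage = "load_inputs"
    try:
        inputs = load_inputs(config)
        stage = "pipeline"
        result = run_pipeline(inputs, config.params)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    os.makedirs(config.outdir, exist_ok=True)
    files: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(config.outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        files[name] = path

    for label, table in result.contrasts.items():
        save(f"de_{label}", table.records)
    for label, p in result.pairs_by_contrast.items():
        save(f"pairs_{label}", p)
    for label, c in result.cis_by_contrast.items():
        save(f"cis_{label}", c)
    for label, net in result.networks.items():
        path = os.path.join(config.outdir, f"network_{label}.tsv")
        write_network(net, path, fmt="tsv")
        files[f"network_{label}"] = path
        gpath = os.path.join(config.outdir, f"network_{label}.graphml")
        write_network(net, gpath, fmt="graphml")
        files[f"network_{label}_graphml"] = gpath
        hub_rows = [
            {"rna_class": cls, "id": nid, "degree": deg}
            for cls, ranked in result.hubs[label].items()
            for nid, deg in ranked
        ]
        save(
            f"hubs_{label}",
            pd.DataFrame(hub_rows, columns=["rna_class", "id", "degree"]),
        )
        save(f"triplets_{label}", result.triplets[label])
    save("shared_molecules", result.shared)
    save("key_pairs", result.key_pairs)
    save("key_pair_trends", result.report["trend"])
    for label, e in result.enrichment.items():
        save(f"enrichment_{label}", e)

    manifest = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "params"
            },
            "params": dataclasses.asdict(config.params),
        },
        "funnel": result.funnel,
        "row_counts": {
            name: sum(1 for _ in open(path)) - 1
            for name, path in files.items()
            if path.endswith(".tsv")
        },
        "checksums": {name: _md5(path) for name, path in files.items()},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    files["manifest"] = manifest_path
    return manifest
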