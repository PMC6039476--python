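"""Per-contrast ceRNA network assembly, hub ranking and triplet extraction.

The network is a typed tripartite graph over DE molecules of one contrast:
miRNA--mRNA and miRNA--lncRNA edges come from seed-match target pairs,
lncRNA--gene edges from the cis-window annotation. A ceRNA triplet
(lncRNA, miRNA, mRNA) exists exactly when the miRNA has edges to both the
lncRNA and the mRNA — the two transcripts compete for that miRNA. Edge
multiplicity is collapsed (one edge per pair; site counts live on edge
attributes), so degrees count distinct partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ContrastTable
from .model import RNA_CLASSES

EDGE_MIRNA_MRNA = "mirna_mrna"
EDGE_MIRNA_LNCRNA = "mirna_lncrna"
EDGE_LNCRNA_CIS_GENE = "lncrna_cis_gene"

TRIPLET_COLUMNS = ["lncrna", "mirna", "mrna", "direction_consistent"]


@dataclass
class CeRNANetwork:
    contrast: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, rna_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["rna_class"] == rna_class
        )


def build_network(
    contrast: ContrastTable,
    de_target_pairs: pd.DataFrame,
    de_cis_pairs: pd.DataFrame,
) -> CeRNANetwork:
    """Assemble the typed graph from DE-restricted target and cis pairs.

    Every pair endpoint must be DE in the contrast (the pipeline restricts
    pairs before this stage; a non-DE endpoint is a pipeline-order error).
    Isolated nodes never occur: nodes enter only through edges.
    """
    rec = contrast.records
    de = rec[rec["is_de"]]
    info = {
        r.id: {"rna_class": r.rna_class, "log2fc": r.log2fc} for r in de.itertuples()
    }

    g = nx.Graph()

    def add_node(mol: str, expected_class: str | None = None) -> None:
        if mol not in info:
            raise ValueError(
                f"molecule {mol!r} in a pair is not DE in contrast {contrast.label!r}; "
                "pairs must be DE-restricted before network assembly"
            )
        meta = info[mol]
        if expected_class is not None and meta["rna_class"] != expected_class:
            raise ValueError(
                f"molecule {mol!r} is {meta['rna_class']}, expected {expected_class}"
            )
        g.add_node(
            mol,
            rna_class=meta["rna_class"],
            log2fc=float(meta["log2fc"]),
            direction="up" if meta["log2fc"] > 0 else "down",
        )

    for row in de_target_pairs.itertuples():
        etype = EDGE_MIRNA_MRNA if row.target_class == "mRNA" else EDGE_MIRNA_LNCRNA
        add_node(row.mirna, "miRNA")
        add_node(row.target, row.target_class)
        g.add_edge(row.mirna, row.target, edge_type=etype, best_site_type=row.best_type)
    for row in de_cis_pairs.itertuples():
        add_node(row.lncrna, "lncRNA")
        add_node(row.gene, "mRNA")
        g.add_edge(
            row.lncrna, row.gene, edge_type=EDGE_LNCRNA_CIS_GENE, best_site_type=""
        )
    return CeRNANetwork(contrast.label, g)


def triplets(network: CeRNANetwork) -> pd.DataFrame:
    """All (lncRNA, miRNA, mRNA) triplets: the miRNA targets both transcripts.

    ``direction_consistent`` marks the classical sponge pattern — the two
    targets co-directional and opposite to the miRNA. It is an annotation,
    never a membership filter.
    """
    g = network.graph
    rows = []
    for m in sorted(n for n, d in g.nodes(data=True) if d["rna_class"] == "miRNA"):
        lnc_nbrs = sorted(
            v
            for v in g.neighbors(m)
            if g.edges[m, v]["edge_type"] == EDGE_MIRNA_LNCRNA
        )
        mrna_nbrs = sorted(
            v
            for v in g.neighbors(m)
            if g.edges[m, v]["edge_type"] == EDGE_MIRNA_MRNA
        )
        fm = g.nodes[m]["log2fc"]
        for lnc in lnc_nbrs:
            for mr in mrna_nbrs:
                fl, fg = g.nodes[lnc]["log2fc"], g.nodes[mr]["log2fc"]
                consistent = bool(np.sign(fl) == np.sign(fg) != np.sign(fm))
                rows.append(
                    {
                        "lncrna": lnc,
                        "mirna": m,
                        "mrna": mr,
                        "direction_consistent": consistent,
                    }
                )
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


def hub_report(network: CeRNANetwork, top_k: int = 5) -> dict[str, list[tuple[str, int]]]:
    """Top-k nodes by degree per RNA class; ties broken lexicographically."""
    g = network.graph
    out: dict[str, list[tuple[str, int]]] = {}
    for cls in RNA_CLASSES:
        ranked = sorted(
            ((n, g.degree[n]) for n, d in g.nodes(data=True) if d["rna_class"] == cls),
            key=lambda item: (-item[1], item[0]),
        )
        out[cls] = ranked[:top_k]
    return out


def subnetwork(network: CeRNANetwork, seeds: list[str]) -> CeRNANetwork:
    """Induced subgraph on the seed nodes plus their direct neighbors."""
    g = network.graph
    unknown = [s for s in seeds if s not in g]
    if unknown:
        raise ValueError(f"seed node(s) not in network: {unknown}")
    keep = set(seeds)
    for s in seeds:
        keep.update(g.neighbors(s))
    return CeRNANetwork(network.contrast, g.subgraph(keep).copy())


def write_network(network: CeRNANetwork, path, fmt: str = "tsv") -> None:
    """Write the network as an edge TSV or GraphML."""
    if fmt == "tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "edge_type": d["edge_type"],
                "contrast": network.contrast,
            }
            for u, v, d in sorted(network.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "edge_type", "contrast"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
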