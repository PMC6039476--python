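"""Network assembly, triplet combinatorics, hub ranking, subnetworks."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import ContrastTable
from cernet.network import (
    build_network,
    hub_report,
    read_network_edges,
    subnetwork,
    triplets,
    write_network,
)

CIS_EMPTY = pd.DataFrame(columns=["lncrna", "gene", "chrom", "gap", "relative_position"])


def _contrast(mols):
    rec = pd.DataFrame(
        {
            "id": [m[0] for m in mols],
            "rna_class": [m[1] for m in mols],
            "log2fc": [m[2] for m in mols],
            "pvalue": 1e-4,
            "is_de": True,
        }
    )
    return ContrastTable("primary_vs_control", rec)


def _pairs(rows):
    return pd.DataFrame(
        [
            {"mirna": m, "target": t, "target_class": c, "best_type": "8mer"}
            for m, t, c in rows
        ],
        columns=["mirna", "target", "target_class", "best_type"],
    )


def _minimal():
    contrast = _contrast(
        [("m1", "miRNA", 3.0), ("G1", "mRNA", -3.0), ("L1", "lncRNA", -3.0)]
    )
    pairs = _pairs([("m1", "G1", "mRNA"), ("m1", "L1", "lncRNA")])
    return build_network(contrast, pairs, CIS_EMPTY)


def test_empty_pair_sets_give_empty_network():
    net = build_network(_contrast([("m1", "miRNA", 3.0)]), _pairs([]), CIS_EMPTY)
    assert net.n_nodes == 0 and net.n_edges == 0


def test_minimal_triplet_network():
    net = _minimal()
    assert net.n_nodes == 3 and net.n_edges == 2
    t = triplets(net)
    assert len(t) == 1
    assert tuple(t.iloc[0][["lncrna", "mirna", "mrna"]]) == ("L1", "m1", "G1")
    assert bool(t.iloc[0]["direction_consistent"])  # targets down, miRNA up


def test_non_de_pair_member_rejected():
    contrast = _contrast([("m1", "miRNA", 3.0), ("G1", "mRNA", -3.0)])
    pairs = _pairs([("m1", "G2", "mRNA")])
    with pytest.raises(ValueError, match="G2"):
        build_network(contrast, pairs, CIS_EMPTY)


def test_star_mirna_triplet_count_is_product():
    a, b = 3, 4
    mols = [("m1", "miRNA", 2.5)]
    rows = []
    for i in range(a):
        mols.append((f"L{i}", "lncRNA", -2.5))
        rows.append(("m1", f"L{i}", "lncRNA"))
    for i in range(b):
        mols.append((f"G{i}", "mRNA", -2.5))
        rows.append(("m1", f"G{i}", "mRNA"))
    net = build_network(_contrast(mols), _pairs(rows), CIS_EMPTY)
    assert len(triplets(net)) == a * b


def test_handshake_lemma_and_bipartiteness(planted_result):
    for net in planted_result.networks.values():
        degrees = dict(net.graph.degree())
        assert sum(degrees.values()) == 2 * net.n_edges
        for u, v, d in net.graph.edges(data=True):
            classes = {net.graph.nodes[u]["rna_class"], net.graph.nodes[v]["rna_class"]}
            expected = {
                "mirna_mrna": {"miRNA", "mRNA"},
                "mirna_lncrna": {"miRNA", "lncRNA"},
                "lncrna_cis_gene": {"lncRNA", "mRNA"},
            }[d["edge_type"]]
            assert classes == expected


def test_hub_report_matches_brute_force(rng):
    # random bipartite-ish network
    mols = [(f"m{i}", "miRNA", 2.5) for i in range(8)]
    mols += [(f"G{i}", "mRNA", -2.5) for i in range(20)]
    rows = []
    for i in range(8):
        for j in range(20):
            if rng.random() < 0.3:
                rows.append((f"m{i}", f"G{j}", "mRNA"))
    net = build_network(_contrast(mols), _pairs(rows), CIS_EMPTY)
    report = hub_report(net, top_k=5)
    g = net.graph
    for cls in ("miRNA", "mRNA"):
        brute = sorted(
            ((n, g.degree[n]) for n, d in g.nodes(data=True) if d["rna_class"] == cls),
            key=lambda x: (-x[1], x[0]),
        )[:5]
        assert report[cls] == brute


def test_minimal_hub_degree():
    report = hub_report(_minimal())
    assert report["miRNA"] == [("m1", 2)]


def test_subnetwork_of_hub_is_whole_network():
    net = _minimal()
    sub = subnetwork(net, ["m1"])
    assert sub.n_nodes == net.n_nodes and sub.n_edges == net.n_edges


def test_subnetwork_unknown_seed_errors():
    with pytest.raises(ValueError, match="not in network"):
        subnetwork(_minimal(), ["nope"])


def test_subnetwork_matches_brute_force_filter(rng):
    mols = [(f"m{i}", "miRNA", 2.5) for i in range(5)]
    mols += [(f"G{i}", "mRNA", -2.5) for i in range(15)]
    rows = [
        (f"m{i}", f"G{j}", "mRNA")
        for i in range(5)
        for j in range(15)
        if rng.random() < 0.25
    ]
    net = build_network(_contrast(mols), _pairs(rows), CIS_EMPTY)
    seeds = [n for n in ("m0", "m1") if n in net.graph]
    if not seeds:
        pytest.skip("random instance left seeds isolated")
    sub = subnetwork(net, seeds)
    keep = set(seeds)
    for s in seeds:
        keep |= set(net.graph.neighbors(s))
    expected_edges = {
        frozenset((u, v)) for u, v in net.graph.edges() if u in keep and v in keep
    }
    assert {frozenset(e) for e in sub.graph.edges()} == expected_edges


def test_network_tsv_round_trip_preserves_edge_multiset(tmp_path):
    net = _minimal()
    p = tmp_path / "net.tsv"
    write_network(net, p, fmt="tsv")
    back = read_network_edges(p)
    assert len(back) == net.n_edges
    assert set(map(frozenset, zip(back["source"], back["target"]))) == set(
        map(frozenset, net.graph.edges())
    )


def test_network_graphml_round_trip(tmp_path):
    net = _minimal()
    p = tmp_path / "net.graphml"
    write_network(net, p, fmt="graphml")
    back = nx.read_graphml(p)
    assert set(back.nodes) == set(net.graph.nodes)
    assert {frozenset(e) for e in back.edges()} == {
        frozenset(e) for e in net.graph.edges()
    }
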