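"""Cross-contrast shared molecules, key-pair extraction, and the worked example."""

import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import ContrastTable
from cernet.dynamics import dynamics_report, extract_key_pairs, shared_molecules
from cernet.fixtures import load_key_pair_fixture
from cernet.model import CONTRAST_A, CONTRAST_B


def _table(label, rows):
    rec = pd.DataFrame(
        rows, columns=["id", "rna_class", "log2fc", "is_de"]
    ).assign(pvalue=1e-4)
    return ContrastTable(label, rec)


def test_disjoint_de_sets_share_nothing():
    a = _table(CONTRAST_A, [("x", "mRNA", 3.0, True), ("y", "mRNA", 3.0, False)])
    b = _table(CONTRAST_B, [("x", "mRNA", 3.0, False), ("y", "mRNA", 3.0, True)])
    assert len(shared_molecules(a, b)) == 0


def test_sign_rule_classifies_reversed_and_concordant():
    a = _table(CONTRAST_A, [("x", "mRNA", 3.0, True), ("y", "mRNA", -2.5, True)])
    b = _table(CONTRAST_B, [("x", "mRNA", -3.0, True), ("y", "mRNA", -4.0, True)])
    shared = shared_molecules(a, b)
    pat = dict(zip(shared["id"], shared["pattern"]))
    assert pat == {"x": "reversed", "y": "concordant"}


def test_shared_set_matches_brute_force_on_random_molecules(rng):
    n = 1000
    ids = [f"g{i}" for i in range(n)]
    de_a = rng.random(n) < 0.3
    de_b = rng.random(n) < 0.3
    lfc_a = rng.normal(0, 3, n)
    lfc_b = rng.normal(0, 3, n)
    a = _table(CONTRAST_A, list(zip(ids, ["mRNA"] * n, lfc_a, de_a)))
    b = _table(CONTRAST_B, list(zip(ids, ["mRNA"] * n, lfc_b, de_b)))
    shared = shared_molecules(a, b)
    expected = {ids[i] for i in range(n) if de_a[i] and de_b[i]}
    assert set(shared["id"]) == expected


def test_worked_example_retains_exactly_the_published_pairs():
    """The packaged key-pair fixture: eight relations survive, twelve decoys
    fail shared membership or the two-contrast pair requirement."""
    fx = load_key_pair_fixture()
    shared = shared_molecules(fx["contrast_a"], fx["contrast_b"])
    key = extract_key_pairs(shared, fx["pairs_a"], fx["pairs_b"])
    assert key[["mirna", "target", "target_class"]].equals(fx["expected_key_pairs"])
    assert ("miR-323b-3p", "TGFBR3") in set(zip(key["mirna"], key["target"]))
    assert key["mirna"].nunique() == 3


def test_worked_example_every_member_reversed():
    fx = load_key_pair_fixture()
    shared = shared_molecules(fx["contrast_a"], fx["contrast_b"])
    key = extract_key_pairs(shared, fx["pairs_a"], fx["pairs_b"])
    report = dynamics_report(shared, key)
    trend = report["trend"]
    assert (trend["mirna_pattern"] == "reversed").all()
    assert (trend["target_pattern"] == "reversed").all()
    # trend signs flip between contrasts for every member
    assert (np.sign(trend["mirna_log2fc_a"]) != np.sign(trend["mirna_log2fc_b"])).all()
    assert (np.sign(trend["target_log2fc_a"]) != np.sign(trend["target_log2fc_b"])).all()


def test_empty_shared_set_gives_no_key_pairs():
    fx = load_key_pair_fixture()
    empty = shared_molecules(
        _table(CONTRAST_A, [("x", "mRNA", 3.0, False)]),
        _table(CONTRAST_B, [("x", "mRNA", 3.0, False)]),
    )
    assert len(extract_key_pairs(empty, fx["pairs_a"], fx["pairs_b"])) == 0


def test_key_pairs_invariant_under_row_permutation(rng):
    fx = load_key_pair_fixture()
    shared = shared_molecules(fx["contrast_a"], fx["contrast_b"])
    key1 = extract_key_pairs(shared, fx["pairs_a"], fx["pairs_b"])
    pa = fx["pairs_a"].sample(frac=1, random_state=7).reset_index(drop=True)
    pb = fx["pairs_b"].sample(frac=1, random_state=8).reset_index(drop=True)
    sh = shared.sample(frac=1, random_state=9).reset_index(drop=True)
    key2 = extract_key_pairs(sh, pa, pb)
    assert key1.equals(key2)


def test_removing_a_de_molecule_only_shrinks_key_pairs():
    fx = load_key_pair_fixture()
    shared = shared_molecules(fx["contrast_a"], fx["contrast_b"])
    full = extract_key_pairs(shared, fx["pairs_a"], fx["pairs_b"])
    full_set = set(zip(full["mirna"], full["target"]))
    rec = fx["contrast_a"].records.copy()
    rec.loc[rec["id"] == "TGFBR3", "is_de"] = False
    weakened = shared_molecules(
        ContrastTable(CONTRAST_A, rec), fx["contrast_b"]
    )
    smaller = extract_key_pairs(weakened, fx["pairs_a"], fx["pairs_b"])
    smaller_set = set(zip(smaller["mirna"], smaller["target"]))
    assert smaller_set <= full_set
    assert ("miR-323b-3p", "TGFBR3") not in smaller_set


def test_require_reversed_filter():
    a = _table(CONTRAST_A, [("m", "miRNA", 3.0, True), ("t", "mRNA", -3.0, True)])
    b = _table(CONTRAST_B, [("m", "miRNA", 4.0, True), ("t", "mRNA", 3.0, True)])
    pairs = pd.DataFrame(
        [{"mirna": "m", "target": "t", "target_class": "mRNA", "best_type": "8mer"}]
    )
    shared = shared_molecules(a, b)
    assert len(extract_key_pairs(shared, pairs, pairs)) == 1
    assert len(extract_key_pairs(shared, pairs, pairs, require_reversed=True)) == 0


def test_report_counts_equal_recount():
    fx = load_key_pair_fixture()
    shared = shared_molecules(fx["contrast_a"], fx["contrast_b"])
    key = extract_key_pairs(shared, fx["pairs_a"], fx["pairs_b"])
    report = dynamics_report(shared, key)
    counts = dict(
        zip(report["shared_counts"]["rna_class"], report["shared_counts"]["n_shared"])
    )
    assert counts == shared.groupby("rna_class").size().to_dict()
    per_mirna = dict(
        zip(report["per_mirna_targets"]["mirna"], report["per_mirna_targets"]["n_targets"])
    )
    assert per_mirna == key.groupby("mirna").size().to_dict()


def test_empty_inputs_give_all_zero_report():
    shared = shared_molecules(
        _table(CONTRAST_A, [("x", "mRNA", 3.0, False)]),
        _table(CONTRAST_B, [("x", "mRNA", 3.0, False)]),
    )
    key = extract_key_pairs(shared, pd.DataFrame(columns=["mirna", "target", "target_class"]),
                            pd.DataFrame(columns=["mirna", "target", "target_class"]))
    report = dynamics_report(shared, key)
    assert len(report["shared_counts"]) == 0
    assert len(report["trend"]) == 0
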