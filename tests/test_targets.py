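"""Seed extraction and site finding against a brute-force complementarity oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.targets import (
    SITE_RANK,
    SeedSite,
    find_seed_sites,
    predict_pairs,
    restrict_to_de,
    seed_of,
    site_pattern,
)
from cernet.diffexpr import ContrastTable

import pandas as pd

from conftest import random_dna, random_rna

# --- independent oracle -----------------------------------------------------

_DNA2RNA = {"A": "U", "C": "G", "G": "C", "T": "A"}


def _rc_to_rna(window: str) -> str:
    """Reverse complement of a DNA window, written in the RNA alphabet."""
    return "".join(_DNA2RNA[b] for b in reversed(window))


def oracle_sites(mirna: str, target: str) -> list[tuple[str, int]]:
    """Brute force: reverse-complement every 6-nt target window and compare
    with seed positions 2-7; classify extensions per the site taxonomy.
    Returns (site_type, 1-based start of the full pattern)."""
    m = mirna.upper().replace("T", "U")
    t = target.upper().replace("U", "T")
    out = []
    for j in range(len(t) - 5):
        if _rc_to_rna(t[j : j + 6]) != m[1:7]:
            continue
        m8 = j > 0 and _rc_to_rna(t[j - 1]) == m[7]
        a1 = j + 6 < len(t) and t[j + 6] == "A"
        if m8 and a1:
            out.append(("8mer", j))
        elif m8:
            out.append(("7mer-m8", j))
        elif a1:
            out.append(("7mer-A1", j + 1))
        else:
            out.append(("6mer", j + 1))
    return out


# --- seed extraction ---------------------------------------------------------

def test_seed_is_positions_2_to_8():
    assert seed_of("UAGCUUAUCAGACUGAUGUUGA") == "AGCUUAU"


def test_short_mirna_rejected():
    with pytest.raises(ValueError, match="too short"):
        seed_of("UAGCUUA")


def test_seed_invariant_to_position_1():
    base = "UAGCUUAUCAGACUGAUGUUGA"
    for b in "ACGU":
        assert seed_of(b + base[1:]) == seed_of(base)


# --- site finding ------------------------------------------------------------

def test_worked_8mer_site():
    sites = find_seed_sites("UAGCUUAUCAGACUGAUGUUGA", "GGATAAGCTAGG")
    assert len(sites) == 1
    s = sites[0]
    assert s.site_type == "8mer"
    assert s.pattern == "ATAAGCTA"
    # the reported start re-extracts the pattern (self-verifying coordinates)
    assert "GGATAAGCTAGG"[s.start - 1 : s.start - 1 + len(s.pattern)] == s.pattern


def test_no_complementary_window_gives_no_sites():
    assert find_seed_sites("UAGCUUAUCAGACUGAUGUUGA", "CCCCCCCCCCCC") == []


def test_concatenated_patterns_each_found():
    m = "UAGCUUAUCAGACUGAUGUUGA"
    pat = site_pattern(m, "7mer-m8")
    target = (pat + "C") * 3 + "C"  # non-A spacer keeps each site 7mer-m8
    sites = find_seed_sites(m, target)
    assert len(sites) == 3
    assert all(s.site_type == "7mer-m8" for s in sites)


@pytest.mark.parametrize("stype", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
def test_planted_pattern_recovers_its_type(stype):
    m = "UAGCUUAUCAGACUGAUGUUGA"
    pat = site_pattern(m, stype)
    # pad so weaker flanks cannot upgrade or downgrade the site
    if stype == "7mer-m8":
        target = "CC" + pat + "C" + "CC"
    elif stype == "7mer-A1":
        target = "CC" + pat + "CC"
    elif stype == "6mer":
        target = "CC" + pat + "C" + "CC"
    else:
        target = "CC" + pat + "CC"
    sites = find_seed_sites(m, target)
    assert [s.site_type for s in sites] == [stype]


def test_sites_match_oracle_on_random_instances(rng):
    """Exhaustive window-by-window complementarity scan agrees on >=100
    random miRNA/target instances."""
    n_checked = 0
    for _ in range(120):
        m = random_rna(rng, 22)
        t = random_dna(rng, 60)
        got = [(s.site_type, s.start) for s in find_seed_sites(m, t)]
        assert got == oracle_sites(m, t)
        n_checked += 1
    assert n_checked >= 100


def test_every_reported_site_self_verifies(rng):
    for _ in range(50):
        m = random_rna(rng, 22)
        t = random_dna(rng, 80)
        for s in find_seed_sites(m, t):
            assert t[s.start - 1 : s.start - 1 + len(s.pattern)] == s.pattern
            assert len(s.pattern) == {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[
                s.site_type
            ]


# --- pair prediction ----------------------------------------------------------

def _mini_universe(rng, n_m=6, n_t=15):
    mirnas = {f"m{i}": random_rna(rng, 22) for i in range(n_m)}
    targets = {f"t{i}": random_dna(rng, 50) for i in range(n_t)}
    classes = {f"t{i}": ("mRNA" if i % 2 else "lncRNA") for i in range(n_t)}
    return mirnas, targets, classes


def test_pairs_match_brute_force_double_loop(rng):
    mirnas, targets, classes = _mini_universe(rng, 8, 30)
    got = predict_pairs(mirnas, targets, classes, min_best_type="6mer")
    expected = set()
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            if oracle_sites(mseq, tseq):
                expected.add((mid, tid))
    assert set(zip(got["mirna"], got["target"])) == expected


def test_stringency_monotonicity(rng):
    mirnas, targets, classes = _mini_universe(rng, 10, 40)
    previous = None
    for min_type in ["6mer", "7mer-A1", "7mer-m8", "8mer"]:
        pairs = predict_pairs(mirnas, targets, classes, min_best_type=min_type)
        current = set(zip(pairs["mirna"], pairs["target"]))
        if previous is not None:
            assert current <= previous
        previous = current


def test_min_sites_monotonicity(rng):
    mirnas, targets, classes = _mini_universe(rng, 10, 40)
    p1 = predict_pairs(mirnas, targets, classes, min_best_type="6mer", min_sites=1)
    p2 = predict_pairs(mirnas, targets, classes, min_best_type="6mer", min_sites=2)
    assert set(zip(p2["mirna"], p2["target"])) <= set(zip(p1["mirna"], p1["target"]))


def test_empty_mirna_set_gives_empty_output():
    assert len(predict_pairs({}, {"t": "ACGT" * 10}, {"t": "mRNA"})) == 0


def test_unannotated_target_errors(rng):
    m = "UAGCUUAUCAGACUGAUGUUGA"
    target = "CC" + site_pattern(m, "8mer") + "CC"
    with pytest.raises(ValueError, match="class"):
        predict_pairs({"m1": m}, {"t1": target}, {})


def test_restrict_to_de_is_set_intersection():
    pairs = pd.DataFrame(
        {
            "mirna": ["m1", "m1", "m2"],
            "target": ["t1", "t2", "t1"],
            "target_class": ["mRNA", "mRNA", "mRNA"],
            "best_type": "8mer",
        }
    )
    rec = pd.DataFrame(
        {
            "id": ["m1", "m2", "t1", "t2"],
            "rna_class": ["miRNA", "miRNA", "mRNA", "mRNA"],
            "log2fc": [3.0, 3.0, -3.0, -3.0],
            "pvalue": 1e-4,
            "is_de": [True, False, True, False],
        }
    )
    table = ContrastTable("primary_vs_control", rec)
    kept = restrict_to_de(pairs, table)
    assert list(zip(kept["mirna"], kept["target"])) == [("m1", "t1")]

    rec_all = rec.assign(is_de=True)
    assert len(restrict_to_de(pairs, ContrastTable("x", rec_all))) == len(pairs)
    rec_none = rec.assign(is_de=False)
    assert len(restrict_to_de(pairs, ContrastTable("x", rec_none))) == 0
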