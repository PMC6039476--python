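"""Packaged osteosarcoma reference fixtures.

Two small data files ship with the package:

* ``osteosarcoma_key_pairs.tsv`` / ``osteosarcoma_key_molecules.tsv`` — the
  eight key miRNA-target relations reported for osteosarcoma tumorigenesis
  and pulmonary metastasis (miR-223-5p with CLSTN2, AC009951.1, LINC01705
  and AC090673.1; miR-378b with ALX4, IGSF3 and SULF1; miR-323b-3p with
  TGFBR3), together with twelve decoy relations that each fail one clause
  of the key-pair definition. The fold-change *signs* follow the reported
  expression trends (every member reversed between the two contrasts, e.g.
  TGFBR3 down in tumorigenesis and up in metastasis); the magnitudes of the
  shared molecules are synthetic placeholders.
* ``osteosarcoma_top_de.tsv`` — the published top-ten up- and down-regulated
  molecules per RNA class for both contrasts, with their printed p-values
  and log2 fold changes. Used to check DE-filter concordance with the
  published cut-offs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffexpr import ContrastTable
from .model import CONTRAST_A, CONTRAST_B


def _data(name: str) -> pd.DataFrame:
    with resources.files("cernet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_top_de_table() -> pd.DataFrame:
    """Published top DE molecules: contrast, rna_class, id, pvalue, log2fc."""
    return _data("osteosarcoma_top_de.tsv")


def load_key_pair_fixture() -> dict:
    """The key-pair worked example as dynamics-stage inputs.

    Returns a dict with contrast tables ``contrast_a`` / ``contrast_b``
    (minimal columns: id, rna_class, log2fc, pvalue, is_de), DE-restricted
    pair sets ``pairs_a`` / ``pairs_b``, and the ``expected_key_pairs``
    frame holding the eight reported relations.
    """
    mols = _data("osteosarcoma_key_molecules.tsv")
    rels = _data("osteosarcoma_key_pairs.tsv")

    def contrast(which: str, label: str) -> ContrastTable:
        rec = pd.DataFrame(
            {
                "id": mols["id"],
                "rna_class": mols["rna_class"],
                "log2fc": mols[f"log2fc_{which}"],
                "pvalue": [1e-4 if de else 0.5 for de in mols[f"de_{which}"]],
                "is_de": mols[f"de_{which}"].astype(bool),
            }
        )
        return ContrastTable(label, rec)

    def pairs(col: str) -> pd.DataFrame:
        sub = rels[rels[col] == 1]
        return pd.DataFrame(
            {
                "mirna": sub["mirna"],
                "target": sub["target"],
                "target_class": sub["target_class"],
                "best_type": "8mer",
            }
        ).reset_index(drop=True)

    expected = (
        rels[rels["is_key"] == 1][["mirna", "target", "target_class"]]
        .sort_values(["mirna", "target"], ignore_index=True)
    )
    return {
        "contrast_a": contrast("a", CONTRAST_A),
        "contrast_b": contrast("b", CONTRAST_B),
        "pairs_a": pairs("in_contrast_a"),
        "pairs_b": pairs("in_contrast_b"),
        "expected_key_pairs": expected,
        "molecules": mols,
        "relations": rels,
    }
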