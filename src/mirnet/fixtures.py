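"""Packaged transcriptions of the published candidate tables.

Two verbatim fold-change tables ship with the package: the 24 candidate
resistance genes with their four within-genotype log2 fold changes, and
the candidate miRNA-mRNA pair table (one row per pair; family blocks of
the print layout are expanded to explicit pairs). Sparse fold-change
cells that the print leaves blank are blank here too. Loading verifies a
SHA-256 checksum so silent fixture edits fail loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "table2_candidate_genes.tsv":
        "b70cdcededc62eb0b63b5d88bc73f4c457adbce285b3db3bcf4d8e0d83909e28",
    "table3_mirna_mrna_pairs.tsv":
        "5c7064ab1b4b1b8c40f987d1ba079b8141817d198461bce55a1a930d0c1fbe35",
}


def _read_checked(name: str) -> pd.DataFrame:
    ref = resources.files("mirnet.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch: {digest} "
            f"(expected {_CHECKSUMS[name]})"
        )
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_paper_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the two packaged candidate tables.

    Returns ``(candidate_genes, candidate_pairs)``: the gene table is
    indexed by ``gene_id`` with the four within-genotype log2FC columns
    (``S_early/S0``, ``S_late/S0``, ``R_early/R0``, ``R_late/R0``); the
    pair table has one row per (miRNA, target) pair with both members'
    fold-change columns.
    """
    table2 = _read_checked("table2_candidate_genes.tsv").set_index(
        "gene_id", drop=False
    )
    table3 = _read_checked("table3_mirna_mrna_pairs.tsv")
    return table2, table3
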