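"""Over-representation testing of gene sets against annotation maps.

The test is the one-sided hypergeometric tail (Fisher's exact test for
enrichment): with a universe of N genes of which K carry a term, the
probability of observing >= k term genes in a selection of size n.
FDR is Benjamini-Hochberg across the tested terms of one namespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """Term -> gene-set annotation over a gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    namespace: str = "BP"

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.universe = frozenset(self.universe)
        if not self.universe:
            raise ValueError("annotation universe is empty")
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(stray)[:3]}"
                )

    @classmethod
    def from_tsv(cls, path, namespace: str | None = None,
                 universe=None) -> "AnnotationMap":
        """Read a (term_id, namespace, gene_id) TSV."""
        df = pd.read_csv(path, sep="\t")
        if namespace is not None:
            df = df[df["namespace"] == namespace]
        terms: dict[str, set[str]] = {}
        for term, gene in zip(df["term_id"], df["gene_id"]):
            terms.setdefault(term, set()).add(gene)
        uni = frozenset(universe) if universe is not None else frozenset(
            df["gene_id"]
        )
        return cls({t: frozenset(g) for t, g in terms.items()}, uni,
                   namespace or "BP")


def enrich(
    selected,
    annot: AnnotationMap,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` genes per term.

    Genes outside the universe are dropped with a warning. Returns one
    row per term with k >= 1 overlap: ``term_id, k, K, n, N, pvalue,
    fdr, significant``, sorted by p-value.
    """
    selected = set(selected)
    stray = selected - annot.universe
    if stray:
        warnings.warn(
            f"{len(stray)} selected genes outside the universe were dropped"
        )
        selected &= annot.universe
    N = len(annot.universe)
    n = len(selected)
    rows = []
    for term, genes in sorted(annot.terms.items()):
        k = len(selected & genes)
        if k < 1:
            continue
        K = len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "pvalue": p})
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "k", "K", "n", "N", "pvalue", "fdr",
                     "significant"]
        )
    result = pd.DataFrame(rows)
    result["fdr"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    result["significant"] = (result["pvalue"] < p_max) & (
        result["fdr"] < fdr_max
    )
    return result.sort_values(
        ["pvalue", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
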