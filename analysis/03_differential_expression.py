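"""Normalize counts and call differential expression over the seven
contrasts.

miRNA counts are normalized to RPM and tested at fold change >= 2 with
P < 0.05; mRNA counts to RPKM and tested at |log2FC| >= 1 with
FDR < 0.05. Also ranks a panel of constitutive features as candidate
qPCR reference genes by the stability of their condition means.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirnet.design import StudyDesign
from mirnet.diffexpr import run_all_comparisons, summarize_counts
from mirnet.normalize import CountMatrix, normalize, reference_stability


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    out = args.outdir
    design = StudyDesign()

    lengths = pd.read_csv(
        out / "mrna_lengths.tsv", sep="\t", index_col="feature_id"
    )["length"]
    mirna = CountMatrix.from_tsv(out / "mirna_counts.tsv", design)
    mrna = CountMatrix.from_tsv(out / "mrna_counts.tsv", design, lengths)

    expr_mirna = normalize(mirna, "rpm")
    expr_mrna = normalize(mrna, "rpkm")
    expr_mirna.to_tsv(out / "mirna_rpm.tsv")
    expr_mrna.to_tsv(out / "mrna_rpkm.tsv")

    de = run_all_comparisons(expr_mirna, expr_mrna)
    de.to_csv(out / "de_table.tsv", sep="\t", index=False)
    summary = summarize_counts(de)
    summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)
    print("up/down calls per contrast:")
    print(summary.to_string(index=False))

    truth = pd.read_csv(out / "truth.tsv", sep="\t",
                        keep_default_na=False, na_values=[])
    null_genes = truth.loc[
        (truth["feature_class"] == "mrna") & (truth["pattern"] == "null"),
        "feature_id",
    ].head(8).tolist()
    stability = reference_stability(expr_mrna, null_genes)
    stability.to_csv(out / "reference_stability.tsv", sep="\t", index=False)
    best = stability.iloc[0]
    print(f"\nmost stable reference candidate: {best['candidate']} "
          f"(CV of condition means = {best['cv']:.3f})")


if __name__ == "__main__":
    main()
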