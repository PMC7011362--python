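"""Integrate miRNA and mRNA profiles into candidate resistance pairs.

A predicted (miRNA, target) pair is supported where both members are DE
with opposite directions in the same contrast; pairs are then kept only
when the miRNA is resistance-related (DE within the resistant genotype
or opposite-expressed between genotypes) and the target does not follow
the same trend in both genotypes.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirnet.design import R_STAGE_COMPARISONS
from mirnet.integration import (
    anti_correlated_pairs,
    pair_report,
    resistance_pair_filter,
)
from mirnet.selection import build_profiles, opposite_within_genotypes


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    out = args.outdir

    de = pd.read_csv(out / "de_table.tsv", sep="\t")
    hits = pd.read_csv(out / "target_hits.tsv", sep="\t")
    dem = de[de["feature_class"] == "mirna"]
    deg = de[de["feature_class"] == "mrna"]

    supported = anti_correlated_pairs(dem, deg, hits)
    per_contrast = supported.groupby("comparison").size()
    print("anti-correlated supported pairs per contrast:")
    print(per_contrast.to_string())

    pool_r = set(
        dem.loc[dem["comparison"].isin(R_STAGE_COMPARISONS)
                & (dem["direction"] != "ns"), "feature_id"]
    )
    pool_opp = set(
        opposite_within_genotypes(
            build_profiles(de, feature_class="mirna")
        )["feature_id"]
    )
    pairs = resistance_pair_filter(supported, pool_r, pool_opp, deg)
    mir_prof = build_profiles(de, feature_class="mirna")
    gene_prof = build_profiles(de, feature_class="mrna")
    report, counts = pair_report(
        pairs, mir_prof.log2fc, gene_prof.log2fc
    )
    supported.to_csv(out / "pairs_supported.tsv", sep="\t", index=False)
    pairs.to_csv(out / "candidate_pairs.tsv", sep="\t", index=False)
    report.to_csv(out / "pair_report.tsv", sep="\t", index=False)
    print(f"\nresistance-related candidate pairs: {len(pairs)} "
          f"({counts['n_mirna']} distinct miRNAs, "
          f"{counts['n_target']} distinct targets)")


if __name__ == "__main__":
    main()
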