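"""Clean and annotate the synthetic small-RNA library.

Runs the quality -> adapter-trim -> length-filter -> annotation cascade
on the FASTQ from step 01 and checks the recovered per-miRNA counts
against the generator's read manifest (the ground truth).
"""

import argparse
from pathlib import Path

import pandas as pd

from mirnet.preprocess import AnnotationCatalog, process_sample


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    out = args.outdir

    adapter = (out / "adapter.txt").read_text().strip()
    catalog = AnnotationCatalog.from_manifest(out / "catalog_manifest.tsv")
    result = process_sample(out / "sample_S0_1.fastq", adapter, catalog)

    result["class_summary"].to_csv(
        out / "preprocess_class_summary.tsv", sep="\t", index=False
    )
    result["mirna_counts"].rename_axis("mirna_id").to_frame().to_csv(
        out / "preprocess_mirna_counts.tsv", sep="\t"
    )

    manifest = pd.read_csv(out / "read_manifest.tsv", sep="\t")
    truth_counts = (
        manifest[manifest["source_class"] == "mirna"]
        .groupby("source_id").size()
    )
    recovered = result["mirna_counts"]
    shared = truth_counts.index.intersection(recovered.index)
    agreement = (
        (recovered[shared] <= truth_counts[shared]).mean()
    )
    summary = result["class_summary"].set_index("class")["n_reads"]
    print(f"input reads: {result['n_input_reads']}")
    print(summary.to_string())
    print(f"miRNA-assigned reads: {recovered.sum():.0f} "
          f"(manifest sources: {truth_counts.sum()})")
    print(f"fraction of miRNAs with counts <= manifest (length noise "
          f"removes reads, never adds): {agreement:.3f}")


if __name__ == "__main__":
    main()
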