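"""Generate the synthetic study inputs.

Builds the 18-sample (2 genotypes x 3 stages x 3 replicates) miRNA and
mRNA count matrices with planted resistance patterns and repression
links, a small-RNA FASTQ for one library with its source manifest, and
the catalogs the preprocessing cascade annotates against. Everything
lands under results/analysis/.
"""

import argparse
from pathlib import Path

from mirnet.design import StudyDesign
from mirnet import synthetic


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=Path("results/analysis"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    design = StudyDesign()
    nb = synthetic.NBParams(mean_baseline=200, dispersion=0.05)
    mirna, mrna, truth = synthetic.generate_counts(
        design, 60, 300, 0.2, nb, seed=args.seed,
        effect_size=2.0, link_fraction=0.7,
    )
    mirna.to_tsv(out / "mirna_counts.tsv")
    mrna.to_tsv(out / "mrna_counts.tsv")
    mrna.feature_lengths.rename_axis("feature_id").to_frame().to_csv(
        out / "mrna_lengths.tsv", sep="\t"
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    mir_cat = synthetic.random_mirna_catalog(20, seed=args.seed + 1)
    contam = synthetic.random_contaminant_catalog(
        ["rRNA", "tRNA", "snoRNA"], 10, seed=args.seed + 2
    )
    adapter = "TGGAATTCTCGGGTGCCAAGG"
    reads, manifest = synthetic.generate_reads(
        mir_cat, contam, 5000, adapter, length_noise=0.05,
        seed=args.seed + 3,
    )
    synthetic.write_fastq(reads, out / "sample_S0_1.fastq")
    manifest.to_csv(out / "read_manifest.tsv", sep="\t", index=False)
    with open(out / "catalog_mirna.fasta", "w") as fh:
        for mid, seq in sorted(mir_cat.items()):
            fh.write(f">{mid}\n{seq}\n")
    for cls, cat in contam.items():
        with open(out / f"catalog_{cls}.fasta", "w") as fh:
            for sid, seq in sorted(cat.items()):
                fh.write(f">{sid}\n{seq}\n")
    with open(out / "catalog_manifest.tsv", "w") as fh:
        fh.write("class\tfasta\n")
        for cls in contam:
            fh.write(f"{cls}\tcatalog_{cls}.fasta\n")
        fh.write("mirna\tcatalog_mirna.fasta\n")
    with open(out / "adapter.txt", "w") as fh:
        fh.write(adapter + "\n")

    planted = (truth["pattern"] != "null").sum()
    linked = (truth["repressors"] != "").sum()
    print(f"wrote 18-sample matrices: {len(mirna.feature_ids)} miRNAs, "
          f"{len(mrna.feature_ids)} mRNAs")
    print(f"planted non-null features: {planted}; "
          f"mRNAs with a repressor link: {linked}")
    print(f"wrote {len(reads)} reads for one library with manifest")


if __name__ == "__main__":
    main()
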