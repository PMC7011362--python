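"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` drives the full cascade on generated inputs: small-RNA
preprocessing (demonstrated on one synthetic FASTQ), normalization,
differential expression over the seven contrasts, the sign-opposition
selections, target prediction on sequences planted for the simulated
repression links, miRNA-mRNA integration, and term enrichment of the
candidate genes. Every intermediate lands as a TSV under the run
directory together with a manifest (seed, parameter hash, per-stage row
counts). All randomness derives from the single config seed; identical
config and seed give byte-identical output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, integration, selection, synthetic, targets
from .design import StudyDesign, R_STAGE_COMPARISONS
from .enrichment import AnnotationMap, enrich
from .normalize import normalize
from .preprocess import AnnotationCatalog, process_sample

logger = logging.getLogger("mirnet.pipeline")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for the demo pipeline."""

    seed: int = 0
    n_mirna: int = 60
    n_mrna: int = 300
    frac_planted: float = 0.2
    mean_baseline: float = 200.0
    dispersion: float = 0.05
    effect_size: float = 2.0
    link_fraction: float = 0.7
    mirna_log2fc_min: float = 1.0
    mirna_p_max: float = 0.05
    mrna_log2fc_min: float = 1.0
    mrna_fdr_max: float = 0.05
    target_cutoff: float = 5.0
    enrich_p_max: float = 0.05
    enrich_fdr_max: float = 0.05
    with_preprocess: bool = True
    n_reads: int = 2000
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage_index: int) -> int:
    return (seed * 1_000_003 + stage_index * 7919 + 17) % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path, **kwargs) -> int:
    df.to_csv(path, sep="\t", index=False, **kwargs)
    return len(df)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages and write the report bundle under ``out_dir``.

    Returns a dict with the in-memory products (count matrices, truth,
    DE table, selections, hit table, candidate pairs, enrichment) and
    the manifest. Raises with the stage name on stage failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()
    stages: list[dict] = []
    bundle: dict = {"design": design}

    def record(stage: str, **counts) -> None:
        logger.info("stage=%s %s", stage,
                    " ".join(f"{k}={v}" for k, v in counts.items()))
        stages.append({"stage": stage, **counts})

    try:
        stage = "preprocess"
        if config.with_preprocess:
            mir_cat = synthetic.random_mirna_catalog(
                20, _stage_seed(config.seed, 0)
            )
            contam = synthetic.random_contaminant_catalog(
                ["rRNA", "tRNA"], 10, _stage_seed(config.seed, 1)
            )
            reads, manifest = synthetic.generate_reads(
                mir_cat, contam, config.n_reads, config.adapter,
                length_noise=0.05, seed=_stage_seed(config.seed, 2),
            )
            catalog = AnnotationCatalog(
                [(cls, cat) for cls, cat in contam.items()]
                + [("mirna", mir_cat)]
            )
            result = process_sample(reads, config.adapter, catalog)
            result["class_summary"].to_csv(
                out / "preprocess_class_summary.tsv", sep="\t", index=False
            )
            result["mirna_counts"].rename_axis("mirna_id").reset_index().to_csv(
                out / "preprocess_mirna_counts.tsv", sep="\t", index=False
            )
            record(stage, n_reads=len(reads),
                   n_mirna_assigned=int(result["mirna_counts"].sum()))

        stage = "simulate"
        nb = synthetic.NBParams(
            mean_baseline=config.mean_baseline, dispersion=config.dispersion
        )
        mirna_counts, mrna_counts, truth = synthetic.generate_counts(
            design, config.n_mirna, config.n_mrna, config.frac_planted,
            nb, _stage_seed(config.seed, 3),
            effect_size=config.effect_size,
            link_fraction=config.link_fraction,
        )
        mirna_counts.to_tsv(out / "mirna_counts.tsv")
        mrna_counts.to_tsv(out / "mrna_counts.tsv")
        _write(truth, out / "truth.tsv")
        # input generation is bookkept separately from the analysis stages
        inputs_info = {
            "n_mirna": config.n_mirna, "n_mrna": config.n_mrna,
            "n_planted": int((truth["pattern"] != "null").sum()),
        }
        logger.info("inputs %s", inputs_info)

        stage = "normalize"
        expr_mirna = normalize(mirna_counts, "rpm")
        expr_mrna = normalize(mrna_counts, "rpkm")
        expr_mirna.to_tsv(out / "mirna_rpm.tsv")
        expr_mrna.to_tsv(out / "mrna_rpkm.tsv")
        record(stage, n_samples=len(design.sample_ids))

        stage = "de"
        mirna_thr = diffexpr.Thresholds(
            config.mirna_log2fc_min, config.mirna_p_max, None
        )
        mrna_thr = diffexpr.Thresholds(
            config.mrna_log2fc_min, None, config.mrna_fdr_max
        )
        de_table = diffexpr.run_all_comparisons(
            expr_mirna, expr_mrna,
            mirna_thresholds=mirna_thr, mrna_thresholds=mrna_thr,
        )
        summary = diffexpr.summarize_counts(de_table)
        n_rows = _write(de_table, out / "de_table.tsv")
        _write(summary, out / "de_summary.tsv")
        record(stage, n_records=n_rows,
               n_de=int((de_table["direction"] != "ns").sum()))

        stage = "selection"
        dem_table = de_table[de_table["feature_class"] == "mirna"]
        deg_table = de_table[de_table["feature_class"] == "mrna"]
        mirna_profiles = selection.build_profiles(de_table, feature_class="mirna")
        gene_profiles = selection.build_profiles(de_table, feature_class="mrna")
        opp_mirna = selection.opposite_within_genotypes(mirna_profiles)
        r_specific = selection.genotype_specific(mirna_profiles, "R")
        candidates = selection.candidate_genes(gene_profiles)
        _, regions = selection.venn_membership(
            dem_table, list(R_STAGE_COMPARISONS)
        )
        venn_df = pd.DataFrame(
            [{"region": "&".join(sorted(sig)), "count": n}
             for sig, n in sorted(regions.items(), key=lambda kv: sorted(kv[0]))]
        )
        _write(opp_mirna, out / "mirna_opposite.tsv")
        _write(r_specific, out / "mirna_R_specific.tsv")
        _write(candidates, out / "candidate_genes.tsv")
        _write(venn_df, out / "venn_regions.tsv")
        record(stage, n_opposite_mirna=len(opp_mirna),
               n_r_specific=len(r_specific), n_candidates=len(candidates))

        stage = "targets"
        links = truth[(truth["feature_class"] == "mrna")
                      & (truth["repressors"] != "")]
        mirna_seqs = synthetic.random_mirna_catalog(
            config.n_mirna, _stage_seed(config.seed, 4), (21, 21)
        )
        mirna_seq_map = dict(
            zip(sorted(truth.loc[truth["feature_class"] == "mirna",
                                 "feature_id"]),
                mirna_seqs.values())
        )
        # one transcript per linked target gene, carrying a perfect site
        # for its planted repressor miRNA
        linked_mirnas = {
            mid: mirna_seq_map[mid] for mid in sorted(
                set(links["repressors"])
            )
        }
        transcripts = {}
        site_rows = []
        rng_seed = _stage_seed(config.seed, 5)
        for i, (_, row) in enumerate(links.iterrows()):
            tx, site_truth = synthetic.generate_target_sequences(
                {row["repressors"]: mirna_seq_map[row["repressors"]]},
                1, {row["repressors"]: "tx_0001"}, None,
                seed=rng_seed + i, transcript_length=300,
            )
            transcripts[row["feature_id"]] = tx["tx_0001"]
            site_truth["transcript_id"] = row["feature_id"]
            site_rows.append(site_truth)
        hits = targets.predict_all(
            linked_mirnas, transcripts, cutoff=config.target_cutoff
        )
        _write(hits, out / "target_hits.tsv")
        if site_rows:
            _write(pd.concat(site_rows, ignore_index=True),
                   out / "target_site_truth.tsv")
        record(stage, n_links=len(links), n_hits=len(hits))

        stage = "integration"
        supported = integration.anti_correlated_pairs(
            dem_table, deg_table, hits
        )
        pool_r = set(
            dem_table.loc[
                dem_table["comparison"].isin(R_STAGE_COMPARISONS)
                & (dem_table["direction"] != "ns"), "feature_id"
            ]
        )
        pool_opp = set(opp_mirna["feature_id"])
        pairs = integration.resistance_pair_filter(
            supported, pool_r, pool_opp, deg_table
        )
        report, pair_counts = integration.pair_report(
            pairs,
            mirna_profiles.log2fc, gene_profiles.log2fc,
        )
        _write(supported, out / "pairs_supported.tsv")
        _write(pairs, out / "candidate_pairs.tsv")
        _write(report, out / "pair_report.tsv")
        record(stage, n_supported=len(supported), n_pairs=len(pairs),
               **pair_counts)

        stage = "enrichment"
        universe = frozenset(truth.loc[truth["feature_class"] == "mrna",
                                       "feature_id"])
        terms: dict[str, frozenset] = {}
        for pattern, grp in truth[truth["feature_class"] == "mrna"].groupby(
            "pattern"
        ):
            terms[f"pattern:{pattern}"] = frozenset(grp["feature_id"])
        annot = AnnotationMap(terms, universe, namespace="BP")
        enriched = enrich(
            set(candidates["feature_id"]), annot,
            p_max=config.enrich_p_max, fdr_max=config.enrich_fdr_max,
        ) if len(candidates) else pd.DataFrame(
            columns=["term_id", "k", "K", "n", "N", "pvalue", "fdr",
                     "significant"]
        )
        _write(enriched, out / "enrichment.tsv")
        record(stage, n_terms=len(enriched),
               n_significant=int(enriched["significant"].sum())
               if len(enriched) else 0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "inputs": inputs_info,
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    bundle.update(
        mirna_counts=mirna_counts, mrna_counts=mrna_counts, truth=truth,
        de_table=de_table, candidates=candidates, opposite_mirnas=opp_mirna,
        r_specific_mirnas=r_specific, hits=hits, supported_pairs=supported,
        candidate_pairs=pairs, pair_report=report, enrichment=enriched,
        manifest=manifest,
    )
    return bundle
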