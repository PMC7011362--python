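"""Small-RNA read cleaning and annotation cascade.

Raw reads are processed per sample through: quality filter (mean Phred
>= 20), 3' adapter trimming, poly-A removal, 20-24 nt length selection,
and ordered exact-match annotation against contaminant catalogs (rRNA,
tRNA, ...) followed by the mature-miRNA catalog -- first match wins.
Reads matching nothing are binned as ``genomic_other`` (the stand-in for
genome-mapped exon/intron/repeat reads, which require a genome and are
out of scope here). The product is a per-sample mature-miRNA count
vector plus a per-class read-fraction summary.

Matching is exact string identity after normalizing RNA to the DNA
alphabet; a 1-mismatch tolerance can be enabled but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

FILTER_CLASSES = ("low_quality", "adapter_only", "polyA", "too_short", "too_long")


@dataclass
class ReadRecord:
    """One small-RNA read and its classification state."""

    id: str
    sequence: str
    quality: str
    class_label: str = "unassigned"
    pretrim_length: int | None = None
    posttrim_length: int | None = None
    trimmed: bool = False

    def mean_phred(self) -> float:
        if not self.quality:
            return 0.0
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        records.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return records


@dataclass
class AnnotationCatalog:
    """Ordered (class name, id -> sequence) catalogs; first match wins.

    The mature-miRNA catalog must be registered under class ``mirna``
    and is conventionally last, after the contaminant classes.
    """

    classes: list[tuple[str, dict[str, str]]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate catalog class names")
        normalized = []
        for name, cat in self.classes:
            normalized.append(
                (name, {sid: s.upper().replace("U", "T") for sid, s in cat.items()})
            )
        self.classes = normalized

    @property
    def class_names(self) -> list[str]:
        return [name for name, _ in self.classes]

    def lookup(self) -> list[tuple[str, dict[str, list[str]]]]:
        """Per class: sequence -> list of ids carrying that sequence."""
        out = []
        for name, cat in self.classes:
            by_seq: dict[str, list[str]] = {}
            for sid, seq in cat.items():
                by_seq.setdefault(seq, []).append(sid)
            out.append((name, by_seq))
        return out

    @classmethod
    def from_manifest(cls, manifest_tsv: str | Path) -> "AnnotationCatalog":
        """Build from a TSV with columns ``class`` and ``fasta`` (paths
        relative to the manifest), one row per catalog in cascade order."""
        manifest_tsv = Path(manifest_tsv)
        df = pd.read_csv(manifest_tsv, sep="\t")
        classes = []
        for _, row in df.iterrows():
            fasta = manifest_tsv.parent / row["fasta"]
            cat = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
            }
            classes.append((row["class"], cat))
        return cls(classes)


def quality_filter(
    reads: Iterable[ReadRecord], min_mean_phred: float = 20.0
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Split reads into (kept, discarded) by mean Phred quality."""
    kept, discarded = [], []
    for read in reads:
        if read.mean_phred() < min_mean_phred:
            discarded.append(replace(read, class_label="low_quality"))
        else:
            kept.append(read)
    return kept, discarded


def trim_adapter(
    read: ReadRecord, adapter: str, min_overlap: int = 5
) -> ReadRecord:
    """Trim the 3' adapter at its leftmost occurrence.

    A match is the full adapter anywhere in the read, or an adapter
    prefix of length >= ``min_overlap`` reaching the read's 3' end.
    Reads reduced to nothing are classed ``adapter_only``. Already
    trimmed reads pass through unchanged, making trimming idempotent.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if read.trimmed:
        return read
    adapter = adapter.upper().replace("U", "T")
    seq = read.sequence
    need = min(min_overlap, len(adapter))
    cut = None
    for p in range(len(seq) - need + 1):
        k = min(len(adapter), len(seq) - p)
        if seq[p: p + k] == adapter[:k]:
            cut = p
            break
    out = replace(
        read,
        pretrim_length=len(seq),
        trimmed=True,
    )
    if cut is None:
        out.posttrim_length = len(seq)
        return out
    out.sequence = seq[:cut]
    out.quality = read.quality[:cut]
    out.posttrim_length = cut
    if cut == 0:
        out.class_label = "adapter_only"
    return out


def length_filter(
    reads: Iterable[ReadRecord],
    min_len: int = 20,
    max_len: int = 24,
    polya_fraction: float = 0.8,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Retain 20-24 nt non-poly-A inserts after trimming.

    Poly-A (adenine fraction >= ``polya_fraction``) takes precedence
    over the length classes; empty (adapter-only) reads keep their
    class.
    """
    kept, discarded = [], []
    for read in reads:
        n = len(read.sequence)
        if n == 0 or read.class_label == "adapter_only":
            discarded.append(replace(read, class_label="adapter_only"))
        elif read.sequence.count("A") / n >= polya_fraction:
            discarded.append(replace(read, class_label="polyA"))
        elif n < min_len:
            discarded.append(replace(read, class_label="too_short"))
        elif n > max_len:
            discarded.append(replace(read, class_label="too_long"))
        else:
            kept.append(read)
    return kept, discarded


def _hamming1_match(seq: str, by_seq: Mapping[str, list[str]]) -> list[str]:
    """Ids whose catalog sequence is within Hamming distance 1 of ``seq``."""
    hits: list[str] = []
    for cat_seq, ids in by_seq.items():
        if len(cat_seq) != len(seq):
            continue
        mismatches = sum(a != b for a, b in zip(cat_seq, seq))
        if mismatches <= 1:
            hits.extend(ids)
    return hits


def classify_and_count(
    reads: Sequence[ReadRecord],
    catalog: AnnotationCatalog,
    allow_one_mismatch: bool = False,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Assign kept reads through the catalog cascade and count miRNAs.

    Returns ``(mirna_counts, class_summary, warnings)``. Counts are per
    mature-miRNA id (fractional when one sequence maps to several ids);
    the summary reports read counts and fractions per class including
    ``genomic_other`` for unmatched reads.
    """
    lookup = catalog.lookup()
    mirna_ids: list[str] = []
    for name, by_seq in lookup:
        if name == "mirna":
            for ids in by_seq.values():
                mirna_ids.extend(ids)
    counts = pd.Series(0.0, index=sorted(mirna_ids), name="count")
    class_counts: dict[str, int] = {name: 0 for name, _ in lookup}
    class_counts["genomic_other"] = 0
    warnings: list[str] = []

    classified: list[ReadRecord] = []
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        assigned = None
        for name, by_seq in lookup:
            ids = by_seq.get(seq)
            if ids is None and allow_one_mismatch:
                ids = _hamming1_match(seq, by_seq) or None
            if ids:
                assigned = name
                if name == "mirna":
                    if len(ids) > 1:
                        warnings.append(
                            f"read {read.id}: sequence shared by {ids}; "
                            "fractional assignment"
                        )
                    for sid in ids:
                        counts[sid] += 1.0 / len(ids)
                break
        label = assigned if assigned is not None else "genomic_other"
        class_counts[label] += 1
        classified.append(replace(read, class_label=label))

    total = max(len(reads), 1)
    summary = pd.DataFrame(
        {
            "class": list(class_counts),
            "n_reads": list(class_counts.values()),
        }
    )
    summary["fraction"] = summary["n_reads"] / total
    return counts, summary, warnings


def process_sample(
    reads: Sequence[ReadRecord] | str | Path,
    adapter: str,
    catalog: AnnotationCatalog,
    min_overlap: int = 5,
    min_mean_phred: float = 20.0,
    allow_one_mismatch: bool = False,
) -> dict:
    """Full per-sample cascade: quality -> trim -> length -> classify.

    ``reads`` may be a FASTQ path or parsed records. The returned dict
    has ``mirna_counts`` (Series), ``class_summary`` (every filter and
    catalog class, counts summing to the input read count), and
    ``warnings``.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    reads = [
        r if isinstance(r, ReadRecord)
        else ReadRecord(r.id, r.sequence, r.quality)
        for r in reads
    ]
    n_input = len(reads)
    kept_q, dropped_q = quality_filter(reads, min_mean_phred)
    trimmed = [trim_adapter(r, adapter, min_overlap) for r in kept_q]
    kept_len, dropped_len = length_filter(trimmed)
    counts, summary, warnings = classify_and_count(
        kept_len, catalog, allow_one_mismatch
    )

    filter_counts = {cls: 0 for cls in FILTER_CLASSES}
    for read in dropped_q + dropped_len:
        filter_counts[read.class_label] += 1
    filter_df = pd.DataFrame(
        {"class": list(filter_counts), "n_reads": list(filter_counts.values())}
    )
    filter_df["fraction"] = filter_df["n_reads"] / max(n_input, 1)
    summary = summary.copy()
    summary["fraction"] = summary["n_reads"] / max(n_input, 1)
    class_summary = pd.concat([filter_df, summary], ignore_index=True)
    assert int(class_summary["n_reads"].sum()) == n_input
    return {
        "mirna_counts": counts,
        "class_summary": class_summary,
        "warnings": warnings,
        "n_input_reads": n_input,
    }
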