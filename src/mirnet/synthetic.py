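"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's input surface:

``generate_counts``
    Negative-binomial (gamma-Poisson) miRNA and mRNA count matrices over
    the 18-sample design, with planted differential-expression patterns
    (opposite expression between genotypes, genotype-specific response,
    coherent response) and planted miRNA -> mRNA repression links. A truth
    table records every planted effect for recovery testing.

``generate_reads``
    Small-RNA FASTQ reads built as mature-miRNA or contaminant inserts
    plus a 3' sequencing adapter, with a manifest of each read's true
    source -- the oracle for the preprocessing cascade.

``generate_target_sequences``
    Transcript FASTA with planted miRNA binding sites (reverse complement
    of the miRNA with controlled mismatch / G:U / gap edits) embedded in
    uniform random background, plus a site truth table whose expected
    expectation scores are computed directly from the penalty constants.

All randomness flows from explicit integer seeds; identical inputs and
seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    StudyDesign,
    WITHIN_GENOTYPE_COMPARISONS,
    condition_name,
)
from .normalize import CountMatrix
from . import targets as _targets

PATTERNS = ("null", "up_R_down_S", "down_R_up_S", "R_specific", "S_specific", "coherent")

#: Default pattern mix among planted features, per feature class.
DEFAULT_MIRNA_PATTERN_WEIGHTS = {
    "up_R_down_S": 0.3,
    "down_R_up_S": 0.3,
    "R_specific": 0.2,
    "S_specific": 0.2,
}
DEFAULT_MRNA_PATTERN_WEIGHTS = {
    "up_R_down_S": 0.4,
    "down_R_up_S": 0.2,
    "coherent": 0.4,
}

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NBParams:
    """Negative-binomial count model parameters.

    ``mean_baseline`` is the expected count of an unperturbed feature;
    ``dispersion`` is the NB overdispersion (variance = mu + dispersion *
    mu^2; 0 degenerates to Poisson); ``library_size_factors`` multiply
    per-sample means (mean approximately 1).
    """

    mean_baseline: float = 100.0
    dispersion: float = 0.1
    library_size_factors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mean_baseline <= 0:
            raise ValueError("mean_baseline must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if (sf <= 0).any():
                raise ValueError("library size factors must be positive")
            if not 0.5 <= sf.mean() <= 2.0:
                raise ValueError("library size factors should average ~1")

    def size_factors(self, n_samples: int) -> np.ndarray:
        if self.library_size_factors is None:
            return np.ones(n_samples)
        sf = np.asarray(self.library_size_factors, dtype=float)
        if sf.size != n_samples:
            raise ValueError(
                f"{sf.size} size factors for {n_samples} samples"
            )
        return sf


def _pattern_offsets(
    pattern: str, effect: float, sign: int, stage_scope: str
) -> dict[str, float]:
    """Per-condition log2 offsets (relative to the genotype baseline)."""
    stages = {
        "both": ("early", "late"),
        "early": ("early",),
        "late": ("late",),
    }[stage_scope]
    off = {cond: 0.0 for g in ("S", "R") for cond in
           (condition_name(g, s) for s in ("0", "early", "late"))}
    if pattern == "null":
        return off
    for s in stages:
        if pattern == "up_R_down_S":
            off[condition_name("R", s)] = +effect
            off[condition_name("S", s)] = -effect
        elif pattern == "down_R_up_S":
            off[condition_name("R", s)] = -effect
            off[condition_name("S", s)] = +effect
        elif pattern == "R_specific":
            off[condition_name("R", s)] = sign * effect
        elif pattern == "S_specific":
            off[condition_name("S", s)] = sign * effect
        elif pattern == "coherent":
            off[condition_name("R", s)] = sign * effect
            off[condition_name("S", s)] = sign * effect
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
    return off


def _assign_patterns(
    n_planted: int, weights: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    names = list(weights)
    w = np.asarray([weights[k] for k in names], dtype=float)
    w = w / w.sum()
    return [names[i] for i in rng.choice(len(names), size=n_planted, p=w)]


def _simulate_class(
    prefix: str,
    n_features: int,
    frac_planted: float,
    weights: Mapping[str, float],
    nb: NBParams,
    design: StudyDesign,
    effect_size: float,
    stage_scope: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    width = len(str(n_features))
    ids = [f"{prefix}_{i + 1:0{width}d}" for i in range(n_features)]
    n_planted = int(round(frac_planted * n_features))
    patterns = ["null"] * (n_features - n_planted) + _assign_patterns(
        n_planted, weights, rng
    )
    signs = rng.choice([-1, 1], size=n_features)

    samples = design.sample_ids
    sf = nb.size_factors(len(samples))
    cond_of = [design.condition_of(s) for s in samples]

    mean_grid = np.empty((n_features, len(samples)))
    truth_rows = []
    for i, (fid, pat, sign) in enumerate(zip(ids, patterns, signs)):
        off = _pattern_offsets(pat, effect_size, int(sign), stage_scope)
        mean_grid[i] = [
            nb.mean_baseline * 2.0 ** off[c] for c in cond_of
        ]
        row = {"feature_id": fid, "pattern": pat}
        for lab in WITHIN_GENOTYPE_COMPARISONS:
            num, den = lab.split("/")
            row[f"lfc_{lab}"] = off[num] - off[den]
        truth_rows.append(row)
    mean_grid *= sf[None, :]

    if nb.dispersion > 0:
        lam = rng.gamma(
            shape=1.0 / nb.dispersion, scale=mean_grid * nb.dispersion
        )
    else:
        lam = mean_grid
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    truth = pd.DataFrame(truth_rows).set_index("feature_id", drop=False)
    return counts_df, truth


def generate_counts(
    design: StudyDesign,
    n_mirna: int,
    n_mrna: int,
    frac_planted: float,
    nb: NBParams,
    seed: int,
    *,
    effect_size: float = 2.0,
    stage_scope: str = "both",
    link_fraction: float = 0.5,
    mirna_pattern_weights: Mapping[str, float] | None = None,
    mrna_pattern_weights: Mapping[str, float] | None = None,
    mrna_length_range: tuple[int, int] = (500, 3000),
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Simulate miRNA and mRNA count matrices with planted structure.

    Returns ``(mirna_counts, mrna_counts, truth)``. ``truth`` has one row
    per feature: ``feature_id``, ``feature_class`` (mirna/mrna),
    ``pattern``, the planted log2 fold change per within-genotype
    comparison (``lfc_<label>`` columns), and ``repressors`` -- a
    semicolon-joined list of planted repressor miRNA ids (mRNAs only).

    ``effect_size`` is the planted per-condition offset in log2 units
    (2.0 = 4-fold); ``stage_scope`` places planted effects in both, only
    the early, or only the late feeding stage; ``link_fraction`` is the
    fraction of planted non-null mRNAs given a repressor miRNA with an
    anti-correlated pattern.
    """
    if n_mirna < 20 or n_mrna < 200:
        raise ValueError("need n_mirna >= 20 and n_mrna >= 200")
    if not 0.0 <= frac_planted < 1.0:
        raise ValueError("frac_planted must be in [0, 1)")
    if stage_scope not in ("both", "early", "late"):
        raise ValueError("stage_scope must be both/early/late")

    rng = np.random.default_rng(seed)
    mirna_counts, mirna_truth = _simulate_class(
        "mir", n_mirna, frac_planted,
        mirna_pattern_weights or DEFAULT_MIRNA_PATTERN_WEIGHTS,
        nb, design, effect_size, stage_scope, rng,
    )
    mrna_counts, mrna_truth = _simulate_class(
        "gene", n_mrna, frac_planted,
        mrna_pattern_weights or DEFAULT_MRNA_PATTERN_WEIGHTS,
        nb, design, effect_size, stage_scope, rng,
    )
    mirna_truth.insert(1, "feature_class", "mirna")
    mrna_truth.insert(1, "feature_class", "mrna")
    mirna_truth["repressors"] = ""
    mrna_truth["repressors"] = ""

    # Plant repression links: each linked mRNA gets a repressor miRNA whose
    # planted pattern is anti-correlated with the mRNA's in >= 1 comparison.
    partner = {
        "up_R_down_S": "down_R_up_S",
        "down_R_up_S": "up_R_down_S",
        # coherent targets pair with a miRNA opposite in the S stages; the
        # miRNA is still DE within R, keeping it in the selection pool.
        "coherent": None,  # resolved per sign below
    }
    mirna_by_pattern: dict[str, list[str]] = {}
    for fid, pat in zip(mirna_truth["feature_id"], mirna_truth["pattern"]):
        mirna_by_pattern.setdefault(pat, []).append(fid)
    linkable = mrna_truth[mrna_truth["pattern"].isin(partner)].index
    for fid in linkable:
        if rng.random() >= link_fraction:
            continue
        pat = mrna_truth.at[fid, "pattern"]
        if pat == "coherent":
            up = mrna_truth.at[fid, "lfc_R_early/R0"] > 0
            want = "up_R_down_S" if up else "down_R_up_S"
        else:
            want = partner[pat]
        pool = mirna_by_pattern.get(want, [])
        if not pool:
            continue
        mrna_truth.at[fid, "repressors"] = pool[rng.integers(len(pool))]

    truth = pd.concat([mirna_truth, mrna_truth], axis=0)
    lengths = pd.Series(
        rng.integers(*mrna_length_range, size=n_mrna),
        index=mrna_counts.index, name="length",
    )
    return (
        CountMatrix(mirna_counts, design),
        CountMatrix(mrna_counts, design, feature_lengths=lengths),
        truth.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Read-level simulation


def random_mirna_catalog(
    n: int, seed: int, length_range: tuple[int, int] = (20, 24)
) -> dict[str, str]:
    """Random mature-miRNA catalog (DNA alphabet, 20-24 nt)."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out[f"syn-miR-{i + 1:04d}"] = "".join(
            DNA[j] for j in rng.integers(0, 4, size=length)
        )
    return out


def random_contaminant_catalog(
    classes: Sequence[str], n_per_class: int, seed: int,
    length_range: tuple[int, int] = (20, 24),
) -> dict[str, dict[str, str]]:
    """Random contaminant catalogs keyed by class (rRNA, tRNA, ...)."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {}
    for cls in classes:
        out[cls] = {}
        for i in range(n_per_class):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            out[cls][f"{cls}_{i + 1:03d}"] = "".join(
                DNA[j] for j in rng.integers(0, 4, size=length)
            )
    return out


@dataclass
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def to_fastq(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{self.quality}\n"


def generate_reads(
    mirnas: Mapping[str, str],
    contaminants: Mapping[str, Mapping[str, str]],
    n_reads: int,
    adapter: str,
    length_noise: float,
    seed: int,
    *,
    contaminant_fraction: float = 0.5,
    read_length: int = 40,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate adapter-ligated small-RNA reads with a source manifest.

    Each read is ``insert + adapter`` truncated to ``read_length``, with a
    constant high-quality line (Phred 40). ``length_noise`` is the
    probability that an insert is perturbed by 1-3 nt at its 3' end
    (truncation or random extension), which pushes it outside the 20-24 nt
    retention window with some probability. The manifest records each
    read's true source class and id.
    """
    if not mirnas or not contaminants or not any(contaminants.values()):
        raise ValueError("miRNA and contaminant catalogs must be non-empty")
    if not 0.0 <= length_noise <= 1.0:
        raise ValueError("length_noise must be a fraction")
    for mid, seq in mirnas.items():
        if not 20 <= len(seq) <= 24:
            raise ValueError(f"mature miRNA {mid} outside 20-24 nt")

    rng = np.random.default_rng(seed)
    mirna_items = sorted(mirnas.items())
    contam_items = sorted(
        (cls, sid, seq)
        for cls, cat in contaminants.items()
        for sid, seq in cat.items()
    )
    records: list[FastqRecord] = []
    manifest_rows = []
    for i in range(n_reads):
        if rng.random() < contaminant_fraction:
            cls, sid, insert = contam_items[rng.integers(len(contam_items))]
        else:
            sid, insert = mirna_items[rng.integers(len(mirna_items))]
            cls = "mirna"
        insert = insert.upper().replace("U", "T")
        if length_noise and rng.random() < length_noise:
            delta = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                insert = insert[: max(1, len(insert) - delta)]
            else:
                insert = insert + "".join(
                    DNA[j] for j in rng.integers(0, 4, size=delta)
                )
        seq = (insert + adapter)[:read_length]
        rid = f"read_{i + 1:06d}"
        records.append(FastqRecord(rid, seq, "I" * len(seq)))
        manifest_rows.append(
            {"read_id": rid, "source_class": cls, "source_id": sid,
             "insert": insert}
        )
    manifest = pd.DataFrame(
        manifest_rows, columns=["read_id", "source_class", "source_id", "insert"]
    )
    return records, manifest


def write_fastq(records: Sequence[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_fastq())


# ---------------------------------------------------------------------------
# Target-site simulation

EDIT_TYPES = ("mismatch", "gu_wobble", "gap")


def _apply_site_edits(
    mirna_seq: str, edits: Sequence[tuple[int, str]]
) -> tuple[str, dict[str, int]]:
    """Build the target-site sequence (5'->3') for a miRNA with edits.

    The unedited site is the reverse complement of the miRNA; miRNA
    position ``i`` (1-based from the 5' end) corresponds to site index
    ``L - i`` (0-based). A mismatch replaces the site base with the miRNA
    base itself (never a pair), a G:U edit requires the miRNA base to be
    G or U, a gap deletes the site base.
    """
    m = mirna_seq.upper().replace("U", "T")
    L = len(m)
    site = list(reverse_complement(m))
    counts = {"mismatch": 0, "gu": 0, "gap": 0}
    n_gaps = sum(1 for _, e in edits if e == "gap")
    if n_gaps > 1:
        raise ValueError("at most one gap edit per site")
    for pos, edit in sorted(edits, key=lambda pe: -pe[0]):
        if not 1 <= pos <= L:
            raise ValueError(f"edit position {pos} outside miRNA 1..{L}")
        idx = L - pos
        base = m[pos - 1]
        if edit == "mismatch":
            site[idx] = base
            counts["mismatch"] += 1
        elif edit == "gu_wobble":
            if base == "G":
                site[idx] = "T"
            elif base == "T":
                site[idx] = "G"
            else:
                raise ValueError(
                    f"G:U edit needs G or U at miRNA position {pos}, got {base}"
                )
            counts["gu"] += 1
        elif edit == "gap":
            del site[idx]
            counts["gap"] += 1
        else:
            raise ValueError(f"unknown edit type {edit!r}")
    return "".join(site), counts


def expected_site_expectation(
    mirna_seq: str, edits: Sequence[tuple[int, str]],
    scoring: "_targets.ScoringScheme | None" = None,
) -> float:
    """Expectation score a site with these edits should receive.

    Computed arithmetically from the penalty constants (no alignment):
    each edit contributes its base penalty, doubled when the miRNA
    position falls in the seed region.
    """
    sc = scoring or _targets.ScoringScheme()
    penalty = {"mismatch": sc.mismatch, "gu_wobble": sc.gu_wobble, "gap": sc.gap}
    total = 0.0
    for pos, edit in edits:
        p = penalty[edit]
        if sc.seed_start <= pos <= sc.seed_end:
            p *= sc.seed_multiplier
        total += p
    return total


def generate_target_sequences(
    mirnas: Mapping[str, str],
    n_transcripts: int,
    planted_sites: Mapping[str, str],
    mutation_spec: Mapping[str, Sequence[tuple[int, str]]] | None = None,
    seed: int = 0,
    *,
    transcript_length: int = 500,
    scoring: "_targets.ScoringScheme | None" = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build transcripts with planted miRNA binding sites.

    ``planted_sites`` maps miRNA id -> transcript id (``tx_0001`` ...);
    ``mutation_spec`` maps miRNA id -> list of (1-based miRNA position,
    edit type) applied to its site. Background sequence is uniform random.

    Returns ``(transcripts, site_truth)`` where ``site_truth`` rows carry
    the planted 1-based site coordinates and the expectation score the
    site should receive under the scoring constants.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be positive")
    mutation_spec = mutation_spec or {}
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_transcripts)))
    tx_ids = [f"tx_{i + 1:0{width}d}" for i in range(n_transcripts)]
    transcripts = {
        tid: "".join(DNA[j] for j in rng.integers(0, 4, size=transcript_length))
        for tid in tx_ids
    }
    truth_rows = []
    for mid in sorted(planted_sites):
        tid = planted_sites[mid]
        if tid not in transcripts:
            raise ValueError(f"unknown transcript id {tid!r}")
        if mid not in mirnas:
            raise ValueError(f"unknown miRNA id {mid!r}")
        edits = list(mutation_spec.get(mid, []))
        site, counts = _apply_site_edits(mirnas[mid], edits)
        tx = transcripts[tid]
        if len(site) > len(tx):
            raise ValueError(
                f"planted site for {mid} ({len(site)} nt) longer than "
                f"transcript {tid} ({len(tx)} nt)"
            )
        start0 = int(rng.integers(0, len(tx) - len(site) + 1))
        transcripts[tid] = tx[:start0] + site + tx[start0 + len(site):]
        truth_rows.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "start": start0 + 1,
                "end": start0 + len(site),
                "expected_expectation": expected_site_expectation(
                    mirnas[mid], edits, scoring
                ),
                "n_mismatch": counts["mismatch"],
                "n_gu": counts["gu"],
                "n_gap": counts["gap"],
            }
        )
    site_truth = pd.DataFrame(
        truth_rows,
        columns=["mirna_id", "transcript_id", "start", "end",
                 "expected_expectation", "n_mismatch", "n_gu", "n_gap"],
    )
    return transcripts, site_truth
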