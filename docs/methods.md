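# Methods

## Study design and contrasts

The analysis is organized around a 2 × 3 factorial: genotypes
S (susceptible wild type) and R (resistant transgenic line), stages
0 (uninfested), early and late feeding, three biological replicates per
condition. All inference is performed over seven contrasts — three
between-genotype contrasts at matched stage (R0/S0, R_early/S_early,
R_late/S_late) and four within-genotype contrasts against the
uninfested baseline (S_early/S0, S_late/S0, R_early/R0, R_late/R0).
Contrast labels are always `numerator/denominator`.

## Count model and the synthetic-data generator

The generator emulates bulk short-read counting with a negative
binomial, parameterized as a gamma–Poisson mixture: for feature *f* in
sample *s*, the mean is

    mu_fs = baseline_f * 2^(offset of the sample's condition) * sizefactor_s

and counts are Poisson with a Gamma(1/phi, mu*phi)-distributed rate
(variance mu + phi*mu²). `dispersion = 0` degenerates to Poisson and is
used for "noise-free" recovery experiments. The NB is the community
standard for overdispersed RNA-seq counts; no claim is made that its
parameters are calibrated to any particular deposited dataset.

Planted patterns place log2 offsets per condition:

* `up_R_down_S` / `down_R_up_S` — opposite response between genotypes;
  by default the offset applies in **both** feeding stages (a
  `stage_scope` option restricts it to early or late only, because the
  broad selection rule accepts a single opposing stage per genotype).
* `R_specific` / `S_specific` — response (random sign) in one genotype
  only.
* `coherent` — same-direction response in both genotypes; exists so the
  integration step's similar-trend exclusion has true negatives.

Repression links attach to planted mRNAs a repressor miRNA whose
pattern is anti-correlated (opposite-pattern partner; for coherent
targets, the miRNA opposing them in the S stages, which keeps the miRNA
inside the resistance pool while the target must be excluded). Links
are recorded in the truth table; `repressors` is empty for miRNAs.

Default generator conditions: baseline 200 counts, dispersion 0.05,
effect size 2.0 log2 units (4-fold), 20 % planted features, equal
library size factors. These mirror the conditions used for the
calibration and recovery experiments below. Per-feature baselines are
constant by default so planted means are exactly `baseline * 2^offset`;
a spread can be layered on via size factors if desired.

Read simulation produces `insert + 3' adapter` truncated to 40 nt with
constant Phred-40 qualities; `length_noise` is the probability that an
insert is perturbed by 1–3 nt at its 3' end. What the generator does
**not** emulate: sequencing error profiles, PCR duplication, quality
degradation along the read, isomiRs, and hairpin precursors. Passing
recovery tests therefore demonstrate the correctness of the cascade's
logic, not robustness to platform-specific artefacts.

## Preprocessing cascade

Order: mean-Phred ≥ 20 filter → leftmost 3' adapter trim (full adapter
anywhere, or an adapter prefix of ≥ 5 nt reaching the read end) →
poly-A removal (≥ 80 % adenine after trimming) → 20–24 nt retention →
ordered exact-match annotation, first match wins, mature miRNAs last.
Unmatched reads are binned `genomic_other`, the stand-in for
genome-mapped exon/intron/repeat reads (genome alignment is out of
scope). Numerical choices that had to be fixed: the poly-A fraction
(0.8), the quality floor (Phred 20), and exact string matching with an
optional 1-mismatch mode (off by default) instead of alignment —
adequate for mature-miRNA counting where reads are the catalog
sequences themselves. A read whose sequence is shared by several
mature miRNA ids is assigned fractionally (1/k to each), logged.
Trimming is idempotent by construction (trimmed records pass through).

## Normalization and reference-gene stability

RPM = count/library_total × 1e6; RPKM = RPM / (length/1e3); RPKM and
FPKM are treated as synonymous single-end quantities. Expression per
condition is the arithmetic mean over replicates. Candidate qPCR
reference genes are ranked by the coefficient of variation (sample SD,
ddof = 1, over mean) of their six condition means; CV > 0.30 flags a
candidate unstable and a configurable floor flags low expression. The
CV statistic and its 0.30 default are this package's quantitative
operationalization of what is otherwise a visual stability check.

## Differential expression

log2FC = log2((μ_num + c)/(μ_den + c)) on normalized per-condition
means with pseudocount c = 1 normalized unit, which keeps fold changes
finite at zero means. Significance is Welch's two-sample t on
log2(x + c) across replicates; rows with zero variance on both sides
get p = 1 when the means agree and p = 0 otherwise. FDR is
Benjamini–Hochberg within each contrast. The empirical-Bayes NB
machinery often used for such data is deliberately replaced by this
fully specified test so the pipeline has no black-box dependency; the
thresholds are kept as stated above (miRNA: FC ≥ 2, P < 0.05; mRNA:
|log2FC| ≥ 1, FDR < 0.05 — the two threshold sets are configurable
because it is ambiguous whether miRNA calls were additionally
FDR-filtered in the original design).

Calibration and power at the default conditions (verified by the
acceptance suite): on pure-null NB data (1000 features, baseline 200,
dispersion 0.05, n = 3, three seeds) the fraction of p < 0.05 falls in
[0.03, 0.07] — Welch-on-log2 at n = 3 is mildly conservative. On
200 null + 50 planted 4-fold features (balanced up/down so that
library-composition shifts largely cancel) the P-based threshold set
attains sensitivity ≥ 0.9 at empirical FDR ≤ 0.10. The FDR-based mRNA
mode is noticeably less sensitive at these sizes — a known cost of
requiring FDR < 0.05 with three replicates — which is why the strict
candidate tier under-recovers at the default noise level and recovers
exactly as noise vanishes.

A note on library composition: with a small feature universe and
unbalanced planted effects, total-count normalization shifts null
features' apparent fold changes (the classic composition effect).
Balanced planting keeps this shift well below the |log2FC| ≥ 1 call
threshold at the default conditions; TMM/median-of-ratios corrections
are intentionally out of scope because the pipeline's contract is
plain RPM/RPKM.

## Selection cascade

All selections are pure functions of the DE table:

* **Venn membership** — the signature of contrasts where a feature is
  DE; region counts reproduce Venn-diagram counting.
* **Opposite between genotypes** — DE in R0/S0 and DE with the
  opposite sign in ≥ 1 post-feeding between-genotype contrast.
* **Opposite within genotypes** — DE in ≥ 1 S-stage and ≥ 1 R-stage
  contrast with opposite signs and no sign conflict within a genotype
  (two DE stages of one genotype must agree).
* **Genotype-specific** — DE in both stage contrasts of one genotype
  and ns in both of the other.
* **Candidate tier** — the strict form: significant, sign-coherent,
  opposite response in all four within-genotype contrasts. By
  construction candidate genes ⊆ opposite-within set.

The broad/strict split operationalizes "opposite during early or late
stages": one opposing stage per genotype suffices for the broad set,
while published candidate rows are DE in all four columns, hence the
all-four rule for the candidate tier. `candidates_from_log2fc` applies
the same sign rule to a bare fold-change matrix (|log2FC| ≥ 1 standing
in for the significance calls), which is how the printed candidate
table is re-classified.

## Target prediction

The scorer aligns the miRNA 5'→3' antiparallel to a transcript window
(window 5'→3' on the sense strand; miRNA position 1 pairs the window's
last base). Per-position penalties: Watson–Crick 0, G:U wobble 0.5,
mismatch 1, indel 2; each penalty doubles when the miRNA position lies
in the seed region, positions 2–13 from the 5' end. The expectation is
the penalty sum; hits require expectation ≤ cutoff (default 5.0, the
psRNATarget-style default — server versions differ between 3.0 and
5.0, so the cutoff is exposed). The search slides windows of length
L−1, L and L+1 (one indel at most), minimizing over all gap
placements; a target-side bulge between miRNA positions g and g+1
takes the seed multiplier of position min(g+1, L). The scan is exact
at miRNA scale, so no dynamic programming is needed; overlapping
candidate windows are merged keeping the minimum expectation, ties
broken by position. Site coordinates are 1-based inclusive on the
transcript. Translation-inhibition classification (central-region
rules) and accessibility/energy terms are not emulated.

## Integration

"Negative correlation" is direction opposition of DE calls within a
shared contrast — a set operation, not a Pearson correlation across
samples, because the quantities of interest are per-contrast pair
counts. The resistance filter keeps pairs whose miRNA is DE within the
resistant genotype (R_early/R0 or R_late/R0) or opposite-expressed
between genotypes, then excludes pairs whose target shows a
similar trend: a same-direction significant call in ≥ 1 S-stage and
≥ 1 R-stage contrast (a weaker numeric same-sign variant is available
via `require_significant_trend=False`). Whether the miRNA pool should
also include between-genotype DEMs is left to the caller — the pool is
an explicit argument.

## Enrichment and qPCR

Over-representation is the one-sided hypergeometric tail
P(X ≥ k | N, K, n) with BH FDR across the tested terms of a namespace;
only terms overlapping the selection appear. The universe defaults to
the expressed genes of the experiment rather than a genome-wide set —
the standard conservative background. 2^-ΔΔCt uses fixed amplification
efficiency 2.0; ΔCt = mean Ct(target) − mean Ct(reference) per
condition, ΔΔCt referenced to a calibrator condition which therefore
scores exactly 1. Concordance is the plain Pearson r (and r²) of qPCR
vs sequencing log2 fold changes; fewer than three points or zero
variance is reported as undefined.

## Orchestration and determinism

`run_pipeline` executes preprocess (optional) → normalize → DE →
selection → targets → integration → enrichment, writing each
intermediate as TSV plus a JSON manifest (seed, parameter hash,
per-stage row counts). All randomness derives from the single config
seed through fixed per-stage arithmetic, so identical config + seed
yields byte-identical bundles. The demo problem sizes (60 miRNAs,
300 mRNAs, 18 samples, 5000 reads, 300-nt transcripts) keep a full run
under a second while leaving every selection non-trivially populated;
they are the package's default desk-scale conditions, and the
acceptance suite uses the same scales.

## Known limitations

* Exact-match annotation cannot represent cross-mapping or isomiR
  ambiguity beyond the fractional-assignment rule.
* Welch-on-log2 with n = 3 is conservative; FDR-thresholded calls at
  these sample sizes favour precision over recall.
* The target scorer is a complementarity model only — no accessibility,
  conservation or degradome evidence.
* The similar-trend exclusion depends on significance calls; a target
  under-powered in one genotype can escape exclusion.
* Fixture tables transcribe a print layout in which some sparse
  fold-change cells are blank; blank cells are preserved, and pair
  rows expand family blocks to explicit (miRNA, target) pairs.
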