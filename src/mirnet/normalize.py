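"""Count containers, library-size normalization, replicate averaging, and
reference-gene stability ranking.

miRNA counts are normalized to reads per million (RPM); mRNA counts to
reads per kilobase of transcript per million mapped reads (RPKM, treated
as synonymous with FPKM for this single-end-style quantification).
Downstream fold changes are computed on per-condition means of the
normalized replicate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign


@dataclass
class CountMatrix:
    """Integer feature x sample count grid bound to a :class:`StudyDesign`.

    ``counts`` rows are features, columns are the design's sample ids.
    ``feature_lengths`` (nt) is required only for RPKM normalization.
    """

    counts: pd.DataFrame
    design: StudyDesign
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        expected = set(self.design.sample_ids)
        got = set(self.counts.columns)
        if got != expected:
            raise ValueError(
                f"sample ids do not match design (missing {sorted(expected - got)[:3]}, "
                f"extra {sorted(got - expected)[:3]})"
            )
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("counts must be finite and non-negative")
        if self.feature_lengths is not None:
            missing = self.counts.index.difference(self.feature_lengths.index)
            if len(missing):
                raise ValueError(f"feature_lengths missing for {list(missing[:3])}")
            if (self.feature_lengths.loc[self.counts.index] <= 0).any():
                raise ValueError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        design: StudyDesign,
        feature_lengths: pd.Series | None = None,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(df, design, feature_lengths)


@dataclass
class ExprMatrix:
    """Normalized abundances on the same axes as the source counts."""

    values: pd.DataFrame
    design: StudyDesign
    unit: str  # "rpm" or "rpkm"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def normalize(counts: CountMatrix, method: str = "rpm") -> ExprMatrix:
    """Normalize a count matrix to RPM or RPKM.

    RPM = count / library_total * 1e6.
    RPKM = count / (library_total/1e6 * length/1e3).
    """
    if method not in ("rpm", "rpkm"):
        raise ValueError(f"unknown normalization method {method!r}")
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero library total for samples {bad}")
    rpm = counts.counts / totals * 1e6
    if method == "rpm":
        return ExprMatrix(rpm, counts.design, "rpm")
    if counts.feature_lengths is None:
        raise ValueError("rpkm normalization requires feature_lengths")
    kb = counts.feature_lengths.loc[counts.counts.index] / 1e3
    return ExprMatrix(rpm.div(kb, axis=0), counts.design, "rpkm")


def condition_means(expr: ExprMatrix) -> pd.DataFrame:
    """Arithmetic mean of replicate values per (feature, condition).

    Mirrors the study's use of the average normalized reads of the three
    biological replicates as the per-condition expression value.
    """
    design = expr.design
    if design.replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    out = {}
    for cond in design.conditions:
        out[cond] = expr.values[design.samples_of(cond)].mean(axis=1)
    return pd.DataFrame(out)


def replicate_values(expr: ExprMatrix, condition: str) -> pd.DataFrame:
    """Replicate columns of one condition (features x replicates)."""
    return expr.values[expr.design.samples_of(condition)]


def reference_stability(
    expr: ExprMatrix,
    candidates: list[str],
    cv_threshold: float = 0.30,
    expression_floor: float = 1.0,
) -> pd.DataFrame:
    """Rank candidate qPCR reference genes by expression stability.

    Stability is the coefficient of variation (sample SD / mean, ddof=1) of
    the six per-condition mean expression values; candidates are ranked
    ascending by CV. A candidate is flagged ``unstable`` when its CV exceeds
    ``cv_threshold`` and ``low_expression`` when its grand mean falls below
    ``expression_floor``. Candidates absent from the matrix are listed with
    status ``missing``.
    """
    columns = ["candidate", "status", "cv", "mean", "unstable",
               "low_expression"]
    if not candidates:
        return pd.DataFrame(columns=columns + ["rank"])
    means = condition_means(expr)
    rows = []
    for cand in candidates:
        if cand not in means.index:
            rows.append(
                {"candidate": cand, "status": "missing", "cv": np.nan,
                 "mean": np.nan, "unstable": None, "low_expression": None}
            )
            continue
        vals = means.loc[cand].to_numpy(dtype=float)
        mean = float(vals.mean())
        cv = float(vals.std(ddof=1) / mean) if mean > 0 else np.inf
        rows.append(
            {"candidate": cand, "status": "ok", "cv": cv, "mean": mean,
             "unstable": bool(cv > cv_threshold),
             "low_expression": bool(mean < expression_floor)}
        )
    report = pd.DataFrame(rows)
    present = report[report["status"] == "ok"].sort_values(
        "cv", kind="mergesort"
    )
    report.loc[present.index, "rank"] = np.arange(1, len(present) + 1)
    return report.sort_values(
        ["status", "rank"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
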