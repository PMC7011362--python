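"""Per-feature, per-contrast differential expression calling.

Fold change is the ratio of pseudocounted per-condition means of
normalized expression, log2((mean_num + c)/(mean_den + c)) with c = 1
normalized unit, so zero means never produce infinite fold changes.
Significance comes from Welch's two-sample t-test on log2(value + c)
across replicates, with Benjamini-Hochberg FDR within each contrast.

Two threshold presets mirror the study's two stated filters: miRNAs are
called at |log2FC| >= 1 and P < 0.05; mRNAs at |log2FC| >= 1 and
FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import Comparison, default_scheme
from .normalize import ExprMatrix, replicate_values


@dataclass(frozen=True)
class Thresholds:
    """DE call thresholds; ``None`` disables a filter."""

    log2fc_min: float = 1.0
    p_max: float | None = 0.05
    fdr_max: float | None = None


#: miRNA mode: fold change >= 2 and P < 0.05 on replicate means.
MIRNA_THRESHOLDS = Thresholds(log2fc_min=1.0, p_max=0.05, fdr_max=None)
#: mRNA mode: |log2FC| >= 1 and FDR < 0.05.
MRNA_THRESHOLDS = Thresholds(log2fc_min=1.0, p_max=None, fdr_max=0.05)

PSEUDOCOUNT = 1.0


def _welch_log_p(num: np.ndarray, den: np.ndarray, c: float) -> np.ndarray:
    """Welch t-test p-values on log2(x + c), rowwise; degenerate rows
    (zero variance on both sides) get p = 1 when the means agree and
    p = 0 otherwise."""
    import warnings

    a = np.log2(num + c)
    b = np.log2(den + c)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicate vectors trigger a scipy precision
        # warning; those rows are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    bad = ~np.isfinite(p)
    if bad.any():
        diff = a[bad].mean(axis=1) - b[bad].mean(axis=1)
        p[bad] = np.where(np.abs(diff) < 1e-12, 1.0, 0.0)
    return p


def de_test(
    expr: ExprMatrix,
    comparison: Comparison | str,
    thresholds: Thresholds = MIRNA_THRESHOLDS,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """DE records for one contrast.

    Returns one row per feature: ``feature_id, comparison, log2fc,
    pvalue, fdr, direction`` with direction ``up``/``down``/``ns`` under
    the threshold rule.
    """
    if isinstance(comparison, str):
        comparison = Comparison.from_label(comparison)
    comparison.validate(expr.design)
    if expr.design.replicates_per_condition < 2:
        raise ValueError("de_test needs >= 2 replicates per condition")

    num = replicate_values(expr, comparison.numerator).to_numpy(dtype=float)
    den = replicate_values(expr, comparison.denominator).to_numpy(dtype=float)
    if (num < 0).any() or (den < 0).any():
        raise ValueError("expression values must be non-negative")

    c = pseudocount
    log2fc = np.log2(num.mean(axis=1) + c) - np.log2(den.mean(axis=1) + c)
    pvalue = _welch_log_p(num, den, c)
    fdr = multipletests(pvalue, method="fdr_bh")[1]

    significant = np.ones(len(pvalue), dtype=bool)
    if thresholds.p_max is not None:
        significant &= pvalue < thresholds.p_max
    if thresholds.fdr_max is not None:
        significant &= fdr < thresholds.fdr_max
    direction = np.where(
        significant & (log2fc >= thresholds.log2fc_min), "up",
        np.where(significant & (log2fc <= -thresholds.log2fc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "comparison": comparison.label,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "direction": direction,
        }
    )


def run_all_comparisons(
    expr_mirna: ExprMatrix | None,
    expr_mrna: ExprMatrix | None,
    scheme: list[Comparison] | None = None,
    mirna_thresholds: Thresholds = MIRNA_THRESHOLDS,
    mrna_thresholds: Thresholds = MRNA_THRESHOLDS,
) -> pd.DataFrame:
    """DE records for every (feature, contrast) over both feature classes.

    The scheme defaults to the seven study contrasts. The returned table
    adds a ``feature_class`` column (``mirna``/``mrna``).
    """
    scheme = default_scheme() if scheme is None else scheme
    frames = []
    for expr, cls, thr in (
        (expr_mirna, "mirna", mirna_thresholds),
        (expr_mrna, "mrna", mrna_thresholds),
    ):
        if expr is None:
            continue
        for comparison in scheme:
            part = de_test(expr, comparison, thr)
            part.insert(1, "feature_class", cls)
            frames.append(part)
    if not frames:
        return pd.DataFrame(
            columns=["feature_id", "feature_class", "comparison", "log2fc",
                     "pvalue", "fdr", "direction"]
        )
    return pd.concat(frames, ignore_index=True)


def summarize_counts(de_table: pd.DataFrame) -> pd.DataFrame:
    """Up/down call counts per contrast and feature class (the study's
    bookkeeping table)."""
    if de_table.empty:
        return pd.DataFrame(columns=["feature_class", "comparison", "up", "down"])
    grouped = (
        de_table[de_table["direction"] != "ns"]
        .groupby(["feature_class", "comparison", "direction"])
        .size()
        .unstack("direction", fill_value=0)
    )
    for col in ("up", "down"):
        if col not in grouped:
            grouped[col] = 0
    return grouped[["up", "down"]].reset_index()
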