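"""Relative qPCR quantification (2^-ddCt) and sequencing concordance.

Expression of a target is normalized to a reference gene within each
condition (dCt = mean Ct_target - mean Ct_reference), referenced to a
calibrator condition (ddCt = dCt_condition - dCt_calibrator), and
reported as 2^-ddCt; the calibrator is exactly 1 by construction.
Amplification efficiency is fixed at 2.0 per cycle.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

CtTable = Mapping[str, Sequence[float]]  # condition -> replicate Ct values


def _mean_ct(table: CtTable, condition: str, who: str) -> float:
    try:
        values = np.asarray(table[condition], dtype=float)
    except KeyError:
        raise ValueError(f"{who} has no Ct values for condition {condition!r}")
    if values.size == 0 or not np.isfinite(values).all():
        raise ValueError(f"{who} Ct values for {condition!r} must be finite")
    return float(values.mean())


def ddct(
    target: CtTable,
    reference: CtTable,
    calibrator: str,
) -> pd.Series:
    """Per-condition relative expression 2^-ddCt.

    ``target`` and ``reference`` map condition -> replicate Ct values;
    the reference must be measured in every condition the target is.
    """
    if calibrator not in target:
        raise ValueError(f"calibrator condition {calibrator!r} not measured")
    dct = {}
    for cond in target:
        dct[cond] = _mean_ct(target, cond, "target") - _mean_ct(
            reference, cond, "reference"
        )
    base = dct[calibrator]
    return pd.Series(
        {cond: 2.0 ** -(d - base) for cond, d in dct.items()},
        name="relative_expression",
    )


def concordance(
    qpcr_log2fc: Sequence[float], seq_log2fc: Sequence[float]
) -> dict[str, float]:
    """Pearson correlation between qPCR and sequencing log2 fold changes.

    Returns ``{"r": ..., "r2": ...}``; with fewer than 3 points or zero
    variance in either vector the correlation is undefined and NaN is
    reported.
    """
    x = np.asarray(qpcr_log2fc, dtype=float)
    y = np.asarray(seq_log2fc, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired fold changes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fold changes must be finite")
    if x.std() == 0 or y.std() == 0:
        return {"r": float("nan"), "r2": float("nan")}
    r = float(pearsonr(x, y).statistic)
    return {"r": r, "r2": r * r}
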