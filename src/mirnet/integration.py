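"""miRNA-mRNA pair integration: anti-correlation and the resistance filter.

"Negative correlation" is implemented as direction opposition of DE
calls within a shared contrast: a predicted (miRNA, target) pair is
supported in contrast c when both members are DE in c with opposite
directions. The resistance filter then keeps pairs whose miRNA belongs
to the resistance-related pool (DE within the resistant genotype, or
opposite-expressed between genotypes after feeding) and drops pairs
whose target shows a similar trend -- a same-direction significant call
in at least one susceptible-stage and one resistant-stage contrast.
"""

from __future__ import annotations

import pandas as pd

from .design import (
    R_STAGE_COMPARISONS,
    S_STAGE_COMPARISONS,
    WITHIN_GENOTYPE_COMPARISONS,
)

_PAIR_COLUMNS = [
    "mirna_id", "target_id", "comparison",
    "mirna_direction", "target_direction", "mirna_log2fc", "target_log2fc",
]


def anti_correlated_pairs(
    dem_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    hits: pd.DataFrame,
) -> pd.DataFrame:
    """Per-contrast anti-correlated (miRNA, target) pairs.

    ``hits`` is a predicted-target table with ``mirna_id`` and
    ``transcript_id`` columns (e.g. from :func:`mirnet.targets.predict_all`).
    Returns one row per (pair, contrast) where both members are DE with
    opposite directions and the pair is predicted.
    """
    if hits.empty:
        return pd.DataFrame(columns=_PAIR_COLUMNS)
    dem = dem_table[dem_table["direction"] != "ns"][
        ["feature_id", "comparison", "direction", "log2fc"]
    ].rename(
        columns={
            "feature_id": "mirna_id",
            "direction": "mirna_direction",
            "log2fc": "mirna_log2fc",
        }
    )
    deg = deg_table[deg_table["direction"] != "ns"][
        ["feature_id", "comparison", "direction", "log2fc"]
    ].rename(
        columns={
            "feature_id": "target_id",
            "direction": "target_direction",
            "log2fc": "target_log2fc",
        }
    )
    pairs = hits[["mirna_id", "transcript_id"]].drop_duplicates().rename(
        columns={"transcript_id": "target_id"}
    )
    merged = pairs.merge(dem, on="mirna_id").merge(
        deg, on=["target_id", "comparison"]
    )
    merged = merged[merged["mirna_direction"] != merged["target_direction"]]
    return (
        merged[_PAIR_COLUMNS]
        .sort_values(["mirna_id", "target_id", "comparison"], kind="mergesort")
        .reset_index(drop=True)
    )


def similar_trend_targets(
    deg_table: pd.DataFrame,
    require_significant: bool = True,
) -> set[str]:
    """Targets with a same-direction call in >= 1 S-stage and >= 1 R-stage
    contrast (the exclusion rule of the integration step).

    With ``require_significant=False`` the weaker numeric notion is used:
    same-sign log2FC of magnitude >= 1 without a significance call.
    """
    sub = deg_table[
        deg_table["comparison"].isin(WITHIN_GENOTYPE_COMPARISONS)
    ].copy()
    if require_significant:
        sub = sub[sub["direction"] != "ns"]
        sub["sign"] = sub["direction"].map({"up": 1, "down": -1})
    else:
        sub = sub[sub["log2fc"].abs() >= 1.0]
        sub["sign"] = sub["log2fc"].gt(0).map({True: 1, False: -1})
    out: set[str] = set()
    for fid, grp in sub.groupby("feature_id"):
        s_signs = set(grp.loc[grp["comparison"].isin(S_STAGE_COMPARISONS), "sign"])
        r_signs = set(grp.loc[grp["comparison"].isin(R_STAGE_COMPARISONS), "sign"])
        if s_signs & r_signs:
            out.add(fid)
    return out


def resistance_pair_filter(
    pairs: pd.DataFrame,
    mirna_pool_r: set[str],
    mirna_pool_opposite: set[str],
    deg_table: pd.DataFrame,
    require_significant_trend: bool = True,
) -> pd.DataFrame:
    """Keep resistance-related pairs and drop similar-trend targets.

    ``mirna_pool_r`` is the set of miRNAs DE in R_early/R0 or R_late/R0;
    ``mirna_pool_opposite`` the set opposite-expressed between genotypes
    after feeding. A pair is kept when its miRNA is in the union of the
    two pools and its target is not a similar-trend gene. The output is
    one row per retained pair with its supporting contrasts joined and a
    ``reason`` column (``mirna_R_specific`` / ``mirna_opposite``).
    """
    if pairs.empty:
        return pd.DataFrame(
            columns=["mirna_id", "target_id", "supporting_comparisons", "reason"]
        )
    pool = set(mirna_pool_r) | set(mirna_pool_opposite)
    kept = pairs[pairs["mirna_id"].isin(pool)]
    excluded = similar_trend_targets(deg_table, require_significant_trend)
    kept = kept[~kept["target_id"].isin(excluded)]
    if kept.empty:
        return pd.DataFrame(
            columns=["mirna_id", "target_id", "supporting_comparisons", "reason"]
        )
    grouped = (
        kept.groupby(["mirna_id", "target_id"])["comparison"]
        .apply(lambda s: ",".join(sorted(s)))
        .rename("supporting_comparisons")
        .reset_index()
    )
    grouped["reason"] = [
        "mirna_R_specific" if mid in mirna_pool_r else "mirna_opposite"
        for mid in grouped["mirna_id"]
    ]
    return grouped.sort_values(
        ["mirna_id", "target_id"], kind="mergesort"
    ).reset_index(drop=True)


def pair_report(
    pairs: pd.DataFrame,
    mirna_log2fc: pd.DataFrame | None = None,
    target_log2fc: pd.DataFrame | None = None,
    descriptions: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flat report of candidate pairs with per-member fold changes.

    ``mirna_log2fc`` / ``target_log2fc`` are feature x comparison frames
    over the four within-genotype contrasts; missing members are left
    blank. Returns the report and summary counts of distinct miRNAs and
    distinct targets.
    """
    cols = ["mirna_id"]
    cols += [f"mirna_lfc_{lab}" for lab in WITHIN_GENOTYPE_COMPARISONS]
    cols += ["target_id"]
    cols += [f"target_lfc_{lab}" for lab in WITHIN_GENOTYPE_COMPARISONS]
    cols += ["description"]
    if pairs.empty:
        report = pd.DataFrame(columns=cols)
        return report, {"n_mirna": 0, "n_target": 0}
    rows = []
    ordered = pairs.sort_values(["mirna_id", "target_id"], kind="mergesort")
    for _, pr in ordered.iterrows():
        row = {"mirna_id": pr["mirna_id"], "target_id": pr["target_id"]}
        for lab in WITHIN_GENOTYPE_COMPARISONS:
            row[f"mirna_lfc_{lab}"] = (
                mirna_log2fc.at[pr["mirna_id"], lab]
                if mirna_log2fc is not None and pr["mirna_id"] in mirna_log2fc.index
                and lab in mirna_log2fc.columns else None
            )
            row[f"target_lfc_{lab}"] = (
                target_log2fc.at[pr["target_id"], lab]
                if target_log2fc is not None and pr["target_id"] in target_log2fc.index
                and lab in target_log2fc.columns else None
            )
        row["description"] = (
            descriptions.get(pr["target_id"], "")
            if descriptions is not None else ""
        )
        rows.append(row)
    report = pd.DataFrame(rows, columns=cols)
    summary = {
        "n_mirna": int(report["mirna_id"].nunique()),
        "n_target": int(report["target_id"].nunique()),
    }
    return report, summary
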