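"""Set logic and sign-opposition classifiers over the DE table.

"Resistance-related" features are defined purely by the pattern of their
DE calls across the seven contrasts: Venn membership across chosen
contrasts, opposite expression between genotypes (before vs after
feeding), opposite expression within genotypes (susceptible stages one
way, resistant stages the other), genotype-specific response, and the
strict candidate tier requiring significant opposite response in all
four within-genotype contrasts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    BETWEEN_GENOTYPE_COMPARISONS,
    R_STAGE_COMPARISONS,
    S_STAGE_COMPARISONS,
    SEVEN_COMPARISONS,
    WITHIN_GENOTYPE_COMPARISONS,
)

_SIGN = {"up": 1, "down": -1, "ns": 0}


@dataclass
class ProfileTable:
    """Per-feature direction and log2FC maps over a contrast scheme.

    ``direction`` and ``log2fc`` are feature x comparison frames with
    identical axes; ``direction`` entries are ``up``/``down``/``ns``.
    """

    direction: pd.DataFrame
    log2fc: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.direction.index.equals(self.log2fc.index) or not (
            self.direction.columns.equals(self.log2fc.columns)
        ):
            raise ValueError("direction and log2fc must share axes")

    @property
    def comparisons(self) -> list[str]:
        return list(self.direction.columns)

    def signs(self) -> pd.DataFrame:
        """+1 / -1 for significant up / down calls, 0 for ns."""
        return self.direction.apply(lambda col: col.map(_SIGN)).astype(int)


def build_profiles(
    de_table: pd.DataFrame,
    comparisons: list[str] | None = None,
    feature_class: str | None = None,
) -> ProfileTable:
    """Pivot a DE table into a :class:`ProfileTable`."""
    table = de_table
    if feature_class is not None:
        table = table[table["feature_class"] == feature_class]
    comparisons = list(comparisons or SEVEN_COMPARISONS)
    table = table[table["comparison"].isin(comparisons)]
    direction = table.pivot(
        index="feature_id", columns="comparison", values="direction"
    ).reindex(columns=comparisons)
    log2fc = table.pivot(
        index="feature_id", columns="comparison", values="log2fc"
    ).reindex(columns=comparisons)
    if direction.isna().any().any():
        raise ValueError("DE table does not cover every (feature, comparison)")
    return ProfileTable(direction, log2fc)


def venn_membership(
    de_table: pd.DataFrame, comparisons: list[str]
) -> tuple[dict[str, frozenset[str]], Counter]:
    """Membership signatures for Venn-diagram counting.

    Returns ``(signatures, region_counts)`` where a feature's signature
    is the subset of ``comparisons`` in which it is DE, and
    ``region_counts`` counts features per non-empty signature.
    """
    known = set(de_table["comparison"].unique())
    for lab in comparisons:
        if lab not in known:
            raise ValueError(f"unknown comparison label {lab!r}")
    sub = de_table[
        de_table["comparison"].isin(comparisons)
        & (de_table["direction"] != "ns")
    ]
    signatures: dict[str, frozenset[str]] = {
        fid: frozenset() for fid in de_table["feature_id"].unique()
    }
    for fid, group in sub.groupby("feature_id"):
        signatures[fid] = frozenset(group["comparison"])
    region_counts: Counter = Counter(
        sig for sig in signatures.values() if sig
    )
    return signatures, region_counts


def opposite_between_genotypes(profiles: ProfileTable) -> pd.DataFrame:
    """Features DE before feeding (R0/S0) that flip sign after feeding.

    Selected iff DE in R0/S0 and DE with the opposite sign in at least
    one of R_early/S_early, R_late/S_late. The ``flip`` column records
    the direction of the reversal.
    """
    labels = list(BETWEEN_GENOTYPE_COMPARISONS)
    signs = profiles.signs()[labels]
    before = signs["R0/S0"]
    after = signs[["R_early/S_early", "R_late/S_late"]]
    flipped = (after.mul(before, axis=0) == -1).any(axis=1) & (before != 0)
    out = pd.DataFrame(
        {
            "feature_id": signs.index[flipped],
            "flip": np.where(
                before[flipped] > 0, "up_before_down_after", "down_before_up_after"
            ),
        }
    )
    return out.reset_index(drop=True)


def _genotype_signs(
    signs: pd.DataFrame, labels: tuple[str, str]
) -> tuple[pd.Series, pd.Series]:
    """(consistent per-genotype sign, conflict flag) over two stage contrasts.

    The sign is the shared direction of the significant calls (0 when
    neither stage is DE); a conflict is both stages DE with opposite signs.
    """
    a, b = (signs[lab] for lab in labels)
    conflict = (a * b) == -1
    sign = np.sign(a + b).astype(int)
    return pd.Series(sign, index=signs.index), conflict


def opposite_within_genotypes(profiles: ProfileTable) -> pd.DataFrame:
    """Features responding in opposite directions in the two genotypes.

    Selected iff DE in >= 1 susceptible-stage contrast and >= 1
    resistant-stage contrast with opposite signs, with no sign conflict
    within either genotype. The ``pattern`` column is ``up_R_down_S`` or
    ``down_R_up_S``.
    """
    signs = profiles.signs()
    s_sign, s_conflict = _genotype_signs(signs, S_STAGE_COMPARISONS)
    r_sign, r_conflict = _genotype_signs(signs, R_STAGE_COMPARISONS)
    selected = (
        (s_sign != 0) & (r_sign != 0) & (s_sign != r_sign)
        & ~s_conflict & ~r_conflict
    )
    out = pd.DataFrame(
        {
            "feature_id": signs.index[selected],
            "pattern": np.where(
                r_sign[selected] > 0, "up_R_down_S", "down_R_up_S"
            ),
        }
    )
    return out.reset_index(drop=True)


def genotype_specific(profiles: ProfileTable, genotype: str) -> pd.DataFrame:
    """Features DE in both stage contrasts of one genotype and ns in both
    stage contrasts of the other."""
    if genotype not in ("S", "R"):
        raise ValueError("genotype must be 'S' or 'R'")
    own = R_STAGE_COMPARISONS if genotype == "R" else S_STAGE_COMPARISONS
    other = S_STAGE_COMPARISONS if genotype == "R" else R_STAGE_COMPARISONS
    signs = profiles.signs()
    selected = (signs[list(own)] != 0).all(axis=1) & (
        signs[list(other)] == 0
    ).all(axis=1)
    out = pd.DataFrame({"feature_id": signs.index[selected]})
    out["genotype"] = genotype
    return out.reset_index(drop=True)


def classify_sign_pattern(
    log2fc: pd.DataFrame, log2fc_min: float = 1.0
) -> pd.Series:
    """Classify rows of a four-column within-genotype log2FC matrix.

    A row is ``up_R_down_S`` when both S values are <= -log2fc_min and
    both R values are >= +log2fc_min, ``down_R_up_S`` for the mirror
    pattern, and ``none`` otherwise. Used both on DE-call fold changes
    and on printed fold-change tables where only the FC matrix is known.
    """
    s = log2fc[list(S_STAGE_COMPARISONS)].to_numpy(dtype=float)
    r = log2fc[list(R_STAGE_COMPARISONS)].to_numpy(dtype=float)
    up_r = (s <= -log2fc_min).all(axis=1) & (r >= log2fc_min).all(axis=1)
    down_r = (s >= log2fc_min).all(axis=1) & (r <= -log2fc_min).all(axis=1)
    return pd.Series(
        np.where(up_r, "up_R_down_S", np.where(down_r, "down_R_up_S", "none")),
        index=log2fc.index,
    )


def candidate_genes(
    profiles: ProfileTable, log2fc_min: float = 1.0
) -> pd.DataFrame:
    """The strict candidate tier: significant opposite response in all
    four within-genotype contrasts.

    Each selected row carries the four log2 fold changes and the class
    (``up_R_down_S`` / ``down_R_up_S``); by construction the output is a
    subset of :func:`opposite_within_genotypes`.
    """
    labels = list(WITHIN_GENOTYPE_COMPARISONS)
    signs = profiles.signs()[labels]
    all_de = (signs != 0).all(axis=1)
    pattern = classify_sign_pattern(profiles.log2fc[labels], log2fc_min)
    selected = all_de & (pattern != "none")
    out = profiles.log2fc.loc[selected, labels].copy()
    out.insert(0, "feature_id", out.index)
    out["pattern"] = pattern[selected]
    return out.reset_index(drop=True)


def candidates_from_log2fc(
    log2fc: pd.DataFrame, log2fc_min: float = 1.0
) -> pd.DataFrame:
    """Apply the candidate rule to a bare four-column log2FC matrix
    (e.g. a published candidate table), with |log2FC| >= threshold
    standing in for the significance calls."""
    pattern = classify_sign_pattern(log2fc, log2fc_min)
    out = log2fc.loc[pattern != "none", list(WITHIN_GENOTYPE_COMPARISONS)].copy()
    out.insert(0, "feature_id", out.index)
    out["pattern"] = pattern[pattern != "none"]
    return out.reset_index(drop=True)
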