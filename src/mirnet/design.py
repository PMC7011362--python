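"""Study design: genotypes, feeding stages, replicates, and contrast scheme.

The experimental layout is a 2 x 3 factorial: two rice genotypes -- the
resistant *BPH6*-transgenic line (``R``) and the susceptible wild type
(``S``) -- sampled uninfested (stage ``0``) and at pooled early and late
brown-planthopper feeding stages, with three biological replicates per
condition (18 libraries in total).

Differential expression is evaluated over seven contrasts: three
between-genotype contrasts at matched stages and four within-genotype
contrasts against the uninfested baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field


GENOTYPES = ("S", "R")
STAGES = ("0", "early", "late")

#: Between-genotype contrasts at matched stage.
BETWEEN_GENOTYPE_COMPARISONS = ("R0/S0", "R_early/S_early", "R_late/S_late")
#: Within-genotype contrasts versus the uninfested baseline.
WITHIN_GENOTYPE_COMPARISONS = ("S_early/S0", "S_late/S0", "R_early/R0", "R_late/R0")
#: The full seven-contrast scheme used throughout the analysis.
SEVEN_COMPARISONS = BETWEEN_GENOTYPE_COMPARISONS + WITHIN_GENOTYPE_COMPARISONS

S_STAGE_COMPARISONS = ("S_early/S0", "S_late/S0")
R_STAGE_COMPARISONS = ("R_early/R0", "R_late/R0")


def condition_name(genotype: str, stage: str) -> str:
    """Condition label, e.g. ``("R", "early") -> "R_early"``, ``("S", "0") -> "S0"``."""
    return f"{genotype}{stage}" if stage == "0" else f"{genotype}_{stage}"


@dataclass(frozen=True)
class StudyDesign:
    """The 2-genotype x 3-stage x n-replicate sampling design.

    Parameters
    ----------
    replicates_per_condition:
        Biological replicates per condition (default 3, as sequenced).
    """

    genotypes: tuple[str, ...] = GENOTYPES
    stages: tuple[str, ...] = STAGES
    replicates_per_condition: int = 3

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be positive")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype labels")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage labels")

    @property
    def conditions(self) -> list[str]:
        return [condition_name(g, s) for g in self.genotypes for s in self.stages]

    @property
    def sample_ids(self) -> list[str]:
        """Unique sample ids, ``<condition>_<replicate>`` (e.g. ``R_late_3``)."""
        return [
            f"{cond}_{r}"
            for cond in self.conditions
            for r in range(1, self.replicates_per_condition + 1)
        ]

    def condition_of(self, sample_id: str) -> str:
        cond, _, rep = sample_id.rpartition("_")
        if cond not in self.conditions or not rep.isdigit():
            raise KeyError(f"sample id {sample_id!r} not in design")
        return cond

    def samples_of(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return [
            f"{condition}_{r}" for r in range(1, self.replicates_per_condition + 1)
        ]


@dataclass(frozen=True)
class Comparison:
    """A ``numerator/denominator`` contrast between two conditions."""

    numerator: str
    denominator: str

    @property
    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @classmethod
    def from_label(cls, label: str) -> "Comparison":
        num, sep, den = label.partition("/")
        if not sep or not num or not den:
            raise ValueError(f"comparison label must be 'num/den', got {label!r}")
        return cls(num, den)

    def validate(self, design: StudyDesign) -> None:
        for cond in (self.numerator, self.denominator):
            if cond not in design.conditions:
                raise ValueError(f"condition {cond!r} not in design")


def default_scheme() -> list[Comparison]:
    """The seven contrasts of the study, in canonical order."""
    return [Comparison.from_label(lab) for lab in SEVEN_COMPARISONS]
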