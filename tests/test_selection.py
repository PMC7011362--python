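"""Venn logic and sign-opposition selection of resistance candidates."""

import numpy as np
import pandas as pd
import pytest

from mirnet.design import StudyDesign
from mirnet.normalize import normalize
from mirnet.selection import (
    build_profiles,
    candidate_genes,
    candidates_from_log2fc,
    genotype_specific,
    opposite_between_genotypes,
    opposite_within_genotypes,
    venn_membership,
)
from mirnet.diffexpr import run_all_comparisons
from mirnet.synthetic import NBParams, generate_counts

from conftest import make_profiles


def de_table_from(rows):
    """Small DE table: rows of (feature, comparison, direction)."""
    return pd.DataFrame(
        [
            {"feature_id": f, "comparison": c, "direction": d,
             "log2fc": {"up": 2.0, "down": -2.0, "ns": 0.0}[d]}
            for f, c, d in rows
        ]
    )


class TestVennMembership:
    def test_feature_de_nowhere_has_empty_signature(self):
        table = de_table_from([("f1", "R_early/R0", "ns"),
                               ("f1", "R_late/R0", "ns")])
        sigs, regions = venn_membership(
            table, ["R_early/R0", "R_late/R0"]
        )
        assert sigs["f1"] == frozenset()
        assert regions == {}

    def test_three_region_small_case(self):
        table = de_table_from(
            [("a", "R_early/R0", "up"), ("a", "R_late/R0", "ns"),
             ("b", "R_early/R0", "up"), ("b", "R_late/R0", "down"),
             ("c", "R_early/R0", "ns"), ("c", "R_late/R0", "up")]
        )
        _, regions = venn_membership(table, ["R_early/R0", "R_late/R0"])
        assert regions[frozenset({"R_early/R0"})] == 1
        assert regions[frozenset({"R_early/R0", "R_late/R0"})] == 1
        assert regions[frozenset({"R_late/R0"})] == 1

    def test_unknown_label_rejected(self):
        table = de_table_from([("a", "R_early/R0", "up")])
        with pytest.raises(ValueError):
            venn_membership(table, ["bogus/label"])


class TestOppositeBetweenGenotypes:
    def test_flip_after_feeding_selected(self):
        # the miR169-family pattern: up before feeding, down after
        profiles = make_profiles(
            {"m1": {"R0/S0": 2.0, "R_late/S_late": -1.5}}
        )
        out = opposite_between_genotypes(profiles)
        assert list(out["feature_id"]) == ["m1"]
        assert out.iloc[0]["flip"] == "up_before_down_after"

    def test_same_direction_after_feeding_not_selected(self):
        profiles = make_profiles(
            {"m1": {"R0/S0": 2.0, "R_early/S_early": 1.5}}
        )
        assert opposite_between_genotypes(profiles).empty

    def test_ns_before_feeding_never_selected(self):
        profiles = make_profiles(
            {"m1": {"R_early/S_early": 3.0, "R_late/S_late": -3.0}}
        )
        assert opposite_between_genotypes(profiles).empty


class TestOppositeWithinGenotypes:
    def test_published_candidate_rows_classified(self):
        profiles = make_profiles(
            {
                # printed candidate rows, up in R / down in S and converse
                "LOC_Os03g44880": {
                    "S_early/S0": -3.0699, "S_late/S0": -7.6904,
                    "R_early/R0": 6.2795, "R_late/R0": 4.4616,
                },
                "LOC_Os01g72270": {
                    "S_early/S0": 1.5876, "S_late/S0": 3.9238,
                    "R_early/R0": -2.0629, "R_late/R0": -1.4023,
                },
            }
        )
        out = opposite_within_genotypes(profiles).set_index("feature_id")
        assert out.loc["LOC_Os03g44880", "pattern"] == "up_R_down_S"
        assert out.loc["LOC_Os01g72270", "pattern"] == "down_R_up_S"

    def test_within_genotype_sign_conflict_disqualifies(self):
        profiles = make_profiles(
            {"g1": {"S_early/S0": 2.0, "S_late/S0": -2.0,
                    "R_early/R0": 1.5, "R_late/R0": 1.5}}
        )
        assert opposite_within_genotypes(profiles).empty

    def test_single_stage_per_genotype_suffices(self):
        profiles = make_profiles(
            {"g1": {"S_early/S0": -1.5, "R_late/R0": 2.0}}
        )
        out = opposite_within_genotypes(profiles)
        assert list(out["feature_id"]) == ["g1"]


class TestGenotypeSpecific:
    def test_definition(self):
        profiles = make_profiles(
            {
                "both_r": {"R_early/R0": 2.0, "R_late/R0": 1.5},
                "one_r": {"R_early/R0": 2.0},
                "r_and_s": {"R_early/R0": 2.0, "R_late/R0": 1.5,
                            "S_early/S0": 2.0},
            }
        )
        out = genotype_specific(profiles, "R")
        assert list(out["feature_id"]) == ["both_r"]

    def test_synthetic_r_specific_cohort_recovered_exactly(self):
        design = StudyDesign()
        nb = NBParams(mean_baseline=500, dispersion=0.0)
        mir, _, truth = generate_counts(
            design, 60, 200, 0.2, nb, seed=21, effect_size=2.5,
            mirna_pattern_weights={"R_specific": 1.0},
        )
        expr = normalize(mir, "rpm")
        table = run_all_comparisons(expr, None)
        profiles = build_profiles(table, feature_class="mirna")
        out = genotype_specific(profiles, "R")
        t = truth[truth["feature_class"] == "mirna"]
        expected = set(t.loc[t["pattern"] == "R_specific", "feature_id"])
        assert set(out["feature_id"]) == expected


class TestCandidateGenes:
    def test_strict_tier_requires_all_four_comparisons(self):
        profiles = make_profiles(
            {
                "full": {"S_early/S0": -2.0, "S_late/S0": -3.0,
                         "R_early/R0": 2.5, "R_late/R0": 1.5},
                "three": {"S_early/S0": -2.0, "S_late/S0": -3.0,
                          "R_early/R0": 2.5},
            }
        )
        cands = candidate_genes(profiles)
        assert list(cands["feature_id"]) == ["full"]
        broad = opposite_within_genotypes(profiles)
        assert set(broad["feature_id"]) == {"full", "three"}

    def test_candidates_subset_of_opposite_within(self):
        rng = np.random.default_rng(8)
        rows = {}
        for i in range(50):
            rows[f"g{i}"] = {
                lab: float(rng.normal(0, 2))
                for lab in ("S_early/S0", "S_late/S0",
                            "R_early/R0", "R_late/R0")
            }
        profiles = make_profiles(rows)
        cands = set(candidate_genes(profiles)["feature_id"])
        broad = set(opposite_within_genotypes(profiles)["feature_id"])
        assert cands <= broad

    def test_synthetic_coherent_opposite_cohort_recovered(self):
        design = StudyDesign()
        nb = NBParams(mean_baseline=500, dispersion=0.0)
        _, mrna, truth = generate_counts(
            design, 20, 300, 0.2, nb, seed=22, effect_size=2.5,
            mrna_pattern_weights={"up_R_down_S": 0.5, "down_R_up_S": 0.5},
        )
        expr = normalize(mrna, "rpm")
        table = run_all_comparisons(None, expr)
        profiles = build_profiles(table, feature_class="mrna")
        cands = candidate_genes(profiles).set_index("feature_id")
        t = truth[truth["feature_class"] == "mrna"].set_index("feature_id")
        planted = t[t["pattern"] != "null"]
        assert set(cands.index) == set(planted.index)
        assert (cands.loc[planted.index, "pattern"]
                == planted["pattern"]).all()

    def test_label_permutation_within_condition_is_invariant(self):
        design = StudyDesign()
        nb = NBParams(mean_baseline=500, dispersion=0.0)
        _, mrna, _ = generate_counts(
            design, 20, 200, 0.2, nb, seed=23, effect_size=2.5,
        )
        expr = normalize(mrna, "rpm")
        base = candidate_genes(
            build_profiles(run_all_comparisons(None, expr),
                           feature_class="mrna")
        )
        # swap replicates 1 and 3 inside two conditions
        values = expr.values.copy()
        for cond in ("R0", "S_late"):
            s = design.samples_of(cond)
            values[[s[0], s[2]]] = values[[s[2], s[0]]].to_numpy()
        expr2 = type(expr)(values, design, expr.unit)
        permuted = candidate_genes(
            build_profiles(run_all_comparisons(None, expr2),
                           feature_class="mrna")
        )
        pd.testing.assert_frame_equal(base, permuted)


class TestCandidatesFromLog2fc:
    def test_plain_matrix_classification(self):
        df = pd.DataFrame(
            {
                "S_early/S0": [-2.0, 1.2, -0.5],
                "S_late/S0": [-1.5, 2.0, -2.0],
                "R_early/R0": [1.1, -1.3, 2.0],
                "R_late/R0": [3.0, -1.1, 2.0],
            },
            index=["a", "b", "c"],
        )
        out = candidates_from_log2fc(df).set_index("feature_id")
        assert out.loc["a", "pattern"] == "up_R_down_S"
        assert out.loc["b", "pattern"] == "down_R_up_S"
        assert "c" not in out.index  # S_early above -1
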