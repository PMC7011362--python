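"""Complementarity expectation scoring and target-site scanning.

The independent oracle here is a deliberately naive enumerator that
builds every alignment (all windows, all single gap placements)
character by character and sums penalties straight from the rules.
"""

import numpy as np
import pytest

from mirnet.synthetic import generate_target_sequences, reverse_complement
from mirnet.targets import (
    MatureMiRNA,
    ScoringScheme,
    predict_all,
    scan_transcript,
    score_site,
)

MIRNA = "UGACUGAGUCAGCAUCGAUGCU"  # 22 nt
SCHEME = ScoringScheme()


def naive_pair_penalty(m, t, pos):
    """Penalty rules restated independently of the implementation."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    if (m, t) in wc:
        p = 0.0
    elif (m, t) in gu:
        p = 0.5
    else:
        p = 1.0
    return p * (2.0 if 2 <= pos <= 13 else 1.0)


def naive_window_score(mirna, window):
    """Minimum expectation over all alignments of one window."""
    m = mirna.upper().replace("U", "T")
    w = window.upper().replace("U", "T")[::-1]  # pair antiparallel
    L = len(m)
    gap_mult = lambda pos: 2.0 if 2 <= pos <= 13 else 1.0
    if len(w) == L:
        return sum(naive_pair_penalty(m[i], w[i], i + 1) for i in range(L))
    scores = []
    if len(w) == L - 1:
        for g in range(L):  # miRNA base g unpaired
            s = 2.0 * gap_mult(g + 1)
            for i in range(L):
                if i == g:
                    continue
                j = i if i < g else i - 1
                s += naive_pair_penalty(m[i], w[j], i + 1)
            scores.append(s)
    elif len(w) == L + 1:
        for g in range(L + 1):  # window base g unpaired
            s = 2.0 * gap_mult(min(g + 1, L))
            for i in range(L):
                j = i if i < g else i + 1
                s += naive_pair_penalty(m[i], w[j], i + 1)
            scores.append(s)
    return min(scores)


def naive_best(mirna, transcript):
    """Exhaustive minimum expectation over every window of the transcript."""
    L = len(mirna)
    best = np.inf
    for wlen in (L - 1, L, L + 1):
        for s in range(len(transcript) - wlen + 1):
            best = min(best, naive_window_score(
                mirna, transcript[s: s + wlen]
            ))
    return best


class TestScoreSite:
    def test_perfect_reverse_complement_scores_zero(self):
        window = reverse_complement(MIRNA)
        out = score_site(MIRNA, window)
        assert out.expectation == 0.0
        assert out.n_mismatch == out.n_gu == out.n_gap == 0
        assert set(out.alignment[1]) == {"|"}

    def test_gu_wobble_in_seed_scores_one(self):
        m = "UGGCUGAGUCAGCAUCGAUGCU"  # G at position 3
        site = list(reverse_complement(m))
        site[len(m) - 3] = "T"  # G:U at miRNA position 3
        out = score_site(m, "".join(site))
        assert out.expectation == pytest.approx(1.0)
        assert out.n_gu == 1

    @pytest.mark.parametrize("pos,expected", [(20, 1.0), (10, 2.0)])
    def test_mismatch_seed_doubling(self, pos, expected):
        m = MIRNA.replace("U", "T")
        site = list(reverse_complement(m))
        site[len(m) - pos] = m[pos - 1]  # same base never pairs
        out = score_site(MIRNA, "".join(site))
        assert out.expectation == pytest.approx(expected)
        assert out.n_mismatch == 1

    def test_gap_window_scored_with_penalty(self):
        m = MIRNA.replace("U", "T")
        site = list(reverse_complement(m))
        del site[2]  # miRNA position L-2 unpaired (non-seed for 22-mer)
        out = score_site(MIRNA, "".join(site))
        assert out.expectation == pytest.approx(2.0)
        assert out.n_gap == 1

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIRNA, "NNNN" + reverse_complement(MIRNA)[4:])

    def test_window_length_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIRNA, reverse_complement(MIRNA)[:-3])

    def test_matches_naive_enumeration_on_random_windows(self):
        rng = np.random.default_rng(31)
        bases = "ACGT"
        for _ in range(100):
            L = int(rng.integers(20, 25))
            m = "".join(bases[i] for i in rng.integers(0, 4, L))
            wlen = L + int(rng.integers(-1, 2))
            w = "".join(bases[i] for i in rng.integers(0, 4, wlen))
            assert score_site(m, w).expectation == pytest.approx(
                naive_window_score(m, w)
            )


class TestScanTranscript:
    def test_planted_perfect_site_found_at_recorded_position(self):
        tx, truth = generate_target_sequences(
            {"mirA": MIRNA}, 1, {"mirA": "tx_0001"}, seed=41,
            transcript_length=250,
        )
        hits = scan_transcript(("mirA", MIRNA), tx["tx_0001"], cutoff=5.0)
        assert len(hits) >= 1
        best = hits[0]
        assert best.expectation == 0.0
        assert (best.start, best.end) == (
            truth.iloc[0]["start"], truth.iloc[0]["end"]
        )

    def test_three_seed_mismatches_exceed_cutoff(self):
        tx, _ = generate_target_sequences(
            {"mirA": MIRNA}, 1, {"mirA": "tx_0001"},
            {"mirA": [(3, "mismatch"), (6, "mismatch"), (9, "mismatch")]},
            seed=42, transcript_length=250,
        )
        # 3 mismatches x penalty 1 x seed doubling = 6 > cutoff 5
        hits = scan_transcript(("mirA", MIRNA), tx["tx_0001"], cutoff=5.0)
        for h in hits:
            assert h.expectation <= 5.0
        assert all(h.expectation != 6.0 for h in hits)

    def test_transcript_shorter_than_mirna_yields_nothing(self):
        assert scan_transcript(MIRNA, "ACGT" * 4) == []

    def test_exhaustive_oracle_equivalence(self):
        rng = np.random.default_rng(43)
        bases = "ACGT"
        for _ in range(60):
            L = int(rng.integers(20, 25))
            m = "".join(bases[i] for i in rng.integers(0, 4, L))
            tx = "".join(bases[i] for i in rng.integers(0, 4, 60))
            oracle = naive_best(m, tx)
            hits = scan_transcript(m, tx, cutoff=1e6)
            assert hits, "with an unbounded cutoff some window must hit"
            assert hits[0].expectation == pytest.approx(oracle)

    def test_monotonicity_edits_never_reduce_expectation(self):
        base = reverse_complement(MIRNA)
        base_score = score_site(MIRNA, base).expectation
        prev = base_score
        site = list(base)
        rng = np.random.default_rng(44)
        m = MIRNA.replace("U", "T")
        for pos in rng.permutation(len(m))[:6]:
            site[len(m) - 1 - pos] = m[pos]  # introduce mismatch
            new = score_site(MIRNA, "".join(site)).expectation
            assert new >= prev - 1e-12
            prev = new


class TestPredictAll:
    def test_empty_transcripts(self):
        out = predict_all({"m": MIRNA}, {})
        assert out.empty

    def test_planted_sites_recovered_and_background_clean(self):
        mirnas = {
            "mirA": MIRNA,
            "mirB": "ACGGAUGCUAGCUAGGCUAAU",
        }
        tx, truth = generate_target_sequences(
            mirnas, 4, {"mirA": "tx_0001", "mirB": "tx_0002"},
            {"mirB": [(3, "mismatch")]}, seed=45, transcript_length=300,
        )
        hits = predict_all(mirnas, tx, cutoff=5.0)
        keyed = hits.set_index(["mirna_id", "transcript_id"])
        assert keyed.loc[("mirA", "tx_0001"), "expectation"] == 0.0
        assert keyed.loc[("mirB", "tx_0002"), "expectation"] == (
            pytest.approx(2.0)
        )
        # frozen-seed background transcripts carry no hits
        background = hits[hits["transcript_id"].isin(["tx_0003", "tx_0004"])]
        assert background.empty
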