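"""Plant miRNA target-site discovery by complementarity expectation scoring.

A candidate site is scored by aligning the miRNA (5'->3') antiparallel to
a transcript window and summing per-position penalties: Watson-Crick pair
0, G:U wobble 0.5, mismatch 1, indel 2, with every penalty doubled in the
seed region (miRNA positions 2-13 from the 5' end). The resulting
"expectation" is 0 for a perfect reverse complement and grows with each
defect; windows at or below a cutoff (default 5.0) are reported as hits.

The search is an exhaustive sliding-window scan over window lengths
L-1, L and L+1 (at most one indel), which is exact at miRNA scale:
``score_site`` is the single-window reference scorer, ``scan_transcript``
a vectorized scan that reconstructs alignments with ``score_site`` only
for reported hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A-T, C-G
_GU = {(2, 3), (3, 2)}  # miRNA G : target T(U), miRNA U : target G
_LETTER = "ACGT"


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty constants for complementarity scoring."""

    wc: float = 0.0
    gu_wobble: float = 0.5
    mismatch: float = 1.0
    gap: float = 2.0
    seed_start: int = 2  # 1-based miRNA positions with doubled penalties
    seed_end: int = 13
    seed_multiplier: float = 2.0
    cutoff: float = 5.0

    def multiplier(self, pos: int) -> float:
        """Penalty multiplier at 1-based miRNA position ``pos``."""
        return self.seed_multiplier if self.seed_start <= pos <= self.seed_end else 1.0

    def pair_penalty(self, mirna_base: str, target_base: str, pos: int) -> float:
        m, t = _CODE[mirna_base], _CODE[target_base]
        if t == _COMP[m]:
            p = self.wc
        elif (m, t) in _GU:
            p = self.gu_wobble
        else:
            p = self.mismatch
        return p * self.multiplier(pos)

    def gap_penalty(self, pos: int) -> float:
        return self.gap * self.multiplier(pos)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet, 20-24 nt."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.id}: miRNA alphabet must be A/C/G/U")
        if not 20 <= len(seq) <= 24:
            raise ValueError(f"{self.id}: mature miRNA must be 20-24 nt")
        object.__setattr__(self, "sequence", seq)


@dataclass
class SiteScore:
    expectation: float
    alignment: tuple[str, str, str]  # miRNA 3'->5', match line, target 5'->3'
    n_mismatch: int
    n_gu: int
    n_gap: int


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive, transcript sense strand
    end: int
    expectation: float
    alignment: tuple[str, str, str]
    n_mismatch: int
    n_gu: int
    n_gap: int


def _clean(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"invalid {what} alphabet: {bad}")
    return seq


def _mirna_seq(mirna) -> tuple[str, str]:
    if isinstance(mirna, MatureMiRNA):
        return mirna.id, _clean(mirna.sequence, "miRNA")
    if isinstance(mirna, tuple):
        return mirna[0], _clean(mirna[1], "miRNA")
    return "miRNA", _clean(str(mirna), "miRNA")


def _score_columns(m: str, w_rev: str, gap_at: int | None,
                   bulge_at: int | None, scheme: ScoringScheme) -> SiteScore:
    """Score one explicit alignment (reversed-window coordinates).

    ``gap_at``: 0-based miRNA index left unpaired (target one base short).
    ``bulge_at``: 0-based reversed-window index left unpaired (target one
    base long). At most one of the two is set.
    """
    cols: list[tuple[str, str]] = []  # (miRNA char or '-', target char or '-')
    i = j = 0
    while i < len(m) or j < len(w_rev):
        if gap_at is not None and i == gap_at and gap_at >= 0:
            cols.append((m[i], "-"))
            i += 1
            gap_at = -1
            continue
        if bulge_at is not None and j == bulge_at and bulge_at >= 0:
            cols.append(("-", w_rev[j]))
            j += 1
            bulge_at = -1
            continue
        cols.append((m[i], w_rev[j]))
        i += 1
        j += 1
    total = 0.0
    n_mm = n_gu = n_gap = 0
    match_line = []
    mirna_pos = 0  # 1-based position of the most recent miRNA base
    for mc, tc in cols:
        if mc != "-":
            mirna_pos += 1
        pos = max(1, min(mirna_pos + (1 if mc == "-" else 0), len(m)))
        if mc == "-" or tc == "-":
            total += scheme.gap_penalty(pos if mc == "-" else mirna_pos)
            n_gap += 1
            match_line.append(" ")
        else:
            p = scheme.pair_penalty(mc, tc, mirna_pos)
            total += p
            if _CODE[tc] == _COMP[_CODE[mc]]:
                match_line.append("|")
            elif (_CODE[mc], _CODE[tc]) in _GU:
                match_line.append("o")
                n_gu += 1
            else:
                match_line.append(".")
                n_mm += 1
    # Render with the miRNA 3'->5' over the target 5'->3'.
    mirna_str = "".join(c[0] for c in cols)[::-1]
    target_str = "".join(c[1] for c in cols)[::-1]
    return SiteScore(
        total, (mirna_str, "".join(match_line)[::-1], target_str),
        n_mm, n_gu, n_gap,
    )


def score_site(mirna, window: str, scheme: ScoringScheme | None = None) -> SiteScore:
    """Score a transcript window against a miRNA (reference scorer).

    ``window`` is the transcript subsequence 5'->3'; its length must be
    within one of the miRNA length. For off-by-one windows all single
    gap placements are tried and the minimum-expectation alignment kept
    (ties broken toward the 3' end of the miRNA, i.e. outside the seed
    when possible).
    """
    scheme = scheme or ScoringScheme()
    _, m = _mirna_seq(mirna)
    w = _clean(window, "transcript")
    L = len(m)
    if not L - 1 <= len(w) <= L + 1:
        raise ValueError(
            f"window length {len(w)} not within 1 of miRNA length {L}"
        )
    w_rev = w[::-1]
    if len(w) == L:
        return _score_columns(m, w_rev, None, None, scheme)
    best: SiteScore | None = None
    if len(w) == L - 1:
        placements = [("gap", g) for g in range(L)]
    else:
        placements = [("bulge", g) for g in range(L + 1)]
    for kind, g in placements:
        s = _score_columns(
            m, w_rev,
            g if kind == "gap" else None,
            g if kind == "bulge" else None,
            scheme,
        )
        if best is None or s.expectation < best.expectation:
            best = s
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Vectorized scanning


def _penalty_table(m: str, scheme: ScoringScheme) -> np.ndarray:
    """P[i, b]: penalty of pairing miRNA position i (0-based) with base b."""
    L = len(m)
    P = np.empty((L, 4))
    for i, mc in enumerate(m):
        for b in range(4):
            P[i, b] = scheme.pair_penalty(mc, _LETTER[b], i + 1)
    return P


def _window_expectations(
    m: str, code: np.ndarray, scheme: ScoringScheme
) -> dict[int, np.ndarray]:
    """Minimum expectation for every window start, per window length.

    Returns ``{window_length: expectations[start]}``; gapped lengths are
    minimized over all single gap placements.
    """
    L = len(m)
    n = code.size
    P = _penalty_table(m, scheme)
    out: dict[int, np.ndarray] = {}

    if n >= L:
        ns = n - L + 1
        E = np.zeros(ns)
        for i in range(L):
            # miRNA[i] pairs the window base at offset L-1-i from the start
            E += P[i, code[L - 1 - i: L - 1 - i + ns]]
        out[L] = E

    if n >= L - 1:
        ns = n - (L - 1) + 1
        # A[i]: miRNA[i] paired before the gap; B[i]: paired after the gap
        A = np.zeros((L, ns))
        B = np.zeros((L, ns))
        for i in range(L - 1):
            A[i] = P[i, code[L - 2 - i: L - 2 - i + ns]]
        for i in range(1, L):
            B[i] = P[i, code[L - 1 - i: L - 1 - i + ns]]
        prefA = np.vstack([np.zeros(ns), np.cumsum(A[:-1], axis=0)])
        sufB = np.vstack([np.cumsum(B[::-1], axis=0)[::-1][1:], np.zeros(ns)])
        gp = np.array([scheme.gap_penalty(g + 1) for g in range(L)])
        out[L - 1] = (prefA + sufB + gp[:, None]).min(axis=0)

    if n >= L + 1:
        ns = n - (L + 1) + 1
        C = np.zeros((L, ns))
        D = np.zeros((L, ns))
        for i in range(L):
            C[i] = P[i, code[L - i: L - i + ns]]       # pairs w'[i], i < bulge
            D[i] = P[i, code[L - 1 - i: L - 1 - i + ns]]  # pairs w'[i+1], i >= bulge
        prefC = np.vstack([np.zeros(ns), np.cumsum(C, axis=0)])  # g = 0..L
        sufD = np.vstack([np.cumsum(D[::-1], axis=0)[::-1], np.zeros(ns)])
        gp = np.array(
            [scheme.gap_penalty(min(g + 1, L)) for g in range(L + 1)]
        )
        out[L + 1] = (prefC + sufD + gp[:, None]).min(axis=0)
    return out


def scan_transcript(
    mirna,
    transcript: str,
    cutoff: float = 5.0,
    max_hits: int | None = None,
    scheme: ScoringScheme | None = None,
    transcript_id: str = "transcript",
) -> list[TargetHit]:
    """Scan a transcript for target sites of one miRNA.

    All windows of length L-1, L and L+1 are scored; windows with
    expectation <= ``cutoff`` become candidate hits, overlapping
    candidates are merged keeping the minimum expectation, and hits are
    returned sorted by (expectation, position). Transcripts shorter than
    the miRNA yield no hits.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    scheme = scheme or ScoringScheme()
    mid, m = _mirna_seq(mirna)
    tx = _clean(transcript, "transcript")
    L = len(m)
    if len(tx) < L:
        return []
    code = np.array([_CODE[c] for c in tx], dtype=np.intp)
    expectations = _window_expectations(m, code, scheme)

    candidates: list[tuple[float, int, int]] = []  # (expectation, start0, wlen)
    for wlen, E in expectations.items():
        for s in np.flatnonzero(E <= cutoff + 1e-9):
            candidates.append((float(E[s]), int(s), wlen))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    kept: list[tuple[float, int, int]] = []
    for exp, s, wlen in candidates:
        if any(s < ks + kw and ks < s + wlen for _, ks, kw in kept):
            continue
        kept.append((exp, s, wlen))
    kept.sort(key=lambda c: (c[0], c[1]))
    if max_hits is not None:
        kept = kept[:max_hits]

    hits = []
    for exp, s, wlen in kept:
        detail = score_site((mid, m), tx[s: s + wlen], scheme)
        hits.append(
            TargetHit(
                mirna_id=mid, transcript_id=transcript_id,
                start=s + 1, end=s + wlen,
                expectation=detail.expectation, alignment=detail.alignment,
                n_mismatch=detail.n_mismatch, n_gu=detail.n_gu,
                n_gap=detail.n_gap,
            )
        )
    return hits


def predict_all(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = 5.0,
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Best hit per (miRNA, transcript) pair at or below the cutoff.

    Returns a tidy hit table sorted by (miRNA id, transcript id) with the
    site coordinates, expectation, edit counts and alignment strings.
    """
    rows = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            hits = scan_transcript(
                (mid, mirnas[mid]), transcripts[tid], cutoff=cutoff,
                scheme=scheme, transcript_id=tid,
            )
            if not hits:
                continue
            best = hits[0]
            rows.append(
                {
                    "mirna_id": mid, "transcript_id": tid,
                    "start": best.start, "end": best.end,
                    "expectation": best.expectation,
                    "n_mismatch": best.n_mismatch, "n_gu": best.n_gu,
                    "n_gap": best.n_gap,
                    "aln_mirna": best.alignment[0],
                    "aln_match": best.alignment[1],
                    "aln_target": best.alignment[2],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "start", "end", "expectation",
                 "n_mismatch", "n_gu", "n_gap", "aln_mirna", "aln_match",
                 "aln_target"],
    )
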