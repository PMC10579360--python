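"""Local-alignment statistics, scoring and the declumped search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicryscan.alignment import (
    alignment_stats,
    recompute_score,
    waterman_eggert_align,
)
from mimicryscan.fixtures import ALIGNED_PAIRS
from mimicryscan.types import AMINO_ACIDS

residues = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=25)


def _reference_aligner():
    """Independent affine local aligner at identical parameters."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -14
    aligner.extend_gap_score = -4
    return aligner


@pytest.mark.parametrize("row", ALIGNED_PAIRS, ids=lambda r: r.antigen[:20])
def test_stats_reproduce_reported_pair_numerators(row, blosum62):
    """The six reported pairs: identity and similarity match as printed."""
    stats = alignment_stats(row.human, row.mtg, blosum62)
    assert stats.length == row.length
    assert stats.n_identity == row.n_identity
    assert stats.n_similarity == row.n_similarity
    assert stats.n_gaps == 0


def test_stats_self_alignment(blosum62):
    s = "ACDEFGHIKLMNPQRSTVWY"
    stats = alignment_stats(s, s, blosum62)
    assert stats == (20, 20, 20, 0)


def test_stats_reject_invalid_columns(blosum62):
    with pytest.raises(ValueError, match="unequal"):
        alignment_stats("AC", "ACD", blosum62)
    with pytest.raises(ValueError, match="gap-vs-gap"):
        alignment_stats("A-C", "A-C", blosum62)


class TestRecomputeScore:
    def test_ungapped_hand_sum(self, blosum62):
        # P-P=7, S-S=4, R-R=5
        assert recompute_score("PSR", "PSR", blosum62, 14, 4) == 16

    def test_affine_gap_arithmetic(self, blosum62):
        # residue columns A-A + C-C + F-F = 4 + 9 + 6; length-2 gap costs 14 + 4
        assert recompute_score("ACDEF", "AC--F", blosum62, 14, 4) == 19 - 18

    def test_two_gap_runs_cost_two_opens(self, blosum62):
        score = recompute_score("ACDEF", "A-D-F", blosum62, 14, 4)
        assert score == (4 + 6 + 6) - 2 * 14

    def test_empty_alignment_is_zero(self, blosum62):
        assert recompute_score("", "", blosum62, 14, 4) == 0


class TestWatermanEggert:
    def test_reported_pair_is_recovered_in_full(self, blosum62):
        alns = waterman_eggert_align(
            "PSRGKSSSYSKQF", "PSRMKAVIYSKHF", blosum62, 14, 4
        )
        assert len(alns) == 1
        a = alns[0]
        assert (a.length, a.n_identity, a.n_gaps) == (13, 8, 0)
        assert a.aligned_query == "PSRGKSSSYSKQF"
        assert a.score == 37

    def test_identical_sequences_full_length(self, blosum62):
        (a,) = waterman_eggert_align("ACDEFGHIK", "ACDEFGHIK", blosum62)
        assert a.n_identity == a.n_similarity == a.length == 9
        assert a.q_start == a.t_start == 1 and a.q_end == a.t_end == 9

    def test_empty_result_iff_best_score_zero(self, blosum62):
        # G-P scores -2: no positive-scoring pair at all
        assert waterman_eggert_align("GGGG", "PPPP", blosum62) == []

    def test_rejects_empty_and_nonfinite(self, blosum62):
        with pytest.raises(ValueError):
            waterman_eggert_align("", "ACD", blosum62)
        with pytest.raises(ValueError):
            waterman_eggert_align("ACD", "ACD", blosum62, gap_open=float("nan"))

    def test_prohibitive_penalties_match_ungapped_enumeration(self, blosum62):
        """With gaps priced out, the optimum is the best diagonal window."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            q = "".join(rng.choice(list(AMINO_ACIDS), 20))
            t = "".join(rng.choice(list(AMINO_ACIDS), 20))
            best = 0
            for i in range(20):
                for j in range(20):
                    tot = 0
                    for k in range(20 - max(i, j)):
                        tot += blosum62.score(q[i + k], t[j + k])
                        best = max(best, tot)
            alns = waterman_eggert_align(q, t, blosum62, 1000, 1000)
            got = alns[0].score if alns else 0
            assert got == best

    def test_deterministic_output(self, blosum62):
        a = waterman_eggert_align("ACDEAACDEA", "ACDEACDEAC", blosum62, 14, 4, 3)
        b = waterman_eggert_align("ACDEAACDEA", "ACDEACDEAC", blosum62, 14, 4, 3)
        assert a == b


@settings(max_examples=150, deadline=None, derandomize=True)
@given(q=residues, t=residues)
def test_alignment_invariants_and_reference_score(q, t, blosum62):
    """Structural invariants hold and the optimal score matches an
    independent aligner on arbitrary sequences."""
    alns = waterman_eggert_align(q, t, blosum62, 14, 4, n_alternatives=3)
    ref = _reference_aligner()
    best = alns[0].score if alns else 0
    assert best == ref.score(q, t)
    seen_pairs: set[tuple[int, int]] = set()
    prev_score = float("inf")
    for a in alns:
        a.validate(query=q, target=t, matrix=blosum62, gap_open=14, gap_extend=4)
        assert a.score <= prev_score
        prev_score = a.score
        qi, tj = a.q_start - 1, a.t_start - 1
        for ca, cb in zip(a.aligned_query, a.aligned_target):
            if ca != "-" and cb != "-":
                assert (qi, tj) not in seen_pairs, "declumping violated"
                seen_pairs.add((qi, tj))
                qi += 1
                tj += 1
            elif ca == "-":
                tj += 1
            else:
                qi += 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(q=residues, t=residues)
def test_raising_gap_open_never_increases_score(q, t, blosum62):
    lo = waterman_eggert_align(q, t, blosum62, 10, 4)
    hi = waterman_eggert_align(q, t, blosum62, 16, 4)
    s_lo = lo[0].score if lo else 0
    s_hi = hi[0].score if hi else 0
    assert s_hi <= s_lo
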