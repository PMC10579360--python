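"""Waterman-Eggert local alignment with affine gap costs.

This module re-implements the classic declumped local-alignment search:
the best local alignment between two protein sequences is found by
Smith-Waterman/Gotoh dynamic programming, and sub-optimal alternatives are
produced by forbidding the residue pairs already used ("declumping") and
re-running the search, so successive alignments never share an aligned
residue pair.

Scoring conventions
-------------------
* Substitution scores come from a :class:`~mimicryscan.matrices.SubstitutionMatrix`
  (BLOSUM62 by default); X scores 0 against everything.
* A gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
* Alignment statistics follow the usual pairwise-report conventions:
  *identity* counts columns with equal residues, *similarity* counts columns
  whose substitution score is strictly positive (identities included), and
  *length* is the column count including gap columns.
* Coordinates are 1-based inclusive on the ungapped sequences.

Tie-breaking among equal-scoring optima is deterministic: the end cell with
the smallest target (then query) end position is tracked back preferring
substitution steps over gaps, and among tied tracebacks the alignment
starting earliest in the target, then with fewest gaps, wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .matrices import SubstitutionMatrix
from .types import ProteinSequence

__all__ = [
    "LocalAlignment",
    "AlignmentStats",
    "alignment_stats",
    "recompute_score",
    "waterman_eggert_align",
]

GAP = "-"
_NEG = -1.0e30

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco


@njit(cache=False)
def _fill(q, t, sub, go, ge, forbid):  # pragma: no cover - exercised via API
    """Gotoh dynamic-programming fill; returns the H, E, F matrices.

    E holds best scores ending in a gap in the query (consuming target),
    F in a gap in the target (consuming query). ``forbid`` masks residue
    pairs excluded by declumping.
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            e2 = E[i, j - 1] - ge
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - go
            f2 = F[i - 1, j] - ge
            if f2 > f:
                f = f2
            F[i, j] = f
            if forbid[i - 1, j - 1]:
                d = _NEG
            else:
                d = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            h = 0.0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


class AlignmentStats(NamedTuple):
    length: int
    n_identity: int
    n_similarity: int
    n_gaps: int


def alignment_stats(
    aligned_query: str, aligned_target: str, matrix: SubstitutionMatrix
) -> AlignmentStats:
    """Column statistics of an aligned pair.

    Returns (length, n_identity, n_similarity, n_gaps) where identity counts
    equal-residue columns, similarity counts residue columns scoring > 0
    under ``matrix`` (identities included) and n_gaps counts columns with
    exactly one gap. Gap-vs-gap columns are invalid.
    """
    if len(aligned_query) != len(aligned_target):
        raise ValueError("aligned strings have unequal lengths")
    n_id = n_sim = n_gap = 0
    for a, b in zip(aligned_query, aligned_target):
        if a == GAP and b == GAP:
            raise ValueError("gap-vs-gap column is not a valid alignment column")
        if a == GAP or b == GAP:
            n_gap += 1
            continue
        if a == b:
            n_id += 1
        if matrix.score(a, b) > 0:
            n_sim += 1
    return AlignmentStats(len(aligned_query), n_id, n_sim, n_gap)


def recompute_score(
    aligned_query: str,
    aligned_target: str,
    matrix: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Score of an aligned pair under the module's affine-gap convention.

    Sum of substitution scores over residue columns minus, for each maximal
    gap run of length L, ``gap_open + (L - 1) * gap_extend``.
    """
    if len(aligned_query) != len(aligned_target):
        raise ValueError("aligned strings have unequal lengths")
    score = 0.0
    in_gap = False
    for a, b in zip(aligned_query, aligned_target):
        if a == GAP and b == GAP:
            raise ValueError("gap-vs-gap column is not a valid alignment column")
        if a == GAP or b == GAP:
            score -= gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += matrix.score(a, b)
            in_gap = False
    return score


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment with coordinates, score and column statistics.

    ``q_start``/``q_end`` and ``t_start``/``t_end`` are 1-based inclusive
    positions on the ungapped query/target. ``length`` is the column count
    (the "Ln" of a hit report); ``n_identity`` and ``n_similarity`` are the
    numerators of the identity and similarity fractions.
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: float
    length: int
    n_identity: int
    n_similarity: int
    n_gaps: int

    @property
    def query_peptide(self) -> str:
        """The aligned query segment with gaps removed."""
        return self.aligned_query.replace(GAP, "")

    @property
    def target_peptide(self) -> str:
        """The aligned target segment with gaps removed."""
        return self.aligned_target.replace(GAP, "")

    @property
    def identity_fraction(self) -> float:
        return self.n_identity / self.length

    @property
    def similarity_fraction(self) -> float:
        return self.n_similarity / self.length

    def validate(
        self,
        query: str | None = None,
        target: str | None = None,
        matrix: SubstitutionMatrix | None = None,
        gap_open: float | None = None,
        gap_extend: float | None = None,
    ) -> None:
        """Check the structural invariants; raises AssertionError on breach."""
        assert len(self.aligned_query) == len(self.aligned_target) == self.length
        assert self.score >= 0
        assert 0 <= self.n_identity <= self.n_similarity <= self.length
        if query is not None:
            assert self.query_peptide == query[self.q_start - 1 : self.q_end]
        if target is not None:
            assert self.target_peptide == target[self.t_start - 1 : self.t_end]
        if matrix is not None:
            stats = alignment_stats(self.aligned_query, self.aligned_target, matrix)
            assert stats == (
                self.length, self.n_identity, self.n_similarity, self.n_gaps,
            )
            if gap_open is not None and gap_extend is not None:
                assert self.score == recompute_score(
                    self.aligned_query, self.aligned_target, matrix,
                    gap_open, gap_extend,
                )

    def to_pair_format(self) -> str:
        """Render a small Matcher-style pair report (1-based coordinates)."""
        frac = lambda n: f"{n}/{self.length}"
        return "\n".join(
            [
                f"# {self.query_id} vs {self.target_id}",
                f"# Length: {self.length}  Score: {self.score:g}",
                f"# Identity: {frac(self.n_identity)}  "
                f"Similarity: {frac(self.n_similarity)}  Gaps: {frac(self.n_gaps)}",
                f"{self.query_id:>12} {self.q_start:>4} {self.aligned_query} {self.q_end}",
                f"{self.target_id:>12} {self.t_start:>4} {self.aligned_target} {self.t_end}",
            ]
        )


def _as_residues(seq) -> tuple[str, str]:
    if isinstance(seq, ProteinSequence):
        return seq.id, seq.residues
    return "", str(seq).upper()


def _traceback(H, E, F, q_enc, t_enc, sub, go, ge, forbid, i, j):
    """Walk back from end cell (i, j); returns aligned column list.

    Columns are (query_index, target_index) 0-based, -1 marking a gap.
    Substitution steps are preferred over gaps, and closing a gap is
    preferred over extending it, which minimizes gap count among ties.
    """
    cols: list[tuple[int, int]] = []
    state = 0  # 0 = H, 1 = E (gap in query), 2 = F (gap in target)
    while True:
        if state == 0:
            v = H[i, j]
            if v <= 0:
                break
            if (
                i > 0
                and j > 0
                and not forbid[i - 1, j - 1]
                and v == H[i - 1, j - 1] + sub[q_enc[i - 1], t_enc[j - 1]]
            ):
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif v == F[i, j]:
                state = 2
            elif v == E[i, j]:
                state = 1
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == 2:
            cols.append((i - 1, -1))
            if F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:
            cols.append((-1, j - 1))
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    cols.reverse()
    return cols


def _build(cols, qid, tid, q, t, matrix, go, ge) -> LocalAlignment:
    aq = "".join(q[qi] if qi >= 0 else GAP for qi, _ in cols)
    at = "".join(t[tj] if tj >= 0 else GAP for _, tj in cols)
    q_idx = [qi for qi, _ in cols if qi >= 0]
    t_idx = [tj for _, tj in cols if tj >= 0]
    stats = alignment_stats(aq, at, matrix)
    score = recompute_score(aq, at, matrix, go, ge)
    if float(score).is_integer():
        score = int(score)
    return LocalAlignment(
        query_id=qid,
        target_id=tid,
        aligned_query=aq,
        aligned_target=at,
        q_start=q_idx[0] + 1,
        q_end=q_idx[-1] + 1,
        t_start=t_idx[0] + 1,
        t_end=t_idx[-1] + 1,
        score=score,
        length=stats.length,
        n_identity=stats.n_identity,
        n_similarity=stats.n_similarity,
        n_gaps=stats.n_gaps,
    )


# Cap on the number of tied end cells examined per round; ties beyond this
# are broken by end-cell position alone (still deterministic).
_MAX_TIED_ENDS = 32


def waterman_eggert_align(
    query,
    target,
    matrix: SubstitutionMatrix,
    gap_open: float = 14.0,
    gap_extend: float = 4.0,
    n_alternatives: int = 1,
) -> list[LocalAlignment]:
    """Best and declumped sub-optimal local alignments of query vs target.

    Returns up to ``n_alternatives`` alignments in non-increasing score
    order; successive alignments share no aligned residue pair. An empty
    list is returned iff the best local score is 0 (nothing aligns better
    than the empty alignment).
    """
    qid, q = _as_residues(query)
    tid, t = _as_residues(target)
    qid = qid or "query"
    tid = tid or "target"
    if not q or not t:
        raise ValueError("cannot align empty sequences")
    if not (np.isfinite(gap_open) and np.isfinite(gap_extend)):
        raise ValueError("gap penalties must be finite")
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")
    if n_alternatives < 1:
        raise ValueError("n_alternatives must be >= 1")

    q_enc = matrix.encode(q)
    t_enc = matrix.encode(t)
    sub = matrix.scores.astype(np.float64)
    go = float(gap_open)
    ge = float(gap_extend)
    forbid = np.zeros((len(q), len(t)), dtype=np.bool_)

    out: list[LocalAlignment] = []
    for _ in range(n_alternatives):
        H, E, F = _fill(q_enc, t_enc, sub, go, ge, forbid)
        best = H.max()
        if best <= 0:
            break
        ends = np.argwhere(H == best)
        # deterministic order: earliest target end, then earliest query end
        ends = sorted(map(tuple, ends), key=lambda ij: (ij[1], ij[0]))
        candidates = []
        for i, j in ends[:_MAX_TIED_ENDS]:
            cols = _traceback(H, E, F, q_enc, t_enc, sub, go, ge, forbid, i, j)
            aln = _build(cols, qid, tid, q, t, matrix, go, ge)
            candidates.append((aln.t_start, aln.n_gaps, aln.q_start, aln))
        aln = min(candidates, key=lambda c: c[:3])[3]
        out.append(aln)
        # mark used residue pairs for declumping
        qi = aln.q_start - 1
        tj = aln.t_start - 1
        for a, b in zip(aln.aligned_query, aln.aligned_target):
            if a != GAP and b != GAP:
                forbid[qi, tj] = True
                qi += 1
                tj += 1
            elif a == GAP:
                tj += 1
            else:
                qi += 1
    return out
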