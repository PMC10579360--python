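"""In-package fixtures: the study's published worked-example values.

``ALIGNED_PAIRS`` holds the six reported epitope-target aligned pairs
(human sequence over microbial-transglutaminase sequence) with their
reported column counts and identity/similarity numerators, parent antigens,
UniProt accessions and disease annotations. ``POLYCLONAL_BACKGROUND`` and
``MONOCLONAL_BACKGROUND`` hold the reported ELISA background cluster sizes
and statistics, and the quoted per-antigen ODs from the reactivity
analysis. These are frozen reference values, used as ground truth by the
test-suite and the worked examples; nothing here is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import LocalAlignment, alignment_stats, recompute_score
from .matrices import SubstitutionMatrix
from .screen import MimicryHit
from .types import Epitope

__all__ = [
    "AlignedPairRow",
    "ALIGNED_PAIRS",
    "POLYCLONAL_BACKGROUND",
    "MONOCLONAL_BACKGROUND",
    "QUOTED_ODS_POLYCLONAL",
    "QUOTED_ODS_MONOCLONAL",
    "aligned_pair_hits",
]


@dataclass(frozen=True)
class AlignedPairRow:
    antigen: str
    accession: str
    diseases: tuple[str, ...]
    human: str
    mtg: str
    length: int
    n_identity: int
    n_similarity: int


ALIGNED_PAIRS: tuple[AlignedPairRow, ...] = (
    AlignedPairRow(
        antigen="Fibrinogen alpha chain",
        accession="P02671",
        diseases=("AIAS", "AS", "RA", "PA"),
        human="PSRGKSSSYSKQF",
        mtg="PSRMKAVIYSKHF",
        length=13,
        n_identity=8,
        n_similarity=9,
    ),
    AlignedPairRow(
        antigen="Histone H1.2",
        accession="P16403",
        diseases=("AIT", "SS"),
        human="SETAPAAPAAAP",
        mtg="NESAPAASSAGP",
        length=12,
        n_identity=7,
        n_similarity=10,
    ),
    AlignedPairRow(
        antigen=(
            "Dihydrolipoyllysine-residue acetyltransferase component of "
            "pyruvate dehydrogenase complex, mitochondrial"
        ),
        accession="P10515",
        diseases=("PBC", "SS", "T1DM"),
        human="AATASPPTPSAQAP",
        mtg="APAASSAGPSFRAP",
        length=14,
        n_identity=7,
        n_similarity=8,
    ),
    AlignedPairRow(
        antigen="Creatine kinase S-type, mitochondrial",
        accession="P17540",
        diseases=("RA", "T1DM"),
        human="REVENVAITALE",
        mtg="REVASVMNRALE",
        length=12,
        n_identity=7,
        n_similarity=8,
    ),
    AlignedPairRow(
        antigen="Dimethyladenosine transferase 2, mitochondrial",
        accession="Q9H5Q4",
        diseases=("MS", "RA"),
        human="LKVVGMFPSRGEKRA",
        mtg="LCTAGFMPSAGEAAA",
        length=15,
        n_identity=7,
        n_similarity=7,
    ),
    AlignedPairRow(
        antigen="Cytochrome c1, heme protein, mitochondrial",
        accession="P08574",
        diseases=("AU", "RA", "T1DM"),
        human="AANNGALPPDLSY",
        mtg="AADNGAGEETKSY",
        length=13,
        n_identity=7,
        n_similarity=8,
    ),
)

#: Reported polyclonal background: 57 antigens, OD mean 0.16, SD 0.12
#: (cutoff 0.16 + 0.12 = 0.28).
POLYCLONAL_BACKGROUND = {"n": 57, "mean": 0.16, "sd": 0.12}

#: Reported monoclonal background: 67 antigens, OD mean 0.15, SD 0.09
#: (cutoff 0.15 + 0.09 = 0.24).
MONOCLONAL_BACKGROUND = {"n": 67, "mean": 0.15, "sd": 0.09}

#: Per-antigen ODs quoted in the polyclonal reactivity narrative.
QUOTED_ODS_POLYCLONAL = {
    "cardiolipin": 0.26,
    "TG6": 0.29,
    "somatotropin": 0.45,
}

#: Per-antigen ODs quoted in the monoclonal reactivity narrative.
QUOTED_ODS_MONOCLONAL = {
    "TG6": 0.16,
    "mitochondria": 0.33,
    "TG3": 0.38,
}


def aligned_pair_hits(
    matrix: SubstitutionMatrix,
    gap_open: float = 14.0,
    gap_extend: float = 4.0,
) -> list[MimicryHit]:
    """The six reported pairs packaged as ready-made mimicry hits.

    Alignment statistics and scores are recomputed from the aligned strings
    (not copied from the reported numerators), so these hits always satisfy
    the alignment invariants. Coordinates are segment-local (the reported
    pairs do not state positions on the full sequences).
    """
    hits = []
    for i, row in enumerate(ALIGNED_PAIRS):
        stats = alignment_stats(row.human, row.mtg, matrix)
        score = recompute_score(row.human, row.mtg, matrix, gap_open, gap_extend)
        if float(score).is_integer():
            score = int(score)
        aln = LocalAlignment(
            query_id=f"PAIR-{i + 1}",
            target_id="mTG",
            aligned_query=row.human,
            aligned_target=row.mtg,
            q_start=1,
            q_end=len(row.human.replace("-", "")),
            t_start=1,
            t_end=len(row.mtg.replace("-", "")),
            score=score,
            length=stats.length,
            n_identity=stats.n_identity,
            n_similarity=stats.n_similarity,
            n_gaps=stats.n_gaps,
        )
        hits.append(
            MimicryHit(
                epitope=Epitope(
                    epitope_id=f"PAIR-{i + 1}",
                    sequence=row.human.replace("-", ""),
                    parent_antigen=row.antigen,
                    antigen_accession=row.accession,
                    diseases=frozenset(row.diseases),
                ),
                alignment=aln,
                passed_identity_length=True,
                immunogenic=True,
                cross_reactive=True,
            )
        )
    return hits
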