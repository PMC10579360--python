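"""The mimicry screening chain.

Every epitope in the catalog is locally aligned against the target protein;
the best alignment per epitope is kept and passed through three filters in
order:

1. identity/length — at least ``min_identity`` identical residues and an
   alignment of at least ``min_length`` columns (``strict_length`` switches
   to strictly greater-than);
2. immunogenicity — the target-side aligned peptide must have at least one
   predicted HLA binding record under the class threshold (50 nM for
   HLA-I, 500 nM for HLA-II by default);
3. cross-reactivity — the epitope's parent antigen must appear in the set
   of antigens the antibody assay called reactive.

Each filter returns a subset of its input, and a hit in the final report
carries all three flags. Antigen matching uses the UniProt accession when
both sides have one, otherwise case-insensitive name matching through a
small user-extensible synonym map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import LocalAlignment, waterman_eggert_align
from .matrices import SubstitutionMatrix, load_matrix
from .types import BindingRecord, Epitope, ProteinSequence, ScreenConfig

__all__ = [
    "MimicryHit",
    "screen_epitopes",
    "apply_identity_length_filter",
    "immunogenicity_filter",
    "intersect_with_reactive",
    "summarize_by_disease",
    "DEFAULT_ANTIGEN_SYNONYMS",
]

logger = logging.getLogger(__name__)

#: Bundled antigen-name synonyms (normalized alias -> normalized canonical
#: name). The assay panel and the epitope catalog often label the same
#: antigen differently; extend via the ``synonyms`` argument of
#: :func:`intersect_with_reactive`.
DEFAULT_ANTIGEN_SYNONYMS: Mapping[str, str] = {
    "fibrinogen": "fibrinogen alpha chain",
    "mitochondria (m2)": (
        "dihydrolipoyllysine-residue acetyltransferase component of "
        "pyruvate dehydrogenase complex, mitochondrial"
    ),
    "mitochondrial m2": (
        "dihydrolipoyllysine-residue acetyltransferase component of "
        "pyruvate dehydrogenase complex, mitochondrial"
    ),
    "histones": "histone h1.2",
    "creatine kinase": "creatine kinase s-type, mitochondrial",
    "cytochrome c1": "cytochrome c1, heme protein, mitochondrial",
}


def _normalize(name: str) -> str:
    return " ".join(name.lower().split())


@dataclass(frozen=True)
class MimicryHit:
    """An epitope-target alignment with its filter-chain evidence.

    ``binding_evidence`` holds the best supporting record per HLA class for
    the target-side peptide; ``immunogenic`` is true only when at least one
    of them falls under its class threshold.
    """

    epitope: Epitope
    alignment: LocalAlignment
    passed_identity_length: bool
    immunogenic: bool = False
    binding_evidence: tuple[BindingRecord, ...] = field(default_factory=tuple)
    cross_reactive: bool = False

    @property
    def diseases(self) -> frozenset[str]:
        return self.epitope.diseases

    def best_ic50(self, hla_class: str) -> float | None:
        """Best (lowest) supporting IC50 for the given HLA class, if any."""
        vals = [r.ic50_nM for r in self.binding_evidence if r.hla_class == hla_class]
        return min(vals) if vals else None


def apply_identity_length_filter(
    alignment: LocalAlignment, config: ScreenConfig
) -> bool:
    """True iff the alignment meets the identity and length cutoffs.

    Inclusive mode (default) requires ``length >= min_length``; strict mode
    requires ``length > min_length``. The published cutoff wording is
    strict ("length > 12") but the published six-pair table contains two
    12-column rows, so inclusive is the default and strict is preserved as
    an option.
    """
    if alignment.n_identity < config.min_identity:
        return False
    if config.strict_length:
        return alignment.length > config.min_length
    return alignment.length >= config.min_length


def screen_epitopes(
    epitopes: Sequence[Epitope],
    target: ProteinSequence,
    config: ScreenConfig,
    matrix: SubstitutionMatrix | None = None,
) -> list[MimicryHit]:
    """Align every epitope to the target and apply the identity/length cutoff.

    Only the top declumped alignment per epitope is filtered. Returns the
    passing candidates ordered by descending identity, then score, then
    epitope id; logs the stage counts.
    """
    if not target.residues:
        raise ValueError("empty target sequence")
    if matrix is None:
        matrix = load_matrix(config.matrix_name)
    hits = []
    for ep in epitopes:
        alns = waterman_eggert_align(
            ep.sequence,
            target,
            matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            n_alternatives=config.n_alternatives,
        )
        if not alns:
            continue
        best = alns[0]
        best = replace(best, query_id=ep.epitope_id)
        if apply_identity_length_filter(best, config):
            hits.append(
                MimicryHit(epitope=ep, alignment=best, passed_identity_length=True)
            )
    hits.sort(
        key=lambda h: (
            -h.alignment.n_identity,
            -h.alignment.score,
            h.epitope.epitope_id,
        )
    )
    logger.info(
        "alignment stage: %d epitopes -> %d passed identity>=%d, length%s%d",
        len(epitopes),
        len(hits),
        config.min_identity,
        ">" if config.strict_length else ">=",
        config.min_length,
    )
    return hits


def immunogenicity_filter(
    hits: Sequence[MimicryHit],
    binding_records: Sequence[BindingRecord],
    config: ScreenConfig,
) -> list[MimicryHit]:
    """Keep hits whose target-side peptide is a predicted strong HLA binder.

    A hit is retained iff the degapped target-side peptide has at least one
    record with IC50 <= ``hla1_ic50_max`` (class I) or <= ``hla2_ic50_max``
    (class II). Retained hits carry the best record per class. Peptides
    absent from the table are dropped and logged as having no prediction.
    """
    if not binding_records:
        logger.warning(
            "immunogenicity filter: EMPTY binding table - every hit will be "
            "dropped; supply predictions for the target-side peptides"
        )
    by_peptide: dict[str, list[BindingRecord]] = {}
    for rec in binding_records:
        by_peptide.setdefault(rec.peptide, []).append(rec)
    out = []
    for hit in hits:
        peptide = hit.alignment.target_peptide
        records = by_peptide.get(peptide)
        if not records:
            logger.info(
                "immunogenicity filter: no prediction for peptide %s "
                "(epitope %s) - dropped", peptide, hit.epitope.epitope_id,
            )
            continue
        best: dict[str, BindingRecord] = {}
        for rec in records:
            cur = best.get(rec.hla_class)
            if cur is None or rec.ic50_nM < cur.ic50_nM:
                best[rec.hla_class] = rec
        thresholds = {"I": config.hla1_ic50_max, "II": config.hla2_ic50_max}
        strong = any(
            rec.ic50_nM <= thresholds[cls] for cls, rec in best.items()
        )
        if strong:
            out.append(
                replace(
                    hit,
                    immunogenic=True,
                    binding_evidence=tuple(
                        best[c] for c in ("I", "II") if c in best
                    ),
                )
            )
    logger.info("immunogenicity stage: %d -> %d hits", len(hits), len(out))
    return out


def intersect_with_reactive(
    hits: Sequence[MimicryHit],
    reactive_antigens: Iterable[str],
    synonyms: Mapping[str, str] | None = None,
) -> list[MimicryHit]:
    """Keep hits whose parent antigen is in the cross-reactive set.

    Matching is by accession when the reactive entry looks like one,
    otherwise by normalized (case/whitespace-insensitive) name, expanded
    through the bundled synonym map merged with ``synonyms``.
    """
    syn = dict(DEFAULT_ANTIGEN_SYNONYMS)
    if synonyms:
        syn.update({_normalize(k): _normalize(v) for k, v in synonyms.items()})

    def canon(name: str) -> str:
        n = _normalize(name)
        return syn.get(n, n)

    reactive = set()
    reactive_accessions = set()
    for a in reactive_antigens:
        a = a.strip()
        if not a:
            continue
        reactive.add(canon(a))
        # accessions are short and case-sensitive; keep verbatim too
        reactive_accessions.add(a)
    out = []
    for hit in hits:
        acc = hit.epitope.antigen_accession
        match = bool(acc and acc in reactive_accessions) or (
            canon(hit.epitope.parent_antigen) in reactive
        )
        if match:
            out.append(replace(hit, cross_reactive=True))
    logger.info("cross-reactivity stage: %d -> %d hits", len(hits), len(out))
    return out


def summarize_by_disease(hits: Sequence[MimicryHit]) -> pd.DataFrame:
    """Count distinct parent antigens per disease tag.

    An antigen implicated in two diseases is counted once under each.
    Returns a DataFrame with columns ``disease`` and ``n_antigens`` sorted
    by descending count, then disease name.
    """
    per_disease: dict[str, set[str]] = {}
    for hit in hits:
        for d in hit.epitope.diseases:
            per_disease.setdefault(d, set()).add(hit.epitope.parent_antigen)
    rows = [
        {"disease": d, "n_antigens": len(ags)}
        for d, ags in per_disease.items()
    ]
    df = pd.DataFrame(rows, columns=["disease", "n_antigens"])
    if not df.empty:
        df = df.sort_values(
            ["n_antigens", "disease"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
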