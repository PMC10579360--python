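"""The screening filter chain: cutoffs, immunogenicity, cross-reactivity."""

import pytest

from mimicryscan.fixtures import ALIGNED_PAIRS, aligned_pair_hits
from mimicryscan.screen import (
    apply_identity_length_filter,
    immunogenicity_filter,
    intersect_with_reactive,
    screen_epitopes,
    summarize_by_disease,
)
from mimicryscan.synthetic import SyntheticSpec, generate_study
from mimicryscan.types import BindingRecord, Epitope, ScreenConfig


def _aln(blosum62, human, mtg, epitope_id="E1"):
    from mimicryscan.alignment import LocalAlignment, alignment_stats, recompute_score

    stats = alignment_stats(human, mtg, blosum62)
    return LocalAlignment(
        query_id=epitope_id, target_id="T",
        aligned_query=human, aligned_target=mtg,
        q_start=1, q_end=len(human.replace("-", "")),
        t_start=1, t_end=len(mtg.replace("-", "")),
        score=recompute_score(human, mtg, blosum62, 14, 4),
        length=stats.length, n_identity=stats.n_identity,
        n_similarity=stats.n_similarity, n_gaps=stats.n_gaps,
    )


class TestIdentityLengthFilter:
    def test_minimum_identity_floor(self, blosum62):
        cfg = ScreenConfig()
        # 6 identities over 20 columns fails regardless of length
        aln = _aln(blosum62, "ACDEFGAAAAAAAAAAAAAA", "ACDEFGWWWWWWWWWWWWWW")
        assert aln.n_identity == 6
        assert not apply_identity_length_filter(aln, cfg)

    def test_reported_pairs_all_pass_default(self, blosum62):
        cfg = ScreenConfig()
        for hit in aligned_pair_hits(blosum62):
            assert apply_identity_length_filter(hit.alignment, cfg)

    def test_length_12_passes_inclusive_fails_strict(self, blosum62):
        row = next(r for r in ALIGNED_PAIRS if r.length == 12)
        aln = _aln(blosum62, row.human, row.mtg)
        assert apply_identity_length_filter(aln, ScreenConfig())
        assert not apply_identity_length_filter(
            aln, ScreenConfig(strict_length=True)
        )


class TestScreenEpitopes:
    def test_planted_epitopes_recovered_background_rejected(
        self, study_bundle, blosum62
    ):
        cfg = ScreenConfig(seed=study_bundle.spec.seed)
        hits = screen_epitopes(
            list(study_bundle.epitopes), study_bundle.target, cfg, matrix=blosum62
        )
        assert {h.epitope.epitope_id for h in hits} == study_bundle.truth_planted_ids

    def test_exact_substring_is_a_full_identity_hit(self, study_bundle, blosum62):
        target = study_bundle.target
        ep = Epitope(
            epitope_id="SUB", sequence=target.residues[40:55], parent_antigen="Ag"
        )
        (hit,) = screen_epitopes([ep], target, ScreenConfig(), matrix=blosum62)
        assert hit.alignment.n_identity == 15
        assert hit.alignment.t_start == 41

    def test_empty_catalog_gives_empty_result(self, study_bundle, blosum62):
        assert screen_epitopes([], study_bundle.target, ScreenConfig(),
                               matrix=blosum62) == []


class TestImmunogenicityFilter:
    cfg = ScreenConfig()

    def _hit(self, blosum62, mtg_pep="PSRMKAVIYSKHF"):
        aln = _aln(blosum62, "PSRGKSSSYSKQF", mtg_pep)
        from mimicryscan.screen import MimicryHit

        return MimicryHit(
            epitope=Epitope(epitope_id="E1", sequence="PSRGKSSSYSKQF",
                            parent_antigen="Ag"),
            alignment=aln, passed_identity_length=True,
        )

    def test_strong_class_i_binder_retained(self, blosum62):
        hit = self._hit(blosum62)
        recs = [BindingRecord("PSRMKAVIYSKHF", "HLA-A*02:01", "I", 30.0)]
        (kept,) = immunogenicity_filter([hit], recs, self.cfg)
        assert kept.immunogenic and kept.best_ic50("I") == 30.0

    def test_weak_binder_on_every_allele_dropped(self, blosum62):
        hit = self._hit(blosum62)
        recs = [
            BindingRecord("PSRMKAVIYSKHF", "HLA-A*02:01", "I", 5000.0),
            BindingRecord("PSRMKAVIYSKHF", "HLA-DRB1*01:01", "II", 5000.0),
        ]
        assert immunogenicity_filter([hit], recs, self.cfg) == []

    def test_class_ii_threshold_is_500(self, blosum62):
        hit = self._hit(blosum62)
        recs = [BindingRecord("PSRMKAVIYSKHF", "HLA-DRB1*01:01", "II", 450.0)]
        (kept,) = immunogenicity_filter([hit], recs, self.cfg)
        assert kept.best_ic50("II") == 450.0

    def test_peptide_without_prediction_dropped(self, blosum62, caplog):
        hit = self._hit(blosum62)
        recs = [BindingRecord("OTHERPEPTIDE", "HLA-A*02:01", "I", 10.0)]
        import logging

        with caplog.at_level(logging.INFO):
            assert immunogenicity_filter([hit], recs, self.cfg) == []
        assert "no prediction" in caplog.text


class TestIntersectWithReactive:
    def test_synonym_map_matches_short_panel_name(self, blosum62):
        hits = [h for h in aligned_pair_hits(blosum62)
                if h.epitope.parent_antigen == "Fibrinogen alpha chain"]
        kept = intersect_with_reactive(hits, {"fibrinogen"})
        assert len(kept) == 1 and kept[0].cross_reactive

    def test_accession_match_wins_over_name(self, blosum62):
        hits = aligned_pair_hits(blosum62)[:1]
        kept = intersect_with_reactive(hits, {"P02671"})
        assert len(kept) == 1

    def test_absent_antigen_dropped_and_empty_set_empties(self, blosum62):
        hits = aligned_pair_hits(blosum62)
        assert intersect_with_reactive(hits, {"unrelated antigen"}) == []
        assert intersect_with_reactive(hits, set()) == []


class TestDiseaseSummary:
    def test_reported_pairs_summary(self, blosum62):
        """The six reported antigens: 4 relate to RA, 3 to T1DM, 2 to SS."""
        df = summarize_by_disease(aligned_pair_hits(blosum62))
        counts = dict(zip(df["disease"], df["n_antigens"]))
        assert counts["RA"] == 4
        assert counts["T1DM"] == 3
        assert counts["SS"] == 2
        singles = ("AIAS", "PBC", "MS", "PA", "AU", "AIT", "AS")
        assert all(counts[d] == 1 for d in singles)

    def test_empty_hits_empty_table(self):
        assert summarize_by_disease([]).empty

    def test_antigen_counted_once_per_disease(self, blosum62):
        hits = aligned_pair_hits(blosum62)[:1]  # four diseases, one antigen
        df = summarize_by_disease(hits)
        assert set(df["n_antigens"]) == {1}
        assert len(df) == 4


def test_pipeline_monotonicity_on_synthetic_study(study_bundle, blosum62):
    """Each successive filter returns a subset of its input."""
    cfg = ScreenConfig()
    s1 = screen_epitopes(list(study_bundle.epitopes), study_bundle.target,
                         cfg, matrix=blosum62)
    s2 = immunogenicity_filter(s1, list(study_bundle.binding_records), cfg)
    s3 = intersect_with_reactive(s2, study_bundle.designed_reactive)
    ids1 = {h.epitope.epitope_id for h in s1}
    ids2 = {h.epitope.epitope_id for h in s2}
    ids3 = {h.epitope.epitope_id for h in s3}
    assert ids3 <= ids2 <= ids1
    assert ids3 == study_bundle.truth_final_ids
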