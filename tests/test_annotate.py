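import numpy as np
import pytest

from geneloss.annotate import (
    DisruptionEvent,
    ReadEvidence,
    call_status,
    detect_disruptions,
    map_exons,
    stop_context,
    validate_events,
)
from geneloss.simulate import PlannedEdit, sim_gene_locus, substream


def _event_keys(events):
    return sorted((e.kind, e.exon_index, e.cds_nt_pos, e.indel_len, e.allele)
                  for e in events)


class TestMapExons:
    def test_planted_identity_recovered_exactly(self, gba3_model):
        genomic, _ = sim_gene_locus(gba3_model, [], intron_len=500, seed=1)
        alignments = map_exons(gba3_model, genomic)
        assert [a.exon_index for a in alignments] == [1, 2, 3, 4, 5]
        assert all(a.identity == 1.0 for a in alignments)
        assert not any(a.missing_data for a in alignments)
        ivs = [a.tgt_interval for a in alignments]
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_substituted_exons_identity_matches_planted_fraction(self, gba3_model):
        """5% random substitutions: per-exon identity equals the planted
        match fraction (exhaustive truth, no alignment ambiguity)."""
        genomic, _ = sim_gene_locus(gba3_model, [], intron_len=500, seed=2)
        rng = substream(99, "subs")
        alignments = map_exons(gba3_model, genomic)
        mutated = list(genomic)
        planted = {a.exon_index: 0 for a in alignments}
        for a in alignments:
            s, e = a.tgt_interval
            for pos in range(s, e):
                if rng.random() < 0.05:
                    old = mutated[pos]
                    mutated[pos] = {"A": "C", "C": "G",
                                    "G": "T", "T": "A"}[old]
                    planted[a.exon_index] += 1
        realigned = map_exons(gba3_model, "".join(mutated))
        for a in realigned:
            exon_len = a.tgt_interval[1] - a.tgt_interval[0]
            expected = 1.0 - planted[a.exon_index] / exon_len
            assert a.identity == pytest.approx(expected, abs=1e-9)

    def test_declared_gc_donor_not_called_as_loss(self, gba3_model):
        # intron 2 of the reference uses the GC donor dialect
        assert gba3_model.donor_dialect[1] == "GC"
        genomic, _ = sim_gene_locus(gba3_model, [], intron_len=500, seed=3)
        alignments = map_exons(gba3_model, genomic)
        assert alignments[1].donor_obs == "GC"
        assert detect_disruptions(alignments, gba3_model) == []

    def test_unmappable_slice_raises(self, gba3_model):
        rng = substream(5, "unrelated-sequence")
        unrelated = "".join(rng.choice(list("ACGT"), size=300))
        with pytest.raises(ValueError, match="locus not found"):
            map_exons(gba3_model, unrelated)


class TestDetectDisruptions:
    def test_identical_target_yields_no_events(self, gba3_model):
        genomic, _ = sim_gene_locus(gba3_model, [], seed=4)
        assert detect_disruptions(map_exons(gba3_model, genomic),
                                  gba3_model) == []

    @pytest.mark.parametrize("length,frameshift", [(13, True), (3, False),
                                                   (1, True), (6, False)])
    def test_deletion_length_sets_frameshift_flag(self, gba3_model, length,
                                                  frameshift):
        plan = [PlannedEdit(kind="deletion", cds_nt_pos=700, length=length)]
        genomic, truth = sim_gene_locus(gba3_model, plan, seed=5)
        events = detect_disruptions(map_exons(gba3_model, genomic), gba3_model)
        dels = [e for e in events if e.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].indel_len == length
        assert dels[0].frameshift is frameshift
        assert dels[0].exon_index == 3

    def test_planted_stop_reports_context_motif(self, gba3_model):
        # Fig-1-style 4-residue motif ending in X at the planted codon
        plan = [PlannedEdit(kind="stop", cds_nt_pos=3 * 200 - 2,
                            stop_codon="TAA")]
        genomic, _ = sim_gene_locus(gba3_model, plan, seed=6)
        events = detect_disruptions(map_exons(gba3_model, genomic), gba3_model)
        stops = [e for e in events if e.kind == "premature_stop"]
        assert len(stops) == 1
        e = stops[0]
        assert e.codon_index == 200
        assert e.allele == "TAA"
        # context = the four residues at codons 196-199, then X
        assert e.stop_context == gba3_model.protein_seq[195:199] + "X"

    def test_frame_tracked_through_upstream_indel(self, gba3_model):
        """A frameshifting deletion changes downstream stop detection exactly
        as brute-force re-translation of the edited CDS predicts."""
        plan = [PlannedEdit(kind="deletion", cds_nt_pos=500, length=1)]
        genomic, truth = sim_gene_locus(gba3_model, plan, seed=7)
        events = detect_disruptions(map_exons(gba3_model, genomic), gba3_model)
        assert _event_keys(events) == _event_keys(truth.events)
        # the frameshift must generate at least one downstream stop
        assert any(e.kind == "premature_stop" for e in events)

    def test_splice_loss_called_at_right_intron(self, gba3_model):
        plan = [PlannedEdit(kind="splice_loss", intron_index=2,
                            splice_site="donor", new_dinucleotide="AT")]
        genomic, _ = sim_gene_locus(gba3_model, plan, seed=8)
        events = detect_disruptions(map_exons(gba3_model, genomic), gba3_model)
        assert len(events) == 1
        e = events[0]
        assert (e.kind, e.splice_site, e.exon_index) == ("splice_loss",
                                                         "donor", 2)
        assert e.observed_site == "AT"

    def test_missing_data_exon_contributes_no_events(self, gba3_model):
        plan = [PlannedEdit(kind="missing", exon_index=3),
                PlannedEdit(kind="stop", cds_nt_pos=3 * 100 - 2)]
        genomic, truth = sim_gene_locus(gba3_model, plan, seed=9)
        alignments = map_exons(gba3_model, genomic)
        assert alignments[2].missing_data
        events = detect_disruptions(alignments, gba3_model)
        assert all(e.exon_index != 3 for e in events)
        assert any(e.kind == "premature_stop" and e.codon_index == 100
                   for e in events)


class TestStopContext:
    @pytest.mark.parametrize("protein,codon,k,expected", [
        ("MAPDR", 6, 3, "PDRX"),     # stop right after the last residue
        ("MADSLF", 7, 4, "DSLFX"),
        ("MA", 2, 3, "MX"),          # left-truncated near the N-terminus
        ("MAPDR", 4, 2, "APX"),
    ])
    def test_context_motifs(self, protein, codon, k, expected):
        assert stop_context(protein, codon, k) == expected

    def test_out_of_range_codon_errors(self):
        with pytest.raises(ValueError):
            stop_context("MAPDR", 7, 3)
        with pytest.raises(ValueError):
            stop_context("MAPDR", 0, 3)


def _ev(species="sp", key=None, project="p1", dis=10, intact=0):
    return ReadEvidence(project_id=project, species=species,
                        event_key=key, reads_disrupted=dis, reads_intact=intact)


class TestValidateEvents:
    @pytest.fixture
    def event(self):
        return DisruptionEvent(species="sp", gene_id="g",
                               kind="premature_stop", exon_index=3,
                               cds_nt_pos=598, codon_index=200, allele="TAA")

    def test_two_fixed_projects_validate_fixed(self, event):
        evidence = [_ev(key=event.key(), project="p1"),
                    _ev(key=event.key(), project="p2")]
        out = validate_events([event], evidence)
        assert out[0].validation == "validated_fixed"
        assert out[0].n_supporting_projects == 2

    def test_one_project_both_alleles_is_polymorphic(self, event):
        evidence = [_ev(key=event.key(), dis=10, intact=8)]
        out = validate_events([event], evidence)
        assert out[0].validation == "validated_polymorphic"

    def test_projects_fixed_for_different_alleles_is_polymorphic(self, event):
        evidence = [_ev(key=event.key(), project="p1", dis=10, intact=0),
                    _ev(key=event.key(), project="p2", dis=0, intact=12)]
        out = validate_events([event], evidence)
        assert out[0].validation == "validated_polymorphic"

    def test_no_evidence_is_unvalidated(self, event):
        assert validate_events([event], [])[0].validation == "unvalidated"

    def test_single_fixed_project_insufficient(self, event):
        out = validate_events([event], [_ev(key=event.key())])
        assert out[0].validation == "unvalidated"

    def test_unknown_event_key_errors(self, event):
        with pytest.raises(ValueError, match="unknown event"):
            validate_events([event], [_ev(key="bogus:1:1:0")])

    def test_adding_concordant_evidence_never_demotes(self, event):
        """Monotonicity: extra fixed-disrupted projects cannot demote a
        validated_fixed call."""
        evidence = [_ev(key=event.key(), project=f"p{i}") for i in range(2, 7)]
        for n in range(2, 6):
            out = validate_events([event], evidence[:n])
            assert out[0].validation == "validated_fixed"


class TestCallStatus:
    def _event(self, validation, disrupting=True):
        if disrupting:
            return DisruptionEvent(species="sp", gene_id="g",
                                   kind="premature_stop", exon_index=1,
                                   cds_nt_pos=10, codon_index=4,
                                   validation=validation)
        return DisruptionEvent(species="sp", gene_id="g", kind="deletion",
                               exon_index=1, cds_nt_pos=10, codon_index=4,
                               indel_len=3, validation=validation)

    def test_fixed_stop_calls_pseudogene(self):
        call = call_status("sp", "g", [self._event("validated_fixed")])
        assert call.status == "pseudogene"

    def test_polymorphic_only_calls_polymorphic_pseudogene(self):
        call = call_status("sp", "g",
                           [self._event("validated_polymorphic")])
        assert call.status == "polymorphic_pseudogene"

    def test_no_events_full_coverage_is_coding(self):
        assert call_status("sp", "g", []).status == "coding"

    def test_unvalidated_frameshifts_stay_unresolved(self):
        call = call_status("sp", "g", [self._event("unvalidated")])
        assert call.status == "unresolved"

    def test_inframe_indel_does_not_disrupt(self):
        call = call_status("sp", "g",
                           [self._event("validated_fixed", disrupting=False)])
        assert call.status == "coding"

    def test_total_over_validation_lattice(self):
        """call_status returns a legal status for every combination of event
        validation states, disrupting flags, and coverage."""
        statuses = {"coding", "pseudogene", "polymorphic_pseudogene",
                    "unresolved"}
        vals = ["validated_fixed", "validated_polymorphic", "unvalidated"]
        for v1 in vals:
            for v2 in vals:
                for disrupting in (True, False):
                    for coverage in (True, False):
                        events = [self._event(v1),
                                  self._event(v2, disrupting=disrupting)]
                        call = call_status("sp", "g", events,
                                           coverage_complete=coverage)
                        assert call.status in statuses
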