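import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import gotoh_local, revcomp, translate
from spliceopanel.homology import (
    EmptySequenceError,
    OrthologueCall,
    ScoringScheme,
    assign_orthologues,
    call_copy_number,
    evalue,
    local_align_protein,
    reciprocal_assign,
    translate_six_frames,
    translated_search,
)
from spliceopanel.panel import Panel
from spliceopanel.synthetic import back_translate, evolve_orthologue, make_decoys

AA = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AA, min_size=1, max_size=12)


class TestLocalAlign:
    def test_self_alignment_acdefg(self):
        # diagonal BLOSUM62 self-scores: 4 + 9 + 6 + 5 + 6 + 6
        hsp = local_align_protein("ACDEFG", "ACDEFG")
        assert hsp.raw_score == 36
        assert hsp.identity_fraction == 1.0
        assert hsp.length == 6

    def test_self_alignment_properties(self):
        seq = "MKWVLLAHEPQRNDYFGITCS"
        hsp = local_align_protein(seq, seq)
        assert hsp.identity_fraction == 1.0
        assert hsp.query_range == hsp.subject_range == (0, len(seq))

    def test_empty_sequence_errors(self):
        with pytest.raises(EmptySequenceError):
            local_align_protein("", "MKV")

    @given(peptides, peptides)
    @settings(max_examples=150, deadline=None)
    def test_score_matches_brute_force_oracle(self, a, b):
        from Bio.Align import substitution_matrices

        matrix = substitution_matrices.load("BLOSUM62")
        expected = gotoh_local(a, b, matrix, 11, 1)
        assert local_align_protein(a, b).raw_score == expected

    @given(peptides, peptides)
    @settings(max_examples=60, deadline=None)
    def test_score_symmetry(self, a, b):
        assert local_align_protein(a, b).raw_score == local_align_protein(b, a).raw_score

    @given(peptides, peptides, peptides)
    @settings(max_examples=60, deadline=None)
    def test_extension_never_decreases_score(self, a, b, suffix):
        base = local_align_protein(a, b).raw_score
        extended = local_align_protein(a + suffix, b).raw_score
        assert extended >= base


class TestTranslateSixFrames:
    def test_single_codon(self):
        frames = dict(translate_six_frames("ATG"))
        assert frames[1] == "M"

    def test_frame_lengths(self):
        nt = "ACGTACGTACGTACG"  # length 15
        for frame, pep in translate_six_frames(nt):
            off = abs(frame) - 1
            assert len(pep) == (len(nt) - off) // 3

    def test_invalid_nucleotide(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            translate_six_frames("ACGU")

    def test_n_codon_translates_to_x(self):
        frames = dict(translate_six_frames("ATGNNT"))
        assert frames[1][1] == "X"

    @given(st.text(alphabet="ACGT", min_size=60, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_minus_one_equals_independent_revcomp_translation(self, nt):
        frames = dict(translate_six_frames(nt))
        assert frames[-1] == translate(revcomp(nt))

    @given(st.text(alphabet="ACGT", min_size=6, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_all_frames_match_oracle(self, nt):
        frames = dict(translate_six_frames(nt))
        for off in range(3):
            assert frames[off + 1] == translate(nt[off:])
            assert frames[-(off + 1)] == translate(revcomp(nt)[off:])


class TestEvalue:
    def test_worked_example(self):
        # 1000 * 10000 * 2^-50
        assert evalue(50, 1000, 10000) == pytest.approx(8.881784e-9, rel=1e-6)

    def test_unit_search_space(self):
        assert evalue(0, 1, 1) == 1.0

    def test_linear_in_n(self):
        assert evalue(30, 100, 2000) == pytest.approx(2 * evalue(30, 100, 1000))

    def test_monotone_decreasing_in_bits(self):
        assert evalue(40, 100, 100) < evalue(30, 100, 100)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 5)


def _db(panel: Panel) -> dict[str, str]:
    return {e.id: e.sequence for e in panel}


class TestTranslatedSearch:
    def test_exact_back_translation_is_top_hit(self, easy_bundle):
        panel = easy_bundle.panel
        target = panel.entries[0]
        nt = back_translate(target.sequence)
        hits = translated_search(nt, _db(panel), e_max=1e-6)
        assert hits[0].subject_id == target.id
        assert hits[0].identity_fraction == 1.0
        assert hits[0].frame == 1

    def test_shuffled_transcript_no_hits(self, easy_bundle):
        panel = easy_bundle.panel
        nt = list(back_translate(panel.entries[0].sequence))
        random.Random(7).shuffle(nt)
        hits = translated_search("".join(nt), _db(panel), e_max=1e-6)
        assert hits == []

    def test_threshold_strictly_exclusive(self, easy_bundle):
        """A hit with evalue exactly e_max is rejected (strict <)."""
        panel = Panel([easy_bundle.panel.entries[0]])
        nt = back_translate(panel.entries[0].sequence)
        hits = translated_search(nt, _db(panel), e_max=1e300)
        exact = hits[0].evalue
        again = translated_search(nt, _db(panel), e_max=exact)
        assert again == []

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            translated_search("ATG", {}, e_max=1.0)


class TestReciprocalAssign:
    def test_back_translations_recover_exactly(self, easy_bundle):
        panel = Panel(easy_bundle.panel.entries[:5])
        decoys = make_decoys(5, (120, 250), seed=9)
        transcripts = {
            f"t_{e.id}": back_translate(e.sequence) for e in panel
        }
        calls = reciprocal_assign(transcripts, panel, decoys)
        found = {c.panel_id for c in calls if c.status == "found"}
        assert found == {e.id for e in panel}
        for c in calls:
            assert c.transcript_ids == [f"t_{c.panel_id}"]

    def test_empty_transcripts_all_absent(self, easy_bundle):
        panel = Panel(easy_bundle.panel.entries[:3])
        calls = reciprocal_assign({}, panel, {})
        assert all(c.status == "absent" for c in calls)
        assert len(calls) == 3

    def test_decoy_transcript_not_assigned(self, easy_bundle):
        panel = Panel(easy_bundle.panel.entries[:3])
        decoys = make_decoys(3, (150, 200), seed=5)
        decoy_nt = back_translate(next(iter(decoys.values())))
        calls = reciprocal_assign({"d1": decoy_nt}, panel, decoys)
        assert all(c.status == "absent" for c in calls)

    def test_overlapping_decoy_ids_rejected(self, easy_bundle):
        panel = Panel(easy_bundle.panel.entries[:2])
        with pytest.raises(ValueError, match="overlap"):
            reciprocal_assign({}, panel, {panel.entries[0].id: "MKV"})

    def test_diverged_orthologues_recovered(self, easy_bundle):
        panel = Panel(easy_bundle.panel.entries[:8])
        decoys = make_decoys(20, (120, 250), seed=3)
        transcripts = {}
        for e in panel:
            orth = evolve_orthologue(e.sequence, 0.3, seed=11, key=e.id)
            transcripts[f"t_{e.id}"] = back_translate(orth)
        result = assign_orthologues(transcripts, panel, decoys)
        found = {c.panel_id for c in result.calls if c.status == "found"}
        assert found == {e.id for e in panel}
        assert all(result.assignments[f"t_{e.id}"] == e.id for e in panel)


class TestCopyNumber:
    def _call(self, tids):
        return OrthologueCall(
            panel_id="P", status="found", transcript_ids=tids,
            copy_count=len(tids), best_evalue=1e-30,
        )

    def test_single_transcript(self):
        calls = call_copy_number([self._call(["t1"])], {"t1": "ATGAAATTTGGG"})
        assert calls[0].copy_count == 1

    def test_identical_transcripts_one_cluster(self):
        nt = "ATGAAATTTGGGCCCAAATTTGGGTAA"
        calls = call_copy_number(
            [self._call(["t1", "t2"])], {"t1": nt, "t2": nt}
        )
        assert calls[0].copy_count == 1

    def test_diverged_copies_two_clusters(self, easy_bundle):
        from spliceopanel.synthetic import _mutate_nt, _rng

        base = back_translate(easy_bundle.panel.entries[0].sequence)
        other = _mutate_nt(base, 0.2, _rng(4, "test-copy"))
        calls = call_copy_number(
            [self._call(["t1", "t2"])], {"t1": base, "t2": other},
            identity_cluster_threshold=0.95,
        )
        assert calls[0].copy_count == 2


class TestOrthologueCallInvariants:
    def test_found_requires_transcripts(self):
        with pytest.raises(ValueError):
            OrthologueCall(panel_id="P", status="found")

    def test_absent_requires_no_transcripts(self):
        with pytest.raises(ValueError):
            OrthologueCall(
                panel_id="P", status="absent", transcript_ids=["t"], copy_count=1
            )
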