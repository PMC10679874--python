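import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import orf_scan
from spliceopanel.crossval import (
    CrossValRecord,
    OrfAnnotation,
    classify_intactness,
    find_orfs,
    flag_chimera,
    infer_exon_chain,
    project_to_contig,
    projections_to_gff3,
    reconcile_platforms,
)
from spliceopanel.homology import Hsp
from spliceopanel.synthetic import make_genome, make_panel


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGAAATAG", min_aa=1)
        fwd = [o for o in orfs if o.frame == 1]
        assert len(fwd) == 1
        orf = fwd[0]
        assert orf.range == (0, 9)
        assert orf.has_start and orf.has_stop
        assert orf.aa_length == 2  # M, K (stop excluded)

    def test_poly_c_has_no_orf(self):
        assert find_orfs("C" * 60, min_aa=1) == []

    def test_open_ended_span_flagged(self):
        orfs = [o for o in find_orfs("ATGAAAAAA", min_aa=1) if o.frame == 1]
        assert len(orfs) == 1
        assert not orfs[0].has_stop

    def test_invalid_nucleotide(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            find_orfs("ATGXX", min_aa=1)

    @given(st.text(alphabet="ACGT", min_size=30, max_size=300))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_codon_walk(self, nt):
        got = {
            (o.frame, o.range[0], o.range[1], o.has_stop)
            for o in find_orfs(nt, min_aa=1)
        }
        assert got == orf_scan(nt, 1)

    def test_min_aa_filters(self):
        nt = "ATGAAATAG"  # 2 aa ORF
        assert find_orfs(nt, min_aa=3) == [
            o for o in find_orfs(nt, min_aa=3) if o.aa_length >= 3
        ]
        assert not [o for o in find_orfs(nt, min_aa=3) if o.frame == 1]


class TestClassifyIntactness:
    def _orf(self, aa_len, has_start=True, has_stop=True):
        span = 3 * (aa_len + (1 if has_stop else 0))
        return OrfAnnotation(
            transcript_id="t", frame=1, range=(0, span),
            has_start=has_start, has_stop=has_stop,
        )

    def test_full_length_intact(self):
        assert classify_intactness(self._orf(100), panel_len=100, min_cov=0.8)

    def test_missing_stop_not_intact(self):
        assert not classify_intactness(
            self._orf(100, has_stop=False), panel_len=100, min_cov=0.8
        )

    def test_boundary_coverage_inclusive(self):
        assert classify_intactness(self._orf(80), panel_len=100, min_cov=0.8)
        assert not classify_intactness(self._orf(79), panel_len=100, min_cov=0.8)

    def test_invalid_panel_len(self):
        with pytest.raises(ValueError):
            classify_intactness(self._orf(10), panel_len=0)


class TestReconcilePlatforms:
    def test_both(self):
        records, tally = reconcile_platforms({"g": True}, {"g": True})
        assert records[0].intact_class == "both"
        assert tally["both"] == 1

    def test_empty_universe(self):
        records, tally = reconcile_platforms({}, {})
        assert records == [] and sum(tally.values()) == 0

    def test_mismatched_universes(self):
        with pytest.raises(ValueError, match="mismatched universes"):
            reconcile_platforms({"a": True}, {"b": True})

    def test_printed_class_counts_fixture(self):
        # 169-gene fixture with classes (118, 40, 2, 9)
        ngs, fl = {}, {}
        layout = [("both", 118), ("ngs_only", 40), ("fl_only", 2), ("neither", 9)]
        i = 0
        for cls, count in layout:
            for _ in range(count):
                gid = f"g{i}"
                ngs[gid] = cls in ("both", "ngs_only")
                fl[gid] = cls in ("both", "fl_only")
                i += 1
        records, tally = reconcile_platforms(ngs, fl)
        assert (tally["both"], tally["ngs_only"], tally["fl_only"], tally["neither"]) == (
            118, 40, 2, 9,
        )
        assert sum(tally.values()) == len(ngs)

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=3),
            st.tuples(st.booleans(), st.booleans()),
            max_size=30,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_tally_sums_to_universe(self, universe):
        ngs = {g: v[0] for g, v in universe.items()}
        fl = {g: v[1] for g, v in universe.items()}
        _, tally = reconcile_platforms(ngs, fl)
        assert sum(tally.values()) == len(universe)


def _hsp(subject, qr, sr, subject_length, score=500):
    return Hsp(
        query_id="t", subject_id=subject, frame=1, query_range=qr,
        subject_range=sr, raw_score=score, bit_score=100.0, evalue=1e-20,
        identity_fraction=0.9, positive_fraction=0.95,
        length=sr[1] - sr[0], subject_length=subject_length,
    )


class TestFlagChimera:
    def test_disjoint_halves_flagged(self):
        hsps = [
            _hsp("A", (0, 300), (0, 100), 200),
            _hsp("B", (310, 600), (100, 197), 200),
        ]
        flagged, breakpoint = flag_chimera(hsps)
        assert flagged
        assert 300 <= breakpoint <= 310

    def test_single_subject_not_flagged(self):
        hsps = [
            _hsp("A", (0, 300), (0, 100), 200),
            _hsp("A", (310, 600), (100, 200), 200),
        ]
        assert flag_chimera(hsps) == (False, None)

    def test_same_paralogue_group_not_flagged(self):
        hsps = [
            _hsp("A1", (0, 300), (0, 100), 200),
            _hsp("A2", (310, 600), (100, 197), 200),
        ]
        flagged, _ = flag_chimera(hsps, group_of={"A1": "grp", "A2": "grp"})
        assert not flagged

    def test_heavy_overlap_not_flagged(self):
        hsps = [
            _hsp("A", (0, 300), (0, 100), 200),
            _hsp("B", (50, 350), (0, 100), 200),
        ]
        flagged, _ = flag_chimera(hsps)
        assert not flagged

    def test_low_coverage_segment_ignored(self):
        hsps = [
            _hsp("A", (0, 300), (0, 100), 200),
            _hsp("B", (310, 400), (0, 30), 200),  # 15% of subject
        ]
        flagged, _ = flag_chimera(hsps, min_segment_cov=0.4)
        assert not flagged

    def test_no_false_positives_on_generator_transcripts(
        self, easy_bundle, easy_assignment
    ):
        """Zero false chimera flags on the seeded non-chimeric transcripts."""
        tome = easy_bundle.transcriptome
        truth = tome.transcript_truth.set_index("transcript_id")
        for tid in tome.ngs:
            if truth.loc[tid, "is_chimera"]:
                continue
            flagged, _ = flag_chimera(easy_assignment.hsps[tid])
            assert not flagged, tid


@pytest.fixture(scope="module")
def mini_panel():
    return make_panel(3, (150, 220), seed=21)


class TestProjection:
    def test_uninterrupted_cds_single_exon(self, mini_panel):
        entry = mini_panel.entries[0]
        genome = make_genome([entry], intron_table={}, seed=21)
        results = project_to_contig(entry, genome.contigs)
        assert len(results) == 1
        r = results[0]
        assert r.exon_count == 1
        assert r.covered_fraction == pytest.approx(1.0)
        assert r.majority_single_contig
        assert r.intron_ranges == []

    def test_absent_protein_empty_result(self, mini_panel):
        entry = mini_panel.entries[0]
        other = mini_panel.entries[1]
        genome = make_genome([other], intron_table={}, seed=22)
        assert project_to_contig(entry, genome.contigs) == []

    def test_majority_flag_strictly_greater_than_half(self):
        # exactly half the protein projected -> flag must be False
        panel = make_panel(1, (200, 200), seed=5)
        entry = panel.entries[0]
        half = entry.sequence[: len(entry.sequence) // 2]
        genome = make_genome(
            [type(entry)(entry.id, entry.name, entry.category, None, half)],
            intron_table={}, seed=5,
        )
        results = project_to_contig(entry, genome.contigs)
        r = results[0]
        assert r.covered_fraction == pytest.approx(0.5)
        assert not r.majority_single_contig

    def test_empty_contigs_errors(self, mini_panel):
        with pytest.raises(ValueError):
            project_to_contig(mini_panel.entries[0], {})

    @pytest.mark.parametrize("n_introns", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_exon_count_matches_truth(self, n_introns):
        panel = make_panel(1, (240, 260), seed=100 + n_introns)
        entry = panel.entries[0]
        genome = make_genome(
            [entry], intron_table={entry.id: n_introns}, seed=100 + n_introns
        )
        r = project_to_contig(entry, genome.contigs)[0]
        assert r.exon_count == n_introns + 1
        assert len(r.intron_ranges) == n_introns

    def test_seven_intron_gene_all_gt_ag(self, easy_bundle):
        entry = easy_bundle.panel.entries[3]
        cid = f"ctg_{entry.id}"
        r = project_to_contig(entry, {cid: easy_bundle.genome.contigs[cid]})[0]
        assert r.exon_count == 8
        assert r.gt_ag == [True] * 7

    def test_minus_strand_projection(self, mini_panel):
        from oracles import revcomp

        entry = mini_panel.entries[2]
        genome = make_genome([entry], intron_table={entry.id: 2}, seed=31)
        cid = f"ctg_{entry.id}"
        flipped = {cid: revcomp(genome.contigs[cid])}
        r = project_to_contig(entry, flipped)[0]
        assert r.strand == -1
        assert r.exon_count == 3

    def test_short_gap_merges_exons(self):
        contig = "A" * 50
        hsps = [
            _hsp("P", (0, 30), (0, 10), 30, score=50),
            _hsp("P", (40, 50 + 10), (10, 20), 30, score=50),
        ]
        # gap of 10 nt < min_intron 30 -> merged
        r = infer_exon_chain(hsps, contig + "A" * 20, min_intron=30)
        assert r.exon_count == 1

    def test_gff3_export_round(self, mini_panel):
        entry = mini_panel.entries[0]
        genome = make_genome([entry], intron_table={entry.id: 1}, seed=77)
        results = project_to_contig(entry, genome.contigs)
        text = projections_to_gff3(results)
        assert text.startswith("##gff-version 3")
        assert text.count("\texon\t") == results[0].exon_count


class TestCrossValRecord:
    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            CrossValRecord(panel_id="g", intact_class="weird")
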