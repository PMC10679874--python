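"""ORF annotation, cross-platform intactness reconciliation, chimera
flagging, and genomic-contig projection with exon-chain inference.

All coordinates are 0-based half-open; minus-strand features are stored in
forward-contig coordinates with a strand field.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .homology import (
    Hsp,
    ScoringScheme,
    _check_nt,
    _frame_to_nt_range,
    iterative_local_hits,
    translate_six_frames,
)
from .panel import PanelEntry

INTACT_CLASSES = ("both", "ngs_only", "fl_only", "neither")


@dataclass(frozen=True)
class OrfAnnotation:
    transcript_id: str
    frame: int
    range: tuple[int, int]      # nt on the forward transcript, stop codon included
    has_start: bool
    has_stop: bool
    reference_coverage: float = 0.0

    @property
    def aa_length(self) -> int:
        codons = (self.range[1] - self.range[0]) // 3
        return codons - 1 if self.has_stop else codons


@dataclass(frozen=True)
class CrossValRecord:
    panel_id: str
    intact_class: str
    chimera_flag: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.intact_class not in INTACT_CLASSES:
            raise ValueError(f"unknown intact class {self.intact_class!r}")


@dataclass
class ProjectionResult:
    protein_id: str
    contig_id: str
    covered_fraction: float
    majority_single_contig: bool
    exon_count: int
    intron_ranges: list[tuple[int, int]] = field(default_factory=list)
    strand: int = 1
    gt_ag: list[bool] = field(default_factory=list)
    exon_ranges: list[tuple[int, int]] = field(default_factory=list)
    chain_score: int = 0


# ---------------------------------------------------------------------------
# ORF finding and intactness
# ---------------------------------------------------------------------------

def find_orfs(nt: str, min_aa: int = 1) -> list[OrfAnnotation]:
    """All maximal ATG..stop spans of >= *min_aa* codons in six frames.

    A span is maximal when its ATG is the first start codon after the
    previous stop in that frame.  Spans running off the 3' end without a
    stop are reported with ``has_stop=False``.  Ranges are on the forward
    strand of the transcript.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    nt = _check_nt(nt)
    out: list[OrfAnnotation] = []
    for frame, pep in translate_six_frames(nt):
        prev_stop = -1
        i = 0
        n = len(pep)
        while i < n:
            if pep[i] == "*":
                prev_stop = i
                i += 1
                continue
            if pep[i] == "M":
                j = i
                while j < n and pep[j] != "*":
                    j += 1
                has_stop = j < n
                aa_len = j - i
                if aa_len >= min_aa:
                    aa_range = (i, j + 1) if has_stop else (i, j)
                    r = _frame_to_nt_range(frame, aa_range, len(nt))
                    out.append(
                        OrfAnnotation(
                            transcript_id="", frame=frame, range=r,
                            has_start=True, has_stop=has_stop,
                        )
                    )
                prev_stop = j
                i = j + 1
            else:
                i += 1
    out.sort(key=lambda o: (-(o.range[1] - o.range[0]), o.frame, o.range))
    return out


def classify_intactness(
    orf: OrfAnnotation, panel_len: int, min_cov: float = 0.8
) -> bool:
    """Intact iff started, stopped, and covering >= *min_cov* of the
    reference protein length (inclusive boundary)."""
    if panel_len < 1:
        raise ValueError("panel_len must be >= 1")
    return orf.has_start and orf.has_stop and (orf.aa_length / panel_len) >= min_cov


def reconcile_platforms(
    ngs: Mapping[str, bool], fl: Mapping[str, bool]
) -> tuple[list[CrossValRecord], Counter]:
    """Classify each gene as both / ngs_only / fl_only / neither."""
    if set(ngs) != set(fl):
        raise ValueError("mismatched universes between platforms")
    records: list[CrossValRecord] = []
    tally: Counter = Counter()
    for gid in ngs:
        cls = {
            (True, True): "both",
            (True, False): "ngs_only",
            (False, True): "fl_only",
            (False, False): "neither",
        }[(bool(ngs[gid]), bool(fl[gid]))]
        records.append(CrossValRecord(panel_id=gid, intact_class=cls))
        tally[cls] += 1
    return records, tally


# ---------------------------------------------------------------------------
# Chimera flagging
# ---------------------------------------------------------------------------

def flag_chimera(
    transcript_hsps: Sequence[Hsp],
    min_segment_cov: float = 0.4,
    max_overlap_frac: float = 0.1,
    group_of: Mapping[str, str] | None = None,
) -> tuple[bool, int | None]:
    """Flag a transcript whose HSPs split it between two unrelated subjects.

    Flagged iff two HSPs to subjects of different paralogue groups occupy
    query ranges overlapping less than ``max_overlap_frac`` of the shorter
    range, each covering >= *min_segment_cov* of its own subject.  The
    breakpoint is the midpoint between the two ranges (transcript nt).
    *group_of* maps subject id to a group token; subjects not listed are
    each their own group.
    """
    group_of = group_of or {}
    candidates = [
        h for h in transcript_hsps if h.subject_coverage() >= min_segment_cov
    ]
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            ga = group_of.get(a.subject_id, a.subject_id)
            gb = group_of.get(b.subject_id, b.subject_id)
            if ga == gb:
                continue
            (s1, e1), (s2, e2) = sorted([a.query_range, b.query_range])
            overlap = max(0, min(e1, e2) - max(s2, s1))
            shorter = min(e1 - s1, e2 - s2)
            if shorter <= 0 or overlap / shorter >= max_overlap_frac:
                continue
            breakpoint = (min(e1, e2) + max(s1, s2)) // 2
            return True, breakpoint
    return False, None


# ---------------------------------------------------------------------------
# Genomic projection and exon chaining
# ---------------------------------------------------------------------------

def _contig_frame_hsps(
    protein_id: str,
    protein: str,
    contig_id: str,
    contig: str,
    scheme: ScoringScheme,
    e_max: float,
) -> list[tuple[Hsp, int]]:
    """Six-frame HSPs of one contig against one protein, as (hsp, strand).

    The search is effectively ungapped (prohibitive gap penalty): an exon
    then yields exactly one gap-free HSP instead of a gapped alignment
    stitched across introns, and multiple exons per frame are recovered by
    query-side masking.
    """
    hsps: list[tuple[Hsp, int]] = []
    n = len(protein)
    ungapped = ScoringScheme(
        matrix_name=scheme.matrix_name, gap_open=10**6, gap_extend=10**6,
        lam=scheme.lam, k=scheme.k,
    )
    for frame, pep in translate_six_frames(contig):
        if not pep:
            continue
        m = len(pep)
        for raw, bits, ev, qr_aa, sr, ident, pos, cols, _blocks in iterative_local_hits(
            pep, protein, ungapped, e_max, m=m, n=n
        ):
            hsps.append(
                (
                    Hsp(
                        query_id=contig_id, subject_id=protein_id, frame=frame,
                        query_range=_frame_to_nt_range(frame, qr_aa, len(contig)),
                        subject_range=sr, raw_score=raw, bit_score=bits, evalue=ev,
                        identity_fraction=ident / cols if cols else 0.0,
                        positive_fraction=pos / cols if cols else 0.0,
                        length=cols, subject_length=n,
                    ),
                    1 if frame > 0 else -1,
                )
            )
    return hsps


def _union_length(ranges: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(ranges):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def _polish_chain_overlaps(
    chain: list[tuple[int, int, int, int]],
    gene_seq: str,
    protein: str,
    matrix,
) -> list[tuple[int, int, int, int]]:
    """Resolve subject overlaps between consecutive ungapped chain segments.

    Segments are ``(gene_start, gene_end, subj_start, subj_end)`` tuples in
    gene orientation.  A chance extension of one exon's HSP across a splice
    junction overlaps its neighbour on the protein; the split point is
    placed where the summed column scores of the two candidate alignments
    are maximal, which recovers the true codon-aligned boundary when one
    side matches exactly.
    """

    def col_score(gene_start: int, subj_start: int, p: int) -> float:
        gpos = gene_start + 3 * (p - subj_start)
        codon = gene_seq[gpos : gpos + 3]
        try:
            aa = str(Seq(codon).translate())
        except Exception:
            return -4.0
        if len(aa) != 1:
            return -4.0
        try:
            return float(matrix[aa, protein[p]])
        except (KeyError, IndexError):
            return -4.0

    out = [list(chain[0])]
    for seg in chain[1:]:
        prev = out[-1]
        cur = list(seg)
        ov = prev[3] - cur[2]
        # only polish gap-free segments (gene span == 3 * subject span)
        prev_ungapped = prev[1] - prev[0] == 3 * (prev[3] - prev[2])
        cur_ungapped = cur[1] - cur[0] == 3 * (cur[3] - cur[2])
        if ov > 0 and prev_ungapped and cur_ungapped:
            lo, hi = cur[2], prev[3]
            best_t, best_score = lo, None
            for t in range(lo, hi + 1):
                s = sum(col_score(prev[0], prev[2], p) for p in range(lo, t)) + sum(
                    col_score(cur[0], cur[2], p) for p in range(t, hi)
                )
                if best_score is None or s >= best_score:
                    best_t, best_score = t, s  # ties keep the upstream exon
            prev[1] -= 3 * (prev[3] - best_t)
            prev[3] = best_t
            cur[0] += 3 * (best_t - cur[2])
            cur[2] = best_t
        if cur[3] > cur[2]:
            out.append(cur)
    return [tuple(seg) for seg in out if seg[3] > seg[2]]


def infer_exon_chain(
    hsps: Sequence[Hsp],
    contig_seq: str,
    min_intron: int = 30,
    check_gt_ag: bool = True,
    overlap_penalty: int = 3,
    protein_seq: str | None = None,
    matrix=None,
) -> ProjectionResult:
    """Best collinear HSP chain on one contig; gaps >= *min_intron* become
    introns, shorter gaps merge into a single exon.

    Consecutive chain members may partially overlap (chance extensions
    across splice junctions); overlapped columns are charged
    *overlap_penalty* per residue during chaining, and when *protein_seq*
    is given the overlap is resolved exactly by optimal split-point
    scoring.  GT..AG is annotated per intron (in gene orientation) but
    never used as a filter.  All input HSPs must target one protein on one
    contig; the strand with the higher-scoring chain wins.
    """
    if not hsps:
        raise ValueError("no HSPs to chain")
    contig_len = len(contig_seq)
    best: tuple[int, list[Hsp], int] | None = None  # (score, chain, strand)
    for strand in (1, -1):
        strand_hsps = [h for h in hsps if (1 if h.frame > 0 else -1) == strand]
        if not strand_hsps:
            continue

        def gene_range(h: Hsp) -> tuple[int, int]:
            s, e = h.query_range
            return (s, e) if strand == 1 else (contig_len - e, contig_len - s)

        order = sorted(strand_hsps, key=lambda h: (h.subject_range, gene_range(h)))
        n = len(order)
        score = [h.raw_score for h in order]
        back = [-1] * n
        for i in range(n):
            for j in range(i):
                j_s, i_s = order[j].subject_range, order[i].subject_range
                j_g, i_g = gene_range(order[j]), gene_range(order[i])
                # partial overlaps allowed (chance extensions across
                # junctions) but both axes must make strict progress
                if not (
                    j_s[0] <= i_s[0] and j_s[1] < i_s[1]
                    and j_g[0] < i_g[0] and j_g[1] < i_g[1]
                ):
                    continue
                ov = max(0, j_s[1] - i_s[0], -(-(j_g[1] - i_g[0]) // 3))
                cand = score[j] + order[i].raw_score - overlap_penalty * ov
                if cand > score[i]:
                    score[i] = cand
                    back[i] = j
        top = max(range(n), key=lambda i: score[i])
        chain = []
        i = top
        while i != -1:
            chain.append(order[i])
            i = back[i]
        chain.reverse()
        if best is None or score[top] > best[0]:
            best = (score[top], chain, strand)

    chain_score, chain, strand = best

    def gene_range(h: Hsp) -> tuple[int, int]:
        s, e = h.query_range
        return (s, e) if strand == 1 else (contig_len - e, contig_len - s)

    gene_seq = contig_seq if strand == 1 else str(Seq(contig_seq).reverse_complement())
    segments = [
        (gene_range(h)[0], gene_range(h)[1], h.subject_range[0], h.subject_range[1])
        for h in chain
    ]
    if protein_seq is not None and len(segments) > 1:
        if matrix is None:
            matrix = ScoringScheme.protein_default().matrix()
        segments = _polish_chain_overlaps(segments, gene_seq, protein_seq, matrix)

    # merge chain segments separated by < min_intron into exons (gene coords)
    exons: list[list[int]] = []
    for gs, ge, _, _ in segments:
        if exons and gs - exons[-1][1] < min_intron:
            exons[-1][1] = max(exons[-1][1], ge)
        else:
            exons.append([gs, ge])
    introns_gene = [
        (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
    ]

    gt_ag = []
    if check_gt_ag:
        for s, e in introns_gene:
            gt_ag.append(gene_seq[s : s + 2] == "GT" and gene_seq[e - 2 : e] == "AG")

    def to_forward(r: tuple[int, int]) -> tuple[int, int]:
        return r if strand == 1 else (contig_len - r[1], contig_len - r[0])

    covered = _union_length((ss, se) for _, _, ss, se in segments)
    subj_len = chain[0].subject_length
    covered_fraction = covered / subj_len if subj_len else 0.0
    return ProjectionResult(
        protein_id=chain[0].subject_id,
        contig_id=chain[0].query_id,
        covered_fraction=covered_fraction,
        majority_single_contig=covered_fraction > 0.5,
        exon_count=len(exons),
        intron_ranges=sorted(to_forward((s, e)) for s, e in introns_gene),
        strand=strand,
        gt_ag=gt_ag,
        exon_ranges=sorted(to_forward((s, e)) for s, e in exons),
        chain_score=chain_score,
    )


def project_to_contig(
    protein: PanelEntry | tuple[str, str],
    contigs: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-3,
    min_intron: int = 30,
    check_gt_ag: bool = True,
) -> list[ProjectionResult]:
    """Project one protein onto genomic contigs via six-frame search.

    Per contig, ``covered_fraction`` is the union of matched protein
    ranges over the protein length; ``majority_single_contig`` is strict
    ``> 0.5``.  Contigs with no accepted HSP are omitted; a protein found
    nowhere yields an empty list.
    """
    if not contigs:
        raise ValueError("contig set must be non-empty")
    scheme = scheme or ScoringScheme.protein_default()
    if isinstance(protein, PanelEntry):
        pid, pseq = protein.id, protein.sequence
    else:
        pid, pseq = protein
    results: list[ProjectionResult] = []
    for cid, contig in contigs.items():
        contig = _check_nt(contig)
        hsps = [
            h for h, _ in _contig_frame_hsps(pid, pseq, cid, contig, scheme, e_max)
        ]
        if not hsps:
            continue
        res = infer_exon_chain(
            hsps, contig, min_intron=min_intron, check_gt_ag=check_gt_ag,
            protein_seq=pseq, matrix=scheme.matrix(),
        )
        # covered_fraction over ALL accepted HSPs on this contig, chained or not
        covered = _union_length(h.subject_range for h in hsps) / len(pseq)
        res.covered_fraction = covered
        res.majority_single_contig = covered > 0.5
        results.append(res)
    results.sort(key=lambda r: -r.chain_score)
    return results


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def projections_to_gff3(results: Iterable[ProjectionResult]) -> str:
    """GFF3 gene/mRNA/exon features for projection results."""
    lines = ["##gff-version 3"]
    for idx, r in enumerate(results, 1):
        if not r.exon_ranges:
            continue
        start = min(s for s, _ in r.exon_ranges) + 1
        end = max(e for _, e in r.exon_ranges)
        strand = "+" if r.strand == 1 else "-"
        gid = f"gene{idx}_{r.protein_id}"
        lines.append(
            f"{r.contig_id}\tspliceopanel\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        lines.append(
            f"{r.contig_id}\tspliceopanel\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={gid}.t1;Parent={gid}"
        )
        for s, e in r.exon_ranges:
            lines.append(
                f"{r.contig_id}\tspliceopanel\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"Parent={gid}.t1"
            )
    return "\n".join(lines) + "\n"


def crossval_to_tsv(records: Iterable[CrossValRecord]) -> str:
    lines = ["panel_id\tintact_class\tchimera_flag\tnote"]
    for r in records:
        lines.append(f"{r.panel_id}\t{r.intact_class}\t{int(r.chimera_flag)}\t{r.note}")
    return "\n".join(lines) + "\n"
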