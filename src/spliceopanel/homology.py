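"""Translated local-alignment search and reciprocal best-hit orthology.

Desk-scale stand-in for a BLASTX/BLASTP screen: full affine-gap
Smith-Waterman per reading frame (via Biopython's C pairwise aligner), with
Karlin-Altschul bit scores and E-values.  No seeding heuristics, no
composition-based statistics — correctness over speed at test sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .panel import Panel

_NT = set("ACGTN")

# Karlin-Altschul parameters for gapped BLOSUM62 11/1 (standard values).
DEFAULT_PROTEIN_LAMBDA = 0.267
DEFAULT_PROTEIN_K = 0.041
# Ungapped values for +2/-3 match/mismatch at uniform base composition.
DEFAULT_NT_LAMBDA = 0.634
DEFAULT_NT_K = 0.41


class EmptySequenceError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and E-value statistics.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length *k* costs ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_PROTEIN_LAMBDA
    k: float = DEFAULT_PROTEIN_K
    match: int | None = None      # nucleotide mode when set
    mismatch: int | None = None

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        return cls(
            matrix_name="match/mismatch",
            gap_open=5,
            gap_extend=2,
            lam=DEFAULT_NT_LAMBDA,
            k=DEFAULT_NT_K,
            match=2,
            mismatch=-3,
        )

    @property
    def is_nucleotide(self) -> bool:
        return self.match is not None

    def matrix(self):
        if self.is_nucleotide:
            arr = substitution_matrices.Array("ACGTN", dims=2)
            for x in "ACGT":
                for y in "ACGT":
                    arr[x, y] = float(self.match if x == y else self.mismatch)
            for x in "ACGTN":  # N is a mask character, strongly penalized
                arr[x, "N"] = -6.0
                arr["N", x] = -6.0
            return arr
        return substitution_matrices.load(self.matrix_name)

    def make_aligner(self, mode: str) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = self.matrix()
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)


def evalue(bit_score: float, m: int, n: int) -> float:
    """Expected chance alignments at this bit score in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("search-space sizes must be >= 1")
    return m * n * 2.0 ** (-bit_score)


@dataclass(frozen=True)
class Hsp:
    """One local-alignment high-scoring pair.

    For translated (frame != 0) searches ``query_range`` is in forward
    nucleotide coordinates on the transcript, BLASTX-style; for
    protein-protein alignments it is in residue coordinates.  Ranges are
    0-based half-open.
    """

    query_id: str
    subject_id: str
    frame: int                      # +1..+3, -1..-3, or 0 for protein-protein
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float
    positive_fraction: float
    length: int                     # alignment columns, gaps included
    subject_length: int

    def subject_coverage(self) -> float:
        s, e = self.subject_range
        return (e - s) / self.subject_length if self.subject_length else 0.0


@dataclass
class OrthologueCall:
    panel_id: str
    status: str                     # "found" | "absent"
    transcript_ids: list[str] = field(default_factory=list)
    copy_count: int = 0
    best_evalue: float | None = None

    def __post_init__(self) -> None:
        found = self.status == "found"
        if found != bool(self.transcript_ids) or found != (self.copy_count >= 1):
            raise ValueError(
                f"inconsistent call for {self.panel_id}: status={self.status}, "
                f"{len(self.transcript_ids)} transcripts, copy_count={self.copy_count}"
            )


# ---------------------------------------------------------------------------
# Core alignment primitives
# ---------------------------------------------------------------------------

def _check_nt(nt: str) -> str:
    nt = nt.upper()
    bad = set(nt) - _NT
    if bad:
        raise ValueError(f"invalid nucleotide: {sorted(bad)}")
    return nt


def _alignment_stats(aln, matrix) -> tuple[int, int, int, int]:
    """(identities, positives, columns, gap_columns) of a pairwise alignment."""
    a, b = str(aln[0]), str(aln[1])
    ident = pos = gaps = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            ident += 1
        try:
            if matrix[x, y] > 0:
                pos += 1
        except (KeyError, IndexError):
            pass
    return ident, pos, len(a), gaps


def local_align_protein(a: str, b: str, scheme: ScoringScheme | None = None) -> Hsp:
    """Optimal local affine-gap alignment of two protein sequences.

    E-value statistics use the two sequence lengths as the search space.
    Tie-breaking between co-optimal alignments follows the aligner's
    deterministic canonical traceback.
    """
    if not a or not b:
        raise EmptySequenceError("empty sequence")
    scheme = scheme or ScoringScheme.protein_default()
    aligner = scheme.make_aligner("local")
    a, b = a.upper(), b.upper()
    raw = int(aligner.score(a, b))
    if raw <= 0:
        return Hsp(
            query_id="query", subject_id="subject", frame=0,
            query_range=(0, 0), subject_range=(0, 0), raw_score=max(raw, 0),
            bit_score=scheme.bit_score(max(raw, 0)),
            evalue=evalue(scheme.bit_score(max(raw, 0)), len(a), len(b)),
            identity_fraction=0.0, positive_fraction=0.0, length=0,
            subject_length=len(b),
        )
    aln = aligner.align(a, b)[0]
    qb, sb = aln.aligned
    qr = (int(qb[0][0]), int(qb[-1][1]))
    sr = (int(sb[0][0]), int(sb[-1][1]))
    ident, pos, cols, _ = _alignment_stats(aln, aligner.substitution_matrix)
    bits = scheme.bit_score(raw)
    return Hsp(
        query_id="query", subject_id="subject", frame=0,
        query_range=qr, subject_range=sr, raw_score=raw, bit_score=bits,
        evalue=evalue(bits, len(a), len(b)),
        identity_fraction=ident / cols if cols else 0.0,
        positive_fraction=pos / cols if cols else 0.0,
        length=cols, subject_length=len(b),
    )


def translate_six_frames(nt: str) -> list[tuple[int, str]]:
    """All six reading-frame translations of a nucleotide sequence.

    Frames +1..+3 read the forward strand at offsets 0..2; -1..-3 read the
    reverse complement likewise.  Stop codons render as ``*``; codons whose
    translation is ambiguous because of N render as ``X``.
    """
    nt = _check_nt(nt)
    out: list[tuple[int, str]] = []
    fwd = Seq(nt)
    rev = fwd.reverse_complement()
    for strand, seq in ((1, fwd), (-1, rev)):
        for off in range(3):
            usable = len(seq) - off
            trimmed = seq[off : off + usable - usable % 3]
            out.append((strand * (off + 1), str(trimmed.translate())))
    return out


def _frame_to_nt_range(frame: int, aa_range: tuple[int, int], nt_len: int) -> tuple[int, int]:
    """Convert a peptide range in a reading frame to forward nt coordinates."""
    off = abs(frame) - 1
    s = off + 3 * aa_range[0]
    e = off + 3 * aa_range[1]
    if frame > 0:
        return (s, e)
    return (nt_len - e, nt_len - s)


def iterative_local_hits(
    query: str,
    subject: str,
    scheme: ScoringScheme,
    e_max: float,
    m: int | None = None,
    n: int | None = None,
    mask_char: str | None = None,
    max_hits: int = 50,
):
    """Repeated local alignment with query-side masking.

    Yields tuples ``(raw, bits, ev, query_range, subject_range, ident, pos,
    cols, blocks)`` for every successive non-overlapping (on the query)
    local hit with ``evalue < e_max``, best first; ``blocks`` pairs the
    gap-free aligned segments ``((qs, qe), (ss, se))``.  Used to recover
    multiple HSPs per frame (split genes, tandem repeats).
    """
    mask_char = mask_char or ("N" if scheme.is_nucleotide else "*")
    aligner = scheme.make_aligner("local")
    matrix = aligner.substitution_matrix
    m = m if m is not None else len(query)
    n = n if n is not None else len(subject)
    q = query
    hits = []
    for _ in range(max_hits):
        raw = aligner.score(q, subject)
        if raw <= 0:
            break
        bits = scheme.bit_score(raw)
        ev = evalue(bits, m, n)
        if ev >= e_max:
            break
        aln = aligner.align(q, subject)[0]
        qb, sb = aln.aligned
        qr = (int(qb[0][0]), int(qb[-1][1]))
        sr = (int(sb[0][0]), int(sb[-1][1]))
        ident, pos, cols, _ = _alignment_stats(aln, matrix)
        blocks = tuple(
            ((int(qs), int(qe)), (int(ss), int(se)))
            for (qs, qe), (ss, se) in zip(qb, sb)
        )
        hits.append((int(raw), bits, ev, qr, sr, ident, pos, cols, blocks))
        q = q[: qr[0]] + mask_char * (qr[1] - qr[0]) + q[qr[1] :]
    return hits


def translated_search(
    transcript: str,
    db: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-6,
    query_id: str = "query",
    db_residues: int | None = None,
    multi_hsp: bool = False,
) -> list[Hsp]:
    """Six-frame translated search of one transcript against a protein set.

    Returns the best HSP per (frame, subject) with ``evalue < e_max``
    (strict), sorted by ascending E-value; with ``multi_hsp`` every
    query-disjoint HSP per frame/subject is reported (needed for chimera
    and split-gene analysis).

    The E-value search space is (frame peptide length) x (total residues in
    *db*, overridable via *db_residues*).
    """
    if not db:
        raise ValueError("database must be non-empty")
    scheme = scheme or ScoringScheme.protein_default()
    nt = _check_nt(transcript)
    n = db_residues if db_residues is not None else sum(len(s) for s in db.values())
    aligner = scheme.make_aligner("local")
    matrix = aligner.substitution_matrix
    hsps: list[Hsp] = []
    for frame, pep in translate_six_frames(nt):
        if not pep:
            continue
        m = len(pep)
        for sid, prot in db.items():
            if not prot:
                continue
            if multi_hsp:
                found = iterative_local_hits(pep, prot, scheme, e_max, m=m, n=n)
            else:
                raw = aligner.score(pep, prot)
                bits = scheme.bit_score(raw)
                ev = evalue(bits, m, n)
                if raw <= 0 or ev >= e_max:
                    continue
                aln = aligner.align(pep, prot)[0]
                qb, sb = aln.aligned
                ident, pos, cols, _ = _alignment_stats(aln, matrix)
                found = [
                    (int(raw), bits, ev,
                     (int(qb[0][0]), int(qb[-1][1])),
                     (int(sb[0][0]), int(sb[-1][1])),
                     ident, pos, cols, None)
                ]
            for raw, bits, ev, qr_aa, sr, ident, pos, cols, _blocks in found:
                hsps.append(
                    Hsp(
                        query_id=query_id, subject_id=sid, frame=frame,
                        query_range=_frame_to_nt_range(frame, qr_aa, len(nt)),
                        subject_range=sr, raw_score=raw, bit_score=bits,
                        evalue=ev,
                        identity_fraction=ident / cols if cols else 0.0,
                        positive_fraction=pos / cols if cols else 0.0,
                        length=cols, subject_length=len(prot),
                    )
                )
    hsps.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id, h.frame))
    return hsps


# ---------------------------------------------------------------------------
# Reciprocal best-hit assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    calls: list[OrthologueCall]
    assignments: dict[str, str]             # transcript id -> panel entry id
    hsps: dict[str, list[Hsp]]              # transcript id -> panel+decoy HSPs


def _panel_member_db(panel: Panel) -> tuple[dict[str, str], dict[str, str]]:
    """(member-sequence db, member id -> entry id map) over a panel."""
    db: dict[str, str] = {}
    member_to_entry: dict[str, str] = {}
    for entry in panel:
        for mid, seq in entry.members:
            db[mid] = seq
            member_to_entry[mid] = entry.id
    return db, member_to_entry


def assign_orthologues(
    transcripts: Mapping[str, str],
    panel: Panel,
    decoys: Mapping[str, str] | None = None,
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-6,
    forward_background: bool = True,
) -> AssignmentResult:
    """Strict reciprocal-best-hit assignment of transcripts to panel entries.

    A transcript is assigned to entry *p* iff its best hit across the panel
    plus the decoy background is a member sequence of *p* (forward test)
    and its best hit within the panel alone is also *p* (reciprocal test),
    both with ``evalue < e_max``.  With ``forward_background=False`` the
    decoy background is ignored — the looser panel-only screen.
    """
    scheme = scheme or ScoringScheme.protein_default()
    decoys = dict(decoys or {})
    panel_db, member_to_entry = _panel_member_db(panel)
    overlap = set(decoys) & set(panel_db)
    if overlap:
        raise ValueError(f"decoys overlap panel member ids: {sorted(overlap)}")
    db = {**panel_db, **decoys}
    n_db = sum(len(s) for s in db.values())

    assignments: dict[str, str] = {}
    best_ev: dict[str, dict[str, float]] = {}
    all_hsps: dict[str, list[Hsp]] = {}
    for tid, nt in transcripts.items():
        hsps = translated_search(
            nt, db, scheme, e_max, query_id=tid, db_residues=n_db
        )
        all_hsps[tid] = hsps
        if not hsps:
            continue
        panel_hits = [h for h in hsps if h.subject_id in member_to_entry]
        if not panel_hits:
            continue
        reciprocal_entry = member_to_entry[panel_hits[0].subject_id]
        if forward_background:
            forward_subject = hsps[0].subject_id
            if forward_subject not in member_to_entry:
                continue  # best background hit wins: transcript is not panel
            if member_to_entry[forward_subject] != reciprocal_entry:
                continue
        assignments[tid] = reciprocal_entry
        best_ev.setdefault(reciprocal_entry, {})[tid] = panel_hits[0].evalue

    calls: list[OrthologueCall] = []
    for entry in panel:
        tids = sorted(t for t, p in assignments.items() if p == entry.id)
        if tids:
            calls.append(
                OrthologueCall(
                    panel_id=entry.id, status="found", transcript_ids=tids,
                    copy_count=len(tids),
                    best_evalue=min(best_ev[entry.id][t] for t in tids),
                )
            )
        else:
            calls.append(OrthologueCall(panel_id=entry.id, status="absent"))
    return AssignmentResult(calls=calls, assignments=assignments, hsps=all_hsps)


def reciprocal_assign(
    transcripts: Mapping[str, str],
    panel: Panel,
    decoys: Mapping[str, str] | None = None,
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-6,
    forward_background: bool = True,
) -> list[OrthologueCall]:
    return assign_orthologues(
        transcripts, panel, decoys, scheme, e_max, forward_background
    ).calls


# ---------------------------------------------------------------------------
# Copy-number calling
# ---------------------------------------------------------------------------

def _nt_identity(a: str, b: str, aligner) -> float:
    aln = aligner.align(a, b)[0]
    x, y = str(aln[0]), str(aln[1])
    ident = sum(1 for p, q in zip(x, y) if p == q and p != "-")
    return ident / len(x) if x else 0.0


def call_copy_number(
    calls: Sequence[OrthologueCall],
    transcripts: Mapping[str, str],
    identity_cluster_threshold: float = 0.95,
) -> list[OrthologueCall]:
    """Single-linkage cluster each entry's transcripts by global nt identity.

    ``copy_count`` becomes the number of clusters at >= the threshold.
    """
    scheme = ScoringScheme.nucleotide_default()
    aligner = scheme.make_aligner("global")
    out: list[OrthologueCall] = []
    for call in calls:
        if call.status != "found" or len(call.transcript_ids) < 2:
            out.append(replace_copy(call, call.copy_count))
            continue
        tids = call.transcript_ids
        parent = list(range(len(tids)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(tids)):
            for j in range(i + 1, len(tids)):
                ident = _nt_identity(transcripts[tids[i]], transcripts[tids[j]], aligner)
                if ident >= identity_cluster_threshold:
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(len(tids))})
        out.append(replace_copy(call, n_clusters))
    return out


def replace_copy(call: OrthologueCall, copy_count: int) -> OrthologueCall:
    return OrthologueCall(
        panel_id=call.panel_id, status=call.status,
        transcript_ids=list(call.transcript_ids), copy_count=copy_count,
        best_evalue=call.best_evalue,
    )


# ---------------------------------------------------------------------------
# Tabular export (BLAST outfmt-6 compatible columns + frame)
# ---------------------------------------------------------------------------

OUTFMT6_HEADER = (
    "qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\t"
    "qstart\tqend\tsstart\tsend\tevalue\tbitscore\tframe"
)


def hsps_to_tsv(hsps: Iterable[Hsp]) -> str:
    lines = [OUTFMT6_HEADER]
    for h in hsps:
        aligned_cols = h.length
        ident = round(h.identity_fraction * aligned_cols)
        pos = round(h.positive_fraction * aligned_cols)
        gaps = 0  # columns tracked implicitly; mismatches = cols - ident - gaps
        mismatch = aligned_cols - ident - gaps
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    h.query_id, h.subject_id,
                    f"{100 * h.identity_fraction:.1f}", aligned_cols, mismatch, 0,
                    h.query_range[0] + 1, h.query_range[1],
                    h.subject_range[0] + 1, h.subject_range[1],
                    f"{h.evalue:.2e}", f"{h.bit_score:.1f}", h.frame,
                )
            )
        )
    return "\n".join(lines) + "\n"
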