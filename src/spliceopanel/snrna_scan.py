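"""snRNA gene detection in genomic contigs: ordered-query homology scan
with fallback, tandem-array calling, motif annotation, and U2/U6 helix
complementarity."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Seq import Seq

from .homology import ScoringScheme, _check_nt, evalue, iterative_local_hits

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]", "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

MOTIF_NAMES = (
    "Sm site", "LSm site", "branch-point interaction", "5'SS interaction",
    "helix Ia", "helix Ib", "helix II",
)

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class SnrnaHit:
    contig_id: str
    query_id: str
    range: tuple[int, int]      # forward contig coordinates, 0-based half-open
    strand: int                 # +1 / -1
    identity_fraction: float
    evalue: float

    @property
    def hit_length(self) -> int:
        return self.range[1] - self.range[0]


@dataclass
class TandemArray:
    contig_id: str
    element_id: str
    copy_count: int
    strand: int
    unit_starts: list[int]
    spacings: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.copy_count < 2:
            raise ValueError("a tandem array needs >= 2 copies")
        if len(self.spacings) != self.copy_count - 1:
            raise ValueError("spacings must have copy_count - 1 entries")


@dataclass(frozen=True)
class MotifAnnotation:
    motif_name: str
    range: tuple[int, int]
    pattern: str


@dataclass
class ScanOutcome:
    hits: list[SnrnaHit]
    successful_query: str | None
    failed_queries: list[str]

    @property
    def status(self) -> str:
        return "ok" if self.successful_query else "all queries failed"


# ---------------------------------------------------------------------------
# Homology scan
# ---------------------------------------------------------------------------

def _scan_one_query(
    contigs: Mapping[str, str],
    qid: str,
    qseq: str,
    scheme: ScoringScheme,
    e_max: float,
    max_hits_per_contig: int = 60,
) -> list[SnrnaHit]:
    hits: list[SnrnaHit] = []
    n_db = sum(len(c) for c in contigs.values())
    for cid, contig in contigs.items():
        contig = _check_nt(contig)
        L = len(contig)
        for strand, seq in ((1, contig), (-1, str(Seq(contig).reverse_complement()))):
            for raw, bits, ev, qr, sr, ident, pos, cols, _blocks in iterative_local_hits(
                seq, qseq, scheme, e_max, m=len(qseq), n=n_db,
                max_hits=max_hits_per_contig,
            ):
                rng = qr if strand == 1 else (L - qr[1], L - qr[0])
                hits.append(
                    SnrnaHit(
                        contig_id=cid, query_id=qid, range=rng, strand=strand,
                        identity_fraction=ident / cols if cols else 0.0,
                        evalue=ev,
                    )
                )
    hits.sort(key=lambda h: (h.contig_id, h.range))
    return hits


def scan_contigs(
    contigs: Mapping[str, str],
    queries: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-6,
    exhaustive: bool = False,
) -> ScanOutcome:
    """Try snRNA queries in order; the first that hits anything wins.

    Each query is searched on both strands of every contig, with repeated
    masking so tandem copies yield one hit each.  With *exhaustive*, all
    queries are run and the union of hits returned (the successful-query
    label is still the first that hit).
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    scheme = scheme or ScoringScheme.nucleotide_default()
    failed: list[str] = []
    all_hits: list[SnrnaHit] = []
    successful: str | None = None
    for qid, qseq in queries:
        hits = _scan_one_query(contigs, qid, _check_nt(qseq), scheme, e_max)
        if hits:
            if successful is None:
                successful = qid
            all_hits.extend(hits)
            if not exhaustive:
                break
        else:
            failed.append(qid)
    all_hits.sort(key=lambda h: (h.contig_id, h.range))
    return ScanOutcome(hits=all_hits, successful_query=successful, failed_queries=failed)


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------

def find_tandem_arrays(
    hits: Sequence[SnrnaHit], max_spacer: int = 1000
) -> list[TandemArray]:
    """Maximal runs of >= 2 same-element, same-strand, same-contig hits with
    successive start-to-start spacing <= *max_spacer*."""
    arrays: list[TandemArray] = []
    groups: dict[tuple[str, str, int], list[SnrnaHit]] = {}
    for h in hits:
        groups.setdefault((h.contig_id, h.query_id, h.strand), []).append(h)
    for (cid, qid, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: h.range)
        run: list[SnrnaHit] = []
        for h in members + [None]:
            if (
                h is not None
                and run
                and h.range[0] - run[-1].range[0] <= max_spacer
            ):
                run.append(h)
                continue
            if len(run) >= 2:
                starts = [r.range[0] for r in run]
                arrays.append(
                    TandemArray(
                        contig_id=cid, element_id=qid, copy_count=len(run),
                        strand=strand, unit_starts=starts,
                        spacings=[b - a for a, b in zip(starts, starts[1:])],
                    )
                )
            run = [h] if h is not None else []
    return arrays


# ---------------------------------------------------------------------------
# Motifs and helices
# ---------------------------------------------------------------------------

def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r}")
        parts.append(IUPAC[ch])
    return re.compile("(?=(" + "".join(parts) + "))")


def annotate_motifs(
    snrna: str, motif_config: str | Sequence[Mapping]
) -> list[MotifAnnotation]:
    """Annotate configured IUPAC motifs on an snRNA sequence.

    *motif_config* is a YAML path or a list of dicts with keys ``name``,
    ``pattern`` and optional ``window`` ([start, end], 0-based half-open,
    constraining the match start).  Overlapping matches are all reported.
    """
    if isinstance(motif_config, str):
        with open(motif_config) as fh:
            motif_config = yaml.safe_load(fh)
    seq = _check_nt(snrna.upper().replace("U", "T"))
    out: list[MotifAnnotation] = []
    for motif in motif_config:
        rx = _iupac_regex(motif["pattern"])
        window = motif.get("window")
        plen = len(motif["pattern"])
        for m in rx.finditer(seq):
            start = m.start()
            if window is not None and not (window[0] <= start < window[1]):
                continue
            out.append(
                MotifAnnotation(
                    motif_name=motif["name"],
                    range=(start, start + plen),
                    pattern=motif["pattern"],
                )
            )
    out.sort(key=lambda a: (a.range, a.motif_name))
    return out


def helix_complementarity(u2_region: str, u6_region: str) -> float:
    """Fraction of antiparallel positions forming Watson-Crick or G.U pairs."""
    a = u2_region.upper().replace("U", "T")
    b = u6_region.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("helix regions must have equal lengths")
    if not a:
        raise ValueError("empty helix region")
    b = b[::-1]
    paired = sum(1 for x, y in zip(a, b) if (x, y) in _WC_PAIRS)
    return paired / len(a)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def hits_to_bed6(hits: Iterable[SnrnaHit]) -> str:
    lines = []
    for h in hits:
        score = min(1000, int(round(1000 * h.identity_fraction)))
        strand = "+" if h.strand == 1 else "-"
        lines.append(
            f"{h.contig_id}\t{h.range[0]}\t{h.range[1]}\t{h.query_id}\t{score}\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def arrays_to_json_obj(arrays: Iterable[TandemArray]) -> list[dict]:
    return [
        {
            "contig_id": a.contig_id,
            "element_id": a.element_id,
            "copy_count": a.copy_count,
            "strand": a.strand,
            "unit_starts": a.unit_starts,
            "spacings": a.spacings,
        }
        for a in arrays
    ]
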