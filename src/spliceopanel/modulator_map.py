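"""Splicing-modulator contact-residue mapping.

Transfers structure-defined drug-contact residues from a reference protein
onto a query through a pairwise global alignment, and reports an overall
similarity percentage.  Reference numbering is the ungapped reference
sequence's 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import yaml

from .homology import EmptySequenceError, ScoringScheme
from .sl_scan import round_half_up


@dataclass(frozen=True)
class ContactSet:
    modulator: str
    protein: str
    contacts: tuple[tuple[int, str], ...]   # (1-based reference position, residue)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.contacts]
        if positions != sorted(set(positions)):
            raise ValueError("contact positions must be strictly increasing")
        for _, res in self.contacts:
            if len(res) != 1:
                raise ValueError("contact residues must be single letters")


@dataclass(frozen=True)
class ResidueMapping:
    ref_pos: int                 # 1-based
    ref_res: str
    query_pos: int | None        # 1-based, None when the contact hits a gap
    query_res: str | None
    conserved: bool


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")


def global_align_protein(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment (end gaps penalized)."""
    if not a or not b:
        raise EmptySequenceError("empty sequence")
    scheme = scheme or ScoringScheme.protein_default()
    aligner = scheme.make_aligner("global")
    aln = aligner.align(a.upper(), b.upper())[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=float(aln.score)
    )


def percent_similarity(
    alignment: PairwiseAlignment, scheme: ScoringScheme | None = None
) -> int:
    """Percentage of alignment columns with a positive substitution score.

    Gap columns count in the denominator but can never be positive.
    Rounded half-up to the nearest integer.
    """
    scheme = scheme or ScoringScheme.protein_default()
    matrix = scheme.matrix()
    positive = 0
    total = len(alignment.aligned_a)
    if total == 0:
        return 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" or y == "-":
            continue
        try:
            if matrix[x, y] > 0:
                positive += 1
        except (KeyError, IndexError):
            pass
    return int(round_half_up(100.0 * positive / total, 0))


def map_contact_residues(
    alignment: PairwiseAlignment, contacts: ContactSet
) -> tuple[list[ResidueMapping], str]:
    """Project contact residues through the alignment; report a verdict.

    The reference is row A of the alignment.  Contacts aligned to a gap in
    the query are unmapped and counted as divergent.  The verdict is
    ``"all contacts conserved"`` or ``"divergence at: <positions>"``.
    """
    ref_len = sum(1 for c in alignment.aligned_a if c != "-")
    for pos, res in contacts.contacts:
        if not 1 <= pos <= ref_len:
            raise ValueError(f"contact position out of range: {pos}")

    wanted = dict(contacts.contacts)
    mappings: list[ResidueMapping] = []
    ref_pos = query_pos = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x != "-":
            ref_pos += 1
        if y != "-":
            query_pos += 1
        if x != "-" and ref_pos in wanted:
            expected = wanted[ref_pos]
            if x != expected:
                raise ValueError(
                    f"contact residue mismatch at {ref_pos}: reference has {x}, "
                    f"contact set expects {expected}"
                )
            if y == "-":
                mappings.append(
                    ResidueMapping(ref_pos, x, None, None, conserved=False)
                )
            else:
                mappings.append(
                    ResidueMapping(ref_pos, x, query_pos, y, conserved=(y == x))
                )
    divergent = [m for m in mappings if not m.conserved]
    if divergent:
        detail = ", ".join(
            f"{m.ref_res}{m.ref_pos}{'-' if m.query_res is None else m.query_res}"
            for m in divergent
        )
        verdict = f"divergence at: {detail}"
    else:
        verdict = "all contacts conserved"
    return mappings, verdict


def load_contact_sets(path: str | None = None) -> list[ContactSet]:
    """Load contact sets from YAML; default is the packaged config."""
    if path is None:
        text = resources.files("spliceopanel").joinpath("data/contacts.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    return [
        ContactSet(
            modulator=d["modulator"],
            protein=d["protein"],
            contacts=tuple((int(c["position"]), c["residue"]) for c in d["contacts"]),
        )
        for d in data
    ]


def mappings_to_tsv(
    mappings: Sequence[ResidueMapping], contacts: ContactSet, verdict: str
) -> str:
    lines = [f"# {contacts.modulator} vs {contacts.protein}: {verdict}"]
    lines.append("ref_pos\tref_res\tquery_pos\tquery_res\tconserved")
    for m in mappings:
        lines.append(
            f"{m.ref_pos}\t{m.ref_res}\t{m.query_pos if m.query_pos else '-'}\t"
            f"{m.query_res or '-'}\t{int(m.conserved)}"
        )
    return "\n".join(lines) + "\n"
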