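"""Spliced-leader (SL) detection at read 5' termini and trans-splicing
prevalence estimation."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

from statsmodels.stats.proportion import proportion_confint


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SLCall:
    record_id: str
    detected: bool
    matched_len: int = 0
    mismatches: int = 0
    read_offset: int = 0


@dataclass(frozen=True)
class PrevalenceEstimate:
    n_flagged: int
    n_total: int
    proportion: float
    ci_low: float
    ci_high: float

    def percent(self, ndigits: int = 1) -> float:
        """Percentage rounded half-up; ndigits=0 gives an integer value."""
        pct = round_half_up(100.0 * self.proportion, ndigits)
        return int(pct) if ndigits == 0 else pct

    @classmethod
    def from_counts(cls, n_flagged: int, n_total: int) -> "PrevalenceEstimate":
        if n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= n_flagged <= n_total:
            raise ValueError("n_flagged must be in [0, n_total]")
        lo, hi = proportion_confint(n_flagged, n_total, alpha=0.05, method="wilson")
        return cls(
            n_flagged=n_flagged,
            n_total=n_total,
            proportion=n_flagged / n_total,
            ci_low=float(lo),
            ci_high=float(hi),
        )


def detect_sl(
    read: str,
    sl: str,
    min_match: int = 12,
    max_mismatch: int = 1,
    window: int = 5,
    record_id: str = "",
) -> SLCall:
    """Look for a suffix of the SL exon near the 5' end of a read.

    Detected iff some suffix of *sl* of length >= *min_match* matches the
    read (no indels) starting within the first *window* nt with
    <= *max_mismatch* mismatches.  The longest qualifying suffix wins;
    ties prefer the smallest read offset.  Only 5'-terminal placements are
    considered — trans-splicing adds the SL at the 5' end.
    """
    if len(sl) < min_match:
        raise ValueError("SL sequence shorter than min_match")
    read, sl = read.upper(), sl.upper()
    for length in range(len(sl), min_match - 1, -1):
        suffix = sl[-length:]
        for offset in range(0, window + 1):
            if offset + length > len(read):
                continue
            seg = read[offset : offset + length]
            mismatches = sum(1 for a, b in zip(seg, suffix) if a != b)
            if mismatches <= max_mismatch:
                return SLCall(
                    record_id=record_id, detected=True, matched_len=length,
                    mismatches=mismatches, read_offset=offset,
                )
    return SLCall(record_id=record_id, detected=False)


def strip_sl(read: str, call: SLCall) -> str:
    """Remove the detected SL prefix (and any offset bases before it)."""
    if not call.detected:
        raise ValueError("cannot strip an undetected SL call")
    return read[call.read_offset + call.matched_len :]


def estimate_prevalence(
    calls: Sequence[SLCall], per_gene: Mapping[str, str] | None = None
) -> PrevalenceEstimate:
    """Aggregate SL calls into a prevalence with a Wilson 95% interval.

    With *per_gene* (record id -> gene id) a gene counts as flagged when at
    least one of its records is detected, and the denominator is the number
    of genes in the map; otherwise records are counted directly.
    """
    if per_gene is not None:
        genes = set(per_gene.values())
        if not genes:
            raise ValueError("empty gene map")
        flagged = {per_gene[c.record_id] for c in calls if c.detected and c.record_id in per_gene}
        return PrevalenceEstimate.from_counts(len(flagged), len(genes))
    if not calls:
        raise ValueError("empty call list")
    return PrevalenceEstimate.from_counts(
        sum(1 for c in calls if c.detected), len(calls)
    )


def default_sl_sequence() -> str:
    """The packaged synthetic 24-mer SL exon."""
    text = resources.files("spliceopanel").joinpath("data/sl_default.fa").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


def calls_to_tsv(calls: Iterable[SLCall]) -> str:
    lines = ["record_id\tdetected\tmatched_len\tmismatches\tread_offset"]
    for c in calls:
        lines.append(
            f"{c.record_id}\t{int(c.detected)}\t{c.matched_len}\t{c.mismatches}\t{c.read_offset}"
        )
    return "\n".join(lines) + "\n"
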