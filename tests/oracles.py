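"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive and shares no code with the package:
plain-Python DP, exhaustive scans, direct enumeration.
"""

from __future__ import annotations

NEG = float("-inf")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# minimal standard-code table for the oracle translator
_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(nt: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(nt))


def translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        out.append(_CODONS.get(codon, "X"))
    return "".join(out)


def gotoh_local(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Brute-force affine-gap Smith-Waterman score.

    A gap of length k costs gap_open + k * gap_extend (BLAST convention).
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
            )
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return int(best)


def gotoh_global(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Brute-force affine-gap Needleman-Wunsch score with penalized end gaps."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
    return int(max(M[n][m], X[n][m], Y[n][m]))


def orf_scan(nt: str, min_aa: int) -> set[tuple[int, int, int, bool]]:
    """Exhaustive codon walk over six frames.

    Returns {(frame, start_nt, end_nt, has_stop)} with ranges on the
    forward strand, stop codon included when present.
    """
    found = set()
    L = len(nt)
    for strand, seq in ((1, nt), (-1, revcomp(nt))):
        for off in range(3):
            codons = [
                seq[i : i + 3] for i in range(off, L - 2, 3)
            ]
            frame = strand * (off + 1)
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    j = i
                    while j < len(codons) and _CODONS.get(codons[j], "X") != "*":
                        j += 1
                    has_stop = j < len(codons)
                    aa_len = j - i
                    if aa_len >= min_aa:
                        last = j + 1 if has_stop else j
                        s = off + 3 * i
                        e = off + 3 * last
                        if strand == -1:
                            s, e = L - e, L - s
                        found.add((frame, s, e, has_stop))
                    i = j + 1
                else:
                    i += 1
    return found


def sl_scan_enumerate(
    read: str, sl: str, min_match: int, max_mismatch: int, window: int
) -> list[tuple[int, int, int]]:
    """All (length, offset, mismatches) placements of an SL suffix."""
    out = []
    for length in range(min_match, len(sl) + 1):
        suffix = sl[-length:]
        for offset in range(0, window + 1):
            if offset + length > len(read):
                continue
            mm = sum(
                1 for a, b in zip(read[offset : offset + length], suffix) if a != b
            )
            if mm <= max_mismatch:
                out.append((length, offset, mm))
    return out


def motif_scan_enumerate(seq: str, pattern: str, iupac: dict[str, str]) -> list[int]:
    """Sliding-window IUPAC match start positions (set semantics)."""
    expanded = []
    for ch in pattern.upper():
        body = iupac[ch].strip("[]")
        expanded.append(set(body))
    starts = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + k] in expanded[k] for k in range(len(pattern))):
            starts.append(i)
    return starts
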