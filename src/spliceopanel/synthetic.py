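"""Seeded synthetic-data generator with full ground truth.

Produces protein panels, decoy backgrounds, NGS-style transcript
assemblies (with diverged orthologues, duplications and chimeras),
full-length reads with a spliced leader at controlled prevalence, and
genomic contigs with GT..AG-split genes and tandem small-RNA arrays.

Randomness: one top-level seed; every component derives its own stream
from (seed, component key), so adding a gene never shifts another gene's
sequence.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import OTHER_CATEGORIES, SNRNP_CATEGORIES, Panel, PanelEntry
from .sl_scan import default_sl_sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

# Fixed most-frequent-codon back-translation table so that translated
# search is exact at divergence 0.
CODON_OF = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}
STOP_CODON = "TAA"

# Full synonymous-codon table for randomized back-translation (used for
# genomic sequence, where frame-shifted readings of a fixed-codon text are
# too structured and create alignment artifacts).
SYNONYMOUS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

_CATEGORY_VOCAB = tuple(SNRNP_CATEGORIES) + (
    "stage-specific:A", "stage-specific:B", "stage-specific:Bact",
    "stage-specific:B*/C", "stage-specific:C*/P", "stage-specific:ILS",
) + tuple(OTHER_CATEGORIES)


def _rng(seed: int, *keys) -> np.random.Generator:
    digest = hashlib.sha256(repr(keys).encode()).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def back_translate(
    protein: str,
    add_stop: bool = True,
    rng: np.random.Generator | None = None,
) -> str:
    """Back-translate; fixed most-frequent codons by default, or uniform
    synonymous-codon randomization when *rng* is given."""
    if rng is None:
        cds = "".join(CODON_OF[aa] for aa in protein)
    else:
        cds = "".join(
            SYNONYMOUS[aa][rng.integers(0, len(SYNONYMOUS[aa]))] for aa in protein
        )
    return cds + STOP_CODON if add_stop else cds


# ---------------------------------------------------------------------------
# Panels and orthologue evolution
# ---------------------------------------------------------------------------

def make_panel(
    n: int, length_range: tuple[int, int] = (120, 250), seed: int = 0
) -> Panel:
    """Random protein panel of *n* entries; reproducible under *seed*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    entries = []
    for i in range(n):
        gid = f"G{i + 1:03d}"
        rng = _rng(seed, "panel", gid)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "M" + _random_seq(rng, length - 1, AA20)
        entries.append(
            PanelEntry(
                id=gid,
                name=f"synthetic protein {gid}",
                category=_CATEGORY_VOCAB[i % len(_CATEGORY_VOCAB)],
                sequence=seq,
            )
        )
    return Panel(entries)


def make_decoys(
    n: int, length_range: tuple[int, int] = (120, 250), seed: int = 0
) -> dict[str, str]:
    """Random decoy proteins emulating an unrelated database background."""
    out = {}
    for i in range(n):
        did = f"decoy{i + 1:03d}"
        rng = _rng(seed, "decoy", did)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out[did] = _random_seq(rng, length, AA20)
    return out


def evolve_orthologue(
    protein: str, divergence: float, seed: int = 0, key: str = ""
) -> str:
    """Per-site substitution with probability *divergence*; the replacement
    residue is uniform over the other 19."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    if divergence == 0:
        return protein
    rng = _rng(seed, "evolve", key, divergence)
    chars = list(protein)
    hits = rng.random(len(chars)) < divergence
    for i in np.flatnonzero(hits):
        alternatives = AA20.replace(chars[i], "") if chars[i] in AA20 else AA20
        chars[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def _mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        alternatives = NT4.replace(chars[i], "") if chars[i] in NT4 else NT4
        chars[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

DEFAULT_SCENARIO = {
    "present_fraction": 0.9,
    "divergence": 0.15,
    "copy_table": {},               # gene id -> copy count (>= 2 forces presence)
    "n_chimeras": 2,
    "copy_nt_divergence": 0.08,
    "sl_prevalence": 0.727,
    "sl_seq": None,                 # None -> packaged default SL
    "utr_range": (20, 80),
}


@dataclass
class SyntheticTranscriptome:
    ngs: dict[str, str]             # assembled-transcript FASTA records
    fl_reads: dict[str, str]        # full-length reads (SL-prepended subset)
    gene_truth: pd.DataFrame        # per panel gene
    transcript_truth: pd.DataFrame  # per emitted NGS transcript
    read_gene_map: dict[str, str] = field(default_factory=dict)


def make_transcriptome(
    panel: Panel, scenario: dict | None = None, seed: int = 0
) -> SyntheticTranscriptome:
    """Emit NGS transcripts + FL reads for a panel under a scenario.

    Present genes get back-translated, diverged CDSs wrapped in random
    UTRs; genes in ``copy_table`` are forced present with that many
    nucleotide-diverged copies; chimeras fuse the head half of one gene's
    CDS to the tail half of another's (NGS only — FL reads are
    non-chimeric by construction).  FL reads carry the SL prepended with
    probability ``sl_prevalence`` per gene.
    """
    sc = {**DEFAULT_SCENARIO, **(scenario or {})}
    sl_seq = sc["sl_seq"] or default_sl_sequence()
    lo_utr, hi_utr = sc["utr_range"]

    ngs: dict[str, str] = {}
    fl: dict[str, str] = {}
    read_gene: dict[str, str] = {}
    gene_rows = []
    tx_rows = []
    half_cds: dict[str, str] = {}   # single-copy present genes, for chimeras

    for entry in panel:
        gid = entry.id
        rng = _rng(seed, "gene", gid)
        copies = int(sc["copy_table"].get(gid, 1))
        present = copies >= 2 or bool(rng.random() < sc["present_fraction"])
        sl_added = bool(rng.random() < sc["sl_prevalence"]) if present else False
        if not present:
            gene_rows.append(
                dict(panel_id=gid, present=False, copy_count=0,
                     divergence=0.0, sl_added=False, chimera_partner="")
            )
            continue
        orth = evolve_orthologue(entry.sequence, sc["divergence"], seed, key=gid)
        base_cds = back_translate(orth)
        for c in range(copies):
            crng = _rng(seed, "copy", gid, c)
            cds = base_cds if c == 0 else _mutate_nt(base_cds, sc["copy_nt_divergence"], crng)
            utr5 = _random_seq(crng, int(crng.integers(lo_utr, hi_utr + 1)), NT4)
            utr3 = _random_seq(crng, int(crng.integers(lo_utr, hi_utr + 1)), NT4)
            tid = f"{gid}_t{c}"
            transcript = utr5 + cds + utr3
            ngs[tid] = transcript
            rid = f"fl_{tid}"
            fl[rid] = (sl_seq + transcript) if sl_added else transcript
            read_gene[rid] = gid
            tx_rows.append(
                dict(transcript_id=tid, panel_id=gid, is_chimera=False,
                     chimera_partner="", sl_added=sl_added)
            )
            if copies == 1 and c == 0:
                half_cds[gid] = base_cds
        gene_rows.append(
            dict(panel_id=gid, present=True, copy_count=copies,
                 divergence=sc["divergence"], sl_added=sl_added, chimera_partner="")
        )

    # chimeras: head half of A + tail half of B, cut at codon boundaries
    chim_rng = _rng(seed, "chimera")
    candidates = sorted(half_cds)
    n_chim = min(int(sc["n_chimeras"]), len(candidates) // 2)
    picked = list(chim_rng.choice(candidates, size=2 * n_chim, replace=False))
    for k in range(n_chim):
        a, b = picked[2 * k], picked[2 * k + 1]
        cds_a, cds_b = half_cds[a], half_cds[b]
        head = cds_a[: (len(cds_a) // 2 // 3) * 3]  # half of A, codon-aligned
        tail = cds_b[(len(cds_b) // 2 // 3) * 3 :]
        crng = _rng(seed, "chimera", a, b)
        utr5 = _random_seq(crng, int(crng.integers(lo_utr, hi_utr + 1)), NT4)
        utr3 = _random_seq(crng, int(crng.integers(lo_utr, hi_utr + 1)), NT4)
        tid = f"chim_{a}_{b}"
        ngs[tid] = utr5 + head + tail + utr3
        tx_rows.append(
            dict(transcript_id=tid, panel_id=a, is_chimera=True,
                 chimera_partner=b, sl_added=False)
        )
        for row in gene_rows:
            if row["panel_id"] == a:
                row["chimera_partner"] = b

    return SyntheticTranscriptome(
        ngs=ngs,
        fl_reads=fl,
        gene_truth=pd.DataFrame(gene_rows),
        transcript_truth=pd.DataFrame(tx_rows),
        read_gene_map=read_gene,
    )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    gene_truth: pd.DataFrame        # per projected gene: contig, intron count...
    snrna_truth: pd.DataFrame       # per tandem-array contig


def _split_with_introns(
    cds: str, n_introns: int, rng: np.random.Generator,
    intron_len_range: tuple[int, int], min_exon_nt: int = 45,
) -> tuple[str, list[tuple[int, int]]]:
    """Interleave GT..AG introns into a CDS at codon boundaries.

    Returns the spliced genomic sequence and intron ranges on it.
    """
    if n_introns == 0:
        return cds, []
    n_codons = len(cds) // 3
    min_exon_codons = max(1, min_exon_nt // 3)
    usable = n_codons - (n_introns + 1) * min_exon_codons
    if usable < 0:
        raise ValueError("CDS too short for requested intron count")
    # choose n_introns distinct codon cut points leaving min exon sizes
    cuts = sorted(
        rng.choice(
            np.arange(min_exon_codons, n_codons - min_exon_codons),
            size=n_introns, replace=False,
        )
    )
    for a, b in zip(cuts, cuts[1:]):
        if b - a < min_exon_codons:
            # resample degenerate layouts deterministically by spreading cuts
            cuts = [
                min_exon_codons + round(i * (n_codons - 2 * min_exon_codons) / n_introns)
                for i in range(n_introns)
            ]
            break
    pieces = []
    introns: list[tuple[int, int]] = []
    prev = 0
    pos = 0
    for cut in cuts:
        exon = cds[prev * 3 : cut * 3]
        pieces.append(exon)
        pos += len(exon)
        ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        intron = "GT" + _random_seq(rng, max(0, ilen - 4), NT4) + "AG"
        pieces.append(intron)
        introns.append((pos, pos + len(intron)))
        pos += len(intron)
        prev = cut
    pieces.append(cds[prev * 3 :])
    return "".join(pieces), introns


def make_genome(
    panel_subset: list[PanelEntry],
    intron_table: dict[str, int] | None = None,
    snrna_unit: str | None = None,
    tandem_copies: int = 0,
    spacer_range: tuple[int, int] = (500, 800),
    seed: int = 0,
    intron_len_range: tuple[int, int] = (40, 120),
    flank_range: tuple[int, int] = (100, 300),
    snrna_contig_len: int = 8000,
) -> SyntheticGenome:
    """Genomic contigs: one per gene (CDS split by GT..AG introns) plus an
    optional contig carrying a tandem small-RNA array."""
    intron_table = intron_table or {}
    contigs: dict[str, str] = {}
    gene_rows = []
    for entry in panel_subset:
        gid = entry.id
        rng = _rng(seed, "genome", gid)
        n_introns = int(intron_table.get(gid, 0))
        cds = back_translate(entry.sequence, rng=rng)
        body, introns = _split_with_introns(cds, n_introns, rng, intron_len_range)
        flank5 = _random_seq(rng, int(rng.integers(*flank_range)), NT4)
        flank3 = _random_seq(rng, int(rng.integers(*flank_range)), NT4)
        cid = f"ctg_{gid}"
        contigs[cid] = flank5 + body + flank3
        gene_rows.append(
            dict(panel_id=gid, contig_id=cid, intron_count=n_introns,
                 exon_count=n_introns + 1, gene_start=len(flank5),
                 gene_end=len(flank5) + len(body))
        )

    snrna_rows = []
    if snrna_unit and tandem_copies > 0:
        rng = _rng(seed, "snrna-array")
        background = _random_seq(rng, snrna_contig_len, NT4)
        starts = []
        pos = 200
        for _ in range(tandem_copies):
            starts.append(pos)
            pos += int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        if starts and starts[-1] + len(snrna_unit) > snrna_contig_len:
            raise ValueError("tandem array does not fit in the contig")
        chars = list(background)
        for s in starts:
            chars[s : s + len(snrna_unit)] = snrna_unit
        contigs["ctg_snrna_array"] = "".join(chars)
        snrna_rows.append(
            dict(contig_id="ctg_snrna_array", copy_count=tandem_copies,
                 unit_length=len(snrna_unit), unit_starts=json.dumps(starts))
        )

    return SyntheticGenome(
        contigs=contigs,
        gene_truth=pd.DataFrame(gene_rows),
        snrna_truth=pd.DataFrame(snrna_rows),
    )


def make_snrna_unit(length: int = 190, seed: int = 0) -> str:
    return _random_seq(_rng(seed, "snrna-unit"), length, NT4)


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

SCENARIOS: dict[str, dict] = {
    "easy": {
        "n_genes": 60,
        "n_decoys": 100,
        "length_range": (120, 250),
        "present_fraction": 0.9,
        "divergence": 0.15,
        "copy_table": {"G003": 2, "G011": 2, "G027": 3},
        "n_chimeras": 2,
        "sl_prevalence": 0.727,
        "utr_range": (20, 80),
    },
    "paperlike": {
        "n_genes": 120,
        "n_decoys": 200,
        "length_range": (120, 400),
        "present_fraction": 0.65,
        "divergence": 0.35,
        "copy_table": {"G003": 2, "G011": 2, "G027": 3, "G040": 2},
        "n_chimeras": 3,
        "sl_prevalence": 0.727,
        "utr_range": (20, 150),
    },
}


@dataclass
class ScenarioBundle:
    panel: Panel
    decoys: dict[str, str]
    transcriptome: SyntheticTranscriptome
    genome: SyntheticGenome
    scenario: dict


def build_scenario(name: str = "easy", seed: int = 0) -> ScenarioBundle:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    sc = dict(SCENARIOS[name])
    panel = make_panel(sc["n_genes"], sc["length_range"], seed)
    decoys = make_decoys(sc["n_decoys"], sc["length_range"], seed)
    tome = make_transcriptome(panel, sc, seed)
    # genomic fixtures: first few genes with 0..7 introns plus a 10-copy array
    subset = panel.entries[:4]
    intron_table = {subset[1].id: 2, subset[2].id: 5, subset[3].id: 7}
    genome = make_genome(
        subset,
        intron_table=intron_table,
        snrna_unit=make_snrna_unit(seed=seed),
        tandem_copies=10,
        spacer_range=(600, 750),
        seed=seed,
    )
    return ScenarioBundle(
        panel=panel, decoys=decoys, transcriptome=tome, genome=genome,
        scenario={**sc, "name": name, "seed": seed},
    )


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_scenario(outdir: str | Path, name: str = "easy", seed: int = 0) -> ScenarioBundle:
    """Materialize a scenario to FASTA/TSV/JSON files under *outdir*."""
    bundle = build_scenario(name, seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "panel.fa", {e.id: e.sequence for e in bundle.panel})
    with open(out / "panel.tsv", "w") as fh:
        fh.write("id\tname\tcategory\tparalogue_group\n")
        for e in bundle.panel:
            fh.write(f"{e.id}\t{e.name}\t{e.category}\t{e.paralogue_group or ''}\n")
    _write_fasta(out / "decoys.fa", bundle.decoys)
    _write_fasta(out / "ngs.fa", bundle.transcriptome.ngs)
    _write_fasta(out / "flreads.fa", bundle.transcriptome.fl_reads)
    _write_fasta(out / "contigs.fa", bundle.genome.contigs)
    bundle.transcriptome.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    bundle.transcriptome.transcript_truth.to_csv(
        out / "truth_transcripts.tsv", sep="\t", index=False
    )
    bundle.genome.gene_truth.to_csv(out / "truth_genome.tsv", sep="\t", index=False)
    bundle.genome.snrna_truth.to_csv(out / "truth_snrna.tsv", sep="\t", index=False)
    with open(out / "genemap.tsv", "w") as fh:
        fh.write("record_id\tgene_id\n")
        for rid, gid in bundle.transcriptome.read_gene_map.items():
            fh.write(f"{rid}\t{gid}\n")
    with open(out / "scenario.json", "w") as fh:
        json.dump(bundle.scenario, fh, indent=1, sort_keys=True)
    return bundle
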