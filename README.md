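# spliceopanel

A toolkit for identifying a reference panel of spliceosomal genes in a
non-model transcriptome/genome, built around desk-scale re-implementations
of the standard screening steps:

- **panel** — model, load, collapse and summarize a reference
  spliceosomal-protein inventory (a 257-entry manifest with categories and
  12 paralogue groups ships with the package; paralogue collapsing yields
  241 search units).
- **homology** — six-frame translated Smith–Waterman search with
  Karlin–Altschul bit scores/E-values, strict reciprocal-best-hit
  orthologue assignment against a decoy background, and copy-number calling
  by single-linkage nucleotide-identity clustering.
- **crossval** — ORF finding and intactness classification, cross-platform
  (assembly vs. full-length reads) reconciliation, chimeric-transcript
  flagging with breakpoint estimation, and genomic-contig projection with
  exon-chain inference (GT..AG annotated, never filtered on).
- **sl_scan** — spliced-leader detection at read 5′ termini (suffix
  matching, mismatch-tolerant, windowed) and trans-splicing prevalence
  estimation with Wilson 95% intervals.
- **snrna_scan** — nucleotide homology scan of genomic contigs with an
  ordered query-fallback strategy, tandem-array calling, IUPAC motif
  annotation and helix complementarity.
- **modulator_map** — global alignment, similarity percentages, and
  transfer of structure-defined drug-contact residues onto query proteins
  with a conservation verdict.
- **synthetic** — a fully seeded generator for panels, decoy backgrounds,
  transcriptomes (diverged orthologues, duplications, chimeras), SL-tagged
  full-length reads, and genomic contigs with GT..AG introns and tandem
  small-RNA arrays — all with ground-truth tables.
- **pipeline** — end-to-end orchestration, run summaries (e.g. FLNC pass
  rates) and cross-species presence/absence matrices.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) with independent brute-force
oracles for the alignment DP, ORF scanning, motif matching and SL
detection, plus an acceptance suite (`tests/test_acceptance.py`) checking
panel accounting, ratio worked examples, oracle equivalence, seeded
truth-recovery on the packaged synthetic scenario, Wilson-interval
coverage, structural fixtures and contact mapping.

## CLI

```sh
spliceopanel synth --scenario easy --seed 1 --out demo/      # synthetic data + truth
spliceopanel panel --manifest demo/panel.tsv --collapse
spliceopanel search --transcripts demo/ngs.fa --manifest demo/panel.tsv \
    --fasta demo/panel.fa --decoys demo/decoys.fa
spliceopanel slscan --sl SL.fa --reads demo/flreads.fa --per-gene demo/genemap.tsv
spliceopanel snrna --contigs demo/contigs.fa --queries u2_candidates.fa
spliceopanel modmap --reference human.fa --query query.fa
spliceopanel run -c config.yaml --out out/                    # full pipeline
```

`spliceopanel run` takes a YAML config naming the panel manifest/FASTA,
transcripts, optional decoys/full-length reads/SL sequence/contigs/snRNA
queries/contact sets, and a `thresholds` block (E-value cutoff, ORF
coverage, SL matching, cluster identity, tandem spacing). Reruns on the
same inputs are byte-identical.

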