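"""End-to-end orchestration, run-summary statistics, and the cross-species
presence/absence comparison."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import crossval, homology, modulator_map, sl_scan, snrna_scan
from .homology import OrthologueCall, ScoringScheme
from .panel import collapse_paralogues, load_panel, summarize_panel
from .sl_scan import round_half_up


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunSummary:
    n_ccs: int | None = None
    n_flnc: int | None = None
    flnc_pass_rate: float | None = None
    n_genes: int = 0
    n_found: int = 0
    n_sl_flagged: int | None = None
    prevalence: dict | None = None


def flnc_pass_rate(n_ccs: int, n_flnc: int) -> float:
    """Percentage of CCS reads classified full-length non-chimeric,
    rounded half-up to one decimal."""
    if n_ccs < 1:
        raise ValueError("n_ccs must be >= 1")
    if n_flnc > n_ccs:
        raise ValueError("n_flnc cannot exceed n_ccs")
    if n_flnc < 0:
        raise ValueError("n_flnc must be >= 0")
    return round_half_up(100.0 * n_flnc / n_ccs, 1)


# ---------------------------------------------------------------------------
# Cross-species comparison
# ---------------------------------------------------------------------------

@dataclass
class SpeciesMatrix:
    matrix: pd.DataFrame                    # bool, rows = panel ids, cols = species
    column_totals: dict[str, int]
    unique_to: dict[str, list[str]]         # species -> ids present only there
    absent_everywhere: list[str]


def compare_species(
    call_sets: Mapping[str, Sequence[OrthologueCall]]
) -> SpeciesMatrix:
    """Presence/absence matrix over identically-panelled call sets."""
    if not call_sets:
        raise ValueError("no call sets given")
    species = list(call_sets)
    universes = {sp: sorted(c.panel_id for c in calls) for sp, calls in call_sets.items()}
    first = universes[species[0]]
    for sp in species[1:]:
        if universes[sp] != first:
            raise ValueError("mismatched panels between species call sets")
    data = {
        sp: {c.panel_id: c.status == "found" for c in calls}
        for sp, calls in call_sets.items()
    }
    matrix = pd.DataFrame(data, dtype=bool).loc[first]
    totals = {sp: int(matrix[sp].sum()) for sp in species}
    presence_counts = matrix.sum(axis=1)
    unique_to = {
        sp: sorted(matrix.index[(matrix[sp]) & (presence_counts == 1)])
        for sp in species
    }
    absent = sorted(matrix.index[presence_counts == 0])
    return SpeciesMatrix(
        matrix=matrix, column_totals=totals, unique_to=unique_to,
        absent_everywhere=absent,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _log_stage(log: list[dict], stage: str, n_in: int, n_out: int, t0: float) -> None:
    elapsed = time.perf_counter() - t0
    print(
        f"[spliceopanel] stage={stage} n_in={n_in} n_out={n_out} "
        f"elapsed={elapsed:.2f}s",
        file=sys.stderr,
    )
    log.append({"stage": stage, "n_in": n_in, "n_out": n_out})


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunSummary:
    """Execute panel -> homology -> crossval -> sl_scan -> snrna_scan ->
    modulator_map in order, writing per-stage reports under *outdir*.

    *config* is a dict or a YAML path.  Outputs are pure functions of the
    inputs: reruns are byte-identical.  A stage failure raises
    ``PipelineError`` naming the stage; optional stages whose inputs are
    missing are skipped with a warning.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    th = config.get("thresholds", {})
    e_max = float(th.get("e_max", 1e-6))
    min_cov = float(th.get("min_cov", 0.8))
    min_aa = int(th.get("min_orf_aa", 50))
    cluster_identity = float(th.get("identity_cluster_threshold", 0.95))
    scheme = ScoringScheme.protein_default()

    # -- panel ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        panel = load_panel(config["panel_manifest"], config.get("panel_fasta"))
        collapsed = collapse_paralogues(panel)
        summary = summarize_panel(collapsed)
    except Exception as exc:
        raise PipelineError("panel", exc)
    _log_stage(log, "panel", len(panel), len(collapsed), t0)

    # -- homology -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        transcripts = _read_fasta(config["transcripts"])
        decoys = _read_fasta(config["decoys"]) if config.get("decoys") else {}
        result = homology.assign_orthologues(
            transcripts, collapsed, decoys, scheme, e_max,
            forward_background=bool(decoys),
        )
        calls = homology.call_copy_number(result.calls, transcripts, cluster_identity)
    except Exception as exc:
        raise PipelineError("homology", exc)
    n_found = sum(1 for c in calls if c.status == "found")
    _log_stage(log, "homology", len(transcripts), n_found, t0)

    # -- crossval -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        fl_reads = _read_fasta(config["fl_reads"]) if config.get("fl_reads") else {}
        member_group = {
            mid: (entry.paralogue_group or entry.id)
            for entry in collapsed
            for mid in entry.member_ids
        }
        chimera_flags: dict[str, bool] = {}
        for tid in transcripts:
            hsps = [h for h in result.hsps.get(tid, []) if h.subject_id in member_group]
            flagged, _ = crossval.flag_chimera(hsps, group_of=member_group)
            chimera_flags[tid] = flagged

        # drop chimeric transcripts, then re-call copy numbers
        clean_calls = []
        for call in calls:
            kept = [t for t in call.transcript_ids if not chimera_flags.get(t)]
            if kept:
                clean_calls.append(
                    OrthologueCall(
                        panel_id=call.panel_id, status="found",
                        transcript_ids=kept, copy_count=len(kept),
                        best_evalue=call.best_evalue,
                    )
                )
            else:
                clean_calls.append(OrthologueCall(panel_id=call.panel_id, status="absent"))
        calls = homology.call_copy_number(clean_calls, transcripts, cluster_identity)

        def best_intact(records: Mapping[str, str], tids: list[str], plen: int) -> bool:
            for tid in tids:
                if tid not in records:
                    continue
                for orf in crossval.find_orfs(records[tid], min_aa=min_aa):
                    if crossval.classify_intactness(orf, plen, min_cov):
                        return True
            return False

        ngs_intact: dict[str, bool] = {}
        fl_intact: dict[str, bool] = {}
        fl_by_tid = {rid.removeprefix("fl_"): seq for rid, seq in fl_reads.items()}
        for call in calls:
            entry = collapsed.get(call.panel_id)
            plen = max(len(seq) for _, seq in entry.members)
            tids = call.transcript_ids
            ngs_intact[call.panel_id] = best_intact(transcripts, tids, plen)
            fl_intact[call.panel_id] = best_intact(fl_by_tid, tids, plen) if fl_reads else False
        records, tally = crossval.reconcile_platforms(ngs_intact, fl_intact)
        records = [
            crossval.CrossValRecord(
                panel_id=r.panel_id, intact_class=r.intact_class,
                chimera_flag=any(
                    chimera_flags.get(t)
                    for t in result.assignments
                    if result.assignments[t] == r.panel_id
                ),
            )
            for r in records
        ]
    except Exception as exc:
        raise PipelineError("crossval", exc)
    _log_stage(log, "crossval", len(calls), len(records), t0)

    # -- sl_scan --------------------------------------------------------
    prevalence = None
    n_sl = None
    t0 = time.perf_counter()
    if config.get("sl_fasta") and fl_reads:
        try:
            sl = next(iter(_read_fasta(config["sl_fasta"]).values()))
            sl_calls = [
                sl_scan.detect_sl(
                    seq, sl,
                    min_match=int(th.get("sl_min_match", 12)),
                    max_mismatch=int(th.get("sl_max_mismatch", 1)),
                    window=int(th.get("sl_window", 5)),
                    record_id=rid,
                )
                for rid, seq in fl_reads.items()
            ]
            genemap = None
            if config.get("genemap"):
                gm = pd.read_csv(config["genemap"], sep="\t", dtype=str)
                genemap = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))
            prevalence = sl_scan.estimate_prevalence(sl_calls, genemap)
            n_sl = prevalence.n_flagged
            (out / "sl_calls.tsv").write_text(sl_scan.calls_to_tsv(sl_calls))
        except Exception as exc:
            raise PipelineError("sl_scan", exc)
        _log_stage(log, "sl_scan", len(fl_reads), n_sl, t0)
    else:
        print("[spliceopanel] warning: sl_scan skipped (no SL sequence)", file=sys.stderr)
        log.append({"stage": "sl_scan", "skipped": True})

    # -- snrna_scan -----------------------------------------------------
    t0 = time.perf_counter()
    if config.get("contigs") and config.get("snrna_queries"):
        try:
            contigs = _read_fasta(config["contigs"])
            queries = list(_read_fasta(config["snrna_queries"]).items())
            outcome = snrna_scan.scan_contigs(contigs, queries, e_max=e_max)
            arrays = snrna_scan.find_tandem_arrays(
                outcome.hits, max_spacer=int(th.get("max_spacer", 1000))
            )
            (out / "snrna_hits.bed").write_text(snrna_scan.hits_to_bed6(outcome.hits))
            (out / "snrna_arrays.json").write_text(
                json.dumps(
                    {
                        "successful_query": outcome.successful_query,
                        "failed_queries": outcome.failed_queries,
                        "arrays": snrna_scan.arrays_to_json_obj(arrays),
                    },
                    indent=1,
                )
            )
        except Exception as exc:
            raise PipelineError("snrna_scan", exc)
        _log_stage(log, "snrna_scan", len(contigs), len(outcome.hits), t0)
    else:
        log.append({"stage": "snrna_scan", "skipped": True})

    # -- modulator_map --------------------------------------------------
    t0 = time.perf_counter()
    if config.get("modmap"):
        try:
            mm = config["modmap"]
            refs = _read_fasta(mm["reference_fasta"])
            qrys = _read_fasta(mm["query_fasta"])
            contact_sets = modulator_map.load_contact_sets(mm.get("contacts"))
            reports = []
            for cs in contact_sets:
                if cs.protein not in refs or cs.protein not in qrys:
                    continue
                aln = modulator_map.global_align_protein(refs[cs.protein], qrys[cs.protein])
                sim = modulator_map.percent_similarity(aln)
                mappings, verdict = modulator_map.map_contact_residues(aln, cs)
                reports.append(
                    modulator_map.mappings_to_tsv(mappings, cs, verdict)
                    + f"# percent_similarity: {sim}\n"
                )
            (out / "modmap.tsv").write_text("".join(reports))
        except Exception as exc:
            raise PipelineError("modulator_map", exc)
        _log_stage(log, "modulator_map", len(contact_sets), len(reports), t0)
    else:
        log.append({"stage": "modulator_map", "skipped": True})

    # -- reports --------------------------------------------------------
    calls_df = pd.DataFrame(
        [
            dict(
                panel_id=c.panel_id, status=c.status,
                transcript_ids=",".join(c.transcript_ids),
                copy_count=c.copy_count,
                best_evalue="" if c.best_evalue is None else f"{c.best_evalue:.3e}",
            )
            for c in calls
        ]
    )
    calls_df.to_csv(out / "orthologue_calls.tsv", sep="\t", index=False)
    (out / "crossval.tsv").write_text(crossval.crossval_to_tsv(records))
    all_hsps = [h for hs in result.hsps.values() for h in hs]
    (out / "hsps.tsv").write_text(homology.hsps_to_tsv(all_hsps))

    summary_obj = RunSummary(
        n_ccs=config.get("n_ccs"),
        n_flnc=config.get("n_flnc"),
        flnc_pass_rate=(
            flnc_pass_rate(config["n_ccs"], config["n_flnc"])
            if config.get("n_ccs") and config.get("n_flnc") is not None
            else None
        ),
        n_genes=summary.total,
        n_found=n_found,
        n_sl_flagged=n_sl,
        prevalence=None if prevalence is None else asdict(prevalence),
    )
    (out / "summary.json").write_text(json.dumps(asdict(summary_obj), indent=1))
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return summary_obj
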