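"""End-to-end orchestration: simulate -> clean -> map -> annotate ->
consensus -> triage -> indels -> TE screen, with TSV reports and a run
manifest.  Re-running with an identical config reproduces identical
outputs."""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import align, consensus as cons, indels as indel_mod, io as fio, preprocess, triage as triage_mod
from .align import GenomeIndex, KmerIndex, Scoring
from .regions import GeneModel, annotate_span, cluster_by_gene, summarize_categories
from .simulate import SimConfig, make_reference_set, simulate_cdna_reads
from .triage import GeneAnnotationTrack, TranscriptDB, TriageParams, TriageResult


class PipelineError(RuntimeError):
    """A stage failed or a required upstream stage was disabled."""


@dataclass
class PipelineConfig:
    out_dir: str = "flcdna_out"
    seed: int = 0
    # stage toggles
    do_simulate: bool = True
    do_clean: bool = True
    do_map: bool = True
    do_annotate: bool = True
    do_consensus: bool = True
    do_triage: bool = True
    do_indels: bool = True
    do_te_screen: bool = True
    # simulation (used when do_simulate)
    sim: SimConfig = field(default_factory=SimConfig)
    # external inputs (used when not do_simulate)
    reads_fastq: Optional[str] = None
    reference_mrna_fasta: Optional[str] = None
    gene_models_gff3: Optional[str] = None
    genome_fasta: Optional[str] = None
    repeats_bed: Optional[str] = None
    vector_fasta: Optional[str] = None
    host_fasta: Optional[str] = None
    other_db_fasta: Optional[str] = None
    # cleaning parameters
    trim_window: int = 10
    min_mean_q: float = 20.0
    min_length: int = 100
    # alignment parameters
    scoring: Scoring = field(default_factory=Scoring)
    min_identity: float = align.DEFAULT_MIN_IDENTITY
    min_aligned: int = align.DEFAULT_MIN_ALIGNED
    min_intron: int = 30
    min_aa: int = 40
    te_min_overlap: float = 0.5
    te_min_unaligned: int = 50  # unaligned clean-read bases triggering the TE screen

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        scoring_raw = raw.pop("scoring", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimConfig(**sim_raw)
        if scoring_raw:
            cfg.scoring = Scoring(**scoring_raw)
        return cfg

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    out_dir: Path
    cleaned: list = field(default_factory=list)
    alignments: dict = field(default_factory=dict)       # read_id -> mRNA alignment
    annotations: list = field(default_factory=list)
    summary: Optional[object] = None                     # CategorySummary
    identity_report: Optional[object] = None
    triage_results: list = field(default_factory=list)
    indel_summary: Optional[object] = None
    te_calls: list = field(default_factory=list)
    truth: Optional[object] = None
    models: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)          # name -> path


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(out_dir=out)

    # ------------------------------------------------------------------ inputs
    if cfg.do_simulate:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        _log("simulate", f"building reference world (n_genes={sim_cfg.n_genes}, seed={cfg.seed})")
        bundle = make_reference_set(sim_cfg)
        reads, truth = simulate_cdna_reads(bundle, sim_cfg)
        _log("simulate", f"emitted {len(reads)} reads")
        fio.write_simulation(out / "sim", bundle, reads, truth)
        res.truth = truth
        models = bundle.models
        genome = bundle.genome
        repeats = bundle.repeats
        vector_lib = {"vector": bundle.vector}
        host_lib = {"host": bundle.host}
        other_db = bundle.other_db
        annotation = GeneAnnotationTrack([
            (loc.gene_id, loc.chrom, loc.start, loc.end, loc.exons)
            for loc in bundle.gene_loci.values()])
    else:
        if not (cfg.reads_fastq and cfg.reference_mrna_fasta and cfg.gene_models_gff3):
            raise PipelineError("simulate disabled: reads_fastq, reference_mrna_fasta "
                                "and gene_models_gff3 inputs are required")
        reads = fio.read_fastq(cfg.reads_fastq)
        models = fio.read_gene_models(cfg.reference_mrna_fasta, cfg.gene_models_gff3)
        genome = fio.read_fasta(cfg.genome_fasta) if cfg.genome_fasta else {}
        repeats = fio.read_repeats_bed(cfg.repeats_bed) if cfg.repeats_bed else []
        vector_lib = fio.read_fasta(cfg.vector_fasta) if cfg.vector_fasta else {}
        host_lib = fio.read_fasta(cfg.host_fasta) if cfg.host_fasta else {}
        other_db = fio.read_fasta(cfg.other_db_fasta) if cfg.other_db_fasta else {}
        annotation = None
    res.models = models

    # ------------------------------------------------------------------ clean
    if cfg.do_clean:
        _log("clean", f"cleaning {len(reads)} raw reads")
        cleaned = preprocess.clean_reads(
            reads, vector_lib, host_lib, window=cfg.trim_window,
            min_mean_q=cfg.min_mean_q, min_length=cfg.min_length,
            scoring=cfg.scoring)
        report = preprocess.cleaning_report(cleaned)
        report.to_csv(out / "cleaning_report.tsv", sep="\t", index=False)
        res.reports["cleaning_report"] = out / "cleaning_report.tsv"
        res.cleaned = cleaned
        kept = [(c.read_id, c.sequence) for c in cleaned if c.status == preprocess.KEPT]
        _log("clean", f"kept {len(kept)} of {len(cleaned)}")
    else:
        res.cleaned = []
        kept = [(r.read_id, r.sequence) for r in reads]

    # ------------------------------------------------------------------ map
    transcripts = {models[g].transcript_id: models[g].sequence for g in models}
    tid2gene = {models[g].transcript_id: g for g in models}
    if cfg.do_map:
        _log("map", f"aligning {len(kept)} reads to {len(transcripts)} reference mRNAs")
        index = KmerIndex(transcripts) if transcripts else None
        for rid, seq in kept:
            aln = align.best_hit(seq, transcripts, scoring=cfg.scoring,
                                 min_identity=cfg.min_identity,
                                 min_aligned=cfg.min_aligned,
                                 query_id=rid, index=index)
            if aln is not None:
                res.alignments[rid] = aln
        _log("map", f"{len(res.alignments)} reads matched the reference set")
        rows = [align.alignment_row(a, query_length=len(dict(kept)[rid]),
                                    min_intron=cfg.min_intron)
                for rid, a in res.alignments.items()]
        align.alignments_to_frame(rows).to_csv(out / "mrna_alignments.tsv", sep="\t",
                                               index=False)
        res.reports["mrna_alignments"] = out / "mrna_alignments.tsv"

    # ------------------------------------------------------------------ annotate
    clusters = {}
    if cfg.do_annotate:
        if not cfg.do_map:
            raise PipelineError("annotate requires the map stage")
        for rid, aln in res.alignments.items():
            model = models[tid2gene[aln.target_id]]
            res.annotations.append(annotate_span(rid, (aln.t_start, aln.t_end), model))
        clusters = cluster_by_gene(res.annotations)
        res.summary = summarize_categories(res.annotations, clusters)
        res.summary.to_tsv(out / "table1.tsv")
        res.reports["table1"] = out / "table1.tsv"
        _log("annotate", f"{len(res.annotations)} cDNAs over {len(clusters)} genes")

    # ------------------------------------------------------------------ consensus
    if cfg.do_consensus:
        if not cfg.do_annotate:
            raise PipelineError("consensus requires the annotate stage")
        seq_of = dict(kept)
        records = []
        for gid in sorted(clusters):
            members = clusters[gid]
            if len(members) < 2:
                continue
            triples = [(m.cdna_id, seq_of[m.cdna_id], res.alignments[m.cdna_id])
                       for m in members]
            records.append((cons.build_consensus(gid, triples), models[gid]))
        res.identity_report = cons.identity_report(records)
        res.identity_report.entries.to_csv(out / "identities.tsv", sep="\t", index=False)
        res.identity_report.to_frame().to_csv(out / "identity_report.tsv", sep="\t",
                                              index=False)
        res.reports["identity_report"] = out / "identity_report.tsv"
        _log("consensus", f"built {len(records)} consensus sequences")

    # ------------------------------------------------------------------ triage
    genome_index = None
    if genome and (cfg.do_triage or cfg.do_te_screen):
        _log("triage", "indexing genome")
        genome_index = GenomeIndex(genome)
    if cfg.do_triage:
        if not cfg.do_map:
            raise PipelineError("triage requires the map stage")
        params = TriageParams(scoring=cfg.scoring, min_identity=cfg.min_identity,
                              min_aligned=cfg.min_aligned, min_aa=cfg.min_aa,
                              min_intron=cfg.min_intron)
        other = TranscriptDB(other_db)
        empty_db = TranscriptDB({})
        results = []
        for rid, seq in kept:
            if rid in res.alignments:
                results.append(TriageResult(rid, triage_mod.REFSEQ_MATCH,
                                            refseq_hit=res.alignments[rid]))
            else:
                results.append(triage_mod.triage(rid, seq, empty_db, other,
                                                 genome_index, annotation, params))
        res.triage_results = results
        counts = triage_mod.triage_counts(results)
        _log("triage", " ".join(f"{k}={v}" for k, v in counts.items()))
        frame = pd.DataFrame([{
            "transcript_id": r.transcript_id,
            "class": r.klass,
            "db_hit": (r.refseq_hit or r.other_hit).target_id if (r.refseq_hit or r.other_hit) else "",
            "genome_chrom": r.genome_alignment.target_id if r.genome_alignment else "",
            "n_blocks": len(align.exon_blocks(r.genome_alignment, cfg.min_intron))
                        if r.genome_alignment else 0,
            "aligned_region": r.context_label,
            "orf_aa": r.orf.aa_length if r.orf else 0,
        } for r in results])
        frame.to_csv(out / "triage.tsv", sep="\t", index=False)
        res.reports["triage"] = out / "triage.tsv"
        # table of genome-supported novel transcripts, published-table layout
        seq_of = dict(kept)
        rows = [align.alignment_row(r.genome_alignment, len(seq_of[r.transcript_id]),
                                    cfg.min_intron, r.context_label)
                for r in results if r.klass == triage_mod.GENOME_ORF]
        align.alignments_to_frame(rows).to_csv(out / "genome_hits.tsv", sep="\t",
                                               index=False)
        res.reports["genome_hits"] = out / "genome_hits.tsv"
        orf_recs = [(r.transcript_id, r.orf.peptide) for r in results
                    if r.orf is not None and r.klass in triage_mod.UNKNOWN_CLASSES]
        fio.write_fasta(out / "novel_orfs.faa", orf_recs)

    # ------------------------------------------------------------------ indels
    if cfg.do_indels:
        if not cfg.do_map:
            raise PipelineError("indel analysis requires the map stage")
        events = []
        for rid, aln in res.alignments.items():
            model = models[tid2gene[aln.target_id]]
            evs = indel_mod.detect_indels(aln, min_intron=cfg.min_intron)
            events.extend(indel_mod.classify_events(evs, model))
        res.indel_summary = indel_mod.summarize_indels(events)
        res.indel_summary.to_frame().to_csv(out / "indel_summary.tsv", sep="\t",
                                            index=False)
        res.reports["indel_summary"] = out / "indel_summary.tsv"
        _log("indels", f"{len(events)} indel events in "
                       f"{len({e.transcript_id for e in events})} transcripts")

    # ------------------------------------------------------------------ TE screen
    if cfg.do_te_screen:
        if not cfg.do_map:
            raise PipelineError("TE screen requires the map stage")
        calls = []
        seq_of = dict(kept)
        if genome_index is not None and repeats:
            for rid, aln in res.alignments.items():
                seq = seq_of[rid]
                covered = sum(e - s for s, e in aln.aligned_query_intervals())
                if len(seq) - covered < cfg.te_min_unaligned:
                    continue
                galn = align.map_to_genome(seq, genome_index, scoring=cfg.scoring,
                                           min_intron=cfg.min_intron,
                                           min_identity=cfg.min_identity,
                                           min_aligned=cfg.min_aligned, query_id=rid)
                if galn is None:
                    continue
                calls.extend(indel_mod.screen_te_exons(
                    galn, repeats, aln, min_overlap=cfg.te_min_overlap,
                    min_intron=cfg.min_intron))
        res.te_calls = calls
        indel_mod.te_calls_frame(calls).to_csv(out / "te_calls.tsv", sep="\t", index=False)
        res.reports["te_calls"] = out / "te_calls.tsv"
        _log("te-screen", f"{len(calls)} exonization calls")

    # ------------------------------------------------------------------ manifest + report
    manifest = {
        "package": "flcdna",
        "version": _version(),
        "seed": cfg.seed,
        "config": _jsonable(cfg.to_dict()),
        "n_raw_reads": len(reads),
        "n_kept": len(kept),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    res.reports["manifest"] = out / "manifest.json"
    (out / "report.md").write_text(make_report(res))
    res.reports["report"] = out / "report.md"
    return res


def _version() -> str:
    from importlib.metadata import version
    try:
        return version("flcdna")
    except Exception:
        return "unknown"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def make_report(res: PipelineResult) -> str:
    """Human-readable markdown summary of a run's stage outputs."""
    lines = ["# Full-length cDNA characterization report", ""]
    if res.cleaned:
        from .preprocess import KEPT
        n = len(res.cleaned)
        kept = sum(1 for c in res.cleaned if c.status == KEPT)
        lines += [f"## Cleaning", "",
                  f"{n} raw reads, {kept} kept after quality/vector/host/length filtering.", ""]
        by_status: dict[str, int] = {}
        for c in res.cleaned:
            by_status[c.status] = by_status.get(c.status, 0) + 1
        for status, count in sorted(by_status.items()):
            lines.append(f"- {status}: {count}")
        lines.append("")
    if res.summary is not None:
        lines += ["## Mapping-region categories", "",
                  res.summary.to_frame().to_markdown(index=False), ""]
    if res.identity_report is not None:
        frame = res.identity_report.to_frame()
        lines += ["## Consensus identity by category", "",
                  frame.to_markdown(index=False) if len(frame) else "No consensus clusters.",
                  ""]
    if res.triage_results:
        from .triage import triage_counts
        counts = triage_counts(res.triage_results)
        lines += ["## Triage", "", f"{len(res.triage_results)} transcripts triaged:"]
        lines += [f"- {k}: {v}" for k, v in counts.items()]
        lines.append("")
    else:
        lines += ["## Triage", "", "0 transcripts", ""]
    if res.indel_summary is not None:
        lines += ["## Indels by region", "",
                  res.indel_summary.to_frame().to_markdown(index=False), ""]
    lines += ["## TE exonization", "", f"{len(res.te_calls)} calls", ""]
    return "\n".join(lines)
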