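"""Novel-transcript triage: database cascade, genome support, ORF calling.

Transcripts that fail to match the curated reference mRNA set are pushed
through a fixed cascade: (1) a secondary database of other mRNAs/ESTs;
(2) intron-aware genome mapping combined with an ORF call.  Genome-backed
ORF-bearing transcripts and free ORF-bearing transcripts form the two
novel-candidate classes; transcripts with neither evidence stay
unclassified rather than being forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import align
from .align import GenomeIndex, KmerIndex, PairwiseAlignment, Scoring

REFSEQ_MATCH = "REFSEQ_MATCH"
OTHER_DB_MATCH = "OTHER_DB_MATCH"
GENOME_ORF = "GENOME_ORF"
ORF_ONLY = "ORF_ONLY"
UNCLASSIFIED = "UNCLASSIFIED"

CLASSES = (REFSEQ_MATCH, OTHER_DB_MATCH, GENOME_ORF, ORF_ONLY, UNCLASSIFIED)
UNKNOWN_CLASSES = (GENOME_ORF, ORF_ONLY, UNCLASSIFIED)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFCall:
    """An ATG-initiated, stop-terminated open reading frame."""

    frame: int                   # 0, 1, 2 (forward frames)
    interval: tuple[int, int]    # nt, half-open; starts at ATG, ends after stop
    aa_length: int
    peptide: str

    def __post_init__(self):
        s, e = self.interval
        if (e - s) % 3 != 0:
            raise ValueError("ORF length not divisible by 3")
        if self.aa_length != (e - s) // 3 - 1:
            raise ValueError("aa length inconsistent with interval")


def _translate(seq: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(seq).translate())


def find_orf(sequence: str, min_aa: int = 40, both_strands: bool = False
             ) -> Optional[ORFCall]:
    """Longest ATG..stop ORF with >= ``min_aa`` amino acids; ties leftmost.

    Scans the three forward frames (the library is directional);
    ``both_strands`` adds the reverse complement, reporting the forward-
    strand-equivalent call only if it is strictly longer.
    """
    seq = sequence.upper()
    best: Optional[ORFCall] = None
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                aa = (i + 3 - start) // 3 - 1
                if aa >= min_aa and (best is None or aa > best.aa_length or
                                     (aa == best.aa_length and start < best.interval[0])):
                    best = ORFCall(frame, (start, i + 3), aa,
                                   _translate(seq[start:i]))
                start = None
    if both_strands:
        from Bio.Seq import Seq
        rc = str(Seq(seq).reverse_complement())
        rc_best = find_orf(rc, min_aa=min_aa, both_strands=False)
        if rc_best is not None and (best is None or rc_best.aa_length > best.aa_length):
            best = rc_best
    return best


@dataclass
class TriageParams:
    scoring: Scoring = field(default_factory=Scoring)
    min_identity: float = align.DEFAULT_MIN_IDENTITY
    min_aligned: int = align.DEFAULT_MIN_ALIGNED
    min_aa: int = 40
    min_intron: int = 30
    max_candidates: int = 5


@dataclass
class TriageResult:
    transcript_id: str
    klass: str
    refseq_hit: Optional[PairwiseAlignment] = None
    other_hit: Optional[PairwiseAlignment] = None
    genome_alignment: Optional[PairwiseAlignment] = None
    context_label: str = ""
    orf: Optional[ORFCall] = None

    @property
    def is_unknown(self) -> bool:
        return self.klass in UNKNOWN_CLASSES


@dataclass
class GeneAnnotationTrack:
    """Genomic gene spans with exon intervals, for context labeling."""

    genes: Sequence[tuple[str, str, int, int, Sequence[tuple[int, int]]]]
    # (gene name, chrom, start, end, exon intervals)


def label_genome_context(blocks: Sequence[tuple[int, int]], chrom: str,
                         track: Optional[GeneAnnotationTrack]) -> str:
    """Label each exon-level block Exon/Intron/Intergenic and compose the
    transcript label, e.g. ``"NAT10 (Intron,Exon)"`` or ``"Intergenic"``.

    A block is Exon when it overlaps an annotated exon by >= 1 nt, Intron
    when it lies inside a gene span without exon overlap, else Intergenic.
    Intervals are half-open, so an abutting block does not overlap.
    """
    if track is None or not blocks:
        return "Intergenic" if blocks else ""
    per_gene: dict[str, list[str]] = {}
    n_intergenic = 0
    for bs, be in blocks:
        label = None
        for name, gchrom, gs, ge, exons in track.genes:
            if gchrom != chrom or be <= gs or bs >= ge:
                continue
            if any(bs < ee and be > es for es, ee in exons):
                label = (name, "Exon")
            else:
                label = (name, "Intron")
            break
        if label is None:
            n_intergenic += 1
        else:
            name, lab = label
            if lab not in per_gene.setdefault(name, []):
                per_gene[name].append(lab)
    if not per_gene:
        return "Intergenic"
    if n_intergenic:
        last = next(reversed(per_gene))
        per_gene[last].append("Intergenic")
    return ", ".join(f"{name} ({','.join(labels)})" for name, labels in per_gene.items())


class TranscriptDB:
    """A searchable transcript database (sequences + k-mer shortlist)."""

    def __init__(self, sequences: Mapping[str, str], k: int = 11):
        self.sequences = dict(sequences)
        self.index = KmerIndex(self.sequences, k=k) if self.sequences else None

    def __len__(self) -> int:
        return len(self.sequences)

    def best_hit(self, query: str, params: TriageParams,
                 query_id: str = "query") -> Optional[PairwiseAlignment]:
        if not self.sequences:
            return None
        return align.best_hit(query, self.sequences, scoring=params.scoring,
                              min_identity=params.min_identity,
                              min_aligned=params.min_aligned,
                              query_id=query_id, index=self.index,
                              max_candidates=params.max_candidates)


def triage(transcript_id: str, sequence: str,
           refseq_db: TranscriptDB,
           other_db: Optional[TranscriptDB] = None,
           genome_index: Optional[GenomeIndex] = None,
           annotation: Optional[GeneAnnotationTrack] = None,
           params: Optional[TriageParams] = None) -> TriageResult:
    """Classify one transcript through the triage cascade.

    A transcript with a reference-set hit never reaches the genome stage.
    ``genome_index=None`` disables genome mapping (no genome hit possible).
    """
    params = params or TriageParams()
    hit = refseq_db.best_hit(sequence, params, query_id=transcript_id)
    if hit is not None:
        return TriageResult(transcript_id, REFSEQ_MATCH, refseq_hit=hit)
    if other_db is not None and len(other_db):
        ohit = other_db.best_hit(sequence, params, query_id=transcript_id)
        if ohit is not None:
            return TriageResult(transcript_id, OTHER_DB_MATCH, other_hit=ohit)
    orf = find_orf(sequence, min_aa=params.min_aa)
    galn = None
    if genome_index is not None:
        galn = align.map_to_genome(sequence, genome_index, scoring=params.scoring,
                                   min_intron=params.min_intron,
                                   min_identity=params.min_identity,
                                   min_aligned=params.min_aligned,
                                   query_id=transcript_id)
    if galn is not None and orf is not None:
        blocks = align.exon_blocks(galn, params.min_intron)
        label = label_genome_context(blocks, galn.target_id, annotation)
        return TriageResult(transcript_id, GENOME_ORF, genome_alignment=galn,
                            context_label=label, orf=orf)
    if galn is None and orf is not None:
        return TriageResult(transcript_id, ORF_ONLY, orf=orf)
    label = ""
    if galn is not None:
        blocks = align.exon_blocks(galn, params.min_intron)
        label = label_genome_context(blocks, galn.target_id, annotation)
    return TriageResult(transcript_id, UNCLASSIFIED, genome_alignment=galn,
                        context_label=label)


def triage_counts(results: Sequence[TriageResult]) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    for r in results:
        counts[r.klass] += 1
    return counts
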