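"""Indel detection/region classification and TE-exonization screening.

Gaps in a transcript-vs-reference-mRNA alignment shorter than the intron
threshold are indels; target-side gaps at or above it are introns and are
never counted as indels.  Indel anchors are left-normalized (the gap is
shifted as far 5' as the sequence allows) so that anchoring is
deterministic under alignment ambiguity.  Separately, exon-level blocks
of a transcript's genome alignment that have no counterpart in its
reference-mRNA alignment are screened against the repeat annotation:
sufficient repeat coverage calls an exonized transposable element, and
lineage-flagged families (e.g. AluYRa2, MER11B) mark the call
species-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import PairwiseAlignment, exon_query_blocks
from .regions import FUNCTIONAL_REGIONS, GeneModel, RegionError
from .simulate import RepeatCopy


@dataclass
class IndelEvent:
    """One alignment gap below the intron threshold."""

    transcript_id: str
    side: str        # 'ins' = extra query bases; 'del' = reference bases absent
    ref_pos: int     # leftmost reference-transcript coordinate after normalization
    length: int
    region: Optional[str] = None


@dataclass
class ExonizationCall:
    transcript_id: str
    block: tuple[int, int]      # genomic interval of the exon block
    chrom: str
    family: str
    overlap_fraction: float
    species_specific: bool
    absent_from_reference_mrna: bool = True


def left_normalized_anchor(ref_pos: int, gap_seq: str, left_context: str) -> int:
    """Leftmost equivalent coordinate for a gap (VCF-style left align).

    A gap of bases G ending a region S = left_context + G can shift left k
    positions iff the last k characters of left_context equal the last k
    characters of S (deleting/inserting the shifted run yields the same
    sequence).  Works identically for deletions and insertions.
    """
    s = left_context + gap_seq
    k = 0
    while k < len(left_context) and left_context[-1 - k] == s[-1 - k]:
        k += 1
    return ref_pos - k


def detect_indels(aln: PairwiseAlignment, min_intron: int = 30) -> list[IndelEvent]:
    """Indel events from one transcript-vs-reference alignment.

    Every gap of length < ``min_intron`` becomes one event anchored at the
    left-normalized leftmost reference coordinate; target-side gaps >=
    ``min_intron`` are introns and yield nothing.  Events are sorted by
    reference position.
    """
    events: list[IndelEvent] = []
    for i, gap in enumerate(aln.gaps):
        if gap.length >= min_intron:
            continue
        # left context = target-side sequence of the block preceding the gap
        left = ""
        for block, tb in zip(aln.blocks, aln.t_block_seqs):
            if block.t_end <= gap.t_pos:
                left = tb
        if gap.side == "target":
            anchor = left_normalized_anchor(gap.t_pos, gap.seq, left)
            events.append(IndelEvent(aln.query_id, "del", anchor, gap.length))
        else:
            anchor = left_normalized_anchor(gap.t_pos, gap.seq, left)
            events.append(IndelEvent(aln.query_id, "ins", anchor, gap.length))
    events.sort(key=lambda e: e.ref_pos)
    return events


def classify_indel_region(event: IndelEvent, model: GeneModel) -> str:
    """Region of an indel's anchor; a deletion spanning a region boundary
    gets the compound label (5UTR_CDS / CDS_3UTR / 5UTR_CDS_3UTR)."""
    if not model.coding:
        return "NR_XR"
    n = len(model.sequence)
    if not 0 <= event.ref_pos < n:
        raise RegionError(f"indel anchor {event.ref_pos} outside transcript")
    if event.side == "ins":
        return model.region_of(event.ref_pos)
    lo = event.ref_pos
    hi = min(event.ref_pos + event.length, n)
    regions = {model.region_of(lo), model.region_of(max(lo, hi - 1))}
    if regions == {"5UTR"}:
        return "5UTR"
    if regions == {"CDS"}:
        return "CDS"
    if regions == {"3UTR"}:
        return "3UTR"
    if regions == {"5UTR", "CDS"}:
        return "5UTR_CDS"
    if regions == {"CDS", "3UTR"}:
        return "CDS_3UTR"
    return "5UTR_CDS_3UTR"


def classify_events(events: Sequence[IndelEvent], model: GeneModel) -> list[IndelEvent]:
    for e in events:
        e.region = classify_indel_region(e, model)
    return events


@dataclass
class IndelSummary:
    """Transcript- and event-level indel counts per region."""

    transcript_counts: dict[str, int]
    event_counts: dict[str, int]

    @property
    def functional_total(self) -> int:
        """Transcripts with indels in the five functional mRNA regions; a
        transcript with indels in k regions contributes once per region."""
        return sum(self.transcript_counts.get(r, 0) for r in FUNCTIONAL_REGIONS)

    def to_frame(self) -> pd.DataFrame:
        regions = list(FUNCTIONAL_REGIONS) + sorted(
            set(self.transcript_counts) - set(FUNCTIONAL_REGIONS))
        rows = [{"region": r,
                 "transcripts": self.transcript_counts.get(r, 0),
                 "events": self.event_counts.get(r, 0)} for r in regions]
        rows.append({"region": "functional_total",
                     "transcripts": self.functional_total,
                     "events": sum(self.event_counts.get(r, 0) for r in FUNCTIONAL_REGIONS)})
        return pd.DataFrame(rows, columns=["region", "transcripts", "events"])


def summarize_indels(events: Sequence[IndelEvent]) -> IndelSummary:
    """Count transcripts (and raw events) per region.

    Events must be classified first.  A transcript with indels in several
    regions counts once in each of them.
    """
    event_counts: dict[str, int] = {}
    per_region_transcripts: dict[str, set[str]] = {}
    for e in events:
        if e.region is None:
            raise ValueError("events must be classified before summarizing")
        event_counts[e.region] = event_counts.get(e.region, 0) + 1
        per_region_transcripts.setdefault(e.region, set()).add(e.transcript_id)
    return IndelSummary({r: len(t) for r, t in per_region_transcripts.items()},
                        event_counts)


def screen_te_exons(genome_aln: PairwiseAlignment,
                    repeats: Sequence[RepeatCopy],
                    mrna_aln: Optional[PairwiseAlignment],
                    min_overlap: float = 0.5,
                    min_intron: int = 30,
                    min_block_len: int = 30,
                    max_mrna_cover: float = 0.2) -> list[ExonizationCall]:
    """Call repeat-derived exon blocks absent from the reference mRNA.

    For each exon-level block of the genome alignment, the fraction of its
    query interval covered by the reference-mRNA alignment decides whether
    the block is "absent" (< ``max_mrna_cover``); absent blocks whose
    genomic interval is covered >= ``min_overlap`` by a single repeat
    family yield an ExonizationCall, flagged species-specific when the
    family is lineage-flagged in the repeat annotation.
    """
    calls: list[ExonizationCall] = []
    if genome_aln is None or genome_aln.is_empty:
        return calls
    chrom = genome_aln.target_id
    mrna_intervals = (mrna_aln.aligned_query_intervals()
                      if mrna_aln is not None and not mrna_aln.is_empty else [])
    for qs, qe, ts, te in exon_query_blocks(genome_aln, min_intron):
        if qe - qs < min_block_len:
            continue
        covered = sum(max(0, min(qe, me) - max(qs, ms)) for ms, me in mrna_intervals)
        if covered / (qe - qs) >= max_mrna_cover:
            continue
        per_family: dict[str, int] = {}
        lineage: dict[str, bool] = {}
        for rep in repeats:
            if rep.chrom != chrom:
                continue
            ov = max(0, min(te, rep.end) - max(ts, rep.start))
            if ov > 0:
                per_family[rep.family] = per_family.get(rep.family, 0) + ov
                lineage[rep.family] = rep.lineage_specific
        if not per_family:
            continue
        family = max(sorted(per_family), key=lambda f: per_family[f])
        frac = per_family[family] / (te - ts)
        if frac >= min_overlap:
            calls.append(ExonizationCall(genome_aln.query_id, (ts, te), chrom,
                                         family, min(frac, 1.0), lineage[family]))
    return calls


def te_calls_frame(calls: Sequence[ExonizationCall]) -> pd.DataFrame:
    rows = [{
        "transcript_id": c.transcript_id,
        "chrom": c.chrom,
        "block_start": c.block[0],
        "block_end": c.block[1],
        "family": c.family,
        "overlap_fraction": round(c.overlap_fraction, 3),
        "species_specific": c.species_specific,
        "absent_from_reference_mrna": c.absent_from_reference_mrna,
    } for c in calls]
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "block_start", "block_end",
                                       "family", "overlap_fraction", "species_specific",
                                       "absent_from_reference_mrna"])
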