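"""Gene models and UTR/CDS region classification of mapped cDNAs.

An mRNA is partitioned by its CDS into a 5'UTR, the CDS, and a 3'UTR.
A cDNA read aligned to the mRNA is categorized by which of the three
regions its aligned span touches, yielding seven categories (the three
single regions, three contiguous combinations, and ``NR_XR`` for hits to
non-coding/predicted reference transcripts).  Reads are then clustered by
the gene their best hit belongs to, and the per-category gene counts are
summarized with percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: canonical category order (single regions 5'->3', then compounds, then
#: non-coding reference hits)
CATEGORIES = (
    "5UTR",
    "5UTR_CDS",
    "CDS",
    "CDS_3UTR",
    "3UTR",
    "5UTR_CDS_3UTR",
    "NR_XR",
)

#: labels used by the TSV exporters (display form of the category keys)
DISPLAY_LABELS = {
    "5UTR_CDS_3UTR": "5UTR-CDS-3UTR",
    "NR_XR": "NR and XR",
}

#: functional mRNA regions used by the indel summary
FUNCTIONAL_REGIONS = ("5UTR", "5UTR_CDS", "CDS", "CDS_3UTR", "3UTR")


class RegionError(ValueError):
    """An aligned span is inconsistent with its gene model."""


@dataclass(frozen=True)
class GeneModel:
    """A reference transcript with CDS boundaries.

    Coordinates are 0-based half-open on the transcript.  Non-coding
    ("NR and XR") models carry no CDS interval.
    """

    gene_id: str
    transcript_id: str
    sequence: str
    cds: Optional[tuple[int, int]] = None
    coding: bool = True

    def __post_init__(self):
        if self.coding:
            if self.cds is None:
                raise ValueError(f"{self.transcript_id}: coding model needs a CDS interval")
            s, e = self.cds
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.transcript_id}: CDS {self.cds} outside transcript")
        elif self.cds is not None:
            raise ValueError(f"{self.transcript_id}: non-coding model must not have a CDS")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_start(self) -> int:
        return self.cds[0]

    @property
    def cds_end(self) -> int:
        return self.cds[1]

    def region_of(self, pos: int) -> str:
        """Region ('5UTR' | 'CDS' | '3UTR') containing transcript position."""
        if not 0 <= pos < len(self.sequence):
            raise RegionError(f"position {pos} outside transcript {self.transcript_id}")
        if not self.coding:
            raise RegionError(f"{self.transcript_id} is non-coding; positions have no region")
        if pos < self.cds[0]:
            return "5UTR"
        if pos < self.cds[1]:
            return "CDS"
        return "3UTR"


@dataclass
class RegionAnnotation:
    """Category assigned to one cDNA from its best-hit aligned span."""

    cdna_id: str
    gene_id: str
    category: str
    overlaps: dict[str, int] = field(default_factory=dict)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def classify_region(span: tuple[int, int], model: GeneModel, min_overlap: int = 1) -> str:
    """Categorize an aligned target span against a gene model.

    ``span`` is 0-based half-open on the model's transcript.  A region is
    "present" when the span overlaps it by at least ``min_overlap`` nt.
    Non-coding models always classify as ``NR_XR``.
    """
    s, e = span
    if e <= s:
        raise RegionError(f"empty span {span}")
    if s < 0 or e > len(model.sequence):
        raise RegionError(
            f"span {span} outside transcript {model.transcript_id} (len {len(model.sequence)})"
        )
    if not model.coding:
        return "NR_XR"
    cs, ce = model.cds
    o5 = _overlap(s, e, 0, cs)
    oc = _overlap(s, e, cs, ce)
    o3 = _overlap(s, e, ce, len(model.sequence))
    present = (o5 >= min_overlap, oc >= min_overlap, o3 >= min_overlap)
    label = {
        (True, False, False): "5UTR",
        (True, True, False): "5UTR_CDS",
        (False, True, False): "CDS",
        (False, True, True): "CDS_3UTR",
        (False, False, True): "3UTR",
        (True, True, True): "5UTR_CDS_3UTR",
    }.get(present)
    if label is None:
        # span shorter than min_overlap in every region, or a (5UTR,3UTR)
        # combination, which cannot happen for a contiguous span over a
        # non-empty CDS with min_overlap=1
        raise RegionError(f"span {span} has no region overlap >= {min_overlap} nt")
    return label


def region_overlaps(span: tuple[int, int], model: GeneModel) -> dict[str, int]:
    """Per-region overlap lengths (nt) of a span; non-coding -> empty."""
    if not model.coding:
        return {}
    s, e = span
    cs, ce = model.cds
    return {
        "5UTR": _overlap(s, e, 0, cs),
        "CDS": _overlap(s, e, cs, ce),
        "3UTR": _overlap(s, e, ce, len(model.sequence)),
    }


def annotate_span(cdna_id: str, span: tuple[int, int], model: GeneModel,
                  min_overlap: int = 1) -> RegionAnnotation:
    """Build the RegionAnnotation for one cDNA from its best-hit span."""
    return RegionAnnotation(
        cdna_id=cdna_id,
        gene_id=model.gene_id,
        category=classify_region(span, model, min_overlap=min_overlap),
        overlaps=region_overlaps(span, model),
    )


def cluster_by_gene(annotations: Iterable[RegionAnnotation]) -> dict[str, list[RegionAnnotation]]:
    """Group annotations by the gene id of their best hit.

    Isoform redundancy is collapsed at the gene-id level: annotations
    against different transcripts of one gene land in one cluster.
    """
    clusters: dict[str, list[RegionAnnotation]] = {}
    for ann in annotations:
        clusters.setdefault(ann.gene_id, []).append(ann)
    return clusters


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 12.35 -> 12.4), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategorySummary:
    """Per-category cDNA and gene counts with gene-fraction percentages.

    Percentages use the distinct-gene count as denominator and are rounded
    half-away-from-zero to one decimal; they need not sum to exactly 100.0.
    """

    cdna_counts: dict[str, int]
    gene_counts: dict[str, int]

    @property
    def total_cdna(self) -> int:
        return sum(self.cdna_counts.values())

    @property
    def total_genes(self) -> int:
        return sum(self.gene_counts.values())

    def percent(self, category: str) -> float:
        total = self.total_genes
        if total == 0:
            return 0.0
        return round_half_up(100.0 * self.gene_counts.get(category, 0) / total, 1)

    @classmethod
    def from_counts(cls, cdna_counts: Mapping[str, int], gene_counts: Mapping[str, int]) -> "CategorySummary":
        return cls(dict(cdna_counts), dict(gene_counts))

    def to_frame(self) -> pd.DataFrame:
        """Summary table: Mapping Region / cDNA / RefSeq / Percent + totals."""
        rows = []
        for cat in CATEGORIES:
            if self.cdna_counts.get(cat, 0) == 0 and self.gene_counts.get(cat, 0) == 0:
                continue
            rows.append({
                "Mapping Region": DISPLAY_LABELS.get(cat, cat),
                "cDNA": self.cdna_counts.get(cat, 0),
                "RefSeq": self.gene_counts.get(cat, 0),
                "Percent": self.percent(cat),
            })
        rows.append({
            "Mapping Region": "Total",
            "cDNA": self.total_cdna,
            "RefSeq": self.total_genes,
            "Percent": 100.0 if self.total_genes else 0.0,
        })
        return pd.DataFrame(rows, columns=["Mapping Region", "cDNA", "RefSeq", "Percent"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_CATEGORY_REGIONS = {
    "5UTR": frozenset({"5UTR"}),
    "5UTR_CDS": frozenset({"5UTR", "CDS"}),
    "CDS": frozenset({"CDS"}),
    "CDS_3UTR": frozenset({"CDS", "3UTR"}),
    "3UTR": frozenset({"3UTR"}),
    "5UTR_CDS_3UTR": frozenset({"5UTR", "CDS", "3UTR"}),
}
_REGIONS_CATEGORY = {v: k for k, v in _CATEGORY_REGIONS.items()}


def combine_categories(categories: Iterable[str]) -> str:
    """Category of the union of regions covered by several spans.

    NR_XR absorbs (a non-coding gene has no regions); a 5UTR member plus a
    CDS_3UTR member combine to 5UTR_CDS_3UTR.  Because every category's
    region set is a contiguous run over (5UTR, CDS, 3UTR), any union that
    arises from cDNAs of one gene maps back to a valid category except the
    disjoint {5UTR, 3UTR} pair, which is resolved to 5UTR_CDS_3UTR.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("no categories to combine")
    if any(c == "NR_XR" for c in cats):
        return "NR_XR"
    regions: set[str] = set()
    for c in cats:
        regions |= _CATEGORY_REGIONS[c]
    if regions == {"5UTR", "3UTR"}:
        return "5UTR_CDS_3UTR"
    return _REGIONS_CATEGORY[frozenset(regions)]


def summarize_categories(annotations: Sequence[RegionAnnotation],
                         clusters: Optional[Mapping[str, list[RegionAnnotation]]] = None,
                         ) -> CategorySummary:
    """Tally cDNA and distinct-gene counts per category.

    Each cDNA contributes to exactly one category (its best-hit category),
    so cDNA counts partition the input.  Each gene likewise counts in
    exactly one category — the category of the union of regions its member
    cDNAs cover — so gene counts sum to the distinct-gene total.
    """
    if clusters is None:
        clusters = cluster_by_gene(annotations)
    cdna_counts: dict[str, int] = {}
    for ann in annotations:
        cdna_counts[ann.category] = cdna_counts.get(ann.category, 0) + 1
    gene_counts: dict[str, int] = {}
    for gene_id, members in clusters.items():
        cat = combine_categories(m.category for m in members)
        gene_counts[cat] = gene_counts.get(cat, 0) + 1
    return CategorySummary(cdna_counts, gene_counts)
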