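"""Synthetic reference set and directional cDNA read simulator.

The generator builds a self-contained toy world mirroring the structure a
full-length cDNA characterization pipeline assumes: an annotated "human"
reference transcriptome (5'UTR/CDS/3'UTR gene models, a few of them
non-coding), a single-chromosome genome embedding each transcript as
spliced exons, intronic/intergenic transposable-element copies with a
repeat annotation, a cloning-vector and a host-contaminant sequence, and
"rhesus" cDNA reads sampled from per-gene diverged transcripts.

Divergence (substitutions and short indels) is planted once per gene on
the simulated rhesus transcript; all reads of a gene share it, as reads
from one species do.  Per-read sequencing error is a separate, optional
layer.  Every planted difference is recorded in a ground-truth ledger
(:class:`SimTruth`) keyed by read, so recovery tests can score the
pipeline against the simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .regions import GeneModel, classify_region

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

#: per-category divergence preset; 100*(1-rate) equals the identity each
#: category is expected to recover
PUBLISHED_CATEGORY_RATES = {
    "5UTR": 0.049,
    "5UTR_CDS": 0.049,
    "5UTR_CDS_3UTR": 0.041,
    "CDS": 0.032,
    "CDS_3UTR": 0.043,
    "3UTR": 0.067,
    "NR_XR": 0.041,
}

#: per-category gene-count weights used by the published-library profile generator
#: (distinct-gene counts of the seven-category annotation summary)
PUBLISHED_CATEGORY_WEIGHTS = {
    "5UTR": 19,
    "5UTR_CDS": 134,
    "CDS": 137,
    "CDS_3UTR": 499,
    "3UTR": 443,
    "5UTR_CDS_3UTR": 181,
}

DEFAULT_TE_FAMILIES = (
    ("AluYRa2", "SINE", True),
    ("MER11B", "LTR", True),
    ("AluY", "SINE", False),
    ("L1PA4", "LINE", False),
)


@dataclass
class SimConfig:
    """Generator parameters.  Lengths are nt; probabilities in [0, 1]."""

    seed: int = 0
    n_genes: int = 100
    n_reads: int = 400
    # reference transcript structure
    utr5_len: tuple[int, int] = (50, 300)
    cds_codons: tuple[int, int] = (100, 500)  # CDS length = 3 * codons
    utr3_len: tuple[int, int] = (100, 900)
    p_noncoding: float = 0.034
    n_exons: tuple[int, int] = (2, 12)
    intron_len: tuple[int, int] = (50, 400)
    intergenic_len: tuple[int, int] = (200, 1000)
    # divergence
    sub_rate_by_region: dict = field(default_factory=lambda: {
        "5UTR": 0.049, "CDS": 0.032, "3UTR": 0.067})
    sub_rate_by_category: Optional[dict] = None
    indel_rate: float = 0.15        # events per kb of transcript
    indel_len_geom_p: float = 0.45  # geometric length parameter
    max_indel_len: int = 20
    # read sampling
    p_5prime_complete: float = 0.2
    read_len: tuple[float, float] = (860.0, 160.0)  # normal(mean, sd), CLEAN length
    read_len_clip: tuple[int, int] = (170, 1174)
    # raw reads are drawn longer than the intended clean length because the
    # quality decay (q_hi -> q_lo over the raw read) places the q=20 trim
    # point at (q_hi-20)/(q_hi-q_lo) of the read: 2/3 for the 40->10 default
    raw_stretch: float = 1.5
    category_weights: Optional[dict] = None  # per-gene targeted categories
    reads_per_gene: tuple[int, int] = (1, 3)
    # contamination / novelty
    p_vector_contam: float = 0.15
    vector_seg_len: tuple[int, int] = (20, 80)
    p_vector_read: float = 0.0825
    p_host_read: float = 0.01
    p_unknown: float = 0.10
    unknown_split: tuple[float, float, float] = (66.0, 60.0, 61.0)  # otherdb, genomic, free
    n_otherdb: int = 6
    n_novel_genomic: int = 6
    n_novel_free: int = 6
    novel_orf_aa: tuple[int, int] = (44, 198)
    # transposable elements
    p_te_exon: float = 0.0
    p_te_read_inclusion: float = 0.6
    te_families: tuple = DEFAULT_TE_FAMILIES
    te_cassette_len: tuple[int, int] = (80, 250)
    # qualities / sequencing error
    quality_decay: tuple[float, float] = (40.0, 10.0)
    quality_sd: float = 4.0
    seq_error: str = "none"  # 'none' | 'quality'

    def validate(self) -> None:
        probs = [self.p_noncoding, self.p_5prime_complete, self.p_vector_contam,
                 self.p_vector_read, self.p_host_read, self.p_unknown,
                 self.p_te_exon, self.p_te_read_inclusion]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.utr5_len, self.cds_codons, self.utr3_len, self.n_exons,
                       self.intron_len, self.intergenic_len, self.vector_seg_len,
                       self.te_cassette_len, self.reads_per_gene, self.novel_orf_aa):
            if lo < 1 or hi < lo:
                raise ValueError("length/count ranges must satisfy 1 <= lo <= hi")
        if self.cds_codons[0] < 20:
            raise ValueError("degenerate CDS length distribution")
        for region in ("5UTR", "CDS", "3UTR"):
            if region not in self.sub_rate_by_region:
                raise ValueError(f"sub_rate_by_region missing {region}")
            if not 0.0 <= self.sub_rate_by_region[region] < 1.0:
                raise ValueError("substitution rates must lie in [0, 1)")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if not 0.0 < self.indel_len_geom_p <= 1.0:
            raise ValueError("indel_len_geom_p must lie in (0, 1]")
        if self.seq_error not in ("none", "quality"):
            raise ValueError("seq_error must be 'none' or 'quality'")
        if self.category_weights is not None and not self.category_weights:
            raise ValueError("category_weights must be non-empty when given")


def published_profile(**overrides) -> SimConfig:
    """SimConfig preset encoding the published library's statistics.

    Per-category divergence rates recover the printed per-category
    identities as 100*(1-rate); read lengths, 5'-completeness, vector and
    unknown fractions follow the published counts.  Sequencing error is
    off so consensus identity measures divergence alone.
    """
    cfg = SimConfig(
        sub_rate_by_category=dict(PUBLISHED_CATEGORY_RATES),
        category_weights=dict(PUBLISHED_CATEGORY_WEIGHTS),
        reads_per_gene=(1, 3),
        p_te_exon=0.02,
    )
    return dataclasses.replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# truth records

@dataclass
class IndelTruth:
    ref_pos: int    # leftmost reference-transcript coordinate
    kind: str       # 'ins' (extra rhesus bases) | 'del' (reference bases absent)
    length: int
    seq: str        # inserted rhesus bases, or deleted reference bases


@dataclass
class GeneTruth:
    """Per-gene divergence ledger and coordinate maps."""

    gene_id: str
    rhesus_seq: str
    substitutions: list[tuple[int, str]]          # (ref position, new base)
    indels: list[IndelTruth]
    rh2ref: np.ndarray        # per rhesus base: ref position it aligns to / precedes
    is_insert: np.ndarray     # per rhesus base: True if inserted (no ref base)
    cds_rh: Optional[tuple[int, int]]
    category: Optional[str] = None       # targeted category, if category mode
    # alternative (TE cassette) transcript, if any
    alt_seq: Optional[str] = None
    alt_rh2ref: Optional[np.ndarray] = None
    alt_is_insert: Optional[np.ndarray] = None
    cassette_rh: Optional[tuple[int, int]] = None  # cassette interval on alt transcript
    te_family: Optional[str] = None

    def ref_span(self, s: int, e: int, alt: bool = False) -> tuple[int, int]:
        """Project a (possibly alternative-) rhesus interval to reference
        transcript coordinates (half-open)."""
        rh2ref = self.alt_rh2ref if alt else self.rh2ref
        is_ins = self.alt_is_insert if alt else self.is_insert
        idx = np.arange(s, e)
        real = idx[~is_ins[s:e]]
        if real.size == 0:
            p = int(rh2ref[s])
            return (p, p)
        return int(rh2ref[real[0]]), int(rh2ref[real[-1]]) + 1


@dataclass
class ReadTruth:
    read_id: str
    kind: str                 # GENE | OTHERDB | NOVEL_GENOME | NOVEL_FREE | VECTOR | HOST
    source_id: str
    rh_interval: tuple[int, int]            # interval on the (alt) rhesus transcript
    ref_interval: Optional[tuple[int, int]]  # projected reference-transcript interval
    category: Optional[str]
    substitutions: tuple[int, ...] = ()      # ref positions of divergence in the span
    indels: tuple = ()                       # IndelTruth within the span
    uses_alt: bool = False
    te_family: Optional[str] = None
    te_read_interval: Optional[tuple[int, int]] = None  # cassette interval on raw read
    vector_interval: Optional[tuple[int, int]] = None   # on raw read
    seq_errors: tuple[int, ...] = ()         # raw-read positions of sequencing errors


@dataclass
class NovelLocus:
    locus_id: str
    transcript: str
    exons: list[tuple[int, int]]  # genomic intervals (empty for free transcripts)
    orf_nt: tuple[int, int]       # ORF interval on the transcript


@dataclass
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]


@dataclass
class RepeatCopy:
    family: str
    te_class: str
    chrom: str
    start: int
    end: int
    strand: str
    lineage_specific: bool


@dataclass
class ReferenceBundle:
    models: dict[str, GeneModel]
    genome: dict[str, str]
    gene_loci: dict[str, GeneLocus]
    repeats: list[RepeatCopy]
    vector: str
    host: str
    other_db: dict[str, str]
    novel_genomic: list[NovelLocus]
    novel_free: list[NovelLocus]
    segments: list[tuple[str, str, int]]  # (kind, name, length) in genome order
    te_genes: dict[str, dict]             # gene_id -> cassette plumbing
    te_consensus: dict[str, str]


@dataclass
class SimTruth:
    """Ground-truth ledger: one record per emitted read, plus the per-gene
    divergence ledgers and the genome segment ledger."""

    reads: dict[str, ReadTruth]
    genes: dict[str, GeneTruth]
    segments: list[tuple[str, str, int]]

    def to_frame(self):
        import pandas as pd
        rows = []
        for rt in self.reads.values():
            rows.append({
                "read_id": rt.read_id,
                "kind": rt.kind,
                "source_id": rt.source_id,
                "rh_start": rt.rh_interval[0],
                "rh_end": rt.rh_interval[1],
                "ref_start": rt.ref_interval[0] if rt.ref_interval else -1,
                "ref_end": rt.ref_interval[1] if rt.ref_interval else -1,
                "category": rt.category or "",
                "n_subs": len(rt.substitutions),
                "n_indels": len(rt.indels),
                "uses_alt": rt.uses_alt,
                "te_family": rt.te_family or "",
                "vector_len": (rt.vector_interval[1] - rt.vector_interval[0])
                              if rt.vector_interval else 0,
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def category_of_subread(self, read_id: str, q_start: int, q_end: int,
                            model: GeneModel) -> Optional[str]:
        """True category of a sub-interval of a raw read (e.g. after
        trimming), in raw-read coordinates."""
        rt = self.reads[read_id]
        if rt.kind != "GENE":
            return None
        voff = rt.vector_interval[1] if rt.vector_interval else 0
        s = max(q_start - voff, 0) + rt.rh_interval[0]
        e = min(q_end - voff + rt.rh_interval[0], rt.rh_interval[1])
        if e <= s:
            return None
        gt = self.genes[rt.source_id]
        span = gt.ref_span(s, e, alt=rt.uses_alt)
        if span[1] <= span[0]:
            return None
        return classify_region(span, model)


# ---------------------------------------------------------------------------
# reference construction

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        c = _rand_seq(rng, 3)
        if c not in STOPS:
            out.append(c)
    return "".join(out)


def _make_transcript(rng: np.random.Generator, cfg: SimConfig, coding: bool) -> tuple[str, Optional[tuple[int, int]]]:
    u5 = int(rng.integers(cfg.utr5_len[0], cfg.utr5_len[1] + 1))
    u3 = int(rng.integers(cfg.utr3_len[0], cfg.utr3_len[1] + 1))
    if not coding:
        return _rand_seq(rng, u5 + u3 + 200), None
    codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    cds = "ATG" + _rand_codons(rng, codons - 2) + STOPS[rng.integers(0, 3)]
    seq = _rand_seq(rng, u5) + cds + _rand_seq(rng, u3)
    return seq, (u5, u5 + len(cds))


def _make_orf_transcript(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, tuple[int, int]]:
    """A transcript guaranteed to contain an ATG..stop ORF of the
    configured amino-acid length."""
    aa = int(rng.integers(cfg.novel_orf_aa[0], cfg.novel_orf_aa[1] + 1))
    orf = "ATG" + _rand_codons(rng, aa) + STOPS[rng.integers(0, 3)]
    # 5'-proximal ORF with a long trailer, as in full-length cDNAs, so the
    # ORF survives quality trimming of the read's 3' end
    pad5 = int(rng.integers(20, 81))
    pad3 = int(rng.integers(200, 501))
    seq = _rand_seq(rng, pad5) + orf + _rand_seq(rng, pad3)
    return seq, (pad5, pad5 + len(orf))


def _split_exons(rng: np.random.Generator, length: int, lo: int, hi: int,
                 min_exon: int = 30) -> list[int]:
    """Split a transcript length into exon lengths (each >= min_exon)."""
    max_exons = max(1, min(hi, length // min_exon))
    n = int(rng.integers(min(lo, max_exons), max_exons + 1))
    if n <= 1:
        return [length]
    # n-1 distinct internal cut points, min_exon apart
    for _ in range(200):
        cuts = np.sort(rng.choice(np.arange(min_exon, length - min_exon + 1), size=n - 1,
                                  replace=False))
        bounds = np.concatenate(([0], cuts, [length]))
        sizes = np.diff(bounds)
        if (sizes >= min_exon).all():
            return [int(s) for s in sizes]
    return [length]


def make_reference_set(config: SimConfig) -> ReferenceBundle:
    """Build the toy reference world (deterministic given config.seed)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_ref, _ = [np.random.default_rng(s) for s in root.spawn(2)]
    rng = rng_ref

    te_consensus = {}
    for fam, te_class, _lineage in config.te_families:
        length = 300 if te_class == "SINE" else (500 if te_class == "LTR" else 800)
        te_consensus[fam] = _rand_seq(rng, length)

    models: dict[str, GeneModel] = {}
    coding_flags = rng.random(config.n_genes) >= config.p_noncoding
    te_flags = rng.random(config.n_genes) < config.p_te_exon
    lineage_fams = [f for f, _c, l in config.te_families if l]

    genome_parts: list[str] = []
    segments: list[tuple[str, str, int]] = []
    gene_loci: dict[str, GeneLocus] = {}
    repeats: list[RepeatCopy] = []
    te_genes: dict[str, dict] = {}
    pos = 0
    chrom = "chr1"
    fam_lookup = {f: (c, l) for f, c, l in config.te_families}

    def emit(seq: str, kind: str, name: str) -> tuple[int, int]:
        nonlocal pos
        genome_parts.append(seq)
        segments.append((kind, name, len(seq)))
        start = pos
        pos += len(seq)
        return start, pos

    for gi in range(config.n_genes):
        gid = f"G{gi:04d}"
        tid = f"{gid}.1"
        coding = bool(coding_flags[gi])
        seq, cds = _make_transcript(rng, config, coding)
        models[gid] = GeneModel(gid, tid, seq, cds, coding)

        emit(_rand_seq(rng, int(rng.integers(*config.intergenic_len, endpoint=True))),
             "intergenic", "")
        # occasionally drop a background TE copy between genes
        if rng.random() < 0.3 and config.te_families:
            fam = config.te_families[rng.integers(0, len(config.te_families))][0]
            copy = _mutate_lightly(rng, te_consensus[fam], 0.05)
            s, e = emit(copy, "te", fam)
            cls, lin = fam_lookup[fam]
            repeats.append(RepeatCopy(fam, cls, chrom, s, e, "+", lin))
            emit(_rand_seq(rng, int(rng.integers(100, 301))), "intergenic", "")

        exon_sizes = _split_exons(rng, len(seq), config.n_exons[0], config.n_exons[1])
        te_here = bool(te_flags[gi]) and coding and len(exon_sizes) >= 2 and lineage_fams
        te_intron_idx = None
        cassette = None
        fam = None
        if te_here:
            fam = lineage_fams[rng.integers(0, len(lineage_fams))]
            te_intron_idx = int(rng.integers(0, len(exon_sizes) - 1))
            clen = int(rng.integers(*config.te_cassette_len, endpoint=True))
            clen = min(clen, len(te_consensus[fam]) - 10)
            coff = int(rng.integers(0, len(te_consensus[fam]) - clen + 1))
            cassette = _mutate_lightly(rng, te_consensus[fam][coff:coff + clen], 0.01)

        gstart = pos
        exons: list[tuple[int, int]] = []
        off = 0
        for k, size in enumerate(exon_sizes):
            exons.append(emit(seq[off:off + size], "exon", gid))
            off += size
            if k < len(exon_sizes) - 1:
                ilen = int(rng.integers(*config.intron_len, endpoint=True))
                if te_here and k == te_intron_idx:
                    # both intron halves must stay real introns (>= the
                    # configured minimum) so the cassette exon is spliced
                    left = max(config.intron_len[0], ilen // 2)
                    emit(_rand_seq(rng, left), "intron", gid)
                    ts, te_end = emit(cassette, "te", fam)
                    cls, lin = fam_lookup[fam]
                    repeats.append(RepeatCopy(fam, cls, chrom, ts, te_end, "+", lin))
                    te_genes[gid] = {
                        "family": fam,
                        "cassette": cassette,
                        "after_exon": k,
                        "genome_interval": (ts, te_end),
                    }
                    emit(_rand_seq(rng, max(config.intron_len[0], ilen - left)), "intron", gid)
                else:
                    emit(_rand_seq(rng, ilen), "intron", gid)
        gene_loci[gid] = GeneLocus(gid, chrom, gstart, pos, exons)

    # novel multi-exon loci on the genome (not in the mRNA reference)
    novel_genomic: list[NovelLocus] = []
    for ni in range(config.n_novel_genomic):
        emit(_rand_seq(rng, int(rng.integers(*config.intergenic_len, endpoint=True))),
             "intergenic", "")
        nid = f"NOVG{ni:03d}"
        tseq, orf = _make_orf_transcript(rng, config)
        exon_sizes = _split_exons(rng, len(tseq), 2, 6)
        exons = []
        off = 0
        for k, size in enumerate(exon_sizes):
            exons.append(emit(tseq[off:off + size], "novel_exon", nid))
            off += size
            if k < len(exon_sizes) - 1:
                emit(_rand_seq(rng, int(rng.integers(*config.intron_len, endpoint=True))),
                     "novel_intron", nid)
        novel_genomic.append(NovelLocus(nid, tseq, exons, orf))
    emit(_rand_seq(rng, int(rng.integers(*config.intergenic_len, endpoint=True))),
         "intergenic", "")

    novel_free = []
    for ni in range(config.n_novel_free):
        tseq, orf = _make_orf_transcript(rng, config)
        novel_free.append(NovelLocus(f"NOVF{ni:03d}", tseq, [], orf))

    other_db = {}
    for ni in range(config.n_otherdb):
        tseq, _ = _make_orf_transcript(rng, config)
        other_db[f"ODB{ni:03d}"] = tseq

    vector = _rand_seq(rng, 2500)
    host = _rand_seq(rng, 8000)
    genome = {chrom: "".join(genome_parts)}
    return ReferenceBundle(models, genome, gene_loci, repeats, vector, host,
                           other_db, novel_genomic, novel_free, segments,
                           te_genes, te_consensus)


def _mutate_lightly(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


# ---------------------------------------------------------------------------
# divergence planting

def _pick_sub(rng: np.random.Generator, base: str) -> str:
    alt = [b for b in "ACGT" if b != base]
    return alt[rng.integers(0, 3)]


def _plant_divergence(rng: np.random.Generator, model: GeneModel,
                      cfg: SimConfig, category: Optional[str]) -> GeneTruth:
    """Mutate one reference transcript into its rhesus counterpart.

    Substitution probability per site comes from the per-category override
    when active, else from the site's region.  Indels are short (< intron
    threshold), planted only where their left-normalized position is
    unambiguous, and kept >= 10 nt apart.
    """
    ref = model.sequence
    n = len(ref)
    if cfg.sub_rate_by_category is not None and category is not None:
        rates = np.full(n, cfg.sub_rate_by_category[category])
    elif not model.coding:
        rates = np.full(n, cfg.sub_rate_by_region["3UTR"])
    else:
        cs, ce = model.cds
        rates = np.empty(n)
        rates[:cs] = cfg.sub_rate_by_region["5UTR"]
        rates[cs:ce] = cfg.sub_rate_by_region["CDS"]
        rates[ce:] = cfg.sub_rate_by_region["3UTR"]

    arr = list(ref)
    subs: list[tuple[int, str]] = []
    for i in np.flatnonzero(rng.random(n) < rates):
        new = _pick_sub(rng, arr[i])
        arr[i] = new
        subs.append((int(i), new))
    seq = "".join(arr)

    n_indels = int(rng.poisson(cfg.indel_rate * n / 1000.0))
    indels: list[IndelTruth] = []
    used: list[int] = []
    for _ in range(n_indels):
        for _attempt in range(200):
            kind = "del" if rng.random() < 0.5 else "ins"
            length = min(int(rng.geometric(cfg.indel_len_geom_p)), cfg.max_indel_len)
            p = int(rng.integers(2, n - length - 2))
            if any(abs(p - u) < 10 for u in used):
                continue
            if kind == "del":
                # forbid one-step left/right shifts of the gap
                if seq[p - 1] == seq[p + length - 1] or seq[p] == seq[p + length]:
                    continue
                indels.append(IndelTruth(p, "del", length, seq[p:p + length]))
            else:
                ins = _rand_seq(rng, length)
                if ins[-1] == seq[p - 1] or ins[0] == seq[p]:
                    continue
                indels.append(IndelTruth(p, "ins", length, ins))
            used.append(p)
            break
    indels.sort(key=lambda iv: iv.ref_pos)

    # build the rhesus sequence and the rhesus->reference map
    parts: list[str] = []
    rh2ref: list[int] = []
    is_ins: list[bool] = []
    cur = 0
    for iv in indels:
        parts.append(seq[cur:iv.ref_pos])
        rh2ref.extend(range(cur, iv.ref_pos))
        is_ins.extend([False] * (iv.ref_pos - cur))
        if iv.kind == "del":
            cur = iv.ref_pos + iv.length
        else:
            parts.append(iv.seq)
            rh2ref.extend([iv.ref_pos] * iv.length)
            is_ins.extend([True] * iv.length)
            cur = iv.ref_pos
    parts.append(seq[cur:])
    rh2ref.extend(range(cur, n))
    is_ins.extend([False] * (n - cur))
    rh_seq = "".join(parts)
    rh2ref_a = np.asarray(rh2ref, dtype=np.int64)
    is_ins_a = np.asarray(is_ins, dtype=bool)

    cds_rh = None
    if model.coding:
        cs, ce = model.cds
        cds_rh = (int(np.searchsorted(rh2ref_a, cs, side="left")),
                  int(np.searchsorted(rh2ref_a, ce, side="left")))
    return GeneTruth(model.gene_id, rh_seq, subs, indels, rh2ref_a, is_ins_a,
                     cds_rh, category=category)


def _attach_cassette(gt: GeneTruth, model: GeneModel, bundle: ReferenceBundle) -> None:
    """Build the alternative transcript carrying the TE cassette exon."""
    info = bundle.te_genes[gt.gene_id]
    locus = bundle.gene_loci[gt.gene_id]
    # reference coordinate of the splice point = cumulative exon length
    ref_break = sum(e - s for s, e in locus.exons[:info["after_exon"] + 1])
    rh_break = int(np.searchsorted(gt.rh2ref, ref_break, side="left"))
    cassette = info["cassette"]
    gt.alt_seq = gt.rhesus_seq[:rh_break] + cassette + gt.rhesus_seq[rh_break:]
    gt.alt_rh2ref = np.concatenate([gt.rh2ref[:rh_break],
                                    np.full(len(cassette), ref_break, dtype=np.int64),
                                    gt.rh2ref[rh_break:]])
    gt.alt_is_insert = np.concatenate([gt.is_insert[:rh_break],
                                       np.ones(len(cassette), dtype=bool),
                                       gt.is_insert[rh_break:]])
    gt.cassette_rh = (rh_break, rh_break + len(cassette))
    gt.te_family = info["family"]


# ---------------------------------------------------------------------------
# read sampling

def _sample_interval(rng, lo: int, hi: int, min_len: int) -> tuple[int, int]:
    """Random sub-interval of [lo, hi) of length >= min_len."""
    span = hi - lo
    min_len = min(min_len, span)
    length = int(rng.integers(min_len, span + 1))
    start = lo + int(rng.integers(0, span - length + 1))
    return start, start + length


def _span_for_category(rng, cat: str, cs: int, ce: int, L: int,
                       margin: int = 10, min_piece: int = 150) -> tuple[int, int]:
    # min_piece keeps single-region reads long enough to be mappable
    # (cDNA reads below ~170 nt are discarded by the pipeline anyway);
    # regions shorter than min_piece cap it at the region length
    if cat == "5UTR":
        return _sample_interval(rng, 0, cs, min_piece)
    if cat == "CDS":
        return _sample_interval(rng, cs, ce, min_piece)
    if cat == "3UTR":
        return _sample_interval(rng, ce, L, min_piece)
    if cat == "5UTR_CDS":
        s = int(rng.integers(0, max(1, cs - margin)))
        e = int(rng.integers(cs + margin, ce + 1))
        return s, e
    if cat == "CDS_3UTR":
        s = int(rng.integers(cs, max(cs + 1, ce - margin)))
        e = int(rng.integers(ce + margin, L + 1))
        return s, e
    if cat == "5UTR_CDS_3UTR":
        s = int(rng.integers(0, max(1, cs - margin)))
        e = int(rng.integers(ce + margin, L + 1))
        return s, e
    raise ValueError(f"cannot target category {cat}")


def _draw_read_len(rng, cfg: SimConfig) -> int:
    mean, sd = cfg.read_len
    lo, hi = cfg.read_len_clip
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def _qualities(rng, cfg: SimConfig, n: int) -> np.ndarray:
    hi, lo = cfg.quality_decay
    means = np.linspace(hi, lo, num=max(n, 2))[:n]
    q = np.rint(rng.normal(means, cfg.quality_sd)).astype(int)
    return np.clip(q, 2, 40)


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: np.ndarray  # Phred scores, same length


def simulate_cdna_reads(refs: ReferenceBundle, config: SimConfig
                        ) -> tuple[list[SimRead], SimTruth]:
    """Sample directional (5'-sequenced) cDNA reads with ground truth.

    In category mode (``category_weights`` set) each coding gene is
    assigned a target category and all its reads realize it; otherwise
    reads are 5'-anchored with probability ``p_5prime_complete`` and
    truncated/windowed otherwise.  Contaminant (vector/host) and novel
    reads are interleaved at the configured rates.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    _, rng_reads = [np.random.default_rng(s) for s in root.spawn(2)]
    rng = rng_reads

    gene_ids = sorted(refs.models)
    truths: dict[str, GeneTruth] = {}

    def gene_truth(gid: str, category: Optional[str]) -> GeneTruth:
        if gid not in truths:
            gt = _plant_divergence(rng, refs.models[gid], config, category)
            if gid in refs.te_genes:
                _attach_cassette(gt, refs.models[gid], refs)
            truths[gid] = gt
        return truths[gid]

    reads: list[SimRead] = []
    read_truth: dict[str, ReadTruth] = {}
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"SIM{counter[0]:06d}"

    def finish(seq: str, rt: ReadTruth) -> None:
        qual = _qualities(rng, config, len(seq))
        if config.seq_error == "quality":
            err_p = 10.0 ** (-qual / 10.0)
            hits = np.flatnonzero(rng.random(len(seq)) < err_p)
            if hits.size:
                arr = list(seq)
                for i in hits:
                    arr[i] = _pick_sub(rng, arr[i])
                seq = "".join(arr)
                rt = dataclasses.replace(rt, seq_errors=tuple(int(i) for i in hits))
        reads.append(SimRead(rt.read_id, seq, qual))
        read_truth[rt.read_id] = rt

    def add_vector_prefix(seq: str, rt: ReadTruth) -> tuple[str, ReadTruth]:
        if rng.random() < config.p_vector_contam:
            vl = int(rng.integers(*config.vector_seg_len, endpoint=True))
            voff = int(rng.integers(0, len(refs.vector) - vl + 1))
            seq = refs.vector[voff:voff + vl] + seq
            rt = dataclasses.replace(rt, vector_interval=(0, vl))
            if rt.te_read_interval is not None:
                s, e = rt.te_read_interval
                rt = dataclasses.replace(rt, te_read_interval=(s + vl, e + vl))
        return seq, rt

    def emit_gene_read(gid: str, category: Optional[str]) -> None:
        model = refs.models[gid]
        gt = gene_truth(gid, category)
        use_alt = (gt.alt_seq is not None and rng.random() < config.p_te_read_inclusion)
        src = gt.alt_seq if use_alt else gt.rhesus_seq
        L = len(src)
        if category is not None and model.coding and not use_alt:
            cs, ce = gt.cds_rh
            s, e = _span_for_category(rng, category, cs, ce, L)
        elif use_alt:
            # make sure the cassette is covered with flanks
            cas_s, cas_e = gt.cassette_rh
            s = int(rng.integers(0, max(1, cas_s - 40)))
            e = int(rng.integers(min(L, cas_e + 40), L + 1))
        else:
            rl = int(round(_draw_read_len(rng, config) * config.raw_stretch))
            if rng.random() < config.p_5prime_complete or rl >= L:
                s = 0
            else:
                s = int(rng.integers(0, L - rl + 1))
            e = min(L, s + rl)
        seq = src[s:e]
        ref_span = gt.ref_span(s, e, alt=use_alt)
        if ref_span[1] <= ref_span[0]:
            ref_span = (ref_span[0], ref_span[0] + 1)
        cat = "NR_XR" if not model.coding else classify_region(ref_span, model)
        subs = tuple(p for p, _ in gt.substitutions if ref_span[0] <= p < ref_span[1])
        indels = tuple(iv for iv in gt.indels if ref_span[0] <= iv.ref_pos < ref_span[1])
        te_iv = None
        fam = None
        if use_alt:
            cas_s, cas_e = gt.cassette_rh
            if s <= cas_s and cas_e <= e:
                te_iv = (cas_s - s, cas_e - s)
                fam = gt.te_family
        rt = ReadTruth(next_id(), "GENE", gid, (s, e), ref_span, cat,
                       substitutions=subs, indels=indels, uses_alt=use_alt,
                       te_family=fam, te_read_interval=te_iv)
        seq, rt = add_vector_prefix(seq, rt)
        finish(seq, rt)

    def emit_novel_read(kind: str) -> None:
        if kind == "OTHERDB":
            keys = sorted(refs.other_db)
            sid = keys[rng.integers(0, len(keys))]
            src = refs.other_db[sid]
            orf = None
        elif kind == "NOVEL_GENOME":
            loc = refs.novel_genomic[rng.integers(0, len(refs.novel_genomic))]
            sid, src, orf = loc.locus_id, loc.transcript, loc.orf_nt
        else:
            loc = refs.novel_free[rng.integers(0, len(refs.novel_free))]
            sid, src, orf = loc.locus_id, loc.transcript, loc.orf_nt
        # near-full-length reads so the planted ORF is present
        s = int(rng.integers(0, min(20, max(1, orf[0] if orf else 20))))
        e = len(src) - int(rng.integers(0, 20))
        rt = ReadTruth(next_id(), kind, sid, (s, e), None, None)
        seq, rt = add_vector_prefix(src[s:e], rt)
        finish(seq, rt)

    def emit_contaminant(kind: str) -> None:
        src = refs.vector if kind == "VECTOR" else refs.host
        rl = min(_draw_read_len(rng, config), len(src))
        s = int(rng.integers(0, len(src) - rl + 1))
        rt = ReadTruth(next_id(), kind, kind.lower(), (s, s + rl), None, None)
        finish(src[s:s + rl], rt)

    def pick_unknown_kind() -> str:
        w = np.asarray(config.unknown_split, dtype=float)
        kinds = ["OTHERDB", "NOVEL_GENOME", "NOVEL_FREE"]
        return kinds[rng.choice(3, p=w / w.sum())]

    if config.category_weights is not None:
        cats = sorted(config.category_weights)
        w = np.asarray([config.category_weights[c] for c in cats], dtype=float)
        w = w / w.sum()
        n_known = 0
        for gid in gene_ids:
            model = refs.models[gid]
            cat = None
            if model.coding:
                cat = cats[rng.choice(len(cats), p=w)]
            n = int(rng.integers(config.reads_per_gene[0], config.reads_per_gene[1] + 1))
            for _ in range(n):
                emit_gene_read(gid, cat)
                n_known += 1
        f = config.p_vector_read + config.p_host_read + config.p_unknown
        n_other = int(round(n_known * f / max(1e-9, 1.0 - f)))
        probs = np.asarray([config.p_vector_read, config.p_host_read, config.p_unknown])
        probs = probs / probs.sum() if probs.sum() > 0 else probs
        for _ in range(n_other):
            r = rng.random()
            if r < probs[0]:
                emit_contaminant("VECTOR")
            elif r < probs[0] + probs[1]:
                emit_contaminant("HOST")
            else:
                emit_novel_read(pick_unknown_kind())
    else:
        for _ in range(config.n_reads):
            r = rng.random()
            if r < config.p_vector_read:
                emit_contaminant("VECTOR")
            elif r < config.p_vector_read + config.p_host_read:
                emit_contaminant("HOST")
            elif r < config.p_vector_read + config.p_host_read + config.p_unknown:
                emit_novel_read(pick_unknown_kind())
            else:
                gid = gene_ids[rng.integers(0, len(gene_ids))]
                emit_gene_read(gid, None)

    return reads, SimTruth(read_truth, truths, list(refs.segments))
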