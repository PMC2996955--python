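"""Pairwise local alignment of cDNAs to reference mRNAs and to a genome.

Transcript-scale alignment is exact affine-gap local DP (Smith-Waterman
with gap cost ``open + (L-1)*extend``), delegated to Biopython's
C ``PairwiseAligner``.  Genome mapping adds a fourth DP state that charges
a flat penalty for arbitrarily long target-side gaps, so spliced
structures (introns) are representable; that kernel is numba-compiled.
All internal coordinates are 0-based half-open.  The TSV exporter follows
the convention matched_length = query_end - query_start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Scoring", "AlignmentBlock", "GapEvent", "PairwiseAlignment",
    "UndefinedIdentityError", "align_local", "identity", "KmerIndex",
    "best_hit", "GenomeIndex", "map_to_genome", "exon_blocks",
    "alignment_row", "alignments_to_frame",
]


@dataclass(frozen=True)
class Scoring:
    """Affine local alignment scores; a gap of length L costs
    ``gap_open + (L-1) * gap_extend`` (both negative)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()

#: hit-acceptance defaults: identity over aligned columns, and the number
#: of aligned (match+mismatch) columns required
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_ALIGNED = 100


class UndefinedIdentityError(ValueError):
    """Identity requested over an interval with zero aligned columns."""


@dataclass(frozen=True)
class AlignmentBlock:
    """A gapless aligned segment (equal-length query/target intervals)."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int

    def __post_init__(self):
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("block intervals differ in length")
        if self.q_end <= self.q_start:
            raise ValueError("empty block")

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class GapEvent:
    """An indel column run: ``side`` names the sequence whose bases are
    skipped (side='target': target bases unaligned, i.e. deletion from the
    query or an intron; side='query': extra query bases, an insertion).

    ``q_pos``/``t_pos`` anchor the gap on both sequences; ``seq`` holds the
    skipped bases (needed for left-normalization downstream)."""

    side: str  # 'query' | 'target'
    q_pos: int
    t_pos: int
    length: int
    seq: str = ""


@dataclass
class PairwiseAlignment:
    """A scored local alignment decomposed into gapless blocks."""

    query_id: str
    target_id: str
    score: float
    blocks: list[AlignmentBlock]
    q_block_seqs: list[str]
    t_block_seqs: list[str]
    matches: int
    mismatches: int
    gaps: list[GapEvent] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.blocks

    @property
    def q_start(self) -> int:
        return self.blocks[0].q_start

    @property
    def q_end(self) -> int:
        return self.blocks[-1].q_end

    @property
    def t_start(self) -> int:
        return self.blocks[0].t_start

    @property
    def t_end(self) -> int:
        return self.blocks[-1].t_end

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def matched_length(self) -> int:
        """Exported matched length: query_end - query_start."""
        return 0 if self.is_empty else self.q_end - self.q_start

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches

    def identity(self, restrict_to: Optional[tuple[int, int]] = None) -> float:
        return identity(self, restrict_to)

    def aligned_query_intervals(self) -> list[tuple[int, int]]:
        return [(b.q_start, b.q_end) for b in self.blocks]


EMPTY = PairwiseAlignment("", "", 0.0, [], [], [], 0, 0)


def _empty(query_id: str, target_id: str) -> PairwiseAlignment:
    return PairwiseAlignment(query_id, target_id, 0.0, [], [], [], 0, 0)


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            # N never counts as a match
            m[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = m
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


_VALID = set("ACGTN")


def _sanitize(seq: str) -> str:
    s = seq.upper()
    if set(s) - _VALID:
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def _build_alignment(query_id: str, target_id: str, score: float,
                     q_blocks: Sequence[tuple[int, int]],
                     t_blocks: Sequence[tuple[int, int]],
                     query: str, target: str) -> PairwiseAlignment:
    blocks: list[AlignmentBlock] = []
    q_seqs: list[str] = []
    t_seqs: list[str] = []
    gaps: list[GapEvent] = []
    matches = mismatches = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if prev_q is not None:
            dq = qs - prev_q
            dt = ts - prev_t
            if dq > 0:
                gaps.append(GapEvent("query", prev_q, prev_t, dq, query[prev_q:qs]))
            if dt > 0:
                gaps.append(GapEvent("target", prev_q + max(dq, 0), prev_t, dt, target[prev_t:ts]))
        blocks.append(AlignmentBlock(qs, qe, ts, te))
        qb, tb = query[qs:qe], target[ts:te]
        q_seqs.append(qb)
        t_seqs.append(tb)
        for a, b in zip(qb, tb):
            if a == b and a != "N":
                matches += 1
            else:
                mismatches += 1
        prev_q, prev_t = qe, te
    return PairwiseAlignment(query_id, target_id, float(score), blocks,
                             q_seqs, t_seqs, matches, mismatches, gaps)


def align_local(query: str, target: str, scoring: Scoring = DEFAULT_SCORING,
                query_id: str = "query", target_id: str = "target") -> PairwiseAlignment:
    """Optimal affine-gap local alignment of two sequences over {A,C,G,T,N}.

    Empty input (or an all-negative score matrix outcome) yields an empty
    alignment with score 0.  Among co-optimal alignments the engine's
    first enumeration order is used, which is deterministic.
    """
    q = _sanitize(query)
    t = _sanitize(target)
    if not q or not t:
        return _empty(query_id, target_id)
    aligner = _aligner(scoring)
    try:
        aln = aligner.align(t, q)[0]
    except IndexError:  # no positive-scoring local alignment
        return _empty(query_id, target_id)
    if aln.score <= 0:
        return _empty(query_id, target_id)
    t_blocks, q_blocks = aln.aligned
    return _build_alignment(query_id, target_id, aln.score,
                            [tuple(b) for b in q_blocks],
                            [tuple(b) for b in t_blocks], q, t)


def identity(aln: PairwiseAlignment, restrict_to: Optional[tuple[int, int]] = None) -> float:
    """Fraction of matching columns, gap columns excluded.

    With ``restrict_to`` (target coordinates, half-open) only block columns
    whose target coordinate falls in the interval count.  Zero aligned
    columns raise :class:`UndefinedIdentityError` rather than returning 0.
    """
    if aln.is_empty:
        raise UndefinedIdentityError("empty alignment")
    if restrict_to is None:
        if aln.aligned_columns == 0:
            raise UndefinedIdentityError("no aligned columns")
        return aln.matches / aln.aligned_columns
    lo, hi = restrict_to
    m = mm = 0
    for block, qb, tb in zip(aln.blocks, aln.q_block_seqs, aln.t_block_seqs):
        for k in range(len(block)):
            tpos = block.t_start + k
            if lo <= tpos < hi:
                if qb[k] == tb[k] and qb[k] != "N":
                    m += 1
                else:
                    mm += 1
    if m + mm == 0:
        raise UndefinedIdentityError(f"no aligned columns in target interval {restrict_to}")
    return m / (m + mm)


# ---------------------------------------------------------------------------
# k-mer seeded best hit against a transcript set

class KmerIndex:
    """Exact k-mer index over a set of target sequences, used only to
    shortlist candidates; scoring is always the full DP."""

    def __init__(self, targets: Mapping[str, str], k: int = 11):
        self.k = k
        self.targets = dict(targets)
        self._index: dict[str, list[str]] = {}
        for tid in sorted(self.targets):
            seq = self.targets[tid].upper()
            seen = set()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if kmer not in seen and "N" not in kmer:
                    seen.add(kmer)
                    self._index.setdefault(kmer, []).append(tid)

    def candidates(self, query: str, max_candidates: int = 5) -> list[str]:
        """Target ids sharing the most k-mers with the query (count desc,
        then lexicographic id), at most ``max_candidates``."""
        q = query.upper()
        counts: dict[str, int] = {}
        seen = set()
        for i in range(len(q) - self.k + 1):
            kmer = q[i:i + self.k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for tid in self._index.get(kmer, ()):
                counts[tid] = counts.get(tid, 0) + 1
        ranked = sorted(counts, key=lambda tid: (-counts[tid], tid))
        return ranked[:max_candidates]


def best_hit(query: str, targets: Mapping[str, str],
             scoring: Scoring = DEFAULT_SCORING,
             min_identity: float = DEFAULT_MIN_IDENTITY,
             min_aligned: int = DEFAULT_MIN_ALIGNED,
             query_id: str = "query",
             index: Optional[KmerIndex] = None,
             max_candidates: int = 5,
             exhaustive: bool = False) -> Optional[PairwiseAlignment]:
    """Highest-scoring acceptable alignment of the query to any target.

    A hit must reach ``min_identity`` over at least ``min_aligned``
    aligned (non-gap) columns.  Ties break by score, then longer aligned
    query span, then lexicographically smaller target id.  Returns None
    (NO_HIT) when nothing passes.  Unless ``exhaustive``, targets are
    shortlisted by shared k-mers before DP.
    """
    if not targets:
        return None
    if exhaustive or len(targets) <= max_candidates:
        cand_ids: list[str] = sorted(targets)
    else:
        if index is None:
            index = KmerIndex(targets)
        cand_ids = index.candidates(query, max_candidates=max_candidates)
    if not cand_ids:
        return None
    # rank candidates by DP score first (cheap, no traceback); only
    # score-maximal candidates need the full alignment for tie-breaking
    q = _sanitize(query)
    if not q:
        return None
    aligner = _aligner(scoring)
    scores = sorted(((aligner.score(_sanitize(targets[tid]), q), tid) for tid in cand_ids),
                    key=lambda st: (-st[0], st[1]))
    best: Optional[PairwiseAlignment] = None
    best_key = None
    for s, tid in scores:
        if s <= 0:
            break
        if best is not None and s < best.score:
            break  # later candidates cannot beat an accepted hit
        aln = align_local(query, targets[tid], scoring, query_id=query_id, target_id=tid)
        if aln.is_empty or aln.aligned_columns < min_aligned:
            continue
        if aln.identity() < min_identity:
            continue
        key = (aln.score, aln.q_end - aln.q_start, _NegStr(tid))
        if best is None or key > best_key:
            best, best_key = aln, key
    return best


class _NegStr(str):
    """String ordered in reverse, so that max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# intron-aware genome mapping (numba DP with a flat long-gap state)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in seq.upper()), dtype=np.int8,
                       count=len(seq))


def _get_intron_kernel():
    import numba

    @numba.njit(cache=True)
    def kernel(q, t, match, mismatch, gap_open, gap_extend, intron_open):
        n = q.shape[0]
        m = t.shape[0]
        NEG = -(1 << 30)
        prevM = np.full(m + 1, NEG, np.int32)
        prevX = np.full(m + 1, NEG, np.int32)
        prevY = np.full(m + 1, NEG, np.int32)
        prevJ = np.full(m + 1, NEG, np.int32)
        curM = np.full(m + 1, NEG, np.int32)
        curX = np.full(m + 1, NEG, np.int32)
        curY = np.full(m + 1, NEG, np.int32)
        curJ = np.full(m + 1, NEG, np.int32)
        tbM = np.zeros((n + 1, m + 1), np.uint8)
        tbX = np.zeros((n + 1, m + 1), np.uint8)
        tbY = np.zeros((n + 1, m + 1), np.uint8)
        tbJ = np.zeros((n + 1, m + 1), np.uint8)
        best = 0
        bi = -1
        bj = -1
        for i in range(1, n + 1):
            qc = q[i - 1]
            curM[0] = NEG
            curX[0] = NEG
            curY[0] = NEG
            curJ[0] = NEG
            for j in range(1, m + 1):
                tc = t[j - 1]
                s = match if (qc == tc and qc < 4) else mismatch
                # M state: diagonal from any state or a fresh local start
                pm, px, py, pj = prevM[j - 1], prevX[j - 1], prevY[j - 1], prevJ[j - 1]
                bestprev = 0
                ptr = 0
                if pm >= bestprev:
                    bestprev = pm
                    ptr = 1
                if py > bestprev:
                    bestprev = py
                    ptr = 3
                if px > bestprev:
                    bestprev = px
                    ptr = 2
                if pj > bestprev:
                    bestprev = pj
                    ptr = 4
                curM[j] = bestprev + s
                tbM[i, j] = ptr
                # X: gap in target (consume query base i)
                xo = prevM[j] + gap_open
                xe = prevX[j] + gap_extend
                if xo >= xe:
                    curX[j] = xo
                    tbX[i, j] = 1
                else:
                    curX[j] = xe
                    tbX[i, j] = 2
                # Y: gap in query (consume target base j), affine
                yo = curM[j - 1] + gap_open
                ye = curY[j - 1] + gap_extend
                if yo >= ye:
                    curY[j] = yo
                    tbY[i, j] = 1
                else:
                    curY[j] = ye
                    tbY[i, j] = 2
                # J: long target-side gap, flat cost
                jo = curM[j - 1] + intron_open
                je = curJ[j - 1]
                if jo >= je:
                    curJ[j] = jo
                    tbJ[i, j] = 1
                else:
                    curJ[j] = je
                    tbJ[i, j] = 2
                if curM[j] > best:
                    best = curM[j]
                    bi = i
                    bj = j
            prevM, curM = curM, prevM
            prevX, curX = curX, prevX
            prevY, curY = curY, prevY
            prevJ, curJ = curJ, prevJ
        return best, bi, bj, tbM, tbX, tbY, tbJ

    return kernel


_INTRON_KERNEL = None


def _intron_dp(q: np.ndarray, t: np.ndarray, scoring: Scoring, intron_open: int):
    global _INTRON_KERNEL
    if _INTRON_KERNEL is None:
        _INTRON_KERNEL = _get_intron_kernel()
    return _INTRON_KERNEL(q, t, scoring.match, scoring.mismatch,
                          scoring.gap_open, scoring.gap_extend, -abs(intron_open))


def _traceback_blocks(bi: int, bj: int, tbM, tbX, tbY, tbJ) -> list[tuple[int, int, int, int]]:
    """Recover gapless blocks (q_start, q_end, t_start, t_end) from the
    intron-DP traceback, ending at M cell (bi, bj)."""
    i, j = bi, bj
    state = 0  # 0=M 1=X 2=Y 3=J
    cols: list[tuple[int, int]] = []  # aligned (qi, tj) pairs, reversed
    while i > 0 and j > 0:
        if state == 0:
            ptr = tbM[i, j]
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
            if ptr == 0:
                break
            state = {1: 0, 2: 1, 3: 2, 4: 3}[ptr]
        elif state == 1:
            ptr = tbX[i, j]
            i -= 1
            state = 0 if ptr == 1 else 1
        elif state == 2:
            ptr = tbY[i, j]
            j -= 1
            state = 0 if ptr == 1 else 2
        else:
            ptr = tbJ[i, j]
            j -= 1
            state = 0 if ptr == 1 else 3
    cols.reverse()
    blocks: list[tuple[int, int, int, int]] = []
    for qi, tj in cols:
        if blocks and blocks[-1][1] == qi and blocks[-1][3] == tj:
            qs, _, ts, _ = blocks[-1]
            blocks[-1] = (qs, qi + 1, ts, tj + 1)
        else:
            blocks.append((qi, qi + 1, tj, tj + 1))
    return blocks


class GenomeIndex:
    """k-mer seed index over genome sequences for window selection."""

    def __init__(self, genome: Mapping[str, str], k: int = 13, max_occ: int = 50):
        self.genome = dict(genome)
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.genome):
            seq = self.genome[chrom].upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                hits = index.setdefault(kmer, [])
                if len(hits) <= max_occ:
                    hits.append((chrom, i))
        # drop over-represented seeds (repeats)
        self._index = {km: h for km, h in index.items() if len(h) <= max_occ}

    def seed_hits(self, query: str) -> dict[str, list[tuple[int, int]]]:
        """Per-chromosome list of (query_pos, genome_pos) exact seed hits."""
        q = query.upper()
        hits: dict[str, list[tuple[int, int]]] = {}
        for i in range(len(q) - self.k + 1):
            for chrom, pos in self._index.get(q[i:i + self.k], ()):
                hits.setdefault(chrom, []).append((i, pos))
        return hits


def _best_window(hits: list[tuple[int, int]], qlen: int, max_cluster_gap: int = 10_000,
                 margin: int = 200) -> tuple[int, int]:
    positions = sorted(p for _, p in hits)
    clusters: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] > max_cluster_gap:
            clusters.append([p])
        else:
            clusters[-1].append(p)
    cluster = max(clusters, key=len)
    lo = cluster[0] - qlen - margin
    hi = cluster[-1] + qlen + margin
    return max(0, lo), hi


def map_to_genome(query: str, genome_index: GenomeIndex,
                  scoring: Scoring = DEFAULT_SCORING,
                  min_intron: int = 30,
                  intron_open: int = 24,
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  min_aligned: int = DEFAULT_MIN_ALIGNED,
                  query_id: str = "query") -> Optional[PairwiseAlignment]:
    """Intron-aware local alignment of a cDNA to the genome.

    Exact k-mer seeds select the chromosome and a window; the intron DP
    aligns the query inside the window.  Target-side gaps of length >=
    ``min_intron`` are introns (flat ``intron_open`` cost in the DP);
    shorter gaps are ordinary affine indels.  Returns None when no seeds
    or no acceptable alignment exist.
    """
    q = _sanitize(query)
    if not q:
        return None
    hits = genome_index.seed_hits(q)
    if not hits:
        return None
    chrom = max(hits, key=lambda c: (len(hits[c]), _NegStr(c)))
    lo, hi = _best_window(hits[chrom], len(q))
    target = genome_index.genome[chrom].upper()
    window = target[lo:min(hi, len(target))]
    score, bi, bj, tbM, tbX, tbY, tbJ = _intron_dp(_encode(q), _encode(window),
                                                   scoring, intron_open)
    if score <= 0 or bi < 0:
        return None
    raw_blocks = _traceback_blocks(bi, bj, tbM, tbX, tbY, tbJ)
    q_blocks = [(qs, qe) for qs, qe, _, _ in raw_blocks]
    t_blocks = [(ts + lo, te + lo) for _, _, ts, te in raw_blocks]
    aln = _build_alignment(query_id, chrom, score, q_blocks, t_blocks, q, target)
    if aln.is_empty or aln.aligned_columns < min_aligned:
        return None
    if aln.identity() < min_identity:
        return None
    return aln


def exon_blocks(aln: PairwiseAlignment, min_intron: int = 30) -> list[tuple[int, int]]:
    """Merge gapless blocks into exon-level blocks.

    Only target-side gaps of length >= ``min_intron`` (introns) split
    blocks; smaller gaps on either side are absorbed.  Returns target
    (genomic) intervals of the exon blocks.
    """
    if aln.is_empty:
        return []
    intron_tpos = {g.t_pos for g in aln.gaps if g.side == "target" and g.length >= min_intron}
    merged: list[list[int]] = []
    for b in aln.blocks:
        if merged and b.t_start != merged[-1][1] and merged[-1][1] not in intron_tpos:
            # small target gap: absorb
            merged[-1][1] = b.t_end
        elif merged and b.t_start == merged[-1][1]:
            merged[-1][1] = b.t_end
        else:
            merged.append([b.t_start, b.t_end])
    return [(s, e) for s, e in merged]


def exon_query_blocks(aln: PairwiseAlignment, min_intron: int = 30) -> list[tuple[int, int, int, int]]:
    """Exon-level blocks as (q_start, q_end, t_start, t_end)."""
    if aln.is_empty:
        return []
    intron_tpos = {g.t_pos for g in aln.gaps if g.side == "target" and g.length >= min_intron}
    merged: list[list[int]] = []
    for b in aln.blocks:
        if merged and not (b.t_start != merged[-1][3] and merged[-1][3] in intron_tpos):
            merged[-1][1] = b.q_end
            merged[-1][3] = b.t_end
        else:
            merged.append([b.q_start, b.q_end, b.t_start, b.t_end])
    return [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# exporters

def alignment_row(aln: PairwiseAlignment, query_length: int,
                  min_intron: int = 30, aligned_region: str = "") -> dict:
    """One exporter row; matched_length = query_end - query_start."""
    return {
        "acc": aln.query_id,
        "length_bp": query_length,
        "matched_bp": aln.matched_length,
        "query_start": aln.q_start,
        "query_end": aln.q_end,
        "chrom": aln.target_id,
        "n_blocks": len(exon_blocks(aln, min_intron)),
        "aligned_region": aligned_region,
    }


def alignments_to_frame(rows: Iterable[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["acc", "length_bp", "matched_bp", "query_start",
                                       "query_end", "chrom", "n_blocks", "aligned_region"])
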