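"""Raw-read cleaning: quality trim, vector/host screen, length filter.

The stage order is quality -> vector -> host -> length.  Each raw read
ends in exactly one state: KEPT, or removed for vector, host, short
length, or low quality.  Trimming only ever narrows the kept interval on
the raw read; retained bases are a literal substring of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import align

KEPT = "KEPT"
REMOVED_VECTOR = "REMOVED_VECTOR"
REMOVED_HOST = "REMOVED_HOST"
REMOVED_SHORT = "REMOVED_SHORT"
REMOVED_QUALITY = "REMOVED_QUALITY"

STATUSES = (KEPT, REMOVED_VECTOR, REMOVED_HOST, REMOVED_SHORT, REMOVED_QUALITY)


@dataclass
class CleanRead:
    """Outcome of cleaning one raw read."""

    read_id: str
    raw_length: int
    status: str
    kept: tuple[int, int]  # half-open interval on the raw read
    sequence: str
    evidence: dict = field(default_factory=dict)


def quality_trim(qualities: Sequence[int], window: int = 10,
                 min_mean_q: float = 20.0) -> tuple[int, int]:
    """Longest interval in which every length-``window`` sliding window has
    mean quality >= ``min_mean_q``.

    Intervals shorter than the window are judged as a single whole-interval
    window (this also covers window > read length).  Ties break leftmost.
    Returns (0, 0) when nothing qualifies.
    """
    q = np.asarray(qualities, dtype=float)
    n = q.size
    if n == 0:
        return (0, 0)
    csum = np.concatenate(([0.0], np.cumsum(q)))
    if window <= n:
        means = (csum[window:] - csum[:-window]) / window  # window starting at i
        good = means >= min_mean_q
    else:
        good = np.zeros(0, dtype=bool)
    best = (0, 0)
    run_start = None
    for i in range(good.size + 1):
        if i < good.size and good[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            length = (i - 1 + window) - run_start
            if length > best[1] - best[0]:
                best = (run_start, i - 1 + window)
            run_start = None
    if best != (0, 0):
        return best
    # no clean full window: fall back to the longest short interval whose
    # own mean passes
    for length in range(min(window - 1, n), 0, -1):
        for s in range(n - length + 1):
            if (csum[s + length] - csum[s]) / length >= min_mean_q:
                return (s, s + length)
    return (0, 0)


def _terminal_trim(seq: str, hits: list[tuple[int, int]], internal_flank: int = 50
                   ) -> tuple[Optional[tuple[int, int]], Optional[tuple[int, int]]]:
    """Apply one vector hit to the read.

    Returns (kept interval or None-if-removed, matched interval).  A hit
    with >= ``internal_flank`` nt of non-vector sequence on both sides
    marks the read as vector-removed (None).  A terminal hit trims the hit
    and everything outside it on that end.
    """
    if not hits:
        return (0, len(seq)), None
    qs, qe = hits[0]
    n = len(seq)
    if qs >= internal_flank and n - qe >= internal_flank:
        return None, (qs, qe)
    if qs < n - qe:
        return (qe, n), (qs, qe)  # 5'-terminal: keep the 3' remainder
    return (0, qs), (qs, qe)      # 3'-terminal: keep the 5' remainder


def vector_screen(seq: str, vector_lib: Mapping[str, str],
                  min_len: int = 20, min_ident: float = 0.95,
                  scoring: align.Scoring = align.DEFAULT_SCORING,
                  internal_flank: int = 50,
                  max_rounds: int = 4) -> tuple[Optional[tuple[int, int]], list]:
    """Trim terminal vector matches; remove reads with internal vector.

    Returns (kept interval on ``seq`` or None when the read is removed,
    list of matched (start, end) vector intervals on the read).  Matches
    must span >= ``min_len`` aligned columns at >= ``min_ident`` identity.
    """
    kept = (0, len(seq))
    matched: list[tuple[int, int]] = []
    for _ in range(max_rounds):
        sub = seq[kept[0]:kept[1]]
        if len(sub) < min_len:
            break
        best = None
        for vid in sorted(vector_lib):
            aln = align.align_local(sub, vector_lib[vid], scoring)
            if aln.is_empty or aln.aligned_columns < min_len:
                continue
            if aln.identity() < min_ident:
                continue
            if best is None or aln.score > best.score:
                best = aln
        if best is None:
            break
        hit = (kept[0] + best.q_start, kept[0] + best.q_end)
        matched.append(hit)
        local_hit = (best.q_start, best.q_end)
        new_kept, _ = _terminal_trim(sub, [local_hit], internal_flank)
        if new_kept is None:
            return None, matched
        kept = (kept[0] + new_kept[0], kept[0] + new_kept[1])
        if kept[1] - kept[0] < min_len:
            return None, matched
    if kept[1] - kept[0] == 0:
        return None, matched
    return kept, matched


def host_screen(seq: str, host_lib: Mapping[str, str],
                min_len: int = 100, min_ident: float = 0.95,
                scoring: align.Scoring = align.DEFAULT_SCORING,
                min_fraction: float = 0.5) -> Optional[tuple[int, int]]:
    """Return the host-matching interval on the read, or None.

    A read counts as host contamination when a host alignment reaches
    ``min_ident`` identity over >= ``min_len`` columns or covers >=
    ``min_fraction`` of the read.
    """
    for hid in sorted(host_lib):
        aln = align.align_local(seq, host_lib[hid], scoring)
        if aln.is_empty:
            continue
        cols = aln.aligned_columns
        if cols < 30 or aln.identity() < min_ident:
            continue
        if cols >= min_len or cols >= min_fraction * len(seq):
            return (aln.q_start, aln.q_end)
    return None


def length_filter(length: int, min_length: int = 100) -> bool:
    """Keep only reads strictly longer than ``min_length``."""
    return length > min_length


def _kmer_set(lib: Mapping[str, str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in lib.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmers.add(s[i:i + k])
    return kmers


def _shares_kmer(seq: str, kmers: set[str], k: int) -> bool:
    s = seq.upper()
    return any(s[i:i + k] in kmers for i in range(len(s) - k + 1))


def clean_reads(reads: Iterable, vector_lib: Mapping[str, str],
                host_lib: Optional[Mapping[str, str]] = None,
                window: int = 10, min_mean_q: float = 20.0,
                min_length: int = 100,
                vector_min_len: int = 20, vector_min_ident: float = 0.95,
                scoring: align.Scoring = align.DEFAULT_SCORING) -> list[CleanRead]:
    """Run the full cleaning cascade over (id, sequence, qualities) reads.

    ``reads`` yields objects with ``read_id``/``sequence``/``quality``
    attributes (e.g. :class:`flcdna.simulate.SimRead`) or (id, seq, qual)
    tuples; ``quality`` may be None, which skips quality trimming.
    """
    # exact k-mer prescreen: a real vector/host match of >= min_len exact-ish
    # bases always shares a k-mer, so skipping non-sharing reads only skips DP
    # that could not have produced a hit
    k = min(12, vector_min_len)
    vec_kmers = _kmer_set(vector_lib, k)
    host_kmers = _kmer_set(host_lib, k) if host_lib else set()
    out: list[CleanRead] = []
    for read in reads:
        if hasattr(read, "read_id"):
            rid, seq, qual = read.read_id, read.sequence, read.quality
        else:
            rid, seq, qual = read
        n = len(seq)
        evidence: dict = {}

        if qual is not None:
            a, b = quality_trim(qual, window=window, min_mean_q=min_mean_q)
        else:
            a, b = 0, n
        if b - a == 0:
            out.append(CleanRead(rid, n, REMOVED_QUALITY, (0, 0), "", evidence))
            continue

        sub = seq[a:b]
        if _shares_kmer(sub, vec_kmers, k):
            kept, matched = vector_screen(sub, vector_lib, min_len=vector_min_len,
                                          min_ident=vector_min_ident, scoring=scoring)
        else:
            kept, matched = (0, len(sub)), []
        if matched:
            evidence["vector_intervals"] = [(a + s, a + e) for s, e in matched]
        if kept is None:
            out.append(CleanRead(rid, n, REMOVED_VECTOR, (0, 0), "", evidence))
            continue
        a, b = a + kept[0], a + kept[1]
        sub = seq[a:b]

        if host_lib and _shares_kmer(sub, host_kmers, k):
            hit = host_screen(sub, host_lib, scoring=scoring)
            if hit is not None:
                evidence["host_interval"] = (a + hit[0], a + hit[1])
                out.append(CleanRead(rid, n, REMOVED_HOST, (0, 0), "", evidence))
                continue

        if not length_filter(b - a, min_length):
            out.append(CleanRead(rid, n, REMOVED_SHORT, (a, b), "", evidence))
            continue
        out.append(CleanRead(rid, n, KEPT, (a, b), sub, evidence))
    return out


def cleaning_report(cleaned: Sequence[CleanRead]) -> pd.DataFrame:
    rows = [{
        "read_id": c.read_id,
        "status": c.status,
        "kept_start": c.kept[0],
        "kept_end": c.kept[1],
        "raw_length": c.raw_length,
        "clean_length": c.kept[1] - c.kept[0] if c.status == KEPT else 0,
    } for c in cleaned]
    return pd.DataFrame(rows, columns=["read_id", "status", "kept_start", "kept_end",
                                       "raw_length", "clean_length"])
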