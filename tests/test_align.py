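"""Alignment engine: DP-oracle equivalence, block bookkeeping, best-hit
selection, intron-aware genome mapping, coordinate conventions."""

import numpy as np
import pytest

from flcdna.align import (GenomeIndex, KmerIndex, Scoring, UndefinedIdentityError,
                          _encode, _intron_dp, align_local, alignment_row, best_hit,
                          exon_blocks, identity, map_to_genome)

from conftest import random_seq
from oracles import brute_local_affine, brute_local_affine_intron


def _mutated_pair(rng, n=150, sub=0.1, indel=True):
    q = random_seq(rng, n)
    out = list(q)
    for i in range(len(out)):
        if rng.random() < sub:
            out[i] = "ACGT"[rng.integers(0, 4)]
    if indel and rng.random() < 0.7:
        p = int(rng.integers(1, len(out) - 6))
        L = int(rng.integers(1, 6))
        if rng.random() < 0.5:
            del out[p:p + L]
        else:
            out[p:p] = list(random_seq(rng, L))
    return q, "".join(out)


def test_identical_sequences_single_block():
    q = random_seq(np.random.default_rng(0), 50)
    aln = align_local(q, q)
    assert aln.n_blocks == 1
    assert aln.matches == 50 and aln.mismatches == 0
    assert aln.identity() == 1.0
    assert aln.score == 50


def test_internal_deletion_two_blocks_target_gap():
    rng = np.random.default_rng(1)
    t = random_seq(rng, 100)
    # delete 5 nt from the query at a shift-proof site
    p = 50
    q = t[:p] + t[p + 5:]
    aln = align_local(q, t)
    assert aln.n_blocks == 2
    assert len(aln.gaps) == 1
    gap = aln.gaps[0]
    assert gap.side == "target" and gap.length == 5


def test_empty_sequence_gives_empty_alignment():
    aln = align_local("", "ACGT")
    assert aln.is_empty and aln.score == 0


def test_score_equals_brute_force_dp():
    """Implementation score == independent quadratic DP on 100 pairs
    (mix of unrelated and mutated-copy pairs, including N runs)."""
    rng = np.random.default_rng(42)
    for k in range(100):
        if k % 2 == 0:
            q, t = random_seq(rng, 150), random_seq(rng, 150)
        else:
            q, t = _mutated_pair(rng)
        if k % 10 == 0:
            q = q[:30] + "NNNNN" + q[35:]
        assert align_local(q, t).score == brute_local_affine(q, t)


def test_score_symmetry_under_swap():
    rng = np.random.default_rng(3)
    for _ in range(15):
        q, t = _mutated_pair(rng, n=120)
        assert align_local(q, t).score == align_local(t, q).score


def test_block_consistency_hamming_equals_mismatches():
    rng = np.random.default_rng(4)
    for _ in range(20):
        q, t = _mutated_pair(rng)
        aln = align_local(q, t)
        qcat = "".join(aln.q_block_seqs)
        tcat = "".join(aln.t_block_seqs)
        assert len(qcat) == len(tcat) == aln.matches + aln.mismatches
        ham = sum(1 for a, b in zip(qcat, tcat) if a != b or a == "N")
        assert ham == aln.mismatches
        # blocks are substrings at the recorded coordinates
        for b, qs, ts in zip(aln.blocks, aln.q_block_seqs, aln.t_block_seqs):
            assert q[b.q_start:b.q_end] == qs
            assert t[b.t_start:b.t_end] == ts


def test_identity_restriction_and_undefined():
    rng = np.random.default_rng(5)
    t = random_seq(rng, 100)
    q = list(t)
    for p in (10, 30, 50, 70, 90):
        q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
    aln = align_local("".join(q), t)
    assert aln.identity() == pytest.approx(0.95)
    assert identity(aln, restrict_to=(0, 20)) == pytest.approx(19 / 20)
    assert identity(aln, restrict_to=(51, 70)) == pytest.approx(1.0)
    with pytest.raises(UndefinedIdentityError):
        identity(aln, restrict_to=(200, 300))


class TestBestHit:
    def _targets(self, rng):
        return {f"T{i}": random_seq(rng, 300) for i in range(8)}

    def test_picks_identical_target(self, rng):
        targets = self._targets(rng)
        q = targets["T3"][50:250]
        hit = best_hit(q, targets, min_aligned=100)
        assert hit is not None and hit.target_id == "T3"

    def test_no_hit_below_identity(self, rng):
        targets = self._targets(rng)
        q = random_seq(rng, 200)
        assert best_hit(q, targets, min_aligned=100) is None

    def test_tie_breaks_to_lexicographic_smaller_id(self, rng):
        seq = random_seq(rng, 200)
        targets = {"B": seq, "A": seq, "C": random_seq(rng, 200)}
        hit = best_hit(seq, targets, min_aligned=100)
        assert hit.target_id == "A"

    def test_seeded_matches_exhaustive(self, rng):
        targets = {f"G{i}": random_seq(rng, 400) for i in range(20)}
        for tid in ("G4", "G11"):
            src = targets[tid]
            q = "".join(c if rng.random() > 0.05 else "ACGT"[rng.integers(0, 4)]
                        for c in src[30:330])
            h1 = best_hit(q, targets, min_aligned=100)
            h2 = best_hit(q, targets, min_aligned=100, exhaustive=True)
            assert h1.target_id == h2.target_id == tid
            assert h1.score == h2.score


def test_intron_dp_equals_brute_four_state():
    rng = np.random.default_rng(6)
    sc = Scoring()
    for k in range(15):
        q = random_seq(rng, 60)
        t = (random_seq(rng, 30) + q[5:30] + random_seq(rng, 80)
             + q[30:55] + random_seq(rng, 20)) if k % 2 else random_seq(rng, 150)
        got = _intron_dp(_encode(q), _encode(t), sc, 24)[0]
        assert got == brute_local_affine_intron(q, t, intron_open=-24)


def test_map_to_genome_recovers_planted_exons(noise_free_world):
    """Noise-free gene reads map back with exon blocks at the planted
    genomic coordinates."""
    cfg, bundle, reads, truth = noise_free_world
    gi = GenomeIndex(bundle.genome)
    checked = 0
    for r in reads:
        rt = truth.reads[r.read_id]
        if rt.kind != "GENE" or rt.uses_alt or checked >= 6:
            continue
        loc = bundle.gene_loci[rt.source_id]
        aln = map_to_genome(r.sequence, gi, query_id=r.read_id)
        assert aln is not None and aln.target_id == loc.chrom
        assert aln.identity() == 1.0
        blocks = exon_blocks(aln)
        a, b = rt.ref_interval
        # expected: reference exons clipped to the read's transcript span
        expected = []
        off = 0
        for es, ee in loc.exons:
            size = ee - es
            lo, hi = max(a, off), min(b, off + size)
            if hi > lo:
                expected.append((es + (lo - off), es + (hi - off)))
            off += size
        # splice junctions with shared sequence are placement-ambiguous
        # (boundaries may shift a few bases at equal score), and a terminal
        # exon overlapped by under ~the intron cost may be dropped by the
        # local alignment; interior structure must match exactly
        full = [iv for iv in expected if iv[1] - iv[0] >= 30]
        assert len(full) <= len(blocks) <= len(expected)
        matched = 0
        for es, ee in full:
            assert any(abs(gs - es) <= 5 and abs(ge - ee) <= 5 for gs, ge in blocks), \
                (es, ee, blocks)
            matched += 1
        assert matched == len(full)
        checked += 1
    assert checked >= 4


def test_novel_free_read_has_no_genome_hit(noise_free_world):
    cfg, bundle, reads, truth = noise_free_world
    gi = GenomeIndex(bundle.genome)
    free = [r for r in reads if truth.reads[r.read_id].kind == "NOVEL_FREE"]
    assert free
    assert map_to_genome(free[0].sequence, gi) is None


def test_exporter_matched_length_convention(noise_free_world):
    """Every exported row satisfies matched_length == query_end - query_start."""
    cfg, bundle, reads, truth = noise_free_world
    gi = GenomeIndex(bundle.genome)
    rows = []
    for r in reads[:12]:
        aln = map_to_genome(r.sequence, gi, query_id=r.read_id)
        if aln is not None:
            rows.append(alignment_row(aln, query_length=len(r.sequence)))
    assert rows
    for row in rows:
        assert row["matched_bp"] == row["query_end"] - row["query_start"]


def test_kmer_index_candidates_ranked_by_shared_kmers(rng):
    targets = {"X": random_seq(rng, 200), "Y": random_seq(rng, 200)}
    q = targets["Y"][20:120]
    idx = KmerIndex(targets)
    cands = idx.candidates(q)
    assert cands[0] == "Y"
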