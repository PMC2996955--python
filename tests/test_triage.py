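"""ORF calling and the novel-transcript triage cascade."""

import numpy as np
import pytest

from flcdna.align import GenomeIndex, exon_blocks
from flcdna.triage import (GENOME_ORF, ORF_ONLY, REFSEQ_MATCH, UNCLASSIFIED,
                           GeneAnnotationTrack, TranscriptDB, TriageParams,
                           find_orf, label_genome_context, triage, triage_counts)

from conftest import random_seq
from oracles import best_orf


class TestFindORF:
    def test_hand_worked_example(self):
        orf = find_orf("ATGAAATAA", min_aa=2)
        assert orf is not None
        assert orf.aa_length == 2 and orf.peptide == "MK"
        assert orf.interval == (0, 9) and orf.frame == 0

    def test_no_atg_means_none(self):
        assert find_orf("C" * 300, min_aa=2) is None

    def test_unterminated_orf_is_not_called(self):
        assert find_orf("ATG" + "AAA" * 50, min_aa=2) is None

    def test_equals_exhaustive_enumeration(self):
        """Best ORF equals brute-force enumeration of every ATG..stop span
        on 200 random 900-mers."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            seq = random_seq(rng, 900)
            got = find_orf(seq, min_aa=40)
            want = best_orf(seq, 40)
            if want is None:
                assert got is None
            else:
                aa, start, end = want
                assert got is not None
                assert (got.aa_length, got.interval[0], got.interval[1]) == (aa, start, end)

    def test_orf_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = random_seq(rng, 600)
            orf = find_orf(seq, min_aa=10)
            if orf is None:
                continue
            s, e = orf.interval
            assert (e - s) % 3 == 0
            assert orf.aa_length == (e - s) // 3 - 1
            assert "*" not in orf.peptide
            assert seq[s:s + 3] == "ATG"
            assert seq[e - 3:e] in {"TAA", "TAG", "TGA"}


class TestGenomeContext:
    def test_all_blocks_outside_genes_is_intergenic(self):
        track = GeneAnnotationTrack([("G", "chr1", 1000, 2000, [(1100, 1300)])])
        assert label_genome_context([(5000, 5200)], "chr1", track) == "Intergenic"

    def test_intron_and_exon_blocks(self):
        track = GeneAnnotationTrack([("G", "chr1", 1000, 2000, [(1100, 1300)])])
        label = label_genome_context([(1010, 1090), (1150, 1250)], "chr1", track)
        assert label == "G (Intron,Exon)"

    def test_abutting_block_is_intron_not_exon(self):
        track = GeneAnnotationTrack([("G", "chr1", 1000, 2000, [(1100, 1300)])])
        assert label_genome_context([(1300, 1400)], "chr1", track) == "G (Intron)"


@pytest.fixture(scope="module")
def triage_world(noise_free_world):
    cfg, bundle, reads, truth = noise_free_world
    refseq = TranscriptDB({bundle.models[g].transcript_id: bundle.models[g].sequence
                           for g in bundle.models})
    other = TranscriptDB(bundle.other_db)
    gi = GenomeIndex(bundle.genome)
    track = GeneAnnotationTrack([(loc.gene_id, loc.chrom, loc.start, loc.end, loc.exons)
                                 for loc in bundle.gene_loci.values()])
    return bundle, reads, truth, refseq, other, gi, track


def test_cascade_on_noise_free_world(triage_world):
    """Triage recovers the planted class of every noise-free read and the
    class counts partition the input."""
    bundle, reads, truth, refseq, other, gi, track = triage_world
    params = TriageParams()
    expected = {"GENE": REFSEQ_MATCH, "OTHERDB": "OTHER_DB_MATCH",
                "NOVEL_GENOME": GENOME_ORF, "NOVEL_FREE": ORF_ONLY}
    results = []
    n_novel = n_correct = 0
    for r in reads:
        rt = truth.reads[r.read_id]
        if rt.kind in ("VECTOR", "HOST"):
            continue
        res = triage(r.read_id, r.sequence, refseq, other, gi, track, params)
        results.append(res)
        want = expected[rt.kind]
        if rt.kind != "GENE":
            n_novel += 1
            n_correct += (res.klass == want)
        else:
            assert res.klass == REFSEQ_MATCH
            assert res.genome_alignment is None, "RefSeq hits must skip genome mapping"
    counts = triage_counts(results)
    assert sum(counts.values()) == len(results)
    assert n_novel >= 5
    assert n_correct / n_novel >= 0.98


def test_novel_genomic_block_count_matches_planted_exons(triage_world):
    bundle, reads, truth, refseq, other, gi, track = triage_world
    params = TriageParams()
    checked = 0
    for r in reads:
        rt = truth.reads[r.read_id]
        if rt.kind != "NOVEL_GENOME":
            continue
        res = triage(r.read_id, r.sequence, refseq, None, gi, track, params)
        assert res.klass == GENOME_ORF
        locus = next(l for l in bundle.novel_genomic if l.locus_id == rt.source_id)
        blocks = exon_blocks(res.genome_alignment, params.min_intron)
        # the read spans (s, e) on the transcript; count exons it overlaps
        s, e = rt.rh_interval
        off, n_full, n_touched = 0, 0, 0
        for es, ee in locus.exons:
            size = ee - es
            overlap = min(e, off + size) - max(s, off)
            if overlap > 0:
                n_touched += 1
            if overlap >= 30:
                n_full += 1
            off += size
        # a terminal exon overlapped by only a few bases may not repay the
        # intron cost in a local alignment, so it can be dropped
        assert n_full <= len(blocks) <= n_touched
        checked += 1
    assert checked >= 1


def test_unclassified_when_no_orf_and_no_genome():
    refseq = TranscriptDB({"T1": random_seq(np.random.default_rng(1), 500)})
    # stop-dense sequence: no ORF of 40 aa
    seq = ("ATGTAA" * 60)
    res = triage("x", seq, refseq, None, None, None, TriageParams())
    assert res.klass == UNCLASSIFIED
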