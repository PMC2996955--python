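"""Indel detection, region classification, and the TE-exonization screen."""

import numpy as np
import pytest

from flcdna import align
from flcdna.align import GenomeIndex, align_local, map_to_genome
from flcdna.indels import (IndelEvent, classify_events, classify_indel_region,
                           detect_indels, left_normalized_anchor, screen_te_exons,
                           summarize_indels)
from flcdna.regions import GeneModel
from flcdna.simulate import SimConfig, make_reference_set, simulate_cdna_reads

from conftest import random_seq


def test_gapless_alignment_yields_no_events(rng):
    t = random_seq(rng, 200)
    assert detect_indels(align_local(t, t)) == []


def test_planted_deletion_detected_near_truth_position(rng):
    for _ in range(10):
        t = random_seq(rng, 400)
        p = int(rng.integers(100, 300))
        q = t[:p] + t[p + 4:]
        events = detect_indels(align_local(q, t))
        assert len(events) == 1
        ev = events[0]
        assert ev.side == "del" and ev.length == 4
        assert abs(ev.ref_pos - p) <= 2  # alignment ambiguity window


def test_planted_insertion_detected(rng):
    t = random_seq(rng, 400)
    q = t[:200] + "ACGTA" + t[200:]
    events = detect_indels(align_local(q, t))
    assert len(events) == 1
    assert events[0].side == "ins" and events[0].length == 5


def test_long_target_gap_is_intron_not_indel(rng):
    t = random_seq(rng, 140) + random_seq(rng, 40) + random_seq(rng, 140)
    q = t[:140] + t[180:]
    aln = align_local(q, t)
    target_gaps = [g for g in aln.gaps if g.side == "target"]
    assert any(g.length >= 30 for g in target_gaps)
    assert detect_indels(aln, min_intron=30) == []


def test_indel_intron_dichotomy(rng):
    """Every target-side gap is counted exactly once: as indel xor intron."""
    for _ in range(10):
        t = random_seq(rng, 600)
        q = t[:100] + t[104:300] + t[340:500] + "AC" + t[500:]
        aln = align_local(q, t)
        events = detect_indels(aln, min_intron=30)
        target_gaps = [g for g in aln.gaps if g.side == "target"]
        query_gaps = [g for g in aln.gaps if g.side == "query"]
        n_introns = sum(1 for g in target_gaps if g.length >= 30)
        assert len(events) == len(target_gaps) + len(query_gaps) - n_introns


def test_left_normalization():
    # deleting either AC from "GACACT" is equivalent; the anchor must be
    # the leftmost choice
    assert left_normalized_anchor(3, "AC", "GAC") == 1
    assert left_normalized_anchor(5, "T", "GACAC") == 5


@pytest.fixture(scope="module")
def model():
    seq = random_seq(np.random.default_rng(50), 900)
    return GeneModel("G", "G.1", seq, (200, 700), True)


class TestClassifyIndelRegion:
    def test_deletion_inside_cds(self, model):
        ev = IndelEvent("t", "del", 300, 4)
        assert classify_indel_region(ev, model) == "CDS"

    def test_deletion_spanning_cds_end(self, model):
        ev = IndelEvent("t", "del", 695, 10)
        assert classify_indel_region(ev, model) == "CDS_3UTR"

    def test_insertion_uses_anchor_point(self, model):
        assert classify_indel_region(IndelEvent("t", "ins", 100, 30), model) == "5UTR"
        assert classify_indel_region(IndelEvent("t", "ins", 700, 3), model) == "3UTR"


class TestSummarize:
    def test_published_per_region_counts_sum_to_functional_total(self):
        counts = {"5UTR": 14, "5UTR_CDS": 7, "CDS": 70, "CDS_3UTR": 11, "3UTR": 98}
        events = []
        i = 0
        for region, n in counts.items():
            for _ in range(n):
                events.append(IndelEvent(f"t{i}", "del", 0, 2, region=region))
                i += 1
        for _ in range(14):  # events outside functional regions
            events.append(IndelEvent(f"t{i}", "del", 0, 2, region="NR_XR"))
            i += 1
        s = summarize_indels(events)
        assert s.transcript_counts["CDS"] == 70
        assert s.functional_total == 200
        assert sum(s.transcript_counts.values()) == 214

    def test_empty_input_all_zero(self):
        s = summarize_indels([])
        assert s.functional_total == 0
        assert (s.to_frame()["transcripts"] == 0).all()

    def test_transcript_with_two_regions_counts_once_per_region(self):
        events = [IndelEvent("t1", "del", 10, 2, region="CDS"),
                  IndelEvent("t1", "del", 50, 2, region="CDS"),
                  IndelEvent("t1", "ins", 400, 1, region="3UTR")]
        s = summarize_indels(events)
        assert s.transcript_counts == {"CDS": 1, "3UTR": 1}
        assert s.event_counts == {"CDS": 2, "3UTR": 1}


def _indel_recovery(n_genes=120, seed=101, indel_rate=1.2):
    """Align each diverged transcript to its reference and score planted
    indel recovery; returns (sensitivity, region accuracy)."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, indel_rate=indel_rate,
                    sub_rate_by_region={"5UTR": 0.01, "CDS": 0.01, "3UTR": 0.01},
                    category_weights={"5UTR_CDS_3UTR": 1.0}, reads_per_gene=(1, 1),
                    p_noncoding=0.0, p_unknown=0.0, p_vector_read=0.0,
                    p_host_read=0.0, p_vector_contam=0.0)
    bundle = make_reference_set(cfg)
    _, truth = simulate_cdna_reads(bundle, cfg)
    n_planted = n_found = n_region = n_region_ok = 0
    for gid, gt in truth.genes.items():
        model = bundle.models[gid]
        aln = align_local(gt.rhesus_seq, model.sequence, query_id=gid)
        events = classify_events(detect_indels(aln), model)
        for iv in gt.indels:
            n_planted += 1
            matches = [e for e in events
                       if abs(e.ref_pos - iv.ref_pos) <= 2 and e.length == iv.length
                       and e.side == ("del" if iv.kind == "del" else "ins")]
            if not matches:
                continue
            n_found += 1
            cs, ce = model.cds
            dist = min(abs(iv.ref_pos - cs), abs(iv.ref_pos - ce),
                       iv.ref_pos, len(model.sequence) - iv.ref_pos)
            if dist >= 5:
                n_region += 1
                true_region = ("5UTR" if iv.ref_pos < cs
                               else "CDS" if iv.ref_pos < ce else "3UTR")
                if matches[0].region is not None and true_region in matches[0].region:
                    n_region_ok += 1
    return n_planted, n_found, n_region, n_region_ok


def test_planted_indel_recovery():
    """>= 200 planted indels: sensitivity >= 0.95; region classification
    accuracy >= 0.99 for events >= 5 nt from region boundaries."""
    n_planted, n_found, n_region, n_region_ok = _indel_recovery()
    assert n_planted >= 200
    assert n_found / n_planted >= 0.95
    assert n_region_ok / n_region >= 0.99


# ---------------------------------------------------------------------------
# TE exonization screen

@pytest.fixture(scope="module")
def te_world():
    cfg = SimConfig(seed=61, n_genes=25, n_reads=90, p_te_exon=0.5,
                    p_te_read_inclusion=1.0, p_unknown=0.0, p_vector_read=0.0,
                    p_host_read=0.0, p_vector_contam=0.0,
                    sub_rate_by_region={"5UTR": 0.0, "CDS": 0.0, "3UTR": 0.0},
                    indel_rate=0.0, quality_decay=(40.0, 35.0))
    bundle = make_reference_set(cfg)
    reads, truth = simulate_cdna_reads(bundle, cfg)
    return bundle, reads, truth


def test_te_screen_sensitivity_and_precision(te_world):
    """Planted TE cassette exons with full repeat coverage are called with
    sensitivity and precision >= 0.95; the family and lineage flag match."""
    bundle, reads, truth = te_world
    gi = GenomeIndex(bundle.genome)
    transcripts = {bundle.models[g].transcript_id: bundle.models[g].sequence
                   for g in bundle.models}
    tid2gene = {bundle.models[g].transcript_id: g for g in bundle.models}
    index = align.KmerIndex(transcripts)
    tp = fn = fp = 0
    n_pos = n_neg = 0
    for r in reads:
        rt = truth.reads[r.read_id]
        if rt.kind != "GENE":
            continue
        hit = align.best_hit(r.sequence, transcripts, index=index)
        galn = map_to_genome(r.sequence, gi, query_id=r.read_id)
        if galn is None:
            continue
        calls = screen_te_exons(galn, bundle.repeats, hit)
        has_te = rt.te_read_interval is not None
        if has_te:
            n_pos += 1
            good = [c for c in calls if c.family == rt.te_family and c.species_specific]
            if good:
                tp += 1
            else:
                fn += 1
        else:
            n_neg += 1
            fp += len(calls)
    assert n_pos >= 10 and n_neg >= 10
    assert tp / n_pos >= 0.95
    assert tp / (tp + fp) >= 0.95


def test_te_screen_threshold_and_negatives(rng):
    from flcdna.simulate import RepeatCopy
    from flcdna.align import AlignmentBlock, PairwiseAlignment
    t = random_seq(rng, 300)
    aln = PairwiseAlignment("x", "chr1", 100.0, [AlignmentBlock(0, 100, 1000, 1100)],
                            [t[:100]], [t[:100]], 100, 0, [])
    # repeat covering 40% of the block with min_overlap 0.5: no call
    reps = [RepeatCopy("AluYRa2", "SINE", "chr1", 1000, 1040, "+", True)]
    assert screen_te_exons(aln, reps, None, min_overlap=0.5) == []
    # no repeat overlap at all: empty
    reps2 = [RepeatCopy("AluYRa2", "SINE", "chr1", 5000, 5300, "+", True)]
    assert screen_te_exons(aln, reps2, None) == []
    # full coverage: called, species-specific
    reps3 = [RepeatCopy("AluYRa2", "SINE", "chr1", 990, 1110, "+", True)]
    calls = screen_te_exons(aln, reps3, None)
    assert len(calls) == 1 and calls[0].species_specific
    assert calls[0].overlap_fraction == 1.0
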