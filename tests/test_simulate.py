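"""Generator contracts: determinism, ledger closure, rate recovery."""

import dataclasses

import numpy as np
import pytest

from flcdna import io as fio
from flcdna.simulate import (SimConfig, make_reference_set, published_profile,
                             simulate_cdna_reads)

from conftest import NOISE_FREE


def _world(**kw):
    cfg = SimConfig(**kw)
    bundle = make_reference_set(cfg)
    reads, truth = simulate_cdna_reads(bundle, cfg)
    return cfg, bundle, reads, truth


def test_seed_determinism_byte_identical(tmp_path):
    """Two runs of one config write byte-identical FASTA/FASTQ outputs."""
    for d in ("a", "b"):
        cfg = SimConfig(seed=1, n_genes=10, n_reads=25)
        bundle = make_reference_set(cfg)
        reads, truth = simulate_cdna_reads(bundle, cfg)
        fio.write_simulation(tmp_path / d, bundle, reads, truth)
    for name in ("reads.fasta", "reads.fastq", "genome.fasta",
                 "reference_mrna.fasta", "repeats.bed", "truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_genome_length_equals_segment_ledger():
    cfg = SimConfig(seed=3, n_genes=50, n_reads=1)
    bundle = make_reference_set(cfg)
    assert len(bundle.genome["chr1"]) == sum(l for _, _, l in bundle.segments)


def test_te_disabled_means_no_intragenic_lineage_repeats():
    cfg = SimConfig(seed=5, n_genes=30, n_reads=1, p_te_exon=0.0)
    bundle = make_reference_set(cfg)
    for rep in bundle.repeats:
        if not rep.lineage_specific:
            continue
        for loc in bundle.gene_loci.values():
            assert not (rep.start < loc.end and rep.end > loc.start), \
                f"lineage repeat {rep.family} inside gene {loc.gene_id}"


def test_te_enabled_plants_annotated_intronic_copies():
    cfg = SimConfig(seed=5, n_genes=30, n_reads=1, p_te_exon=0.3)
    bundle = make_reference_set(cfg)
    assert bundle.te_genes, "expected at least one TE gene at p_te_exon=0.3"
    for gid, info in bundle.te_genes.items():
        s, e = info["genome_interval"]
        loc = bundle.gene_loci[gid]
        assert loc.start <= s < e <= loc.end
        assert not any(s < ee and e > es for es, ee in loc.exons), \
            "TE copy must sit in an intron"
        assert any(r.start == s and r.end == e for r in bundle.repeats)


def test_noise_free_reads_are_exact_substrings(noise_free_world):
    cfg, bundle, reads, truth = noise_free_world
    n_gene = 0
    for r in reads:
        rt = truth.reads[r.read_id]
        if rt.kind != "GENE" or rt.uses_alt:
            continue
        assert r.sequence in bundle.models[rt.source_id].sequence
        n_gene += 1
    assert n_gene > 20


def test_p_unknown_one_names_no_reference_gene():
    _, _, _, truth = _world(seed=2, n_genes=10, n_reads=30, p_unknown=1.0,
                            p_vector_read=0.0, p_host_read=0.0)
    assert all(rt.kind != "GENE" for rt in truth.reads.values())


def test_gene_level_ledger_closure():
    """Replaying the recorded substitutions and indels on the reference
    transcript reconstructs the rhesus transcript exactly."""
    _, bundle, _, truth = _world(seed=9, n_genes=20, n_reads=60, indel_rate=1.0)
    assert truth.genes, "no gene truth generated"
    for gid, gt in truth.genes.items():
        ref = list(bundle.models[gid].sequence)
        for pos, new in gt.substitutions:
            ref[pos] = new
        seq = "".join(ref)
        for iv in sorted(gt.indels, key=lambda i: -i.ref_pos):
            if iv.kind == "del":
                assert seq[iv.ref_pos:iv.ref_pos + iv.length] == iv.seq
                seq = seq[:iv.ref_pos] + seq[iv.ref_pos + iv.length:]
            else:
                seq = seq[:iv.ref_pos] + iv.seq + seq[iv.ref_pos:]
        assert seq == gt.rhesus_seq


def test_read_level_ledger_closure_substitutions_only():
    """With indels off, diffing a read against the reference substring
    finds exactly the recorded substitution positions."""
    _, bundle, reads, truth = _world(seed=13, n_genes=15, n_reads=40,
                                     indel_rate=0.0, p_vector_contam=0.0,
                                     p_vector_read=0.0, p_host_read=0.0,
                                     p_unknown=0.0)
    checked = 0
    for r in reads:
        rt = truth.reads[r.read_id]
        if rt.kind != "GENE" or rt.uses_alt:
            continue
        ref = bundle.models[rt.source_id].sequence
        a, b = rt.ref_interval
        refsub = ref[a:b]
        assert len(refsub) == len(r.sequence)
        diffs = {a + i for i, (x, y) in enumerate(zip(r.sequence, refsub)) if x != y}
        assert diffs == set(rt.substitutions)
        checked += 1
    assert checked > 10


@pytest.mark.parametrize("rate", [0.05])
def test_substitution_rate_recovery_3utr(rate):
    """Empirical 3'UTR substitution rate within 3 binomial SE of the
    configured rate over >= 10 kb of simulated 3'UTR sequence."""
    cfg = SimConfig(seed=17, n_genes=40,
                    sub_rate_by_region={"5UTR": 0.0, "CDS": 0.0, "3UTR": rate},
                    utr3_len=(400, 900), indel_rate=0.0,
                    # category mode plants divergence for every gene
                    category_weights={"3UTR": 1.0}, reads_per_gene=(1, 1))
    bundle = make_reference_set(cfg)
    _, truth = simulate_cdna_reads(bundle, cfg)
    total = hits = 0
    for gid, gt in truth.genes.items():
        model = bundle.models[gid]
        if not model.coding:
            continue
        ce = model.cds[1]
        n3 = len(model.sequence) - ce
        total += n3
        hits += sum(1 for p, _ in gt.substitutions if p >= ce)
    assert total >= 10_000
    se = np.sqrt(rate * (1 - rate) / total)
    assert abs(hits / total - rate) <= 3 * se


def test_config_validation_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        SimConfig(cds_codons=(0, 10)).validate()
    with pytest.raises(ValueError):
        SimConfig(p_unknown=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(sub_rate_by_region={"CDS": 0.1}).validate()
    with pytest.raises(ValueError):
        SimConfig(indel_len_geom_p=0.0).validate()


def test_quality_decays_along_read(diverged_world):
    _, _, reads, _ = diverged_world
    long_reads = [r for r in reads if len(r.quality) > 400]
    assert long_reads
    head = np.mean([r.quality[:50].mean() for r in long_reads])
    tail = np.mean([r.quality[-50:].mean() for r in long_reads])
    assert head > tail + 10


def test_published_profile_category_rates_and_weights():
    cfg = published_profile(seed=4, n_genes=30)
    cfg.validate()
    assert cfg.sub_rate_by_category["CDS"] == pytest.approx(0.032)
    assert cfg.sub_rate_by_category["3UTR"] == pytest.approx(0.067)
    bundle = make_reference_set(cfg)
    reads, truth = simulate_cdna_reads(bundle, cfg)
    # all reads of one gene share the gene's targeted category world
    cats = {gt.category for gt in truth.genes.values() if gt.category}
    assert cats <= set(cfg.category_weights)
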