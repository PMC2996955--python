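"""File I/O: FASTA/FASTQ, GFF3 gene models, BED repeats, truth tables.

Readers go through Biopython/gffutils; writers emit plain text with
deterministic ordering so identical runs produce byte-identical files.
GFF3 is 1-based inclusive; BED is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .regions import GeneModel
from .simulate import ReferenceBundle, RepeatCopy, SimRead


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path) -> list[SimRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = np.asarray(rec.letter_annotations["phred_quality"], dtype=int)
        out.append(SimRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path, reads: Iterable[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qstr = "".join(chr(int(q) + 33) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qstr}\n")


def write_gene_models_gff3(path, models: Mapping[str, GeneModel]) -> None:
    """Gene models as GFF3 on transcript coordinates (seqid = transcript)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(models):
            m = models[gid]
            n = len(m.sequence)
            tid = m.transcript_id
            biotype = "protein_coding" if m.coding else "non_coding"
            fh.write(f"{tid}\tflcdna\tmRNA\t1\t{n}\t.\t+\t.\t"
                     f"ID={tid};gene_id={gid};biotype={biotype}\n")
            if m.coding:
                cs, ce = m.cds
                if cs > 0:
                    fh.write(f"{tid}\tflcdna\tfive_prime_UTR\t1\t{cs}\t.\t+\t.\tParent={tid}\n")
                fh.write(f"{tid}\tflcdna\tCDS\t{cs + 1}\t{ce}\t.\t+\t0\tParent={tid}\n")
                if ce < n:
                    fh.write(f"{tid}\tflcdna\tthree_prime_UTR\t{ce + 1}\t{n}\t.\t+\t.\tParent={tid}\n")


def read_gene_models(fasta_path, gff3_path) -> dict[str, GeneModel]:
    """Load gene models from a transcript FASTA + GFF3 (CDS on transcript
    coordinates, 1-based inclusive)."""
    import gffutils
    seqs = read_fasta(fasta_path)
    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: dict[str, GeneModel] = {}
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        gid = mrna.attributes.get("gene_id", [tid])[0]
        coding = mrna.attributes.get("biotype", ["protein_coding"])[0] == "protein_coding"
        cds = None
        if coding:
            cds_feats = [f for f in db.children(mrna, featuretype="CDS")]
            if cds_feats:
                cds = (min(f.start for f in cds_feats) - 1, max(f.end for f in cds_feats))
            else:
                coding = False
        models[gid] = GeneModel(gid, tid, seqs[tid], cds, coding)
    return models


def write_repeats_bed(path, repeats: Sequence[RepeatCopy]) -> None:
    """Repeat annotation as BED6(+2): chrom, start, end, family, score,
    strand, class, lineage_specific."""
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}\t"
                     f"{r.te_class}\t{int(r.lineage_specific)}\n")


def read_repeats_bed(path) -> list[RepeatCopy]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            te_class = f[6] if len(f) > 6 else "Unknown"
            lineage = bool(int(f[7])) if len(f) > 7 else False
            out.append(RepeatCopy(f[3], te_class, f[0], int(f[1]), int(f[2]),
                                  f[5] if len(f) > 5 else "+", lineage))
    return out


def load_published_genome_hits():
    """Published mapping summary of 60 novel placental cDNAs against the
    human genome (accession, lengths, query span, chromosome, block count,
    genomic context), used to validate the exporter's coordinate
    convention (matched length = query_end - query_start)."""
    import importlib.resources as resources
    import pandas as pd
    with resources.files("flcdna").joinpath("data/published_genome_hits.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_simulation(out_dir, bundle: ReferenceBundle, reads: Sequence[SimRead],
                     truth) -> None:
    """Write the full simulated world to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "reads.fasta", [(r.read_id, r.sequence) for r in reads])
    write_fastq(out / "reads.fastq", reads)
    write_fasta(out / "reference_mrna.fasta",
                [(bundle.models[g].transcript_id, bundle.models[g].sequence)
                 for g in sorted(bundle.models)])
    write_gene_models_gff3(out / "gene_models.gff3", bundle.models)
    write_fasta(out / "genome.fasta", sorted(bundle.genome.items()))
    write_repeats_bed(out / "repeats.bed", bundle.repeats)
    write_fasta(out / "vector.fasta", [("vector", bundle.vector)])
    write_fasta(out / "host.fasta", [("host", bundle.host)])
    write_fasta(out / "other_db.fasta", sorted(bundle.other_db.items()))
    truth.write_tsv(out / "truth.tsv")
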