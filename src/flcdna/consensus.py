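"""Per-gene consensus building and per-region identity statistics.

Clusters with at least two member cDNAs are collapsed into a consensus by
reference-anchored column-wise majority vote: each member's alignment to
the reference transcript places its bases on reference columns, and each
covered column takes the majority base (ties resolve toward the base that
agrees with the reference, then alphabetically).  Identity of the
consensus against the reference, restricted to the consensus's category
span, recovers the species divergence of that gene region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import PairwiseAlignment
from .regions import GeneModel, classify_region

#: reporting order of the five category rows
REPORT_ORDER = ("5UTR_CDS", "5UTR_CDS_3UTR", "CDS", "CDS_3UTR", "3UTR")


@dataclass
class ConsensusRecord:
    """Majority-vote consensus of one gene cluster, anchored on the
    reference transcript.  ``columns[i]`` is the reference coordinate of
    consensus base i; uncovered reference columns are absent."""

    gene_id: str
    member_ids: list[str]
    consensus: str
    columns: np.ndarray          # reference positions, sorted
    support: np.ndarray          # members covering each column

    @property
    def member_count(self) -> int:
        return len(self.member_ids)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.columns[0]), int(self.columns[-1]) + 1


def build_consensus(gene_id: str,
                    members: Sequence[tuple[str, str, PairwiseAlignment]]
                    ) -> ConsensusRecord:
    """Column-wise majority consensus of >= 2 reads of one gene.

    ``members`` are (read_id, read_sequence, alignment-to-reference)
    triples; the alignment's target must be the gene's reference
    transcript.  Insertions relative to the reference are ignored (the
    consensus lives on reference columns); reference columns covered by no
    member are absent from the consensus.
    """
    if len(members) < 2:
        raise ValueError(f"{gene_id}: consensus needs >= 2 members, got {len(members)}")
    votes: dict[int, dict[str, int]] = {}
    refbase: dict[int, str] = {}
    for _rid, _seq, aln in members:
        for block, qb, tb in zip(aln.blocks, aln.q_block_seqs, aln.t_block_seqs):
            for k in range(len(block)):
                col = block.t_start + k
                votes.setdefault(col, {})
                votes[col][qb[k]] = votes[col].get(qb[k], 0) + 1
                refbase[col] = tb[k]
    cols = np.array(sorted(votes), dtype=np.int64)
    bases = []
    support = []
    for col in cols:
        v = votes[int(col)]
        top = max(v.values())
        tied = sorted(b for b, c in v.items() if c == top)
        if len(tied) > 1 and refbase[int(col)] in tied:
            base = refbase[int(col)]
        else:
            base = tied[0]
        bases.append(base)
        support.append(sum(v.values()))
    return ConsensusRecord(gene_id, [m[0] for m in members], "".join(bases),
                           cols, np.asarray(support))


def consensus_identity(record: ConsensusRecord, model: GeneModel,
                       restrict_to: Optional[tuple[int, int]] = None) -> float:
    """Fraction of consensus columns agreeing with the reference base,
    optionally restricted to a reference interval."""
    ref = model.sequence
    mask = np.ones(len(record.columns), dtype=bool)
    if restrict_to is not None:
        lo, hi = restrict_to
        mask = (record.columns >= lo) & (record.columns < hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no consensus columns in the requested interval")
    agree = sum(1 for i in idx if record.consensus[i] == ref[record.columns[i]])
    return agree / idx.size


def per_region_identity(record: ConsensusRecord, model: GeneModel
                        ) -> tuple[str, float]:
    """(category, identity %) of a consensus against its reference model.

    The category is that of the consensus's covered span; identity is
    computed over the covered columns inside that span (which is the whole
    consensus) and reported as a percentage.
    """
    category = classify_region(record.span, model)
    pct = 100.0 * consensus_identity(record, model)
    return category, pct


@dataclass
class IdentityReport:
    """Per-category identity distribution (n, mean %, raw values)."""

    entries: pd.DataFrame  # columns: gene_id, category, identity_pct, n_members

    def to_frame(self) -> pd.DataFrame:
        rows = []
        present = list(self.entries["category"].unique())
        ordered = [c for c in REPORT_ORDER if c in present]
        ordered += [c for c in present if c not in REPORT_ORDER]
        for cat in ordered:
            vals = self.entries.loc[self.entries["category"] == cat, "identity_pct"]
            rows.append({"category": cat, "n": len(vals),
                         "mean_pct": round(float(vals.mean()), 2)})
        return pd.DataFrame(rows, columns=["category", "n", "mean_pct"])

    def mean(self, category: str) -> float:
        vals = self.entries.loc[self.entries["category"] == category, "identity_pct"]
        if len(vals) == 0:
            raise KeyError(f"no consensus in category {category}")
        return float(vals.mean())

    def identities(self, category: str) -> np.ndarray:
        return self.entries.loc[self.entries["category"] == category,
                                "identity_pct"].to_numpy()


def identity_report(records: Sequence[tuple[ConsensusRecord, GeneModel]]) -> IdentityReport:
    """Identity report over consensus records (empty categories omitted).

    Records whose identity is undefined (no aligned columns) are skipped
    with a warning rather than polluting the means.
    """
    import warnings
    rows = []
    for record, model in records:
        try:
            cat, pct = per_region_identity(record, model)
        except ValueError as exc:
            warnings.warn(f"{record.gene_id}: identity undefined ({exc}); skipped")
            continue
        rows.append({"gene_id": record.gene_id, "category": cat,
                     "identity_pct": pct, "n_members": record.member_count})
    frame = pd.DataFrame(rows, columns=["gene_id", "category", "identity_pct", "n_members"])
    return IdentityReport(frame)
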