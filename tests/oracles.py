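"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions, without
reference to the package's implementations: quadratic/cubic dynamic
programs, exhaustive enumerations, and per-base labeling.
"""

from __future__ import annotations

NEG = float("-inf")


def brute_local_affine(q: str, t: str, match: int = 1, mismatch: int = -2,
                       gap_open: int = -5, gap_extend: int = -1) -> float:
    """Textbook three-state Smith-Waterman-Gotoh, score only.

    A gap of length L costs gap_open + (L-1)*gap_extend.  'N' never
    matches anything.
    """
    n, m = len(q), len(t)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        qc = q[i - 1]
        for j in range(1, m + 1):
            tc = t[j - 1]
            s = match if (qc == tc and qc != "N") else mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def brute_local_affine_intron(q: str, t: str, match: int = 1, mismatch: int = -2,
                              gap_open: int = -5, gap_extend: int = -1,
                              intron_open: int = -24) -> float:
    """Four-state variant: target-side gaps may alternatively pay a flat
    opening cost with free extension (the intron state)."""
    n, m = len(q), len(t)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    J = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        qc = q[i - 1]
        for j in range(1, m + 1):
            tc = t[j - 1]
            s = match if (qc == tc and qc != "N") else mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1], J[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            J[i][j] = max(M[i][j - 1] + intron_open, J[i][j - 1])
            if M[i][j] > best:
                best = M[i][j]
    return best


def exhaustive_quality_interval(quals, window: int, min_mean_q: float) -> tuple[int, int]:
    """Longest interval where every full sliding window passes; intervals
    shorter than the window are one whole-interval window.  Leftmost ties.
    Checked by brute-force enumeration of all O(n^2) intervals."""
    n = len(quals)

    def ok(a, b):
        if b - a < window:
            return sum(quals[a:b]) / (b - a) >= min_mean_q
        for s in range(a, b - window + 1):
            if sum(quals[s:s + window]) / window < min_mean_q:
                return False
        return True

    best = (0, 0)
    for length in range(n, 0, -1):
        for a in range(0, n - length + 1):
            if ok(a, a + length):
                return (a, a + length)
    return best


def enumerate_orfs(seq: str, min_aa: int):
    """All forward-frame ATG..stop ORFs with >= min_aa amino acids, as
    (aa_length, start, end) tuples; brute enumeration over every ATG."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j:j + 3] in stops:
                aa = (j + 3 - i) // 3 - 1
                if aa >= min_aa:
                    out.append((aa, i, j + 3))
                break
            j += 3
    return out


def best_orf(seq: str, min_aa: int):
    """(aa_length, start, end) of the longest ORF, leftmost on ties."""
    orfs = enumerate_orfs(seq, min_aa)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o[0], -o[1]))


def per_base_region_labels(span: tuple[int, int], cds: tuple[int, int],
                           length: int) -> set[str]:
    """Label every base of the span 5UTR/CDS/3UTR and return the set."""
    labels = set()
    for p in range(*span):
        if p < cds[0]:
            labels.add("5UTR")
        elif p < cds[1]:
            labels.add("CDS")
        else:
            labels.add("3UTR")
    return labels


def label_set_to_category(labels: set[str]) -> str:
    order = ["5UTR", "CDS", "3UTR"]
    present = [r for r in order if r in labels]
    return "_".join(present)
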