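"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is deliberately naive (exhaustive enumeration, O(n^2) scans,
exact rational arithmetic) and shares no code path with the package.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_iupac_hits(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Position-by-position IUPAC match on both strands.

    A minus-strand hit at i means the reverse complement of seq[i:i+m]
    matches the pattern left to right. Sequence N matches nothing.
    """
    seq = seq.upper()
    m = len(pattern)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i:i + m]
        if all(window[k] in IUPAC_SETS[pattern[k]] for k in range(m)):
            hits.append((i, "+"))
        rc = "".join(DNA_COMPLEMENT[c] for c in reversed(window))
        if all(rc[k] in IUPAC_SETS[pattern[k]] for k in range(m)):
            hits.append((i, "-"))
    return sorted(hits)


def brute_greedy_pairs(a, b, max_dist: int, strict: bool) -> set[tuple[int, int]]:
    """All-pairs enumeration + greedy nearest-first matching of peak summits.

    Returns the matched (summit_a, summit_b) set; peaks are dicts or
    objects with .chrom and .summit.
    """
    cands = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            if pa.chrom != pb.chrom:
                continue
            d = abs(pa.summit - pb.summit)
            ok = d < max_dist if strict else d <= max_dist
            if ok:
                cands.append((d, min(pa.summit, pb.summit), max(pa.summit, pb.summit), i, j))
    cands.sort()
    used_a, used_b, out = set(), set(), set()
    for d, _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.add((a[i].summit, b[j].summit))
    return out


def brute_overlap_count(query, ref, max_center_dist: int) -> int:
    """O(n^2) count of query peaks with any ref center within the distance."""
    n = 0
    for q in query:
        qc = (q.start + q.end) // 2
        for r in ref:
            if r.chrom == q.chrom and abs(qc - (r.start + r.end) // 2) <= max_center_dist:
                n += 1
                break
    return n


def exact_hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(M, K, n) by exact enumeration."""
    total = comb(M, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j <= M - K:
            acc += Fraction(comb(K, j) * comb(M - K, n - j), total)
    return acc


def literal_bh(pvalues) -> list[float]:
    """p_i * N / rank_i with ranks by ascending p, stable ties."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    return [pvalues[i] * n / rank[i] for i in range(n)]


def brute_nearest_tss(genes, chrom: str, summit: int):
    """Exhaustive nearest-TSS gene with (distance, tss, gene_id) ordering."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        key = (abs(summit - g.tss), g.tss, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g)
    return None if best is None else best[1]
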