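"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (nested loops, exhaustive
enumeration) and shares no code path with the package internals.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def iv_overlaps(a, b) -> bool:
    """a, b = (chrom, start, end)."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def brute_merge(intervals):
    """Merge overlapping/book-ended (chrom, start, end) triples."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur = None
        for s, e in ivs:
            if cur is None:
                cur = [s, e]
            elif s <= cur[1]:
                cur[1] = max(cur[1], e)
            else:
                out.append((chrom, cur[0], cur[1]))
                cur = [s, e]
        if cur is not None:
            out.append((chrom, cur[0], cur[1]))
    return out


def brute_count_overlapping(query, subject):
    """Number of query triples overlapped by >= 1 subject triple."""
    return sum(1 for q in query if any(iv_overlaps(q, s) for s in subject))


def brute_nearest_tss(anchor_chrom, anchor, genes):
    """genes: list of (gene_id, chrom, tss).  Returns (gene_id, dist) or None."""
    candidates = [(abs(t - anchor), g) for g, c, t in genes if c == anchor_chrom]
    if not candidates:
        return None
    best = min(d for d, _ in candidates)
    return (min(g for d, g in candidates if d == best), best)


def brute_bound_genes(anchors, genes, window):
    """anchors: list of (chrom, pos); genes: (gene_id, chrom, tss).
    Inclusive window at both boundaries."""
    bound = set()
    for g, gc, t in genes:
        for pc, p in anchors:
            if pc == gc and t - window <= p <= t + window:
                bound.add(g)
                break
    return bound


def brute_venn3(A, B, C):
    """Triples per input set -> dict membership-class -> cluster count.

    Clusters are merged (book-ended) intervals of the pooled union; a set
    belongs to a cluster's class when one of its intervals lies inside.
    """
    pooled = list(A) + list(B) + list(C)
    clusters = brute_merge(pooled)

    def inside(iv, cluster):
        return iv[0] == cluster[0] and cluster[1] <= iv[1] and iv[2] <= cluster[2]

    counts = {k: 0 for k in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
    for cl in clusters:
        members = ""
        for name, regions in (("A", A), ("B", B), ("C", C)):
            if any(inside(iv, cl) for iv in regions):
                members += name
        counts[members] += 1
    return counts


def brute_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws (N <= 12)."""
    category = set(range(K))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(category & set(draw)) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total


def brute_iupac_match(seq, motif, table):
    """Offsets where an IUPAC motif matches (forward strand only)."""
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(seq[i + j] in table[m] for j, m in enumerate(motif)):
            hits.append(i)
    return hits
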