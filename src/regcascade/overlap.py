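"""Region co-occupancy and resampling significance tests.

Overlap means sharing at least one base pair; book-ended half-open
intervals do not overlap.  Co-occupancy is reported asymmetrically as
the fraction of the *query* set overlapped by the subject set.  Two
constructed nulls are provided: uniform per-chromosome relocation of a
region set (for region-overlap significance) and uniform fixed-size
gene-set resampling (for gene-set intersection significance).  Both
report the pseudocount empirical p-value ``(1 + exceedances) / (1 +
n_iter)``, which is never exactly zero; the smallest reportable p is
``1 / (n_iter + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import (
    ChromSizes,
    GeneSet,
    GenomicInterval,
    RegionSet,
    ValidationError,
    merge_regions,
)


@dataclass(frozen=True)
class OverlapResult:
    n_query: int
    n_overlapping: int
    fraction: float
    p_empirical: float | None = None


@dataclass(frozen=True)
class Venn3Partition:
    """Counts of merged union clusters by membership class."""

    labels: tuple[str, str, str]
    a_only: int
    b_only: int
    c_only: int
    ab: int
    ac: int
    bc: int
    abc: int

    @property
    def n_clusters(self) -> int:
        return self.a_only + self.b_only + self.c_only + self.ab + self.ac + self.bc + self.abc

    def to_dict(self) -> dict[str, int]:
        a, b, c = self.labels
        return {
            a: self.a_only, b: self.b_only, c: self.c_only,
            f"{a}+{b}": self.ab, f"{a}+{c}": self.ac, f"{b}+{c}": self.bc,
            f"{a}+{b}+{c}": self.abc,
        }


@dataclass(frozen=True)
class NullDistribution:
    n_iter: int
    seed: int
    statistics: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.statistics) != self.n_iter:
            raise ValidationError("null distribution length != n_iter")

    def to_tsv(self, path) -> None:
        """Dump the null statistics as a single-column TSV for audit."""
        with open(path, "w") as fh:
            fh.write(f"# n_iter={self.n_iter}\tseed={self.seed}\n")
            fh.writelines(f"{int(s)}\n" for s in self.statistics)


@dataclass(frozen=True)
class ResamplingResult:
    observed: int
    p_empirical: float
    null: NullDistribution


def _count_overlaps(query: RegionSet, subject: RegionSet) -> np.ndarray:
    """Number of subject intervals overlapping each query interval,
    in ``query.intervals`` order."""
    counts = np.zeros(len(query), dtype=np.int64)
    subj = subject.by_chrom()
    for chrom, q in query.by_chrom().items():
        s = subj.get(chrom)
        if s is None:
            continue
        s_starts = np.sort(s["starts"])
        s_ends = np.sort(s["ends"])
        n_start_before_qend = np.searchsorted(s_starts, q["ends"], side="left")
        n_end_before_qstart = np.searchsorted(s_ends, q["starts"], side="right")
        counts[q["idx"]] = n_start_before_qend - n_end_before_qstart
    return counts


def cooccupancy(query: RegionSet, subject: RegionSet) -> OverlapResult:
    """Fraction of query regions sharing >= 1 bp with >= 1 subject region."""
    if len(query) == 0:
        raise ValidationError("co-occupancy fraction undefined for empty query set")
    n_overlapping = int((_count_overlaps(query, subject) > 0).sum())
    return OverlapResult(len(query), n_overlapping, n_overlapping / len(query))


def union_clusters(sets: Sequence[RegionSet]) -> tuple[RegionSet, list[int]]:
    """Merge the union of several region sets into maximal clusters and
    report, per cluster, a bitmask of which input sets contributed >= 1
    interval (bit i = set i)."""
    pooled = RegionSet("union", [iv for rs in sets for iv in rs.intervals])
    clusters = merge_regions(pooled)
    masks = [0] * len(clusters)
    cl = clusters.by_chrom()
    for bit, rs in enumerate(sets):
        for chrom, arrs in rs.by_chrom().items():
            entry = cl.get(chrom)
            if entry is None:
                continue
            # each input interval lies fully inside exactly one cluster
            pos = np.searchsorted(entry["starts"], arrs["starts"], side="right") - 1
            for p in entry["idx"][pos]:
                masks[int(p)] |= 1 << bit
    return clusters, masks


def venn3(A: RegionSet, B: RegionSet, C: RegionSet) -> Venn3Partition:
    """Three-way overlap partition over merged union clusters."""
    if len(A) == 0 and len(B) == 0 and len(C) == 0:
        return Venn3Partition((A.label, B.label, C.label), 0, 0, 0, 0, 0, 0, 0)
    _, masks = union_clusters([A, B, C])
    counts = {m: 0 for m in range(1, 8)}
    for m in masks:
        counts[m] += 1
    return Venn3Partition(
        (A.label, B.label, C.label),
        a_only=counts[1], b_only=counts[2], c_only=counts[4],
        ab=counts[3], ac=counts[5], bc=counts[6], abc=counts[7],
    )


def _empirical_p(null: np.ndarray, observed: float) -> float:
    return float((1 + int((null >= observed).sum())) / (1 + len(null)))


def bootstrap_overlap_test(
    A: RegionSet,
    B: RegionSet,
    sizes: ChromSizes,
    n_iter: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Relocation null for the number of A regions overlapped by B.

    Each B interval is independently relocated uniformly within its own
    chromosome, preserving its length and the per-chromosome interval
    counts; relocated intervals may overlap each other.  The statistic is
    the number of A regions overlapped by >= 1 (relocated) B region.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    for iv in B:
        if iv.chrom not in sizes:
            raise ValidationError(f"chromosome {iv.chrom!r} of subject set not in chrom sizes")
        if len(iv) > sizes[iv.chrom]:
            raise ValidationError(
                f"interval of length {len(iv)} longer than chromosome {iv.chrom}"
            )
    observed = int((_count_overlaps(A, B) > 0).sum())

    a_by_chrom = A.by_chrom()
    plans = []  # per chromosome shared by A and B: (lengths, n_valid_starts, a_starts_sorted, a_ends_sorted, n_a)
    a_chrom_base = 0
    for chrom, arrs in B.by_chrom().items():
        lengths = arrs["ends"] - arrs["starts"]
        high = sizes[chrom] - lengths + 1  # exclusive upper bound on start
        a = a_by_chrom.get(chrom)
        if a is None or len(a["idx"]) == 0:
            plans.append((lengths, high, None, None))
        else:
            plans.append((lengths, high, np.sort(a["starts"]), np.sort(a["ends"])))

    rng = np.random.default_rng(seed)
    null = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        total = 0
        for lengths, high, a_starts, a_ends in plans:
            starts = rng.integers(0, high)
            if a_starts is None:
                continue
            ends = starts + lengths
            b_starts = np.sort(starts)
            b_ends = np.sort(ends)
            n_per_a = (
                np.searchsorted(b_starts, a_ends, side="left")
                - np.searchsorted(b_ends, a_starts, side="right")
            )
            total += int((n_per_a > 0).sum())
        null[it] = total
    return ResamplingResult(
        observed,
        _empirical_p(null, observed),
        NullDistribution(n_iter, seed, null),
    )


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    N genes in the universe, K in the category, n drawn, k observed in
    both.  Returns 1 for k = 0.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("require 0 <= K, n <= N")
    if k < 0 or k > min(K, n):
        raise ValidationError(f"infeasible overlap k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def monte_carlo_set_test(
    universe: GeneSet | Iterable[str],
    setA: GeneSet | Iterable[str],
    setB: GeneSet | Iterable[str],
    n_iter: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Empirical upper-tail probability of a gene-set intersection size.

    Null: draw |A| and |B| genes uniformly without replacement from the
    universe, independently, each iteration; the statistic is the
    intersection size.  Its null mean is |A||B| / |universe|.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    uni = sorted(universe.gene_ids if isinstance(universe, GeneSet) else set(universe))
    ids_a = set(setA.gene_ids if isinstance(setA, GeneSet) else setA)
    ids_b = set(setB.gene_ids if isinstance(setB, GeneSet) else setB)
    uni_set = set(uni)
    if not ids_a <= uni_set or not ids_b <= uni_set:
        raise ValidationError("setA and setB must be subsets of the universe")
    observed = len(ids_a & ids_b)
    N, nA, nB = len(uni), len(ids_a), len(ids_b)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_iter, dtype=np.int64)
    mask = np.zeros(N, dtype=bool)
    for it in range(n_iter):
        ia = rng.choice(N, size=nA, replace=False)
        ib = rng.choice(N, size=nB, replace=False)
        mask[ia] = True
        null[it] = int(mask[ib].sum())
        mask[ia] = False
    return ResamplingResult(
        observed,
        _empirical_p(null, observed),
        NullDistribution(n_iter, seed, null),
    )
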