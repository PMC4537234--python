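"""Core genomic data types and interval algebra.

Everything in this package works on 0-based half-open coordinates
(the BED convention).  The only place a coordinate conversion happens
is GTF ingestion in :mod:`regcascade.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Input violated a documented contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``.

    ``summit`` is the absolute coordinate of a narrowPeak point-source
    call when one was provided; ``attrs`` holds any extra columns
    (signalValue, pValue, qValue) retained from narrowPeak input.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None
    attrs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Share >= 1 bp (book-ended intervals do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for chrom, length in self.items():
            if not chrom:
                raise ValidationError("chromosome name must be non-empty")
            if int(length) <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length")
            self[chrom] = int(length)

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValidationError(f"chromosome {interval.chrom!r} not in chrom sizes")
        if interval.end > self[interval.chrom]:
            raise ValidationError(
                f"interval end {interval.end} exceeds length of {interval.chrom}"
            )


class RegionSet:
    """A labeled, sorted collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``; each interval
    carries a stable ``region_id`` (unique within the set).  Per-chromosome
    numpy views are cached for fast overlap arithmetic.
    """

    def __init__(
        self,
        label: str,
        intervals: Iterable[GenomicInterval],
        region_ids: Sequence[str] | None = None,
        chrom_sizes: ChromSizes | None = None,
    ):
        ivs = list(intervals)
        if region_ids is None:
            ids = [f"{label}:{i}" for i in range(len(ivs))]
        else:
            ids = list(region_ids)
            if len(ids) != len(ivs):
                raise ValidationError("region_ids length mismatch")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate region_ids in set {label!r}")
        if chrom_sizes is not None:
            for iv in ivs:
                chrom_sizes.validate_interval(iv)
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(ivs[i] for i in order)
        self.region_ids: tuple[str, ...] = tuple(ids[i] for i in order)
        self._by_chrom: dict[str, dict[str, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(iv.chrom for iv in self.intervals))

    def by_chrom(self) -> dict[str, dict[str, np.ndarray]]:
        """Per-chromosome arrays: starts, ends (position-sorted) and idx
        giving each interval's index into ``self.intervals``."""
        if self._by_chrom is None:
            out: dict[str, dict[str, np.ndarray]] = {}
            for chrom in self.chroms:
                idx = np.array(
                    [i for i, iv in enumerate(self.intervals) if iv.chrom == chrom],
                    dtype=np.int64,
                )
                starts = np.array([self.intervals[i].start for i in idx], dtype=np.int64)
                ends = np.array([self.intervals[i].end for i in idx], dtype=np.int64)
                out[chrom] = {"starts": starts, "ends": ends, "idx": idx}
            self._by_chrom = out
        return self._by_chrom

    def anchors(self) -> np.ndarray:
        """Anchor coordinate per interval (summit when present, else midpoint)."""
        return np.array(
            [
                iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
                for iv in self.intervals
            ],
            dtype=np.int64,
        )

    def total_coverage(self) -> int:
        """Total bp covered by the union of the intervals."""
        total = 0
        for chrom, arrs in self.by_chrom().items():
            order = np.argsort(arrs["starts"], kind="stable")
            cur_s = cur_e = None
            for s, e in zip(arrs["starts"][order], arrs["ends"][order]):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
        return int(total)


def merge_regions(rs: RegionSet) -> RegionSet:
    """Merge overlapping or book-ended intervals into maximal intervals.

    Idempotent; total covered length is preserved.
    """
    merged: list[GenomicInterval] = []
    for chrom in rs.chroms:
        arrs = rs.by_chrom()[chrom]
        order = np.argsort(arrs["starts"], kind="stable")
        cur_s = cur_e = None
        for s, e in zip(arrs["starts"][order], arrs["ends"][order]):
            s, e = int(s), int(e)
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_e is not None:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return RegionSet(rs.label, merged, region_ids=[f"{rs.label}:m{i}" for i in range(len(merged))])


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its transcription start site (TSS)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.tss < 0:
            raise ValidationError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    """Gene-level differential expression: log2 fold change + FDR q-value."""

    gene_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValidationError(f"log2fc for {self.gene_id} is not finite")
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValidationError(
                f"qvalue for {self.gene_id} outside [0, 1]: {self.qvalue}"
            )


class ExpressionTable:
    """Differential-expression table keyed by unique gene_id."""

    def __init__(self, records: Iterable[ExpressionRecord]):
        self.records: tuple[ExpressionRecord, ...] = tuple(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
        self._index = {rec.gene_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExpressionRecord]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> ExpressionRecord:
        return self._index[gene_id]

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(rec.gene_id for rec in self.records)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with derivation provenance.

    ``provenance`` is an ordered tuple of ``(stage, params)`` records;
    every derivation appends one entry, so a derived set can always be
    recomputed.  ``support`` optionally maps gene_id -> supporting
    region_ids (for binding-derived sets).
    """

    label: str
    gene_ids: frozenset[str]
    provenance: tuple[tuple[str, tuple[tuple[str, object], ...]], ...] = ()
    support: tuple[tuple[str, tuple[str, ...]], ...] = ()

    @classmethod
    def build(
        cls,
        label: str,
        gene_ids: Iterable[str],
        stage: str | None = None,
        params: Mapping[str, object] | None = None,
        support: Mapping[str, Sequence[str]] | None = None,
    ) -> "GeneSet":
        prov = ()
        if stage is not None:
            prov = ((stage, tuple(sorted((params or {}).items(), key=lambda kv: kv[0]))),)
        supp = tuple(
            sorted((g, tuple(r)) for g, r in (support or {}).items())
        )
        return cls(label, frozenset(gene_ids), prov, supp)

    def derive(
        self,
        label: str,
        gene_ids: Iterable[str],
        stage: str,
        params: Mapping[str, object] | None = None,
        support: Mapping[str, Sequence[str]] | None = None,
    ) -> "GeneSet":
        new_ids = frozenset(gene_ids)
        if not new_ids <= self.gene_ids:
            raise ValidationError(f"derived set {label!r} is not a subset of {self.label!r}")
        entry = (stage, tuple(sorted((params or {}).items(), key=lambda kv: kv[0])))
        supp = tuple(sorted((g, tuple(r)) for g, r in (support or {}).items()))
        return GeneSet(label, new_ids, self.provenance + (entry,), supp)

    def union(self, other: "GeneSet", label: str, stage: str = "union") -> "GeneSet":
        entry = (stage, (("left", self.label), ("right", other.label)))
        return GeneSet(
            label,
            self.gene_ids | other.gene_ids,
            self.provenance + other.provenance + (entry,),
        )

    def intersect(self, other: "GeneSet", label: str, stage: str = "intersection") -> "GeneSet":
        entry = (stage, (("left", self.label), ("right", other.label)))
        return GeneSet(
            label,
            self.gene_ids & other.gene_ids,
            self.provenance + other.provenance + (entry,),
        )

    def sorted_ids(self) -> list[str]:
        return sorted(self.gene_ids)

    def support_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.support)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids
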