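"""Readers and writers for the standard text formats.

Supported inputs: BED3/BED6/narrowPeak region files, BED6 or GTF gene
annotation, two-column chrom.sizes, and TSV expression tables with a
mandatory ``gene_id / log2fc / qvalue`` header.  All readers emit the
package-internal 0-based half-open convention; GTF (1-based inclusive)
is converted on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import (
    ChromSizes,
    ExpressionRecord,
    ExpressionTable,
    GeneRecord,
    GenomicInterval,
    GeneSet,
    ParseError,
    RegionSet,
    ValidationError,
)

REGION_FORMATS = ("bed3", "bed6", "narrowPeak")
_NCOLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}
_SKIP = ("#", "track", "browser")


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or any(line.startswith(p) for p in _SKIP):
                continue
            yield lineno, line.split("\t")


def read_regions(path: str | Path, format: str = "bed6", label: str | None = None) -> RegionSet:
    """Read a BED3/BED6/narrowPeak file into a :class:`RegionSet`.

    region_ids are assigned ``label:<line-index>`` in file order (0-based
    over data lines); narrowPeak extra columns are retained, with the
    summit offset converted to an absolute coordinate.
    """
    if format not in REGION_FORMATS:
        raise ValidationError(f"unknown region format {format!r}")
    label = label if label is not None else Path(path).stem
    need = _NCOLS[format]
    intervals: list[GenomicInterval] = []
    ids: list[str] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < need:
            raise ParseError(
                f"{path}:{lineno}: expected >= {need} columns for {format}, got {len(cols)}"
            )
        try:
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = score = None
        strand = "."
        summit = None
        attrs: tuple[tuple[str, float], ...] = ()
        if format in ("bed6", "narrowPeak"):
            name = cols[3] if cols[3] not in (".", "") else None
            try:
                score = float(cols[4]) if cols[4] != "." else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = cols[5] if cols[5] in ("+", "-") else "."
        if format == "narrowPeak":
            try:
                sig, pval, qval, offset = (
                    float(cols[6]),
                    float(cols[7]),
                    float(cols[8]),
                    int(cols[9]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed narrowPeak columns") from exc
            attrs = (("signalValue", sig), ("pValue", pval), ("qValue", qval))
            if offset >= 0:
                summit = start + offset
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score,
                                strand=strand, summit=summit, attrs=attrs)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        ids.append(f"{label}:{len(ids)}")
    return RegionSet(label, intervals, region_ids=ids)


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_genes(path: str | Path, format: str = "bed6", attribute: str = "gene_id") -> list[GeneRecord]:
    """Read gene records from BED6 or GTF.

    BED6: the name column is the gene_id; TSS = start (+) or end-1 (-).
    GTF: rows of feature type ``gene`` or ``transcript`` contribute; per
    gene the 5'-most TSS on its strand is kept, after converting the
    1-based inclusive GTF coordinates to 0-based half-open.
    """
    if format == "bed6":
        records: list[GeneRecord] = []
        seen: set[str] = set()
        for lineno, cols in _data_lines(path):
            if len(cols) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 gene row needs 6 columns")
            chrom, start, end, gene_id, _score, strand = cols[:6]
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: gene {gene_id!r} missing strand")
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            start_i, end_i = int(start), int(end)
            tss = start_i if strand == "+" else end_i - 1
            records.append(GeneRecord(gene_id, chrom, tss, strand))
        return records
    if format == "gtf":
        best: dict[str, GeneRecord] = {}
        for lineno, cols in _data_lines(path):
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: GTF row needs 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_str = cols[:9]
            if feature not in ("gene", "transcript"):
                continue
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: missing strand")
            attrs = dict(_GTF_ATTR_RE.findall(attr_str))
            if attribute not in attrs:
                raise ParseError(f"{path}:{lineno}: no {attribute!r} attribute")
            gene_id = attrs[attribute]
            start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            tss = start0 if strand == "+" else end0 - 1
            prev = best.get(gene_id)
            if prev is None:
                best[gene_id] = GeneRecord(gene_id, chrom, tss, strand)
            else:
                if prev.strand != strand or prev.chrom != chrom:
                    raise ValidationError(
                        f"{path}:{lineno}: conflicting location for gene {gene_id!r}"
                    )
                five_prime = min(prev.tss, tss) if strand == "+" else max(prev.tss, tss)
                best[gene_id] = GeneRecord(gene_id, chrom, five_prime, strand)
        return list(best.values())
    raise ValidationError(f"unknown gene format {format!r}")


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV with header columns gene_id, log2fc, qvalue (extras ignored)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2fc", "qvalue"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            log2fc = float(getattr(row, "log2fc"))
            qvalue = float(getattr(row, "qvalue"))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric value for gene {row.gene_id!r}") from exc
        records.append(ExpressionRecord(str(row.gene_id), log2fc, qvalue))
    return ExpressionTable(records)


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    sizes: dict[str, int] = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: chrom.sizes row needs 2 columns")
        try:
            sizes[cols[0]] = int(cols[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer length") from exc
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sizes:
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_region_set(rs: RegionSet, path: str | Path, format: str = "bed6") -> None:
    """Write a RegionSet as BED6; the name column carries the region_id."""
    if format != "bed6":
        raise ValidationError(f"unsupported output format {format!r}")
    with open(path, "w") as fh:
        for rid, iv in zip(rs.region_ids, rs.intervals):
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rid}\t{score}\t{iv.strand}\n")


def write_gene_records(genes: Iterable[GeneRecord], path: str | Path, body: int = 1) -> None:
    """Write gene records as BED6 (a ``body``-bp stub downstream of the TSS)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.tss + body
            else:
                start, end = max(0, g.tss - body + 1), g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    """One gene per line, sorted, with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# gene_set\t{gs.label}\n")
        for stage, params in gs.provenance:
            rendered = ";".join(f"{k}={v}" for k, v in params)
            fh.write(f"# stage\t{stage}\t{rendered}\n")
        for gene_id in gs.sorted_ids():
            fh.write(gene_id + "\n")


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    ids: list[str] = []
    found_label = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line.split("\t")
                if len(parts) >= 2 and parts[0] == "# gene_set":
                    found_label = parts[1]
                continue
            if line.strip():
                ids.append(line.strip())
    return GeneSet.build(label or found_label or Path(path).stem, ids)
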