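"""IUPAC consensus-motif scanning and motif-module co-occurrence.

A motif module is the co-occurrence of a partner motif within a fixed
window (default +/- 50 bp, midpoint to midpoint) of an anchor motif
inside one bound region.  Enrichment is assessed against a per-region
mononucleotide-shuffle null that preserves each region's exact base
composition.  Default consensi: RUNX = TGYGGTY, E-box/MyoD = CAGCTG,
AP-1 = TGASTCA; all are configurable, loadable from a two-column TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval, RegionSet, ValidationError

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValidationError("motif consensus must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValidationError(f"invalid IUPAC character(s) {sorted(bad)} in motif {self.name!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def regex(self) -> re.Pattern[str]:
        # lookahead so overlapping matches are all reported
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
            for c in self.iupac
        )
        return re.compile(f"(?=({body}))")

    def reverse_regex(self) -> re.Pattern[str]:
        return ConsensusMotif(self.name, reverse_complement(self.iupac)).regex()


DEFAULT_MOTIFS: tuple[ConsensusMotif, ...] = (
    ConsensusMotif("RUNX", "TGYGGTY"),
    ConsensusMotif("MYOD", "CAGCTG"),
    ConsensusMotif("AP1", "TGASTCA"),
)


def read_motif_table(path: str | Path) -> list[ConsensusMotif]:
    """Two-column TSV (name, iupac); '#' lines skipped."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"motif table row needs 2 columns: {line!r}")
            motifs.append(ConsensusMotif(parts[0], parts[1]))
    return motifs


@dataclass(frozen=True)
class MotifMatch:
    region_id: str
    offset: int
    strand: str
    motif: str


@dataclass(frozen=True)
class ModuleResult:
    anchor: str
    partner: str
    window_bp: int
    n_regions_with_module: int
    n_regions_with_anchor: int
    fold_enrichment: float
    p_empirical: float


def scan_consensus(
    sequence: str,
    motif: ConsensusMotif,
    both_strands: bool = True,
    region_id: str = "",
) -> list[MotifMatch]:
    """All offsets where the motif (or, with ``both_strands``, its reverse
    complement) matches.  Reverse-complement hits are reported with '-'
    strand at the forward-coordinate offset.  An N in the sequence never
    matches a non-N motif position."""
    seq = sequence.upper()
    matches = [
        MotifMatch(region_id, m.start(), "+", motif.name)
        for m in motif.regex().finditer(seq)
    ]
    if both_strands:
        matches += [
            MotifMatch(region_id, m.start(), "-", motif.name)
            for m in motif.reverse_regex().finditer(seq)
        ]
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


class GenomeSource:
    """Fetch region sequences from a genome FASTA (via pyfaidx)."""

    def __init__(self, fasta: str | Path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(fasta))

    def get(self, interval: GenomicInterval, region_id: str = "") -> str:
        if interval.chrom not in self._fa:
            raise ValidationError(f"chromosome {interval.chrom!r} absent from FASTA")
        chrom_len = len(self._fa[interval.chrom])
        if interval.end > chrom_len:
            raise ValidationError(
                f"region {interval.chrom}:{interval.start}-{interval.end} outside sequence"
            )
        return str(self._fa[interval.chrom][interval.start:interval.end]).upper()


class DictSource:
    """Region sequences keyed by region_id (e.g. from a per-region FASTA)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = dict(sequences)

    def get(self, interval: GenomicInterval, region_id: str = "") -> str:
        if region_id not in self._seqs:
            raise ValidationError(f"no sequence for region {region_id!r}")
        seq = self._seqs[region_id].upper()
        if len(seq) != len(interval):
            raise ValidationError(
                f"sequence length {len(seq)} != region length {len(interval)} for {region_id!r}"
            )
        return seq


def as_sequence_source(source):
    if isinstance(source, (str, Path)):
        return GenomeSource(source)
    if isinstance(source, Mapping):
        return DictSource(source)
    if hasattr(source, "get"):
        return source
    raise ValidationError("unsupported sequence source")


def region_sequences(regions: RegionSet, source) -> list[str]:
    src = as_sequence_source(source)
    return [src.get(iv, rid) for rid, iv in zip(regions.region_ids, regions.intervals)]


def fraction_with_motif(
    regions: RegionSet,
    source,
    motif: ConsensusMotif,
    both_strands: bool = True,
) -> float:
    """Fraction of regions with >= 1 motif match on either strand."""
    if len(regions) == 0:
        raise ValidationError("motif fraction undefined for empty region set")
    seqs = region_sequences(regions, source)
    n_hit = sum(1 for s in seqs if scan_consensus(s, motif, both_strands))
    return n_hit / len(regions)


def _midpoints(seq: str, motif: ConsensusMotif) -> list[float]:
    return [m.offset + len(motif) / 2 for m in scan_consensus(seq, motif, True)]


def _has_module(anchor_mids: Sequence[float], partner_mids: Sequence[float], window_bp: int) -> bool:
    return any(abs(a - p) <= window_bp for a in anchor_mids for p in partner_mids)


def module_cooccurrence(
    regions: RegionSet,
    source,
    anchor: ConsensusMotif,
    partners: Sequence[ConsensusMotif],
    window_bp: int = 50,
    n_shuffles: int = 999,
    seed: int = 0,
) -> list[ModuleResult]:
    """Anchor-partner module counts with a mononucleotide-shuffle null.

    A region contains a module when some partner-match midpoint lies
    within +/- ``window_bp`` of some anchor-match midpoint.  Each null
    iteration independently permutes every region's sequence (exact
    composition preserved) and recounts; fold enrichment is observed
    module-region count over the null mean.
    """
    if window_bp <= 0:
        raise ValidationError(f"window_bp must be > 0, got {window_bp}")
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    seqs = region_sequences(regions, source)
    anchor_mids = [_midpoints(s, anchor) for s in seqs]
    n_with_anchor = sum(1 for mids in anchor_mids if mids)
    observed = {
        p.name: sum(
            1
            for s, a_mids in zip(seqs, anchor_mids)
            if a_mids and _has_module(a_mids, _midpoints(s, p), window_bp)
        )
        for p in partners
    }

    rng = np.random.default_rng(seed)
    null_counts = {p.name: np.zeros(n_shuffles, dtype=np.int64) for p in partners}
    arrays = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
    for it in range(n_shuffles):
        for arr in arrays:
            shuffled = rng.permutation(arr).tobytes().decode("ascii")
            a_mids = _midpoints(shuffled, anchor)
            if not a_mids:
                continue
            for p in partners:
                if _has_module(a_mids, _midpoints(shuffled, p), window_bp):
                    null_counts[p.name][it] += 1

    results = []
    for p in partners:
        null = null_counts[p.name]
        obs = observed[p.name]
        if n_with_anchor == 0:
            results.append(ModuleResult(anchor.name, p.name, window_bp, 0, 0, 0.0, 1.0))
            continue
        mean_null = float(null.mean())
        if mean_null > 0:
            fold = obs / mean_null
        else:
            fold = float("inf") if obs > 0 else 0.0
        p_emp = float((1 + int((null >= obs).sum())) / (1 + n_shuffles))
        results.append(
            ModuleResult(anchor.name, p.name, window_bp, obs, n_with_anchor, fold, p_emp)
        )
    return results


def mononucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Permute a sequence's characters (exact composition preserved)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")
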