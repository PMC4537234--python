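"""Seeded synthetic dataset generator with planted ground truth.

Emulates the structure of a TF co-occupancy study at desk scale: a toy
genome, a TSS annotation with minimum spacing, three TF peak sets with
controlled pairwise/triple co-occupancy (partner peaks jittered around
the anchor TF's peaks plus independent background peaks), histone-mark
and open-chromatin peaks planted preferentially at TF peaks, consensus
motifs planted at peak centers over an i.i.d. uniform background, and
two expression tables (culture-like and in-vivo-like) in which genes
near anchor-TF peaks are enriched for significant fold changes with a
configurable direction bias.  Expression significance is simulated
through z-statistics whose normal-tail p-values are Benjamini-Hochberg
adjusted, so the emitted q-value column has realistic rank structure.

Identical seed => byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as rcio
from .cascade import CascadeReport, RunConfig
from .core import (
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    RegionSet,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# planted consensus instances (concrete realizations of the scanner's
# default IUPAC consensi RUNX=TGYGGTY, E-box=CAGCTG, AP-1=TGASTCA)
ANCHOR_MOTIF_SEQ = "TGTGGTT"
MYOD_MOTIF_SEQ = "CAGCTG"
CJUN_MOTIF_SEQ = "TGACTCA"


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 500
    n_runx1_peaks: int = 1_000
    peak_length_mean: float = 200.0
    peak_length_sd: float = 50.0
    peak_length_min: int = 50
    p_myod_given_runx1: float = 0.46
    p_cjun_given_runx1: float = 0.47
    n_background_peaks: int = 500
    jitter_bp: int = 100
    p_mark_given_peak: float = 0.70
    p_atac_given_peak: float = 0.25
    n_background_marks: int = 300
    mark_length_bp: int = 600
    atac_length_bp: int = 300
    p_motif_anchor: float = 0.95
    p_motif_partner_in_window: float = 0.60
    p_responsive_bound: float = 0.30
    p_responsive_unbound: float = 0.05
    effect_size: float = 2.0
    effect_sd: float = 0.25
    z_shift: float = 6.0
    null_log2fc_sd: float = 0.20
    direction_bias: float = 0.75
    min_tss_spacing: int = 20_000
    responsive_window: int = 200_000
    write_fasta: bool = True

    def __post_init__(self) -> None:
        probs = {
            "p_myod_given_runx1": self.p_myod_given_runx1,
            "p_cjun_given_runx1": self.p_cjun_given_runx1,
            "p_mark_given_peak": self.p_mark_given_peak,
            "p_atac_given_peak": self.p_atac_given_peak,
            "p_motif_anchor": self.p_motif_anchor,
            "p_motif_partner_in_window": self.p_motif_partner_in_window,
            "p_responsive_bound": self.p_responsive_bound,
            "p_responsive_unbound": self.p_responsive_unbound,
            "direction_bias": self.direction_bias,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.p_responsive_bound < self.p_responsive_unbound:
            raise ValidationError(
                "p_responsive_bound must be >= p_responsive_unbound"
            )
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_runx1_peaks"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def dataset_id(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Planted labels, consistent with the emitted files."""

    dataset_id: str
    config: dict
    gene_ids: list[str]
    gene_bound: list[bool]
    gene_rmj_near: list[bool]
    gene_hc_near: list[bool]
    gene_responsive_pm: list[bool]
    gene_direction_pm: list[int]
    gene_responsive_mdx: list[bool]
    gene_direction_mdx: list[int]
    peak_chrom: list[str]
    peak_center: list[int]
    peak_myod: list[bool]
    peak_cjun: list[bool]
    peak_marked: list[bool]
    peak_open: list[bool]
    peak_motif_anchor: list[bool]
    motif_positions: list[list]  # [chrom, start, motif_name]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def _select(self, mask: Sequence[bool]) -> frozenset:
        return frozenset(g for g, m in zip(self.gene_ids, mask) if m)

    def true_responsive(self) -> frozenset:
        return self._select(self.gene_responsive_pm)

    def true_regulated(self) -> frozenset:
        return self._select(
            [r and b for r, b in zip(self.gene_responsive_pm, self.gene_bound)]
        )

    def true_rmj_regulated(self) -> frozenset:
        return self._select(
            [r and n for r, n in zip(self.gene_responsive_pm, self.gene_rmj_near)]
        )

    def true_high_confidence(self) -> frozenset:
        return self._select(
            [r and n for r, n in zip(self.gene_responsive_pm, self.gene_hc_near)]
        )

    def true_in_vivo(self) -> frozenset:
        return frozenset(
            g
            for g, r_pm, near, r_mdx in zip(
                self.gene_ids, self.gene_responsive_pm,
                self.gene_rmj_near, self.gene_responsive_mdx,
            )
            if r_pm and near and r_mdx
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    chrom_sizes: ChromSizes
    genes: list[GeneRecord]
    regions: dict[str, RegionSet]
    expression_pm: pd.DataFrame
    expression_mdx: pd.DataFrame
    ground_truth: GroundTruth
    sequences: dict[str, np.ndarray] | None = None
    paths: dict[str, str] = field(default_factory=dict)

    def run_config(self, **overrides) -> RunConfig:
        if not self.paths:
            raise ValidationError("dataset was generated in-memory; no file paths")
        base = dict(
            genes=self.paths["genes"],
            expression=self.paths["expression_pm"],
            runx1=self.paths["runx1"],
            myod=self.paths["myod"],
            cjun=self.paths["cjun"],
            h3k4me1=self.paths["h3k4me1"],
            h3k27ac=self.paths["h3k27ac"],
            atac=self.paths["atac"],
            chrom_sizes=self.paths["chrom_sizes"],
            fasta=self.paths.get("fasta"),
            expression_invivo=self.paths["expression_mdx"],
            window_bp=self.config.responsive_window,
        )
        base.update(overrides)
        return RunConfig(**base)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone in p)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _truncated_normal_lengths(rng, n, mean, sd, minimum) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.maximum(lengths, minimum)


def _place_uniform_peaks(rng, n, n_chroms, chrom_length, lengths, edge_margin=250):
    chroms = rng.integers(0, n_chroms, size=n)
    half = lengths // 2
    low = np.maximum(half + 1, edge_margin)
    high = chrom_length - low
    if np.any(high <= low):
        raise ValidationError("chromosome too short for requested peak lengths")
    centers = rng.integers(low, high)
    return chroms, centers


def _intervals(chrom_names, chroms, centers, lengths) -> list[GenomicInterval]:
    starts = centers - lengths // 2
    ends = starts + lengths
    return [
        GenomicInterval(chrom_names[c], int(s), int(e))
        for c, s, e in zip(chroms, starts, ends)
    ]


def generate_dataset(config: SyntheticConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full dataset (optionally writing all files to ``outdir``).

    Raises :class:`ValidationError` when genes cannot be packed at the
    required minimum TSS spacing.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    L = config.chrom_length
    sizes = ChromSizes({name: L for name in chrom_names})

    # --- gene annotation: TSS uniform over a spacing grid, jittered ---
    margin = min(50_000, max(1000, L // 20))
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneRecord] = []
    gene_idx = 0
    jitter_half = max(1, config.min_tss_spacing // 4)
    for ci, count in enumerate(per_chrom):
        slots = np.arange(margin, L - margin, config.min_tss_spacing)
        if len(slots) < count:
            raise ValidationError(
                f"cannot place {count} genes with spacing {config.min_tss_spacing} "
                f"on a {L} bp chromosome"
            )
        chosen = np.sort(rng.choice(len(slots), size=count, replace=False))
        tss = slots[chosen] + rng.integers(-jitter_half, jitter_half + 1, size=count)
        strands = rng.integers(0, 2, size=count)
        for t, s in zip(tss, strands):
            genes.append(
                GeneRecord(f"g{gene_idx:05d}", chrom_names[ci], int(t), "+" if s == 0 else "-")
            )
            gene_idx += 1

    # --- anchor-TF peaks and per-peak planted labels ---
    n = config.n_runx1_peaks
    runx1_len = _truncated_normal_lengths(
        rng, n, config.peak_length_mean, config.peak_length_sd, config.peak_length_min
    )
    runx1_chrom, runx1_center = _place_uniform_peaks(
        rng, n, config.n_chroms, L, runx1_len
    )
    myod_flag = rng.random(n) < config.p_myod_given_runx1
    cjun_flag = rng.random(n) < config.p_cjun_given_runx1
    marked_flag = rng.random(n) < config.p_mark_given_peak
    open_flag = rng.random(n) < config.p_atac_given_peak
    motif_anchor_flag = rng.random(n) < config.p_motif_anchor
    motif_myod_flag = myod_flag & (rng.random(n) < config.p_motif_partner_in_window)
    motif_cjun_flag = cjun_flag & (rng.random(n) < config.p_motif_partner_in_window)

    def coplanted(flag: np.ndarray) -> list[GenomicInterval]:
        k = int(flag.sum())
        lengths = _truncated_normal_lengths(
            rng, k, config.peak_length_mean, config.peak_length_sd, config.peak_length_min
        )
        jit = (
            rng.integers(-config.jitter_bp, config.jitter_bp + 1, size=k)
            if config.jitter_bp > 0
            else np.zeros(k, dtype=np.int64)
        )
        centers = runx1_center[flag] + jit
        half = lengths // 2
        centers = np.clip(centers, half + 1, L - half - 1)
        return _intervals(chrom_names, runx1_chrom[flag], centers, lengths)

    def background(n_bg: int) -> list[GenomicInterval]:
        if n_bg <= 0:
            return []
        lengths = _truncated_normal_lengths(
            rng, n_bg, config.peak_length_mean, config.peak_length_sd, config.peak_length_min
        )
        chroms, centers = _place_uniform_peaks(rng, n_bg, config.n_chroms, L, lengths)
        return _intervals(chrom_names, chroms, centers, lengths)

    myod_ivs = coplanted(myod_flag) + background(config.n_background_peaks)
    cjun_ivs = coplanted(cjun_flag) + background(config.n_background_peaks)

    def mark_track(flag: np.ndarray, length: int, jitter: int) -> list[GenomicInterval]:
        k = int(flag.sum())
        jit = rng.integers(-jitter, jitter + 1, size=k)
        centers = np.clip(runx1_center[flag] + jit, length // 2 + 1, L - length // 2 - 1)
        lengths = np.full(k, length, dtype=np.int64)
        planted = _intervals(chrom_names, runx1_chrom[flag], centers, lengths)
        n_bg = config.n_background_marks
        if n_bg > 0:
            bg_len = np.full(n_bg, length, dtype=np.int64)
            chroms, bg_centers = _place_uniform_peaks(rng, n_bg, config.n_chroms, L, bg_len)
            planted += _intervals(chrom_names, chroms, bg_centers, bg_len)
        return planted

    h3k4me1_ivs = mark_track(marked_flag, config.mark_length_bp, 100)
    h3k27ac_ivs = mark_track(marked_flag, config.mark_length_bp, 100)
    atac_ivs = mark_track(open_flag, config.atac_length_bp, 50)

    regions = {
        "runx1": RegionSet("runx1", _intervals(chrom_names, runx1_chrom, runx1_center, runx1_len)),
        "myod": RegionSet("myod", myod_ivs),
        "cjun": RegionSet("cjun", cjun_ivs),
        "h3k4me1": RegionSet("h3k4me1", h3k4me1_ivs),
        "h3k27ac": RegionSet("h3k27ac", h3k27ac_ivs),
        "atac": RegionSet("atac", atac_ivs),
    }

    # --- per-gene truth labels from actual peak placements ---
    w = config.responsive_window

    def near_any(gene: GeneRecord, mask: np.ndarray) -> bool:
        sel = (runx1_chrom == chrom_names.index(gene.chrom)) & mask
        if not sel.any():
            return False
        c = runx1_center[sel]
        return bool(np.any((c >= gene.tss - w) & (c <= gene.tss + w)))

    all_mask = np.ones(n, dtype=bool)
    rmj_mask = myod_flag & cjun_flag
    hc_mask = rmj_mask & marked_flag & open_flag
    gene_bound = [near_any(g, all_mask) for g in genes]
    gene_rmj_near = [near_any(g, rmj_mask) for g in genes]
    gene_hc_near = [near_any(g, hc_mask) for g in genes]

    # --- expression tables ---
    def expression_table(bound: Sequence[bool]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        m = len(genes)
        p_resp = np.where(bound, config.p_responsive_bound, config.p_responsive_unbound)
        responsive = rng.random(m) < p_resp
        direction = np.where(rng.random(m) < config.direction_bias, 1, -1)
        z = rng.normal(0.0, 1.0, size=m) + responsive * direction * config.z_shift
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        qvals = _benjamini_hochberg(pvals)
        log2fc = np.where(
            responsive,
            direction * (config.effect_size + rng.normal(0.0, config.effect_sd, size=m)),
            rng.normal(0.0, config.null_log2fc_sd, size=m),
        )
        df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "log2fc": log2fc,
                "pvalue": pvals,
                "qvalue": qvals,
            }
        )
        return df, responsive, direction

    pm_df, pm_resp, pm_dir = expression_table(gene_bound)
    mdx_df, mdx_resp, mdx_dir = expression_table(gene_bound)

    # --- genome sequence with planted motifs ---
    sequences: dict[str, np.ndarray] | None = None
    motif_positions: list[list] = []
    if config.write_fasta:
        sequences = {
            name: _BASES[rng.integers(0, 4, size=L)] for name in chrom_names
        }
        anchor = np.frombuffer(ANCHOR_MOTIF_SEQ.encode(), dtype=np.uint8)
        myod_m = np.frombuffer(MYOD_MOTIF_SEQ.encode(), dtype=np.uint8)
        cjun_m = np.frombuffer(CJUN_MOTIF_SEQ.encode(), dtype=np.uint8)
        off_m = rng.integers(16, 45, size=n)  # upstream partner offset
        off_c = rng.integers(9, 38, size=n)  # downstream partner offset
        for i in range(n):
            if not motif_anchor_flag[i]:
                continue
            chrom = chrom_names[runx1_chrom[i]]
            seq = sequences[chrom]
            a_start = int(runx1_center[i]) - len(anchor) // 2
            seq[a_start:a_start + len(anchor)] = anchor
            motif_positions.append([chrom, a_start, "RUNX"])
            if motif_myod_flag[i]:
                s = a_start - int(off_m[i])
                seq[s:s + len(myod_m)] = myod_m
                motif_positions.append([chrom, s, "MYOD"])
            if motif_cjun_flag[i]:
                s = a_start + len(anchor) + int(off_c[i])
                seq[s:s + len(cjun_m)] = cjun_m
                motif_positions.append([chrom, s, "AP1"])

    truth = GroundTruth(
        dataset_id=config.dataset_id(),
        config=asdict(config),
        gene_ids=[g.gene_id for g in genes],
        gene_bound=[bool(b) for b in gene_bound],
        gene_rmj_near=[bool(b) for b in gene_rmj_near],
        gene_hc_near=[bool(b) for b in gene_hc_near],
        gene_responsive_pm=[bool(b) for b in pm_resp],
        gene_direction_pm=[int(d) for d in pm_dir],
        gene_responsive_mdx=[bool(b) for b in mdx_resp],
        gene_direction_mdx=[int(d) for d in mdx_dir],
        peak_chrom=[chrom_names[c] for c in runx1_chrom],
        peak_center=[int(c) for c in runx1_center],
        peak_myod=[bool(b) for b in myod_flag],
        peak_cjun=[bool(b) for b in cjun_flag],
        peak_marked=[bool(b) for b in marked_flag],
        peak_open=[bool(b) for b in open_flag],
        peak_motif_anchor=[bool(b) for b in motif_anchor_flag],
        motif_positions=motif_positions,
    )

    ds = SyntheticDataset(
        config=config,
        chrom_sizes=sizes,
        genes=genes,
        regions=regions,
        expression_pm=pm_df,
        expression_mdx=mdx_df,
        ground_truth=truth,
        sequences=sequences,
    )
    if outdir is not None:
        _write_dataset(ds, Path(outdir))
    return ds


def _write_fasta(sequences: Mapping[str, np.ndarray], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, arr in sequences.items():
            fh.write(f">{name}\n")
            s = arr.tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width])
                fh.write("\n")


def _write_expression(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_dataset(ds: SyntheticDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.bed",
        "expression_pm": outdir / "expression_pm.tsv",
        "expression_mdx": outdir / "expression_mdx.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    rcio.write_chrom_sizes(ds.chrom_sizes, paths["chrom_sizes"])
    body = min(5000, max(1, min(g.tss for g in ds.genes)))
    rcio.write_gene_records(ds.genes, paths["genes"], body=body)
    _write_expression(ds.expression_pm, paths["expression_pm"])
    _write_expression(ds.expression_mdx, paths["expression_mdx"])
    for name, rs in ds.regions.items():
        paths[name] = outdir / f"{name}.bed"
        rcio.write_region_set(rs, paths[name])
    if ds.sequences is not None:
        paths["fasta"] = outdir / "genome.fa"
        _write_fasta(ds.sequences, paths["fasta"])
    ds.ground_truth.to_json(paths["ground_truth"])
    ds.paths = {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Recovery against planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageRecovery:
    stage: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    degenerate: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecoveryReport:
    dataset_id: str
    stages: tuple[StageRecovery, ...]

    def stage(self, name: str) -> StageRecovery:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"dataset_id": self.dataset_id, "stages": [s.to_dict() for s in self.stages]}


def recovery_report(ground_truth: GroundTruth, report: CascadeReport) -> RecoveryReport:
    """Confusion counts of each derived gene set against the planted labels.

    Sensitivity is None (flagged degenerate) when a stage has no planted
    positives.  Raises when the report's gene universe does not match the
    ground truth's dataset.
    """
    universe = set(ground_truth.gene_ids)
    truth_sets = {
        "responsive": ground_truth.true_responsive(),
        "regulated": ground_truth.true_regulated(),
        "rmj_regulated": ground_truth.true_rmj_regulated(),
        "high_confidence": ground_truth.true_high_confidence(),
        "in_vivo": ground_truth.true_in_vivo(),
    }
    stages = []
    for stage, truth in truth_sets.items():
        if stage not in report.gene_sets:
            continue
        predicted = set(report.gene_sets[stage])
        if not predicted <= universe:
            raise ValidationError(
                "cascade report and ground truth describe different datasets"
            )
        tp = len(predicted & truth)
        fp = len(predicted - truth)
        fn = len(truth - predicted)
        tn = len(universe) - tp - fp - fn
        degenerate = len(truth) == 0
        sens = None if degenerate else tp / (tp + fn)
        spec = None if (tn + fp) == 0 else tn / (tn + fp)
        stages.append(StageRecovery(stage, tp, fp, fn, tn, sens, spec, degenerate))
    return RecoveryReport(ground_truth.dataset_id, tuple(stages))
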