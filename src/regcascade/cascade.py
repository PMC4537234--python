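"""Staged multi-evidence integration.

The cascade derives nested gene subsets from gene-level differential
expression plus region-level binding and chromatin evidence:

  I    responsive      — passes the q-value and linear fold-change thresholds
  II   regulated       — responsive AND TF-bound within a TSS window
  III  rmj_regulated   — responsive AND near a region co-bound by all
                         three factors (Runx1, MyoD, c-Jun)
  IV   high_confidence — RMJ-regulated AND the supporting co-bound region
                         is an active enhancer (H3K4me1 AND H3K27ac) in
                         open chromatin (ATAC)
  (+)  in_vivo         — RMJ-regulated AND responsive in an independent
                         in-vivo expression contrast

Each stage is a pure set derivation with recorded provenance; the
nesting invariant (IV subset of III subset of II subset of I) is asserted on every
full run.  Significance of the stage-III and stage-IV intersections is
reported with an exact hypergeometric tail and a Monte Carlo gene-set
resampling p-value respectively.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from . import io as rcio
from .annotation import AnchorMode, bound_genes, location_distribution
from .core import (
    ExpressionTable,
    GeneRecord,
    GeneSet,
    RegionSet,
    ValidationError,
)
from .overlap import (
    ResamplingResult,
    Venn3Partition,
    _count_overlaps,
    cooccupancy,
    hypergeom_tail,
    monte_carlo_set_test,
    bootstrap_overlap_test,
    union_clusters,
    venn3,
)


@dataclass(frozen=True)
class ThresholdSpec:
    """Selection thresholds: FDR q-value below ``q_max`` and linear fold
    change above ``fc_min`` (both strict, as printed)."""

    q_max: float
    fc_min: float

    def __post_init__(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValidationError(f"q_max must be in (0, 1], got {self.q_max}")
        if self.fc_min <= 1.0:
            raise ValidationError(f"fc_min must be > 1, got {self.fc_min}")

    @property
    def log2_fc_min(self) -> float:
        return math.log2(self.fc_min)


def select_responsive(
    table: ExpressionTable,
    spec: ThresholdSpec,
    label: str = "responsive",
) -> tuple[GeneSet, GeneSet]:
    """Split a differential-expression table into up- and down-regulated
    gene sets at the given thresholds; the two sets are disjoint."""
    cut = spec.log2_fc_min
    params = {"q_max": spec.q_max, "fc_min": spec.fc_min}
    up = [r.gene_id for r in table if r.qvalue < spec.q_max and r.log2fc > cut]
    down = [r.gene_id for r in table if r.qvalue < spec.q_max and r.log2fc < -cut]
    return (
        GeneSet.build(f"{label}_up", up, stage="select_responsive", params={**params, "direction": "up"}),
        GeneSet.build(f"{label}_down", down, stage="select_responsive", params={**params, "direction": "down"}),
    )


@dataclass(frozen=True)
class RegulatedResult:
    genes: GeneSet
    bound_fraction: float


def derive_regulated(responsive: GeneSet, bound: GeneSet, label: str = "regulated") -> RegulatedResult:
    """Responsive genes that are also TF-bound; reports the bound fraction
    of the responsive set."""
    ids = responsive.gene_ids & bound.gene_ids
    frac = len(ids) / len(responsive) if len(responsive) else 0.0
    genes = responsive.derive(
        label, ids, stage="derive_regulated",
        params={"bound_set": bound.label},
        support={g: bound.support_map().get(g, ()) for g in ids},
    )
    return RegulatedResult(genes, frac)


def rmj_regions(runx1: RegionSet, myod: RegionSet, cjun: RegionSet, label: str = "RMJ") -> RegionSet:
    """Merged union clusters receiving >= 1 interval from each of the three
    factors (the triple-overlap class of the three-way partition)."""
    if len(runx1) == 0 and len(myod) == 0 and len(cjun) == 0:
        return RegionSet(label, [])
    clusters, masks = union_clusters([runx1, myod, cjun])
    keep = [iv for iv, m in zip(clusters.intervals, masks) if m == 0b111]
    return RegionSet(label, keep, region_ids=[f"{label}:{i}" for i in range(len(keep))])


@dataclass(frozen=True)
class RmjRegulatedResult:
    genes: GeneSet
    p_hypergeom: float
    n_universe: int
    n_rmj_bound: int
    n_responsive: int


def derive_rmj_regulated(
    responsive: GeneSet,
    rmj: RegionSet,
    genes: Sequence[GeneRecord],
    window_bp: int = 200_000,
    anchor: AnchorMode = "summit_or_midpoint",
    label: str = "rmj_regulated",
) -> RmjRegulatedResult:
    """Responsive genes with an RMJ region anchor within the TSS window;
    the hypergeometric tail is evaluated against the full annotation as
    the gene universe."""
    universe = [g.gene_id for g in genes]
    if len(rmj) == 0:
        empty = responsive.derive(label, (), stage="derive_rmj_regulated",
                                  params={"window_bp": window_bp, "n_rmj_regions": 0})
        return RmjRegulatedResult(empty, 1.0, len(universe), 0, len(responsive))
    rmj_bound = bound_genes(rmj, genes, window_bp=window_bp, anchor=anchor)
    ids = responsive.gene_ids & rmj_bound.gene_ids
    p = hypergeom_tail(
        len(universe),
        len(rmj_bound),
        len(responsive.gene_ids & set(universe)),
        len(ids),
    )
    out = responsive.derive(
        label, ids, stage="derive_rmj_regulated",
        params={"window_bp": window_bp, "n_rmj_regions": len(rmj)},
        support={g: rmj_bound.support_map().get(g, ()) for g in ids},
    )
    return RmjRegulatedResult(out, p, len(universe), len(rmj_bound), len(responsive))


@dataclass(frozen=True)
class EnhancerState:
    active_enhancer: bool
    open_chromatin: bool


@dataclass(frozen=True)
class EnhancerStateAnnotation:
    flags: tuple[tuple[str, EnhancerState], ...]
    fraction_active: float
    fraction_open: float
    fraction_active_and_open: float

    def as_map(self) -> dict[str, EnhancerState]:
        return dict(self.flags)


def annotate_enhancer_state(
    rs: RegionSet,
    h3k4me1: RegionSet,
    h3k27ac: RegionSet,
    atac: RegionSet,
) -> EnhancerStateAnnotation:
    """Per-region flags: active_enhancer = overlaps both histone marks;
    open_chromatin = overlaps an ATAC region.  Summary fractions are over
    all regions in ``rs``."""
    me1 = _count_overlaps(rs, h3k4me1) > 0
    ac = _count_overlaps(rs, h3k27ac) > 0
    op = _count_overlaps(rs, atac) > 0
    active = me1 & ac
    flags = tuple(
        (rid, EnhancerState(bool(a), bool(o)))
        for rid, a, o in zip(rs.region_ids, active, op)
    )
    n = len(rs)
    if n == 0:
        return EnhancerStateAnnotation((), 0.0, 0.0, 0.0)
    return EnhancerStateAnnotation(
        flags,
        float(active.sum()) / n,
        float(op.sum()) / n,
        float((active & op).sum()) / n,
    )


Conjunction = Literal["region", "gene"]


@dataclass(frozen=True)
class HighConfidenceResult:
    genes: GeneSet
    monte_carlo: ResamplingResult | None


def derive_high_confidence(
    rmj_regulated: GeneSet,
    rmj: RegionSet,
    state: EnhancerStateAnnotation,
    genes: Sequence[GeneRecord],
    window_bp: int = 200_000,
    anchor: AnchorMode = "summit_or_midpoint",
    conjunction: Conjunction = "region",
    n_iter: int = 0,
    seed: int = 0,
    label: str = "high_confidence",
) -> HighConfidenceResult:
    """RMJ-regulated genes supported by enhancer-state evidence.

    ``conjunction='region'`` (default, stricter): the SAME supporting RMJ
    region must be both an active enhancer and open chromatin.
    ``conjunction='gene'``: some supporting region is active and some
    (possibly different) region is open.  With ``n_iter`` > 0 a Monte
    Carlo gene-set resampling p-value for the intersection of the
    responsive ancestor with the evidence-supported bound genes is
    reported.
    """
    flags = state.as_map()
    if conjunction == "region":
        keep_ids = {rid for rid, st in flags.items() if st.active_enhancer and st.open_chromatin}
        keep = RegionSet(
            rmj.label,
            [iv for rid, iv in zip(rmj.region_ids, rmj.intervals) if rid in keep_ids],
            region_ids=[rid for rid in rmj.region_ids if rid in keep_ids],
        )
        supported = (
            bound_genes(keep, genes, window_bp=window_bp, anchor=anchor)
            if len(keep)
            else GeneSet.build("supported", ())
        )
    elif conjunction == "gene":
        active_ids = {rid for rid, st in flags.items() if st.active_enhancer}
        open_ids = {rid for rid, st in flags.items() if st.open_chromatin}
        all_bound = bound_genes(rmj, genes, window_bp=window_bp, anchor=anchor)
        supp = all_bound.support_map()
        keep_genes = {
            g for g, rids in supp.items()
            if set(rids) & active_ids and set(rids) & open_ids
        }
        supported = GeneSet.build("supported", keep_genes, support={g: supp[g] for g in keep_genes})
    else:
        raise ValidationError(f"unknown conjunction mode {conjunction!r}")

    ids = rmj_regulated.gene_ids & supported.gene_ids
    out = rmj_regulated.derive(
        label, ids, stage="derive_high_confidence",
        params={"conjunction": conjunction, "window_bp": window_bp},
        support={g: supported.support_map().get(g, ()) for g in ids},
    )
    mc = None
    if n_iter > 0:
        universe = GeneSet.build("universe", (g.gene_id for g in genes))
        mc = monte_carlo_set_test(
            universe,
            rmj_regulated.gene_ids & universe.gene_ids,
            supported.gene_ids & universe.gene_ids,
            n_iter=n_iter,
            seed=seed,
        )
    return HighConfidenceResult(out, mc)


def derive_in_vivo(
    rmj_regulated: GeneSet,
    in_vivo_responsive: GeneSet,
    label: str = "in_vivo",
) -> GeneSet:
    """Cross the (culture-derived) RMJ-regulated subset with an in-vivo
    responsive gene set; provenance records both parents."""
    ids = rmj_regulated.gene_ids & in_vivo_responsive.gene_ids
    return rmj_regulated.derive(
        label, ids, stage="derive_in_vivo",
        params={"crossed_with": in_vivo_responsive.label},
    )


# ---------------------------------------------------------------------------
# Full cascade run
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Inputs and parameters for one full cascade run (fully serializable;
    a copy is embedded in every report)."""

    genes: str
    expression: str
    runx1: str
    myod: str
    cjun: str
    h3k4me1: str
    h3k27ac: str
    atac: str
    chrom_sizes: str | None = None
    fasta: str | None = None
    expression_invivo: str | None = None
    gene_format: str = "bed6"
    region_format: str = "bed6"
    q_max: float = 0.1
    fc_min: float = 1.5
    q_max_invivo: float = 0.05
    fc_min_invivo: float = 1.7
    window_bp: int = 200_000
    anchor: str = "summit_or_midpoint"
    rmj_mode: str = "cluster"  # or "independent": each TF bound separately
    hc_conjunction: str = "region"
    n_iter_bootstrap: int = 0  # 0 disables the relocation test
    n_iter_monte_carlo: int = 2_000
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CascadeReport:
    """Counts, fractions, p-values and derived gene sets from one run."""

    config: dict
    n_genes_annotation: int
    n_peaks: dict[str, int]
    location: dict
    n_responsive: int
    n_up: int
    n_down: int
    n_bound_genes: int
    n_regulated: int
    bound_fraction: float
    cooccupancy_fractions: dict[str, float]
    venn3_counts: dict[str, int]
    n_rmj_regions: int
    n_rmj_regulated: int
    p_hypergeom_rmj: float
    enhancer_fractions: dict[str, float]
    n_high_confidence: int
    p_monte_carlo_hc: float | None
    bootstrap: dict[str, dict] | None
    gene_sets: dict[str, list[str]]
    n_invivo_responsive: int | None = None
    n_invivo_up: int | None = None
    n_invivo_down: int | None = None
    n_in_vivo: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CascadeReport":
        with open(path) as fh:
            data = json.load(fh)
        missing = [k for k in cls.__dataclass_fields__ if k not in data]  # type: ignore[attr-defined]
        extra = [k for k in data if k not in cls.__dataclass_fields__]  # type: ignore[attr-defined]
        if missing or extra:
            raise ValidationError(
                f"report schema mismatch (missing {missing}, unexpected {extra})"
            )
        return cls(**data)

    def summary_text(self) -> str:
        lines = [
            "cascade summary",
            f"  annotated genes          {self.n_genes_annotation}",
            f"  peaks                    "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.n_peaks.items())),
            f"  responsive genes         {self.n_responsive} (up {self.n_up}, down {self.n_down})",
            f"  TF-bound genes           {self.n_bound_genes}",
            f"  regulated genes          {self.n_regulated} (bound fraction {self.bound_fraction:.3f})",
            f"  co-occupancy             "
            + ", ".join(f"{k}={v:.3f}" for k, v in sorted(self.cooccupancy_fractions.items())),
            f"  triple-overlap regions   {self.n_rmj_regions}",
            f"  RMJ-regulated genes      {self.n_rmj_regulated} (hypergeometric p {self.p_hypergeom_rmj:.3g})",
            f"  enhancer fractions       "
            + ", ".join(f"{k}={v:.3f}" for k, v in sorted(self.enhancer_fractions.items())),
            f"  high-confidence genes    {self.n_high_confidence}"
            + (
                f" (Monte Carlo p {self.p_monte_carlo_hc:.3g})"
                if self.p_monte_carlo_hc is not None
                else ""
            ),
        ]
        if self.bootstrap:
            for name, res in sorted(self.bootstrap.items()):
                lines.append(
                    f"  bootstrap {name:<14} observed {res['observed']}, p {res['p_empirical']:.3g}"
                )
        if self.n_in_vivo is not None:
            lines.append(
                f"  in-vivo responsive       {self.n_invivo_responsive} "
                f"(up {self.n_invivo_up}, down {self.n_invivo_down})"
            )
            lines.append(f"  in-vivo regulated        {self.n_in_vivo}")
        return "\n".join(lines) + "\n"


def _check_nesting(report_sets: Mapping[str, frozenset]) -> None:
    chain = ["high_confidence", "rmj_regulated", "regulated", "responsive"]
    for inner, outer in zip(chain, chain[1:]):
        if not report_sets[inner] <= report_sets[outer]:
            raise ValidationError(f"nesting violated: {inner} not within {outer}")
    if "in_vivo" in report_sets and not report_sets["in_vivo"] <= report_sets["rmj_regulated"]:
        raise ValidationError("nesting violated: in_vivo not within rmj_regulated")


def run_cascade(cfg: RunConfig) -> CascadeReport:
    """Execute stages I-IV (plus the optional in-vivo cross) and return a
    fully populated, deterministic :class:`CascadeReport`."""
    required = [cfg.genes, cfg.expression, cfg.runx1, cfg.myod, cfg.cjun,
                cfg.h3k4me1, cfg.h3k27ac, cfg.atac]
    optional = [cfg.chrom_sizes, cfg.fasta, cfg.expression_invivo]
    for path in required + [p for p in optional if p]:
        if not Path(path).exists():
            raise ValidationError(f"missing input file: {path}")
    if cfg.n_iter_bootstrap > 0 and not cfg.chrom_sizes:
        raise ValidationError("bootstrap test requires chrom_sizes")

    genes = rcio.read_genes(cfg.genes, format=cfg.gene_format)
    table = rcio.read_expression_table(cfg.expression)
    region_sets = {
        name: rcio.read_regions(getattr(cfg, name), format=cfg.region_format, label=name)
        for name in ("runx1", "myod", "cjun", "h3k4me1", "h3k27ac", "atac")
    }
    runx1, myod, cjun = region_sets["runx1"], region_sets["myod"], region_sets["cjun"]

    # stage I: responsive genes
    up, down = select_responsive(table, ThresholdSpec(cfg.q_max, cfg.fc_min))
    responsive = up.union(down, "responsive", stage="select_responsive")

    # stage II: TF-bound and regulated
    runx1_bound = bound_genes(runx1, genes, window_bp=cfg.window_bp, anchor=cfg.anchor)
    regulated = derive_regulated(responsive, runx1_bound)

    # region-level co-occupancy evidence
    coocc = {
        "myod_of_runx1": cooccupancy(runx1, myod).fraction,
        "runx1_of_cjun": cooccupancy(cjun, runx1).fraction if len(cjun) else 0.0,
    }
    partition = venn3(runx1, myod, cjun)

    # stage III: RMJ-regulated
    if cfg.rmj_mode == "cluster":
        rmj = rmj_regions(runx1, myod, cjun)
        rmj_res = derive_rmj_regulated(
            responsive, rmj, genes, window_bp=cfg.window_bp, anchor=cfg.anchor
        )
    elif cfg.rmj_mode == "independent":
        rmj = rmj_regions(runx1, myod, cjun)
        per_tf = [
            bound_genes(rs, genes, window_bp=cfg.window_bp, anchor=cfg.anchor)
            for rs in (runx1, myod, cjun)
        ]
        ids = responsive.gene_ids
        for bs in per_tf:
            ids = ids & bs.gene_ids
        universe = [g.gene_id for g in genes]
        k_set = per_tf[0].gene_ids & per_tf[1].gene_ids & per_tf[2].gene_ids
        p = hypergeom_tail(len(universe), len(k_set), len(responsive), len(ids))
        out = responsive.derive(
            "rmj_regulated", ids, stage="derive_rmj_regulated",
            params={"window_bp": cfg.window_bp, "mode": "independent"},
        )
        rmj_res = RmjRegulatedResult(out, p, len(universe), len(k_set), len(responsive))
    else:
        raise ValidationError(f"unknown rmj_mode {cfg.rmj_mode!r}")

    # stage IV: enhancer-state filter
    state_rmj = annotate_enhancer_state(
        rmj, region_sets["h3k4me1"], region_sets["h3k27ac"], region_sets["atac"]
    )
    state_runx1 = annotate_enhancer_state(
        runx1, region_sets["h3k4me1"], region_sets["h3k27ac"], region_sets["atac"]
    )
    hc = derive_high_confidence(
        rmj_res.genes, rmj, state_rmj, genes,
        window_bp=cfg.window_bp, anchor=cfg.anchor,
        conjunction=cfg.hc_conjunction,
        n_iter=cfg.n_iter_monte_carlo, seed=cfg.seed,
    )

    bootstrap = None
    if cfg.n_iter_bootstrap > 0:
        sizes = rcio.read_chrom_sizes(cfg.chrom_sizes)
        bootstrap = {}
        for name, query, subject in (
            ("runx1_vs_myod", runx1, myod),
            ("cjun_vs_runx1", cjun, runx1),
        ):
            res = bootstrap_overlap_test(
                query, subject, sizes, n_iter=cfg.n_iter_bootstrap, seed=cfg.seed
            )
            bootstrap[name] = {
                "observed": res.observed,
                "p_empirical": res.p_empirical,
                "n_iter": cfg.n_iter_bootstrap,
                "seed": cfg.seed,
            }

    loc = location_distribution(runx1, genes, anchor=cfg.anchor) if len(runx1) else None

    gene_sets = {
        "responsive": responsive.sorted_ids(),
        "responsive_up": up.sorted_ids(),
        "responsive_down": down.sorted_ids(),
        "bound": runx1_bound.sorted_ids(),
        "regulated": regulated.genes.sorted_ids(),
        "rmj_regulated": rmj_res.genes.sorted_ids(),
        "high_confidence": hc.genes.sorted_ids(),
    }

    n_invivo_responsive = n_invivo_up = n_invivo_down = n_in_vivo = None
    if cfg.expression_invivo:
        table_iv = rcio.read_expression_table(cfg.expression_invivo)
        up_iv, down_iv = select_responsive(
            table_iv, ThresholdSpec(cfg.q_max_invivo, cfg.fc_min_invivo), label="invivo"
        )
        responsive_iv = up_iv.union(down_iv, "invivo_responsive", stage="select_responsive")
        in_vivo = derive_in_vivo(rmj_res.genes, responsive_iv)
        n_invivo_responsive, n_invivo_up, n_invivo_down = (
            len(responsive_iv), len(up_iv), len(down_iv),
        )
        n_in_vivo = len(in_vivo)
        gene_sets["invivo_responsive"] = responsive_iv.sorted_ids()
        gene_sets["in_vivo"] = in_vivo.sorted_ids()

    sets_for_check = {k: frozenset(v) for k, v in gene_sets.items() if k in
                      ("responsive", "regulated", "rmj_regulated", "high_confidence", "in_vivo")}
    _check_nesting(sets_for_check)

    return CascadeReport(
        config=cfg.to_dict(),
        n_genes_annotation=len(genes),
        n_peaks={name: len(rs) for name, rs in region_sets.items()},
        location={
            "fractions": loc.fractions if loc else {},
            "within_100kb": loc.fraction_within_100kb if loc else None,
            "within_200kb": loc.fraction_within_200kb if loc else None,
            "n_unassigned": loc.n_unassigned if loc else None,
        },
        n_responsive=len(responsive),
        n_up=len(up),
        n_down=len(down),
        n_bound_genes=len(runx1_bound),
        n_regulated=len(regulated.genes),
        bound_fraction=regulated.bound_fraction,
        cooccupancy_fractions=coocc,
        venn3_counts=partition.to_dict(),
        n_rmj_regions=len(rmj),
        n_rmj_regulated=len(rmj_res.genes),
        p_hypergeom_rmj=rmj_res.p_hypergeom,
        enhancer_fractions={
            "runx1_active": state_runx1.fraction_active,
            "runx1_open": state_runx1.fraction_open,
            "rmj_active": state_rmj.fraction_active,
            "rmj_open": state_rmj.fraction_open,
        },
        n_high_confidence=len(hc.genes),
        p_monte_carlo_hc=hc.monte_carlo.p_empirical if hc.monte_carlo else None,
        bootstrap=bootstrap,
        gene_sets=gene_sets,
        n_invivo_responsive=n_invivo_responsive,
        n_invivo_up=n_invivo_up,
        n_invivo_down=n_invivo_down,
        n_in_vivo=n_in_vivo,
    )
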