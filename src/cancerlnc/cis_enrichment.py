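"""Enrichment of mapped transposon common-insertion sites (hCIS) in gene sets.

Common insertion sites from mouse transposon-mutagenesis screens, mapped to
orthologous human coordinates upstream (the mapping itself is consumed, not
computed), are tested for enrichment in a focal lncRNA set four ways:

* per-gene intersection counts and a Fisher test focal vs background,
* genome-partition insertion rates per megabase for five precedence-ordered
  classes (gold protein-coding > other protein-coding > focal lncRNA > other
  lncRNA > intergenic),
* a length-matched empirical null: resample background genes matching the
  focal gene-length distribution and recompute insertions per Mb,
* a relocation empirical null: randomly relocate the genes (lengths
  preserved) within the non-protein-coding genome and recount genes hitting
  at least one insertion.

Empirical p-values use the plain counting rule
``p = #{null >= observed} / n_iter`` (no pseudocount); a conservative
``(r+1)/(N+1)`` mode is available by flag.

Input filtering follows the screening conventions: insertion records longer
than 1000 bp are discarded, and (optionally) records overlapping any
protein-coding gene span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cancerlnc.genome_model import (
    GeneModel,
    GenomeLayout,
    Interval,
    IntervalSet,
    merge_intervals,
    subtract,
)
from cancerlnc.neighborhood import match_distribution

__all__ = [
    "MAX_CIS_LENGTH",
    "InsertionSite",
    "ClassRates",
    "EmpiricalNullResult",
    "read_insertion_table",
    "packaged_insertion_table_path",
    "filter_insertions",
    "genes_with_insertions",
    "set_enrichment_test",
    "class_rates",
    "insertions_per_mb",
    "length_matched_null",
    "relocation_null",
    "empirical_p",
]

MAX_CIS_LENGTH = 1000


@dataclass(frozen=True)
class InsertionSite:
    """One mapped insertion site, with optional provenance."""

    interval: Interval
    cancer_type: str = ""
    pubmed_id: str = ""
    mouse_interval: Interval | None = None


@dataclass
class EmpiricalNullResult:
    """Observed statistic, its resampling null, and the empirical p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    direction: str
    n_iter: int
    seed: int


@dataclass
class ClassRates:
    """Per-class span (bp), insertion counts and insertion rate per Mb."""

    bp: dict[str, int]
    counts: dict[str, int]

    CLASS_ORDER = ["gold_pc", "other_pc", "focal_lnc", "other_lnc", "intergenic"]

    @property
    def rates_per_mb(self) -> dict[str, float]:
        return {
            cls: self.counts[cls] / (self.bp[cls] / 1e6) if self.bp[cls] else math.nan
            for cls in self.CLASS_ORDER
        }

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.CLASS_ORDER,
                "bp": [self.bp[c] for c in self.CLASS_ORDER],
                "n_insertions": [self.counts[c] for c in self.CLASS_ORDER],
                "per_mb": [self.rates_per_mb[c] for c in self.CLASS_ORDER],
            }
        )


def packaged_insertion_table_path() -> Path:
    """Path to the packaged insertion-site fixture (human+mouse coordinates)."""
    return Path(resources.files("cancerlnc") / "data" / "insertion_sites_table1.tsv")


def read_insertion_table(path: str | Path) -> list[InsertionSite]:
    """Read an insertion-site TSV carrying human (and optionally mouse)
    coordinates, source cancer type and publication id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sites = []
    for _, row in df.iterrows():
        human = Interval(
            row["chrom_human"],
            int(row["start_human"]),
            int(row["end_human"]),
            label=row.get("gene_name", "") or "",
        )
        mouse = None
        if "chrom_mouse" in df.columns and isinstance(row.get("chrom_mouse"), str):
            mouse = Interval(
                row["chrom_mouse"], int(row["start_mouse"]), int(row["end_mouse"])
            )
        sites.append(
            InsertionSite(
                interval=human,
                cancer_type=row.get("cancer_type_mouse", "") or "",
                pubmed_id=str(row.get("pubmed_id", "") or ""),
                mouse_interval=mouse,
            )
        )
    return sites


def filter_insertions(
    raw: IntervalSet | Iterable[Interval],
    pc_spans: IntervalSet | None = None,
    max_len: int = MAX_CIS_LENGTH,
    exclude_pc: bool = True,
) -> tuple[IntervalSet, dict[str, int]]:
    """Drop insertions longer than ``max_len`` bp and, if ``exclude_pc``,
    those overlapping >=1 bp of any protein-coding gene span. Returns the kept
    set and counts at each filtering step."""
    raw = IntervalSet(raw) if not isinstance(raw, IntervalSet) else raw
    counts = {"input": len(raw)}
    kept = [iv for iv in raw if iv.length <= max_len]
    counts["after_length_filter"] = len(kept)
    if exclude_pc and pc_spans is not None:
        merged = merge_intervals(pc_spans).by_chrom()
        kept = [
            iv
            for iv in kept
            if not any(iv.start < s.end and s.start < iv.end for s in merged.get(iv.chrom, []))
        ]
    counts["after_pc_filter"] = len(kept)
    return IntervalSet(kept), counts


def _gene_span_sets(
    genes: Iterable[GeneModel],
    mask: IntervalSet | None,
) -> dict[str, IntervalSet]:
    """Per-gene span as an interval set, optionally with the mask subtracted."""
    out = {}
    for g in genes:
        spans = IntervalSet([g.span])
        if mask is not None:
            spans = subtract(spans, mask)
        out[g.gene_id] = spans
    return out


def genes_with_insertions(
    genes: Iterable[GeneModel],
    insertions: IntervalSet,
    mask_pc: bool = False,
    pc_spans: IntervalSet | None = None,
) -> pd.Series:
    """Number of insertions intersecting each gene's (optionally
    protein-coding-masked) span; half-open, >=1 bp overlap."""
    mask = pc_spans if mask_pc else None
    span_sets = _gene_span_sets(genes, mask)
    ins_by_chrom = insertions.by_chrom()
    counts = {}
    for gid, spans in span_sets.items():
        n = 0
        for ins_chrom, ins_list in ins_by_chrom.items():
            gene_ivs = [iv for iv in spans if iv.chrom == ins_chrom]
            if not gene_ivs:
                continue
            for ins in ins_list:
                if any(ins.start < iv.end and iv.start < ins.end for iv in gene_ivs):
                    n += 1
        counts[gid] = n
    return pd.Series(counts, name="n_insertions").sort_index()


def set_enrichment_test(
    focal: Iterable[GeneModel],
    background: Iterable[GeneModel],
    insertions: IntervalSet,
    mask_pc: bool = False,
    pc_spans: IntervalSet | None = None,
) -> dict:
    """Fisher test on (has >=1 insertion) x (focal / background)."""
    focal, background = list(focal), list(background)
    if not focal or not background:
        raise ValueError("empty gene set")
    f_ids = {g.gene_id for g in focal}
    b_ids = {g.gene_id for g in background}
    if f_ids & b_ids:
        raise ValueError("focal and background sets overlap")
    fc = genes_with_insertions(focal, insertions, mask_pc, pc_spans)
    bc = genes_with_insertions(background, insertions, mask_pc, pc_spans)
    a, b = int((fc >= 1).sum()), int((fc == 0).sum())
    c, d = int((bc >= 1).sum()), int((bc == 0).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "focal_with_insertion": a,
        "focal_without": b,
        "background_with_insertion": c,
        "background_without": d,
        "odds_ratio": float(odds),
        "fisher_p": float(p),
    }


def class_rates(
    layout: GenomeLayout,
    gold_pc: Iterable[GeneModel],
    other_pc: Iterable[GeneModel],
    focal_lnc: Iterable[GeneModel],
    other_lnc: Iterable[GeneModel],
    insertions: IntervalSet,
) -> ClassRates:
    """Partition the genome into five precedence-ordered classes and count
    insertions per class (each insertion assigned to the highest-precedence
    class it overlaps; intergenic if none)."""
    class_spans: dict[str, IntervalSet] = {}
    claimed: IntervalSet = IntervalSet([])
    for cls, genes in [
        ("gold_pc", gold_pc),
        ("other_pc", other_pc),
        ("focal_lnc", focal_lnc),
        ("other_lnc", other_lnc),
    ]:
        spans = []
        for g in genes:
            if g.chrom not in layout:
                raise ValueError(f"gene {g.gene_id} on chromosome missing from layout")
            spans.append(g.span)
        merged = merge_intervals(IntervalSet(spans)) if spans else IntervalSet([])
        exclusive = subtract(merged, claimed) if len(claimed) else merged
        class_spans[cls] = exclusive
        claimed = merge_intervals(IntervalSet(list(claimed) + list(merged)))

    bp = {cls: class_spans[cls].total_bp for cls in class_spans}
    bp["intergenic"] = layout.genome_size - sum(bp.values())

    by_cls_chrom = {
        cls: class_spans[cls].by_chrom() for cls in class_spans
    }
    counts = {cls: 0 for cls in ClassRates.CLASS_ORDER}
    for ins in insertions:
        assigned = "intergenic"
        for cls in ["gold_pc", "other_pc", "focal_lnc", "other_lnc"]:
            ivs = by_cls_chrom[cls].get(ins.chrom, [])
            if any(ins.start < iv.end and iv.start < ins.end for iv in ivs):
                assigned = cls
                break
        counts[assigned] += 1
    return ClassRates(bp=bp, counts=counts)


def insertions_per_mb(
    genes: Iterable[GeneModel],
    insertions: IntervalSet,
    pc_mask: IntervalSet | None = None,
) -> float:
    """Insertions intersecting the aggregate (masked) gene span, per Mb of
    that span."""
    genes = list(genes)
    spans = IntervalSet([g.span for g in genes])
    if pc_mask is not None:
        spans = subtract(spans, pc_mask)
    merged = merge_intervals(spans)
    total_bp = sum(iv.length for iv in merged)
    if total_bp == 0:
        return math.nan
    by_chrom = merged.by_chrom()
    n = sum(
        1
        for ins in insertions
        if any(
            ins.start < iv.end and iv.start < ins.end
            for iv in by_chrom.get(ins.chrom, [])
        )
    )
    return n / (total_bp / 1e6)


def empirical_p(
    observed: float, null_values: Sequence[float] | np.ndarray, direction: str = "greater",
    conservative: bool = False,
) -> float:
    """Counting empirical p: the fraction of null values at least as extreme
    as the observed statistic (``>=`` for direction "greater", ``<=`` for
    "less"); optionally the conservative (r+1)/(N+1) variant."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    if direction == "greater":
        r = int(np.sum(null_values >= observed))
    elif direction == "less":
        r = int(np.sum(null_values <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = null_values.size
    return (r + 1) / (n + 1) if conservative else r / n


def length_matched_null(
    focal: Sequence[GeneModel],
    background: Sequence[GeneModel],
    insertions: IntervalSet,
    n_iter: int = 1000,
    seed: int = 0,
    pc_mask: IntervalSet | None = None,
    n_bins: int = 20,
) -> EmpiricalNullResult:
    """Null for the focal insertion rate: resample background genes matching
    the focal gene-length distribution and recompute insertions per Mb of
    aggregate (masked) span each iteration."""
    focal, background = list(focal), list(background)
    observed = insertions_per_mb(focal, insertions, pc_mask)
    pool = {g.gene_id: float(g.gene_length) for g in background}
    target = [float(g.gene_length) for g in focal]
    by_id = {g.gene_id: g for g in background}
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_iter)
    for i in range(n_iter):
        # samples capped at |focal| genes so the null statistic has the same
        # sampling variance as the observed one
        sample = match_distribution(
            pool, target, n_bins=n_bins, seed=rng, size=len(focal)
        )
        nulls[i] = insertions_per_mb(
            [by_id[g] for g in sample.ids], insertions, pc_mask
        )
    p = empirical_p(observed, nulls, "greater")
    return EmpiricalNullResult(
        observed=observed, null_values=nulls, p_value=p,
        direction="greater", n_iter=n_iter, seed=seed,
    )


def _allowed_gaps(
    layout: GenomeLayout, excluded: IntervalSet | None
) -> list[tuple[str, int, int]]:
    gaps: list[tuple[str, int, int]] = []
    excl_by_chrom = (
        merge_intervals(excluded).by_chrom() if excluded is not None and len(excluded) else {}
    )
    for chrom in layout.chromosomes:
        pos = 0
        for iv in excl_by_chrom.get(chrom, []):
            if iv.start > pos:
                gaps.append((chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < layout[chrom]:
            gaps.append((chrom, pos, layout[chrom]))
    return gaps


def relocation_null(
    genes: Sequence[GeneModel],
    insertions: IntervalSet,
    layout: GenomeLayout,
    excluded: IntervalSet | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    same_chromosome: bool = False,
) -> EmpiricalNullResult:
    """Null for the number of genes hitting >=1 insertion: relocate each gene
    (length preserved) uniformly at random within the complement of the
    excluded regions, on any chromosome by default; relocated genes may
    overlap each other."""
    genes = list(genes)
    gaps = _allowed_gaps(layout, excluded)
    if not gaps:
        raise ValueError("no allowed space for relocation")

    ins_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in merge_intervals(insertions).by_chrom().items():
        ins_by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )

    def hits(chrom: str, start: int, end: int) -> bool:
        if chrom not in ins_by_chrom:
            return False
        starts, ends = ins_by_chrom[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    observed = sum(
        1 for g in genes if hits(g.chrom, g.span.start, g.span.end)
    )

    gap_chroms = [g[0] for g in gaps]
    gap_starts = np.array([g[1] for g in gaps])
    gap_ends = np.array([g[2] for g in gaps])
    rng = np.random.default_rng(seed)

    lengths = [g.gene_length for g in genes]
    chrom_of = [g.chrom for g in genes]
    placements: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for gi, L in enumerate(lengths):
        if same_chromosome:
            mask = np.array([c == chrom_of[gi] for c in gap_chroms])
        else:
            mask = np.ones(len(gaps), dtype=bool)
        capacity = (gap_ends - gap_starts) - L + 1
        capacity = np.where(mask, np.maximum(capacity, 0), 0)
        total = int(capacity.sum())
        if total <= 0:
            raise ValueError(
                f"gene {genes[gi].gene_id} (length {L}) does not fit in any allowed gap"
            )
        placements[gi] = (capacity, np.cumsum(capacity), np.array([total]))

    nulls = np.empty(n_iter)
    for it in range(n_iter):
        count = 0
        for gi, L in enumerate(lengths):
            capacity, cumcap, total = placements[gi]
            u = int(rng.integers(0, total[0]))
            gap_idx = int(np.searchsorted(cumcap, u, side="right"))
            offset = u - (cumcap[gap_idx - 1] if gap_idx else 0)
            start = int(gap_starts[gap_idx]) + offset
            if hits(gap_chroms[gap_idx], start, start + L):
                count += 1
        nulls[it] = count
    p = empirical_p(float(observed), nulls, "greater")
    return EmpiricalNullResult(
        observed=float(observed), null_values=nulls, p_value=p,
        direction="greater", n_iter=n_iter, seed=seed,
    )
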