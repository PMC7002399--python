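"""Feature-enrichment panel: focal vs background gene sets across genomic features.

Each comparison yields an effect size and a p-value:

* quantitative features (gene length, conservation, expression...): effect is
  the log2 fold-change of focal over background means; significance is the
  two-sided Wilcoxon rank-sum test. The asymmetry (mean-based effect,
  rank-based test) is deliberate and documented.
* qualitative features (SNP proximity, list membership, repeat-class
  overlap...): effect is the log2 odds ratio of a 2x2 table; significance is
  the two-sided Fisher exact test. A Haldane +0.5 continuity correction is
  applied to the odds ratio only when the table has a zero cell, and the row
  is flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cancerlnc.genome_model import (
    GeneModel,
    IntervalSet,
    ScoreTrack,
    coverage_fraction,
    mean_base_score,
    nearest_tss_distance,
    point_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureComparison",
    "compare_quantitative",
    "compare_qualitative",
    "tss_within_distance",
    "te_class_enrichment",
    "run_feature_panel",
    "PanelInputs",
]

SNP_DISTANCE_DEFAULT = 100_000


@dataclass
class FeatureComparison:
    """Effect size and significance of one focal-vs-background comparison."""

    feature: str
    kind: str  # "quantitative" | "qualitative"
    effect: float  # log2 fold-change of means, or log2 odds ratio
    p_value: float
    n_focal: int
    n_background: int
    region: str = ""
    flag: str = ""

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "kind": self.kind,
            "region": self.region,
            "effect": self.effect,
            "p_value": self.p_value,
            "n_focal": self.n_focal,
            "n_background": self.n_background,
            "flag": self.flag,
        }


def compare_quantitative(
    values: Mapping[str, float],
    focal: Iterable[str],
    background: Iterable[str],
    feature: str = "",
    region: str = "",
) -> FeatureComparison:
    """Two-sided Wilcoxon rank-sum on a per-gene quantitative feature.

    Effect = log2(mean focal / mean background); undefined (NaN, flagged)
    when either mean is non-positive, but the rank test is still computed.
    """
    x = np.array([values[g] for g in sorted(set(focal)) if g in values and not _isnan(values[g])])
    y = np.array([values[g] for g in sorted(set(background)) if g in values and not _isnan(values[g])])
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"{feature or 'feature'}: need >=2 non-missing values per set")
    flag = ""
    mx, my = float(np.mean(x)), float(np.mean(y))
    if mx > 0 and my > 0:
        effect = math.log2(mx / my)
    else:
        effect, flag = math.nan, "non-positive mean"
    if np.array_equal(np.sort(x), np.sort(y)):
        p = 1.0  # identical samples: no evidence of shift even with heavy ties
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return FeatureComparison(
        feature=feature, kind="quantitative", effect=effect, p_value=p,
        n_focal=len(x), n_background=len(y), region=region, flag=flag,
    )


def _isnan(v: float) -> bool:
    return isinstance(v, float) and math.isnan(v)


def odds_ratio_2x2(table: Sequence[Sequence[float]]) -> tuple[float, str]:
    """Cross-product odds ratio with Haldane +0.5 only on zero-cell tables."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), "zero cell (+0.5 correction)"
    return (a * d) / (b * c), ""


def compare_qualitative(
    flags: Mapping[str, bool],
    focal: Iterable[str],
    background: Iterable[str],
    feature: str = "",
    region: str = "",
) -> FeatureComparison:
    """Two-sided Fisher exact test on a binary per-gene feature."""
    focal = sorted(set(focal))
    background = sorted(set(background))
    if not focal or not background:
        raise ValueError(f"{feature or 'feature'}: empty gene set")
    a = sum(1 for g in focal if flags.get(g, False))
    b = len(focal) - a
    c = sum(1 for g in background if flags.get(g, False))
    d = len(background) - c
    table = [[a, b], [c, d]]
    odds, flag = odds_ratio_2x2(table)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return FeatureComparison(
        feature=feature, kind="qualitative", effect=math.log2(odds),
        p_value=float(p), n_focal=len(focal), n_background=len(background),
        region=region, flag=flag,
    )


def tss_within_distance(
    genes: Mapping[str, GeneModel],
    points: IntervalSet,
    distance: int = SNP_DISTANCE_DEFAULT,
) -> dict[str, bool]:
    """True per gene iff the nearest same-chromosome point lies within
    ``distance`` bp of the gene TSS (no point on the chromosome -> False)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    if len(points) == 0:
        return {g: False for g in genes}
    tss = {gid: (gm.chrom, gm.tss) for gid, gm in genes.items()}
    nearest = nearest_tss_distance(tss, point_map(points))
    return {
        gid: (partner is not None and dist <= distance)
        for gid, (dist, partner) in nearest.items()
    }


def te_class_enrichment(
    genes: Mapping[str, GeneModel],
    repeats: IntervalSet,
    focal: Iterable[str],
    background: Iterable[str],
) -> list[FeatureComparison]:
    """Per repeat class: does the class overlap gene TSSs (width-1 points)
    more often in the focal set than the background?"""
    classes = sorted({iv.label for iv in repeats if iv.label})
    out = []
    for cls in classes:
        cls_ivs = [iv for iv in repeats if iv.label == cls]
        by_chrom: dict[str, list] = {}
        for iv in cls_ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        flags = {}
        for gid, gm in genes.items():
            tss = gm.tss
            flags[gid] = any(
                iv.start <= tss < iv.end for iv in by_chrom.get(gm.chrom, [])
            )
        out.append(
            compare_qualitative(
                flags, focal, background, feature=f"TE:{cls}", region="TSS"
            )
        )
    return out


@dataclass
class PanelInputs:
    """Feature sources for a full panel run. Optional sources may be None;
    the corresponding rows are skipped with a logged warning."""

    genes: Mapping[str, GeneModel]
    focal: Sequence[str]
    background: Sequence[str]
    conservation_track: ScoreTrack | None = None
    conserved_elements: IntervalSet | None = None
    repeats: IntervalSet | None = None
    cancer_snps: IntervalSet | None = None
    noncancer_snps: IntervalSet | None = None
    silenced_genes: Iterable[str] | None = None
    diffexp_genes: Iterable[str] | None = None
    expression: pd.DataFrame | None = None  # genes x sample groups
    extra_numeric: Mapping[str, Mapping[str, float]] | None = None  # e.g. GC
    snp_distance: int = SNP_DISTANCE_DEFAULT


def _gene_regions(gm: GeneModel, region: str) -> IntervalSet:
    if region == "exons":
        return gm.exonic_union
    if region == "promoter":
        return IntervalSet([gm.promoter()])
    raise ValueError(f"unknown region {region!r}")


def run_feature_panel(inputs: PanelInputs) -> pd.DataFrame:
    """Run every available comparison; one row per (feature, region, group).

    Output ordering is deterministic: annotation-derived quantitative
    features, conservation, expression, then qualitative memberships and
    repeat classes.
    """
    genes, focal, background = inputs.genes, list(inputs.focal), list(inputs.background)
    rows: list[FeatureComparison] = []

    for feature, fn in [
        ("gene_length", lambda g: g.gene_length),
        ("exonic_length", lambda g: g.exonic_length),
        ("exonic_content", lambda g: g.exonic_content),
    ]:
        values = {gid: float(fn(gm)) for gid, gm in genes.items()}
        rows.append(compare_quantitative(values, focal, background, feature, "gene"))

    if inputs.extra_numeric:
        for feature in sorted(inputs.extra_numeric):
            rows.append(
                compare_quantitative(
                    inputs.extra_numeric[feature], focal, background, feature, "gene"
                )
            )

    if inputs.repeats is not None and len(inputs.repeats):
        values = {}
        for gid, gm in genes.items():
            try:
                values[gid] = coverage_fraction(gm.exonic_union, inputs.repeats)
            except ValueError:
                values[gid] = math.nan
        rows.append(
            compare_quantitative(values, focal, background, "repeats_coverage", "exons")
        )
    else:
        logger.warning("repeats source missing: skipping repeats_coverage")

    for region in ("exons", "promoter"):
        if inputs.conservation_track is not None:
            values = {
                gid: mean_base_score(_gene_regions(gm, region), inputs.conservation_track)
                for gid, gm in genes.items()
            }
            rows.append(
                compare_quantitative(
                    values, focal, background, "conservation_mean", region
                )
            )
        else:
            logger.warning("conservation track missing: skipping conservation_mean")
        if inputs.conserved_elements is not None:
            values = {
                gid: coverage_fraction(_gene_regions(gm, region), inputs.conserved_elements)
                for gid, gm in genes.items()
            }
            rows.append(
                compare_quantitative(
                    values, focal, background, "conserved_elements_coverage", region
                )
            )
        else:
            logger.warning("conserved elements missing: skipping element coverage")

    if inputs.expression is not None:
        for group in inputs.expression.columns:
            values = inputs.expression[group].to_dict()
            rows.append(
                compare_quantitative(
                    values, focal, background, f"expression:{group}", "gene"
                )
            )
    else:
        logger.warning("expression matrix missing: skipping expression rows")

    for feature, points in [
        ("cancer_snp_within_100kb", inputs.cancer_snps),
        ("noncancer_snp_within_100kb", inputs.noncancer_snps),
    ]:
        if points is None:
            logger.warning("%s source missing: skipped", feature)
            continue
        flags = tss_within_distance(genes, points, inputs.snp_distance)
        rows.append(compare_qualitative(flags, focal, background, feature, "TSS"))

    for feature, members in [
        ("epigenetically_silenced", inputs.silenced_genes),
        ("differentially_expressed", inputs.diffexp_genes),
    ]:
        if members is None:
            logger.warning("%s list missing: skipped", feature)
            continue
        members = set(members)
        flags = {gid: gid in members for gid in genes}
        rows.append(compare_qualitative(flags, focal, background, feature, "gene"))

    if inputs.repeats is not None and len(inputs.repeats):
        rows.extend(te_class_enrichment(genes, inputs.repeats, focal, background))

    return pd.DataFrame([r.as_dict() for r in rows])
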