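"""Genomic neighbourhood of lncRNAs: proximity, orientation, matched controls,
and coexpression with empirical nulls.

The module implements four related pieces:

* distribution-matched resampling (``match_distribution``): draw a subset of a
  background pool whose distribution over a covariate (gene length, TSS-TSS
  distance, conservation, expression...) matches a target set, using quantile
  bins of the target. This is the workhorse control for every "matched
  background" comparison in the pipeline.
* orientation classification of each lncRNA relative to its closest
  protein-coding gene, a seven-way partition: overlapping (sense/antisense),
  divergent (head-to-head promoters), convergent (3' ends facing), same-strand
  with the protein-coding gene up- or downstream, and intergenic (no
  protein-coding gene within 10 kb).
* enrichment of gold-standard partners among divergent lncRNAs.
* per-sample Pearson coexpression of lncRNA/protein-coding gene pairs
  (TSS-TSS < 200 kb) with two controls: distance-matched control pairs and a
  shuffled-pairing empirical null.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cancerlnc.genome_model import GeneModel

__all__ = [
    "GENIC_DISTANCE",
    "PAIR_DISTANCE",
    "CLASS_PRECEDENCE",
    "MatchedSample",
    "GenomicClass",
    "match_distribution",
    "select_pf_subset",
    "classify_transcript",
    "classify_gene",
    "classify_all",
    "divergent_partner_enrichment",
    "pair_correlation",
    "build_pairs",
    "distance_matched_control_pairs",
    "shuffled_pair_null",
    "ShuffledPairNull",
]

GENIC_DISTANCE = 10_000  # genic vs intergenic threshold (bp)
PAIR_DISTANCE = 200_000  # TSS-TSS threshold for coexpression pairs (bp)

CLASS_PRECEDENCE = [
    "overlapping_sense",
    "overlapping_antisense",
    "divergent",
    "convergent",
    "samestrand_pc_up",
    "samestrand_pc_down",
    "intergenic",
]


# ---------------------------------------------------------------------------
# Distribution-matched sampling


@dataclass
class MatchedSample:
    """A subset of a pool matched to a target distribution by quantile bins."""

    ids: list[str]
    bin_edges: np.ndarray
    target_proportions: np.ndarray
    achieved_proportions: np.ndarray
    dropped_bins: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)


def _quantile_bins(target: np.ndarray, n_bins: int) -> np.ndarray:
    """Open-ended quantile bin edges of the target (duplicates collapsed).

    Edges are anchored at observed target values (no interpolation), so every
    interior bin contains at least one target value even when the target is
    smaller than the bin count; interpolated edges would create zero-weight
    bins whose pool members could never be sampled.
    """
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    inner = np.unique(np.quantile(target, qs, method="lower"))
    return np.concatenate([[-np.inf], inner, [np.inf]])


def match_distribution(
    pool: Mapping[str, float],
    target: Sequence[float] | np.ndarray,
    n_bins: int = 20,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> MatchedSample:
    """Sample pool ids (without replacement) to match the target distribution.

    Bins are quantile bins of the target (outermost bins open-ended so every
    pool value is assignable). The total sample size is the largest N such
    that every bin's demand ``ceil(N * p_bin)`` is available in the pool,
    optionally capped at ``size`` (resampling nulls cap at the focal set
    size, so the null statistic carries the focal statistic's sampling
    variance); a target bin with no pool candidates is dropped with a warning
    and N recomputed over the remaining bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    target = np.asarray(target, dtype=float)
    if target.size == 0:
        raise ValueError("empty target")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges = _quantile_bins(target, n_bins)
    nb = len(edges) - 1
    t_bin = np.clip(np.searchsorted(edges, target, side="right") - 1, 0, nb - 1)
    p = np.bincount(t_bin, minlength=nb) / target.size

    pool_ids = sorted(pool)
    pool_vals = np.array([pool[i] for i in pool_ids], dtype=float)
    g_bin = np.clip(np.searchsorted(edges, pool_vals, side="right") - 1, 0, nb - 1)
    avail = np.bincount(g_bin, minlength=nb)

    dropped = [b for b in range(nb) if p[b] > 0 and avail[b] == 0]
    if dropped:
        warnings.warn(
            f"{len(dropped)} target bin(s) have no pool candidates; dropped",
            stacklevel=2,
        )
        p = p.copy()
        p[dropped] = 0.0
        if p.sum() == 0:
            raise ValueError("no target bin has pool candidates")
        p = p / p.sum()

    active = np.flatnonzero(p > 0)
    n_max = int(np.floor(np.min(avail[active] / p[active])))
    while n_max > 0 and np.any(np.ceil(n_max * p[active]) > avail[active]):
        n_max -= 1
    if size is not None:
        n_max = min(n_max, size)

    # largest-remainder allocation: per-bin demands sum exactly to N (the
    # ceil rule above only determines feasibility), capped by availability
    raw = n_max * p[active]
    demands = np.floor(raw).astype(int)
    remainder = n_max - int(demands.sum())
    if remainder > 0:
        frac_order = np.argsort(-(raw - demands), kind="stable")
        for j in frac_order:
            if remainder == 0:
                break
            if demands[j] < avail[active][j]:
                demands[j] += 1
                remainder -= 1
    ids: list[str] = []
    for b, demand in zip(active, demands):
        if demand == 0:
            continue
        members = [pool_ids[i] for i in np.flatnonzero(g_bin == b)]
        take = rng.choice(len(members), size=min(int(demand), len(members)), replace=False)
        ids.extend(members[i] for i in sorted(take))

    achieved = np.bincount(
        np.clip(
            np.searchsorted(edges, [pool[i] for i in ids], side="right") - 1, 0, nb - 1
        ),
        minlength=nb,
    ) / max(len(ids), 1)
    return MatchedSample(
        ids=ids,
        bin_edges=edges,
        target_proportions=p,
        achieved_proportions=achieved,
        dropped_bins=dropped,
    )


def select_pf_subset(
    background: Iterable[str],
    conservation: Mapping[str, float],
    expression: Mapping[str, float],
    reference: Iterable[str],
    seed: int = 0,
    n_bins: int = 20,
    min_size: int = 10,
) -> list[str]:
    """Two-stage matched subsampling of background genes: first match the
    reference's conservation distribution, then (within that subset) its
    expression distribution — the "potentially functional" background."""
    background = [g for g in background if g in conservation and g in expression]
    reference = list(reference)
    rng = np.random.default_rng(seed)
    stage1 = match_distribution(
        {g: conservation[g] for g in background},
        [conservation[g] for g in reference],
        n_bins=n_bins,
        seed=rng,
    )
    stage2 = match_distribution(
        {g: expression[g] for g in stage1.ids},
        [expression[g] for g in reference],
        n_bins=n_bins,
        seed=rng,
    )
    if len(stage2.ids) < min_size:
        raise ValueError(
            f"matched subset too small ({len(stage2.ids)} < {min_size})"
        )
    return stage2.ids


# ---------------------------------------------------------------------------
# Orientation classification


@dataclass(frozen=True)
class GenomicClass:
    """Orientation class of one lncRNA gene relative to protein-coding genes."""

    gene_id: str
    genomic_class: str
    partner: str | None
    tss_distance: float


def _pc_table(pc_genes: Iterable[GeneModel]) -> dict[str, list[tuple]]:
    by_chrom: dict[str, list[tuple]] = {}
    for g in pc_genes:
        span = g.span
        by_chrom.setdefault(g.chrom, []).append(
            (span.start, span.end, g.strand, g.tss, g.gene_id)
        )
    for entries in by_chrom.values():
        entries.sort(key=lambda e: (e[0], e[4]))
    return by_chrom


def classify_transcript(
    span_start: int,
    span_end: int,
    strand: str,
    chrom: str,
    pc_by_chrom: Mapping[str, list[tuple]],
    genic_distance: int = GENIC_DISTANCE,
) -> tuple[str, str | None, float]:
    """Classify one transcript span; returns (class, partner id, TSS distance)."""
    tss = span_start if strand != "-" else span_end - 1
    entries = pc_by_chrom.get(chrom, [])

    # 1. span overlap with a protein-coding gene
    best_overlap = None
    for s, e, pstrand, ptss, pid in entries:
        ov = min(e, span_end) - max(s, span_start)
        if ov > 0:
            cand = (-ov, pid)
            if best_overlap is None or cand < best_overlap[0]:
                best_overlap = (cand, pstrand, ptss, pid)
    if best_overlap is not None:
        _, pstrand, ptss, pid = best_overlap
        cls = "overlapping_sense" if pstrand == strand else "overlapping_antisense"
        return cls, pid, float(abs(ptss - tss))

    # nearest by TSS-TSS and minimum span gap
    nearest = None
    span_gap_min = math.inf
    for s, e, pstrand, ptss, pid in entries:
        d = abs(ptss - tss)
        cand = (d, pid, pstrand, ptss)
        if nearest is None or cand < nearest:
            nearest = cand
        gap = max(s - span_end, span_start - e, 0)
        span_gap_min = min(span_gap_min, gap)

    # 2. intergenic: nothing close by either measure
    if nearest is None or (nearest[0] > genic_distance and span_gap_min > genic_distance):
        return "intergenic", None, float("nan") if nearest is None else float(nearest[0])

    d, pid, pstrand, ptss = nearest
    # 3. orientation of the nearest protein-coding gene
    if pstrand != strand:
        # divergent: partner TSS on the 5' side of the lncRNA TSS (promoters
        # back to back, transcription pointing apart); otherwise convergent
        upstream = ptss <= tss if strand != "-" else ptss >= tss
        cls = "divergent" if upstream else "convergent"
    else:
        upstream = ptss < tss if strand != "-" else ptss > tss
        cls = "samestrand_pc_up" if upstream else "samestrand_pc_down"
    return cls, pid, float(d)


def classify_gene(
    lnc: GeneModel,
    pc_genes: Iterable[GeneModel] | Mapping[str, list[tuple]],
    genic_distance: int = GENIC_DISTANCE,
) -> GenomicClass:
    """Gene-level class: the modal class over transcripts; ties resolve by
    the fixed precedence order (overlap > divergent > convergent >
    same-strand > intergenic)."""
    pc_by_chrom = (
        pc_genes if isinstance(pc_genes, Mapping) else _pc_table(pc_genes)
    )
    if not pc_by_chrom:
        raise ValueError("protein-coding set is empty")
    per_tx = [
        classify_transcript(
            t.span.start, t.span.end, t.strand, t.chrom, pc_by_chrom, genic_distance
        )
        for t in lnc.transcripts
    ]
    votes = Counter(cls for cls, _, _ in per_tx)
    top = max(votes.values())
    winner = min(
        (cls for cls, n in votes.items() if n == top),
        key=CLASS_PRECEDENCE.index,
    )
    # partner/distance from the first transcript voting for the winner
    for cls, pid, d in per_tx:
        if cls == winner:
            return GenomicClass(lnc.gene_id, winner, pid, d)
    raise AssertionError("unreachable")


def classify_all(
    lncs: Iterable[GeneModel],
    pc_genes: Iterable[GeneModel],
    genic_distance: int = GENIC_DISTANCE,
) -> pd.DataFrame:
    pc_by_chrom = _pc_table(pc_genes)
    rows = [classify_gene(l, pc_by_chrom, genic_distance) for l in lncs]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "genomic_class": [r.genomic_class for r in rows],
            "partner": [r.partner for r in rows],
            "tss_distance": [r.tss_distance for r in rows],
        }
    )


def divergent_partner_enrichment(
    classes: pd.DataFrame,
    gold_pc: Iterable[str],
    focal: Iterable[str],
    background: Iterable[str],
) -> dict:
    """Among divergent lncRNAs of each set, the fraction whose partner is a
    gold-standard protein-coding gene, with a two-sided Fisher test."""
    gold = set(gold_pc)
    div = classes[classes["genomic_class"] == "divergent"]
    res: dict = {}
    counts = {}
    for name, ids in (("focal", set(focal)), ("background", set(background))):
        sub = div[div["gene_id"].isin(ids)]
        n = len(sub)
        k = int(sub["partner"].isin(gold).sum())
        res[f"{name}_divergent"] = n
        res[f"{name}_divergent_to_gold"] = k
        res[f"{name}_fraction"] = k / n if n else math.nan
        if n == 0:
            res.setdefault("flags", []).append(f"no divergent genes in {name} set")
        counts[name] = (k, n - k)
    table = [list(counts["focal"]), list(counts["background"])]
    if min(counts["focal"][0] + counts["focal"][1], counts["background"][0] + counts["background"][1]) > 0:
        from cancerlnc.feature_panel import odds_ratio_2x2

        odds, flag = odds_ratio_2x2(table)
        _, p = stats.fisher_exact(table, alternative="two-sided")
        res["odds_ratio"], res["fisher_p"] = float(odds), float(p)
        if flag:
            res.setdefault("flags", []).append(flag)
    else:
        res["odds_ratio"], res["fisher_p"] = math.nan, math.nan
    return res


# ---------------------------------------------------------------------------
# Coexpression and its nulls


def build_pairs(
    lncs: Iterable[GeneModel],
    pc_genes: Iterable[GeneModel],
    max_distance: int = PAIR_DISTANCE,
) -> pd.DataFrame:
    """All (lncRNA, closest protein-coding partner) pairs with TSS-TSS
    distance under the pairing threshold."""
    from cancerlnc.genome_model import gene_tss_map, nearest_tss_distance

    lncs = list(lncs)
    pc_tss = gene_tss_map(pc_genes)
    nearest = nearest_tss_distance(gene_tss_map(lncs), pc_tss)
    rows = []
    for lnc in lncs:
        d, partner = nearest[lnc.gene_id]
        if partner is not None and d < max_distance:
            rows.append((lnc.gene_id, partner, d))
    return pd.DataFrame(rows, columns=["lnc_id", "pc_id", "tss_distance"])


def _transform(mat: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(mat + 1.0)
    if transform == "raw":
        return mat
    raise ValueError(f"unknown transform {transform!r}")


def pair_correlation(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    transform: str = "log2p1",
) -> pd.Series:
    """Per-sample Pearson correlation between lncRNA and partner expression
    across pairs (default transform log2(x+1)). Samples where either vector
    has zero variance yield NaN."""
    usable = pairs[
        pairs["lnc_id"].isin(expression.index) & pairs["pc_id"].isin(expression.index)
    ]
    if len(usable) < 3:
        raise ValueError("need >=3 pairs with expression for both members")
    x = _transform(expression.loc[usable["lnc_id"]].to_numpy(dtype=float), transform)
    y = _transform(expression.loc[usable["pc_id"]].to_numpy(dtype=float), transform)
    out = {}
    for j, sample in enumerate(expression.columns):
        xv, yv = x[:, j], y[:, j]
        if np.std(xv) == 0 or np.std(yv) == 0:
            out[sample] = math.nan
            continue
        out[sample] = float(stats.pearsonr(xv, yv).statistic)
    return pd.Series(out, name="pearson_r")


def distance_matched_control_pairs(
    observed: pd.DataFrame,
    candidate_lncs: Iterable[GeneModel],
    pc_partners: Iterable[GeneModel],
    seed: int = 0,
    max_distance: int = PAIR_DISTANCE,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Control pairs drawn from candidate lncRNAs and the same protein-coding
    partners, matching the observed TSS-TSS distance distribution."""
    observed_lncs = set(observed["lnc_id"])
    candidates = [g for g in candidate_lncs if g.gene_id not in observed_lncs]
    partners = {g.gene_id: g for g in pc_partners}
    # pool: every candidate lncRNA paired with its nearest observed partner
    pool_pairs = build_pairs(candidates, partners.values(), max_distance)
    if pool_pairs.empty:
        warnings.warn("no candidate pairs within distance threshold", stacklevel=2)
        return pool_pairs
    pool = dict(zip(pool_pairs["lnc_id"], pool_pairs["tss_distance"]))
    sample = match_distribution(
        pool, observed["tss_distance"].to_numpy(), n_bins=n_bins, seed=seed,
        size=len(observed),
    )
    return pool_pairs[pool_pairs["lnc_id"].isin(set(sample.ids))].reset_index(drop=True)


@dataclass
class ShuffledPairNull:
    """Observed per-sample correlations vs a shuffled-pairing null."""

    observed: pd.Series
    null_values: np.ndarray  # (n_iter, n_samples)
    ks_statistic: float
    ks_p: float  # pooled: observed per-sample r vs all null r values
    n_iter: int
    seed: int

    @property
    def pooled_null(self) -> np.ndarray:
        vals = self.null_values.ravel()
        return vals[~np.isnan(vals)]


def shuffled_pair_null(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
    transform: str = "log2p1",
) -> ShuffledPairNull:
    """Empirical null for pair coexpression: permute the partner assignment
    (within the same partner set, preserving samples) ``n_iter`` times and
    recompute every per-sample correlation; compare observed vs pooled null
    with a two-sample KS test."""
    rng = np.random.default_rng(seed)
    observed = pair_correlation(pairs, expression, transform)
    partners = pairs["pc_id"].to_numpy()
    nulls = np.full((n_iter, expression.shape[1]), np.nan)
    shuffled = pairs.copy()
    for i in range(n_iter):
        shuffled["pc_id"] = rng.permutation(partners)
        nulls[i] = pair_correlation(shuffled, expression, transform).to_numpy()
    obs_vals = observed.dropna().to_numpy()
    pooled = nulls.ravel()
    pooled = pooled[~np.isnan(pooled)]
    ks = stats.ks_2samp(obs_vals, pooled)
    return ShuffledPairNull(
        observed=observed,
        null_values=nulls,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        n_iter=n_iter,
        seed=seed,
    )
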