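"""Seeded generator of a miniature genome plus companion datasets with planted
effects, so every pipeline stage can be exercised end-to-end without any
external download.

The generator emulates the statistical structure the pipeline is designed to
detect. A focal ("census") subset of lncRNAs is planted with the features the
real census displays against background lncRNAs:

* longer genes (a length multiplier),
* placement near gold-standard protein-coding genes, with an excess of
  divergent (head-to-head) orientation,
* more conserved exons/promoters, higher expression,
* germline-SNP proximity, a TSS repeat-class preference,
* a higher density of insertion sites within their spans,
* lower q-values in ranked driver predictions.

Every artefact type draws from its own RNG stream (derived from the master
seed with a fixed stream index), so adding a generator never perturbs the
output of existing ones, and regenerating with the same config is
byte-identical.

Genes are placed without mutual overlap (single-transcript by default; a
multi-transcript mode exercises the majority-vote orientation rule), which
keeps score tracks well-defined. The generator does not attempt
sequence-level realism, mutation spectra or tumour evolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from cancerlnc.genome_model import (
    GeneModel,
    GenomeLayout,
    Interval,
    IntervalSet,
    Transcript,
    merge_intervals,
    subtract,
    write_bed,
    write_gtf,
)

__all__ = ["SimulationConfig", "SyntheticBundle", "generate_bundle"]

# fixed RNG stream indices per artefact type
_STREAMS = {
    "genome": 1,
    "snps": 2,
    "conservation": 3,
    "repeats": 4,
    "expression": 5,
    "insertions": 6,
    "predictions": 7,
    "census": 8,
}


@dataclass
class SimulationConfig:
    """All planted effects and sizes of the synthetic study.

    Defaults are the documented strong-effect configuration: each module's
    headline statistic should point in the planted direction. Setting the
    multipliers/probabilities to their background values (1.0 / equal
    probabilities / equal rates) yields an effect-free genome for null
    calibration.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 10_000_000

    # annotation
    n_pc_genes: int = 400
    gold_pc_fraction: float = 0.1
    n_lnc_genes: int = 400
    census_fraction: float = 0.1
    pc_mean_length: float = 20_000.0
    lnc_mean_length: float = 8_000.0
    length_sigma: float = 0.5  # log-normal shape for gene lengths
    census_length_multiplier: float = 3.0
    census_prox_prob: float = 0.5  # P(census lncRNA placed near a gold pc gene)
    proximity_distance: int = 50_000
    divergent_prob_census: float = 0.3
    divergent_prob_background: float = 0.05
    multi_transcript: bool = False
    n_exons_max: int = 4

    # SNP catalogues
    n_cancer_snps: int = 300
    n_noncancer_snps: int = 600
    snp_prox_prob: float = 0.5  # P(cancer SNP planted near a census TSS)
    snp_window: int = 100_000

    # conservation
    cons_mean_census: float = 0.5
    cons_mean_background: float = 0.15

    # repeats
    te_classes: tuple[str, ...] = ("Simple_repeat", "LINE", "SINE", "LTR")
    te_tss_prob_census: float = 0.5  # Simple_repeat at census TSSs
    te_tss_prob_background: float = 0.05
    n_random_repeats: int = 400

    # expression
    n_samples: int = 11
    expr_log_mean: float = 4.0  # natural-log scale
    expr_log_sigma: float = 1.5
    census_expression_multiplier: float = 4.0
    pair_target_r: float = 0.7  # planted per-sample coexpression of pairs
    pair_distance: int = 200_000

    # insertion sites
    cis_rate_focal: float = 20.0  # insertions per Mb inside census spans
    cis_rate_background: float = 0.5  # per Mb elsewhere outside pc genes
    cis_max_length: int = 1000

    # predictions: true drivers get FDR q-values far below the 0.1 cutoff,
    # so the low-q law is strongly concentrated near zero
    n_cohorts: int = 3
    prediction_pi: float = 0.8  # P(census gene draws from the low-q law)
    q_beta_a: float = 1.0
    q_beta_b: float = 500.0

    def validate(self) -> None:
        probs = [
            self.gold_pc_fraction, self.census_fraction, self.census_prox_prob,
            self.divergent_prob_census, self.divergent_prob_background,
            self.snp_prox_prob, self.te_tss_prob_census,
            self.te_tss_prob_background, self.prediction_pi,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.cis_rate_focal < 0 or self.cis_rate_background < 0:
            raise ValueError("insertion rates must be >= 0")
        if min(self.pc_mean_length, self.lnc_mean_length, self.chromosome_length) <= 0:
            raise ValueError("lengths must be positive")

    def rng(self, artefact: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[artefact]])

    @classmethod
    def effect_free(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A configuration with every planted effect switched off: the focal
        set is statistically indistinguishable from the background. Used for
        null calibration of the resampling tests."""
        neutral = dict(
            census_length_multiplier=1.0,
            census_prox_prob=0.0,
            divergent_prob_census=cls.divergent_prob_background,
            snp_prox_prob=0.0,
            cons_mean_census=cls.cons_mean_background,
            te_tss_prob_census=cls.te_tss_prob_background,
            census_expression_multiplier=1.0,
            pair_target_r=0.0,
            cis_rate_focal=cls.cis_rate_background,
            prediction_pi=0.0,
        )
        neutral.update(overrides)
        return cls(seed=seed, **neutral)


@dataclass
class SyntheticBundle:
    """In-memory synthetic study: annotation, tracks, matrices and truth."""

    config: SimulationConfig
    layout: GenomeLayout
    genes: dict[str, GeneModel]
    pc_ids: list[str]
    gold_pc_ids: list[str]
    lnc_ids: list[str]
    census_ids: list[str]
    cancer_snps: IntervalSet = field(default_factory=IntervalSet)
    noncancer_snps: IntervalSet = field(default_factory=IntervalSet)
    conservation_records: list[tuple[str, int, int, float]] = field(default_factory=list)
    conserved_elements: IntervalSet = field(default_factory=IntervalSet)
    repeats: IntervalSet = field(default_factory=IntervalSet)
    expression: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None
    insertions: IntervalSet = field(default_factory=IntervalSet)
    predictions: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    @property
    def pc_genes(self) -> list[GeneModel]:
        return [self.genes[g] for g in self.pc_ids]

    @property
    def lnc_genes(self) -> list[GeneModel]:
        return [self.genes[g] for g in self.lnc_ids]

    @property
    def pc_spans(self) -> IntervalSet:
        return IntervalSet([self.genes[g].span for g in self.pc_ids])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artefact in the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in self.layout.lengths.items():
                fh.write(f"{chrom}\t{size}\n")

        paths["gtf"] = outdir / "annotation.gtf"
        write_gtf(self.genes, paths["gtf"])

        for name, ivs in [
            ("cancer_snps", self.cancer_snps),
            ("noncancer_snps", self.noncancer_snps),
            ("conserved_elements", self.conserved_elements),
            ("repeats", self.repeats),
            ("insertions", self.insertions),
        ]:
            paths[name] = outdir / f"{name}.bed"
            write_bed(ivs, paths[name])

        paths["conservation"] = outdir / "conservation.bedgraph"
        with open(paths["conservation"], "w") as fh:
            for chrom, start, end, value in self.conservation_records:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")

        if self.expression is not None:
            paths["expression"] = outdir / "expression.tsv"
            self.expression.round(4).to_csv(paths["expression"], sep="\t")
        if self.predictions is not None:
            paths["predictions"] = outdir / "predictions.tsv"
            self.predictions.to_csv(paths["predictions"], sep="\t", index=False)

        paths["census"] = outdir / "census.tsv"
        self._write_census(paths["census"])

        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths

    def _write_census(self, path: Path) -> None:
        rng = self.config.rng("census")
        cancer_types = ["breast", "liver", "lung", "colorectal", "leukaemia"]
        roles = ["oncogene", "tumour_suppressor", "both"]
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tgene_name\tbiotype\trole\tcancer_types\tevidence_classes\treference\n"
            )
            for gid in self.census_ids:
                k = int(rng.integers(1, 4))
                types = sorted(
                    rng.choice(cancer_types, size=k, replace=False).tolist()
                )
                role = roles[int(rng.integers(0, 3)) if k > 1 else 0]
                evidence = ["t"] + (["v"] if rng.random() < 0.3 else [])
                fh.write(
                    f"{gid}\t{self.genes[gid].name}\tlncRNA\t{role}\t"
                    f"{','.join(types)}\t{','.join(evidence)}\tsynthetic\n"
                )


# ---------------------------------------------------------------------------
# Annotation


def _make_exons(
    chrom: str, start: int, length: int, strand: str, rng: np.random.Generator,
    n_exons_max: int,
) -> tuple[Interval, ...]:
    """2..n_exons_max exons inside [start, start+length), first/last anchored
    so the span equals the requested length."""
    end = start + length
    n_exons = int(rng.integers(2, n_exons_max + 1)) if length >= 400 else 1
    if n_exons == 1:
        return (Interval(chrom, start, end, strand),)
    # cut the span into 2*n_exons-1 alternating exon/intron blocks
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append(Interval(chrom, start + int(bounds[i]), start + int(bounds[i + 1]), strand))
    return tuple(exons)


def _single_gene(
    gid: str, name: str, biotype: str, chrom: str, start: int, length: int,
    strand: str, rng: np.random.Generator, cfg: SimulationConfig,
) -> GeneModel:
    exons = _make_exons(chrom, start, length, strand, rng, cfg.n_exons_max)
    txs = [Transcript(f"{gid}.t1", gid, strand, exons)]
    if cfg.multi_transcript and len(exons) > 1 and rng.random() < 0.5:
        # a second transcript using a subset of exons (same span not required)
        keep = sorted(
            rng.choice(len(exons), size=max(1, len(exons) - 1), replace=False)
        )
        txs.append(
            Transcript(f"{gid}.t2", gid, strand, tuple(exons[i] for i in keep))
        )
    return GeneModel(gid, name, biotype, tuple(txs))


class _Placer:
    """Tracks occupied spans per chromosome; rejection-samples free slots."""

    def __init__(self, layout: GenomeLayout):
        self.layout = layout
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in layout.chromosomes
        }

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.layout[chrom]:
            return False
        return not any(s < end and start < e for s, e in self.occupied[chrom])

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place_uniform(
        self, length: int, rng: np.random.Generator, max_tries: int = 200
    ) -> tuple[str, int]:
        chroms = self.layout.chromosomes
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, self.layout[chrom] - length))
            if self.is_free(chrom, start, start + length):
                self.claim(chrom, start, start + length)
                return chrom, start
        raise ValueError(
            f"infeasible packing: could not place a gene of length {length}"
        )


def generate_genome(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate the annotation half of the bundle: layout, protein-coding and
    lncRNA genes with planted length/proximity/orientation effects, and the
    truth record of every planted latent."""
    cfg.validate()
    rng = cfg.rng("genome")
    layout = GenomeLayout(
        {f"chr{i + 1}": cfg.chromosome_length for i in range(cfg.n_chromosomes)}
    )
    placer = _Placer(layout)
    genes: dict[str, GeneModel] = {}

    def draw_length(mean: float) -> int:
        mu = math.log(mean) - cfg.length_sigma**2 / 2
        return max(300, int(rng.lognormal(mu, cfg.length_sigma)))

    # protein-coding genes
    pc_ids, gold_pc_ids = [], []
    n_gold = int(round(cfg.n_pc_genes * cfg.gold_pc_fraction))
    for i in range(cfg.n_pc_genes):
        gid = f"PC{i + 1:05d}"
        L = draw_length(cfg.pc_mean_length)
        chrom, start = placer.place_uniform(L, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        genes[gid] = _single_gene(
            gid, gid, "protein_coding", chrom, start, L, strand, rng, cfg
        )
        pc_ids.append(gid)
        if i < n_gold:
            gold_pc_ids.append(gid)

    pc_tss = {g: (genes[g].chrom, genes[g].tss, genes[g].strand, genes[g].span) for g in pc_ids}

    def place_divergent(partner: str, L: int) -> tuple[str, int, str] | None:
        chrom, _tss, pstrand, span = pc_tss[partner]
        gap = int(rng.integers(200, 2000))
        if pstrand == "+":
            end = span.start - gap
            start = end - L
            strand = "-"
        else:
            start = span.end - 1 + gap
            end = start + L
            strand = "+"
        if start >= 0 and end <= layout[chrom] and placer.is_free(chrom, start, end):
            placer.claim(chrom, start, end)
            return chrom, start, strand
        return None

    def place_near(partner: str, L: int) -> tuple[str, int, str] | None:
        chrom, tss, _s, _span = pc_tss[partner]
        for _ in range(50):
            offset = int(rng.integers(-cfg.proximity_distance, cfg.proximity_distance))
            strand = "+" if rng.random() < 0.5 else "-"
            start = tss + offset if strand == "+" else tss + offset - L + 1
            if 0 <= start and start + L <= layout[chrom] and placer.is_free(chrom, start, start + L):
                placer.claim(chrom, start, start + L)
                return chrom, start, strand
        return None

    lnc_ids, census_ids = [], []
    divergent_planted: list[str] = []
    n_census = int(round(cfg.n_lnc_genes * cfg.census_fraction))
    for i in range(cfg.n_lnc_genes):
        gid = f"LNC{i + 1:05d}"
        is_census = i < n_census
        mean_len = cfg.lnc_mean_length * (
            cfg.census_length_multiplier if is_census else 1.0
        )
        L = draw_length(mean_len)
        div_prob = (
            cfg.divergent_prob_census if is_census else cfg.divergent_prob_background
        )
        placed = None
        strandinfo = None
        if rng.random() < div_prob:
            pool = gold_pc_ids if is_census else pc_ids
            partner = pool[int(rng.integers(0, len(pool)))]
            strandinfo = place_divergent(partner, L)
            if strandinfo is not None:
                divergent_planted.append(gid)
        if strandinfo is None and is_census and rng.random() < cfg.census_prox_prob:
            partner = gold_pc_ids[int(rng.integers(0, len(gold_pc_ids)))]
            strandinfo = place_near(partner, L)
        if strandinfo is None:
            chrom, start = placer.place_uniform(L, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            strandinfo = (chrom, start, strand)
        chrom, start, strand = strandinfo
        genes[gid] = _single_gene(gid, gid, "lncRNA", chrom, start, L, strand, rng, cfg)
        lnc_ids.append(gid)
        if is_census:
            census_ids.append(gid)

    bundle = SyntheticBundle(
        config=cfg,
        layout=layout,
        genes=genes,
        pc_ids=pc_ids,
        gold_pc_ids=gold_pc_ids,
        lnc_ids=lnc_ids,
        census_ids=census_ids,
    )
    bundle.truth = {
        "seed": cfg.seed,
        "census_ids": census_ids,
        "gold_pc_ids": gold_pc_ids,
        "divergent_planted": divergent_planted,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, (list, tuple))
        },
    }
    return bundle


# ---------------------------------------------------------------------------
# Companion artefacts


def generate_snps(bundle: SyntheticBundle) -> None:
    cfg = bundle.config
    rng = cfg.rng("snps")
    layout = bundle.layout
    chroms = layout.chromosomes

    def uniform_point() -> tuple[str, int]:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        return chrom, int(rng.integers(0, layout[chrom] - 1))

    cancer = []
    census_tss = [
        (bundle.genes[g].chrom, bundle.genes[g].tss) for g in bundle.census_ids
    ]
    for i in range(cfg.n_cancer_snps):
        if census_tss and rng.random() < cfg.snp_prox_prob:
            chrom, tss = census_tss[int(rng.integers(0, len(census_tss)))]
            pos = int(
                np.clip(
                    tss + rng.integers(-cfg.snp_window, cfg.snp_window),
                    0,
                    layout[chrom] - 2,
                )
            )
        else:
            chrom, pos = uniform_point()
        cancer.append(Interval(chrom, pos, pos + 1, label=f"csnp{i}"))
    noncancer = []
    for i in range(cfg.n_noncancer_snps):
        chrom, pos = uniform_point()
        noncancer.append(Interval(chrom, pos, pos + 1, label=f"nsnp{i}"))
    bundle.cancer_snps = IntervalSet(cancer)
    bundle.noncancer_snps = IntervalSet(noncancer)


def generate_conservation(bundle: SyntheticBundle) -> None:
    """Per-exon and per-promoter conservation scores: census genes draw from a
    higher mean; conserved elements cover each exon proportionally to its
    score. Scores outside annotated regions are missing (0)."""
    cfg = bundle.config
    rng = cfg.rng("conservation")
    records: list[tuple[str, int, int, float]] = []
    elements: list[Interval] = []
    census = set(bundle.census_ids)
    for gid in bundle.lnc_ids + bundle.pc_ids:
        gene = bundle.genes[gid]
        mean = cfg.cons_mean_census if gid in census else cfg.cons_mean_background
        if gene.biotype == "protein_coding":
            mean = 0.6  # protein-coding exons are strongly conserved
        regions = list(gene.exonic_union) + [gene.promoter(bundle.layout)]
        for iv in regions:
            score = float(np.clip(rng.normal(mean, 0.1), 0.0, 1.0))
            records.append((iv.chrom, iv.start, iv.end, score))
            cov = int(iv.length * score)
            if cov > 0:
                elements.append(Interval(iv.chrom, iv.start, iv.start + cov))
    # promoters may abut/overlap exon records of the same gene or neighbours;
    # resolve overlaps by clipping against what is already recorded
    records.sort()
    clipped: list[tuple[str, int, int, float]] = []
    last_end: dict[str, int] = {}
    for chrom, start, end, score in records:
        start = max(start, last_end.get(chrom, 0))
        if start < end:
            clipped.append((chrom, start, end, score))
            last_end[chrom] = end
    bundle.conservation_records = clipped
    bundle.conserved_elements = merge_intervals(IntervalSet(elements))


def generate_repeats(bundle: SyntheticBundle) -> None:
    cfg = bundle.config
    rng = cfg.rng("repeats")
    layout = bundle.layout
    chroms = layout.chromosomes
    repeats: list[Interval] = []
    census = set(bundle.census_ids)
    # planted class at lncRNA TSSs
    for gid in bundle.lnc_ids:
        p = cfg.te_tss_prob_census if gid in census else cfg.te_tss_prob_background
        if rng.random() < p:
            gene = bundle.genes[gid]
            start = max(0, gene.tss - int(rng.integers(5, 50)))
            end = min(layout[gene.chrom], gene.tss + int(rng.integers(5, 50)) + 1)
            repeats.append(Interval(gene.chrom, start, end, label="Simple_repeat"))
    # uniform background repeats of every class
    for i in range(cfg.n_random_repeats):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = int(rng.integers(100, 1000))
        start = int(rng.integers(0, layout[chrom] - L))
        cls = cfg.te_classes[int(rng.integers(0, len(cfg.te_classes)))]
        repeats.append(Interval(chrom, start, start + L, label=cls))
    bundle.repeats = IntervalSet(repeats)


def generate_expression(bundle: SyntheticBundle) -> None:
    """Log-normal expression for every gene; paired genes (lncRNA and its
    nearest protein-coding partner within the pairing distance) share a
    per-sample latent factor weighted to hit the target per-sample Pearson
    correlation on the log scale."""
    from cancerlnc.neighborhood import build_pairs

    cfg = bundle.config
    rng = cfg.rng("expression")
    pairs = build_pairs(bundle.lnc_genes, bundle.pc_genes, cfg.pair_distance)
    bundle.pairs = pairs
    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    gene_ids = bundle.lnc_ids + bundle.pc_ids
    census = set(bundle.census_ids)
    shift = math.log(cfg.census_expression_multiplier)

    log_expr = pd.DataFrame(index=gene_ids, columns=samples, dtype=float)
    r = cfg.pair_target_r
    w_shared, w_noise = math.sqrt(max(r, 0.0)), math.sqrt(max(1.0 - r, 0.0))
    paired = set(pairs["lnc_id"]) | set(pairs["pc_id"])
    for gid in gene_ids:
        if gid in paired:
            continue
        mu = cfg.expr_log_mean + (shift if gid in census else 0.0)
        log_expr.loc[gid] = mu + cfg.expr_log_sigma * rng.standard_normal(cfg.n_samples)
    # one latent per protein-coding partner, shared by every lncRNA paired
    # with it, so pairs with a common partner stay mutually consistent
    latents: dict[str, np.ndarray] = {}
    for pc_id in pd.unique(pairs["pc_id"]):
        z = rng.standard_normal(cfg.n_samples)
        latents[pc_id] = z
        mu = cfg.expr_log_mean + (shift if pc_id in census else 0.0)
        noise = rng.standard_normal(cfg.n_samples)
        log_expr.loc[pc_id] = mu + cfg.expr_log_sigma * (
            w_shared * z + w_noise * noise
        )
    for _, row in pairs.iterrows():
        gid = row["lnc_id"]
        mu = cfg.expr_log_mean + (shift if gid in census else 0.0)
        noise = rng.standard_normal(cfg.n_samples)
        log_expr.loc[gid] = mu + cfg.expr_log_sigma * (
            w_shared * latents[row["pc_id"]] + w_noise * noise
        )
    bundle.expression = np.exp(log_expr)
    bundle.expression.index.name = "gene_id"


def generate_insertions(bundle: SyntheticBundle) -> None:
    """Poisson-placed insertion sites: rate ``cis_rate_focal`` per Mb within
    census lncRNA spans, ``cis_rate_background`` per Mb elsewhere outside
    protein-coding genes; lengths uniform in [1, cis_max_length]."""
    cfg = bundle.config
    rng = cfg.rng("insertions")
    focal_spans = merge_intervals(
        IntervalSet([bundle.genes[g].span for g in bundle.census_ids])
    )
    genome = IntervalSet(
        [
            Interval(c, 0, bundle.layout[c])
            for c in bundle.layout.chromosomes
        ]
    )
    background_space = subtract(subtract(genome, bundle.pc_spans), focal_spans)

    def place(space: IntervalSet, rate_per_mb: float, tag: str) -> list[Interval]:
        ivs = list(space)
        if not ivs or rate_per_mb == 0:
            return []
        lengths = np.array([iv.length for iv in ivs], dtype=float)
        total = lengths.sum()
        n = int(rng.poisson(rate_per_mb * total / 1e6))
        out = []
        if n == 0:
            return out
        which = rng.choice(len(ivs), size=n, p=lengths / total)
        for k, idx in enumerate(sorted(which.tolist())):
            iv = ivs[idx]
            L = int(rng.integers(1, cfg.cis_max_length + 1))
            start = int(rng.integers(iv.start, iv.end))
            end = min(start + L, bundle.layout[iv.chrom])
            out.append(Interval(iv.chrom, start, end, label=f"{tag}{k}"))
        return out

    sites = place(focal_spans, cfg.cis_rate_focal, "cisF") + place(
        background_space, cfg.cis_rate_background, "cisB"
    )
    bundle.insertions = IntervalSet(sites)


def generate_predictions(bundle: SyntheticBundle) -> None:
    """Ranked driver predictions per cohort: census genes draw q-values from
    a low-concentrated Beta law with probability ``prediction_pi``, all other
    draws are uniform on [0, 1]."""
    cfg = bundle.config
    rng = cfg.rng("predictions")
    census = set(bundle.census_ids)
    rows = []
    for c in range(cfg.n_cohorts):
        cohort = f"cohort{c + 1}"
        for gid in bundle.lnc_ids:
            if gid in census and rng.random() < cfg.prediction_pi:
                q = float(rng.beta(cfg.q_beta_a, cfg.q_beta_b))
            else:
                q = float(rng.uniform())
            rows.append((gid, cohort, round(q, 6)))
    bundle.predictions = pd.DataFrame(rows, columns=["gene_id", "cohort", "q_value"])


def generate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate the full synthetic study (annotation + all companion data)."""
    bundle = generate_genome(cfg)
    generate_snps(bundle)
    generate_conservation(bundle)
    generate_repeats(bundle)
    generate_expression(bundle)
    generate_insertions(bundle)
    generate_predictions(bundle)
    return bundle
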