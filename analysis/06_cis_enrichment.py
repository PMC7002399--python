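#!/usr/bin/env python
"""Insertion-site enrichment in the census set: filtering, per-gene hits,
the Fisher set test, per-class insertion rates, and both empirical nulls
(length-matched resampling and genomic relocation).

Also parses the packaged real insertion-site table as a worked example.
Reads the bundle written by 01_simulate.py; writes ``results/class_rates.tsv``
and ``results/cis_enrichment.json``.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cancerlnc.census import load_census
from cancerlnc.cis_enrichment import (
    class_rates,
    filter_insertions,
    genes_with_insertions,
    length_matched_null,
    packaged_insertion_table_path,
    read_insertion_table,
    relocation_null,
    set_enrichment_test,
)
from cancerlnc.genome_model import IntervalSet, read_bed, read_chrom_sizes, read_gtf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic_data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-iter-length", type=int, default=200)
    ap.add_argument("--n-iter-relocate", type=int, default=500)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # worked example on the packaged real records
    sites = read_insertion_table(packaged_insertion_table_path())
    per_gene = pd.Series([s.interval.label for s in sites]).value_counts()
    print(
        f"packaged insertion table: {len(sites)} records over {len(per_gene)} "
        f"genes; {', '.join(sorted(per_gene[per_gene == 2].index))} carry two"
    )

    genes = read_gtf(args.data / "annotation.gtf")
    layout = read_chrom_sizes(args.data / "genome.chrom.sizes")
    focal_ids = [e.gene_id for e in load_census(args.data / "census.tsv")]
    lnc = [g for g, gm in genes.items() if gm.biotype == "lncRNA"]
    background_ids = [g for g in lnc if g not in set(focal_ids)]
    pc_ids = [g for g, gm in genes.items() if gm.biotype == "protein_coding"]
    gold = set(json.loads((args.data / "truth.json").read_text())["gold_pc_ids"])

    pc_spans = IntervalSet([genes[g].span for g in pc_ids])
    raw = read_bed(args.data / "insertions.bed")
    filtered, counts = filter_insertions(raw, pc_spans)
    print(f"insertions: {counts}")

    focal = [genes[g] for g in focal_ids]
    background = [genes[g] for g in background_ids]
    hits = genes_with_insertions(focal, filtered)
    enr = set_enrichment_test(focal, background, filtered)
    print(
        f"census genes with >=1 insertion: {int((hits >= 1).sum())}/{len(focal)} "
        f"vs background {enr['background_with_insertion']}/{len(background)} "
        f"(OR {enr['odds_ratio']:.1f}, Fisher p {enr['fisher_p']:.2e})"
    )

    rates = class_rates(
        layout,
        [genes[g] for g in pc_ids if g in gold],
        [genes[g] for g in pc_ids if g not in gold],
        focal,
        background,
        filtered,
    )
    rates.as_frame().to_csv(args.out / "class_rates.tsv", sep="\t", index=False)
    print("insertions per Mb by class:",
          {k: round(v, 2) for k, v in rates.rates_per_mb.items()})

    lm = length_matched_null(
        focal, background, filtered, n_iter=args.n_iter_length,
        seed=args.seed, pc_mask=pc_spans,
    )
    rel = relocation_null(
        focal, filtered, layout, excluded=pc_spans,
        n_iter=args.n_iter_relocate, seed=args.seed,
    )
    print(
        f"length-matched null: observed {lm.observed:.2f}/Mb, "
        f"p = {lm.p_value} ({lm.n_iter} iterations)"
    )
    print(
        f"relocation null: observed {rel.observed:.0f} genes hit, "
        f"p = {rel.p_value} ({rel.n_iter} iterations)"
    )

    (args.out / "cis_enrichment.json").write_text(
        json.dumps(
            {
                "filter_counts": counts,
                "set_enrichment": enr,
                "class_rates_per_mb": rates.rates_per_mb,
                "length_matched_null": {"observed_per_mb": lm.observed, "p": lm.p_value},
                "relocation_null": {"observed_genes_hit": rel.observed, "p": rel.p_value},
            },
            indent=1,
            sort_keys=True,
        )
    )


if __name__ == "__main__":
    main()
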