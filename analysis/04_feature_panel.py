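#!/usr/bin/env python
"""Compare the census set with the background lncRNAs across the feature
panel: gene/exonic length, exonic content, repeat coverage, conservation of
exons and promoters, per-sample expression, SNP proximity and TSS
repeat-class enrichment.

Reads the bundle written by 01_simulate.py; writes
``results/feature_panel.tsv`` and prints the significant rows.
"""

import argparse
from pathlib import Path

import pandas as pd

from cancerlnc.census import load_census
from cancerlnc.feature_panel import PanelInputs, run_feature_panel
from cancerlnc.genome_model import read_bed, read_bedgraph, read_gtf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic_data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genes = read_gtf(args.data / "annotation.gtf")
    focal = [e.gene_id for e in load_census(args.data / "census.tsv")]
    background = [
        g for g, gm in genes.items()
        if gm.biotype == "lncRNA" and g not in set(focal)
    ]
    panel = run_feature_panel(
        PanelInputs(
            genes=genes,
            focal=focal,
            background=background,
            conservation_track=read_bedgraph(args.data / "conservation.bedgraph"),
            conserved_elements=read_bed(args.data / "conserved_elements.bed"),
            repeats=read_bed(args.data / "repeats.bed"),
            cancer_snps=read_bed(args.data / "cancer_snps.bed"),
            noncancer_snps=read_bed(args.data / "noncancer_snps.bed"),
            expression=pd.read_csv(args.data / "expression.tsv", sep="\t", index_col=0),
        )
    )
    panel.to_csv(args.out / "feature_panel.tsv", sep="\t", index=False)

    sig = panel[panel.p_value < 0.01]
    print(f"feature panel: {len(panel)} comparisons, {len(sig)} with p < 0.01")
    for _, row in sig.iterrows():
        print(
            f"  {row.feature:<35s} [{row.region:<8s}] "
            f"effect {row.effect:+.2f}  p {row.p_value:.2e}"
        )


if __name__ == "__main__":
    main()
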