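#!/usr/bin/env python
"""Genomic neighbourhood of the census lncRNAs: orientation classes relative
to protein-coding genes, the divergent-partner enrichment towards gold
protein-coding genes, and coexpression of census/partner pairs against both
the distance-matched control pairs and the shuffled-pairing null.

Reads the bundle written by 01_simulate.py; writes
``results/genomic_classes.tsv`` and ``results/neighborhood.json``.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from scipy import stats

from cancerlnc.census import load_census
from cancerlnc.genome_model import read_gtf
from cancerlnc.neighborhood import (
    build_pairs,
    classify_all,
    distance_matched_control_pairs,
    divergent_partner_enrichment,
    pair_correlation,
    shuffled_pair_null,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic_data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-iter", type=int, default=200)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genes = read_gtf(args.data / "annotation.gtf")
    focal = [e.gene_id for e in load_census(args.data / "census.tsv")]
    lnc = [g for g, gm in genes.items() if gm.biotype == "lncRNA"]
    background = [g for g in lnc if g not in set(focal)]
    pc = [gm for gm in genes.values() if gm.biotype == "protein_coding"]
    gold = json.loads((args.data / "truth.json").read_text())["gold_pc_ids"]

    classes = classify_all([genes[g] for g in lnc], pc)
    classes.to_csv(args.out / "genomic_classes.tsv", sep="\t", index=False)
    counts = classes["genomic_class"].value_counts()
    print("orientation classes:", dict(counts))

    div = divergent_partner_enrichment(classes, gold, focal, background)
    print(
        f"divergent-to-gold: focal {div['focal_divergent_to_gold']}/"
        f"{div['focal_divergent']} vs background "
        f"{div['background_divergent_to_gold']}/{div['background_divergent']} "
        f"(OR {div['odds_ratio']:.1f}, Fisher p {div['fisher_p']:.2e})"
    )

    expression = pd.read_csv(args.data / "expression.tsv", sep="\t", index_col=0)
    pairs = build_pairs([genes[g] for g in focal], pc)
    out = {"class_counts": counts.to_dict(), "divergent_enrichment": div}
    if len(pairs) >= 3:
        null = shuffled_pair_null(pairs, expression, n_iter=args.n_iter, seed=args.seed)
        control = distance_matched_control_pairs(
            pairs, [genes[g] for g in background],
            [genes[p] for p in set(pairs["pc_id"])], seed=args.seed,
        )
        r_ctrl = pair_correlation(control, expression) if len(control) >= 3 else None
        print(
            f"coexpression: {len(pairs)} pairs, observed mean r "
            f"{null.observed.mean():.3f}; shuffled null mean r "
            f"{null.pooled_null.mean():.3f} (KS p {null.ks_p:.2e})"
        )
        out["coexpression"] = {
            "n_pairs": len(pairs),
            "observed_mean_r": float(null.observed.mean()),
            "shuffled_null_mean_r": float(null.pooled_null.mean()),
            "ks_p_vs_shuffled": null.ks_p,
        }
        if r_ctrl is not None:
            ks = stats.ks_2samp(null.observed.dropna(), r_ctrl.dropna())
            print(
                f"  distance-matched control pairs ({len(control)}): mean r "
                f"{r_ctrl.mean():.3f} (KS p vs observed {ks.pvalue:.2e})"
            )
            out["coexpression"]["control_mean_r"] = float(r_ctrl.mean())
            out["coexpression"]["ks_p_vs_control"] = float(ks.pvalue)

    (args.out / "neighborhood.json").write_text(
        json.dumps(out, indent=1, sort_keys=True)
    )


if __name__ == "__main__":
    main()
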