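#!/usr/bin/env python
"""Summarise the packaged census fixture: how many genes, what roles, how
many gene-cancer relationships, and how deep the evidence runs.

Writes ``results/census_summary.json``.
"""

import argparse
import json
from pathlib import Path

from cancerlnc.census import (
    census_fraction,
    load_census,
    packaged_census_path,
    summarize_census,
)

GENCODE_LNC_LOCI = 15_941  # background lncRNA catalogue size


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--census", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results/census_summary.json"))
    args = ap.parse_args()

    path = args.census or packaged_census_path()
    entries = load_census(path)
    s = summarize_census(entries)
    n_lnc = s.n_genes - s.n_pseudogene
    payload = s.as_dict()
    payload["fraction_of_background_pct"] = census_fraction(n_lnc, GENCODE_LNC_LOCI)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=1, sort_keys=True))

    print(f"census: {s.n_genes} genes ({s.n_pseudogene} pseudogene biotype)")
    print(
        f"  roles: {s.role_counts['oncogene']} oncogene / "
        f"{s.role_counts['tumour_suppressor']} tumour suppressor / "
        f"{s.role_counts['both']} dual"
    )
    print(f"  {s.n_relationships} unique gene-cancer relationships")
    print(f"  {s.n_genes_min_evidence[3]} genes with >=3 evidence classes")
    print(
        f"  {n_lnc} lncRNA-biotype genes = "
        f"{payload['fraction_of_background_pct']}% of {GENCODE_LNC_LOCI} loci"
    )


if __name__ == "__main__":
    main()
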