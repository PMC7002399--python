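"""Data model, validation and summary statistics for a curated cancer-lncRNA census.

A census entry links one lncRNA gene to one or more cancer types, a functional
role (oncogene, tumour suppressor, or both depending on tissue), and the
classes of evidence supporting the link:

* ``t`` - in vitro: knockdown/overexpression in cultured cancer cells changes
  cancer-associated phenotypes (proliferation, migration, apoptosis...);
* ``v`` - in vivo: altered tumorigenicity in animal models;
* ``g`` - germline variants predisposing to cancer;
* ``s`` - somatic mutations under positive selection in tumours;
* ``p`` - prognosis: expression statistically linked to disease progression.

Prognostic association alone never suffices: every valid entry carries at
least one of ``t``/``v``/``g``/``s``. Class ``p`` may only extend an already
supported gene to an additional cancer type.

The packaged fixture ``data/census_v1_synthetic.tsv`` is a synthetic stand-in
table: a census release whose per-gene rows are generated, not curated, but
whose marginal counts match the published version-1 census (122 genes, 8
pseudogene-biotype entries, 77/35/10 oncogene/TSG/dual split, 333 unique
gene-cancer relationships over 29 cancer types, 19 genes with three or more
evidence classes).
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

VALID_EVIDENCE = frozenset("tvgsp")
CORE_EVIDENCE = frozenset("tvgs")
VALID_ROLES = ("oncogene", "tumour_suppressor", "both")

__all__ = [
    "CensusEntry",
    "CensusSummary",
    "CensusValidationError",
    "load_census",
    "write_census",
    "summarize_census",
    "census_fraction",
    "packaged_census_path",
]


class CensusValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CensusEntry:
    """One census gene: roles, cancer types and evidence classes."""

    gene_id: str
    name: str
    role: str
    cancer_types: frozenset[str]
    evidence_classes: frozenset[str]
    biotype: str = "lncRNA"
    reference: str = ""

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise CensusValidationError(
                f"{self.gene_id}: unknown role {self.role!r} "
                f"(expected one of {VALID_ROLES})"
            )
        if not self.cancer_types:
            raise CensusValidationError(f"{self.gene_id}: no cancer types")
        bad = self.evidence_classes - VALID_EVIDENCE
        if bad:
            raise CensusValidationError(
                f"{self.gene_id}: unknown evidence classes {sorted(bad)}"
            )
        if not (self.evidence_classes & CORE_EVIDENCE):
            raise CensusValidationError(
                f"{self.gene_id}: prognostic evidence (class p) alone is not "
                "sufficient; at least one of t/v/g/s is required"
            )

    @property
    def n_evidence_classes(self) -> int:
        return len(self.evidence_classes)


@dataclass(frozen=True)
class CensusSummary:
    """Marginal counts of a census release."""

    n_genes: int
    n_pseudogene: int
    role_counts: Mapping[str, int]
    n_relationships: int
    evidence_histogram: Mapping[str, int]
    n_genes_min_evidence: Mapping[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_pseudogene": self.n_pseudogene,
            "role_counts": dict(self.role_counts),
            "n_relationships": self.n_relationships,
            "evidence_histogram": dict(self.evidence_histogram),
            "n_genes_min_evidence": {str(k): v for k, v in self.n_genes_min_evidence.items()},
        }


def packaged_census_path() -> Path:
    """Path to the packaged synthetic census fixture."""
    return Path(resources.files("cancerlnc") / "data" / "census_v1_synthetic.tsv")


_COLUMNS = [
    "gene_id",
    "gene_name",
    "biotype",
    "role",
    "cancer_types",
    "evidence_classes",
    "reference",
]


def load_census(
    path: str | Path,
    annotation: Mapping[str, "object"] | None = None,
    cancer_vocabulary: Iterable[str] | None = None,
) -> list[CensusEntry]:
    """Load and validate a census TSV.

    ``cancer_types`` and ``evidence_classes`` columns are comma-separated.
    With ``annotation`` (gene_id -> GeneModel), ids are cross-checked and the
    annotation biotype attached. Unknown cancer-type labels against a supplied
    controlled vocabulary warn but do not fail (the census is versioned data).
    """
    entries: list[CensusEntry] = []
    seen: set[str] = set()
    vocab = set(cancer_vocabulary) if cancer_vocabulary is not None else None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_id" not in reader.fieldnames:
            raise CensusValidationError(f"{path}: missing header with gene_id column")
        for row in reader:
            gene_id = row["gene_id"].strip()
            if gene_id in seen:
                raise CensusValidationError(f"duplicate gene id {gene_id}")
            seen.add(gene_id)
            cancers = frozenset(
                c.strip() for c in row["cancer_types"].split(",") if c.strip()
            )
            if vocab is not None:
                unknown = cancers - vocab
                if unknown:
                    warnings.warn(
                        f"{gene_id}: cancer types outside controlled vocabulary: "
                        f"{sorted(unknown)}",
                        stacklevel=2,
                    )
            evidence = frozenset(
                e.strip() for e in row["evidence_classes"].split(",") if e.strip()
            )
            biotype = row.get("biotype", "lncRNA") or "lncRNA"
            if annotation is not None:
                if gene_id not in annotation:
                    raise CensusValidationError(
                        f"{gene_id}: not present in supplied annotation"
                    )
                biotype = annotation[gene_id].biotype  # type: ignore[attr-defined]
            entries.append(
                CensusEntry(
                    gene_id=gene_id,
                    name=row.get("gene_name", gene_id) or gene_id,
                    role=row["role"].strip(),
                    cancer_types=cancers,
                    evidence_classes=evidence,
                    biotype=biotype,
                    reference=row.get("reference", "") or "",
                )
            )
    if not entries:
        warnings.warn(f"{path}: census file contains no entries", stacklevel=2)
    return entries


def write_census(entries: Sequence[CensusEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for e in sorted(entries, key=lambda x: x.gene_id):
            writer.writerow(
                [
                    e.gene_id,
                    e.name,
                    e.biotype,
                    e.role,
                    ",".join(sorted(e.cancer_types)),
                    ",".join(sorted(e.evidence_classes)),
                    e.reference,
                ]
            )


def summarize_census(entries: Sequence[CensusEntry], min_evidence: int = 3) -> CensusSummary:
    """Deterministic marginal counts; invariant under row permutation."""
    if not entries:
        raise CensusValidationError("cannot summarise an empty census")
    role_counts = Counter(e.role for e in entries)
    relationships = {(e.gene_id, c) for e in entries for c in e.cancer_types}
    evidence_hist = Counter(cls for e in entries for cls in e.evidence_classes)
    n_min = {
        min_evidence: sum(1 for e in entries if e.n_evidence_classes >= min_evidence)
    }
    return CensusSummary(
        n_genes=len(entries),
        n_pseudogene=sum(1 for e in entries if e.biotype == "pseudogene"),
        role_counts={r: role_counts.get(r, 0) for r in VALID_ROLES},
        n_relationships=len(relationships),
        evidence_histogram=dict(sorted(evidence_hist.items())),
        n_genes_min_evidence=n_min,
    )


def census_fraction(n_census: int, n_background: int) -> float:
    """Census share of a background catalogue, as a percentage to 2 decimals."""
    if n_background <= 0:
        raise ValueError("background size must be positive")
    return round(100.0 * n_census / n_background, 2)
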