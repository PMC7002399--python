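"""Genome annotation and interval algebra.

All coordinates are internally 0-based half-open (BED convention). GTF input
and output (1-based, fully closed) are converted at the boundary, so the two
converters are exact inverses. Strand is ``+``, ``-`` or ``.``.

Gene geometry is derived, never trusted from the annotation's gene line: the
gene span is the min/max over the exons of all transcripts, the exonic union
is the per-base union of exons, introns are the remaining bases of the span,
and the promoter is the 200 nt window centred on the strand-aware TSS
(clipped to the chromosome when a :class:`GenomeLayout` is supplied).
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "Transcript",
    "GeneModel",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "ScoreTrack",
    "read_bedgraph",
    "merge_intervals",
    "subtract",
    "coverage_fraction",
    "mean_base_score",
    "nearest_tss_distance",
]

_BIOTYPE_MAP = {
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "protein_coding": "protein_coding",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
}


class GtfParseError(ValueError):
    """Raised on a malformed GTF record; carries the 1-based line number."""


def normalize_biotype(raw: str) -> str:
    """Map an annotation biotype string onto the four internal biotypes."""
    return _BIOTYPE_MAP.get(raw, "other")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths; the bounds for clipping and relocation."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def genome_size(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of intervals with per-chromosome indexing."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = sorted(intervals)
        self._by_chrom: dict[str, list[Interval]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def by_chrom(self) -> dict[str, list[Interval]]:
        if self._by_chrom is None:
            out: dict[str, list[Interval]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, []).append(iv)
            self._by_chrom = out
        return self._by_chrom

    @property
    def total_bp(self) -> int:
        """Total merged base pairs (overlaps counted once)."""
        return sum(iv.length for iv in merge_intervals(self).intervals)

    def validate_against(self, layout: GenomeLayout) -> None:
        for iv in self.intervals:
            if iv.chrom not in layout:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > layout[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {layout[iv.chrom]}"
                )


@dataclass(frozen=True)
class Transcript:
    """A transcript: an ordered list of disjoint exons on one strand."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes {chroms}")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        object.__setattr__(self, "exons", tuple(ordered))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: span.start on +, span.end - 1 on -."""
        return self.span.start if self.strand != "-" else self.span.end - 1


@dataclass
class GeneModel:
    """An annotated gene with derived geometry."""

    gene_id: str
    name: str
    biotype: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        self.transcripts = tuple(self.transcripts)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> Interval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return Interval(self.chrom, start, end, self.strand, self.gene_id)

    @property
    def tss(self) -> int:
        span = self.span
        return span.start if self.strand != "-" else span.end - 1

    @property
    def exonic_union(self) -> IntervalSet:
        """Per-base union of exons over all transcripts."""
        return merge_intervals(
            IntervalSet(e for t in self.transcripts for e in t.exons)
        )

    @property
    def exonic_length(self) -> int:
        return sum(iv.length for iv in self.exonic_union)

    @property
    def gene_length(self) -> int:
        return self.span.length

    @property
    def exonic_content(self) -> float:
        return self.exonic_length / self.gene_length

    def promoter(self, layout: GenomeLayout | None = None, flank: int = 100) -> Interval:
        """The ``2*flank`` nt window centred on the TSS, clipped to the chromosome."""
        tss = self.tss
        start = max(0, tss - flank)
        end = tss + flank
        if layout is not None and self.chrom in layout:
            end = min(end, layout[self.chrom])
        return Interval(self.chrom, start, end, self.strand, f"{self.gene_id}_promoter")


# ---------------------------------------------------------------------------
# Annotation IO

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read a GENCODE-dialect GTF into gene models keyed by gene id.

    Only ``exon`` features are required: gene/transcript structure is rebuilt
    from exon parentage, so the derived span is always consistent with the
    exons. 1-based inclusive coordinates become 0-based half-open.
    """
    exons: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # transcript -> (gene_id, strand)
    gene_meta: dict[str, tuple[str, str]] = {}  # gene -> (name, biotype)
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id")
            if gene_id not in gene_meta:
                gene_order.append(gene_id)
            name = attributes.get("gene_name", gene_id)
            biotype = normalize_biotype(
                attributes.get("gene_type", attributes.get("gene_biotype", ""))
            )
            if feature == "gene" or gene_id not in gene_meta:
                gene_meta[gene_id] = (name, biotype)
            if feature in ("transcript", "exon"):
                tx_id = attributes.get("transcript_id")
                if tx_id is None:
                    raise GtfParseError(
                        f"{path}: line {lineno}: {feature} without transcript_id"
                    )
                tx_meta.setdefault(tx_id, (gene_id, strand))
            if feature == "exon":
                exons.setdefault(tx_id, []).append(
                    Interval(chrom, start1 - 1, end1, strand)
                )

    genes: dict[str, GeneModel] = {}
    tx_by_gene: dict[str, list[Transcript]] = {}
    for tx_id, exon_list in exons.items():
        gene_id, strand = tx_meta[tx_id]
        tx_by_gene.setdefault(gene_id, []).append(
            Transcript(tx_id, gene_id, strand, tuple(exon_list))
        )
    for gene_id in gene_order:
        if gene_id not in tx_by_gene:
            continue  # gene line without exons: skip silently
        name, biotype = gene_meta[gene_id]
        txs = sorted(tx_by_gene[gene_id], key=lambda t: t.transcript_id)
        genes[gene_id] = GeneModel(gene_id, name, biotype, tuple(txs))
    return genes


def write_gtf(genes: Mapping[str, GeneModel] | Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GENCODE-dialect GTF (1-based inclusive)."""
    if isinstance(genes, Mapping):
        genes = list(genes.values())
    with open(path, "w") as fh:
        for gene in genes:
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.name}"; '
                f'gene_type "{gene.biotype}";'
            )
            span = gene.span
            fh.write(
                f"{gene.chrom}\tcancerlnc\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tattrs = attrs + f' transcript_id "{tx.transcript_id}";'
                tspan = tx.span
                fh.write(
                    f"{gene.chrom}\tcancerlnc\ttranscript\t{tspan.start + 1}\t"
                    f"{tspan.end}\t.\t{tx.strand}\t.\t{tattrs}\n"
                )
                for exon in tx.exons:
                    fh.write(
                        f"{gene.chrom}\tcancerlnc\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{tx.strand}\t.\t{tattrs}\n"
                    )


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3+ (optional name, score, strand columns)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: need >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                intervals.append(Interval(chrom, start, end, strand, label))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    out = IntervalSet(intervals)
    if layout is not None:
        out.validate_against(layout)
    return out


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED6 (name and strand preserved; score column written as 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            if name in lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            lengths[name] = int(size)
    return GenomeLayout(lengths)


# ---------------------------------------------------------------------------
# Score tracks (bedGraph)


class ScoreTrack:
    """Per-base scores stored as non-overlapping scored intervals per chromosome.

    Positions not covered by any record score ``missing_value`` (0 by default,
    matching the usual conservation-track convention).
    """

    def __init__(
        self,
        records: Iterable[tuple[str, int, int, float]],
        missing_value: float = 0.0,
    ):
        self.missing_value = missing_value
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not (0 <= start < end):
                raise ValueError(f"invalid track record {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
                if e1 > s2:
                    raise ValueError(f"overlapping track records on {chrom}")
            self._starts[chrom] = np.array([r[0] for r in recs])
            self._ends[chrom] = np.array([r[1] for r in recs])
            self._values[chrom] = np.array([r[2] for r in recs])

    def interval_sum(self, iv: Interval) -> float:
        """Sum of per-base scores over an interval (missing bases contribute
        ``missing_value``)."""
        if iv.chrom not in self._starts:
            return self.missing_value * iv.length
        starts, ends, values = (
            self._starts[iv.chrom],
            self._ends[iv.chrom],
            self._values[iv.chrom],
        )
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        covered = 0
        total = 0.0
        for i in range(lo, hi):
            ov = min(ends[i], iv.end) - max(starts[i], iv.start)
            if ov > 0:
                total += values[i] * ov
                covered += ov
        total += self.missing_value * (iv.length - covered)
        return total


def read_bedgraph(path: str | Path, missing_value: float = 0.0) -> ScoreTrack:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            records.append((chrom, int(start), int(end), float(value)))
    return ScoreTrack(records, missing_value=missing_value)


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(intervals: IntervalSet | Iterable[Interval]) -> IntervalSet:
    """Union of intervals: overlapping or bookended runs collapse to one."""
    if not isinstance(intervals, IntervalSet):
        intervals = IntervalSet(intervals)
    merged: list[Interval] = []
    for chrom, ivs in sorted(intervals.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return IntervalSet(merged)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """A minus B, per base. Labels and strands of A are dropped (geometry only)."""
    b_by_chrom = {c: ivs for c, ivs in merge_intervals(b).by_chrom().items()}
    out: list[Interval] = []
    for iv in a:
        cuts = b_by_chrom.get(iv.chrom, [])
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos:
                continue
            if cut.start >= iv.end:
                break
            if cut.start > pos:
                out.append(Interval(iv.chrom, pos, min(cut.start, iv.end)))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(Interval(iv.chrom, pos, iv.end))
    return IntervalSet(out)


def intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Number of bases covered by both sets (each set merged first)."""
    total = 0
    b_by_chrom = merge_intervals(b).by_chrom()
    for iv in merge_intervals(a):
        for cut in b_by_chrom.get(iv.chrom, []):
            ov = min(iv.end, cut.end) - max(iv.start, cut.start)
            if ov > 0:
                total += ov
    return total


def coverage_fraction(target: IntervalSet, cover: IntervalSet) -> float:
    """Fraction of target bases covered by the (merged) cover set."""
    if len(target) == 0:
        raise ValueError("empty target")
    return intersect_bp(target, cover) / target.total_bp


def mean_base_score(target: IntervalSet, track: ScoreTrack) -> float:
    """Arithmetic mean of per-base scores over the merged target bases."""
    merged = merge_intervals(target)
    total_bp = sum(iv.length for iv in merged)
    if total_bp == 0:
        raise ValueError("empty target")
    return sum(track.interval_sum(iv) for iv in merged) / total_bp


def nearest_tss_distance(
    query_tss: Mapping[str, tuple[str, int]],
    subject_tss: Mapping[str, tuple[str, int]],
) -> dict[str, tuple[float, str | None]]:
    """Nearest subject per query by absolute TSS-to-TSS distance.

    Parameters are mappings ``id -> (chrom, position)``. Distances are
    strand-ignored and computed within chromosomes only; a query with no
    same-chromosome subject gets ``(nan, None)``. Ties break to the
    lexicographically smaller subject id, so output is deterministic.
    """
    if not subject_tss:
        raise ValueError("empty subject set")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for sid, (chrom, pos) in subject_tss.items():
        by_chrom.setdefault(chrom, []).append((pos, sid))
    for entries in by_chrom.values():
        entries.sort()
    result: dict[str, tuple[float, str | None]] = {}
    for qid, (chrom, pos) in query_tss.items():
        entries = by_chrom.get(chrom)
        if not entries:
            result[qid] = (float("nan"), None)
            continue
        positions = [p for p, _ in entries]
        i = bisect_left(positions, pos)
        d0: int | None = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                d = abs(entries[j][0] - pos)
                d0 = d if d0 is None else min(d0, d)
        assert d0 is not None
        # candidates sit at pos-d0 and pos+d0; within an equal-position run
        # the first entry carries the lexicographically smallest id
        best_id: str | None = None
        for p in (pos - d0, pos + d0):
            k = bisect_left(positions, p)
            if k < len(positions) and positions[k] == p:
                sid = entries[k][1]
                if best_id is None or sid < best_id:
                    best_id = sid
        result[qid] = (float(d0), best_id)
    return result


def gene_tss_map(genes: Iterable[GeneModel]) -> dict[str, tuple[str, int]]:
    """Convenience: ``gene_id -> (chrom, TSS)`` for nearest-feature queries."""
    return {g.gene_id: (g.chrom, g.tss) for g in genes}


def point_map(points: IntervalSet) -> dict[str, tuple[str, int]]:
    """Treat intervals as points (their start); ids from labels or ordinals."""
    out = {}
    for i, iv in enumerate(points):
        pid = iv.label or f"pt{i}"
        if pid in out:
            pid = f"{pid}_{i}"
        out[pid] = (iv.chrom, iv.start)
    return out
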