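"""Gene catalogs: interval arithmetic, maximal loci, deduplication and set construction.

All coordinates are 0-based half-open ``[start, end)`` on a named chromosome;
GTF's 1-based closed convention is converted at the I/O boundary (see
:mod:`lncstab.annotio`).  A gene's counting territory is its *maximal locus*:
the span covering every annotated isoform, together with the union of all
exons, whose total length normalizes RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 nt on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneRecord:
    """One annotated gene with its isoform exon structure.

    ``isoforms`` is a list of exon lists; each exon is a ``(start, end)``
    tuple.  Exons within one isoform must be disjoint; they are stored sorted.
    ``biotype`` is annotation evidence only ({'coding', 'lncRNA', 'other'}),
    never inferred from sequence.
    """

    gene_id: str
    source: str
    chrom: str
    strand: str
    isoforms: list[list[tuple[int, int]]]
    has_protein_id: bool = False
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not self.isoforms or any(not iso for iso in self.isoforms):
            raise ValueError(f"gene {self.gene_id}: empty isoform/exon list")
        clean = []
        for iso in self.isoforms:
            exons = sorted((int(s), int(e)) for s, e in iso)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"gene {self.gene_id}: overlapping exons within one isoform"
                    )
            for s, e in exons:
                if s >= e:
                    raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
            clean.append(exons)
        self.isoforms = clean

    @property
    def span(self) -> GenomicInterval:
        start = min(s for iso in self.isoforms for s, _ in iso)
        end = max(e for iso in self.isoforms for _, e in iso)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class MaximalLocus:
    """Counting territory of a gene: full span plus exonic union."""

    gene_id: str
    locus_span: GenomicInterval
    exonic_union: tuple[tuple[int, int], ...]
    exonic_length_nt: int


@dataclass
class GeneCatalog:
    """Collection of GeneRecords keyed by gene_id, with source provenance."""

    records: dict[str, GeneRecord] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def add(self, record: GeneRecord) -> None:
        if record.gene_id in self.records:
            raise ValueError(f"duplicate gene_id {record.gene_id!r}")
        self.records[record.gene_id] = record


def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge intervals into a minimal disjoint sorted union.

    Adjacent (touching) intervals are merged, so no two members of the result
    are mergeable.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return []
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le:  # overlap or adjacency
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def build_maximal_locus(gene: GeneRecord) -> MaximalLocus:
    """Union all isoforms' exons into the gene's maximal locus."""
    exons = [exon for iso in gene.isoforms for exon in iso]
    union = union_intervals(exons)
    length = sum(e - s for s, e in union)
    return MaximalLocus(
        gene_id=gene.gene_id,
        locus_span=gene.span,
        exonic_union=tuple(union),
        exonic_length_nt=length,
    )


def spliced_length(gene: GeneRecord) -> int:
    """Exonic-union length in nucleotides (the gene's spliced length)."""
    return build_maximal_locus(gene).exonic_length_nt


def _contained(inner: GenomicInterval, outer: GenomicInterval) -> bool:
    return (
        inner.chrom == outer.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def deduplicate(catalog: GeneCatalog) -> GeneCatalog:
    """Remove genes whose span is completely contained within another gene's span.

    Containment is strand-agnostic and span-based.  Two genes with identical
    spans contain each other; the lexicographically larger gene_id is removed,
    which makes the operation deterministic and idempotent.  A gene is removed
    only when its container is itself retained, so chains of containment never
    drop a gene together with its container.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in catalog:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    kept: dict[str, GeneRecord] = {}
    for chrom_recs in by_chrom.values():
        # Sort widest-first so containers are decided before their containees;
        # ties (equal spans) keep the lexicographically smaller id.
        order = sorted(
            chrom_recs,
            key=lambda r: (r.span.start, -(r.span.end), r.gene_id),
        )
        retained: list[GeneRecord] = []
        for rec in order:
            span = rec.span
            contained = False
            for other in retained:
                osp = other.span
                if osp.start > span.start:
                    continue
                if _contained(span, osp) and not (
                    osp.start == span.start
                    and osp.end == span.end
                    and other.gene_id > rec.gene_id
                ):
                    contained = True
                    break
            if not contained:
                retained.append(rec)
        for rec in retained:
            kept[rec.gene_id] = rec

    out = GeneCatalog(provenance=list(catalog.provenance))
    for gene_id in catalog.records:  # preserve input order
        if gene_id in kept:
            out.add(catalog.records[gene_id])
    return out


def merge_catalogs(catalogs: Iterable[GeneCatalog]) -> GeneCatalog:
    """Union of catalogs; identical gene_ids across catalogs keep one copy."""
    out = GeneCatalog()
    for cat in catalogs:
        out.provenance.extend(cat.provenance)
        for rec in cat:
            if rec.gene_id not in out:
                out.add(rec)
    return out


def build_lncrna_set(
    catalogs: list[GeneCatalog], min_len_nt: int = 200
) -> GeneCatalog:
    """Combine lncRNA sources, eliminate redundancies, keep genes > min_len_nt.

    Length is the spliced (exonic-union) length and the cutoff is strict: a
    gene is retained only when its spliced length exceeds ``min_len_nt``,
    matching the definition of lncRNAs as noncoding transcripts longer than
    200 nucleotides.
    """
    if not catalogs:
        raise ValueError("at least one source catalog required")
    merged = merge_catalogs(catalogs)
    deduped = deduplicate(merged)
    out = GeneCatalog(provenance=list(deduped.provenance))
    for rec in deduped:
        if spliced_length(rec) > min_len_nt:
            out.add(rec)
    return out


def partition_coding_noncoding(
    catalog: GeneCatalog, lnc: GeneCatalog
) -> tuple[GeneCatalog, GeneCatalog]:
    """Split out protein-coding genes, and those free of any lncRNA overlap.

    Returns ``(coding, coding_nonoverlapping)``: ``coding`` holds every record
    with protein-ID evidence; ``coding_nonoverlapping`` drops any coding gene
    whose span shares >= 1 nt with a lncRNA span (strand-agnostic overlap).
    """
    coding = GeneCatalog(provenance=list(catalog.provenance))
    for rec in catalog:
        if rec.has_protein_id:
            coding.add(rec)

    lnc_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in lnc:
        sp = rec.span
        lnc_by_chrom.setdefault(rec.chrom, []).append((sp.start, sp.end))
    for chrom in lnc_by_chrom:
        lnc_by_chrom[chrom] = union_intervals(lnc_by_chrom[chrom])

    nonoverlapping = GeneCatalog(provenance=list(catalog.provenance))
    for rec in coding:
        sp = rec.span
        spans = lnc_by_chrom.get(rec.chrom, [])
        if not any(s < sp.end and sp.start < e for s, e in spans):
            nonoverlapping.add(rec)
    return coding, nonoverlapping
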