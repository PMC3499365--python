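"""Annotation and table I/O: GTF and BED dialects in, BED12/TSV out.

Internal convention is 0-based half-open.  GTF (1-based, closed) is converted
on read: a GTF feature at ``[101, 200]`` becomes ``[100, 200)``.  BED is
already 0-based half-open and passes through unchanged.

Readers are line-based so that malformed input can be reported with the file
name and 1-based line number, which is the error contract every loader here
honours.
"""

from __future__ import annotations

import re
from pathlib import Path

from .genome import GeneCatalog, GeneRecord, build_maximal_locus

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


class AnnotationError(ValueError):
    """Malformed annotation input, carrying file and line context."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _check_strand(strand: str, path, lineno) -> str:
    if strand not in ("+", "-"):
        raise AnnotationError(path, lineno, f"unknown strand symbol {strand!r}")
    return strand


def read_bed(path: str | Path, source: str = "", biotype: str = "other",
             has_protein_id: bool = False) -> GeneCatalog:
    """Read BED6 or BED12 gene records (one gene per line).

    BED12 block columns define the gene's exons; BED6 lines become
    single-exon genes.  Scores are ignored.
    """
    catalog = GeneCatalog(provenance=[str(path)])
    src = source or Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise AnnotationError(path, lineno,
                                      f"expected >=6 BED columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError:
                raise AnnotationError(path, lineno, "non-integer coordinates") from None
            name = f[3]
            strand = _check_strand(f[5], path, lineno)
            if len(f) >= 12:
                try:
                    n_blocks = int(f[9])
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    starts = [int(x) for x in f[11].rstrip(",").split(",")]
                except ValueError:
                    raise AnnotationError(path, lineno, "malformed block columns") from None
                if not (len(sizes) == len(starts) == n_blocks):
                    raise AnnotationError(path, lineno, "block count mismatch")
                exons = [(start + off, start + off + sz)
                         for off, sz in zip(starts, sizes)]
            else:
                exons = [(start, end)]
            try:
                rec = GeneRecord(gene_id=name, source=src, chrom=chrom,
                                 strand=strand, isoforms=[exons],
                                 has_protein_id=has_protein_id, biotype=biotype)
            except ValueError as exc:
                raise AnnotationError(path, lineno, str(exc)) from None
            if name in catalog:
                # extra line for an existing gene = an additional isoform
                catalog[name].isoforms.append(rec.isoforms[0])
            else:
                catalog.add(rec)
    return catalog


def read_gtf(path: str | Path, source: str = "", biotype: str = "other",
             has_protein_id: bool = False) -> GeneCatalog:
    """Read exon features from a GTF file, grouping transcripts into genes.

    Coordinates are converted from GTF's 1-based closed convention to the
    internal 0-based half-open one.  Requires ``gene_id`` and
    ``transcript_id`` attributes on exon features; other feature types are
    ignored.
    """
    src = source or Path(path).stem
    transcripts: dict[tuple[str, str], dict] = {}
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise AnnotationError(path, lineno,
                                      f"expected 9 GTF columns, got {len(f)}")
            if f[2] != "exon":
                continue
            chrom = f[0]
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                raise AnnotationError(path, lineno, "non-integer coordinates") from None
            strand = _check_strand(f[6], path, lineno)
            attrs = dict(_GTF_ATTR.findall(f[8]))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationError(path, lineno,
                                      "missing gene_id/transcript_id attribute")
            key = (attrs["gene_id"], attrs["transcript_id"])
            tx = transcripts.setdefault(
                key, {"chrom": chrom, "strand": strand, "exons": []})
            if tx["chrom"] != chrom or tx["strand"] != strand:
                raise AnnotationError(path, lineno,
                                      "transcript spans chromosomes/strands")
            tx["exons"].append((start1 - 1, end1))  # GTF 1-based closed -> half-open
            if attrs["gene_id"] not in gene_order:
                gene_order.append(attrs["gene_id"])

    catalog = GeneCatalog(provenance=[str(path)])
    for gene_id in gene_order:
        isoforms = [tx["exons"] for (gid, _), tx in transcripts.items()
                    if gid == gene_id]
        meta = next(tx for (gid, _), tx in transcripts.items() if gid == gene_id)
        catalog.add(GeneRecord(gene_id=gene_id, source=src, chrom=meta["chrom"],
                               strand=meta["strand"], isoforms=isoforms,
                               has_protein_id=has_protein_id, biotype=biotype))
    return catalog


def load_annotations(files: list[tuple[str | Path, str, str]],
                     biotype: str = "other",
                     has_protein_id: bool = False) -> GeneCatalog:
    """Load several annotation files into one catalog.

    ``files`` is a list of ``(path, source_tag, dialect)`` with dialect
    ``"bed"`` or ``"gtf"``.  When the same gene_id occurs in more than one
    source the colliding records are disambiguated by prefixing
    ``"<source>:"`` to the id; unique ids keep their plain names.
    """
    readers = {"bed": read_bed, "gtf": read_gtf}
    catalogs = []
    for path, source, dialect in files:
        try:
            reader = readers[dialect.lower()]
        except KeyError:
            raise ValueError(f"unknown annotation dialect {dialect!r}") from None
        catalogs.append(reader(path, source=source, biotype=biotype,
                               has_protein_id=has_protein_id))

    seen: dict[str, int] = {}
    for cat in catalogs:
        for rec in cat:
            seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1

    merged = GeneCatalog()
    for cat in catalogs:
        merged.provenance.extend(cat.provenance)
        for rec in cat:
            if seen[rec.gene_id] > 1:
                rec.gene_id = f"{rec.source}:{rec.gene_id}"
            merged.add(rec)
    return merged


def read_fragments_bed(path: str | Path):
    """Read aligned fragments from BED6/BED12 lines into FragmentAlignments."""
    from .genome import GenomicInterval
    from .quantify import FragmentAlignment

    frags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise AnnotationError(path, lineno,
                                      f"expected >=6 BED columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError:
                raise AnnotationError(path, lineno, "non-integer coordinates") from None
            strand = _check_strand(f[5], path, lineno)
            blocks = ()
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                blocks = tuple((start + off, start + off + sz)
                               for off, sz in zip(starts, sizes))
            frags.append(FragmentAlignment(
                fragment_id=f[3],
                interval=GenomicInterval(chrom, start, end, strand),
                blocks=blocks))
    return frags


def write_fragments_bed(fragments, path: str | Path) -> None:
    """Write FragmentAlignments as BED6 (outer spans only)."""
    with open(path, "w") as fh:
        for frag in fragments:
            iv = frag.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag.fragment_id}"
                     f"\t0\t{iv.strand}\n")


def write_bed12(catalog: GeneCatalog, path: str | Path) -> None:
    """Write one BED12 line per gene; blocks are the exonic union."""
    with open(path, "w") as fh:
        for rec in catalog:
            locus = build_maximal_locus(rec)
            span = locus.locus_span
            sizes = ",".join(str(e - s) for s, e in locus.exonic_union)
            starts = ",".join(str(s - span.start) for s, _ in locus.exonic_union)
            fh.write("\t".join([
                rec.chrom, str(span.start), str(span.end), rec.gene_id, "0",
                rec.strand, str(span.start), str(span.end), "0",
                str(len(locus.exonic_union)), sizes, starts,
            ]) + "\n")


def write_counts_tsv(counts: dict[str, dict[str, int]], path: str | Path) -> None:
    """Write a gene x sample count matrix as TSV (first column gene_id)."""
    samples = sorted(counts)
    genes: list[str] = []
    for sample in samples:
        for gene in counts[sample]:
            if gene not in genes:
                genes.append(gene)
    with open(path, "w") as fh:
        fh.write("\t".join(["gene_id"] + samples) + "\n")
        for gene in genes:
            fh.write("\t".join([gene] + [str(counts[s].get(gene, 0))
                                         for s in samples]) + "\n")


def read_counts_tsv(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a gene x sample TSV count matrix into sample -> gene -> count."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "gene_id":
            raise AnnotationError(path, 1, "expected header gene_id<TAB>samples")
        samples = header[1:]
        counts: dict[str, dict[str, int]] = {s: {} for s in samples}
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(header):
                raise AnnotationError(path, lineno, "column count mismatch")
            try:
                for s, v in zip(samples, f[1:]):
                    counts[s][f[0]] = int(v)
            except ValueError:
                raise AnnotationError(path, lineno, "non-integer count") from None
    return counts


def write_catalog_manifest(catalog: GeneCatalog, path: str | Path) -> None:
    """Write the catalog as a TSV manifest."""
    cols = ["gene_id", "source", "chrom", "start", "end", "strand",
            "exonic_length", "biotype"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in catalog:
            locus = build_maximal_locus(rec)
            span = locus.locus_span
            fh.write("\t".join([
                rec.gene_id, rec.source, rec.chrom, str(span.start),
                str(span.end), rec.strand, str(locus.exonic_length_nt),
                rec.biotype,
            ]) + "\n")
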