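"""Read filtering, exonic fragment counting, RPKM and fold changes.

Expression of a gene is measured as RPKM over its maximal locus: fragments
are counted when they lie within the locus span and touch the exonic union,
then normalized by exonic-union length (kb) and library size (millions).
Fold changes (depleted/control RPKM ratios) are called on genes passing an
RPKM > 1 expression filter in at least one sample.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import GenomicInterval, MaximalLocus


@dataclass
class ReadRecord:
    """A sequencing read with per-base qualities (numeric Phred scores)."""

    read_id: str
    sequence: str
    qualities: Sequence[int]
    mate_of: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class FragmentAlignment:
    """Aligned fragment: outer span plus aligned blocks (e.g. across a junction)."""

    fragment_id: str
    interval: GenomicInterval
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.blocks:
            self.blocks = ((self.interval.start, self.interval.end),)
        blocks = tuple(sorted(self.blocks))
        for (s, e) in blocks:
            if s < self.interval.start or e > self.interval.end:
                raise ValueError(
                    f"fragment {self.fragment_id}: block outside outer span")
        for (_, e1), (s2, _) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError(
                    f"fragment {self.fragment_id}: overlapping blocks")
        self.blocks = blocks


@dataclass
class ExpressionRecord:
    gene_id: str
    sample_id: str
    count: int
    exonic_length_nt: int
    library_size: int
    rpkm: float


@dataclass
class FoldChangeRecord:
    gene_id: str
    rpkm_control: float
    rpkm_depleted: float
    fc: float
    log2fc: float
    direction: str  # {'up', 'down', 'unchanged'}


def _longest_adapter_match(sequence: str, adapter: str) -> int:
    """Length of the longest adapter substring occurring in the read."""
    best = 0
    for length in range(len(adapter), 0, -1):
        for start in range(0, len(adapter) - length + 1):
            if adapter[start:start + length] in sequence:
                best = length
                break
        if best:
            break
    return best


def filter_reads(reads: Iterable[ReadRecord], adapter: str,
                 max_adapter_match_nt: int = 11,
                 quality_floor: int = 20,
                 min_len_nt: int = 32) -> list[ReadRecord]:
    """Apply the adapter / terminal-quality / length filters to reads.

    Reads containing an adapter match strictly longer than
    ``max_adapter_match_nt`` (default 11 nt) are removed outright; remaining
    reads have terminal bases below ``quality_floor`` trimmed from both ends,
    and reads shorter than ``min_len_nt`` (default 32 nt) after trimming are
    discarded.  Input order is preserved.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    kept: list[ReadRecord] = []
    for read in reads:
        if _longest_adapter_match(read.sequence, adapter) > max_adapter_match_nt:
            continue
        quals = list(read.qualities)
        lo, hi = 0, len(quals)
        while lo < hi and quals[lo] < quality_floor:
            lo += 1
        while hi > lo and quals[hi - 1] < quality_floor:
            hi -= 1
        if hi - lo < min_len_nt:
            continue
        kept.append(ReadRecord(read.read_id, read.sequence[lo:hi],
                               quals[lo:hi], read.mate_of))
    return kept


def count_exonic_fragments(fragments: Iterable[FragmentAlignment],
                           locus: MaximalLocus) -> int:
    """Count fragments that are exonic within the gene's maximal locus.

    A fragment counts when its outer span lies within the locus span and at
    least one aligned block overlaps the exonic union by >= 1 nt.  Each
    fragment counts at most once.
    """
    span = locus.locus_span
    starts = [s for s, _ in locus.exonic_union]
    ends = [e for _, e in locus.exonic_union]
    n = 0
    for frag in fragments:
        iv = frag.interval
        if iv.chrom != span.chrom:
            continue
        if iv.start < span.start or iv.end > span.end:
            continue
        for bs, be in frag.blocks:
            # exon intervals are disjoint+sorted: candidate exon is the last
            # one starting before the block ends
            i = bisect_right(starts, be - 1) - 1
            if i >= 0 and ends[i] > bs:
                n += 1
                break
    return n


def compute_rpkm(count: int, exonic_length_nt: int, library_size: int) -> float:
    """Reads per kilobase of exonic length per million library fragments."""
    if exonic_length_nt <= 0:
        raise ValueError("exonic length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (exonic_length_nt / 1000.0) / (library_size / 1e6)


def expression_table(counts: dict[str, dict[str, int]],
                     lengths: dict[str, int],
                     library_sizes: dict[str, int] | None = None
                     ) -> list[ExpressionRecord]:
    """Build per-gene per-sample ExpressionRecords from a count matrix.

    ``counts`` maps sample_id -> {gene_id: count}.  Library sizes default to
    the total counted fragments per sample.
    """
    records = []
    for sample_id, gene_counts in counts.items():
        lib = (library_sizes[sample_id] if library_sizes
               else sum(gene_counts.values()))
        for gene_id, count in gene_counts.items():
            records.append(ExpressionRecord(
                gene_id=gene_id, sample_id=sample_id, count=count,
                exonic_length_nt=lengths[gene_id], library_size=lib,
                rpkm=compute_rpkm(count, lengths[gene_id], lib)))
    return records


def expression_filter(records: Iterable[ExpressionRecord],
                      min_rpkm: float = 1.0) -> set[str]:
    """Genes expressed above ``min_rpkm`` (strictly) in at least one sample."""
    by_gene: dict[str, dict[str, float]] = {}
    samples: set[str] = set()
    for rec in records:
        by_gene.setdefault(rec.gene_id, {})[rec.sample_id] = rec.rpkm
        samples.add(rec.sample_id)
    for gene_id, per_sample in by_gene.items():
        missing = samples - per_sample.keys()
        if missing:
            raise ValueError(
                f"gene {gene_id}: missing sample record(s) {sorted(missing)}")
    return {g for g, per_sample in by_gene.items()
            if any(r > min_rpkm for r in per_sample.values())}


def fold_changes(records: Iterable[ExpressionRecord],
                 control_sample: str, depleted_sample: str,
                 genes: Iterable[str] | None = None,
                 fc_threshold: float = 2.0,
                 pseudocount: float = 0.0) -> list[FoldChangeRecord]:
    """Depleted/control RPKM fold changes with direction calls.

    ``genes`` restricts output (normally the expression_filter survivors).
    With pseudocount 0, a gene at zero in one sample yields an infinite or
    zero fc and a +/-inf log2fc; callers producing distribution plots should
    pass a small pseudocount (e.g. 0.1) to keep log ratios finite.
    """
    rpkms: dict[str, dict[str, float]] = {}
    for rec in records:
        if rec.rpkm < 0:
            raise ValueError(f"gene {rec.gene_id}: negative RPKM")
        rpkms.setdefault(rec.gene_id, {})[rec.sample_id] = rec.rpkm
    wanted = set(genes) if genes is not None else set(rpkms)

    out = []
    for gene_id in rpkms:
        if gene_id not in wanted:
            continue
        per = rpkms[gene_id]
        if control_sample not in per or depleted_sample not in per:
            raise ValueError(f"gene {gene_id}: missing sample record")
        c = per[control_sample] + pseudocount
        d = per[depleted_sample] + pseudocount
        fc = math.inf if c == 0 and d > 0 else (0.0 if d == 0 and c == 0 else d / c)
        log2fc = math.log2(fc) if 0 < fc < math.inf else (
            math.inf if fc == math.inf else -math.inf)
        if fc > fc_threshold:
            direction = "up"
        elif fc < 1.0 / fc_threshold:
            direction = "down"
        else:
            direction = "unchanged"
        out.append(FoldChangeRecord(gene_id, per[control_sample],
                                    per[depleted_sample], fc, log2fc, direction))
    return out
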