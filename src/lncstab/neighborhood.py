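"""TSS-neighborhood analysis of lncRNA genes.

For each lncRNA, find the nearest transcription start site (TSS) of an
expressed protein-coding gene, record the gap, whether the lncRNA sits on
the promoter (upstream) or gene-body (downstream) side of that TSS in the
coding gene's orientation, and whether the two genes share a strand (sense)
or not (antisense).  Window enrichment asks whether upregulated lncRNAs pile
up within a fixed window upstream of TSSs, Fisher-tested against the
downstream window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffstats import TestResult, fisher_exact, pearson_correlation
from .genome import GeneCatalog, GeneRecord


@dataclass
class NeighborLink:
    lnc_gene_id: str
    coding_gene_id: str
    distance_nt: int  # gap between lncRNA span and coding TSS; 0 if TSS inside span
    side: str  # {'upstream', 'downstream', 'overlapping'}
    orientation: str  # {'sense', 'antisense'}


@dataclass
class WindowEnrichment:
    window_nt: int
    n_up_in_window: int
    n_down_in_window: int
    n_total: int
    fisher_result: TestResult


def tss_of(gene: GeneRecord) -> int:
    """0-based position of the gene's first transcribed base."""
    span = gene.span
    return span.start if gene.strand == "+" else span.end - 1


def _link_to(lnc: GeneRecord, coding: GeneRecord) -> NeighborLink:
    span = lnc.span
    tss = tss_of(coding)
    # gap = number of bases strictly between the lncRNA span and the TSS
    # point; 0 when the TSS falls inside or immediately adjacent to the span
    # (this definition is symmetric under reflecting the genome)
    if span.start - 1 <= tss <= span.end:
        distance = 0
        side = "overlapping"
    else:
        distance = (tss - span.end if tss > span.end
                    else span.start - 1 - tss)
        # which side of the TSS, in the coding gene's orientation?
        lnc_before_tss = span.end <= tss
        if coding.strand == "+":
            side = "upstream" if lnc_before_tss else "downstream"
        else:
            side = "downstream" if lnc_before_tss else "upstream"
    orientation = "sense" if lnc.strand == coding.strand else "antisense"
    return NeighborLink(lnc.gene_id, coding.gene_id, distance, side, orientation)


def nearest_expressed_tss(lnc: GeneRecord,
                          coding_expressed: GeneCatalog) -> NeighborLink | None:
    """Link a lncRNA to the closest expressed coding TSS on its chromosome.

    Distance is the gap between the lncRNA gene span and the TSS point
    (0 when the TSS falls inside the span).  Ties are broken by the smaller
    coding gene_id.  Returns None when the chromosome has no expressed
    coding gene.
    """
    best: NeighborLink | None = None
    for coding in coding_expressed:
        if coding.chrom != lnc.chrom:
            continue
        link = _link_to(lnc, coding)
        if (best is None
                or link.distance_nt < best.distance_nt
                or (link.distance_nt == best.distance_nt
                    and link.coding_gene_id < best.coding_gene_id)):
            best = link
    return best


def link_all(lncs: GeneCatalog, coding_expressed: GeneCatalog
             ) -> list[NeighborLink]:
    """Nearest-TSS links for every lncRNA that has a coding gene on its chromosome."""
    links = []
    for lnc in lncs:
        link = nearest_expressed_tss(lnc, coding_expressed)
        if link is not None:
            links.append(link)
    return links


def window_enrichment(links: list[NeighborLink],
                      window_nt: int = 5000) -> WindowEnrichment:
    """Upstream-vs-downstream asymmetry of links within a TSS window.

    Counts links with 0 < distance <= window_nt on each side (overlapping
    links belong to neither window) and Fisher-tests the 2x2 table
    [[up_in, total - up_in], [down_in, total - down_in]].
    """
    if not links:
        raise ValueError("empty link set")
    n_total = len(links)
    n_up = sum(1 for l in links
               if l.side == "upstream" and 0 < l.distance_nt <= window_nt)
    n_down = sum(1 for l in links
                 if l.side == "downstream" and 0 < l.distance_nt <= window_nt)
    fr = fisher_exact([[n_up, n_total - n_up], [n_down, n_total - n_down]])
    return WindowEnrichment(window_nt, n_up, n_down, n_total, fr)


def neighbor_fc_correlation(links: list[NeighborLink],
                            lnc_log2fc: dict[str, float],
                            coding_log2fc: dict[str, float]) -> TestResult:
    """Pearson correlation of lncRNA vs neighboring-coding log2 fold changes."""
    pairs = [(lnc_log2fc[l.lnc_gene_id], coding_log2fc[l.coding_gene_id])
             for l in links]
    if len(pairs) < 3:
        raise ValueError("need >= 3 linked pairs")
    x, y = zip(*pairs)
    return pearson_correlation(x, y)


def signed_distance(link: NeighborLink) -> int:
    """Distance signed by side: upstream negative, downstream positive."""
    if link.side == "upstream":
        return -link.distance_nt
    if link.side == "downstream":
        return link.distance_nt
    return 0


def distance_histogram(links: list[NeighborLink],
                       bin_nt: int = 10000) -> dict[tuple[int, int], int]:
    """Histogram of signed TSS distances in fixed-width bins.

    Bins are ``(lo, hi]`` for positive (downstream) distances and mirrored
    for upstream; distance 0 falls in the first downstream-side bin
    ``(-bin, 0]``... Concretely: a signed distance d lands in bin
    ``(k*bin, (k+1)*bin]`` with ``k = ceil(d/bin) - 1``.  Bin counts sum to
    the number of links.
    """
    if not links:
        raise ValueError("empty link set")
    hist: dict[tuple[int, int], int] = {}
    for link in links:
        d = signed_distance(link)
        k = int(np.ceil(d / bin_nt)) - 1
        key = (k * bin_nt, (k + 1) * bin_nt)
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items()))


def independence_diagnostics(lnc_log2fc, lengths, expression
                             ) -> tuple[TestResult, TestResult]:
    """Correlations of log2 fold change with log length and log expression.

    Tests whether the fold-change response depends on transcript size or
    baseline expression; on the real data neither correlation is expected.
    """
    fc = np.asarray(lnc_log2fc, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if not (fc.size == lengths.size == expression.size):
        raise ValueError("fold-change, length and expression vectors must align")
    r_len = pearson_correlation(fc, np.log10(lengths))
    r_expr = pearson_correlation(fc, np.log10(expression))
    return r_len, r_expr
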