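#!/usr/bin/env python
"""TSS neighborhood of the upregulated lncRNAs.

Links every upregulated lncRNA to its nearest expressed coding TSS, writes
the link table (results/neighbor_links.tsv), the signed-distance histogram
(results/distance_histogram.tsv), and reports the 5-kb window asymmetry
(Fisher's exact test), the antisense fraction among close upstream links,
and the lncRNA-vs-neighbor fold-change correlation.
"""

import math
from pathlib import Path

from lncstab import annotio, neighborhood
from lncstab.genome import GeneCatalog

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_fc():
    fc, direction = {}, {}
    with open(ROOT / "foldchanges.tsv") as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            fc[f[0]] = float(f[5])
            direction[f[0]] = f[6]
    return fc, direction


def main() -> None:
    coding = annotio.read_bed(ROOT / "sim" / "coding.bed", biotype="coding",
                              has_protein_id=True)
    lnc = annotio.read_bed(ROOT / "sim" / "lnc.bed", biotype="lncRNA")
    fc, direction = load_fc()

    coding_expressed = GeneCatalog()
    for rec in coding:
        if rec.gene_id in fc:  # fold-change table covers expressed genes
            coding_expressed.add(rec)
    up_lnc = GeneCatalog()
    for rec in lnc:
        if direction.get(rec.gene_id) == "up":
            up_lnc.add(rec)

    links = neighborhood.link_all(up_lnc, coding_expressed)
    with open(ROOT / "neighbor_links.tsv", "w") as fh:
        fh.write("lnc_gene_id\tcoding_gene_id\tdistance\tside\torientation\t"
                 "lnc_log2fc\tcoding_log2fc\n")
        for l in links:
            fh.write(f"{l.lnc_gene_id}\t{l.coding_gene_id}\t{l.distance_nt}\t"
                     f"{l.side}\t{l.orientation}\t"
                     f"{fc.get(l.lnc_gene_id, math.nan):.4g}\t"
                     f"{fc.get(l.coding_gene_id, math.nan):.4g}\n")

    hist = neighborhood.distance_histogram(links)
    with open(ROOT / "distance_histogram.tsv", "w") as fh:
        fh.write("bin_lo\tbin_hi\tcount\n")
        for (lo, hi), n in hist.items():
            fh.write(f"{lo}\t{hi}\t{n}\n")

    we = neighborhood.window_enrichment(links, window_nt=5000)
    print(f"{len(links)} upregulated lncRNAs linked; within 5 kb: "
          f"{we.n_up_in_window} upstream vs {we.n_down_in_window} downstream "
          f"(Fisher p {we.fisher_result.p_value:.3g})")

    close_up = [l for l in links
                if l.side == "upstream" and 0 < l.distance_nt <= 5000]
    if close_up:
        anti = sum(l.orientation == "antisense" for l in close_up)
        print(f"antisense among <=5-kb upstream links: {anti}/{len(close_up)}")

    usable = [l for l in links if l.coding_gene_id in fc
              and math.isfinite(fc[l.lnc_gene_id])
              and math.isfinite(fc[l.coding_gene_id])]
    if len(usable) >= 3:
        res = neighborhood.neighbor_fc_correlation(
            usable, {l.lnc_gene_id: fc[l.lnc_gene_id] for l in usable},
            {l.coding_gene_id: fc[l.coding_gene_id] for l in usable})
        print(f"lncRNA vs neighbor fold-change correlation: "
              f"r {res.statistic:+.3f} (p {res.p_value:.3g})")


if __name__ == "__main__":
    main()
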