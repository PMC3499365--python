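#!/usr/bin/env python
"""Quantify expression and call fold changes on the simulated dataset.

RPKM over each gene's maximal locus, the RPKM > 1 expression filter, and
depleted/control fold-change calls at the 2-fold threshold, written to
results/expression.tsv and results/foldchanges.tsv.
"""

from pathlib import Path

from lncstab import annotio, quantify
from lncstab.genome import build_maximal_locus

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    coding = annotio.read_bed(ROOT / "sim" / "coding.bed", biotype="coding",
                              has_protein_id=True)
    lnc = annotio.read_bed(ROOT / "sim" / "lnc.bed", biotype="lncRNA")
    counts = annotio.read_counts_tsv(ROOT / "sim" / "counts.tsv")

    lengths = {r.gene_id: build_maximal_locus(r).exonic_length_nt
               for cat in (coding, lnc) for r in cat}
    records = quantify.expression_table(counts, lengths)
    with open(ROOT / "expression.tsv", "w") as fh:
        fh.write("gene_id\tsample\tcount\tlength\tlibrary_size\trpkm\n")
        for r in sorted(records, key=lambda r: (r.gene_id, r.sample_id)):
            fh.write(f"{r.gene_id}\t{r.sample_id}\t{r.count}\t"
                     f"{r.exonic_length_nt}\t{r.library_size}\t{r.rpkm:.6g}\n")

    expressed = quantify.expression_filter(records, min_rpkm=1.0)
    fcs = quantify.fold_changes(records, "control", "depleted",
                                genes=expressed)
    biotype = {r.gene_id: r.biotype for cat in (coding, lnc) for r in cat}
    with open(ROOT / "foldchanges.tsv", "w") as fh:
        fh.write("gene_id\tbiotype\trpkm_control\trpkm_depleted\tfc\t"
                 "log2fc\tdirection\n")
        for r in sorted(fcs, key=lambda r: r.gene_id):
            fh.write(f"{r.gene_id}\t{biotype[r.gene_id]}\t"
                     f"{r.rpkm_control:.6g}\t{r.rpkm_depleted:.6g}\t"
                     f"{r.fc:.6g}\t{r.log2fc:.6g}\t{r.direction}\n")

    for label in ("coding", "lncRNA"):
        cls = [r for r in fcs if biotype[r.gene_id] == label]
        up = sum(r.direction == "up" for r in cls)
        down = sum(r.direction == "down" for r in cls)
        print(f"{label}: {len(cls)} expressed, {up} up "
              f"({100 * up / len(cls):.1f}%), {down} down "
              f"({100 * down / len(cls):.1f}%)")


if __name__ == "__main__":
    main()
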