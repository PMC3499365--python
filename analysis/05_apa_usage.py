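#!/usr/bin/env python
"""Proximal/distal poly(A)-site usage shift on simulated 3'UTR coverage.

Simulates 3'UTR fragments for a panel of genes whose proximal-site usage
rises from 0.5 (control) to 0.8 (depleted), quantifies the
proximal/distal RPKM ratio fold change per gene, and scans a synthetic
3'-end sequence for the canonical poly(A)-signal hexamer 16 nt upstream of
its cleavage site.  Writes results/apa_usage.tsv.
"""

from pathlib import Path

import numpy as np

from lncstab.apa import apa_usage, partition_utr, scan_polya_signal
from lncstab.synthetic import simulate_apa

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260925


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    rfcs = []
    with open(ROOT / "apa_usage.tsv", "w") as fh:
        fh.write("gene_id\tratio_control\tratio_depleted\tratio_fold_change\n")
        for i in range(20):
            part = partition_utr(f"APA{i:02d}", "c1", 10_000, 12_000, 14_000, "+")
            frags, _ = simulate_apa(part, usage_control=0.5,
                                    usage_depleted=0.8, n_fragments=2000,
                                    seed=SEED + i)
            res = apa_usage(frags, part,
                            {"control": 10_000, "depleted": 10_000})
            rfcs.append(res.ratio_fold_change)
            fh.write(f"{part.gene_id}\t{res.ratio['control']:.4g}\t"
                     f"{res.ratio['depleted']:.4g}\t"
                     f"{res.ratio_fold_change:.4g}\n")

    print(f"proximal/distal usage ratio fold change over 20 genes: "
          f"median {np.median(rfcs):.2f} (analytic expectation "
          f"(0.8/0.2)/(0.5/0.5) = 4.0)")

    # poly(A)-signal geometry: canonical hexamer ending 16 nt upstream of
    # the cleavage site, as in the most upregulated snoRNA-host lncRNA
    seq = "GC" * 20 + "AATAAA" + "ACTGTC" * 2 + "CTGA"
    hits = scan_polya_signal(seq, cleavage_index=len(seq))
    for h in hits:
        print(f"poly(A) signal {h.hexamer} at offset {h.offset_nt} nt "
              f"upstream of the cleavage site")
    mutated = seq.replace("AATAAA", "AGTACT")
    assert scan_polya_signal(mutated, len(mutated)) == []
    print("mutated signal (AGTACT) is not detected as canonical, as expected")


if __name__ == "__main__":
    main()
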