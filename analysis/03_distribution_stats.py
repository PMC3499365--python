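#!/usr/bin/env python
"""Fold-change distribution statistics per gene class.

Sample skewness with D'Agostino's K-squared omnibus test per class, the
coding-vs-lncRNA Kolmogorov-Smirnov and Student's t comparisons, the
chi-squared test on lncRNA up- vs down-proportions, plus exported kernel
density and ECDF curves (results/density_*.tsv, results/ecdf_*.tsv).
"""

import math
from pathlib import Path

from lncstab import diffstats

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_foldchanges():
    classes = {"coding": [], "lncRNA": []}
    directions = {"coding": {"up": 0, "down": 0, "n": 0},
                  "lncRNA": {"up": 0, "down": 0, "n": 0}}
    with open(ROOT / "foldchanges.tsv") as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            log2fc = float(f[5])
            if math.isfinite(log2fc):
                classes[f[1]].append(log2fc)
            directions[f[1]]["n"] += 1
            if f[6] in ("up", "down"):
                directions[f[1]][f[6]] += 1
    return classes, directions


def main() -> None:
    classes, directions = load_foldchanges()

    for label, values in classes.items():
        res = diffstats.dagostino_k2(values)
        print(f"{label}: n={len(values)}, skewness {res.g1:+.3f}, "
              f"K-squared {res.k2:.1f}, p {res.p_value:.3g}")
        grid, density, xs, ecdf = diffstats.density_and_ecdf(values)
        with open(ROOT / f"density_{label}.tsv", "w") as fh:
            fh.write("log2fc\tdensity\n")
            for g, d in zip(grid, density):
                fh.write(f"{g:.6g}\t{d:.6g}\n")
        with open(ROOT / f"ecdf_{label}.tsv", "w") as fh:
            fh.write("log2fc\tecdf\n")
            for x, e in zip(xs, ecdf):
                fh.write(f"{x:.6g}\t{e:.6g}\n")

    ks = diffstats.ks_two_sample(classes["coding"], classes["lncRNA"])
    tt = diffstats.student_t_two_sample(classes["coding"], classes["lncRNA"])
    print(f"coding vs lncRNA: KS D={ks.statistic:.3f} (p {ks.p_value:.3g}), "
          f"t={tt.statistic:.2f} (p {tt.p_value:.3g})")

    d = directions["lncRNA"]
    chi = diffstats.chi2_two_proportions(d["up"], d["n"], d["down"], d["n"])
    print(f"lncRNA up {d['up']}/{d['n']} vs down {d['down']}/{d['n']}: "
          f"chi2 {chi.statistic:.1f}, p {chi.p_value:.3g}")


if __name__ == "__main__":
    main()
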