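# lncstab

Analysis pipeline for studying the **selective stabilization of long
noncoding RNAs (lncRNAs) upon depletion of the nuclear poly(A)-binding
protein (PABPN1)**. Knocking down PABPN1 in human cells leaves most
protein-coding mRNAs untouched but causes a minority of polyadenylated
lncRNAs — many of them snoRNA-host transcripts positioned upstream-antisense
of coding-gene promoters — to accumulate, because PABPN1 normally routes
them into polyadenylation-dependent decay. This package re-implements the
computational side of that analysis as a tested, reusable library plus a set
of narrative analysis scripts, exercised end-to-end on seeded synthetic data
with known ground truth.

It is written for computational biologists who want to run, audit, or adapt
the individual stages:

1. **Catalog construction** — multi-source gene annotations (GTF/BED) merged
   into coding and lncRNA catalogs; redundant genes (spans completely
   contained within another gene) removed; lncRNAs kept only when their
   spliced length exceeds 200 nt.
2. **Quantification** — fragments counted when exonic within a gene's
   *maximal locus* (the union of all isoforms), expression as
   RPKM = count / (exonic kb) / (library millions), genes kept when
   RPKM > 1 in at least one sample, fold change FC = RPKM_depleted /
   RPKM_control with up/down calls at FC > 2 (resp. < 1/2).
3. **Distribution statistics** — per-class log₂ FC sample skewness
   g₁ = m₃/m₂^{3/2} with D'Agostino's K² omnibus normality test
   (K² = Z(g₁)² + Z(g₂)² ~ χ²₂), two-sample Kolmogorov–Smirnov and Student's
   t class comparisons, χ² on up- vs down-proportions, Fisher's exact test,
   Gaussian-kernel densities and ECDFs.
4. **TSS neighborhoods** — each lncRNA linked to the nearest expressed
   coding-gene transcription start site; signed distance, upstream/downstream
   side in the coding gene's frame, sense/antisense orientation; 5-kb window
   asymmetry Fisher-tested; fold-change correlation diagnostics.
5. **Alternative polyadenylation** — 3′UTRs split at the proximal poly(A)
   site; per-sample proximal/distal RPKM ratios; a ratio fold change > 1
   reports increased proximal-site usage; AAUAAA-family hexamer scanning
   upstream of cleavage sites.
6. **Kinetics** — comparative-Ct (ΔΔCt) qPCR fold changes, first-order decay
   fits A(t) = e^{−kt} (t½ = ln2/k) from transcription-shutoff time courses,
   ChIP fold-enrichment / percent-input and RNA-IP enrichment arithmetic.

A seeded synthetic-data module generates annotations, two-condition count
tables, 3′UTR fragment coverage, decay chases and Ct tables with truth
manifests, so every stage can be scored against known parameters.

## Worked example

Run the numbered analysis scripts in order (each writes tables under
`results/`):

```bash
python analysis/01_simulate_data.py
python analysis/02_expression_foldchanges.py
python analysis/03_distribution_stats.py
python analysis/04_tss_neighborhood.py
```

which prints, for the default seed:

```
coding: 500 expressed, 0 up (0.0%), 1 down (0.2%)
lncRNA: 150 expressed, 20 up (13.3%), 1 down (0.7%)
coding: n=500, skewness -0.150, K-squared 3.7, p 0.158
lncRNA: n=150, skewness +1.755, K-squared 54.5, p 1.49e-12
coding vs lncRNA: KS D=0.165 (p 0.00324), t=-7.49 (p 2.33e-13)
lncRNA up 20/150 vs down 1/150: chi2 18.5, p 1.71e-05
20 upregulated lncRNAs linked; within 5 kb: 4 upstream vs 0 downstream (Fisher p 0.106)
lncRNA vs neighbor fold-change correlation: r -0.062 (p 0.796)
```

Reading this: the simulation planted a >2-fold effect in 13% of lncRNAs and
none in coding genes, and the pipeline recovers exactly that structure — the
lncRNA class shows a 13.3% up-fraction and a strongly right-skewed log₂
fold-change distribution (skewness +1.76, K² p ≈ 10⁻¹²) while the coding
class stays symmetric near zero; the two distributions differ by KS and t
tests; and the up- vs down-proportion difference is highly significant by
χ². The neighbor fold changes are uncorrelated, as simulated.
`analysis/05_apa_usage.py` and `analysis/06_decay_kinetics.py` exercise the
poly(A)-usage shift (median ratio fold change 3.88 against the analytic 4.0)
and decay fitting (a 60→180 min half-life stabilization recovered at 60 and
203 min).

The same stages are available as subcommands of the `lncstab` console
script (`simulate`, `catalog`, `quantify`, `diffexp`, `neighbors`, `apa`,
`decay`, `report`).

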