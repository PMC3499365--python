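# Methods

## Coordinate conventions and catalog construction

All genomic coordinates are internally 0-based, half-open `[start, end)`;
GTF input (1-based, closed) is converted at the I/O boundary, BED passes
through unchanged. A gene is a set of isoforms, each a sorted list of
disjoint exons; its *maximal locus* is the span covering every isoform
together with the exonic union, whose length (in nt) is the gene's spliced
length and the RPKM normalizer.

Catalog rules, each with a deliberate convention where the underlying
procedure is ambiguous:

- **Redundancy removal.** A gene is dropped when its span is completely
  contained within another *retained* gene's span. Containment is
  strand-agnostic and span-based (not exon-based). Genes with identical
  spans contain each other; the lexicographically larger gene id is dropped,
  making the operation deterministic and idempotent. Processing is
  widest-first so containment chains resolve to the outermost gene.
- **lncRNA length cutoff.** "Longer than 200 nt" is applied to the spliced
  (exonic-union) length with a strict inequality, consistent with the
  definition of lncRNAs as noncoding transcripts > 200 nt. A 200-nt gene is
  excluded, a 201-nt gene retained.
- **Multi-source merging.** Identical gene ids across sources keep one copy;
  colliding ids naming different genes are disambiguated by source-prefixing,
  then the same containment rule removes cross-source redundancy.
- **Coding/noncoding partition.** "Coding" means the annotation carries
  protein-ID evidence; no coding-potential scoring is performed. The
  non-overlapping coding subset drops any coding gene sharing ≥ 1 nt of span
  with a lncRNA, strand-agnostic.
- Genes on unplaced/alternate contigs are retained; filtering them is the
  caller's concern.

## Quantification

Read filtering follows the adapter / quality / length scheme: reads with an
adapter substring match strictly longer than 11 nt are removed, terminal
bases below the quality floor (default Phred 20) are trimmed from both ends,
and reads shorter than 32 nt after trimming are discarded.

A fragment counts toward a gene when its outer span lies within the maximal
locus and at least one aligned block overlaps the exonic union by ≥ 1 nt;
each fragment counts at most once per gene, but a fragment overlapping two
genes' unions counts once for each (no disambiguation is attempted, since
none is defined for this analysis). Paired mates are treated as one
fragment; this only rescales library size, to which RPKM ratios are
invariant. The "mappable region" is approximated by the exonic-union length
— exact on synthetic data, the standard simplification otherwise.

RPKM = count / (exonic_length/1000) / (library_size/10⁶) with library size
defaulting to the total counted fragments per sample. A gene is *expressed*
when RPKM > 1 (strict) in at least one sample. Fold change is the
depleted/control RPKM ratio on expressed genes; "up" means FC > 2 (strict),
"down" FC < 1/2. The default pseudocount is 0 — the RPKM > 1 filter
guards the denominator, and a filtered gene at 0 in one sample legitimately
yields an infinite or zero ratio. For distribution statistics (skewness,
KDE, ECDF, class tests) a pseudocount of 0.1 RPKM is applied so every log₂
ratio is finite; direction calls always use pseudocount 0.

## Distribution statistics

Sample skewness is the biased moment estimator g₁ = m₃/m₂^{3/2} (the input
to D'Agostino's transformation); the bias-adjusted G₁ is available by flag.
D'Agostino's K² combines the skewness deviate Z(g₁) with the Anscombe–Glynn
kurtosis deviate Z(g₂), K² = Z(g₁)² + Z(g₂)² referred to χ² with 2 df, and
requires n ≥ 20; a skewness-only Z test is exposed separately. The
two-sample KS test uses the asymptotic two-sided p-value. The two-proportion
χ² builds the 2×2 table `[[x1, n1−x1], [x2, n2−x2]]` with df = 1; Yates'
continuity correction is off by default and available by flag (the printed
significance bounds hold either way). Fisher's exact test is two-sided by
the conventional rule — sum over tables, margins fixed, with hypergeometric
probability ≤ that of the observed table. Student's t defaults to pooled
variance as named, with Welch by flag. Kernel densities are Gaussian with
Silverman's bandwidth. No multiple-testing correction is applied anywhere;
the analysis reports a small number of planned tests.

## TSS neighborhoods

The TSS is the first transcribed base: `span.start` on `+`, `span.end − 1`
on `−`. The distance between a lncRNA and a coding TSS is the number of
bases strictly between the lncRNA span and the TSS point — 0 when the TSS
falls inside or immediately adjacent to the span. This "gap" definition is
exactly symmetric under reflecting the genome (a property the test suite
checks); measuring to interval endpoints instead would be off by one on one
side. Side is assigned in the coding gene's frame: a lncRNA on the promoter
side of the TSS is *upstream*. Orientation is *sense* when strands match.
Nearest-TSS ties break on the smaller gene id. Window membership uses
0 < d ≤ window (default 5 kb), so overlapping links belong to neither
window; the enrichment 2×2 is
`[[n_up_in_window, total − n_up_in_window], [n_down_in_window, total − n_down_in_window]]`.
Signed-distance histograms bin at 10 kb with `(lo, hi]` bins, upstream
negative.

## Alternative polyadenylation

The 3′UTR between the stop codon and the distal poly(A) site is split at
the proximal site into proximal and distal segments that tile it exactly;
poly(A)-site coordinates are inputs (taken from annotation, not called de
novo). Fragments are assigned to the segment containing their 3′-most
aligned base — a boundary-spanning fragment therefore goes to the distal
segment on `+` genes. Per-sample usage is the proximal/distal RPKM ratio;
the condition fold change of that ratio is library-size invariant, and a
value > 1 reports a shift toward the proximal site. A sample with zero
distal signal leaves its ratio undefined and flags the result rather than
dividing by zero.

Poly(A)-signal scanning normalizes U≡T, accepts a configurable hexamer list
(canonical AAUAAA by default), and reports every hexamer whose end falls
within the window (default 50 nt) upstream of the cleavage index, ordered by
offset. The canonical geometry of interest is a hexamer ending ~16 nt
upstream of the cleavage site.

## Kinetics

ΔΔCt fold change is `E^−[(Ct_t,case − Ct_r,case) − (Ct_t,ctl − Ct_r,ctl)]`
with efficiency E = 2 (perfect doubling) by default; no standard-curve
calibration is modeled. Decay time courses are normalized to a stable
reference transcript and to t = 0, then fitted as ln A(t) = −k·t by linear
least squares with an intercept (absorbing normalization noise); the fit is
exact on noiseless exponentials and robust at the 3–6 point scale of a
typical chase. k is clipped at 0 and a transcript with k < 10⁻⁴/min is
flagged stable — a 72-h chase would show under 1% decay. Half-life is
ln 2 / k. First-order (single-exponential) decay is the standard
interpretation of an RNA decay rate; no multi-exponential model is offered.
ChIP and RNA-IP enrichments are pure ratio arithmetic (fold over no-antibody
control; percent input normalized to control; IP:input double ratio against
a reference RNA and a control IP) and are invariant to common rescaling of
their numerator/denominator pairs.

## Synthetic data: what it emulates, and what it does not

The generators are seeded (`numpy.random.default_rng`; same config + seed ⇒
identical output) and every one returns a truth manifest. Defaults encode
the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_coding`, `n_lnc` | 500, 150 | desk-scale catalog (runs in seconds) |
| `frac_lnc_up` | 0.13 | fraction of lncRNAs truly upregulated (13%) |
| `effect_size_log2` | 2.0 | mean true log₂ FC of upregulated lncRNAs (≈4-fold), sd 0.25, floored at 1.1 so every planted effect exceeds the 2-fold threshold |
| `upstream_bias` | 0.8 | probability a lncRNA is placed on the promoter side of its paired coding TSS |
| `antisense_bias` | 0.8 | probability of opposite strand |
| `placement_window_nt` | 20 000 | maximal lncRNA–TSS gap |
| `baseline_mean_count` | 300 | log-normal (sd 0.8) per-gene baseline |
| `dispersion` | 0.01 | negative-binomial dispersion (var = μ + 0.01 μ²) |

Coding genes occupy evenly spaced slots ≥ 200 kb apart — far enough that
each lncRNA's paired TSS is provably its nearest, keeping placement truth
labels exact. Counts are negative binomial: one library per condition, as in
the underlying experimental design, so the dispersion stands for technical
plus residual between-library variation rather than biological replication.
At the default baseline it puts the null log₂-ratio sd near 0.24, which
keeps spurious 2-fold calls well below 1% — the generator's own null
calibration — while leaving planted ≥ 2-fold effects trivially detectable.
Coding genes carry zero true effect; the small down-shift sometimes visible
in coding fold changes is a real composition effect (upregulated lncRNAs
inflate the depleted library size) and is left in deliberately.

What passing on this synthetic data does **not** show: recovery of the
genome-scale catalog numbers (469 expressed lncRNAs, 60/16 up/down, class
skewness 0.33/0.87, the 24-vs-1 window counts), which depend on the real
HeLa libraries and the full multi-source annotation; robustness to
mappability artifacts, overlapping-gene read ambiguity at real densities,
or annotation errors; and any FASTQ-level error structure (fragments are
emitted as clean single-block alignments inside exons). Decay, APA and qPCR
generators use multiplicative log-normal noise, which is idealized but
matches the scale-invariance of the downstream estimators.

Analysis problem sizes (500 + 150 genes, 2 000 APA fragments per gene,
100–500 decay/qPCR replicates, 2 000 null test replicates) were chosen so
the full suite and the acceptance script each run in well under a minute of
CPU while keeping Monte-Carlo error far inside the asserted tolerances.

## Known limitations

- Deduplication is span-based; two genes sharing a span but with disjoint
  exon structures are still treated as redundant.
- Fragments overlapping two genes count once per gene; no expectation-style
  assignment is attempted.
- The Fisher 2×2 for window enrichment is one documented choice among
  plausible constructions (e.g. a binomial test on 24 vs 1); the reported
  significance bound is robust across them.
- The decay fit assumes a single first-order component; biphasic decay will
  be summarized by an effective rate with reduced r².
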