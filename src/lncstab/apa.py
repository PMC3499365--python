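"""Alternative polyadenylation: proximal/distal 3'UTR usage and poly(A) signals.

The 3'UTR of a gene with two annotated poly(A) sites is split at the
proximal site: the proximal segment runs from the stop codon to the proximal
poly(A) site, the distal segment from there to the distal site.  Segment
RPKMs give a per-sample proximal/distal usage ratio whose depleted/control
fold change > 1 reports increased proximal poly(A)-site usage.

Poly(A)-signal scanning locates hexamers (canonically AAUAAA) within a
window upstream of an annotated cleavage site, RNA/DNA alphabet agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import GenomicInterval
from .quantify import FragmentAlignment, compute_rpkm

CANONICAL_HEXAMER = "AATAAA"


@dataclass
class UtrPartition:
    gene_id: str
    strand: str
    stop_codon_end: int
    proximal_pa_site: int
    distal_pa_site: int
    proximal_segment: GenomicInterval
    distal_segment: GenomicInterval


@dataclass
class ApaResult:
    gene_id: str
    rpkm_proximal: dict[str, float]
    rpkm_distal: dict[str, float]
    ratio: dict[str, float | None]  # proximal/distal per sample; None if undefined
    ratio_fold_change: float | None  # depleted ratio / control ratio
    flagged: bool = False


@dataclass(frozen=True)
class PolyASignalHit:
    hexamer: str
    position: int  # start of the hexamer in the scanned sequence
    offset_nt: int  # distance from hexamer end to the cleavage site

    def __post_init__(self) -> None:
        if len(self.hexamer) != 6:
            raise ValueError("poly(A) signal must be a hexamer")
        if self.offset_nt < 0:
            raise ValueError("offset must be non-negative")


def partition_utr(gene_id: str, chrom: str, stop_codon_end: int,
                  proximal_pa: int, distal_pa: int, strand: str) -> UtrPartition:
    """Split a 3'UTR into proximal and distal segments at the proximal pA site.

    Coordinates are given in genomic space but must be in strict
    transcription order: stop < proximal pA < distal pA reading along the
    strand (so on '-' the genomic values decrease).
    """
    if strand == "+":
        ok = stop_codon_end < proximal_pa < distal_pa
        prox = (stop_codon_end, proximal_pa)
        dist = (proximal_pa, distal_pa)
    elif strand == "-":
        ok = stop_codon_end > proximal_pa > distal_pa
        prox = (proximal_pa, stop_codon_end)
        dist = (distal_pa, proximal_pa)
    else:
        raise ValueError(f"unknown strand symbol {strand!r}")
    if not ok:
        raise ValueError(
            f"gene {gene_id}: stop/proximal/distal coordinates not in "
            f"transcription order on {strand} strand")
    return UtrPartition(
        gene_id=gene_id, strand=strand, stop_codon_end=stop_codon_end,
        proximal_pa_site=proximal_pa, distal_pa_site=distal_pa,
        proximal_segment=GenomicInterval(chrom, *prox, strand=strand),
        distal_segment=GenomicInterval(chrom, *dist, strand=strand))


def _three_prime_end(frag: FragmentAlignment, strand: str) -> int:
    """Position of the fragment's 3'-most aligned base on the given strand."""
    return frag.interval.end - 1 if strand == "+" else frag.interval.start


def assign_fragment(frag: FragmentAlignment, partition: UtrPartition) -> str | None:
    """Assign a fragment to 'proximal' or 'distal' by its 3'-most aligned base."""
    pos = _three_prime_end(frag, partition.strand)
    for name, seg in (("proximal", partition.proximal_segment),
                      ("distal", partition.distal_segment)):
        if frag.interval.chrom == seg.chrom and seg.start <= pos < seg.end:
            return name
    return None


def apa_usage(fragments_per_sample: dict[str, Iterable[FragmentAlignment]],
              partition: UtrPartition,
              library_sizes: dict[str, int],
              control_sample: str = "control",
              depleted_sample: str = "depleted") -> ApaResult:
    """Quantify proximal/distal 3'UTR usage and its condition fold change.

    Fragments are assigned to the segment containing their 3'-most aligned
    base; per-sample segment RPKMs give ratio = RPKM_prox / RPKM_dist, and
    ratio_fold_change = ratio_depleted / ratio_control.  A sample with zero
    distal signal leaves its ratio (and the fold change) undefined and flags
    the result.
    """
    rpkm_prox: dict[str, float] = {}
    rpkm_dist: dict[str, float] = {}
    ratio: dict[str, float | None] = {}
    flagged = False
    for sample, frags in fragments_per_sample.items():
        lib = library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"sample {sample}: library size must be positive")
        n_prox = n_dist = 0
        for frag in frags:
            seg = assign_fragment(frag, partition)
            if seg == "proximal":
                n_prox += 1
            elif seg == "distal":
                n_dist += 1
        rpkm_prox[sample] = compute_rpkm(
            n_prox, partition.proximal_segment.length, lib)
        rpkm_dist[sample] = compute_rpkm(
            n_dist, partition.distal_segment.length, lib)
        if n_dist == 0:
            ratio[sample] = None
            flagged = True
        else:
            ratio[sample] = rpkm_prox[sample] / rpkm_dist[sample]

    rfc = None
    rc, rd = ratio.get(control_sample), ratio.get(depleted_sample)
    if rc and rd is not None:
        rfc = rd / rc
    return ApaResult(gene_id=partition.gene_id, rpkm_proximal=rpkm_prox,
                     rpkm_distal=rpkm_dist, ratio=ratio,
                     ratio_fold_change=rfc, flagged=flagged)


def scan_polya_signal(sequence: str, cleavage_index: int,
                      window_nt: int = 50,
                      hexamers: Sequence[str] = (CANONICAL_HEXAMER,)
                      ) -> list[PolyASignalHit]:
    """Find poly(A)-signal hexamers upstream of a cleavage site.

    Reports every occurrence of a listed hexamer whose last base lies within
    ``window_nt`` nucleotides upstream of ``cleavage_index`` (the 0-based
    position of the first base after the cleavage site).  U and T are
    equivalent; matching is case-insensitive.  Hits are ordered by
    ascending offset (distance from hexamer end to the cleavage site,
    nearest first).
    """
    if not (0 <= cleavage_index <= len(sequence)):
        raise ValueError(
            f"cleavage index {cleavage_index} outside sequence of "
            f"length {len(sequence)}")
    if window_nt < 6:
        raise ValueError("window must be at least one hexamer wide")
    seq = sequence.upper().replace("U", "T")
    wanted = {h.upper().replace("U", "T") for h in hexamers}
    for h in wanted:
        if len(h) != 6:
            raise ValueError(f"poly(A) signal {h!r} is not a hexamer")
    hits = []
    lo = max(0, cleavage_index - window_nt - 6)
    for start in range(lo, cleavage_index - 5):
        kmer = seq[start:start + 6]
        if kmer in wanted:
            offset = cleavage_index - (start + 6)
            hits.append(PolyASignalHit(hexamer=kmer, position=start,
                                       offset_nt=offset))
    hits.sort(key=lambda h: h.offset_nt)
    return hits


def scan_polya_fasta(path, cleavage_indices: dict[str, int] | None = None,
                     window_nt: int = 50,
                     hexamers: Sequence[str] = (CANONICAL_HEXAMER,)
                     ) -> dict[str, list[PolyASignalHit]]:
    """Scan every FASTA record for poly(A)-signal hexamers.

    ``cleavage_indices`` maps record id to the cleavage position within the
    record; records not listed are scanned at their 3' end (the cleavage
    site is taken as the end of the sequence, the natural convention for
    3'-end-anchored sequences).
    """
    from Bio import SeqIO

    cleavage_indices = cleavage_indices or {}
    out = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        cleavage = cleavage_indices.get(record.id, len(seq))
        out[record.id] = scan_polya_signal(seq, cleavage, window_nt=window_nt,
                                           hexamers=hexamers)
    return out
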