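"""Read filtering, exonic counting, RPKM arithmetic and fold-change calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncstab.genome import GenomicInterval, build_maximal_locus
from lncstab.quantify import (
    FragmentAlignment,
    ReadRecord,
    compute_rpkm,
    count_exonic_fragments,
    expression_filter,
    expression_table,
    filter_reads,
    fold_changes,
)

from conftest import make_gene


def read(seq, q=40, rid="r"):
    return ReadRecord(rid, seq, [q] * len(seq))


class TestFilterReads:
    ADAPTER = "AGATCGGAAGAGCACACGTC"

    def test_adapter_match_over_11nt_removed(self):
        r = read(self.ADAPTER[:12] + "C" * 88)
        assert filter_reads([r], self.ADAPTER) == []

    def test_adapter_match_of_exactly_11nt_kept(self):
        r = read(self.ADAPTER[:11] + "C" * 89)
        assert len(filter_reads([r], self.ADAPTER)) == 1

    def test_trimmed_below_32nt_discarded(self):
        # 31 good bases flanked by low-quality tails
        quals = [2] * 5 + [40] * 31 + [2] * 5
        r = ReadRecord("r", "A" * 41, quals)
        assert filter_reads([r], self.ADAPTER) == []

    def test_trimmed_to_exactly_32nt_kept(self):
        quals = [2] * 5 + [40] * 32 + [2] * 5
        r = ReadRecord("r", "A" * 42, quals)
        out = filter_reads([r], self.ADAPTER)
        assert len(out) == 1 and len(out[0].sequence) == 32

    def test_clean_read_unchanged_and_order_preserved(self):
        reads = [read("ACGT" * 25, rid=f"r{i}") for i in range(3)]
        out = filter_reads(reads, self.ADAPTER)
        assert [r.read_id for r in out] == ["r0", "r1", "r2"]
        assert out[0].sequence == "ACGT" * 25

    def test_empty_input_empty_output(self):
        assert filter_reads([], self.ADAPTER) == []


def frag(chrom, start, end, blocks=None, fid="f"):
    return FragmentAlignment(fid, GenomicInterval(chrom, start, end, "+"),
                             tuple(blocks) if blocks else ())


def brute_force_count(fragments, locus):
    n = 0
    for f in fragments:
        if f.interval.chrom != locus.locus_span.chrom:
            continue
        if not (locus.locus_span.start <= f.interval.start
                and f.interval.end <= locus.locus_span.end):
            continue
        exonic = any(bs < ee and es < be
                     for bs, be in f.blocks
                     for es, ee in locus.exonic_union)
        n += exonic
    return n


class TestExonicCounting:
    LOCUS = build_maximal_locus(
        make_gene("g", "c1", 1000, 9000, exons=[(1000, 2000), (8000, 9000)]))

    def test_fragment_inside_exon_counts(self):
        assert count_exonic_fragments([frag("c1", 1200, 1300)], self.LOCUS) == 1

    def test_intronic_fragment_does_not_count(self):
        assert count_exonic_fragments([frag("c1", 3000, 3100)], self.LOCUS) == 0

    def test_fragment_outside_span_does_not_count(self):
        assert count_exonic_fragments([frag("c1", 500, 1500)], self.LOCUS) == 0
        assert count_exonic_fragments([frag("c2", 1200, 1300)], self.LOCUS) == 0

    def test_junction_fragment_with_exonic_block_counts(self):
        f = frag("c1", 1900, 8100, blocks=[(1900, 2000), (8000, 8100)])
        assert count_exonic_fragments([f], self.LOCUS) == 1

    def test_one_nt_overlap_counts(self):
        assert count_exonic_fragments([frag("c1", 1999, 2050)], self.LOCUS) == 1
        assert count_exonic_fragments([frag("c1", 2000, 2050)], self.LOCUS) == 0

    def test_random_fragments_match_brute_force_oracle(self, rng):
        loci = [
            build_maximal_locus(make_gene(
                "a", "c1", 0, 5000, exons=[(0, 1000), (4000, 5000)])),
            build_maximal_locus(make_gene(
                "b", "c1", 3000, 20000, exons=[(3000, 3500), (10000, 20000)])),
            build_maximal_locus(make_gene("c", "c2", 100, 700)),
        ]
        frags = []
        for i in range(50):
            chrom = "c1" if rng.random() < 0.8 else "c2"
            start = int(rng.integers(0, 20000))
            length = int(rng.integers(50, 2000))
            if rng.random() < 0.3:
                gap = int(rng.integers(100, 3000))
                blocks = [(start, start + length // 2),
                          (start + length // 2 + gap, start + length + gap)]
                f = frag(chrom, start, start + length + gap, blocks, fid=f"f{i}")
            else:
                f = frag(chrom, start, start + length, fid=f"f{i}")
            frags.append(f)
        for locus in loci:
            assert (count_exonic_fragments(frags, locus)
                    == brute_force_count(frags, locus))


class TestRpkm:
    def test_closed_form(self):
        assert compute_rpkm(200, 1000, 2_000_000) == pytest.approx(100.0)

    def test_zero_count_zero_rpkm(self):
        assert compute_rpkm(0, 1000, 1_000_000) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 1000)
        with pytest.raises(ValueError):
            compute_rpkm(1, 1000, 0)

    @given(count=st.integers(0, 10**6), length=st.integers(1, 10**5),
           lib=st.integers(1, 10**8), k=st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, count, length, lib, k):
        base = compute_rpkm(count, length, lib)
        scaled = compute_rpkm(count * k, length, lib * k)
        assert scaled == pytest.approx(base, rel=1e-12)


def table(ctrl, depl, lengths=None):
    genes = list(ctrl)
    lengths = lengths or {g: 1000 for g in genes}
    return expression_table({"control": ctrl, "depleted": depl}, lengths)


class TestExpressionFilter:
    def test_expressed_in_one_sample_is_enough(self):
        recs = table({"g": 1, "o": 99}, {"g": 24, "o": 76})
        for r in recs:
            r.rpkm = {"control": {"g": 0.5, "o": 3.0},
                      "depleted": {"g": 1.2, "o": 3.0}}[r.sample_id][r.gene_id]
        assert "g" in expression_filter(recs, min_rpkm=1.0)

    def test_strict_inequality_at_threshold(self):
        recs = [r for r in table({"a": 10, "b": 10}, {"a": 10, "b": 10})]
        rpkm = recs[0].rpkm
        assert expression_filter(recs, min_rpkm=rpkm) == set()
        assert expression_filter(recs, min_rpkm=rpkm * 0.999) == {"a", "b"}

    def test_zero_everywhere_excluded(self):
        recs = table({"g": 0, "h": 100}, {"g": 0, "h": 100})
        assert "g" not in expression_filter(recs, min_rpkm=0.5)

    def test_missing_sample_record_is_error(self):
        recs = table({"g": 5, "h": 5}, {"g": 5, "h": 5})
        with pytest.raises(ValueError, match="missing sample"):
            expression_filter(recs[:-1])


class TestFoldChanges:
    def test_simple_up_call(self):
        recs = table({"g": 2, "o": 98}, {"g": 8, "o": 92})
        # force RPKMs directly for determinism
        for r in recs:
            r.rpkm = {"control": {"g": 2.0, "o": 1.0},
                      "depleted": {"g": 8.0, "o": 1.0}}[r.sample_id][r.gene_id]
        fc = {r.gene_id: r for r in fold_changes(recs, "control", "depleted")}
        assert fc["g"].fc == pytest.approx(4.0)
        assert fc["g"].direction == "up"
        assert fc["o"].direction == "unchanged"

    def test_equal_rpkm_unchanged(self):
        recs = table({"g": 8}, {"g": 8})
        fc = fold_changes(recs, "control", "depleted")[0]
        assert fc.fc == pytest.approx(1.0)
        assert fc.direction == "unchanged"

    def test_threshold_is_strict(self):
        recs = table({"g": 1}, {"g": 1})
        for r in recs:
            r.rpkm = 1.0 if r.sample_id == "control" else 2.0
        assert fold_changes(recs, "control", "depleted")[0].direction \
            == "unchanged"

    def test_reciprocal_property(self, rng):
        ctrl = {f"g{i}": int(rng.integers(1, 500)) for i in range(40)}
        depl = {f"g{i}": int(rng.integers(1, 500)) for i in range(40)}
        recs = table(ctrl, depl)
        fwd = {r.gene_id: r.fc for r in fold_changes(recs, "control", "depleted")}
        rev = {r.gene_id: r.fc for r in fold_changes(recs, "depleted", "control")}
        for g in fwd:
            assert fwd[g] * rev[g] == pytest.approx(1.0, rel=1e-12)

    def test_direction_calls_match_brute_force(self, rng):
        ctrl = {f"g{i}": int(rng.integers(0, 300)) for i in range(100)}
        depl = {f"g{i}": int(rng.integers(0, 300)) for i in range(100)}
        recs = table(ctrl, depl)
        rpkms = {}
        for r in recs:
            rpkms.setdefault(r.gene_id, {})[r.sample_id] = r.rpkm
        for rec in fold_changes(recs, "control", "depleted", pseudocount=0.1):
            c = rpkms[rec.gene_id]["control"] + 0.1
            d = rpkms[rec.gene_id]["depleted"] + 0.1
            expect = "up" if d / c > 2 else ("down" if d / c < 0.5 else "unchanged")
            assert rec.direction == expect

    def test_infinite_fc_with_zero_pseudocount(self):
        recs = table({"g": 0, "o": 100}, {"g": 50, "o": 50})
        for r in recs:
            if r.gene_id == "g":
                r.rpkm = 0.0 if r.sample_id == "control" else 5.0
        rec = fold_changes(recs, "control", "depleted")[0]
        assert math.isinf(rec.fc) and rec.direction == "up"


def test_direction_recovery_on_synthetic_fourfold_effects():
    """>= 95% of genes with a true 4-fold effect at healthy baselines are called up."""
    from lncstab.synthetic import SimulationConfig, TruthManifest, simulate_annotation, simulate_counts

    cfg = SimulationConfig(seed=11, n_coding=300, n_lnc=100, frac_lnc_up=0.0,
                           baseline_mean_count=500.0)
    coding, lnc, _ = simulate_annotation(cfg)
    truth = TruthManifest()
    changed = [g.gene_id for g in lnc][:40]
    for gid in changed:
        truth.log2_fc[gid] = 2.0  # exactly 4-fold
    counts, truth = simulate_counts(coding, lnc, cfg, truth)
    lengths = {r.gene_id: build_maximal_locus(r).exonic_length_nt
               for cat in (coding, lnc) for r in cat}
    recs = expression_table(counts, lengths)
    calls = {r.gene_id: r.direction
             for r in fold_changes(recs, "control", "depleted")}
    recovered = sum(calls[g] == "up" for g in changed)
    assert recovered / len(changed) >= 0.95
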