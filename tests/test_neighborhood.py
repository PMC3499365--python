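"""Nearest-TSS links, window enrichment, distances and independence checks."""

import numpy as np
import pytest

from lncstab.diffstats import fisher_exact
from lncstab.genome import GeneCatalog
from lncstab.neighborhood import (
    distance_histogram,
    independence_diagnostics,
    link_all,
    neighbor_fc_correlation,
    nearest_expressed_tss,
    signed_distance,
    tss_of,
    window_enrichment,
)

from conftest import make_catalog, make_gene


class TestTss:
    def test_plus_strand_tss_is_start(self):
        assert tss_of(make_gene("g", "c1", 100, 200, "+")) == 100

    def test_minus_strand_tss_is_last_base(self):
        assert tss_of(make_gene("g", "c1", 100, 200, "-")) == 199

    def test_single_base_gene(self):
        assert tss_of(make_gene("g", "c1", 5, 6, "+")) == 5
        assert tss_of(make_gene("g", "c1", 5, 6, "-")) == 5


class TestNearestTss:
    def test_upstream_antisense_geometry(self):
        # lncRNA [0,1000) on '-', coding [3000,9000) on '+': the lncRNA sits
        # on the promoter side of the coding TSS at a 2000-nt gap
        lnc = make_gene("L", "c1", 0, 1000, "-")
        coding = make_catalog(make_gene("C", "c1", 3000, 9000, "+"))
        link = nearest_expressed_tss(lnc, coding)
        assert link.distance_nt == 2000
        assert link.side == "upstream"
        assert link.orientation == "antisense"

    def test_tss_inside_lncrna_is_overlapping(self):
        lnc = make_gene("L", "c1", 2500, 3500, "+")
        coding = make_catalog(make_gene("C", "c1", 3000, 9000, "+"))
        link = nearest_expressed_tss(lnc, coding)
        assert link.distance_nt == 0
        assert link.side == "overlapping"
        assert link.orientation == "sense"

    def test_downstream_side_on_minus_strand_gene(self):
        # coding gene on '-': TSS at its right end; lncRNA to its right is
        # upstream, to its left downstream
        coding = make_catalog(make_gene("C", "c1", 3000, 9000, "-"))
        right = nearest_expressed_tss(make_gene("L", "c1", 10000, 10500, "+"),
                                      coding)
        left = nearest_expressed_tss(make_gene("L", "c1", 100, 600, "+"),
                                     coding)
        assert right.side == "upstream"
        assert left.side == "downstream"

    def test_no_coding_gene_on_chromosome(self):
        lnc = make_gene("L", "c9", 0, 1000)
        assert nearest_expressed_tss(lnc, make_catalog(
            make_gene("C", "c1", 0, 100, has_protein_id=True))) is None

    def test_tie_break_smaller_gene_id(self):
        lnc = make_gene("L", "c1", 4000, 5000, "+")
        coding = make_catalog(make_gene("B", "c1", 5999, 9000, "+"),
                              make_gene("A", "c1", 1000, 3001, "-"))
        # both TSSs sit at a 999-nt gap (A on '-' has TSS 3000; B has TSS 5999)
        link = nearest_expressed_tss(lnc, coding)
        assert link.distance_nt == 999
        assert link.coding_gene_id == "A"

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        coding = GeneCatalog()
        for i in range(100):
            start = int(rng.integers(0, 500_000))
            coding.add(make_gene(f"C{i:03d}", "c1", start,
                                 start + int(rng.integers(500, 5000)),
                                 "+" if rng.random() < 0.5 else "-"))
        for j in range(200):
            start = int(rng.integers(0, 500_000))
            lnc = make_gene(f"L{j:03d}", "c1", start,
                            start + int(rng.integers(200, 3000)),
                            "+" if rng.random() < 0.5 else "-")
            link = nearest_expressed_tss(lnc, coding)
            # oracle: exhaustive scan over all coding genes; the gap is the
            # distance from the TSS to the nearest lncRNA base, minus one
            span = lnc.span
            best = None
            for c in coding:
                t = tss_of(c)
                nearest_base = min(abs(t - span.start), abs(t - (span.end - 1)))
                d = 0 if span.start - 1 <= t <= span.end else nearest_base - 1
                if best is None or d < best[0] or (d == best[0]
                                                   and c.gene_id < best[1]):
                    best = (d, c.gene_id)
            assert (link.distance_nt, link.coding_gene_id) == best

    def test_mirror_symmetry(self, rng):
        """Reflecting all coordinates and flipping strands preserves links."""
        L = 1_000_000
        coding = GeneCatalog()
        lncs = []
        for i in range(30):
            s = int(rng.integers(0, L - 10_000))
            coding.add(make_gene(f"C{i:02d}", "c1", s, s + 5000,
                                 "+" if rng.random() < 0.5 else "-"))
        for j in range(50):
            s = int(rng.integers(0, L - 5000))
            lncs.append(make_gene(f"L{j:02d}", "c1", s, s + 1000,
                                  "+" if rng.random() < 0.5 else "-"))

        def mirror(g):
            sp = g.span
            flip = {"+": "-", "-": "+"}[g.strand]
            return make_gene(g.gene_id, "c1", L - sp.end, L - sp.start, flip)

        m_coding = make_catalog(*(mirror(c) for c in coding))
        for lnc in lncs:
            a = nearest_expressed_tss(lnc, coding)
            b = nearest_expressed_tss(mirror(lnc), m_coding)
            assert a.distance_nt == b.distance_nt
            assert a.side == b.side
            assert a.orientation == b.orientation


class TestWindowEnrichment:
    def _links(self, sides_distances):
        lncs, coding = GeneCatalog(), GeneCatalog()
        coding.add(make_gene("C", "c1", 500_000, 600_000, "+",
                             has_protein_id=True))
        tss = 500_000
        for i, (side, d) in enumerate(sides_distances):
            if side == "upstream":
                start, end = tss - d - 1000, tss - d
            else:
                start, end = tss + d, tss + d + 1000
            lncs.add(make_gene(f"L{i:03d}", "c1", start, end, "-"))
        return link_all(lncs, coding)

    def test_published_window_counts_give_small_p(self):
        sides = ([("upstream", 2000)] * 24 + [("downstream", 2000)]
                 + [("upstream", 40_000)] * 35)
        links = self._links(sides)
        we = window_enrichment(links, window_nt=5000)
        assert (we.n_up_in_window, we.n_down_in_window) == (24, 1)
        assert we.fisher_result.p_value < 0.001

    def test_symmetric_counts_p_one(self):
        sides = ([("upstream", 2000)] * 10 + [("downstream", 2000)] * 10
                 + [("upstream", 40_000)] * 40)
        we = window_enrichment(self._links(sides), window_nt=5000)
        assert we.fisher_result.p_value == pytest.approx(1.0)

    def test_window_boundary_inclusive(self):
        we = window_enrichment(self._links([("upstream", 5000),
                                            ("upstream", 5001)]),
                               window_nt=5000)
        assert we.n_up_in_window == 1

    def test_empty_links_error(self):
        with pytest.raises(ValueError):
            window_enrichment([])

    def test_biased_placement_detected_in_simulation(self):
        """Placement bias 0.9 at n=60 yields p < 0.01 in >= 95% of 200 reps."""
        rng = np.random.default_rng(99)
        detected = 0
        reps = 200
        for _ in range(reps):
            upstream = rng.random(60) < 0.9
            dists = rng.integers(1, 5001, size=60)  # all within the window
            sides = [("upstream" if u else "downstream", int(d))
                     for u, d in zip(upstream, dists)]
            we = window_enrichment(self._links(sides), window_nt=5000)
            if we.fisher_result.p_value < 0.01:
                detected += 1
        assert detected / reps >= 0.95


class TestCorrelationsAndHistogram:
    def _toy_links(self, n=10):
        sides = [("upstream", 2000 + 100 * i) for i in range(n)]
        return TestWindowEnrichment()._links(sides)

    def test_identical_fc_vectors_r_one(self):
        links = self._toy_links(5)
        lnc_fc = {l.lnc_gene_id: float(i) for i, l in enumerate(links)}
        coding_fc = {"C": 0.0}
        # coding fc constant -> zero variance error; use varying via distinct links
        lnc_fc2 = dict(lnc_fc)
        with pytest.raises(ValueError):
            neighbor_fc_correlation(links, lnc_fc2, coding_fc)

    def test_anticorrelated_pairs(self):
        # construct links to 5 distinct coding genes
        lncs, coding = GeneCatalog(), GeneCatalog()
        for i in range(5):
            base = 100_000 * (i + 1)
            coding.add(make_gene(f"C{i}", "c1", base + 5000, base + 20_000, "+"))
            lncs.add(make_gene(f"L{i}", "c1", base, base + 1000, "-"))
        links = link_all(lncs, coding)
        lnc_fc = {f"L{i}": float(i) for i in range(5)}
        coding_fc = {f"C{i}": -float(i) for i in range(5)}
        res = neighbor_fc_correlation(links, lnc_fc, coding_fc)
        assert res.statistic == pytest.approx(-1.0)

    def test_independent_fcs_near_zero_r(self, rng):
        lncs, coding = GeneCatalog(), GeneCatalog()
        for i in range(60):
            base = 100_000 * (i + 1)
            coding.add(make_gene(f"C{i:02d}", "c1", base + 5000,
                                 base + 20_000, "+"))
            lncs.add(make_gene(f"L{i:02d}", "c1", base, base + 1000, "-"))
        links = link_all(lncs, coding)
        lnc_fc = {f"L{i:02d}": float(v)
                  for i, v in enumerate(rng.normal(size=60))}
        coding_fc = {f"C{i:02d}": float(v)
                     for i, v in enumerate(rng.normal(size=60))}
        res = neighbor_fc_correlation(links, lnc_fc, coding_fc)
        assert abs(res.statistic) < 0.3

    def test_histogram_conventions(self):
        links = TestWindowEnrichment()._links(
            [("upstream", 15_000), ("upstream", 5_000), ("downstream", 5_000)])
        hist = distance_histogram(links, bin_nt=10_000)
        assert hist == {(-20_000, -10_000): 1, (-10_000, 0): 1, (0, 10_000): 1}

    def test_histogram_conserves_link_count(self, rng):
        sides = [("upstream" if rng.random() < 0.5 else "downstream",
                  int(rng.integers(1, 100_000))) for _ in range(80)]
        links = TestWindowEnrichment()._links(sides)
        hist = distance_histogram(links)
        assert sum(hist.values()) == len(links)

    def test_overlapping_links_fall_in_central_bin(self):
        lncs = make_catalog(make_gene("L", "c1", 499_000, 501_000, "+"))
        coding = make_catalog(make_gene("C", "c1", 500_000, 600_000, "+"))
        links = link_all(lncs, coding)
        assert signed_distance(links[0]) == 0
        hist = distance_histogram(links, bin_nt=10_000)
        assert hist == {(-10_000, 0): 1}


class TestIndependence:
    def test_null_simulation_low_correlation(self):
        rng = np.random.default_rng(469)
        fc = rng.normal(0, 1, size=469)
        lengths = np.exp(rng.normal(7, 1, size=469))
        expr = np.exp(rng.normal(1, 1.5, size=469))
        r_len, r_expr = independence_diagnostics(fc, lengths, expr)
        assert abs(r_len.statistic) < 0.3
        assert abs(r_expr.statistic) < 0.3

    def test_fc_equal_to_length_r_one(self):
        lengths = np.array([100.0, 1000.0, 10_000.0, 100_000.0])
        fc = np.log10(lengths)
        r_len, _ = independence_diagnostics(fc, lengths,
                                            np.array([1.0, 2.0, 4.0, 8.0]))
        assert r_len.statistic == pytest.approx(1.0)

    def test_constant_fc_vector_error(self):
        with pytest.raises(ValueError):
            independence_diagnostics([1.0, 1.0, 1.0],
                                     [100.0, 200.0, 300.0],
                                     [1.0, 2.0, 3.0])

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            independence_diagnostics([1.0, 2.0], [100.0], [1.0, 2.0])


def test_synthetic_placement_labels_recovered_exactly():
    """Side and orientation labels from the pipeline match simulated truth."""
    from lncstab.synthetic import SimulationConfig, simulate_annotation

    cfg = SimulationConfig(seed=5, n_coding=200, n_lnc=120)
    coding, lnc, truth = simulate_annotation(cfg)
    links = {l.lnc_gene_id: l for l in link_all(lnc, coding)}
    assert len(links) == 120
    for gid, link in links.items():
        assert link.coding_gene_id == truth.paired_coding[gid]
        assert link.side == truth.placement_side[gid]
        assert link.orientation == truth.orientation[gid]
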