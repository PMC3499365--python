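"""End-to-end orchestration: counts -> RPKM -> fold changes -> statistics -> neighborhoods.

`run_pipeline` composes the analysis stages in their natural order and
returns an :class:`AnalysisReport` whose payload is deterministic for fixed
inputs: gene counts, up/down calls and percentages per class, skewness and
normality tests, class-comparison tests, TSS-window enrichment, and
correlation diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import diffstats, neighborhood, quantify
from .genome import GeneCatalog, build_maximal_locus
from .synthetic import CONTROL, DEPLETED


@dataclass
class RunConfig:
    control_sample: str = CONTROL
    depleted_sample: str = DEPLETED
    min_rpkm: float = 1.0
    fc_threshold: float = 2.0
    window_nt: int = 5000
    min_len_nt: int = 200
    pseudocount: float = 0.1  # used only for log2-fc distribution vectors
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_rpkm, self.fc_threshold, self.window_nt,
               self.min_len_nt) <= 0:
            raise ValueError("thresholds must be positive")
        if self.control_sample == self.depleted_sample:
            raise ValueError("control and depleted sample labels must differ")


@dataclass
class ClassSummary:
    n_expressed: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float
    skewness: float | None = None
    k2_statistic: float | None = None
    k2_p_value: float | None = None


@dataclass
class AnalysisReport:
    config: dict[str, Any]
    coding: ClassSummary
    lnc: ClassSummary
    ks_coding_vs_lnc: dict[str, float]
    t_coding_vs_lnc: dict[str, float]
    chi2_lnc_up_vs_down: dict[str, float]
    chi2_lnc_up_vs_coding_up: dict[str, float]
    window_enrichment: dict[str, Any] | None = None
    neighbor_fc_correlation: dict[str, float] | None = None
    independence: dict[str, dict[str, float]] | None = None
    tables: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), indent=2, default=default,
                          allow_nan=True)


def _class_summary(fcs: list[quantify.FoldChangeRecord],
                   log2_vector: list[float]) -> ClassSummary:
    n = len(fcs)
    n_up = sum(1 for r in fcs if r.direction == "up")
    n_down = sum(1 for r in fcs if r.direction == "down")
    summary = ClassSummary(
        n_expressed=n, n_up=n_up, n_down=n_down,
        pct_up=100.0 * n_up / n if n else math.nan,
        pct_down=100.0 * n_down / n if n else math.nan)
    finite = [v for v in log2_vector if math.isfinite(v)]
    if len(finite) >= 20:
        res = diffstats.dagostino_k2(finite)
        summary.skewness = res.g1
        summary.k2_statistic = res.k2
        summary.k2_p_value = res.p_value
    elif len(finite) >= 3 and np.var(finite) > 0:
        summary.skewness = diffstats.sample_skewness(finite)
    return summary


def run_pipeline(coding: GeneCatalog, lnc: GeneCatalog,
                 counts: dict[str, dict[str, int]],
                 config: RunConfig | None = None) -> AnalysisReport:
    """Run the core expression analysis on catalogs plus a count matrix.

    ``counts`` maps sample -> gene -> exonic fragment count, covering every
    gene of both catalogs.  Stages: RPKM over maximal loci, RPKM > min
    expression filter, fold-change calling per class, distribution and
    class-comparison statistics, then the TSS-neighborhood analysis of the
    upregulated lncRNAs.
    """
    config = config or RunConfig()
    lengths = {}
    for cat in (coding, lnc):
        for rec in cat:
            lengths[rec.gene_id] = build_maximal_locus(rec).exonic_length_nt

    records = quantify.expression_table(counts, lengths)
    expressed = quantify.expression_filter(records, min_rpkm=config.min_rpkm)

    coding_ids = {g.gene_id for g in coding}
    lnc_ids = {g.gene_id for g in lnc}

    def class_results(ids):
        genes = ids & expressed
        calls = quantify.fold_changes(
            records, config.control_sample, config.depleted_sample,
            genes=genes, fc_threshold=config.fc_threshold, pseudocount=0.0)
        smooth = quantify.fold_changes(
            records, config.control_sample, config.depleted_sample,
            genes=genes, fc_threshold=config.fc_threshold,
            pseudocount=config.pseudocount)
        return calls, [r.log2fc for r in smooth]

    coding_fcs, coding_vec = class_results(coding_ids)
    lnc_fcs, lnc_vec = class_results(lnc_ids)

    coding_summary = _class_summary(coding_fcs, coding_vec)
    lnc_summary = _class_summary(lnc_fcs, lnc_vec)

    coding_finite = [v for v in coding_vec if math.isfinite(v)]
    lnc_finite = [v for v in lnc_vec if math.isfinite(v)]
    ks = diffstats.ks_two_sample(coding_finite, lnc_finite)
    tt = diffstats.student_t_two_sample(coding_finite, lnc_finite)
    def proportions_test(x1, n1, x2, n2):
        # equal (possibly empty) proportions: nothing to test
        try:
            res = diffstats.chi2_two_proportions(x1, n1, x2, n2)
            return {"chi2": res.statistic, "p": res.p_value}
        except ValueError:
            return {"chi2": 0.0, "p": 1.0}

    chi_ud = proportions_test(
        lnc_summary.n_up, lnc_summary.n_expressed,
        lnc_summary.n_down, lnc_summary.n_expressed)
    chi_vs_coding = proportions_test(
        lnc_summary.n_up, lnc_summary.n_expressed,
        coding_summary.n_up, coding_summary.n_expressed)

    # TSS neighborhood of the upregulated lncRNAs
    up_ids = {r.gene_id for r in lnc_fcs if r.direction == "up"}
    coding_expressed = GeneCatalog()
    for rec in coding:
        if rec.gene_id in expressed:
            coding_expressed.add(rec)
    up_lnc = GeneCatalog()
    for rec in lnc:
        if rec.gene_id in up_ids:
            up_lnc.add(rec)

    window = None
    neighbor_corr = None
    if len(up_lnc) and len(coding_expressed):
        links = neighborhood.link_all(up_lnc, coding_expressed)
        if links:
            try:
                we = neighborhood.window_enrichment(links, config.window_nt)
                window = {
                    "window_nt": we.window_nt,
                    "n_up_in_window": we.n_up_in_window,
                    "n_down_in_window": we.n_down_in_window,
                    "n_total": we.n_total,
                    "fisher_p": we.fisher_result.p_value,
                }
            except ValueError:
                # no link in either window: nothing to test
                window = {"window_nt": config.window_nt, "n_up_in_window": 0,
                          "n_down_in_window": 0, "n_total": len(links),
                          "fisher_p": 1.0}
            lnc_fc_map = {r.gene_id: r.log2fc for r in lnc_fcs}
            coding_fc_map = {r.gene_id: r.log2fc for r in coding_fcs}
            usable = [l for l in links
                      if l.coding_gene_id in coding_fc_map
                      and math.isfinite(lnc_fc_map[l.lnc_gene_id])
                      and math.isfinite(coding_fc_map[l.coding_gene_id])]
            if len(usable) >= 3:
                try:
                    res = neighborhood.neighbor_fc_correlation(
                        usable, lnc_fc_map, coding_fc_map)
                    neighbor_corr = {"r": res.statistic, "p": res.p_value}
                except ValueError:
                    neighbor_corr = None

    independence = None
    lnc_fc_map = {r.gene_id: r.log2fc for r in lnc_fcs}
    rpkm_ctrl = {r.gene_id: r.rpkm for r in records
                 if r.sample_id == config.control_sample}
    diag_ids = [g for g in sorted(lnc_ids & expressed)
                if math.isfinite(lnc_fc_map.get(g, math.nan))
                and rpkm_ctrl.get(g, 0) > 0]
    if len(diag_ids) >= 3:
        try:
            r_len, r_expr = neighborhood.independence_diagnostics(
                [lnc_fc_map[g] for g in diag_ids],
                [lengths[g] for g in diag_ids],
                [rpkm_ctrl[g] for g in diag_ids])
            independence = {
                "length": {"r": r_len.statistic, "p": r_len.p_value},
                "expression": {"r": r_expr.statistic, "p": r_expr.p_value},
            }
        except ValueError:
            independence = None

    return AnalysisReport(
        config=dataclasses.asdict(config),
        coding=coding_summary, lnc=lnc_summary,
        ks_coding_vs_lnc={"D": ks.statistic, "p": ks.p_value},
        t_coding_vs_lnc={"t": tt.statistic, "p": tt.p_value},
        chi2_lnc_up_vs_down=chi_ud,
        chi2_lnc_up_vs_coding_up=chi_vs_coding,
        window_enrichment=window,
        neighbor_fc_correlation=neighbor_corr,
        independence=independence,
    )
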