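"""qPCR fold changes, RNA decay kinetics, and IP enrichment arithmetic.

Relative quantification follows the standard comparative-Ct scheme: one
cycle of qPCR corresponds to one doubling, so a target whose
reference-corrected Ct drops by dCt between conditions changed
``efficiency**(-ddCt)``-fold.  Decay time courses from transcription-shutoff
(actinomycin D) experiments are normalized to a stable reference transcript
and to the t=0 point, then fitted to a first-order model
``A(t) = exp(-k t)`` by log-linear least squares; the half-life is
``ln(2)/k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

STABLE_K_TOLERANCE = 1e-4  # per minute; below this a transcript is called stable


@dataclass
class QpcrRecord:
    sample_id: str
    target_gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be positive and finite")


@dataclass
class TimeCourse:
    gene_id: str
    condition: str
    points: list[tuple[float, float]]  # (time in minutes, normalized abundance)
    reference_gene: str = ""

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if not times or times[0] != 0:
            raise ValueError("time course must start at t = 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if not math.isclose(self.points[0][1], 1.0, rel_tol=1e-9):
            raise ValueError("abundance must be normalized to 1 at t = 0")


@dataclass
class DecayFit:
    gene_id: str
    condition: str
    k: float  # per minute, >= 0
    half_life: float  # minutes; inf when stable
    r_squared: float
    stable: bool


def ddct_fold_change(ct_target_case: float, ct_ref_case: float,
                     ct_target_control: float, ct_ref_control: float,
                     efficiency: float = 2.0) -> float:
    """Comparative-Ct fold change of a target between case and control.

    Returns ``efficiency**-ddCt`` with
    ``ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctl - Ct_ref,ctl)``.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct value")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return efficiency ** (-ddct)


def normalize_timecourse(gene_id: str, condition: str,
                         times: Sequence[float],
                         target: Sequence[float],
                         reference: Sequence[float],
                         reference_gene: str = "") -> TimeCourse:
    """Normalize a raw decay series to a reference transcript and to t = 0.

    ``abundance(t) = (target(t)/reference(t)) / (target(0)/reference(0))``.
    """
    if len(times) != len(target) or len(times) != len(reference):
        raise ValueError("times, target and reference series must align")
    if any(r == 0 for r in reference):
        raise ValueError("zero reference value")
    ratio0 = target[0] / reference[0]
    points = [(float(t), (tg / rf) / ratio0)
              for t, tg, rf in zip(times, target, reference)]
    return TimeCourse(gene_id=gene_id, condition=condition, points=points,
                      reference_gene=reference_gene)


def fit_first_order_decay(tc: TimeCourse) -> DecayFit:
    """Least-squares first-order decay fit on the log scale.

    Fits ``ln A(t) = -k t`` (intercept included to absorb normalization
    noise), clips k at 0, and flags the transcript stable when
    k < 1e-4 / min — slow enough that a 72-h chase would show under 1%
    decay, i.e. indistinguishable from no decay at experimental time scales.
    """
    if len(tc.points) < 3:
        raise ValueError("need >= 3 timepoints for a decay fit")
    t = np.array([p[0] for p in tc.points], dtype=float)
    a = np.array([p[1] for p in tc.points], dtype=float)
    if (a <= 0).any():
        raise ValueError("non-positive abundance in time course")
    y = np.log(a)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    k = max(0.0, -float(slope))
    stable = k < STABLE_K_TOLERANCE
    half_life = math.inf if stable else math.log(2) / k
    return DecayFit(gene_id=tc.gene_id, condition=tc.condition, k=k,
                    half_life=half_life, r_squared=r2, stable=stable)


def chip_enrichment(signal_ab: float, signal_control: float,
                    input_signal: float | None = None,
                    control_input_signal: float | None = None,
                    mode: str = "fold_over_control") -> float:
    """ChIP signal as fold over a no-antibody control, or as percent input.

    ``fold_over_control``: antibody signal / control-purification signal.
    ``percent_input``: 100 * ab/input, normalized by the same quantity for
    the control purification.
    """
    if mode == "fold_over_control":
        if signal_control <= 0:
            raise ValueError("control signal must be positive")
        return signal_ab / signal_control
    if mode == "percent_input":
        if input_signal is None or control_input_signal is None:
            raise ValueError("percent_input mode needs input signals")
        if input_signal <= 0 or control_input_signal <= 0:
            raise ValueError("input signals must be positive")
        if signal_control <= 0:
            raise ValueError("control signal must be positive")
        pct_ab = 100.0 * signal_ab / input_signal
        pct_ctl = 100.0 * signal_control / control_input_signal
        return pct_ab / pct_ctl
    raise ValueError(f"unknown mode {mode!r}")


def rip_enrichment(ip_target: float, input_target: float,
                   ip_ref: float, input_ref: float,
                   control_ip_target: float, control_input_target: float,
                   control_ip_ref: float, control_input_ref: float) -> float:
    """RNA-IP enrichment: IP:input ratio vs a reference RNA, over a control IP.

    ``[(IP_t/in_t)/(IP_r/in_r)] / [(cIP_t/cin_t)/(cIP_r/cin_r)]``.
    """
    vals = (ip_target, input_target, ip_ref, input_ref, control_ip_target,
            control_input_target, control_ip_ref, control_input_ref)
    if any(v <= 0 for v in vals):
        raise ValueError("all IP/input signals must be positive")
    case = (ip_target / input_target) / (ip_ref / input_ref)
    control = ((control_ip_target / control_input_target)
               / (control_ip_ref / control_input_ref))
    return case / control
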