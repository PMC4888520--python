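"""Deterministic confusion-matrix model of screening-test performance.

The expected 2x2 table for one gene follows from the parameters alone:

    TP = prevalence * N * (sum over classes: proportion * sensitivity) * coverage
    FN = prevalence * N - TP
    FP = supplied false-positive count (0 in the main model, where a
         confirmatory assay is assumed to remove false calls)
    TN = N - prevalence * N - FP

Variants of uncertain significance are assumed unreported and sit inside
the true negatives.  Performance metrics (sensitivity, specificity, PPV,
NPV) are computed from the integer-rounded cells, since reported counts
are whole women; the continuous cells remain available for uncertainty
propagation and for checking against the cohort simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .parameters import GeneModel, PlatformPerformance, PopulationConfig

__all__ = [
    "ConfusionCounts",
    "TestPerformance",
    "round_half_away",
    "expected_confusion",
    "performance_metrics",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding (ties to even);
    reported counts of women use the convention familiar from hand
    calculation, where 0.5 rounds up.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Expected 2x2 table cells for one gene in one population.

    Cells are continuous expected counts of women; ``tp_rounded`` etc.
    give the nearest-integer views used for reporting and for metric
    calculation.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValueError(f"confusion cell {name} must be >= 0, got {v!r}")

    @property
    def tp_rounded(self) -> int:
        return round_half_away(self.tp)

    @property
    def fp_rounded(self) -> int:
        return round_half_away(self.fp)

    @property
    def fn_rounded(self) -> int:
        return round_half_away(self.fn)

    @property
    def tn_rounded(self) -> int:
        return round_half_away(self.tn)

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def carriers(self) -> float:
        """Expected number of women truly carrying a pathogenic mutation."""
        return self.tp + self.fn

    def rounded(self) -> "ConfusionCounts":
        """Integer view of the table (each cell rounded independently)."""
        return ConfusionCounts(
            tp=self.tp_rounded, fp=self.fp_rounded,
            fn=self.fn_rounded, tn=self.tn_rounded,
        )


@dataclass(frozen=True)
class TestPerformance:
    """Analytic performance metrics as proportions in [0, 1].

    A metric whose denominator is zero is undefined and carried as
    ``None`` rather than silently coerced to 0 or 1.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_percent_strings(self) -> dict[str, str]:
        """Metrics formatted as one-decimal percentages, e.g. ``'77.5 %'``."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = "undefined" if v is None else f"{100 * v:.1f} %"
        return out


def expected_confusion(
    gene: GeneModel,
    platform: PlatformPerformance,
    pop: PopulationConfig,
    fp_count: float = 0.0,
) -> ConfusionCounts:
    """Expected confusion-matrix cells for one gene.

    Parameters
    ----------
    gene, platform, pop
        Validated model parameters.
    fp_count
        Expected number of false-positive women.  The main model uses 0
        (false calls are assumed eliminated by a confirmatory assay); the
        uncertainty analysis passes sampled values.

    Returns
    -------
    ConfusionCounts
        Continuous expected cells; ``.rounded()`` for the reporting view.
    """
    if fp_count < 0:
        raise ValueError(f"fp_count must be >= 0, got {fp_count}")
    carriers = gene.prevalence * pop.size
    detect_rate = (
        gene.spectrum.p_indel * platform.sens_indel
        + gene.spectrum.p_snv * platform.sens_snv
        + gene.spectrum.p_cnv * platform.sens_cnv
    )
    tp = carriers * detect_rate * gene.coverage
    fn = carriers - tp
    tn = pop.size - carriers - fp_count
    return ConfusionCounts(tp=tp, fp=float(fp_count), fn=fn, tn=tn)


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def performance_metrics(counts: ConfusionCounts, use_rounded: bool = True) -> TestPerformance:
    """Sensitivity, specificity, PPV and NPV from a confusion table.

    By default metrics are computed from the rounded integer cells — the
    convention that makes reported percentages consistent with reported
    whole-women counts (93 detected of 120 carriers gives 77.5 %, whereas
    the continuous cells would give 77.7 %).  Pass ``use_rounded=False``
    for the continuous ratios.
    """
    c = counts.rounded() if use_rounded else counts
    return TestPerformance(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )
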