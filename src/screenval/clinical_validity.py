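"""Penetrance-based projection of breast-cancer outcomes per test result.

Analytic validity says how many women land in each confusion cell;
clinical validity asks how many of them will actually develop disease.
Carriers — whether detected (true positives) or missed (false negatives)
— accrue cancer at their gene's lifetime penetrance (central value plus a
low/high literature range); women with no pathogenic mutation (true
negatives, and any false positives) accrue cancer at the background
lifetime risk.

Counts enter as the rounded integer cells (projections describe whole
women), per-gene contributions are summed, and the summed expectation is
rounded once for reporting.  True-negative women are counted once across
the gene panel: population minus all carriers minus false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .analytic_validity import ConfusionCounts, round_half_away
from .parameters import PenetranceEstimate, PopulationConfig

__all__ = ["ScenarioOutcome", "ClinicalOutcome", "project_cancers", "scenario_report"]

#: reporting order and numbering of the four outcome scenarios
SCENARIOS = ("true_positive", "false_positive", "false_negative", "true_negative")


@dataclass(frozen=True)
class ScenarioOutcome:
    """Headcount and expected cancers for one test-outcome group."""

    n_women: int
    cancers_central: float
    cancers_low: float
    cancers_high: float

    def __post_init__(self) -> None:
        if self.n_women < 0:
            raise ValueError(f"n_women must be >= 0, got {self.n_women}")
        if not self.cancers_low <= self.cancers_central <= self.cancers_high:
            raise ValueError(
                "expected cancers must satisfy low <= central <= high, got "
                f"{self.cancers_low}, {self.cancers_central}, {self.cancers_high}"
            )
        if self.cancers_high > self.n_women + 1e-9:
            raise ValueError(
                f"expected cancers ({self.cancers_high}) cannot exceed "
                f"headcount ({self.n_women})"
            )

    @property
    def cancers_rounded(self) -> int:
        return round_half_away(self.cancers_central)

    @property
    def cancers_low_rounded(self) -> int:
        return round_half_away(self.cancers_low)

    @property
    def cancers_high_rounded(self) -> int:
        return round_half_away(self.cancers_high)

    @property
    def no_cancer_rounded(self) -> int:
        """Women in this group predicted *not* to develop cancer (central)."""
        return self.n_women - self.cancers_rounded


@dataclass(frozen=True)
class ClinicalOutcome:
    """Projected cancers per scenario, combined over the gene panel.

    ``per_gene`` holds each gene's true-positive and false-negative
    contributions; the non-carrier pool is a panel-level quantity and only
    appears in the combined scenarios.
    """

    true_positive: ScenarioOutcome
    false_positive: ScenarioOutcome
    false_negative: ScenarioOutcome
    true_negative: ScenarioOutcome
    per_gene: Mapping[str, Mapping[str, ScenarioOutcome]]
    population_size: int

    def scenario(self, name: str) -> ScenarioOutcome:
        if name not in SCENARIOS:
            raise KeyError(name)
        return getattr(self, name)


def project_cancers(
    counts: Mapping[str, ConfusionCounts],
    penetrance: Mapping[str, PenetranceEstimate],
    pop: PopulationConfig,
) -> ClinicalOutcome:
    """Apply penetrance and background risk to confusion-matrix cells.

    Parameters
    ----------
    counts
        Per-gene confusion cells (continuous; rounded internally).
    penetrance
        Per-gene lifetime penetrance estimates, keyed like ``counts``.
    pop
        Population size and background lifetime risk.

    Returns
    -------
    ClinicalOutcome
        Headcounts and expected cancer counts (central / low / high) for
        the four scenarios, plus per-gene carrier contributions.
    """
    if set(counts) != set(penetrance):
        raise ValueError(
            f"counts and penetrance must cover the same genes, got "
            f"{sorted(counts)} vs {sorted(penetrance)}"
        )

    per_gene: dict[str, dict[str, ScenarioOutcome]] = {}
    tp_n = fn_n = fp_n = carriers_n = 0
    tp_c = [0.0, 0.0, 0.0]  # central, low, high
    fn_c = [0.0, 0.0, 0.0]
    for name, cell in counts.items():
        pen = penetrance[name]
        r = cell.rounded()
        tp_n += r.tp_rounded
        fn_n += r.fn_rounded
        fp_n += r.fp_rounded
        carriers_n += r.tp_rounded + r.fn_rounded
        gene_tp = ScenarioOutcome(
            n_women=r.tp_rounded,
            cancers_central=r.tp_rounded * pen.central,
            cancers_low=r.tp_rounded * pen.low,
            cancers_high=r.tp_rounded * pen.high,
        )
        gene_fn = ScenarioOutcome(
            n_women=r.fn_rounded,
            cancers_central=r.fn_rounded * pen.central,
            cancers_low=r.fn_rounded * pen.low,
            cancers_high=r.fn_rounded * pen.high,
        )
        per_gene[name] = {"true_positive": gene_tp, "false_negative": gene_fn}
        for i, v in enumerate((pen.central, pen.low, pen.high)):
            tp_c[i] += r.tp_rounded * v
            fn_c[i] += r.fn_rounded * v

    tn_n = pop.size - carriers_n - fp_n
    if tn_n < 0:
        raise ValueError(
            f"carriers ({carriers_n}) plus false positives ({fp_n}) exceed "
            f"population size ({pop.size})"
        )
    tn_cancers = tn_n * pop.background_risk
    fp_cancers = fp_n * pop.background_risk  # false positives carry no mutation

    return ClinicalOutcome(
        true_positive=ScenarioOutcome(tp_n, tp_c[0], tp_c[1], tp_c[2]),
        false_positive=ScenarioOutcome(fp_n, fp_cancers, fp_cancers, fp_cancers),
        false_negative=ScenarioOutcome(fn_n, fn_c[0], fn_c[1], fn_c[2]),
        true_negative=ScenarioOutcome(tn_n, tn_cancers, tn_cancers, tn_cancers),
        per_gene=per_gene,
        population_size=pop.size,
    )


def scenario_report(outcome: ClinicalOutcome) -> list[dict]:
    """Structured per-scenario report.

    One record per scenario, in reporting order: headcount, expected
    cancers (rounded central with rounded low/high range), and — for
    carrier scenarios — the number of women predicted not to develop
    cancer despite carrying a mutation (headcount minus expected cancers),
    which bounds the potential for unnecessary intervention among true
    positives.
    """
    records = []
    for i, name in enumerate(SCENARIOS, start=1):
        s = outcome.scenario(name)
        rec = {
            "scenario": i,
            "outcome": name,
            "n_women": s.n_women,
            "expected_cancers": s.cancers_rounded,
            "cancers_low": s.cancers_low_rounded,
            "cancers_high": s.cancers_high_rounded,
        }
        if name in ("true_positive", "false_negative"):
            rec["predicted_no_cancer"] = s.no_cancer_rounded
        records.append(rec)
    return records
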