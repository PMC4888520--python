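"""Individual-level cohort simulator: synthetic data generator and oracle.

Every expectation in the deterministic model has a generative counterpart
here.  Each simulated woman independently:

1. draws a carrier state from a single categorical over
   {gene 1, gene 2, ..., none} (disjoint assignment — no double carriers,
   matching the deterministic model's treatment of prevalences);
2. if a carrier, draws a mutation class from her gene's spectrum;
3. draws a horizontal-coverage lottery (Bernoulli at the gene's coverage)
   and, if covered, a detection lottery at the class sensitivity — she is
   detected only if both succeed, matching the multiplicative
   ``class sensitivity x coverage`` structure of the expectation formula;
4. draws lifetime breast cancer at her gene's central penetrance if a
   carrier, else at the background risk.

Non-carriers are never called positive (per-class specificity 1, as in
the main model where confirmatory testing removes false positives), so
``detected`` implies carrier.  Tabulated cell counts at large n agree
with the analytic expectations to within binomial sampling error — that
agreement is the module's reason to exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .analytic_validity import ConfusionCounts
from .parameters import ModelConfig

__all__ = ["SimulationResult", "simulate"]

_CLASS_NAMES = np.array(["none", "indel", "snv", "cnv"])


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one simulated cohort.

    Attributes
    ----------
    counts
        Per-gene empirical confusion cells (true negatives for gene g are
        all non-carriers of g, as in the per-gene analytic table).
    cancers
        Per-scenario cancer tallies over the whole panel:
        ``true_positive``, ``false_negative``, ``true_negative``
        (non-carriers; false positives do not occur in the simulator).
    n
        Cohort size.
    table
        Per-individual records (``None`` unless requested): id,
        carrier_gene, mutation_class, covered, detected, cancer.
    """

    counts: Mapping[str, ConfusionCounts]
    cancers: Mapping[str, int]
    n: int
    seed: int
    table: Optional[pd.DataFrame] = None


def simulate(
    config: ModelConfig,
    seed: int,
    n_override: Optional[int] = None,
    keep_table: bool = True,
) -> SimulationResult:
    """Simulate a cohort of individual women under the model parameters.

    Parameters
    ----------
    config
        Validated model (genes, platform, population).
    seed
        RNG seed; identical seeds give identical cohorts.
    n_override
        Cohort size; defaults to the configured population size.  Larger
        cohorts tighten the oracle comparison without touching the model.
    keep_table
        If False, only tabulated counts are returned — useful at
        oracle scale (10^7 individuals) where the per-individual frame is
        ballast.
    """
    n = int(n_override) if n_override is not None else config.population.size
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    genes = config.genes
    platform = config.platform

    # carrier state: categorical over genes + none via one uniform draw
    prevs = np.array([g.prevalence for g in genes])
    cuts = np.cumsum(prevs)  # [p1, p1+p2, ...]; u >= cuts[-1] -> non-carrier
    u = rng.random(n)
    carrier_idx = np.searchsorted(cuts, u, side="right")  # len(genes) = none
    is_carrier = carrier_idx < len(genes)

    # mutation class per carrier from the gene's spectrum
    class_code = np.zeros(n, dtype=np.int8)  # 0 none, 1 indel, 2 snv, 3 cnv
    u_class = rng.random(n)
    # coverage and detection lotteries (drawn for everyone to keep the
    # stream shape fixed; only carriers' draws matter)
    u_cov = rng.random(n)
    u_det = rng.random(n)
    covered = np.zeros(n, dtype=bool)
    detected = np.zeros(n, dtype=bool)

    class_sens = np.array([0.0, platform.sens_indel, platform.sens_snv, platform.sens_cnv])
    for gi, gene in enumerate(genes):
        mask = carrier_idx == gi
        if not mask.any():
            continue
        sp = gene.spectrum
        cc = np.select(
            [u_class[mask] < sp.p_indel, u_class[mask] < sp.p_indel + sp.p_snv],
            [1, 2],
            default=3,
        ).astype(np.int8)
        class_code[mask] = cc
        cov = u_cov[mask] < gene.coverage
        covered[mask] = cov
        detected[mask] = cov & (u_det[mask] < class_sens[cc])

    # lifetime cancer: gene penetrance for carriers, background otherwise
    risk = np.full(n, config.population.background_risk)
    for gi, gene in enumerate(genes):
        risk[carrier_idx == gi] = gene.penetrance.central
    cancer = rng.random(n) < risk

    counts: dict[str, ConfusionCounts] = {}
    for gi, gene in enumerate(genes):
        mask = carrier_idx == gi
        tp = int(np.count_nonzero(mask & detected))
        fn = int(np.count_nonzero(mask & ~detected))
        counts[gene.name] = ConfusionCounts(
            tp=float(tp), fp=0.0, fn=float(fn), tn=float(n - tp - fn)
        )

    cancers = {
        "true_positive": int(np.count_nonzero(is_carrier & detected & cancer)),
        "false_negative": int(np.count_nonzero(is_carrier & ~detected & cancer)),
        "true_negative": int(np.count_nonzero(~is_carrier & cancer)),
    }

    table = None
    if keep_table:
        gene_names = np.array([g.name for g in genes] + ["none"])
        table = pd.DataFrame(
            {
                "id": np.arange(n),
                "carrier_gene": pd.Categorical.from_codes(
                    carrier_idx, categories=list(gene_names)
                ),
                "mutation_class": pd.Categorical.from_codes(
                    class_code, categories=list(_CLASS_NAMES)
                ),
                "covered": covered,
                "detected": detected,
                "cancer": cancer,
            }
        )
    return SimulationResult(counts=counts, cancers=cancers, n=n, seed=seed, table=table)
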