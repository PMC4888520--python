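"""Monte Carlo parameter-uncertainty analysis of the screening model.

The deterministic confusion-matrix model is re-evaluated many times
(100,000 replicates by default) with inputs drawn from uncertainty
distributions:

* the CNV share of the mutation spectrum stays fixed at its point value,
  while the indel share is drawn from a truncated normal and the SNV share
  takes up the remainder so the spectrum still sums to one;
* CNV detection sensitivity stays fixed (at 0 in the default model), while
  indel and SNV sensitivities are drawn as ``1 - deficit`` with
  gamma-distributed deficits, truncated so the result stays in [0, 1];
* false positives, zero in the main model, are drawn from a distribution
  heavily skewed towards zero and capped at a fraction (default 10 %) of
  that replicate's true positives.

Within each replicate the cell calculations are exactly those of the main
model — no count-level noise is added unless ``count_sampling`` is
requested — so the output spread reflects parameter uncertainty only.

Sampling uses inverse-CDF transforms of a single uniform stream per
parameter, with an independent substream per gene keyed on the gene name:
adding or reordering genes never perturbs another gene's draws, and
shifting one distribution's location while holding the seed produces a
monotonically coupled set of replicates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .analytic_validity import expected_confusion
from .parameters import (
    ConfigError,
    GeneModel,
    ModelConfig,
    MutationSpectrum,
    PlatformPerformance,
)

__all__ = [
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "default_mc_specs",
    "degenerate_mc_specs",
    "sample_parameters",
    "run_mc",
]

_FAMILIES = ("fixed", "normal", "gamma", "scaled-beta", "truncated-exponential")

#: parameters every per-gene spec map must provide
_REQUIRED_PARAMS = ("p_indel", "sens_indel", "sens_snv", "fp_frac")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    Parameters
    ----------
    family
        One of ``fixed`` (point mass; params ``(value,)``), ``normal``
        (``(mu, sigma)``), ``gamma`` (``(shape, scale)``), ``scaled-beta``
        (``(a, b)``, stretched over ``bounds``), or
        ``truncated-exponential`` (``(scale,)``).
    params
        Family-specific parameters, as above.
    bounds
        Optional ``(lo, hi)`` truncation interval.  For ``normal``,
        ``gamma`` and ``truncated-exponential`` the distribution is
        renormalised on the interval (inverse-CDF truncation, not
        clipping); for ``scaled-beta`` the interval is the support.
    complement
        If True the spec describes a *deficit*: the sampled value is
        ``1 - x``.  Used for sensitivities modelled as one minus a
        gamma-distributed error rate.
    """

    family: str
    params: tuple[float, ...]
    bounds: Optional[tuple[float, float]] = None
    complement: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"unknown distribution family {self.family!r}; expected one of {_FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo < hi:
                raise ConfigError(f"bounds must satisfy lo < hi, got {self.bounds}")
            object.__setattr__(self, "bounds", (float(lo), float(hi)))
        n_expected = {
            "fixed": 1, "normal": 2, "gamma": 2,
            "scaled-beta": 2, "truncated-exponential": 1,
        }[self.family]
        if len(self.params) != n_expected:
            raise ConfigError(
                f"{self.family} family takes {n_expected} parameter(s), got {self.params}"
            )
        if self.family in ("scaled-beta", "truncated-exponential") and self.bounds is None:
            raise ConfigError(f"{self.family} family requires bounds")
        if self.family == "normal" and self.params[1] <= 0:
            raise ConfigError(f"normal sigma must be > 0, got {self.params[1]}")
        if self.family == "gamma" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ConfigError(f"gamma shape and scale must be > 0, got {self.params}")
        if self.family == "scaled-beta" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ConfigError(f"beta a and b must be > 0, got {self.params}")
        if self.family == "truncated-exponential" and self.params[0] <= 0:
            raise ConfigError(f"exponential scale must be > 0, got {self.params[0]}")
        # truncation interval must carry probability mass
        frozen = self._frozen()
        if frozen is not None and self.bounds is not None:
            lo, hi = self.bounds
            if frozen.cdf(hi) - frozen.cdf(lo) <= 0:
                raise ConfigError(
                    f"{self.family}{self.params} has no support on bounds {self.bounds}"
                )
        if self.family == "fixed" and self.bounds is not None:
            lo, hi = self.bounds
            if not lo <= self.params[0] <= hi:
                raise ConfigError(
                    f"fixed value {self.params[0]} outside bounds {self.bounds}"
                )

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(self.params[0], self.params[1])
        if self.family == "gamma":
            return stats.gamma(self.params[0], scale=self.params[1])
        if self.family == "truncated-exponential":
            return stats.expon(scale=self.params[0])
        return None

    def mean(self) -> float:
        """Exact mean of the sampled value (after truncation/complement).

        Closed form via the truncated distribution's expectation; serves
        as the analytic reference for law-of-large-numbers checks.
        """
        if self.family == "fixed":
            m = self.params[0]
        elif self.family == "scaled-beta":
            a, b = self.params
            lo, hi = self.bounds
            m = lo + (hi - lo) * a / (a + b)
        else:
            frozen = self._frozen()
            if self.bounds is None:
                m = frozen.mean()
            else:
                lo, hi = self.bounds
                trunc = stats.truncnorm(
                    (lo - self.params[0]) / self.params[1],
                    (hi - self.params[0]) / self.params[1],
                    loc=self.params[0], scale=self.params[1],
                ) if self.family == "normal" else None
                if trunc is not None:
                    m = trunc.mean()
                else:
                    # numeric expectation on the truncated support
                    from scipy.integrate import quad
                    z = frozen.cdf(hi) - frozen.cdf(lo)
                    m = quad(lambda x: x * frozen.pdf(x), lo, hi)[0] / z
        return 1.0 - m if self.complement else m

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw from the spec by inverse-CDF transform of ``rng`` uniforms."""
        u = rng.random(size)
        if self.family == "fixed":
            x = np.full_like(np.asarray(u, dtype=float), self.params[0]) if size is not None \
                else self.params[0]
        elif self.family == "scaled-beta":
            lo, hi = self.bounds
            x = lo + (hi - lo) * stats.beta.ppf(u, self.params[0], self.params[1])
        else:
            frozen = self._frozen()
            if self.bounds is None:
                x = frozen.ppf(u)
            else:
                lo, hi = self.bounds
                c_lo, c_hi = frozen.cdf(lo), frozen.cdf(hi)
                x = frozen.ppf(c_lo + u * (c_hi - c_lo))
        return 1.0 - x if self.complement else x


@dataclass(frozen=True)
class MCConfig:
    """Configuration for a Monte Carlo run.

    ``specs`` maps gene name to a per-parameter spec map with keys
    ``p_indel``, ``sens_indel``, ``sens_snv`` and ``fp_frac`` (the
    false-positive count as a fraction of ``fp_rate_cap x TP``).
    """

    n_replicates: int
    seed: int
    specs: Mapping[str, Mapping[str, DistributionSpec]]
    fp_rate_cap: float = 0.10

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if not 0.0 <= self.fp_rate_cap <= 1.0:
            raise ConfigError(f"fp_rate_cap must be in [0, 1], got {self.fp_rate_cap}")
        for gene_name, spec_map in self.specs.items():
            for key in _REQUIRED_PARAMS:
                if key not in spec_map:
                    raise ConfigError(f"specs[{gene_name!r}] missing parameter {key!r}")


def default_mc_specs(config: ModelConfig) -> dict[str, dict[str, DistributionSpec]]:
    """Default uncertainty distributions, centred on each gene's point values.

    The exact distribution parameters are calibration choices of this
    package (documented in the methods note), overridable per parameter:

    * ``p_indel`` ~ Normal(point value, 0.05) truncated to [0, 1 - p_cnv];
    * ``sens_indel`` = 1 - Gamma(4, 0.05) deficit (mean deficit 0.20);
    * ``sens_snv`` = 1 - Gamma(4, 0.0075) deficit (mean deficit 0.03);
    * ``fp_frac`` ~ Exponential(0.25) truncated to [0, 1] — heavily skewed
      towards zero, scaled at evaluation time by ``fp_rate_cap x TP``.
    """
    specs = {}
    for gene in config.genes:
        specs[gene.name] = {
            "p_indel": DistributionSpec(
                "normal", (gene.spectrum.p_indel, 0.05),
                bounds=(0.0, 1.0 - gene.spectrum.p_cnv),
            ),
            "sens_indel": DistributionSpec(
                "gamma", (4.0, 0.05), bounds=(0.0, 1.0), complement=True,
            ),
            "sens_snv": DistributionSpec(
                "gamma", (4.0, 0.0075), bounds=(0.0, 1.0), complement=True,
            ),
            "fp_frac": DistributionSpec(
                "truncated-exponential", (0.25,), bounds=(0.0, 1.0),
            ),
        }
    return specs


def degenerate_mc_specs(config: ModelConfig) -> dict[str, dict[str, DistributionSpec]]:
    """Point-mass specs at the main-model values: every replicate equals the
    deterministic model (useful as a collapse check)."""
    specs = {}
    for gene in config.genes:
        specs[gene.name] = {
            "p_indel": DistributionSpec("fixed", (gene.spectrum.p_indel,)),
            "sens_indel": DistributionSpec("fixed", (config.platform.sens_indel,)),
            "sens_snv": DistributionSpec("fixed", (config.platform.sens_snv,)),
            "fp_frac": DistributionSpec("fixed", (0.0,)),
        }
    return specs


def _gene_rng(seed: int, gene_name: str) -> np.random.Generator:
    # substream keyed on the gene name, not list position
    key = zlib.crc32(gene_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def sample_parameters(
    gene: GeneModel,
    platform: PlatformPerformance,
    specs: Mapping[str, DistributionSpec],
    rng: np.random.Generator,
    fp_rate_cap: float = 0.10,
    pop=None,
) -> tuple[GeneModel, PlatformPerformance, float]:
    """Draw one perturbed parameter set for one gene.

    The CNV spectrum share and CNV sensitivity keep their point values;
    ``p_snv`` is set to ``1 - p_cnv - p_indel`` so the spectrum sums to
    one.  The false-positive count is the drawn ``fp_frac`` times
    ``fp_rate_cap`` times the replicate's true positives (0 if ``pop`` is
    not supplied).

    Returns the perturbed gene model, perturbed platform, and fp count.
    """
    p_cnv = gene.spectrum.p_cnv
    p_indel = float(specs["p_indel"].sample(rng))
    p_snv = 1.0 - p_cnv - p_indel
    if p_snv < 0:
        raise ConfigError(
            f"p_indel draw {p_indel} exceeds 1 - p_cnv = {1 - p_cnv}; "
            "tighten the p_indel spec bounds"
        )
    sens_indel = float(np.clip(specs["sens_indel"].sample(rng), 0.0, 1.0))
    sens_snv = float(np.clip(specs["sens_snv"].sample(rng), 0.0, 1.0))
    fp_frac = float(specs["fp_frac"].sample(rng))

    pert_gene = replace(
        gene, spectrum=MutationSpectrum(p_indel=p_indel, p_snv=p_snv, p_cnv=p_cnv)
    )
    pert_platform = replace(platform, sens_indel=sens_indel, sens_snv=sens_snv)
    if pop is not None:
        tp = expected_confusion(pert_gene, pert_platform, pop).tp
        fp_count = fp_frac * fp_rate_cap * tp
    else:
        fp_count = 0.0
    return pert_gene, pert_platform, fp_count


_CELLS = ("tp", "fp", "fn", "tn")


@dataclass(frozen=True)
class MCResult:
    """Replicate-level cells and summary statistics per gene."""

    replicates: Mapping[str, pd.DataFrame]  # gene -> columns tp, fp, fn, tn
    seed: int
    n_replicates: int

    def summary(self, rounded: bool = True) -> pd.DataFrame:
        """Mean, SD, median, quartiles, min, max per cell per gene.

        With ``rounded=True`` (default) statistics are over the
        integer-rounded replicate cells, matching how counts of women are
        reported; quartiles use linear interpolation.
        """
        rows = []
        for gene_name, df in self.replicates.items():
            vals = df[list(_CELLS)].to_numpy()
            if rounded:
                vals = np.floor(vals + 0.5)  # cells are non-negative
            for j, cell in enumerate(_CELLS):
                v = vals[:, j]
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                rows.append({
                    "gene": gene_name, "cell": cell,
                    "mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                    "median": float(med), "q1": float(q1), "q3": float(q3),
                    "min": float(v.min()), "max": float(v.max()),
                })
        return pd.DataFrame(rows).set_index(["gene", "cell"])


def run_mc(
    config: ModelConfig,
    mc: MCConfig,
    count_sampling: bool = False,
) -> MCResult:
    """Re-run the deterministic model under sampled parameters.

    Each replicate draws ``p_indel``, ``sens_indel``, ``sens_snv`` and the
    false-positive fraction from their specs and evaluates the main-model
    cell formulas; cells stay continuous (expected counts) unless
    ``count_sampling=True``, which instead draws integer cohorts
    (binomial detection among the rounded carrier count).

    Deterministic for a given ``(config, mc)``: per-gene substreams are
    keyed on gene names.
    """
    n = mc.n_replicates
    replicates: dict[str, pd.DataFrame] = {}
    for gene in config.genes:
        if gene.name not in mc.specs:
            raise ConfigError(f"no distribution specs supplied for gene {gene.name!r}")
        specs = mc.specs[gene.name]
        rng = _gene_rng(mc.seed, gene.name)

        p_cnv = gene.spectrum.p_cnv
        p_indel = np.asarray(specs["p_indel"].sample(rng, n), dtype=float)
        sens_indel = np.clip(specs["sens_indel"].sample(rng, n), 0.0, 1.0)
        sens_snv = np.clip(specs["sens_snv"].sample(rng, n), 0.0, 1.0)
        fp_frac = np.asarray(specs["fp_frac"].sample(rng, n), dtype=float)

        p_snv = 1.0 - p_cnv - p_indel
        if np.any(p_snv < -1e-12):
            raise ConfigError(
                f"p_indel spec for {gene.name} can exceed 1 - p_cnv; "
                "set bounds no wider than [0, 1 - p_cnv]"
            )
        p_snv = np.clip(p_snv, 0.0, None)

        carriers = gene.prevalence * config.population.size
        detect = (
            p_indel * sens_indel
            + p_snv * sens_snv
            + p_cnv * config.platform.sens_cnv
        ) * gene.coverage

        if count_sampling:
            carriers_int = int(np.floor(carriers + 0.5))
            tp = rng.binomial(carriers_int, detect).astype(float)
            fn = carriers_int - tp
            fp = np.floor(fp_frac * mc.fp_rate_cap * tp + 0.5)
            tn = config.population.size - carriers_int - fp
        else:
            tp = carriers * detect
            fn = carriers - tp
            fp = fp_frac * mc.fp_rate_cap * tp
            tn = config.population.size - carriers - fp

        replicates[gene.name] = pd.DataFrame(
            {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        )
    return MCResult(replicates=replicates, seed=mc.seed, n_replicates=n)
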