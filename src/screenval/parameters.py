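"""Model parameters for population genomic-screening test performance.

All quantities the model consumes live here: per-gene carrier prevalence,
the mutation-class spectrum (indel / SNV / CNV split), platform detection
sensitivity and specificity per class, horizontal gene coverage, lifetime
penetrance, and the population being screened.  A built-in preset carries
the default UK unselected-population model (100,000 women, BRCA1/BRCA2);
arbitrary models are loaded from a YAML configuration file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ConfigError",
    "MutationSpectrum",
    "PlatformPerformance",
    "PenetranceEstimate",
    "GeneModel",
    "PopulationConfig",
    "ModelConfig",
    "load_config",
    "save_config",
    "default_preset",
]

#: tolerance for the spectrum summing to one; generous enough to survive
#: text round-trips of decimal fractions, tight enough to catch typos
SPECTRUM_TOL = 1e-9


class ConfigError(ValueError):
    """A model parameter failed validation; the message names the field."""


def _check_prob(value: float, name: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{name} must be a number, got {value!r}")
    if math.isnan(value) or not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class MutationSpectrum:
    """Split of pathogenic mutations into small indels, SNVs and CNVs.

    The three proportions must sum to one: every pathogenic mutation in the
    model belongs to exactly one class, and each class has its own platform
    detection sensitivity.
    """

    p_indel: float
    p_snv: float
    p_cnv: float

    def __post_init__(self) -> None:
        for name in ("p_indel", "p_snv", "p_cnv"):
            _check_prob(getattr(self, name), f"spectrum.{name}")
        total = self.p_indel + self.p_snv + self.p_cnv
        if abs(total - 1.0) > SPECTRUM_TOL:
            raise ConfigError(
                f"spectrum proportions must sum to 1, got {total!r} "
                f"(indel={self.p_indel}, snv={self.p_snv}, cnv={self.p_cnv})"
            )


@dataclass(frozen=True)
class PlatformPerformance:
    """Per-mutation-class detection sensitivity and specificity of the assay.

    Specificities are carried per class for completeness, but the main model
    collapses false positives to zero (a confirmatory assay is assumed to
    remove them), so the default preset sets every specificity to 1.
    """

    sens_indel: float
    sens_snv: float
    sens_cnv: float
    spec_indel: float = 1.0
    spec_snv: float = 1.0
    spec_cnv: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "sens_indel", "sens_snv", "sens_cnv",
            "spec_indel", "spec_snv", "spec_cnv",
        ):
            _check_prob(getattr(self, name), f"platform.{name}")


@dataclass(frozen=True)
class PenetranceEstimate:
    """Lifetime disease probability for a mutation carrier.

    ``central`` is the point estimate used by the deterministic model;
    ``low``/``high`` bracket the literature range and drive the reported
    outcome ranges.
    """

    central: float
    low: float
    high: float

    def __post_init__(self) -> None:
        for name in ("central", "low", "high"):
            _check_prob(getattr(self, name), f"penetrance.{name}")
        if not self.low <= self.central <= self.high:
            raise ConfigError(
                f"penetrance must satisfy low <= central <= high, got "
                f"low={self.low}, central={self.central}, high={self.high}"
            )


@dataclass(frozen=True)
class GeneModel:
    """One gene's screening parameters.

    Parameters
    ----------
    name
        Gene symbol, e.g. ``"BRCA1"``.
    prevalence
        Carrier frequency of pathogenic mutations in the unselected
        population.
    spectrum
        Mutation-class split for this gene.
    coverage
        Horizontal coverage: fraction of the gene's genomic region actually
        covered by sequencing reads.
    penetrance
        Lifetime breast-cancer risk for carriers of a pathogenic mutation
        in this gene.
    """

    name: str
    prevalence: float
    spectrum: MutationSpectrum
    coverage: float
    penetrance: PenetranceEstimate

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("gene name must be a non-empty string")
        _check_prob(self.prevalence, f"{self.name}.prevalence")
        _check_prob(self.coverage, f"{self.name}.coverage")


@dataclass(frozen=True)
class PopulationConfig:
    """The screened population: its size and background lifetime risk."""

    size: int
    background_risk: float

    def __post_init__(self) -> None:
        if not isinstance(self.size, int) or isinstance(self.size, bool) or self.size < 1:
            raise ConfigError(f"population.size must be a positive integer, got {self.size!r}")
        _check_prob(self.background_risk, "population.background_risk")


@dataclass(frozen=True)
class ModelConfig:
    """A complete, validated model: genes, platform, population."""

    genes: tuple[GeneModel, ...]
    platform: PlatformPerformance
    population: PopulationConfig

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate gene names in config: {names}")
        total_prev = sum(g.prevalence for g in self.genes)
        if total_prev > 1.0:
            raise ConfigError(
                f"summed gene prevalences exceed 1 ({total_prev}); carrier "
                "states are modelled as disjoint"
            )

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


# ---------------------------------------------------------------------------
# YAML config I/O


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing field {where}.{key}")
    return mapping[key]


def load_config(path: Union[str, Path]) -> ModelConfig:
    """Load and validate a model configuration from a YAML file.

    The schema (see README) has three top-level keys: ``population``
    (``size``, ``background_risk``), ``platform`` (``sens_indel``,
    ``sens_snv``, ``sens_cnv`` and optional ``spec_*``), and ``genes``, a
    list of mappings each with ``name``, ``prevalence``, ``coverage``,
    ``spectrum`` (``indel``/``snv``/``cnv``) and ``penetrance``
    (``central``/``low``/``high``).

    Raises
    ------
    ConfigError
        If a field is missing, a proportion falls outside [0, 1], or a
        spectrum does not sum to one.  The message names the field.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    pop_raw = _require(raw, "population", "config")
    population = PopulationConfig(
        size=_require(pop_raw, "size", "population"),
        background_risk=_require(pop_raw, "background_risk", "population"),
    )

    plat_raw = _require(raw, "platform", "config")
    platform = PlatformPerformance(
        sens_indel=_require(plat_raw, "sens_indel", "platform"),
        sens_snv=_require(plat_raw, "sens_snv", "platform"),
        sens_cnv=_require(plat_raw, "sens_cnv", "platform"),
        spec_indel=plat_raw.get("spec_indel", 1.0),
        spec_snv=plat_raw.get("spec_snv", 1.0),
        spec_cnv=plat_raw.get("spec_cnv", 1.0),
    )

    genes = []
    for i, g in enumerate(_require(raw, "genes", "config")):
        where = f"genes[{i}]"
        spec_raw = _require(g, "spectrum", where)
        pen_raw = _require(g, "penetrance", where)
        genes.append(
            GeneModel(
                name=_require(g, "name", where),
                prevalence=_require(g, "prevalence", where),
                coverage=_require(g, "coverage", where),
                spectrum=MutationSpectrum(
                    p_indel=_require(spec_raw, "indel", f"{where}.spectrum"),
                    p_snv=_require(spec_raw, "snv", f"{where}.spectrum"),
                    p_cnv=_require(spec_raw, "cnv", f"{where}.spectrum"),
                ),
                penetrance=PenetranceEstimate(
                    central=_require(pen_raw, "central", f"{where}.penetrance"),
                    low=_require(pen_raw, "low", f"{where}.penetrance"),
                    high=_require(pen_raw, "high", f"{where}.penetrance"),
                ),
            )
        )
    return ModelConfig(genes=tuple(genes), platform=platform, population=population)


def save_config(config: ModelConfig, path: Union[str, Path]) -> None:
    """Write a model configuration to YAML; inverse of :func:`load_config`."""
    doc = {
        "population": {
            "size": config.population.size,
            "background_risk": config.population.background_risk,
        },
        "platform": {
            "sens_indel": config.platform.sens_indel,
            "sens_snv": config.platform.sens_snv,
            "sens_cnv": config.platform.sens_cnv,
            "spec_indel": config.platform.spec_indel,
            "spec_snv": config.platform.spec_snv,
            "spec_cnv": config.platform.spec_cnv,
        },
        "genes": [
            {
                "name": g.name,
                "prevalence": g.prevalence,
                "coverage": g.coverage,
                "spectrum": {
                    "indel": g.spectrum.p_indel,
                    "snv": g.spectrum.p_snv,
                    "cnv": g.spectrum.p_cnv,
                },
                "penetrance": {
                    "central": g.penetrance.central,
                    "low": g.penetrance.low,
                    "high": g.penetrance.high,
                },
            }
            for g in config.genes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_preset() -> ModelConfig:
    """The built-in UK unselected-population screening model.

    100,000 women screened by whole-genome sequencing for pathogenic BRCA1
    and BRCA2 mutations.  Carrier prevalences are 0.12 % (BRCA1) and 0.2 %
    (BRCA2); mutation spectra, horizontal coverage and per-class platform
    sensitivities reflect published performance of clinical WGS (indels
    80 %, SNVs 97 %, CNVs undetected).  Lifetime breast-cancer penetrance
    is 59 % (range 57–71 %) for BRCA1 carriers and 51 % (range 45–87.5 %)
    for BRCA2 carriers, against a 12.5 % background lifetime risk.
    """
    platform = PlatformPerformance(
        sens_indel=0.8,
        sens_snv=0.97,
        sens_cnv=0.0,
        spec_indel=1.0,
        spec_snv=1.0,
        spec_cnv=1.0,
    )
    brca1 = GeneModel(
        name="BRCA1",
        prevalence=0.0012,
        spectrum=MutationSpectrum(p_indel=0.54, p_snv=0.36, p_cnv=0.1),
        coverage=0.9941,
        penetrance=PenetranceEstimate(central=0.59, low=0.57, high=0.71),
    )
    brca2 = GeneModel(
        name="BRCA2",
        prevalence=0.002,
        spectrum=MutationSpectrum(p_indel=0.69, p_snv=0.21, p_cnv=0.1),
        coverage=0.9997,
        penetrance=PenetranceEstimate(central=0.51, low=0.45, high=0.875),
    )
    population = PopulationConfig(size=100_000, background_risk=0.125)
    return ModelConfig(genes=(brca1, brca2), platform=platform, population=population)
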