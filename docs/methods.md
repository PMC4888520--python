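# Methods

## The model

`screenval` models the performance of whole-genome sequencing (WGS) used as
a population screen for pathogenic BRCA1/BRCA2 mutations in a hypothetical
unselected cohort of 100,000 women. It has three layers, each consuming the
output of the previous one, plus an individual-level simulator that acts as
a stochastic oracle for all of them.

### Analytic validity (deterministic)

For each gene the expected confusion-matrix cells follow directly from the
parameters. With carrier prevalence π, population size N, mutation-class
spectrum (p_indel, p_snv, p_cnv), per-class detection sensitivities
(s_indel, s_snv, s_cnv) and horizontal coverage c:

    TP = π · N · (p_indel·s_indel + p_snv·s_snv + p_cnv·s_cnv) · c
    FN = π · N − TP
    FP = 0 in the main model (a confirmatory assay is assumed to remove
         false calls; the uncertainty analysis relaxes this)
    TN = N − π·N − FP

Variants of uncertain significance are assumed unreported and are counted
inside TN. Sensitivity, specificity, PPV and NPV are the usual ratios.

**Rounding convention.** Cells are rounded to whole women half-away-from-
zero, and the performance metrics are computed from the *rounded* cells.
This is deliberate: the continuous BRCA1 cells give TP/carriers =
93.19/120 = 77.7 %, whereas reporting whole women (93 of 120) gives
77.5 % — the convention under which counts and percentages in a report are
mutually consistent. The continuous cells remain available
(`use_rounded=False`) for uncertainty propagation and oracle comparison.
One consequence worth knowing: the BRCA1 NPV from rounded cells is
99880/99907 = 0.99973, which this package formats as "100.0 %" at one
decimal (round-half-away); the raw proportion is always present in JSON
output, and downstream checks should use the proportion (e.g. NPV ≥ 0.999)
rather than the formatted string.

### Parameter uncertainty (Monte Carlo)

The deterministic model is re-evaluated (default 100,000 replicates) with
inputs drawn from uncertainty distributions. Within a replicate the cell
formulas are unchanged — no count-level noise is added — so the output
spread isolates parameter uncertainty. Structure:

- the CNV spectrum share stays fixed at its point value; the indel share is
  drawn from a truncated normal and the SNV share takes the remainder, so
  every replicate's spectrum sums to one;
- CNV sensitivity stays fixed (0 by default: current pipelines do not call
  CNVs reliably); indel and SNV sensitivities are drawn as 1 − deficit with
  gamma-distributed deficits truncated so the result stays in [0, 1];
- the false-positive count is a draw from a distribution heavily skewed
  towards zero, capped at 10 % of that replicate's true positives;
- carrier prevalence is treated as a fixed input and not varied.

The *families* above are part of the model; the *numeric parameters* of the
default distributions are calibration choices of this package and are fully
overridable per gene and per parameter:

| parameter    | default spec                               | rationale |
|--------------|--------------------------------------------|-----------|
| `p_indel`    | Normal(point value, 0.05), truncated to [0, 1−p_cnv] | sd 0.05 spans the spread of published spectra |
| `sens_indel` | 1 − Gamma(shape 4, scale 0.05), i.e. deficit mean 0.20, sd 0.10 | centred on the 80 % point value, right tail of poorer assays |
| `sens_snv`   | 1 − Gamma(shape 4, scale 0.0075), deficit mean 0.03 | centred on 97 % |
| `fp_frac`    | Exponential(scale 0.25) truncated to [0, 1], times 0.1·TP | "less than 10 % of TP, heavily skewed to 0" |

Because these calibration constants are not externally fixed, summary
means/SDs of the replicate distribution are reported but not asserted
against any external table; the package's guarantees about the Monte Carlo
layer are structural (collapse, conservation, reproducibility, monotone
coupling — see the test suite).

**Sampling mechanics.** Every draw is an inverse-CDF transform of a single
uniform stream (`scipy.stats` ppf with CDF-interval truncation, not
clipping). This has two useful consequences: truncation is exact (the
truncated-normal mean matches `scipy.stats.truncnorm` in closed form), and
holding the seed while shifting a distribution's location produces a
replicate-by-replicate monotone coupling, which the tests exploit as a
stress check. Each gene gets an independent RNG substream keyed on a hash
of its *name* (`SeedSequence(seed, spawn_key=(crc32(name),))`), so adding
or reordering genes never perturbs another gene's draws.

**Quartiles** use linear interpolation (`numpy.percentile` default), and
summary statistics are computed over the integer-rounded replicate cells
by default, matching how counts of women are reported; pass
`rounded=False` for statistics on the continuous cells.

An optional `count_sampling` mode replaces the expected-value cells with
binomially drawn integer cohorts per replicate, for users who want
population-finiteness noise on top of parameter uncertainty.

### Clinical validity (penetrance projection)

Carriers — detected (TP) or missed (FN) — accrue lifetime breast cancer at
their gene's penetrance: central 0.59 (range 0.57–0.71) for BRCA1, 0.51
(range 0.45–0.875) for BRCA2. Women without a pathogenic mutation (TN, and
any FP) accrue cancer at the background lifetime risk of 0.125. The
projection consumes the *rounded* cells (it describes whole women), sums
per-gene contributions, and rounds the summed expectation once for
reporting ("round after sum"): 93×0.59 + 151×0.51 = 131.88 → 132 expected
cancers among the 244 true-positive women, with range endpoints 121 and
198 reproduced the same way. The true-negative pool is counted once across
the gene panel (N − all carriers − FP = 99,680), giving 99,680 × 0.125 =
12,460 background cancers. The four scenarios partition the population:
244 / 0 / 76 / 99,680.

One projected figure resists reproduction: the published lower bound for
cancers among missed carriers is 36, while the rounded cells give
27×0.57 + 49×0.45 = 37.44 → 37 (the 36 is instead consistent with the
Monte-Carlo mean FN cells 26/48). This package reports the computed 37 and
notes the discrepancy rather than forcing agreement.

Double carriers are ignored (prevalences treated as disjoint); at these
frequencies the error is below one woman in 100,000.

### Cohort simulator (oracle)

Each simulated woman independently draws: carrier state from one
categorical over {BRCA1, BRCA2, none} (disjoint — no double carriers);
mutation class from her gene's spectrum; a coverage Bernoulli at the
gene's horizontal coverage and, if covered, a detection Bernoulli at the
class sensitivity (so detection probability is sensitivity × coverage,
matching the expectation formula's multiplicative structure — independence
is a simplicity choice, as any dependence model with the same marginal
would give the same expectations); and lifetime cancer at her gene's
central penetrance, or the background risk for non-carriers. Non-carriers
are never called positive, mirroring the main model's specificity-1
assumption.

The simulator's role is empirical validation: at large n every tabulated
cell and every scenario's cancer count must land within 3 binomial
standard errors of the corresponding analytic expectation. The acceptance
test runs it at n = 10⁷ (a 100× scale-up of the modelled population,
chosen to make the 3-SE band narrow relative to the quantities checked);
unit tests use n = 2×10⁶.

What the synthetic cohort does **not** emulate: family structure or
inheritance, age structure or time-to-onset, sequence-level reads and
variant calling, VUS reclassification, double carriers, or correlation
between coverage and mutation class. Passing oracle tests therefore
demonstrates internal consistency of the expectation algebra, not fidelity
to real sequencing data — platform performance enters only as parameters.

## Degenerate inputs and numerical choices

- Proportions are validated to [0, 1]; spectra must sum to 1 within 1e-9
  (float-text round-trip safety).
- Performance metrics with a zero denominator are carried as `None`
  ("undefined"), never coerced to 0.
- A point-mass ("fixed") distribution spec for every parameter collapses
  the Monte Carlo to the deterministic model in every replicate; the
  collapse test asserts bit-identical replicates rather than `sd == 0`,
  since the sample SD of 10³ identical floats picks up ~1e-14 accumulation
  noise.
- Zero prevalence, zero sensitivity, and saturated (everyone a detected
  carrier) inputs are all exercised in the tests.

## Known limitations

- Penetrance is a single lifetime probability; no age-specific risk, no
  competing mortality, no intervention effects.
- The Monte Carlo varies spectrum and sensitivities but not prevalence,
  coverage or penetrance; its default distribution constants are
  calibration choices, so its output spread should be read as illustrative
  of parameter uncertainty, not as a validated credible interval.
- Specificity is parameterised per mutation class but the shipped model
  sets it to 1 (confirmatory testing assumed); false positives enter only
  through the uncertainty analysis's skewed draw.
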