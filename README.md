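# screenval

Test-performance modelling for population genomic screening.

`screenval` answers a question faced by anyone designing a programme that
reports secondary genomic findings: **if whole-genome sequencing (WGS) were
used to screen an unselected population for pathogenic BRCA1/BRCA2
mutations, how many carriers would it find, how many would it miss, and
what would that mean for future breast-cancer cases?** It is written for
clinical-genetics and public-health modellers who want the arithmetic of
such a screen to be explicit, parameterised and reproducible.

The package has four layers:

1. **Analytic validity** — a deterministic confusion-matrix model. For a
   gene with carrier prevalence π, class spectrum (p_indel, p_snv, p_cnv),
   per-class detection sensitivities (s_indel, s_snv, s_cnv) and horizontal
   coverage c, in a population of N women:

       TP = π·N·(p_indel·s_indel + p_snv·s_snv + p_cnv·s_cnv)·c
       FN = π·N − TP,   FP = 0 (confirmatory testing),   TN = N − π·N − FP

   with sensitivity, specificity, PPV and NPV computed from the rounded
   cells (whole women).
2. **Parameter uncertainty** — a Monte Carlo analysis (100,000 replicates)
   that re-runs the deterministic model with the indel share, the indel and
   SNV sensitivities and a zero-skewed false-positive count drawn from
   configurable distributions.
3. **Clinical validity** — penetrance projection: carriers accrue lifetime
   breast cancer at their gene's penetrance (0.59 for BRCA1, 0.51 for
   BRCA2, with literature ranges), non-carriers at the 12.5 % background
   lifetime risk, yielding expected cancer counts for each of four outcome
   scenarios.
4. **Cohort simulator** — an individual-level synthetic-data generator
   (carrier → mutation class → coverage/detection → cancer) that serves as
   a brute-force oracle: every expectation above is checked against seeded
   simulations at large n.

See `docs/methods.md` for the full model description, the rounding
convention, and the calibration choices behind the Monte Carlo defaults.

## Worked example

The built-in preset models 100,000 unselected UK women (BRCA1 prevalence
0.12 %, BRCA2 0.2 %; WGS detecting 80 % of small indels, 97 % of SNVs and
no CNVs).

```
$ screenval run-main --preset default --out-prefix out/main
BRCA1 main model  Has variant  No variant   Total
Detected: yes              93           0      93
Detected: no               27       99880   99907
Total                     120       99880  100000

sensitivity: 77.5 %  specificity: 100.0 %  ppv: 100.0 %  npv: 100.0 %

BRCA2 main model  Has variant  No variant   Total
Detected: yes             151           0     151
Detected: no               49       99800   99849
Total                     200       99800  100000

sensitivity: 75.5 %  specificity: 100.0 %  ppv: 100.0 %  npv: 100.0 %
```

Of 120 BRCA1 carriers the screen detects 93 and misses 27 (mostly CNVs,
which the platform cannot call), an analytic sensitivity of 77.5 %; BRCA2
fares similarly at 75.5 %. With false positives removed by confirmatory
testing, specificity and PPV are 100 %; NPV is 99880/99907 = 0.9997 (the
JSON output carries the raw proportion). Projecting penetrance onto these
cells:

```
$ screenval project --preset default --out-prefix out/proj
Population screened: 100000
├─ Scenario 1 (true positive): 244 women
│    expected breast cancers: 132 (range 121-198)
│    predicted not to develop cancer: 112
├─ Scenario 2 (false positive): 0 women
│    expected breast cancers: 0
├─ Scenario 3 (false negative): 76 women
│    expected breast cancers: 41 (range 37-62)
│    predicted not to develop cancer: 35
└─ Scenario 4 (true negative): 99680 women
     expected breast cancers: 12460
```

Read: 244 women would be told they carry a pathogenic mutation; about 132
of them (range 121–198 across penetrance estimates) are expected to develop
breast cancer and could benefit from intervention, while the other 112
would face intervention decisions without developing the disease. Another
41 expected cancers occur among the 76 carriers the screen misses, against
12,460 background cases among the 99,680 women with no mutation.

The other subcommands: `screenval run-mc --preset default --reps 100000
--seed 1` writes the Monte Carlo summary (mean, SD, median, IQR, min, max
per confusion cell per gene), and `screenval simulate --preset default
--n 1000000 --seed 1` writes a per-individual synthetic cohort as CSV.
Custom models are YAML files (`--config model.yaml`) with `population`,
`platform` and `genes` sections; `screenval.save_config(default_preset(),
"model.yaml")` writes a template to edit.

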