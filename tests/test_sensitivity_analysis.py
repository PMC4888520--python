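"""Monte Carlo uncertainty analysis: sampling, determinism, collapse."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screenval import (
    ConfigError,
    DistributionSpec,
    MCConfig,
    default_mc_specs,
    degenerate_mc_specs,
    run_mc,
    sample_parameters,
)

CELLS = ["tp", "fp", "fn", "tn"]


class TestDistributionSpec:
    def test_truncated_normal_mean_matches_closed_form(self):
        # oracle: scipy's truncated-normal expectation
        spec = DistributionSpec("normal", (0.54, 0.05), bounds=(0.0, 0.9))
        rng = np.random.default_rng(42)
        draws = spec.sample(rng, 10_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - spec.mean()) < 3 * se
        assert spec.mean() == pytest.approx(
            stats.truncnorm(
                (0 - 0.54) / 0.05, (0.9 - 0.54) / 0.05, loc=0.54, scale=0.05
            ).mean(),
            abs=1e-12,
        )

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("normal", (0.54, 0.05), bounds=(0.4, 0.6)),
            DistributionSpec("gamma", (4.0, 0.05), bounds=(0.0, 0.5)),
            DistributionSpec("scaled-beta", (2.0, 5.0), bounds=(0.1, 0.3)),
            DistributionSpec("truncated-exponential", (0.25,), bounds=(0.0, 1.0)),
        ],
        ids=lambda s: s.family,
    )
    def test_draws_respect_bounds(self, spec):
        draws = spec.sample(np.random.default_rng(7), 5_000)
        lo, hi = spec.bounds
        assert draws.min() >= lo - 1e-12 and draws.max() <= hi + 1e-12

    def test_complement_gives_one_minus_deficit(self):
        spec = DistributionSpec("gamma", (4.0, 0.05), bounds=(0.0, 1.0), complement=True)
        draws = spec.sample(np.random.default_rng(0), 5_000)
        assert np.all((draws >= 0.0) & (draws <= 1.0))
        # deficit mean is shape*scale = 0.20 (truncation barely binds)
        assert draws.mean() == pytest.approx(0.80, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="lognormal", params=(1.0,)),
            dict(family="gamma", params=(-1.0, 0.05)),
            dict(family="normal", params=(0.5, 0.0)),
            dict(family="truncated-exponential", params=(0.25,)),  # bounds required
            dict(family="fixed", params=(2.0,), bounds=(0.0, 1.0)),  # outside bounds
            dict(family="normal", params=(0.5, 0.1), bounds=(0.9, 0.8)),  # lo >= hi
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            DistributionSpec(**kwargs)


class TestSampleParameters:
    def test_structural_constraints_hold_for_every_draw(self, preset):
        gene = preset.gene("BRCA1")
        specs = default_mc_specs(preset)["BRCA1"]
        rng = np.random.default_rng(11)
        for _ in range(200):
            pg, pp, fp = sample_parameters(
                gene, preset.platform, specs, rng, pop=preset.population
            )
            s = pg.spectrum
            assert s.p_cnv == gene.spectrum.p_cnv  # CNV share stays fixed
            assert s.p_indel + s.p_snv + s.p_cnv == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= pp.sens_indel <= 1.0 and 0.0 <= pp.sens_snv <= 1.0
            assert pp.sens_cnv == preset.platform.sens_cnv  # stays fixed at 0
            assert fp >= 0.0

    def test_fp_capped_at_fraction_of_tp(self, preset):
        from screenval import expected_confusion

        gene = preset.gene("BRCA1")
        specs = default_mc_specs(preset)["BRCA1"]
        rng = np.random.default_rng(5)
        for _ in range(100):
            pg, pp, fp = sample_parameters(
                gene, preset.platform, specs, rng, fp_rate_cap=0.1, pop=preset.population
            )
            tp = expected_confusion(pg, pp, preset.population).tp
            assert fp <= 0.1 * tp + 1e-12

    def test_degenerate_specs_reproduce_main_model(self, preset):
        gene = preset.gene("BRCA1")
        specs = degenerate_mc_specs(preset)["BRCA1"]
        pg, pp, fp = sample_parameters(
            gene, preset.platform, specs, np.random.default_rng(0), pop=preset.population
        )
        assert pg == gene and pp == preset.platform and fp == 0.0


class TestRunMC:
    def test_degenerate_collapse(self, preset):
        mc = MCConfig(n_replicates=500, seed=3, specs=degenerate_mc_specs(preset))
        result = run_mc(preset, mc)
        df = result.replicates["BRCA1"]
        assert df["tp"].nunique() == 1
        assert df["tp"].iloc[0] == pytest.approx(93.1909104, abs=1e-9)
        assert (df["fp"] == 0).all()
        summ = result.summary(rounded=False)
        assert summ.loc[("BRCA1", "tp"), "min"] == summ.loc[("BRCA1", "tp"), "max"]

    def test_seeded_determinism(self, preset):
        mc = MCConfig(n_replicates=2_000, seed=17, specs=default_mc_specs(preset))
        r1, r2 = run_mc(preset, mc), run_mc(preset, mc)
        for gene in r1.replicates:
            pd.testing.assert_frame_equal(
                r1.replicates[gene], r2.replicates[gene], check_exact=True
            )

    def test_replicates_conserve_population(self, preset):
        mc = MCConfig(n_replicates=2_000, seed=2, specs=default_mc_specs(preset))
        result = run_mc(preset, mc)
        for df in result.replicates.values():
            totals = df[CELLS].sum(axis=1)
            assert np.allclose(totals, preset.population.size, atol=1e-9)

    def test_gene_substreams_independent_of_panel(self, preset):
        import dataclasses

        mc_full = MCConfig(n_replicates=1_000, seed=9, specs=default_mc_specs(preset))
        solo = dataclasses.replace(preset, genes=(preset.gene("BRCA2"),))
        mc_solo = MCConfig(n_replicates=1_000, seed=9, specs=default_mc_specs(solo))
        full = run_mc(preset, mc_full).replicates["BRCA2"]
        alone = run_mc(solo, mc_solo).replicates["BRCA2"]
        pd.testing.assert_frame_equal(full, alone, check_exact=True)

    def test_raising_sens_indel_location_raises_tp(self, preset):
        # paired seeds: the uniform stream is shared, so a smaller deficit
        # scale lifts sensitivity replicate-by-replicate
        specs_lo = default_mc_specs(preset)
        specs_hi = default_mc_specs(preset)
        for g in specs_hi:
            specs_hi[g] = dict(specs_hi[g])
            specs_hi[g]["sens_indel"] = DistributionSpec(
                "gamma", (4.0, 0.025), bounds=(0.0, 1.0), complement=True
            )
        tp_lo = run_mc(preset, MCConfig(2_000, 21, specs_lo)).replicates["BRCA1"]["tp"]
        tp_hi = run_mc(preset, MCConfig(2_000, 21, specs_hi)).replicates["BRCA1"]["tp"]
        assert (tp_hi >= tp_lo - 1e-12).all()
        assert tp_hi.mean() > tp_lo.mean()

    def test_summary_shape_and_ordering(self, preset):
        mc = MCConfig(n_replicates=5_000, seed=1, specs=default_mc_specs(preset))
        summ = run_mc(preset, mc).summary()
        assert list(summ.columns) == ["mean", "sd", "median", "q1", "q3", "min", "max"]
        assert set(summ.index) == {(g.name, c) for g in preset.genes for c in CELLS}
        assert (summ["min"] <= summ["q1"]).all()
        assert (summ["q1"] <= summ["median"]).all()
        assert (summ["median"] <= summ["q3"]).all()
        assert (summ["q3"] <= summ["max"]).all()
        assert (summ["sd"] >= 0).all()

    def test_count_sampling_gives_integer_cohorts(self, preset):
        mc = MCConfig(n_replicates=1_000, seed=4, specs=default_mc_specs(preset))
        result = run_mc(preset, mc, count_sampling=True)
        df = result.replicates["BRCA1"]
        assert np.allclose(df[CELLS], np.round(df[CELLS]))
        assert np.allclose(df[CELLS].sum(axis=1), preset.population.size)

    def test_missing_gene_spec_rejected(self, preset):
        specs = default_mc_specs(preset)
        del specs["BRCA2"]
        with pytest.raises(ConfigError, match="BRCA2"):
            run_mc(preset, MCConfig(10, 0, specs))
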