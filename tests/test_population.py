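"""Cohort scheduler: initialization, determinism, mortality, gestation, audits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import heterodeb as hd
from heterodeb.deb import body_mass_kg, scaled_reserve_density
from heterodeb.population import (GROUPS, Cohort, MortalityModel,
                                  init_population, mortality_probability,
                                  run_experiment, run_replicate)

from conftest import meanfield_replicate


class TestInitPopulation:
    @pytest.mark.parametrize("fraction", [0.8, 0.5])
    def test_initial_condition_is_exact(self, params, fraction):
        config = hd.PopulationConfig(n_individuals=4,
                                     init_reserve_fraction=fraction)
        cohort = init_population(config, params, "normotherm")
        np.testing.assert_allclose(
            scaled_reserve_density(cohort.state, params), fraction)

    def test_paired_groups_start_identical(self, params):
        config = hd.PopulationConfig(n_individuals=4)
        a = init_population(config, params, "normotherm")
        b = init_population(config, params, "heterotherm")
        np.testing.assert_array_equal(np.asarray(a.state.E),
                                      np.asarray(b.state.E))
        assert np.all(body_mass_kg(a.state, params)
                      == body_mass_kg(b.state, params))

    def test_pregnant_females_hold_reproduction_capital(self, params):
        config = hd.PopulationConfig(n_individuals=2, pregnancy=True)
        cohort = init_population(config, params, "normotherm")
        assert np.all(np.asarray(cohort.state.ER) > 0)
        np.testing.assert_allclose(
            scaled_reserve_density(cohort.state, params), 0.8)

    def test_individual_view_roundtrip(self, params):
        config = hd.PopulationConfig(n_individuals=2, pregnancy=True)
        cohort = init_population(config, params, "heterotherm")
        ind = cohort.individual(1)
        assert ind.group == "heterotherm" and ind.alive and ind.pregnant
        assert ind.embryo is not None and ind.embryo.V_e > 0


class TestMortalityModel:
    def test_logistic_midpoint_and_asymptote(self):
        model = MortalityModel(e50=0.2, b=40.0, pmax=0.1)
        assert mortality_probability(0.2, model) == pytest.approx(0.05)
        assert mortality_probability(50.0, model) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing_in_condition(self):
        model = MortalityModel()
        e = np.linspace(0.0, 1.0, 200)
        p = mortality_probability(e, model)
        assert np.all(np.diff(p) < 0)

    def test_zero_pmax_means_certain_survival(self, params, env):
        config = hd.PopulationConfig(n_individuals=5, n_replicates=2, seed=3,
                                     init_reserve_fraction=0.5)
        result = run_experiment(config, params, env, MortalityModel(pmax=0.0))
        assert result.endpoints["survived"].all()


class TestDeterminismAndScheduling:
    def test_identical_seeds_give_bit_identical_endpoints(self, params, env,
                                                          small_config):
        a = run_experiment(small_config, params, env)
        b = run_experiment(small_config, params, env)
        pd.testing.assert_frame_equal(a.endpoints, b.endpoints)
        pd.testing.assert_frame_equal(a.daily, b.daily)

    def test_dead_individuals_are_frozen(self, params, env):
        # Start emaciated with aggressive mortality so deaths happen early.
        config = hd.PopulationConfig(n_individuals=10, n_replicates=1, seed=5,
                                     init_reserve_fraction=0.5)
        rng = np.random.default_rng(1)
        rep = run_replicate(config, params, env, rng,
                            MortalityModel(e50=0.6, b=30.0, pmax=0.5))
        res = rep["normotherm"]
        alive = res["alive"]
        assert not alive[-1].all(), "expected deaths under aggressive model"
        for i in np.nonzero(~alive[-1])[0]:
            death_day = int(np.nonzero(~alive[:, i])[0][0])
            frozen = res["mass"][death_day:, i]
            np.testing.assert_allclose(frozen, frozen[0])

    def test_two_master_seeds_agree_within_sampling_error(self, params, env):
        config = hd.PopulationConfig(n_individuals=25, n_replicates=5, seed=1)
        other = dataclasses.replace(config, seed=2)
        means, ses = [], []
        for cfg in (config, other):
            ep = run_experiment(cfg, params, env).endpoints
            norm = ep[ep.group == "normotherm"]["final_mass"]
            means.append(norm.mean())
            ses.append(norm.std() / np.sqrt(len(norm)))
        assert abs(means[0] - means[1]) < 3 * max(ses)

    def test_pooled_size_is_625_by_default(self, baseline_result):
        counts = baseline_result.endpoints.groupby("group").size()
        assert (counts == 625).all()
        assert baseline_result.n_pooled == 625


class TestBaselineEnergetics:
    def test_everyone_loses_mass_over_winter(self, baseline_result):
        ep = baseline_result.endpoints
        assert (ep["final_mass"] < ep["init_mass"]).all()

    def test_heterotherm_advantage_in_tb_independent_mode(self, params, env,
                                                          meanfield_config):
        rep = meanfield_replicate(params, env, meanfield_config)
        mass_n = rep["normotherm"]["mass"][:, 0]
        mass_h = rep["heterotherm"]["mass"][:, 0]
        gap = mass_h - mass_n
        assert gap[-1] > 0
        # the daily-mean advantage grows monotonically through the winter
        assert np.all(np.diff(gap) >= -1e-12)
        assert np.all(np.diff(gap)[5:] > 0)

    def test_tb_dependent_feeding_shrinks_the_gap(self, params, env,
                                                  meanfield_config):
        indep = meanfield_replicate(params, env, meanfield_config)
        dep = meanfield_replicate(params, env, meanfield_config,
                                  feeding_mode="tb_dependent")
        gap_indep = indep["heterotherm"]["mass"][-1, 0] \
            - indep["normotherm"]["mass"][-1, 0]
        gap_dep = dep["heterotherm"]["mass"][-1, 0] \
            - dep["normotherm"]["mass"][-1, 0]
        assert 0 <= gap_dep < gap_indep

    def test_ingestion_identical_across_groups_when_tb_independent(
            self, params, env, meanfield_config):
        # With feeding driven by the normothermic reference trajectory, the
        # assimilation term of FMR is shared, so FMR differences are bounded
        # by the metabolic part; verify via the energy books instead.
        rep = meanfield_replicate(params, env, meanfield_config)
        assim_n = rep["normotherm"]["cohort"].assimilated[0]
        assim_h = rep["heterotherm"]["cohort"].assimilated[0]
        assert assim_n == pytest.approx(assim_h, rel=1e-12)

    def test_whole_winter_energy_audit(self, params, env):
        config = hd.PopulationConfig(n_individuals=5, n_replicates=1, seed=9,
                                     pregnancy=True)
        rng = np.random.default_rng(2)
        rep = run_replicate(config, params, env, rng, MortalityModel(pmax=0.0))
        for group in GROUPS:
            cohort: Cohort = rep[group]["cohort"]
            state0 = init_population(config, params, group).state
            delta = (np.asarray(cohort.state.E) - np.asarray(state0.E)
                     + np.asarray(cohort.state.ER) - np.asarray(state0.ER)
                     + params.EG * (np.asarray(cohort.state.V)
                                    - np.asarray(state0.V)))
            balance = cohort.assimilated - delta - cohort.dissipated \
                - cohort.embryo_dissipated - cohort.embryo_stored
            np.testing.assert_allclose(
                balance, 0.0, atol=1e-6 * cohort.assimilated.max())


class TestGestation:
    def test_no_development_during_embryonic_arrest(self, params, env,
                                                    meanfield_config):
        config = dataclasses.replace(meanfield_config, pregnancy=True)
        rng = np.random.default_rng(0)
        mort = MortalityModel(pmax=0.0)
        gest = config.gestation.resolve(env.dates)
        from heterodeb.population import daily_step, init_population
        cohort = init_population(config, params, "normotherm")
        v0 = cohort.embryo_V.copy()
        for day in range(gest[0]):
            daily_step(cohort, day, env, config, params, mort, rng, gest)
        np.testing.assert_array_equal(cohort.embryo_V, v0)
        assert cohort.embryo_dissipated[0] == 0.0

    def test_birth_happens_and_each_mother_has_one_calf(self, params, env,
                                                        meanfield_config):
        config = dataclasses.replace(meanfield_config, pregnancy=True)
        rep = meanfield_replicate(params, env, config)
        for group in GROUPS:
            cohort = rep[group]["cohort"]
            assert cohort.gave_birth.all()
            assert np.isfinite(cohort.calf_mass).all()
            assert not cohort.has_embryo.any()

    def test_maternal_independent_mode_equalizes_embryo_growth(
            self, params, env, meanfield_config):
        config = dataclasses.replace(meanfield_config, pregnancy=True,
                                     embryo_mode="maternal_independent")
        rep = meanfield_replicate(params, env, config)
        calf_n = rep["normotherm"]["cohort"].calf_mass[0]
        calf_h = rep["heterotherm"]["cohort"].calf_mass[0]
        assert calf_h == pytest.approx(calf_n, rel=1e-9)

    def test_tb_corrected_embryos_born_strictly_lighter(self, params, env,
                                                        meanfield_config):
        config = dataclasses.replace(meanfield_config, pregnancy=True,
                                     embryo_mode="maternal_tb_corrected")
        rep = meanfield_replicate(params, env, config)
        calf_n = rep["normotherm"]["cohort"].calf_mass[0]
        calf_h = rep["heterotherm"]["cohort"].calf_mass[0]
        assert calf_h < calf_n

    def test_heterotherm_mothers_keep_larger_reproduction_buffer(
            self, params, env, meanfield_config):
        config = dataclasses.replace(meanfield_config, pregnancy=True)
        rep = meanfield_replicate(params, env, config)
        er_n = np.asarray(rep["normotherm"]["cohort"].state.ER)[0]
        er_h = np.asarray(rep["heterotherm"]["cohort"].state.ER)[0]
        assert er_h > er_n
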