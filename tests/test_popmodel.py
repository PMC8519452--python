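"""Deterministic recursion: census semantics, scenarios, sweeps, fitting."""

import numpy as np
import pytest

from homingdrive import (
    Allele,
    FitnessScheme,
    PopulationState,
    ScenarioConfig,
    Sex,
    derive_rates,
    fit_somatic_cost,
    mendelian_rates,
    simulate_fixation_mimic,
    simulate_release,
    step_generation,
    sweep_functional_resistance,
    sweep_table,
)
from homingdrive.genetics import GENOTYPE_BY_LABEL, GENOTYPES, WT, WW
from homingdrive.popmodel import (
    control_scenario,
    relative_reproductive_output,
    release_scenario,
)

NO_COSTS = FitnessScheme.none()


def adults(comp, generation=0):
    return PopulationState.adults_from_dict(
        {GENOTYPE_BY_LABEL[k]: v for k, v in comp.items()}, generation
    )


class TestStepGeneration:
    def test_all_wild_type_is_a_fixed_point(self, printed_rates):
        state = adults({"W/W": 1.0})
        for _ in range(5):
            juv, state = step_generation(state, printed_rates, NO_COSTS)
            assert juv.freq_f[0] == 1.0 and state.freq_f[0] == 1.0

    def test_hardy_weinberg_step_with_recessive_lethal(self):
        # Mendelian null transgene at 20% heterozygotes: allele freq 0.1,
        # juvenile carriers 1 - 0.9^2 = 0.19, adults W/T = 0.18/0.99.
        state = adults({"W/T": 0.2, "W/W": 0.8})
        juv, adu = step_generation(state, mendelian_rates(), NO_COSTS)
        assert juv.carrier() == pytest.approx(0.19, abs=1e-12)
        i_wt = GENOTYPES.index(WT)
        assert adu.freq_f[i_wt] == pytest.approx(0.18 / 0.99, abs=1e-12)

    def test_drive_cross_juvenile_homozygote_fraction(self, printed_rates,
                                                      observed_costs):
        state = adults({"W/T": 1.0})
        juv, _ = step_generation(state, printed_rates, observed_costs)
        i_tt = GENOTYPES.index(GENOTYPE_BY_LABEL["T/T"])
        assert juv.freq_f[i_tt] == pytest.approx(0.846351, abs=1e-9)

    def test_requires_adult_stage(self, printed_rates):
        state = adults({"W/W": 1.0})
        juv, _ = step_generation(state, printed_rates, NO_COSTS)
        with pytest.raises(ValueError, match="adult"):
            step_generation(juv, printed_rates, NO_COSTS)

    def test_total_fecundity_loss_flags_extinction(self, printed_rates):
        sterile = FitnessScheme(fecundity_cost_f=1.0)
        state = adults({"W/T": 1.0})
        juv, adu = step_generation(state, printed_rates, sterile)
        assert juv.extinct and adu.extinct
        # subsequent steps propagate the extinct state instead of dividing by 0
        juv2, adu2 = step_generation(adu, printed_rates, sterile)
        assert adu2.extinct

    def test_frequency_conservation_over_random_scenarios(self):
        rng = np.random.default_rng(11)
        viable = [g for g in GENOTYPES if g.is_viable]
        for _ in range(1000):
            rates = derive_rates(rng.uniform(0.5, 1), rng.uniform(0.5, 1),
                                 rng.random(), rng.random())
            fitness = FitnessScheme(*(rng.random(3) * 0.95))
            weights = rng.dirichlet(np.ones(len(viable)))
            state = PopulationState.adults_from_dict(dict(zip(viable, weights)))
            juv, adu = step_generation(state, rates, fitness)
            for v in (juv.freq_f, juv.freq_m, adu.freq_f, adu.freq_m):
                if not adu.extinct:
                    assert abs(v.sum() - 1.0) <= 1e-10

    def test_sex_symmetry_with_identical_parameters(self):
        rates = derive_rates(0.91, 0.91, 0.3, 0.1)
        fitness = FitnessScheme(0.0, 0.4, 0.4)  # same somatic cost both sexes
        state = adults({"W/T": 0.35, "W/W": 0.65})
        for _ in range(6):
            juv, state = step_generation(state, rates, fitness)
            assert np.array_equal(state.freq_f, state.freq_m)


class TestSimulateRelease:
    def test_no_cost_release_rises_after_release(self):
        traj = simulate_release(release_scenario("no_cost", generations=12))
        series = traj.carrier_series()
        assert series[0] == pytest.approx(0.2)
        assert series[1] > 0.20

    def test_control_release_declines_by_recessive_lethal_purge(self):
        traj = simulate_release(control_scenario(generations=6))
        series = traj.carrier_series()
        assert series[0] == pytest.approx(0.2, abs=1e-12)
        assert series[1] == pytest.approx(0.19, abs=1e-12)
        assert series[2] == pytest.approx(21.0 / 121.0, abs=1e-12)
        assert all(b < a for a, b in zip(series[1:], series[2:]))

    def test_control_adult_allele_frequency_follows_recessive_lethal_decline(self):
        # classical recessive-lethal decline q' = q/(1+q) among adults
        traj = simulate_release(control_scenario(generations=8))
        q = 0.1
        for rec in traj.records[1:]:
            q = q / (1.0 + q)
            assert rec.allele_frequency(Allele.T) == pytest.approx(q, abs=1e-12)

    def test_zero_release_is_flat_wild_type(self, printed_rates):
        config = ScenarioConfig("custom", printed_rates, NO_COSTS,
                                {WW: 1.0}, 5)
        traj = simulate_release(config)
        assert all(rec.adult_carrier == 0.0 for rec in traj.records)

    def test_carrier_frequency_non_increasing_in_somatic_cost(self):
        # drive advantage ordering: more somatic cost, fewer carriers
        for gen in (2, 4, 6):
            previous = 1.0
            for cost in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
                fitness = FitnessScheme(0.216, cost, cost)
                traj = simulate_release(
                    release_scenario("custom", fitness=fitness, generations=gen)
                )
                series = traj.carrier_series()
                carrier = series[gen] if len(series) > gen else 0.0
                assert carrier <= previous + 1e-12
                previous = carrier

    def test_plotting_hook_writes_figure(self, tmp_path):
        from homingdrive.popmodel import plot_carrier_curves

        traj = simulate_release(release_scenario("no_cost", generations=3))
        target = tmp_path / "curves.png"
        plot_carrier_curves({"no_cost": traj}, str(target))
        assert target.stat().st_size > 0

    def test_tidy_frame_layout(self):
        frame = simulate_release(release_scenario("no_cost", generations=2)).to_frame()
        assert list(frame.columns) == ["generation", "stage", "metric", "sex", "value"]
        assert set(frame["generation"]) == {0, 1, 2}


class TestFixationMimic:
    def test_zero_generations_returns_only_founding_record(self, printed_rates):
        traj = simulate_fixation_mimic(printed_rates, NO_COSTS, 0)
        assert len(traj) == 1 and traj[0].generation == 0
        assert traj[0].adult_carrier == 1.0

    def test_without_functional_repair_output_stays_suppressed(self, printed_rates):
        traj = simulate_fixation_mimic(printed_rates, NO_COSTS, 40)
        out = traj.output_series()
        # reproductive output equilibrates far below wild type and stays there
        assert max(out[1:]) < 0.35
        assert out[-1] == pytest.approx(out[-2], abs=1e-9)

    def test_functional_repair_sweeps_and_restores_output(self, printed_rates):
        traj = simulate_fixation_mimic(printed_rates.with_p(0.005), NO_COSTS, 30)
        r_series = traj.allele_series(Allele.r)
        assert all(b >= a - 1e-12 for a, b in zip(r_series, r_series[1:]))
        assert r_series[-1] > 0.8
        assert traj.output_series()[-1] > 0.95

    def test_observed_costs_lose_the_drive_from_fixation(self, printed_rates,
                                                         observed_costs):
        # with the measured heterozygote costs homing cannot hold the drive
        # at fixation: carriers decline and output recovers without any
        # functional resistance
        traj = simulate_fixation_mimic(printed_rates, observed_costs, 30)
        assert traj.carrier_series()[-1] < 0.1
        assert traj.output_series()[-1] > 0.9


class TestResistanceSweep:
    def test_single_p_matches_simulate_release(self):
        base = release_scenario("observed_cost", generations=8)
        sweep = sweep_functional_resistance(base, [0.25])
        direct = simulate_release(
            release_scenario("observed_cost", p=0.25, generations=8)
        )
        assert sweep[0.25].carrier_series() == direct.carrier_series()

    def test_empty_p_list_rejected(self):
        with pytest.raises(ValueError):
            sweep_functional_resistance(release_scenario("no_cost"), [])

    def test_early_generations_insensitive_to_p(self):
        base = release_scenario("observed_cost", generations=12)
        sweep = sweep_functional_resistance(base, [0.0, 0.05, 0.25, 1.0])
        series = {p: t.carrier_series() for p, t in sweep.items()}
        ps = list(series)
        for g in range(6):
            vals = [series[p][g] for p in ps]
            assert max(vals) - min(vals) < 0.02

    def test_extreme_p_values_diverge_when_drive_persists(self):
        base = release_scenario("no_cost", generations=40)
        sweep = sweep_functional_resistance(base, [0.0, 1.0])
        s0, s1 = sweep[0.0].carrier_series(), sweep[1.0].carrier_series()
        assert abs(s0[-1] - s1[-1]) > 0.05

    def test_long_table_format(self):
        base = release_scenario("no_cost", generations=3)
        table = sweep_table(sweep_functional_resistance(base, [0.0, 0.5]))
        assert list(table.columns) == ["generation", "p", "carrier_freq"]
        assert len(table) == 2 * 4


class TestFitSomaticCost:
    def test_recovers_generating_cost_exactly(self):
        base = release_scenario("observed_cost", generations=8)
        truth = simulate_release(
            release_scenario("custom", fitness=FitnessScheme(0.216, 0.9, 0.9),
                             generations=8)
        ).carrier_series()
        fit = fit_somatic_cost(truth, base, [0.0, 0.3, 0.6, 0.9])
        assert fit.best_cost == 0.9
        sse_at_best = fit.sse_table.set_index("cost").loc[0.9, "sse"]
        assert sse_at_best == pytest.approx(0.0, abs=1e-20)

    def test_recovers_intermediate_cost(self):
        base = release_scenario("observed_cost", generations=6)
        truth = simulate_release(
            release_scenario("custom", fitness=FitnessScheme(0.216, 0.5, 0.5),
                             generations=6)
        ).carrier_series()
        fit = fit_somatic_cost(truth, base, [0.3, 0.5, 0.7])
        assert fit.best_cost == 0.5

    def test_constant_equilibrium_series_prefers_no_cost(self):
        eq = simulate_release(release_scenario("no_cost", generations=40))
        eq_carrier = eq.carrier_series()[-1]
        base = release_scenario("no_cost", release_frequency=eq_carrier,
                                generations=8)
        observed = [eq_carrier] * 9
        fit = fit_somatic_cost(observed, base, [0.0, 0.25, 0.5, 0.75])
        assert fit.best_cost == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_somatic_cost([0.2], release_scenario("no_cost"), [0.0, 0.5])


class TestReproductiveOutput:
    def test_wild_type_population_has_unit_output(self, printed_rates):
        state = adults({"W/W": 1.0})
        assert relative_reproductive_output(state, printed_rates, NO_COSTS) == 1.0

    def test_output_bounded_by_unit_interval(self):
        rng = np.random.default_rng(3)
        viable = [g for g in GENOTYPES if g.is_viable]
        for _ in range(100):
            rates = derive_rates(rng.uniform(0.5, 1), rng.uniform(0.5, 1),
                                 rng.random(), rng.random())
            fitness = FitnessScheme(*rng.random(3))
            weights = rng.dirichlet(np.ones(len(viable)))
            state = PopulationState.adults_from_dict(dict(zip(viable, weights)))
            out = relative_reproductive_output(state, rates, fitness)
            assert 0.0 <= out <= 1.0
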