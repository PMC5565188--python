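"""Bootstrap recruitment simulation: chain algebra, oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import seedfate as sf
from seedfate.simulation import chain_product


class TestChainProduct:
    def test_powers_of_one_half(self):
        assert chain_product(1, 0.5, 0.5, 0.5) == pytest.approx((0.25, 0.125))

    def test_zero_is_absorbing(self):
        assert chain_product(0.3, 0.0, 0.5, 0.5) == (0.0, 0.0)
        newly, surviving = chain_product(0.3, 0.5, 0.5, 0.0)
        assert newly > 0 and surviving == 0.0

    def test_field_scale_magnitudes(self):
        newly, surviving = chain_product(0.7, 0.057, 0.523, 0.085)
        assert newly == pytest.approx(0.0208677, abs=1e-7)
        assert surviving == pytest.approx(0.00177375, abs=1e-7)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_inputs_are_rejected(self, bad):
        with pytest.raises(sf.ValidationError):
            chain_product(bad, 0.5, 0.5, 0.5)


class TestRunSimulation:
    def test_single_replicate_groups_are_deterministic(self):
        tables = sf.tables_from_truth(sf.study_truth())
        dispersal = sf.DispersalDistribution({sf.OPEN: 1.0})
        config = sf.SimulationConfig(n_iterations=50, rng_seed=3)
        result = sf.run_seed_fate_simulation(tables, dispersal, sf.STUDY_COVER, config)
        oracle = sf.analytic_expected_outcome(tables, dispersal, sf.STUDY_COVER, config)
        for pathway in (sf.DISPERSED, sf.UNDISPERSED):
            for quantity in ("p_newly_emerged", "p_surviving"):
                s = result.summaries[pathway][quantity]
                assert s["se"] == pytest.approx(0.0, abs=1e-15)
                assert s["mean"] == pytest.approx(oracle[pathway][quantity], abs=1e-12)

    def test_fair_pick_from_zero_one_group_converges_to_half(self):
        ones = {(m, t): [1.0] for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS}
        tables = {
            sf.PREDATION_SURVIVAL: sf.TransitionTable(
                sf.PREDATION_SURVIVAL,
                {(sf.OPEN,): [0.0, 1.0], (sf.EPHEDRA,): [1.0], (sf.PISTACIA,): [1.0]},
            ),
            sf.EMERGENCE: sf.TransitionTable(sf.EMERGENCE, dict(ones)),
            sf.SEEDLING_SURVIVAL: sf.TransitionTable(sf.SEEDLING_SURVIVAL, dict(ones)),
        }
        dispersal = sf.DispersalDistribution({sf.OPEN: 1.0})
        n = 20000
        config = sf.SimulationConfig(n_iterations=n, rng_seed=7)
        result = sf.run_seed_fate_simulation(tables, dispersal, None, config)
        mc_se = 0.5 / np.sqrt(n)
        assert result.summaries[sf.DISPERSED]["p_newly_emerged"]["mean"] == pytest.approx(
            0.5, abs=3 * mc_se
        )

    def test_zero_ephedra_seedling_survival_forces_zero_undispersed_outcome(
        self, study_estimates
    ):
        tables, dispersal, cover = study_estimates
        for key, values in tables[sf.SEEDLING_SURVIVAL].groups.items():
            if key[0] == sf.EPHEDRA:
                assert all(v == 0.0 for v in values)
        result = sf.run_seed_fate_simulation(
            tables, dispersal, cover, sf.SimulationConfig(n_iterations=500, rng_seed=9)
        )
        assert np.all(result.undispersed.p_surviving == 0.0)
        assert result.advantage["surviving"] == np.inf

    def test_missing_group_names_the_offender(self, small_tables, uniform_dispersal):
        broken = dict(small_tables)
        groups = {
            k: v
            for k, v in small_tables[sf.EMERGENCE].groups.items()
            if k != (sf.OPEN, sf.DIGESTED)
        }
        broken[sf.EMERGENCE] = sf.TransitionTable(sf.EMERGENCE, groups)
        with pytest.raises(sf.SimulationError, match="OPEN"):
            sf.run_seed_fate_simulation(
                broken, uniform_dispersal, None, sf.SimulationConfig(rng_seed=0)
            )

    def test_reproducibility_is_bit_identical(self, study_estimates):
        tables, dispersal, cover = study_estimates
        config = sf.SimulationConfig(n_iterations=200, rng_seed=17)
        r1 = sf.run_seed_fate_simulation(tables, dispersal, cover, config)
        r2 = sf.run_seed_fate_simulation(tables, dispersal, cover, config)
        for pathway in (sf.DISPERSED, sf.UNDISPERSED):
            assert np.array_equal(r1.outcome(pathway).p_newly_emerged, r2.outcome(pathway).p_newly_emerged)
            assert np.array_equal(r1.outcome(pathway).p_surviving, r2.outcome(pathway).p_surviving)
        assert r1.summaries == r2.summaries
        assert r1.stage_losses == r2.stage_losses

    def test_draw_and_weighting_modes_are_first_class(self, study_estimates):
        tables, dispersal, cover = study_estimates
        for draw in (sf.SINGLE_REPLICATE, sf.RESAMPLED_MEAN):
            for weighting in (sf.DISPERSAL_ONLY, sf.DISPERSAL_TIMES_COVER):
                config = sf.SimulationConfig(
                    n_iterations=100,
                    rng_seed=1,
                    iteration_draw_mode=draw,
                    weighting_mode=weighting,
                )
                result = sf.run_seed_fate_simulation(tables, dispersal, cover, config)
                assert result.config.iteration_draw_mode == draw
                assert result.config.weighting_mode == weighting

    def test_resampled_mean_shrinks_iteration_spread(self, study_estimates):
        # a resampled mean of n replicates varies less than a single pick
        tables, dispersal, cover = study_estimates
        base = dict(n_iterations=2000, rng_seed=5)
        single = sf.run_seed_fate_simulation(
            tables, dispersal, cover,
            sf.SimulationConfig(iteration_draw_mode=sf.SINGLE_REPLICATE, **base),
        )
        resampled = sf.run_seed_fate_simulation(
            tables, dispersal, cover,
            sf.SimulationConfig(iteration_draw_mode=sf.RESAMPLED_MEAN, **base),
        )
        assert (
            resampled.summaries[sf.DISPERSED]["p_newly_emerged"]["se"]
            < single.summaries[sf.DISPERSED]["p_newly_emerged"]["se"]
        )

    def test_unstudied_microhabitat_mass_can_be_sent_to_zero_recruitment(
        self, study_estimates
    ):
        # deposition over all four microhabitats: OTHER carries 20% of seeds
        # but has no stage tables, so those seeds recruit nothing — outcomes
        # shrink by exactly the factor of mass kept on studied microhabitats
        tables, _, cover = study_estimates
        core = {sf.OPEN: 0.5, sf.EPHEDRA: 0.125, sf.PISTACIA: 0.175}
        with_other = sf.DispersalDistribution({**{m: p for m, p in core.items()}, sf.OTHER: 0.2})
        renorm = sf.DispersalDistribution({m: p / 0.8 for m, p in core.items()})
        config = sf.SimulationConfig(rng_seed=0)
        zeroed = sf.analytic_expected_outcome(
            tables, with_other, cover, config, unstudied_to_zero=True
        )
        renormed = sf.analytic_expected_outcome(tables, renorm, cover, config)
        for quantity in ("p_newly_emerged", "p_surviving"):
            assert zeroed[sf.DISPERSED][quantity] == pytest.approx(
                0.8 * renormed[sf.DISPERSED][quantity]
            )
            # the undispersed pathway never touches deposition
            assert zeroed[sf.UNDISPERSED][quantity] == pytest.approx(
                renormed[sf.UNDISPERSED][quantity]
            )
        result = sf.run_seed_fate_simulation(
            tables, with_other, cover,
            sf.SimulationConfig(n_iterations=200, rng_seed=4), unstudied_to_zero=True,
        )
        assert result.dispersed.p_newly_emerged.mean() < renormed[sf.DISPERSED]["p_newly_emerged"]

    def test_invalid_configs_are_rejected(self):
        with pytest.raises(sf.ConfigurationError):
            sf.SimulationConfig(n_iterations=0)
        with pytest.raises(sf.ConfigurationError):
            sf.SimulationConfig(iteration_draw_mode="GUESS")
        with pytest.raises(sf.ConfigurationError):
            sf.SimulationConfig(undispersed_treatment_mix={sf.RED: 0.5, sf.YELLOW: 0.2})


class TestOracleAndInvariants:
    @staticmethod
    def _random_tables(rng):
        def group():
            return list(rng.uniform(0.0, 1.0, size=rng.integers(1, 5)))

        pred = sf.TransitionTable(
            sf.PREDATION_SURVIVAL, {(m,): group() for m in sf.CORE_MICROHABITATS}
        )
        emer = sf.TransitionTable(
            sf.EMERGENCE,
            {(m, t): group() for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS},
        )
        surv = sf.TransitionTable(
            sf.SEEDLING_SURVIVAL,
            {(m, t): group() for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS},
        )
        probs = rng.dirichlet(np.ones(3))
        dispersal = sf.DispersalDistribution(
            dict(zip(sf.CORE_MICROHABITATS, probs))
        )
        return {sf.PREDATION_SURVIVAL: pred, sf.EMERGENCE: emer, sf.SEEDLING_SURVIVAL: surv}, dispersal

    def test_simulation_mean_matches_analytic_oracle(self):
        rng = np.random.default_rng(101)
        n = 50_000
        for trial in range(3):
            tables, dispersal = self._random_tables(rng)
            config = sf.SimulationConfig(n_iterations=n, rng_seed=1000 + trial)
            result = sf.run_seed_fate_simulation(tables, dispersal, None, config)
            oracle = sf.analytic_expected_outcome(tables, dispersal, None, config)
            for pathway in (sf.DISPERSED, sf.UNDISPERSED):
                for quantity in ("p_newly_emerged", "p_surviving"):
                    values = getattr(
                        result.outcome(pathway),
                        quantity,
                    )
                    mc_se = values.std(ddof=1) / np.sqrt(n)
                    assert abs(values.mean() - oracle[pathway][quantity]) <= max(
                        3 * mc_se, 1e-12
                    )

    def test_iteration_ordering_invariant(self, study_estimates):
        tables, dispersal, cover = study_estimates
        result = sf.run_seed_fate_simulation(
            tables, dispersal, cover, sf.SimulationConfig(n_iterations=1000, rng_seed=13)
        )
        for pathway in (sf.DISPERSED, sf.UNDISPERSED):
            out = result.outcome(pathway)
            assert np.all(out.p_surviving <= out.p_newly_emerged)
            assert np.all(out.p_newly_emerged <= out.survived_predation)
            assert np.all(out.survived_predation <= 1.0)

    def test_fate_fractions_recompose_to_one(self, study_estimates):
        tables, dispersal, cover = study_estimates
        result = sf.run_seed_fate_simulation(
            tables, dispersal, cover, sf.SimulationConfig(n_iterations=500, rng_seed=23)
        )
        losses = sf.stage_loss_decomposition(result)
        for pathway in (sf.DISPERSED, sf.UNDISPERSED):
            fate = losses[pathway]["fate_fractions"]
            assert sum(fate.values()) == pytest.approx(1.0, abs=1e-9)
            # same holds per iteration, not only on average
            out = result.outcome(pathway)
            per_iter = (
                (1.0 - out.survived_predation)
                + (out.survived_predation - out.p_newly_emerged)
                + (out.p_newly_emerged - out.p_surviving)
                + out.p_surviving
            )
            assert np.allclose(per_iter, 1.0, atol=1e-9)

    @given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(min_value=0.01, max_value=0.5))
    def test_raising_a_stage_never_decreases_the_expected_outcome(self, seed, bump):
        rng = np.random.default_rng(seed)
        tables, dispersal = self._random_tables(rng)
        config = sf.SimulationConfig(rng_seed=0)
        base = sf.analytic_expected_outcome(tables, dispersal, None, config)

        raised_groups = {
            k: [min(1.0, v + bump) for v in values]
            for k, values in tables[sf.EMERGENCE].groups.items()
        }
        raised = dict(tables)
        raised[sf.EMERGENCE] = sf.TransitionTable(sf.EMERGENCE, raised_groups)
        higher = sf.analytic_expected_outcome(raised, dispersal, None, config)
        for pathway in (sf.DISPERSED, sf.UNDISPERSED):
            for quantity in ("p_newly_emerged", "p_surviving"):
                assert higher[pathway][quantity] >= base[pathway][quantity] - 1e-12


class TestLossesAndAdvantage:
    def test_no_variability_losses_are_complements_of_stage_survivals(self):
        truth = sf.study_truth()
        s2, s3, s4 = 0.057, 0.523, 0.085
        tables = {
            sf.PREDATION_SURVIVAL: sf.TransitionTable(
                sf.PREDATION_SURVIVAL, {(m,): [s2] for m in sf.CORE_MICROHABITATS}
            ),
            sf.EMERGENCE: sf.TransitionTable(
                sf.EMERGENCE,
                {(m, t): [s3] for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS},
            ),
            sf.SEEDLING_SURVIVAL: sf.TransitionTable(
                sf.SEEDLING_SURVIVAL,
                {(m, t): [s4] for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS},
            ),
        }
        dispersal = sf.DispersalDistribution({sf.OPEN: 1.0})
        result = sf.run_seed_fate_simulation(
            tables, dispersal, None, sf.SimulationConfig(n_iterations=10, rng_seed=0)
        )
        losses = sf.stage_loss_decomposition(result)[sf.DISPERSED]
        assert losses["predation_mortality"] == pytest.approx(1 - s2)
        assert losses["emergence_failure_of_survivors"] == pytest.approx(1 - s3)
        assert losses["seedling_mortality_of_emerged"] == pytest.approx(1 - s4)

    def test_all_survivals_one_gives_zero_losses(self):
        ones_by_m = {(m,): [1.0] for m in sf.CORE_MICROHABITATS}
        ones_by_mt = {(m, t): [1.0] for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS}
        tables = {
            sf.PREDATION_SURVIVAL: sf.TransitionTable(sf.PREDATION_SURVIVAL, ones_by_m),
            sf.EMERGENCE: sf.TransitionTable(sf.EMERGENCE, dict(ones_by_mt)),
            sf.SEEDLING_SURVIVAL: sf.TransitionTable(sf.SEEDLING_SURVIVAL, dict(ones_by_mt)),
        }
        dispersal = sf.DispersalDistribution({sf.OPEN: 0.5, sf.EPHEDRA: 0.5})
        result = sf.run_seed_fate_simulation(
            tables, dispersal, None, sf.SimulationConfig(n_iterations=5, rng_seed=0)
        )
        losses = sf.stage_loss_decomposition(result)
        for pathway in (sf.DISPERSED, sf.UNDISPERSED):
            assert losses[pathway]["predation_mortality"] == 0.0
            assert losses[pathway]["emergence_failure_of_survivors"] == 0.0
            assert losses[pathway]["seedling_mortality_of_emerged"] == 0.0

    def test_total_predation_flags_downstream_fractions_undefined(self):
        zeros_by_m = {(m,): [0.0] for m in sf.CORE_MICROHABITATS}
        some_by_mt = {(m, t): [0.5] for m in sf.CORE_MICROHABITATS for t in sf.TREATMENTS}
        tables = {
            sf.PREDATION_SURVIVAL: sf.TransitionTable(sf.PREDATION_SURVIVAL, zeros_by_m),
            sf.EMERGENCE: sf.TransitionTable(sf.EMERGENCE, dict(some_by_mt)),
            sf.SEEDLING_SURVIVAL: sf.TransitionTable(sf.SEEDLING_SURVIVAL, dict(some_by_mt)),
        }
        dispersal = sf.DispersalDistribution({sf.OPEN: 1.0})
        n = 20
        result = sf.run_seed_fate_simulation(
            tables, dispersal, None, sf.SimulationConfig(n_iterations=n, rng_seed=0)
        )
        losses = sf.stage_loss_decomposition(result)[sf.DISPERSED]
        assert losses["predation_mortality"] == 1.0
        assert np.isnan(losses["emergence_failure_of_survivors"])
        assert losses["n_undefined_emergence_fraction"] == n

    def test_advantage_ratios(self):
        assert sf.simulation._ratio(0.030, 0.0025) == pytest.approx(12.0)
        assert sf.simulation._ratio(0.4, 0.4) == 1.0
        assert sf.simulation._ratio(0.1, 0.0) == np.inf
        assert np.isnan(sf.simulation._ratio(0.0, 0.0))

    def test_result_json_spells_out_infinite_advantage(self, study_estimates):
        tables, dispersal, cover = study_estimates
        result = sf.run_seed_fate_simulation(
            tables, dispersal, cover, sf.SimulationConfig(n_iterations=50, rng_seed=2)
        )
        payload = result.to_json()
        assert payload["advantage"]["surviving"] == "infinite"
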