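import numpy as np
import pandas as pd
import pytest

from likertcomp import ScenarioParams, run_grid, run_scenario, replication_grid
from likertcomp.engine import RESULT_COLUMNS, _scenario_seed


def small_scenario(**overrides):
    base = dict(
        test_type="unpaired", K=5, p=0.05, I=2, N1=50, N2=50,
        s2_a=0.32, s2_b=0.32, D_effect=0.4, n_runs=200, seed=42,
    )
    base.update(overrides)
    return ScenarioParams(**base)


class TestScenarioValidation:
    def test_paired_requires_equal_group_sizes(self):
        with pytest.raises(ValueError):
            small_scenario(test_type="paired", N1=50, N2=100)

    def test_variance_ordering_enforced(self):
        with pytest.raises(ValueError):
            small_scenario(s2_a=1.28, s2_b=0.08)

    def test_welch_decided_by_population_variances(self):
        assert not small_scenario().welch
        assert small_scenario(s2_a=0.08, s2_b=1.28).welch

    def test_unknown_dgp_rejected(self):
        with pytest.raises(ValueError):
            small_scenario(dgp="cauchy")


class TestRunScenario:
    def test_powers_are_rejection_proportions(self):
        res = run_scenario(small_scenario())
        for value in (res.power_ilr, res.power_orig):
            assert 0.0 <= value <= 1.0
            assert (value * res.n_runs) == pytest.approx(round(value * res.n_runs))
        assert res.delta_power == res.power_ilr - res.power_orig

    def test_deterministic_given_seed(self):
        a = run_scenario(small_scenario())
        b = run_scenario(small_scenario())
        assert a.power_ilr == b.power_ilr
        assert a.power_orig == b.power_orig

    def test_size_close_to_alpha_under_null(self):
        res = run_scenario(small_scenario(D_effect=0.0, n_runs=4000))
        band = 3 * np.sqrt(0.05 * 0.95 / 4000)
        assert res.power_ilr == pytest.approx(0.05, abs=band)
        assert res.power_orig == pytest.approx(0.05, abs=band)

    def test_power_increases_with_effect_size(self):
        powers = [
            run_scenario(small_scenario(D_effect=d, n_runs=500, seed=7)).power_orig
            for d in (0.2, 0.6, 1.0)
        ]
        assert powers[0] < powers[1] < powers[2]

    def test_paired_variant_runs(self):
        res = run_scenario(small_scenario(test_type="paired", D_effect=0.8))
        assert res.power_ilr > 0.5

    def test_ilr_loses_power_under_heavy_tails(self):
        # headline direction at a high-variance setting
        res = run_scenario(small_scenario(
            N1=100, N2=100, s2_a=1.28, s2_b=1.28, n_runs=1000))
        assert res.delta_power < 0

    def test_normal_dgp_comparison_mode(self):
        # under a normal DGP the compositional path does not lose power
        # at matched settings (within 2 Monte-Carlo standard errors)
        res = run_scenario(small_scenario(
            dgp="normal", N1=100, N2=100, s2_a=1.28, s2_b=1.28, n_runs=2000))
        mc_se = np.sqrt(2 * 0.25 / 2000)
        assert res.delta_power >= -2 * mc_se


class TestRunGrid:
    def test_replication_grid_has_3600_scenarios(self):
        for test_type in ("unpaired", "paired"):
            assert len(replication_grid(test_type)) == 3600

    def test_empty_grid_gives_empty_table(self):
        table = run_grid([], master_seed=1)
        assert table.empty
        assert list(table.columns) == RESULT_COLUMNS

    def test_grid_is_reproducible(self):
        scenarios = [small_scenario(seed=None, n_runs=100) for _ in range(3)]
        a = run_grid(scenarios, master_seed=5)
        b = run_grid(scenarios, master_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_master_seeds_differ(self):
        scenarios = [small_scenario(seed=None, n_runs=400)]
        a = run_grid(scenarios, master_seed=1)
        b = run_grid(scenarios, master_seed=2)
        assert (a["power_ilr"] != b["power_ilr"]).any() or (
            a["power_orig"] != b["power_orig"]
        ).any()

    def test_substreams_are_independent_of_position_content(self):
        seeds = {_scenario_seed(3, i) for i in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)

    def test_s2_total_column(self):
        table = run_grid([small_scenario(s2_a=0.08, s2_b=1.28, n_runs=50)])
        assert table.loc[0, "s2_total"] == pytest.approx(1.36)

    def test_permissive_mode_skips_bad_entries(self):
        good = small_scenario(n_runs=50)
        bad = object.__new__(ScenarioParams)  # bypasses validation
        object.__setattr__(bad, "__dict__", {**good.__dict__, "N1": -1})
        with pytest.raises(Exception):
            run_grid([good, bad], master_seed=0)
        table = run_grid([good, bad], master_seed=0, permissive=True)
        assert len(table) == 1
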