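import numpy as np
import pandas as pd
import pytest

import graywhale_sdp as g
from graywhale_sdp.disturbance import ExposureSeries
from graywhale_sdp.simulate import disturbed_proportion


def zero_fitness_leave_policy(small_policy):
    """A policy whose continuation surface is zero everywhere: leaving
    (worth survival x terminal fitness > 0) dominates every other action."""
    from dataclasses import replace as _  # noqa: F401 (documentation only)

    pol = g.PolicyTable(
        lengths=small_policy.lengths,
        Vbar=np.zeros_like(small_policy.Vbar),
        fat_grids=small_policy.fat_grids,
        fetal_grid=small_policy.fetal_grid,
        area=small_policy.area,
        season=small_policy.season,
        prey=small_policy.prey,
        bio=small_policy.bio,
        fitness=small_policy.fitness,
        rule="argmax",
    )
    return pol


class TestSimulatePopulation:
    def test_none_vs_allzero_exposure_bit_identical(self, small_policy, area,
                                                    season):
        cfg = g.SimulationConfig(n_replicates=2, population_size=15)
        a = g.simulate_population(small_policy, cfg, exposure=None, seed=11)
        b = g.simulate_population(
            small_policy, cfg, exposure=ExposureSeries.zeros(area, season),
            seed=11)
        np.testing.assert_array_equal(a.area_counts, b.area_counts)
        np.testing.assert_array_equal(a.cell_counts, b.cell_counts)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_degenerate_policy_everyone_leaves(self, small_policy):
        pol = zero_fitness_leave_policy(small_policy)
        cfg = g.SimulationConfig(n_replicates=2, population_size=20)
        res = g.simulate_population(pol, cfg, seed=4)
        # after the last arrival, everyone has left on their arrival bin
        assert res.area_counts[:, -1, 2].min() == 20
        out = res.outcomes
        left = out[~out.died]
        assert (left.departure_bin == left.arrival_bin).all()

    def test_determinism_and_replicate_stream_independence(self, small_policy):
        cfg2 = g.SimulationConfig(n_replicates=2, population_size=10)
        cfg3 = g.SimulationConfig(n_replicates=3, population_size=10)
        a = g.simulate_population(small_policy, cfg2, seed=9)
        b = g.simulate_population(small_policy, cfg3, seed=9)
        np.testing.assert_array_equal(a.cell_counts, b.cell_counts[:2])
        pd.testing.assert_frame_equal(
            a.outcomes, b.outcomes[b.outcomes.replicate < 2])

    def test_occupancy_partition(self, small_policy):
        cfg = g.SimulationConfig(n_replicates=3, population_size=25)
        res = g.simulate_population(small_policy, cfg, seed=2)
        totals = res.area_counts.sum(axis=2)
        assert np.all(totals == 25)
        in_cells = res.cell_counts.sum(axis=2)
        in_area = res.area_counts[:, :, 0] + res.area_counts[:, :, 1]
        np.testing.assert_array_equal(in_cells, in_area)

    def test_arrival_timing(self, small_policy, season):
        cfg = g.SimulationConfig(n_replicates=1, population_size=40)
        res = g.simulate_population(small_policy, cfg, seed=5)
        arr = res.outcomes.arrival_bin.to_numpy() // season.bins_per_day
        assert arr.mean() == pytest.approx(
            season.day_of_date(cfg.arrival_mean_date), abs=4)


class TestEnergyLedger:
    def test_single_female_full_season_conservation(self, area, season,
                                                    truth):
        """Per-bin budget identity on a deterministic-prey season trace."""
        det_truth = g.ScenarioTruth(prey={k: (m, 0.0)
                                          for k, (m, _) in truth.prey.items()})
        prey = g.prey_field_from_truth(det_truth, n_categories=3)
        bio = g.BioenergeticParams(annual_mortality=0.0)
        solver = g.PolicySolver(n_fat=16, n_fetal=8, n_lengths=1,
                                rule="argmax")
        solver.fit(area, season, prey, bio=bio, fitness="medium")
        cfg = g.SimulationConfig(n_replicates=1, population_size=1)
        res = g.simulate_population(solver.policy_, cfg, seed=21, trace=True)
        tr = res.trace
        assert len(tr) > 100
        growth_bin = bio.fetal_growth_m_per_day / season.bins_per_day
        for row in tr.itertuples():
            dfat = row.fat_after_kg - row.fat_before_kg
            if row.fat_after_kg >= bio.fat_max(12.7) - 1e-9:
                continue  # storage capacity clamp
            realized = row.fetal_after_m - row.fetal_before_m
            fet_energy = realized / growth_bin * row.fetal_cost_MJ
            if dfat >= 0:
                flow = dfat * bio.catabolic_yield_MJ_per_kg / bio.deposition_efficiency
            else:
                flow = dfat * bio.catabolic_yield_MJ_per_kg
            resid = (row.intake_MJ - row.metabolic_MJ - row.travel_MJ
                     - fet_energy - flow)
            assert abs(resid) < 1e-9


@pytest.fixture(scope="module")
def run(small_policy):
    cfg = g.SimulationConfig(n_replicates=4, population_size=30)
    return g.simulate_population(small_policy, cfg, seed=7)


class TestSummaries:

    def test_weekly_pooling_means(self, run, season):
        occ = g.occupancy_series(run)
        manual = (run.area_counts[:, :, 0] / 30.0).reshape(
            4, season.n_weeks, season.bins_per_week).mean(axis=2)
        np.testing.assert_allclose(occ.weekly_area[:, :, 0], manual)
        frame = occ.weekly_area_frame()
        assert set(frame["area"]) == {"nearshore", "offshore", "outside"}

    def test_constant_week_has_zero_within_replicate_variance(self, run):
        occ = g.occupancy_series(run)
        flat = occ.prop_area.copy()
        flat[:] = 0.4
        wk = flat[:, :28, 0].reshape(run.n_replicates, 1, 28).mean(axis=2)
        assert np.allclose(wk, 0.4)

    def test_disturbed_proportion_requires_exposure(self, run):
        with pytest.raises(ValueError):
            disturbed_proportion(run)

    def test_disturbed_proportion_bounded_by_in_area(self, small_policy, area,
                                                     season):
        series = ExposureSeries(np.full((11, season.n_bins), 0.3), area,
                                season)
        cfg = g.SimulationConfig(n_replicates=2, population_size=20)
        res = g.simulate_population(small_policy, cfg, exposure=series, seed=1)
        per_bin, weekly = disturbed_proportion(res)
        in_area = (res.area_counts[:, :, 0] + res.area_counts[:, :, 1]) / 20.0
        assert np.all(per_bin <= in_area + 1e-12)
        assert per_bin.max() > 0  # the exposure actually bites

    def test_reproduction_summary_mean_and_sd(self, run):
        rep = g.reproduction_summary(run)
        manual = run.outcomes.groupby("replicate")["success"].mean()
        assert rep.mean == pytest.approx(manual.mean())
        assert rep.sd == pytest.approx(manual.std(ddof=1))
        assert rep.n == 4

    def test_compensation_for_later_arrival(self, small_policy):
        """Shifting mean arrival 3 days later moves mean reproduction by
        less than the across-replicate spread (capital breeders compensate
        early-season foraging loss)."""
        import datetime as dt

        base = g.SimulationConfig(n_replicates=6, population_size=40)
        late = g.SimulationConfig(
            n_replicates=6, population_size=40,
            arrival_mean_date=dt.date(2015, 6, 18))
        r1 = g.reproduction_summary(
            g.simulate_population(small_policy, base, seed=31))
        r2 = g.reproduction_summary(
            g.simulate_population(small_policy, late, seed=31))
        assert abs(r1.mean - r2.mean) < max(r1.sd, r2.sd)
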