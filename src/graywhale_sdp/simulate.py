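"""Forward Monte-Carlo simulation of pregnant females over a foraging season.

Each replicate population draws per-female static parameters (length,
starting fat and fetal length, arrival date) and then steps through the
season in 6-h bins.  In every bin an in-area female is first tested for
acoustic disturbance (relocation to the nearest undisturbed cell, losing
the bin's foraging); otherwise she draws one of the four behaviors from the
policy's interpolated action probabilities for the governing day, her
energy state is updated, and she faces the background mortality hazard.
Leaving the feeding ground is absorbing; at season end every remaining
female departs.  Reproductive success is a Bernoulli draw with probability
(overwinter survival x terminal reproductive fitness) at departure.

Randomness is organized so that runs with and without disturbance are
coupled: one master seed spawns per-replicate streams, and within a
replicate the initial-state, behavior, disturbance and outcome draws come
from separate substreams, all drawn on a fixed per-bin schedule regardless
of state.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bioenergetics import LengthDistribution, allocate_core, survival_to_next_season
from .disturbance import DisturbanceRule, ExposureSeries, nearest_undisturbed
from .policy import A_FEED, A_LEAVE, A_WITHIN, N_FIXED, PolicyTable

# location codes (>= 0 is a 0-based cell index)
LOC_PENDING = -1   # not yet arrived
LOC_DEPARTED = -2
LOC_DEAD = -3

AREA_NEARSHORE, AREA_OFFSHORE, AREA_OUTSIDE = 0, 1, 2


@dataclass(frozen=True)
class TruncNorm:
    mean: float
    sd: float
    lo: float
    hi: float

    def rvs(self, rng, size):
        a, b = (self.lo - self.mean) / self.sd, (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=size, random_state=rng)


@dataclass
class SimulationConfig:
    """Monte-Carlo settings and individual-parameter distributions."""

    n_replicates: int = 100
    population_size: int = 50
    population_dist: str = "fixed"           # fixed | poisson
    arrival_mean_date: dt.date = dt.date(2015, 6, 15)
    arrival_sd_days: float = 5.0
    L_min: float = 11.0
    dive_fraction: TruncNorm = field(
        default_factory=lambda: TruncNorm(0.75, 0.08, 0.4, 1.0))
    travel_speed_kmh: TruncNorm = field(
        default_factory=lambda: TruncNorm(3.6, 0.5, 2.0, 6.0))
    travel_time_h: TruncNorm = field(
        default_factory=lambda: TruncNorm(5.0, 0.8, 2.0, 6.0))
    travel_linearity: TruncNorm = field(
        default_factory=lambda: TruncNorm(0.85, 0.08, 0.5, 1.0))
    dive_cycle_min: TruncNorm = field(
        default_factory=lambda: TruncNorm(5.0, 1.0, 2.0, 10.0))
    initial_location: str = "uniform_split"  # uniform_split | prey_weighted
    response: DisturbanceRule = field(default_factory=DisturbanceRule)


@dataclass
class SimulationResult:
    """Raw output of :func:`simulate_population`."""

    policy: PolicyTable
    config: SimulationConfig
    exposure: ExposureSeries | None
    seed: int
    pop_sizes: np.ndarray                    # (n_rep,)
    area_counts: np.ndarray                  # (n_rep, n_bins, 3)
    cell_counts: np.ndarray                  # (n_rep, n_bins, n_cells)
    disturbed_counts: np.ndarray             # (n_rep, n_bins)
    outcomes: pd.DataFrame
    trace: pd.DataFrame | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.pop_sizes)


def _draw_initial_cells(rng, n, policy: PolicyTable, how: str) -> np.ndarray:
    area = policy.area
    if how == "uniform_split":
        near = [area.index(c) for c in area.nearshore_ids]
        off = [area.index(c) for c in area.offshore_ids]
        pick_off = rng.uniform(size=n) < 0.5
        out = np.empty(n, np.intp)
        out[~pick_off] = rng.choice(near, size=int((~pick_off).sum()))
        out[pick_off] = rng.choice(off, size=int(pick_off.sum()))
        return out
    if how == "prey_weighted":
        period = policy.season.period_of_day(0)
        means = np.array([
            np.dot(*policy.prey.categories(c, period)[::-1])
            for c in area.ids
        ])
        w = means / means.sum()
        return rng.choice(len(area.ids), size=n, p=w)
    raise ValueError(f"unknown initial_location {how!r}")


def _categories_from_uniform(u, loc, cum_by_cell):
    """Category index per female from a shared uniform and cell cumprobs."""
    k = np.zeros(len(u), np.intp)
    in_area = loc >= 0
    if in_area.any():
        rows = cum_by_cell[loc[in_area]]           # (m, K)
        k[in_area] = (u[in_area][:, None] > rows).sum(axis=1)
    return k


def simulate_population(
    policy: PolicyTable,
    config: SimulationConfig | None = None,
    exposure: ExposureSeries | None = None,
    seed: int = 0,
    trace: bool = False,
) -> SimulationResult:
    """Run the seeded replicate simulation under a fitted policy."""
    config = config or SimulationConfig()
    season = policy.season
    area = policy.area
    bio = policy.bio
    if exposure is not None and (exposure.season.n_bins != season.n_bins
                                 or exposure.area.ids != area.ids):
        raise ValueError("exposure grid does not match the policy's season/area")
    n_cells = area.n_cells
    n_bins, n_days, bins = season.n_bins, season.n_days, season.bins_per_day
    nearshore = np.array([area.cell(c).zone == "nearshore" for c in area.ids])

    length_dist = LengthDistribution(L_min=config.L_min)
    arrival_mean_day = season.day_of_date(config.arrival_mean_date)

    # per-period category tables, in cell order
    cat_vals = {p: policy.category_values(p) for p in set(season.week_periods)}
    cat_cum = {p: np.cumsum(policy.category_probs(p), axis=1)
               for p in set(season.week_periods)}

    met_bin_of_L = lambda L: bio.metabolic_MJ_per_day(L) / bins
    fet_cost_bin = bio.fetal_cost_MJ_per_day() / bins
    fet_growth_bin = bio.fetal_growth_m_per_day / bins
    s_bin = bio.survival_per_hours(season.bin_hours)
    resp = config.response.response_probability

    n_rep = config.n_replicates
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_rep)

    pop_sizes = np.empty(n_rep, int)
    area_counts = np.zeros((n_rep, n_bins, 3), np.int32)
    cell_counts = np.zeros((n_rep, n_bins, n_cells), np.int32)
    disturbed_counts = np.zeros((n_rep, n_bins), np.int32)
    outcome_rows = []
    trace_rows = [] if trace else None

    for rep in range(n_rep):
        init_rng, beh_rng, dist_rng, out_rng = (
            np.random.default_rng(s) for s in rep_seeds[rep].spawn(4))
        if config.population_dist == "poisson":
            n = max(1, int(init_rng.poisson(config.population_size)))
        else:
            n = int(config.population_size)
        pop_sizes[rep] = n

        L = length_dist.rvs(n, init_rng)
        frac = TruncNorm(bio.initial_fat_frac_mean, bio.initial_fat_frac_sd,
                         bio.initial_fat_frac_lo, bio.initial_fat_frac_hi
                         ).rvs(init_rng, n)
        fat = frac * bio.total_mass(L)
        fetal = TruncNorm(bio.initial_fetal_m_mean, bio.initial_fetal_m_sd,
                          bio.initial_fetal_m_lo, bio.initial_fetal_m_hi
                          ).rvs(init_rng, n)
        arrival_day = np.clip(
            np.rint(init_rng.normal(arrival_mean_day, config.arrival_sd_days,
                                    size=n)), 0, n_days - 1
        ).astype(int)
        arrival_bin = arrival_day * bins
        init_cell = _draw_initial_cells(init_rng, n, policy, config.initial_location)
        li = policy.length_index(L)
        met_bin = met_bin_of_L(L)
        cap_bin = bio.max_intake_MJ_per_day(L) / bins

        # fixed per-bin draw schedule keeps paired scenarios coupled
        u_cat = beh_rng.uniform(size=(n_days, n))
        u_act = beh_rng.uniform(size=(n_bins, n))
        dive = config.dive_fraction.rvs(beh_rng, (n_bins, n))
        lin = config.travel_linearity.rvs(beh_rng, (n_bins, n))
        config.travel_speed_kmh.rvs(beh_rng, (n_bins, n))   # recorded draws,
        config.dive_cycle_min.rvs(beh_rng, (n_bins, n))     # not energy-active
        u_mort = beh_rng.uniform(size=(n_bins, n))
        u_succ = out_rng.uniform(size=n)
        u_dist = (dist_rng.uniform(size=(n_bins, n))
                  if exposure is not None else None)

        loc = np.full(n, LOC_PENDING, np.intp)
        k = np.zeros(n, np.intp)
        dep_fat = np.full(n, np.nan)
        dep_fetal = np.full(n, np.nan)
        dep_bin = np.full(n, -1, int)
        died = np.zeros(n, bool)
        # one behavior is drawn per female per day (each day's probabilities
        # govern its four 6-h bins); arrivals and disturbance responses
        # trigger a fresh draw mid-day
        A_NONE, A_TRAVEL_REST = -1, -2
        day_action = np.full(n, A_NONE, int)

        for b in range(n_bins):
            day = b // bins
            period = season.period_of_day(day)
            evals = cat_vals[period]
            cum = cat_cum[period]
            if b % bins == 0:
                k = _categories_from_uniform(u_cat[day], loc, cum)
                day_action[:] = A_NONE
            just_arrived = (loc == LOC_PENDING) & (arrival_bin == b)
            if just_arrived.any():
                loc[just_arrived] = init_cell[just_arrived]
                k = np.where(just_arrived,
                             _categories_from_uniform(u_cat[day], loc, cum), k)
                day_action[just_arrived] = A_NONE

            in_area = loc >= 0
            disturbed = np.zeros(n, bool)
            intake = np.zeros(n)
            travel = np.zeros(n)
            if exposure is not None and in_area.any():
                p_here = np.zeros(n)
                p_here[in_area] = exposure.p[loc[in_area], b]
                disturbed = in_area & (u_dist[b] < p_here * resp)
                if disturbed.any():
                    dest_of = {
                        c: area.index(nearest_undisturbed(
                            area, area.ids[c], exposure.p[:, b]))
                        for c in np.unique(loc[disturbed])
                    }
                    new_loc = loc.copy()
                    for c, d in dest_of.items():
                        new_loc[disturbed & (loc == c)] = d
                    loc = new_loc
                    travel[disturbed] = (bio.travel_cost_inter_MJ()
                                         / lin[b][disturbed])
                    k = np.where(disturbed,
                                 _categories_from_uniform(u_cat[day], loc, cum),
                                 k)
                    day_action[disturbed] = A_NONE

            need = in_area & ~disturbed & (day_action == A_NONE)
            if need.any():
                idx = np.nonzero(need)[0]
                pi = policy.action_probabilities(
                    day, li[idx], loc[idx], k[idx], fat[idx], fetal[idx])
                action = (u_act[b][idx][:, None] > np.cumsum(pi, axis=1)
                          ).sum(axis=1)
                day_action[idx] = np.minimum(action, pi.shape[1] - 1)
                leaving = idx[day_action[idx] == A_LEAVE]
                if len(leaving):
                    dep_fat[leaving] = fat[leaving]
                    dep_fetal[leaving] = fetal[leaving]
                    dep_bin[leaving] = b
                    loc[leaving] = LOC_DEPARTED

            acting = (loc >= 0) & ~disturbed
            if acting.any():
                idx = np.nonzero(acting)[0]
                feed = idx[day_action[idx] == A_FEED]
                intake[feed] = np.minimum(
                    evals[loc[feed], k[feed]] * dive[b][feed], cap_bin[feed])
                within = idx[day_action[idx] == A_WITHIN]
                intake[within] = np.minimum(
                    evals[loc[within], k[within]] * dive[b][within]
                    * bio.within_cell_foraging_fraction, cap_bin[within])
                travel[within] = (bio.travel_cost_within_MJ() / bins
                                  / lin[b][within])
                moving = idx[day_action[idx] >= N_FIXED]
                if len(moving):
                    j = day_action[moving] - N_FIXED
                    src = loc[moving]
                    dest = np.where(j < src, j, j + 1)
                    loc[moving] = dest
                    travel[moving] = bio.travel_cost_inter_MJ() / lin[b][moving]
                    k[moving] = _categories_from_uniform(
                        u_cat[day], loc, cum)[moving]
                    day_action[moving] = A_TRAVEL_REST

            stepping = (loc >= 0) | disturbed
            if stepping.any():
                s = np.nonzero(stepping)[0]
                f2, g2, alive = allocate_core(
                    fat[s], fetal[s], intake[s], met_bin[s], fet_cost_bin,
                    fet_growth_bin, travel[s], bio, L[s])
                if trace:
                    for jj, i in enumerate(s):
                        trace_rows.append((
                            rep, int(i), b, float(intake[i]), float(met_bin[i]),
                            fet_cost_bin, float(travel[i]), float(fat[i]),
                            float(f2[jj]), float(fetal[i]), float(g2[jj]),
                            bool(alive[jj])))
                fat[s], fetal[s] = f2, g2
                starved = s[~alive]
                loc[starved] = LOC_DEAD
                died[starved] = True
                # background hazard
                still = s[alive]
                chance = still[u_mort[b][still] < 1.0 - s_bin]
                loc[chance] = LOC_DEAD
                died[chance] = True

            in_area = loc >= 0
            near_ct = int((in_area & nearshore[np.clip(loc, 0, None)]).sum())
            off_ct = int(in_area.sum()) - near_ct
            area_counts[rep, b] = (near_ct, off_ct, n - near_ct - off_ct)
            if in_area.any():
                cell_counts[rep, b] = np.bincount(loc[in_area],
                                                  minlength=n_cells)
            disturbed_counts[rep, b] = int(disturbed.sum())

        # season end: everyone still in the area departs
        remaining = loc >= 0
        dep_fat[remaining] = fat[remaining]
        dep_fetal[remaining] = fetal[remaining]
        dep_bin[remaining] = n_bins - 1

        ok = ~died
        p_succ = np.zeros(n)
        if ok.any():
            p_succ[ok] = (
                survival_to_next_season(L[ok], dep_fat[ok], policy.fitness, bio)
                * policy.fitness(dep_fat[ok], dep_fetal[ok], L[ok], bio)
            )
        success = ok & (u_succ < p_succ)
        for i in range(n):
            outcome_rows.append((
                rep, i, float(L[i]), int(arrival_bin[i]), int(dep_bin[i]),
                float(dep_fat[i]) if np.isfinite(dep_fat[i]) else np.nan,
                float(dep_fetal[i]) if np.isfinite(dep_fetal[i]) else np.nan,
                bool(died[i]), float(p_succ[i]), bool(success[i])))

    outcomes = pd.DataFrame(
        outcome_rows,
        columns=["replicate", "female", "length_m", "arrival_bin",
                 "departure_bin", "departure_fat_kg", "fetal_len_m", "died",
                 "p_success", "success"],
    )
    trace_df = None
    if trace:
        trace_df = pd.DataFrame(
            trace_rows,
            columns=["replicate", "female", "bin", "intake_MJ",
                     "metabolic_MJ", "fetal_cost_MJ", "travel_MJ",
                     "fat_before_kg", "fat_after_kg", "fetal_before_m",
                     "fetal_after_m", "alive"],
        )
    return SimulationResult(
        policy=policy, config=config, exposure=exposure, seed=seed,
        pop_sizes=pop_sizes, area_counts=area_counts, cell_counts=cell_counts,
        disturbed_counts=disturbed_counts, outcomes=outcomes, trace=trace_df,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class OccupancySummary:
    """Per-bin proportions and weekly pooled occupancy."""

    prop_area: np.ndarray          # (n_rep, n_bins, 3): nearshore/offshore/outside
    prop_cells: np.ndarray         # (n_rep, n_bins, n_cells)
    weekly_area: np.ndarray        # (n_rep, n_weeks, 3)
    weekly_cells: np.ndarray       # (n_rep, n_weeks, n_cells)
    weekly_nearshore_share: np.ndarray  # (n_rep, n_weeks), NaN when no whale in-area
    season: object
    area: object

    def weekly_area_frame(self) -> pd.DataFrame:
        n_rep, n_weeks, _ = self.weekly_area.shape
        labels = ("nearshore", "offshore", "outside")
        rows = []
        for a, lab in enumerate(labels):
            m = self.weekly_area[:, :, a].mean(axis=0)
            s = self.weekly_area[:, :, a].std(axis=0, ddof=1) if n_rep > 1 \
                else np.zeros(n_weeks)
            for w in range(n_weeks):
                rows.append((w, lab, m[w], s[w]))
        return pd.DataFrame(rows, columns=["week", "area", "mean", "sd"])

    def weekly_cell_frame(self) -> pd.DataFrame:
        n_rep, n_weeks, n_cells = self.weekly_cells.shape
        rows = []
        for c in range(n_cells):
            m = self.weekly_cells[:, :, c].mean(axis=0)
            s = self.weekly_cells[:, :, c].std(axis=0, ddof=1) if n_rep > 1 \
                else np.zeros(n_weeks)
            for w in range(n_weeks):
                rows.append((w, self.area.ids[c], m[w], s[w]))
        return pd.DataFrame(rows, columns=["week", "cell", "mean", "sd"])


def occupancy_series(result: SimulationResult) -> OccupancySummary:
    """Per-bin occupancy proportions and weekly pooled means.

    Proportions are of the whole replicate population (nearshore + offshore
    + outside = 1; females dead mid-season count as outside from their death
    bin).  The weekly nearshore share (nearshore / in-area) is also
    reported, since it isolates habitat choice from arrival timing.
    """
    season = result.policy.season
    n_rep, n_bins, _ = result.area_counts.shape
    pop = result.pop_sizes[:, None, None].astype(float)
    prop_area = result.area_counts / pop
    prop_cells = result.cell_counts / pop
    bw = season.bins_per_week
    n_weeks = season.n_weeks
    weekly_area = prop_area.reshape(n_rep, n_weeks, bw, 3).mean(axis=2)
    weekly_cells = prop_cells.reshape(n_rep, n_weeks, bw, -1).mean(axis=2)
    in_area = result.area_counts[:, :, 0] + result.area_counts[:, :, 1]
    with np.errstate(invalid="ignore"):
        share = np.where(in_area > 0,
                         result.area_counts[:, :, 0] / np.maximum(in_area, 1),
                         np.nan)
    share_w = share.reshape(n_rep, n_weeks, bw)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # weeks with no whale in-area yield all-NaN slices by design
        _warnings.simplefilter("ignore", RuntimeWarning)
        weekly_share = np.nanmean(share_w, axis=2)
    return OccupancySummary(prop_area, prop_cells, weekly_area, weekly_cells,
                            weekly_share, season, result.policy.area)


def disturbed_proportion(result: SimulationResult):
    """Per-bin and weekly pooled proportion of the population disturbed."""
    if result.exposure is None:
        raise ValueError("simulation was run without disturbance")
    season = result.policy.season
    pop = result.pop_sizes[:, None].astype(float)
    per_bin = result.disturbed_counts / pop
    weekly = per_bin.reshape(result.n_replicates, season.n_weeks,
                             season.bins_per_week).mean(axis=2)
    return per_bin, weekly


@dataclass
class ReproductionSummary:
    per_replicate: np.ndarray
    mean: float
    sd: float
    n: int


def reproduction_summary(result: SimulationResult) -> ReproductionSummary:
    """Per-replicate proportion of females that successfully reproduced."""
    grp = result.outcomes.groupby("replicate")["success"].mean()
    per_rep = grp.to_numpy(float)
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    return ReproductionSummary(per_rep, float(per_rep.mean()), sd, len(per_rep))
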