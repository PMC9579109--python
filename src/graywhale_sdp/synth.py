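"""Seeded generators for every input the pipeline consumes.

Nothing from the 2015 field campaigns is redistributable, so each data
stream the analysis expects is emulated with the statistical structure the
corresponding fitting stage assumes: lognormal prey-energy samples per cell
and season period (offshore means at least five times nearshore, the
outermost offshore cell richest); a moving seismic source producing
block-level maximum-SPL records that exceed the 163-dB behavioral
threshold near the track; daily nearshore proportions of pregnant females
with zero inflation and environmental covariate effects; scan-survey block
densities with hurdle structure and partial cell coverage; a pregnant
fraction among identified whales; and a photo-identification roster with
calving histories respecting the two-year minimum inter-birth interval.
Every generator is a deterministic function of a truth object and a seed,
and is the measurable inverse of its fitting stage.

The acoustic source model (point source, fixed source level, log-distance
spreading, Gaussian dB noise) is a deliberately crude stand-in that only
aims at plausible exceedance footprints, not acoustic realism.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .fieldstats import photoid_design, scan_design
from .habitat import PERIODS, PreyField, SeasonGrid, StudyArea


def _default_prey_truth() -> dict:
    """(cell, period) -> (lognormal mean MJ per bout, sigma_log).

    Offshore means are at least five times nearshore.  Cells 8-10 peak in
    mid season; the outermost cell 11 is the overall richest, with a
    late-season surge (benthic amphipod biomass accumulating over the
    summer).  Cell 2 shares the nearshore mean with lower variability.
    """
    truth = {}
    # nearshore beds deplete over the season and are largely senescent by fall
    nearshore_mean = {"early": 110.0, "mid": 100.0, "late": 50.0}
    offshore_mean = {
        8: {"early": 550.0, "mid": 620.0, "late": 640.0},
        9: {"early": 560.0, "mid": 630.0, "late": 650.0},
        10: {"early": 580.0, "mid": 660.0, "late": 650.0},
        11: {"early": 500.0, "mid": 640.0, "late": 850.0},
    }
    for cell in range(1, 8):
        sigma = 0.2 if cell == 2 else 0.4
        for p in PERIODS:
            truth[(cell, p)] = (nearshore_mean[p], sigma)
    # offshore amphipod beds are rich and comparatively stable day to day
    for cell, means in offshore_mean.items():
        for p in PERIODS:
            truth[(cell, p)] = (means[p], 0.05)
    return truth


def _default_survey_plan() -> list[dict]:
    """Seismic-source track: nearshore traverse early, then alternating
    stints over offshore cells 8 and 9 (while one is ensonified the other
    stays a quiet refuge, as in the 2015 field season)."""
    return [
        {"day0": 30, "day1": 50, "x0": 5.0, "y0": 9.0, "x1": 75.0, "y1": 9.0},
        {"day0": 55, "day1": 70, "x0": 25.0, "y0": 34.0, "x1": 25.0, "y1": 34.0},
        {"day0": 70, "day1": 85, "x0": 45.0, "y0": 34.0, "x1": 45.0, "y1": 34.0},
        {"day0": 85, "day1": 100, "x0": 25.0, "y0": 34.0, "x1": 25.0, "y1": 34.0},
        {"day0": 100, "day1": 110, "x0": 45.0, "y0": 34.0, "x1": 45.0, "y1": 34.0},
    ]


def offshore_survey_plan() -> list[dict]:
    """Track confined to offshore cells 8 and 9 (refuge cells 10/11 untouched)."""
    return [
        {"day0": 40, "day1": 75, "x0": 25.0, "y0": 34.0, "x1": 45.0, "y1": 34.0},
        {"day0": 75, "day1": 110, "x0": 45.0, "y0": 34.0, "x1": 25.0, "y1": 34.0},
    ]


@dataclass
class ScenarioTruth:
    """Ground truth driving every synthetic generator."""

    prey: dict = field(default_factory=_default_prey_truth)
    survey_plan: list = field(default_factory=_default_survey_plan)
    source_level_db: float = 230.0
    # 17 log10(r) puts the 163-dB radius near 9 km: one offshore cell can be
    # ensonified while its neighbor 20 km away stays a refuge
    spreading_loss_coeff: float = 17.0
    noise_sd_db: float = 2.0
    nearshore_blocks_per_cell: int = 12
    offshore_blocks_per_cell: int = 6
    # regression truths on the fitting design scale (intercept, visibility,
    # beaufort, week_z, week_z^2) and (intercept, coverage, week_z..^3)
    zib_alpha: tuple = (0.8, 0.8, -0.5, -0.4, -0.3)
    zib_mu: tuple = (-1.0, 0.5, -0.3, -0.4, 0.15)
    zib_phi: float = 15.0
    hg_alpha: tuple = (0.3, 1.2, -0.5, -0.3, 0.1)
    hg_mu: tuple = (-2.0, -0.8, -0.4, 0.1, 0.05)
    hg_omega: float = 2.0
    ppreg_coefs: tuple = (-1.1, 0.3, -0.2, -0.3, 0.25)
    n_group: int = 18
    roster_size: int = 27
    roster_years: tuple = (2004, 2016)
    annual_calving_prob: float = 0.35
    master_seed: int = 20150515

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prey"] = {f"{c}|{p}": v for (c, p), v in self.prey.items()}
        return d


def prey_field_from_truth(truth: ScenarioTruth, n_categories: int = 10,
                          coverage_quantile: float = 0.995) -> PreyField:
    """PreyField directly from the truth's lognormal means/sigmas."""
    rows = []
    for (cell, period), (mean, sigma) in truth.prey.items():
        mu = np.log(mean) - sigma**2 / 2.0
        rows.append({"cell": cell, "period": period, "mu_log": mu,
                     "sigma_log": sigma})
    return PreyField(pd.DataFrame(rows), n_categories=n_categories,
                     coverage_quantile=coverage_quantile)


def gen_prey_survey(truth: ScenarioTruth, n_samples: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Lognormal prey-energy samples (MJ per 6-h bout) per cell x period."""
    if n_samples < 2:
        raise ValueError("need n_samples >= 2 per stratum")
    rows = []
    for (cell, period), (mean, sigma) in sorted(truth.prey.items()):
        mu = np.log(mean) - sigma**2 / 2.0
        vals = (np.exp(rng.normal(mu, sigma, size=n_samples)) if sigma > 0
                else np.full(n_samples, np.exp(mu)))
        for v in vals:
            rows.append({"cell": cell, "period": period, "energy_MJ": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# acoustics
# ---------------------------------------------------------------------------

def _block_centroids(area: StudyArea, truth: ScenarioTruth):
    """Deterministic block layout: small grids around each cell centroid."""
    rows = []
    bid = 0
    for c in area.cells:
        if c.zone == "nearshore":
            n, spacing, a = truth.nearshore_blocks_per_cell, 2.0, 1.0
        else:
            n, spacing, a = truth.offshore_blocks_per_cell, 10.0, 100.0
        side = int(np.ceil(np.sqrt(n)))
        made = 0
        for i in range(side):
            for j in range(side):
                if made >= n:
                    break
                rows.append({
                    "block_id": bid, "cell": c.id, "area_km2": a,
                    "bx": c.x + (i - (side - 1) / 2) * spacing,
                    "by": c.y + (j - (side - 1) / 2) * spacing,
                })
                bid += 1
                made += 1
    return pd.DataFrame(rows)


def _source_position(plan: list[dict], day: int):
    for seg in plan:
        if seg["day0"] <= day < seg["day1"]:
            f = (day - seg["day0"]) / max(seg["day1"] - seg["day0"], 1)
            return (seg["x0"] + f * (seg["x1"] - seg["x0"]),
                    seg["y0"] + f * (seg["y1"] - seg["y0"]))
    return None


def gen_acoustic_field(truth: ScenarioTruth, area: StudyArea,
                       season: SeasonGrid,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Block-level maximum-SPL records for the survey plan.

    For each 6-h bin of an active survey day, every block reports one
    window with max SPL = source level - loss * log10(range in m) + noise.
    Off-survey bins produce no records.
    """
    blocks = _block_centroids(area, truth)
    rows = []
    start = pd.Timestamp(season.start_date)
    for day in range(season.n_days):
        pos = _source_position(truth.survey_plan, day)
        if pos is None:
            continue
        dx = blocks["bx"].to_numpy() - pos[0]
        dy = blocks["by"].to_numpy() - pos[1]
        r_m = np.maximum(np.hypot(dx, dy) * 1000.0, 1.0)
        base = (truth.source_level_db
                - truth.spreading_loss_coeff * np.log10(r_m))
        for b in range(season.bins_per_day):
            spl = base + (rng.normal(0.0, truth.noise_sd_db, size=len(blocks))
                          if truth.noise_sd_db > 0 else 0.0)
            ts = start + pd.Timedelta(days=day, hours=season.bin_hours * b)
            rows.append(pd.DataFrame({
                "block_id": blocks["block_id"],
                "cell": blocks["cell"],
                "area_km2": blocks["area_km2"],
                "timestamp_iso": ts.isoformat(),
                "max_spl_db": spl,
            }))
    if not rows:
        return pd.DataFrame(columns=["block_id", "cell", "area_km2",
                                     "timestamp_iso", "max_spl_db"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# photo-identification and scan surveys
# ---------------------------------------------------------------------------

def _draw_conditions(rng, n):
    beaufort = np.clip(rng.normal(2.5, 1.2, size=n), 0.0, 6.0)
    visibility = rng.beta(6.0, 2.0, size=n)
    return beaufort, visibility


def gen_photoid(truth: ScenarioTruth, season: SeasonGrid,
                rng: np.random.Generator, n_days: int = 100) -> pd.DataFrame:
    """Daily nearshore proportions of pregnant females (surveyed days only).

    The proportion is drawn from the zero-inflated beta truth and reported
    as a continuous value (the regression's own assumption); a rounded
    count out of ``n_group`` is also provided.
    """
    days = np.sort(rng.choice(np.arange(10, season.n_days - 10), size=n_days,
                              replace=False))
    weeks = days // 7
    beaufort, visibility = _draw_conditions(rng, n_days)
    df = pd.DataFrame({"week": weeks, "beaufort": beaufort,
                       "visibility": visibility})
    X, _ = photoid_design(df, season.n_weeks)
    alpha = expit(X @ np.asarray(truth.zib_alpha))
    mu = expit(X @ np.asarray(truth.zib_mu))
    nonzero = rng.uniform(size=n_days) < alpha
    p = np.zeros(n_days)
    a = mu * truth.zib_phi
    b = (1 - mu) * truth.zib_phi
    p[nonzero] = rng.beta(a[nonzero], b[nonzero])
    p = np.minimum(p, 1.0 - 1e-9)
    df["date"] = [season.date_of_day(int(d)).isoformat() for d in days]
    df["surveyed"] = True
    df["n_group"] = truth.n_group
    df["p_near"] = p
    df["n_seen"] = np.rint(p * truth.n_group).astype(int)
    return df


def gen_scan_surveys(truth: ScenarioTruth, area: StudyArea,
                     season: SeasonGrid, rng: np.random.Generator,
                     n_surveys: int = 120,
                     blocks_per_cell: int = 4) -> pd.DataFrame:
    """Block-level scan-survey density records for the nearshore cells.

    Each survey covers every nearshore cell with a drawn coverage fraction;
    the cell's density for that survey comes from the hurdle-gamma truth
    and is spread uniformly over the covered blocks (one boundary block is
    pre-split into two smaller blocks), so block aggregation recovers it
    exactly.
    """
    rows = []
    survey_days = np.sort(rng.choice(np.arange(10, season.n_days - 10),
                                     size=n_surveys, replace=True))
    a_vec = np.asarray(truth.hg_alpha)
    b_vec = np.asarray(truth.hg_mu)
    bid = 0
    for sid, day in enumerate(survey_days):
        week = int(day) // 7
        for cell in area.nearshore_ids:
            coverage = float(rng.beta(5.0, 2.0))
            df1 = pd.DataFrame({"week": [week], "coverage": [coverage]})
            X, _ = scan_design(df1, season.n_weeks, week_powers=3,
                               with_coverage=True)
            alpha = float(expit(X @ a_vec)[0])
            mu = float(np.exp(X @ b_vec)[0])
            if rng.uniform() < alpha:
                density = float(rng.gamma(truth.hg_omega,
                                          mu / truth.hg_omega))
            else:
                density = 0.0
            covered = coverage * area.cell(cell).area_km2
            block_areas = [covered * f for f in (0.4, 0.3, 0.2, 0.1)]
            block_areas = block_areas[:blocks_per_cell]
            for ba in block_areas:
                rows.append({
                    "survey_id": sid, "block_id": bid, "cell": cell,
                    "density": density, "area_km2": ba,
                    "coverage": coverage, "week": week,
                })
                bid += 1
    return pd.DataFrame(rows)


def gen_ppreg_daily(truth: ScenarioTruth, season: SeasonGrid,
                    rng: np.random.Generator, n_days: int = 100,
                    mean_identified: float = 15.0) -> pd.DataFrame:
    """Daily pregnant / identified counts from the logistic truth."""
    days = np.sort(rng.choice(np.arange(10, season.n_days - 10), size=n_days,
                              replace=False))
    weeks = days // 7
    beaufort, visibility = _draw_conditions(rng, n_days)
    df = pd.DataFrame({"week": weeks, "beaufort": beaufort,
                       "visibility": visibility})
    X, _ = photoid_design(df, season.n_weeks)
    p = expit(X @ np.asarray(truth.ppreg_coefs))
    n_id = rng.poisson(mean_identified, size=n_days) + 1
    df["n_identified"] = n_id
    df["n_pregnant"] = rng.binomial(n_id, p)
    return df


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------

def gen_roster(truth: ScenarioTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Photo-identification roster with >= 2-year inter-birth intervals."""
    if truth.roster_size < 1:
        raise ValueError("roster size must be >= 1")
    y0, y1 = truth.roster_years
    rows = []
    for fid in range(truth.roster_size):
        last = -10
        calf_years = []
        for year in range(y0, y1 + 1):
            if year - last >= 2 and rng.uniform() < truth.annual_calving_prob:
                calf_years.append(year)
                last = year
        rows.append({"female_id": fid,
                     "calf_years": ";".join(map(str, calf_years))})
    return pd.DataFrame(rows)


def calves_in_year(roster: pd.DataFrame, year: int) -> int:
    return int(sum(str(year) in str(c).split(";")
                   for c in roster["calf_years"]))


def roster_reproductive_rate(roster: pd.DataFrame, year1: int,
                             year2: int) -> float:
    """Observed rate from a roster: year-2 calves over available mothers."""
    from .fieldstats import reproductive_rate

    return reproductive_rate(len(roster), calves_in_year(roster, year1),
                             calves_in_year(roster, year2))


# ---------------------------------------------------------------------------
# full scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    truth: ScenarioTruth
    area: StudyArea
    season: SeasonGrid
    prey: PreyField
    acoustic: pd.DataFrame
    photoid: pd.DataFrame
    scans: pd.DataFrame
    ppreg_daily: pd.DataFrame
    roster: pd.DataFrame


def generate_scenario(truth: ScenarioTruth | None = None,
                      area: StudyArea | None = None,
                      season: SeasonGrid | None = None,
                      seed: int | None = None,
                      n_categories: int = 10) -> SyntheticScenario:
    """Generate every synthetic input stream from one truth and seed."""
    truth = truth or ScenarioTruth()
    area = area or StudyArea.default()
    season = season or SeasonGrid()
    seed = truth.master_seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_ac, r_ph, r_sc, r_pp, r_ro = (np.random.default_rng(s)
                                    for s in ss.spawn(5))
    return SyntheticScenario(
        truth=truth,
        area=area,
        season=season,
        prey=prey_field_from_truth(truth, n_categories=n_categories),
        acoustic=gen_acoustic_field(truth, area, season, r_ac),
        photoid=gen_photoid(truth, season, r_ph),
        scans=gen_scan_surveys(truth, area, season, r_sc),
        ppreg_daily=gen_ppreg_daily(truth, season, r_pp),
        roster=gen_roster(truth, r_ro),
    )


def write_scenario(scenario: SyntheticScenario, outdir) -> None:
    """Write a complete scenario directory of CSVs plus the truth as YAML."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scenario.area.to_csv(out / "cells.csv")
    scenario.prey.to_csv(out / "prey_params.csv")
    scenario.acoustic.to_csv(out / "acoustic_blocks.csv", index=False)
    scenario.photoid.to_csv(out / "photoid_days.csv", index=False)
    scenario.scans.to_csv(out / "scan_blocks.csv", index=False)
    scenario.ppreg_daily.to_csv(out / "ppreg_daily.csv", index=False)
    scenario.roster.to_csv(out / "roster.csv", index=False)
    (out / "truth.yaml").write_text(
        yaml.safe_dump(scenario.truth.to_dict(), sort_keys=True))
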