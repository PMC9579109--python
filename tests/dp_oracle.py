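"""Brute-force oracle for the backward iteration on tiny integer instances.

Instances are constructed so every state transition lands exactly on a grid
node (unit fat spacing, unit catabolic yield and deposition efficiency,
integer energies and costs, fetal growth equal to the fetal grid spacing).
The oracle is an independent recursive expectimax over exact continuous
states: action values are re-derived from the instance parameters, the
expectation over prey categories is taken explicitly, and the max is taken
over actions — none of the solver's vectorized shift/interpolation code is
reused.
"""

from dataclasses import dataclass

import numpy as np

import graywhale_sdp as g
from graywhale_sdp.bioenergetics import survival_to_next_season
from graywhale_sdp.habitat import CategoricalPreyField, FeedingCell, StudyArea

TOY_L = 12.0


@dataclass
class TinySeason:
    """Duck-typed season with a handful of days, all in one prey period."""

    n_days: int
    bins_per_day: int = 4
    week_periods: tuple = ("early",)

    def period_of_day(self, d):
        return "early"


@dataclass
class ToyInstance:
    area: StudyArea
    season: TinySeason
    prey: CategoricalPreyField
    bio: g.BioenergeticParams
    fitness: g.FitnessFunction
    n_fat: int
    n_fetal: int
    fetal_max: float


def toy_area(n_cells: int) -> StudyArea:
    ids = list(range(1, n_cells + 1))
    cells = [
        FeedingCell(i, "nearshore", False, 100.0,
                    tuple(j for j in ids if j != i), float(i), 0.0)
        for i in ids
    ]
    return StudyArea(cells, strict=False)


def make_instance(rng: np.random.Generator) -> ToyInstance:
    n_cells = int(rng.integers(1, 3))
    n_fetal = int(rng.integers(2, 4))
    grow_fetus = bool(rng.integers(0, 2)) and n_fetal >= 3
    n_days = int(rng.integers(2, min(5, n_fetal) if grow_fetus else 5))
    n_fat = int(rng.integers(4, 6))
    growth = 1.0 if grow_fetus else 0.0
    fetal_max = float(n_fetal - 1) if grow_fetus else 1.0
    fet_cost = float(rng.integers(0, 2)) if grow_fetus else 0.0
    bio = g.BioenergeticParams(
        mass_coeff=1.0, mass_exp=0.0,
        metabolic_coeff_MJ=float(rng.integers(1, 3)),
        max_intake_coeff_MJ=1e9,
        fetal_growth_m_per_day=growth,
        fetal_energy_MJ_per_m=fet_cost if grow_fetus else 0.0,
        catabolic_yield_MJ_per_kg=1.0,
        deposition_efficiency=1.0,
        reduced_growth_factor=1.0,
        fat_floor_frac=1.0,
        fat_max_frac=float(n_fat - 1),
        annual_mortality=float(rng.choice([0.0, 0.3])),
        foraging_fraction_mean=0.25,
        within_cell_foraging_fraction=0.5,
        inter_cell_distance_km=float(rng.integers(1, 3)),
        within_cell_distance_km=float(rng.integers(1, 3)),
        travel_MJ_per_km=1.0,
    )
    K = int(rng.integers(2, 4))
    table = {}
    for c in range(1, n_cells + 1):
        vals = rng.choice([0.0, 2.0, 4.0, 6.0, 8.0], size=K, replace=False)
        w = rng.integers(1, 5, size=K).astype(float)
        table[(c, "early")] = (vals, w / w.sum())
    prey = CategoricalPreyField(table, n_categories=K)
    fitness = g.FitnessFunction.from_variant(
        str(rng.choice(["low", "medium", "high"])))
    return ToyInstance(
        area=toy_area(n_cells), season=TinySeason(n_days), prey=prey,
        bio=bio, fitness=fitness, n_fat=n_fat, n_fetal=n_fetal,
        fetal_max=fetal_max,
    )


def solve_dp(inst: ToyInstance):
    solver = g.PolicySolver(
        n_fat=inst.n_fat, n_fetal=inst.n_fetal, n_lengths=1,
        fetal_max_m=inst.fetal_max, rule="argmax", epsilon=1e-12,
        L_min=TOY_L, L_max=TOY_L,
    )
    solver.fit(inst.area, inst.season, inst.prey, bio=inst.bio,
               fitness=inst.fitness)
    return solver.policy_


def oracle(inst: ToyInstance):
    """Return vbar(t, fat, fetal, cell_index) by exhaustive recursion."""
    bio, fit = inst.bio, inst.fitness
    met = bio.metabolic_coeff_MJ
    fet_cost = bio.fetal_energy_MJ_per_m * bio.fetal_growth_m_per_day
    growth = bio.fetal_growth_m_per_day
    floor, fmax = 1.0, float(inst.n_fat - 1)
    gmax = inst.fetal_max
    t_in = bio.travel_MJ_per_km * bio.inter_cell_distance_km
    t_wi = bio.travel_MJ_per_km * bio.within_cell_distance_km
    s_day = (1.0 - bio.annual_mortality) ** (24.0 / 8760.0)
    n_cells = inst.area.n_cells
    cats = {c: inst.prey.categories(c + 1, "early") for c in range(n_cells)}

    def term(f, gg):
        return float(fit(f, gg, TOY_L, bio))

    def surv(f):
        return float(survival_to_next_season(TOY_L, f, fit, bio))

    memo = {}

    def step(f, gg, intake, travel):
        bal = intake - (met + fet_cost + travel)
        f2 = f + bal
        alive = f2 >= floor
        f2 = min(max(f2, 0.0), fmax)
        g2 = min(gg + growth, gmax)
        return f2, g2, alive

    def value_k(t, f, gg, c, e):
        opts = [surv(f) * term(f, gg)]
        f2, g2, alive = step(f, gg, e, 0.0)
        opts.append(s_day * vbar(t + 1, f2, g2, c) if alive else 0.0)
        f2, g2, alive = step(f, gg, e * 0.5, t_wi)
        opts.append(s_day * vbar(t + 1, f2, g2, c) if alive else 0.0)
        for j in range(n_cells):
            if j == c:
                continue
            f2, g2, alive = step(f, gg, 0.0, t_in)
            opts.append(s_day * vbar(t + 1, f2, g2, j) if alive else 0.0)
        return max(opts)

    def vbar(t, f, gg, c):
        key = (t, f, gg, c)
        if key in memo:
            return memo[key]
        if t == inst.season.n_days:
            v = term(f, gg)
        else:
            vals, probs = cats[c]
            v = sum(p * value_k(t, f, gg, c, e)
                    for e, p in zip(vals, probs))
        memo[key] = v
        return v

    return vbar
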