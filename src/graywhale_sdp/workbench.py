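"""Scenario configuration, orchestration, and the factorial grid runner.

A Scenario pins one combination of reproductive-fitness variant and
minimum maternal length, with or without acoustic disturbance, plus the
Monte-Carlo sizes and the master seed.  The experimental design of record
is the 3 x 4 factorial (three fitness variants x four minimum lengths =
twelve model permutations), run with and without disturbance.  Policies
depend only on the fitness variant (the policy length grid always spans
11-14 m; the minimum length acts through the simulated length draws), so
the grid runner caches one backward iteration per variant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .bioenergetics import ALLOWED_L_MIN, BioenergeticParams, FitnessFunction
from .disturbance import ExposureSeries, exposure_probability
from .fieldstats import cohens_d
from .habitat import SeasonGrid, StudyArea
from .policy import PolicySolver, PolicyTable
from .simulate import (SimulationConfig, occupancy_series,
                       reproduction_summary, simulate_population)
from .synth import ScenarioTruth, gen_acoustic_field, prey_field_from_truth

logger = logging.getLogger(__name__)


@dataclass
class Scenario:
    """One model permutation plus run sizes."""

    fitness_variant: str = "low"
    L_min: float = 11.0
    disturbance: bool = False
    n_replicates: int = 100
    population_size: int = 50
    seed: int = 0
    rule: str = "class_softmax"
    temperature: float = 0.0005
    epsilon: float = 1e-6
    n_fat: int = 60
    n_fetal: int = 30
    n_lengths: int = 7
    n_categories: int = 10
    allow_custom: bool = False

    def __post_init__(self):
        if self.fitness_variant not in FitnessFunction.VARIANTS:
            raise ValueError(f"unknown fitness variant {self.fitness_variant!r}")
        if not self.allow_custom and self.L_min not in ALLOWED_L_MIN:
            raise ValueError(
                f"L_min {self.L_min} not in {ALLOWED_L_MIN} "
                "(pass allow_custom=True to override)")

    def to_dict(self):
        return asdict(self)


@dataclass
class Inputs:
    """Shared inputs for a scenario run (defaults are the synthetic scenario)."""

    area: StudyArea = field(default_factory=StudyArea.default)
    season: SeasonGrid = field(default_factory=SeasonGrid)
    truth: ScenarioTruth = field(default_factory=ScenarioTruth)
    prey: object = None
    exposure: ExposureSeries | None = None
    bio: BioenergeticParams = field(default_factory=BioenergeticParams)

    def __post_init__(self):
        if self.prey is None:
            self.prey = prey_field_from_truth(self.truth)

    def default_exposure(self) -> ExposureSeries:
        """Exposure from the synthetic seismic survey (fixed acoustic seed,
        so paired disturbed/undisturbed scenarios share one sound field)."""
        if self.exposure is None:
            rng = np.random.default_rng(self.truth.master_seed)
            grid = gen_acoustic_field(self.truth, self.area, self.season, rng)
            self.exposure = exposure_probability(grid, self.area, self.season)
        return self.exposure


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def solve_policy(scenario: Scenario, inputs: Inputs) -> PolicyTable:
    prey = (inputs.prey
            if inputs.prey.n_categories == scenario.n_categories
            else prey_field_from_truth(inputs.truth,
                                       n_categories=scenario.n_categories))
    solver = PolicySolver(
        n_fat=scenario.n_fat, n_fetal=scenario.n_fetal,
        n_lengths=scenario.n_lengths, rule=scenario.rule,
        epsilon=scenario.epsilon, temperature=scenario.temperature,
    )
    t0 = time.perf_counter()
    solver.fit(inputs.area, inputs.season, prey, bio=inputs.bio,
               fitness=scenario.fitness_variant)
    logger.info("backward iteration (%s): %.1f s", scenario.fitness_variant,
                time.perf_counter() - t0)
    return solver.policy_


def run_scenario(scenario: Scenario, inputs: Inputs | None = None,
                 policy: PolicyTable | None = None) -> dict:
    """End-to-end run: policy, simulation, summaries, provenance snapshot."""
    inputs = inputs or Inputs()
    if policy is None:
        policy = solve_policy(scenario, inputs)
    exposure = inputs.default_exposure() if scenario.disturbance else None
    sim_cfg = SimulationConfig(
        n_replicates=scenario.n_replicates,
        population_size=scenario.population_size,
        L_min=scenario.L_min,
    )
    t0 = time.perf_counter()
    result = simulate_population(policy, sim_cfg, exposure=exposure,
                                 seed=scenario.seed)
    logger.info("forward simulation (%d replicates): %.1f s",
                scenario.n_replicates, time.perf_counter() - t0)
    occ = occupancy_series(result)
    rep = reproduction_summary(result)
    resolved = {
        "scenario": scenario.to_dict(),
        "bio": inputs.bio.to_dict(),
        "fitness": asdict(policy.fitness),
        "policy_hash": policy.config_hash(),
    }
    return {
        "scenario": scenario,
        "policy": policy,
        "result": result,
        "occupancy": occ,
        "reproduction": rep,
        "resolved_config": resolved,
        "config_hash": config_hash(resolved),
    }


def run_grid(base: Scenario | None = None, inputs: Inputs | None = None,
             variants=FitnessFunction.VARIANTS,
             L_mins=ALLOWED_L_MIN) -> dict:
    """The factorial of fitness variants x minimum lengths.

    Returns {(variant, L_min): bundle}; one policy solve per variant.
    """
    from dataclasses import replace

    base = base or Scenario()
    inputs = inputs or Inputs()
    policies = {}
    out = {}
    for v in variants:
        sc_v = replace(base, fitness_variant=v, L_min=11.0)
        policies[v] = solve_policy(sc_v, inputs)
        for lmin in L_mins:
            sc = replace(base, fitness_variant=v, L_min=lmin)
            out[(v, lmin)] = run_scenario(sc, inputs, policy=policies[v])
    return out


def compare_scenarios(bundle_a: dict, bundle_b: dict) -> dict:
    """Weekly Cohen's d per area and cell, plus a reproduction effect size.

    Positive d means the first bundle has the larger mean.
    """
    occ_a, occ_b = bundle_a["occupancy"], bundle_b["occupancy"]
    if occ_a.weekly_area.shape != occ_b.weekly_area.shape:
        raise ValueError("bundles were run on different grids")
    n_a = occ_a.weekly_area.shape[0]
    n_b = occ_b.weekly_area.shape[0]
    n_weeks = occ_a.weekly_area.shape[1]

    def weekly_d(arr_a, arr_b):
        out = np.empty(arr_a.shape[1:][::-1], object).T  # (n_weeks, k)
        k = arr_a.shape[2]
        out = np.empty((n_weeks, k), object)
        for w in range(n_weeks):
            for j in range(k):
                a = arr_a[:, w, j]
                b = arr_b[:, w, j]
                out[w, j] = cohens_d(a.mean(), a.std(ddof=1), n_a,
                                     b.mean(), b.std(ddof=1), n_b)
        return out

    rep_a = bundle_a["reproduction"]
    rep_b = bundle_b["reproduction"]
    rep_d = cohens_d(rep_a.mean, rep_a.sd, rep_a.n,
                     rep_b.mean, rep_b.sd, rep_b.n)
    return {
        "weekly_area_d": weekly_d(occ_a.weekly_area, occ_b.weekly_area),
        "weekly_cell_d": weekly_d(occ_a.weekly_cells, occ_b.weekly_cells),
        "reproduction_d": rep_d,
    }
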