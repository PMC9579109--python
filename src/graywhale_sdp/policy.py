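"""Backward iteration: expected-fitness values and behavior probabilities.

The dynamic program runs on daily decision steps over a discretized state
space (fat mass x fetal length x location x current prey category).  At
each day a female may (0) leave the foraging ground for the season,
(1) feed in her current cell, (2) travel within the cell (partial foraging),
or (3..) travel to any other cell (no foraging that day).  The value of
leaving is overwinter survival times terminal reproductive fitness at the
current state; the value of the other actions is the background-survival-
discounted expectation of the next day's value at the energy-updated state,
with the expectation taken over the destination cell's prey categories
(categories are redrawn independently each day).

Action probabilities follow either an epsilon-argmax rule (uniform over all
actions within ``epsilon`` of the best; the default for the operation) or a
softmax with temperature (used by the shipped scenarios, where behavioral
stochasticity is wanted).  Only the category-averaged continuation surface
``Vbar(day, cell, fat, fetal)`` is stored; action values and probabilities
at any state are recomputed from it on demand, which keeps the policy
artifact small and lets the forward simulation interpolate probabilities
between grid nodes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .bioenergetics import (
    BioenergeticParams,
    FitnessFunction,
    allocate_core,
    survival_to_next_season,
)
from .habitat import PreyField, SeasonGrid, StudyArea

logger = logging.getLogger(__name__)

#: fixed action slots before the per-destination travel actions
A_LEAVE, A_FEED, A_WITHIN = 0, 1, 2
N_FIXED = 3


def n_actions(n_cells: int) -> int:
    return N_FIXED + n_cells - 1


def travel_dest_index(action: int, cell_index: int) -> int:
    """0-based destination cell index of a travel action (action >= 3)."""
    j = action - N_FIXED
    return j if j < cell_index else j + 1


def _bilerp(A: np.ndarray, f, g, fstep: float, gstep: float):
    """Bilinear interpolation of A (nF, nG) on uniform grids starting at 0.

    Coordinates outside the grid hull are clamped to the boundary.
    """
    nF, nG = A.shape
    uf = np.clip(np.asarray(f, float) / fstep, 0.0, nF - 1.0)
    ug = np.clip(np.asarray(g, float) / gstep, 0.0, nG - 1.0)
    i0 = np.minimum(uf.astype(np.intp), nF - 2)
    j0 = np.minimum(ug.astype(np.intp), nG - 2)
    wf = uf - i0
    wg = ug - j0
    return (
        A[i0, j0] * (1 - wf) * (1 - wg)
        + A[i0 + 1, j0] * wf * (1 - wg)
        + A[i0, j0 + 1] * (1 - wf) * wg
        + A[i0 + 1, j0 + 1] * wf * wg
    )


def _gather_bilerp(V: np.ndarray, cell_idx, f, g, fstep: float, gstep: float):
    """Bilinear interpolation into V (n_cells, nF, nG) with per-point cells."""
    n_cells, nF, nG = V.shape
    flat = V.reshape(n_cells * nF * nG)
    uf = np.clip(np.asarray(f, float) / fstep, 0.0, nF - 1.0)
    ug = np.clip(np.asarray(g, float) / gstep, 0.0, nG - 1.0)
    i0 = np.minimum(uf.astype(np.intp), nF - 2)
    j0 = np.minimum(ug.astype(np.intp), nG - 2)
    wf = uf - i0
    wg = ug - j0
    base = np.asarray(cell_idx, np.intp) * (nF * nG) + i0 * nG + j0
    return (
        flat[base] * (1 - wf) * (1 - wg)
        + flat[base + nG] * wf * (1 - wg)
        + flat[base + 1] * (1 - wf) * wg
        + flat[base + nG + 1] * wf * wg
    )


def policy_probabilities(values: np.ndarray, rule: str, epsilon: float,
                         temperature: float) -> np.ndarray:
    """Distribution over actions from their values (action axis last).

    Rules:

    - ``argmax``: uniform over every action within ``epsilon`` of the best
      (the minimal reading of behavior derived from an optimality
      computation; the default for the operation).
    - ``softmax``: Boltzmann weights over all actions.
    - ``class_softmax``: a nested rule — Boltzmann weights over the four
      behavior classes (leave, feed, travel within, travel to another
      cell), the travel class entering with its best destination's value;
      the travel-class probability is then spread over destinations by a
      second Boltzmann at the same temperature.  This keeps the ten
      destination variants from being over-weighted relative to the other
      three options (the classic red-bus/blue-bus artifact of a flat
      softmax) while still mixing among near-equivalent destinations.
    """
    if rule == "argmax":
        m = values.max(axis=-1, keepdims=True)
        tie = values >= m - epsilon
        return tie / tie.sum(axis=-1, keepdims=True)
    if rule == "softmax":
        z = np.exp((values - values.max(axis=-1, keepdims=True)) / temperature)
        return z / z.sum(axis=-1, keepdims=True)
    if rule == "class_softmax":
        travel = values[..., N_FIXED:]
        tmax = travel.max(axis=-1, keepdims=True)
        cls = np.concatenate([values[..., :N_FIXED], tmax], axis=-1)
        z = np.exp((cls - cls.max(axis=-1, keepdims=True)) / temperature)
        z /= z.sum(axis=-1, keepdims=True)
        dest = np.exp((travel - tmax) / temperature)
        dest /= dest.sum(axis=-1, keepdims=True)
        return np.concatenate([z[..., :N_FIXED], z[..., N_FIXED:] * dest],
                              axis=-1)
    raise ValueError(f"unknown policy rule {rule!r}")


def terminal_values(fat_grid: np.ndarray, fetal_grid: np.ndarray, L: float,
                    fitness: FitnessFunction,
                    bio: BioenergeticParams) -> np.ndarray:
    """Terminal fitness surface V(last day, fat, fetal) for one length."""
    F, G = np.meshgrid(fat_grid, fetal_grid, indexing="ij")
    return np.asarray(fitness(F, G, L, bio), float)


@dataclass
class PolicyTable:
    """Fitted policy: continuation surfaces plus everything needed to query it."""

    lengths: np.ndarray                  # (nL,)
    Vbar: np.ndarray                     # (nL, n_days+1, n_cells, nF, nG)
    fat_grids: np.ndarray                # (nL, nF)
    fetal_grid: np.ndarray               # (nG,)
    area: StudyArea
    season: SeasonGrid
    prey: PreyField
    bio: BioenergeticParams
    fitness: FitnessFunction
    rule: str = "argmax"
    epsilon: float = 1e-6
    temperature: float = 0.0005

    def __post_init__(self):
        self._warned_hull = False
        n_cells = self.area.n_cells
        # category tables per period, in cell order
        self._cat_values = {}
        self._cat_probs = {}
        for period in set(self.season.week_periods):
            v, p = self.prey.category_table(self.area.ids, period)
            self._cat_values[period] = v
            self._cat_probs[period] = p

    # -- basic geometry -------------------------------------------------
    @property
    def n_lengths(self) -> int:
        return len(self.lengths)

    @property
    def n_actions(self) -> int:
        return n_actions(self.area.n_cells)

    def length_index(self, L) -> np.ndarray:
        """Nearest policy-length index for each female length."""
        return np.argmin(
            np.abs(np.asarray(L, float)[..., None] - self.lengths), axis=-1
        )

    def category_values(self, period: str) -> np.ndarray:
        return self._cat_values[period]

    def category_probs(self, period: str) -> np.ndarray:
        return self._cat_probs[period]

    # -- action values ---------------------------------------------------
    def action_values(self, day, li, ci, k, f, g) -> np.ndarray:
        """Daily action values for a batch of states.

        Parameters are parallel arrays: policy-length index ``li``, 0-based
        cell index ``ci``, prey-category index ``k``, fat ``f`` (kg) and
        fetal length ``g`` (m).  Returns an array (m, n_actions).
        """
        day = int(day)
        li = np.asarray(li, np.intp)
        ci = np.asarray(ci, np.intp)
        k = np.asarray(k, np.intp)
        f = np.asarray(f, float)
        g = np.asarray(g, float)
        m = f.shape[0]
        n_cells = self.area.n_cells
        out = np.empty((m, self.n_actions))
        period = self.season.period_of_day(day)
        evals = self._cat_values[period]           # (n_cells, K)
        bio = self.bio
        s_day = bio.survival_per_hours(24.0)
        bins = self.season.bins_per_day
        fet_cost = bio.fetal_cost_MJ_per_day()
        fet_growth = bio.fetal_growth_m_per_day
        gstep = self.fetal_grid[1] - self.fetal_grid[0]

        for lidx in np.unique(li):
            sel = np.nonzero(li == lidx)[0]
            L = float(self.lengths[lidx])
            fat_grid = self.fat_grids[lidx]
            fstep = fat_grid[1] - fat_grid[0]
            Vnext = self.Vbar[lidx, day + 1]       # (n_cells, nF, nG)
            met = bio.metabolic_MJ_per_day(L)
            fs, gs, cs, ks = f[sel], g[sel], ci[sel], k[sel]
            if np.any(fs > fat_grid[-1] + 1e-9) and not self._warned_hull:
                logger.warning("state outside grid hull; clamping")
                self._warned_hull = True
            # leave: overwinter survival x terminal fitness now
            out[sel, A_LEAVE] = survival_to_next_season(
                L, fs, self.fitness, bio
            ) * self.fitness(fs, gs, L, bio)
            e = evals[cs, ks]
            cap = bio.max_intake_MJ_per_day(L)
            # feed
            intake = np.minimum(bins * e * bio.foraging_fraction_mean, cap)
            ff, fg, fa = allocate_core(
                fs, gs, intake, met, fet_cost, fet_growth, 0.0, bio, L
            )
            out[sel, A_FEED] = fa * s_day * _gather_bilerp(
                Vnext, cs, ff, fg, fstep, gstep
            )
            # travel within the cell: partial foraging plus a travel cost
            intake_w = np.minimum(
                bins * e * bio.foraging_fraction_mean
                * bio.within_cell_foraging_fraction, cap)
            wf, wg, wa = allocate_core(
                fs, gs, intake_w, met, fet_cost, fet_growth,
                bio.travel_cost_within_MJ(), bio, L,
            )
            out[sel, A_WITHIN] = wa * s_day * _gather_bilerp(
                Vnext, cs, wf, wg, fstep, gstep
            )
            # travel to each other cell: no foraging that day
            tf, tg, ta = allocate_core(
                fs, gs, 0.0, met, fet_cost, fet_growth,
                bio.travel_cost_inter_MJ(), bio, L,
            )
            allc = np.arange(n_cells - 1)
            dests = np.where(allc[None, :] < cs[:, None], allc[None, :],
                             allc[None, :] + 1)           # (m_sel, n_cells-1)
            tv = _gather_bilerp(
                Vnext,
                dests,
                np.broadcast_to(tf[:, None], dests.shape),
                np.broadcast_to(tg[:, None], dests.shape),
                fstep,
                gstep,
            )
            out[sel, N_FIXED:] = (ta * s_day)[:, None] * tv
        return out

    # -- probabilities ---------------------------------------------------
    def action_probabilities(self, day, li, ci, k, f, g) -> np.ndarray:
        """Behavior distribution at continuous states (batched).

        Probabilities are computed at the four surrounding (fat, fetal)
        grid nodes, blended bilinearly, and renormalized.
        """
        li = np.atleast_1d(np.asarray(li, np.intp))
        ci = np.atleast_1d(np.asarray(ci, np.intp))
        k = np.atleast_1d(np.asarray(k, np.intp))
        f = np.atleast_1d(np.asarray(f, float))
        g = np.atleast_1d(np.asarray(g, float))
        m = f.shape[0]
        nF = self.fat_grids.shape[1]
        nG = len(self.fetal_grid)
        gstep = self.fetal_grid[1] - self.fetal_grid[0]
        fsteps = self.fat_grids[li, 1] - self.fat_grids[li, 0]
        uf = np.clip(f / fsteps, 0.0, nF - 1.0)
        ug = np.clip(g / gstep, 0.0, nG - 1.0)
        i0 = np.minimum(uf.astype(np.intp), nF - 2)
        j0 = np.minimum(ug.astype(np.intp), nG - 2)
        wf = uf - i0
        wg = ug - j0
        pi = np.zeros((m, self.n_actions))
        for di, dj, w in (
            (0, 0, (1 - wf) * (1 - wg)),
            (1, 0, wf * (1 - wg)),
            (0, 1, (1 - wf) * wg),
            (1, 1, wf * wg),
        ):
            fn = self.fat_grids[li, i0 + di]
            gn = self.fetal_grid[j0 + dj]
            vals = self.action_values(day, li, ci, k, fn, gn)
            pi += w[:, None] * policy_probabilities(
                vals, self.rule, self.epsilon, self.temperature
            )
        pi /= pi.sum(axis=1, keepdims=True)
        return pi

    def value_at(self, day, li, ci, f, g):
        """Category-averaged value surface, interpolated (diagnostics)."""
        li = int(li)
        gstep = self.fetal_grid[1] - self.fetal_grid[0]
        fstep = self.fat_grids[li, 1] - self.fat_grids[li, 0]
        return _bilerp(self.Vbar[li, day, ci], f, g, fstep, gstep)

    # -- persistence -----------------------------------------------------
    def config_hash(self) -> str:
        payload = json.dumps(self._meta(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def _meta(self) -> dict:
        from dataclasses import asdict

        return {
            "lengths": self.lengths.tolist(),
            "fetal_grid": [float(self.fetal_grid[0]), float(self.fetal_grid[-1]),
                           len(self.fetal_grid)],
            "n_fat": int(self.fat_grids.shape[1]),
            "rule": self.rule,
            "epsilon": self.epsilon,
            "temperature": self.temperature,
            "area_csv": self.area.to_csv_string(),
            "season": {
                "start_date": str(self.season.start_date),
                "n_weeks": self.season.n_weeks,
                "bin_hours": self.season.bin_hours,
                "week_periods": list(self.season.week_periods),
            },
            "prey": {
                "params": self.prey.params.to_dict(orient="list"),
                "n_categories": self.prey.n_categories,
                "coverage_quantile": self.prey.coverage_quantile,
            },
            "bio": self.bio.to_dict(),
            "fitness": asdict(self.fitness),
        }

    def save(self, path) -> None:
        """Binary array container plus a JSON sidecar with grid/config info."""
        import pathlib

        path = pathlib.Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            lengths=self.lengths,
            Vbar=self.Vbar,
            fat_grids=self.fat_grids,
            fetal_grid=self.fetal_grid,
        )
        meta = self._meta()
        meta["config_hash"] = self.config_hash()
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=str))

    @classmethod
    def load(cls, path) -> "PolicyTable":
        import datetime as dt
        import io
        import pathlib

        import pandas as pd

        path = pathlib.Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        area = StudyArea.from_csv(io.StringIO(meta["area_csv"]))
        season = SeasonGrid(
            start_date=dt.date.fromisoformat(meta["season"]["start_date"]),
            n_weeks=meta["season"]["n_weeks"],
            bin_hours=meta["season"]["bin_hours"],
            week_periods=tuple(meta["season"]["week_periods"]),
        )
        prey = PreyField(
            pd.DataFrame(meta["prey"]["params"]),
            n_categories=meta["prey"]["n_categories"],
            coverage_quantile=meta["prey"]["coverage_quantile"],
        )
        fit_kw = dict(meta["fitness"])
        return cls(
            lengths=arrs["lengths"],
            Vbar=arrs["Vbar"],
            fat_grids=arrs["fat_grids"],
            fetal_grid=arrs["fetal_grid"],
            area=area,
            season=season,
            prey=prey,
            bio=BioenergeticParams(**meta["bio"]),
            fitness=FitnessFunction(**fit_kw),
            rule=meta["rule"],
            epsilon=meta["epsilon"],
            temperature=meta["temperature"],
        )


class PolicySolver(BaseEstimator):
    """Backward-iteration solver producing a :class:`PolicyTable`.

    Parameters
    ----------
    n_fat, n_fetal : int
        Grid resolution for fat mass (kg, spanning [0, fat_max(L)]) and
        fetal length (m, spanning [0, fetal_max_m]).
    n_lengths : int
        Number of maternal lengths on the coarse policy grid spanning
        [L_min, L_max]; the simulation picks the nearest length.
    rule, epsilon, temperature : str, float, float
        Behavior-probability rule; see :func:`policy_probabilities`.
    """

    def __init__(
        self,
        n_fat: int = 60,
        n_fetal: int = 30,
        n_lengths: int = 7,
        fetal_max_m: float = 1.3,
        rule: str = "argmax",
        epsilon: float = 1e-6,
        temperature: float = 0.0005,
        L_min: float = 11.0,
        L_max: float = 14.0,
    ):
        self.n_fat = n_fat
        self.n_fetal = n_fetal
        self.n_lengths = n_lengths
        self.fetal_max_m = fetal_max_m
        self.rule = rule
        self.epsilon = epsilon
        self.temperature = temperature
        self.L_min = L_min
        self.L_max = L_max

    def fit(
        self,
        area: StudyArea,
        season: SeasonGrid,
        prey: PreyField,
        bio: BioenergeticParams | None = None,
        fitness: FitnessFunction | str = "low",
    ) -> "PolicySolver":
        bio = bio or BioenergeticParams()
        if isinstance(fitness, str):
            fitness = FitnessFunction.from_variant(fitness)
        if self.n_lengths == 1:
            lengths = np.array([(self.L_min + self.L_max) / 2.0])
        else:
            lengths = np.linspace(self.L_min, self.L_max, self.n_lengths)
        nF, nG = self.n_fat, self.n_fetal
        fetal_grid = np.linspace(0.0, self.fetal_max_m, nG)
        fat_grids = np.stack(
            [np.linspace(0.0, bio.fat_max(L), nF) for L in lengths]
        )
        n_days = season.n_days
        Vbar = np.empty((len(lengths), n_days + 1, area.n_cells, nF, nG))
        for lidx, L in enumerate(lengths):
            Vbar[lidx] = self._solve_length(
                float(L), fat_grids[lidx], fetal_grid, area, season, prey,
                bio, fitness,
            )
        self.policy_ = PolicyTable(
            lengths=lengths,
            Vbar=Vbar,
            fat_grids=fat_grids,
            fetal_grid=fetal_grid,
            area=area,
            season=season,
            prey=prey,
            bio=bio,
            fitness=fitness,
            rule=self.rule,
            epsilon=self.epsilon,
            temperature=self.temperature,
        )
        return self

    # ------------------------------------------------------------------
    def _solve_length(self, L, fat_grid, fetal_grid, area, season, prey,
                      bio, fitness) -> np.ndarray:
        """Backward iteration for one maternal length.

        Because the daily costs are state-independent, the energy update on
        the grid is a uniform shift of the fat and fetal coordinates, so the
        next-day expectation reduces to a separable (row/column) linear
        interpolation of the continuation surface.
        """
        nF, nG = len(fat_grid), len(fetal_grid)
        n_cells = area.n_cells
        nA = n_actions(n_cells)
        n_days = season.n_days
        fstep = fat_grid[1] - fat_grid[0]
        gstep = fetal_grid[1] - fetal_grid[0]
        F, G = np.meshgrid(fat_grid, fetal_grid, indexing="ij")
        term = terminal_values(fat_grid, fetal_grid, L, fitness, bio)
        surv = np.asarray(survival_to_next_season(L, F, fitness, bio))
        leave_val = surv * term
        met = bio.metabolic_MJ_per_day(L)
        fet_cost = bio.fetal_cost_MJ_per_day()
        fet_growth = bio.fetal_growth_m_per_day
        floor = bio.fat_floor(L)
        fmax = bio.fat_max(L)
        rgf = bio.reduced_growth_factor
        eff = bio.deposition_efficiency
        yld = bio.catabolic_yield_MJ_per_kg
        s_day = bio.survival_per_hours(24.0)
        bins = season.bins_per_day
        K = prey.n_categories

        cap = bio.max_intake_MJ_per_day(L)

        def shift(intake: float, travel: float):
            """Uniform state shift and survival rows for one daily action."""
            intake = min(intake, cap)
            full_need = met + fet_cost + travel
            if intake >= full_need:
                dfat = (intake - full_need) * eff / yld
                growth = fet_growth
            else:
                bal = intake - (met + fet_cost * rgf + travel)
                dfat = bal * eff / yld if bal >= 0 else bal / yld
                growth = fet_growth * rgf
            alive = (fat_grid + dfat >= floor).astype(float)
            f2 = np.clip(fat_grid + dfat, 0.0, fmax)
            g2 = np.clip(fetal_grid + growth, fetal_grid[0], fetal_grid[-1])
            uf = f2 / fstep
            i0 = np.minimum(uf.astype(np.intp), nF - 2)
            wf = (uf - i0)[:, None]
            ug = g2 / gstep
            j0 = np.minimum(ug.astype(np.intp), nG - 2)
            wg = ug - j0
            return i0, wf, j0, wg, alive

        def interp(V, sh):
            """Continuation at the shifted grid; V is (nF, nG) or (m, nF, nG)."""
            i0, wf, j0, wg, alive = sh
            A = V[..., i0, :] * (1 - wf) + V[..., i0 + 1, :] * wf
            B = A[..., :, j0] * (1 - wg) + A[..., :, j0 + 1] * wg
            return s_day * alive[:, None] * B

        # cells sharing prey categories share the feed/within updates
        Vbar = np.empty((n_days + 1, n_cells, nF, nG))
        Vbar[n_days] = term[None, :, :]
        vals = np.empty((n_cells, K, nF, nG, nA))
        others_of = [[j for j in range(n_cells) if j != ci]
                     for ci in range(n_cells)]
        for t in range(n_days - 1, -1, -1):
            period = season.period_of_day(t)
            evals, probs = prey.category_table(area.ids, period)
            groups: dict[bytes, list[int]] = {}
            for ci in range(n_cells):
                groups.setdefault(evals[ci].tobytes(), []).append(ci)
            Vnext = Vbar[t + 1]
            # travel-to destination values shared by every source cell
            sh_t = shift(0.0, bio.travel_cost_inter_MJ())
            trav = interp(Vnext, sh_t)                    # (n_cells, nF, nG)
            for ci in range(n_cells):
                vals[ci, :, :, :, A_LEAVE] = leave_val[None]
                vals[ci, :, :, :, N_FIXED:] = np.moveaxis(
                    trav[others_of[ci]], 0, -1)[None]
            for cell_list in groups.values():
                sub = np.array(cell_list, np.intp)
                for k in range(K):
                    e = float(evals[sub[0], k])
                    intake = bins * e * bio.foraging_fraction_mean
                    feed_v = interp(Vnext[sub], shift(intake, 0.0))
                    within_v = interp(
                        Vnext[sub],
                        shift(intake * bio.within_cell_foraging_fraction,
                              bio.travel_cost_within_MJ()))
                    vals[sub, k, :, :, A_FEED] = feed_v
                    vals[sub, k, :, :, A_WITHIN] = within_v
            pi = policy_probabilities(vals, self.rule, self.epsilon,
                                      self.temperature)
            V = np.einsum("ckfga,ckfga->ckfg", pi, vals)
            if not np.isfinite(V).all():
                c, k, i, j = np.argwhere(~np.isfinite(V))[0]
                raise FloatingPointError(
                    f"non-finite value at day {t}, cell index {c}, "
                    f"category {k}, fat node {i}, fetal node {j}"
                )
            Vbar[t] = np.einsum("ck,ckfg->cfg", probs, V)
        return Vbar


def backward_iterate(
    area: StudyArea,
    season: SeasonGrid,
    prey: PreyField,
    bio: BioenergeticParams | None = None,
    fitness: FitnessFunction | str = "low",
    **solver_params,
) -> PolicyTable:
    """Functional wrapper around :class:`PolicySolver`."""
    solver = PolicySolver(**solver_params)
    return solver.fit(area, season, prey, bio=bio, fitness=fitness).policy_


def action_probabilities(policy: PolicyTable, day, li, ci, k, f, g):
    """Functional wrapper over :meth:`PolicyTable.action_probabilities`."""
    return policy.action_probabilities(day, li, ci, k, f, g)
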