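"""Study-area geometry, season calendar, and the stochastic prey-energy field.

The feeding ground off northeast Sakhalin Island is modeled as 11 abstract
cells: seven nearshore (ids 1-7, of which 1, 3, 5, 7 hug the coast) and four
offshore (ids 8-11).  Cells carry an area (used to convert occupancy
proportions to densities) and an ordered neighbor list (used to resolve
"next closest cell" when a whale is displaced by disturbance).  No spatial
projection is attempted; centroids exist only to order neighbors and to
drive the synthetic acoustic generator.

Daily prey energy available to a foraging whale is modeled per cell and
season period (early / mid / late) as a lognormal distribution of megajoules
per 6-h foraging bout, discretized into equally spaced categories for use as
a state variable in the dynamic-programming stage.
"""

from __future__ import annotations

import datetime as dt
import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PERIODS = ("early", "mid", "late")

NEARSHORE_IDS = (1, 2, 3, 4, 5, 6, 7)
OFFSHORE_IDS = (8, 9, 10, 11)
COASTAL_IDS = (1, 3, 5, 7)


class ValidationError(ValueError):
    """Raised when a cell map or season configuration is inconsistent."""


@dataclass(frozen=True)
class FeedingCell:
    """One feeding cell of the study area.

    Parameters
    ----------
    id : int
        Cell id in 1..11.
    zone : str
        ``"nearshore"`` or ``"offshore"``.
    coastal : bool
        True for the coast-hugging nearshore cells (1, 3, 5, 7).
    area_km2 : float
        Cell area, km^2.
    neighbors : tuple of int
        All other cell ids ordered by proximity; the first entry is the
        closest cell.
    x, y : float
        Abstract centroid coordinates (km); used only for neighbor ordering
        and synthetic acoustics.
    """

    id: int
    zone: str
    coastal: bool
    area_km2: float
    neighbors: tuple[int, ...]
    x: float = float("nan")
    y: float = float("nan")


class StudyArea:
    """Validated map of feeding cells.

    ``strict=True`` enforces the standard 11-cell topology (zone counts,
    coastal subset, symmetric neighbor relation, cells 8 and 9 being each
    other's closest cell).  Toy maps used in dynamic-programming tests pass
    ``strict=False``.
    """

    def __init__(self, cells: list[FeedingCell], strict: bool = True):
        ids = [c.id for c in cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate cell id(s) {dupes}")
        self._cells = {c.id: c for c in cells}
        self.ids = tuple(sorted(ids))
        self.strict = strict
        self._validate(strict)

    def _validate(self, strict: bool) -> None:
        for c in self._cells.values():
            if c.area_km2 <= 0:
                raise ValidationError(f"cell {c.id}: non-positive area")
            if strict and len(c.neighbors) < 1:
                raise ValidationError(f"cell {c.id}: no neighbors")
            for n in c.neighbors:
                if n not in self._cells:
                    raise ValidationError(
                        f"cell {c.id}: neighbor {n} is not a cell in the map"
                    )
                if c.id not in self._cells[n].neighbors:
                    raise ValidationError(
                        f"cell {c.id}: neighbor relation with {n} is not symmetric"
                    )
            if c.id in c.neighbors:
                raise ValidationError(f"cell {c.id}: lists itself as neighbor")
        if not strict:
            return
        if self.ids != tuple(range(1, 12)):
            raise ValidationError(
                f"expected cell ids 1..11, got {self.ids}"
            )
        for cid in NEARSHORE_IDS:
            if self._cells[cid].zone != "nearshore":
                raise ValidationError(f"cell {cid}: must be nearshore")
        for cid in OFFSHORE_IDS:
            if self._cells[cid].zone != "offshore":
                raise ValidationError(f"cell {cid}: must be offshore")
        coastal = tuple(sorted(c.id for c in self._cells.values() if c.coastal))
        if coastal != COASTAL_IDS:
            raise ValidationError(
                f"coastal cells must be {COASTAL_IDS}, got {coastal}"
            )
        if self._cells[8].neighbors[0] != 9:
            raise ValidationError("cell 8: first neighbor must be cell 9")
        if self._cells[9].neighbors[0] != 8:
            raise ValidationError("cell 9: first neighbor must be cell 8")

    # -- access ---------------------------------------------------------
    def cell(self, cid: int) -> FeedingCell:
        return self._cells[cid]

    @property
    def n_cells(self) -> int:
        return len(self._cells)

    def index(self, cid: int) -> int:
        """0-based array index of a cell id."""
        return self.ids.index(cid)

    @property
    def nearshore_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.cells if c.zone == "nearshore")

    @property
    def offshore_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.cells if c.zone == "offshore")

    @property
    def cells(self) -> list[FeedingCell]:
        return [self._cells[i] for i in self.ids]

    def areas(self) -> np.ndarray:
        return np.array([c.area_km2 for c in self.cells])

    # -- construction ---------------------------------------------------
    @classmethod
    def default(cls) -> "StudyArea":
        """The standard 11-cell map.

        Coastal cells 1, 3, 5, 7 are paired with seaward cells 2, 4, 6 along
        the coast; offshore cells 8-11 form a chain farther out, with 8 and 9
        adjacent.  Neighbor order is by centroid distance, which reproduces
        the mandated 8<->9 adjacency.
        """
        geom = {
            # id: (zone, coastal, area_km2, x, y)
            1: ("nearshore", True, 120.0, 10.0, 3.0),
            2: ("nearshore", False, 150.0, 10.0, 9.0),
            3: ("nearshore", True, 120.0, 30.0, 3.0),
            4: ("nearshore", False, 150.0, 30.0, 9.0),
            5: ("nearshore", True, 120.0, 50.0, 3.0),
            6: ("nearshore", False, 150.0, 50.0, 9.0),
            7: ("nearshore", True, 140.0, 70.0, 3.0),
            8: ("offshore", False, 400.0, 25.0, 34.0),
            9: ("offshore", False, 400.0, 45.0, 34.0),
            10: ("offshore", False, 450.0, 65.0, 36.0),
            11: ("offshore", False, 500.0, 85.0, 38.0),
        }
        cells = []
        for cid, (zone, coastal, area, x, y) in geom.items():
            others = sorted(
                (o for o in geom if o != cid),
                key=lambda o: (
                    math.hypot(geom[o][3] - x, geom[o][4] - y),
                    o,
                ),
            )
            cells.append(
                FeedingCell(cid, zone, coastal, area, tuple(others), x, y)
            )
        return cls(cells, strict=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict: bool = True) -> "StudyArea":
        cells = []
        for _, r in df.iterrows():
            neighbors = tuple(
                int(t) for t in str(r["neighbors"]).split(";") if t != ""
            )
            cells.append(
                FeedingCell(
                    id=int(r["id"]),
                    zone=str(r["zone"]),
                    coastal=bool(r["coastal"]),
                    area_km2=float(r["area_km2"]),
                    neighbors=neighbors,
                    x=float(r.get("x", float("nan"))),
                    y=float(r.get("y", float("nan"))),
                )
            )
        return cls(cells, strict=strict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.cells],
                "zone": [c.zone for c in self.cells],
                "coastal": [c.coastal for c in self.cells],
                "area_km2": [c.area_km2 for c in self.cells],
                "neighbors": [";".join(map(str, c.neighbors)) for c in self.cells],
                "x": [c.x for c in self.cells],
                "y": [c.y for c in self.cells],
            }
        )

    @classmethod
    def from_csv(cls, path, strict: bool = True) -> "StudyArea":
        return cls.from_frame(pd.read_csv(path), strict=strict)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return buf.getvalue()


def build_study_area(config: pd.DataFrame | None = None) -> StudyArea:
    """Build and validate the cell map from a geometry table.

    With no argument, returns the default 11-cell map.
    """
    if config is None:
        return StudyArea.default()
    return StudyArea.from_frame(config, strict=True)


# ---------------------------------------------------------------------------
# season calendar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonGrid:
    """Foraging-season calendar: 25 weeks of daily decisions in 6-h bins.

    The season opens mid-May (whales may be present from the first day) and
    runs ``n_weeks`` weeks.  Decisions in the dynamic program are daily;
    the forward simulation and the acoustic exposure series run on 6-h bins
    (four per day).  Each week belongs to one of three prey periods
    (early / mid / late), by default an equal three-way split of the season.
    """

    start_date: dt.date = dt.date(2015, 5, 15)
    n_weeks: int = 25
    bin_hours: int = 6
    week_periods: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.bin_hours != 6:
            raise ValidationError("bin_hours must be 6")
        if self.week_periods is None:
            periods = tuple(
                PERIODS[min(2, (3 * w) // self.n_weeks)]
                for w in range(self.n_weeks)
            )
            object.__setattr__(self, "week_periods", periods)
        if len(self.week_periods) != self.n_weeks:
            raise ValidationError("week_periods must have one entry per week")
        for p in self.week_periods:
            if p not in PERIODS:
                raise ValidationError(f"unknown period {p!r}")

    @property
    def n_days(self) -> int:
        return self.n_weeks * 7

    @property
    def bins_per_day(self) -> int:
        return 24 // self.bin_hours

    @property
    def bins_per_week(self) -> int:
        return 7 * self.bins_per_day

    @property
    def n_bins(self) -> int:
        return self.n_weeks * self.bins_per_week

    def _check_bin(self, b: int) -> None:
        if not 0 <= b < self.n_bins:
            raise ValidationError(f"bin {b} outside season [0, {self.n_bins})")

    def day_of_bin(self, b):
        b = np.asarray(b)
        if np.any(b < 0) or np.any(b >= self.n_bins):
            raise ValidationError("bin outside season")
        return b // self.bins_per_day

    def week_of_day(self, d):
        d = np.asarray(d)
        if np.any(d < 0) or np.any(d >= self.n_days):
            raise ValidationError("day outside season")
        return d // 7

    def week_of_bin(self, b):
        return self.week_of_day(self.day_of_bin(b))

    def period_of_week(self, w: int) -> str:
        if not 0 <= w < self.n_weeks:
            raise ValidationError(f"week {w} outside season")
        return self.week_periods[w]

    def period_of_day(self, d: int) -> str:
        return self.period_of_week(int(self.week_of_day(d)))

    def period_of_bin(self, b: int) -> str:
        return self.period_of_day(int(self.day_of_bin(b)))

    def date_of_day(self, d: int) -> dt.date:
        return self.start_date + dt.timedelta(days=int(d))

    def day_of_date(self, date: dt.date) -> int:
        return (date - self.start_date).days

    def bin_of_timestamp(self, ts) -> int:
        """Map a timestamp to its 6-h bin index; error outside the season."""
        ts = pd.Timestamp(ts)
        delta = ts - pd.Timestamp(self.start_date)
        b = int(delta.total_seconds() // (self.bin_hours * 3600))
        self._check_bin(b)
        return b


def period_of(bin_index: int, season_grid: SeasonGrid) -> str:
    """Season period (early/mid/late) of a 6-h bin."""
    return season_grid.period_of_bin(bin_index)


# ---------------------------------------------------------------------------
# prey field
# ---------------------------------------------------------------------------

def fit_prey_lognormal(samples: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood lognormal parameters per cell x period.

    Parameters
    ----------
    samples : DataFrame
        Columns ``cell``, ``period``, ``energy_MJ`` with positive energies
        (MJ per 6-h foraging bout) and at least two samples per stratum.

    Returns
    -------
    DataFrame with columns ``cell, period, mu_log, sigma_log`` where
    ``mu_log``/``sigma_log`` are the mean and population (n-denominator)
    standard deviation of the log samples.
    """
    if (samples["energy_MJ"] <= 0).any():
        bad = samples.loc[samples["energy_MJ"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive prey energy in cell {bad['cell']} period {bad['period']}"
        )
    rows = []
    for (cell, period), grp in samples.groupby(["cell", "period"], sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"cell {cell} period {period}: need >= 2 samples to fit sigma"
            )
        logs = np.log(grp["energy_MJ"].to_numpy(float))
        if logs.std(ddof=0) == 0:
            raise ValueError(
                f"cell {cell} period {period}: zero-variance samples, "
                "sigma is a single point"
            )
        rows.append(
            {
                "cell": int(cell),
                "period": str(period),
                "mu_log": float(logs.mean()),
                "sigma_log": float(logs.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def discretize_lognormal(
    mu: float, sigma: float, n_categories: int, coverage_quantile: float = 0.995
) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced discrete categories of a lognormal prey distribution.

    Category values run from the ``1 - coverage_quantile`` to the
    ``coverage_quantile`` lognormal quantile; each category receives the
    lognormal mass of the half-open interval nearest to it (midpoint edges),
    renormalized to sum to one.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if not 0.5 < coverage_quantile < 1:
        raise ValueError("coverage_quantile must be in (0.5, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 or n_categories == 1:
        centre = math.exp(mu)
        if n_categories == 1:
            return np.array([centre]), np.array([1.0])
        # degenerate distribution: still emit an (arbitrary, tiny) spread of
        # categories with all mass on the one nearest exp(mu)
        sigma = max(sigma, 1e-12)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    lo = dist.ppf(1 - coverage_quantile)
    hi = dist.ppf(coverage_quantile)
    values = np.linspace(lo, hi, n_categories)
    edges = np.concatenate(([0.0], (values[1:] + values[:-1]) / 2, [np.inf]))
    probs = np.diff(dist.cdf(edges))
    total = probs.sum()
    if total <= 0:  # numerically degenerate: all mass nearest exp(mu)
        probs = np.zeros(n_categories)
        probs[np.argmin(np.abs(values - math.exp(mu)))] = 1.0
    else:
        probs = probs / total
    return values, probs


class PreyField:
    """Lognormal prey-energy parameters and discrete categories per cell x period.

    Energies are MJ per 6-h foraging bout.
    """

    def __init__(
        self,
        params: pd.DataFrame,
        n_categories: int = 10,
        coverage_quantile: float = 0.995,
    ):
        need = {"cell", "period", "mu_log", "sigma_log"}
        if not need.issubset(params.columns):
            raise ValidationError(f"prey parameter table needs columns {sorted(need)}")
        if (params["sigma_log"] < 0).any():
            raise ValidationError("sigma_log must be >= 0")
        self.params = params.reset_index(drop=True)
        self.n_categories = int(n_categories)
        self.coverage_quantile = float(coverage_quantile)
        self._lookup = {
            (int(r.cell), str(r.period)): (float(r.mu_log), float(r.sigma_log))
            for r in params.itertuples()
        }
        self._cats: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def mu_sigma(self, cell: int, period: str) -> tuple[float, float]:
        return self._lookup[(int(cell), period)]

    def categories(self, cell: int, period: str) -> tuple[np.ndarray, np.ndarray]:
        key = (int(cell), period)
        if key not in self._cats:
            mu, sigma = self._lookup[key]
            self._cats[key] = discretize_lognormal(
                mu, sigma, self.n_categories, self.coverage_quantile
            )
        return self._cats[key]

    def category_table(self, cells, period: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (values, probs), each shaped (n_cells, K), in cell order."""
        vals = np.stack([self.categories(c, period)[0] for c in cells])
        probs = np.stack([self.categories(c, period)[1] for c in cells])
        return vals, probs

    def to_frame(self) -> pd.DataFrame:
        return self.params.copy()

    @classmethod
    def from_csv(cls, path, **kw) -> "PreyField":
        return cls(pd.read_csv(path), **kw)

    def to_csv(self, path) -> None:
        self.params.to_csv(path, index=False)


def discretize_prey(mu, sigma, n_categories, coverage_quantile=0.995):
    """Alias for :func:`discretize_lognormal` (operation name used elsewhere)."""
    return discretize_lognormal(mu, sigma, n_categories, coverage_quantile)


class CategoricalPreyField:
    """Prey field with directly specified discrete categories.

    Mainly for toy dynamic-programming instances where exact category
    values and probabilities (rather than a discretized lognormal) are
    wanted.  ``table`` maps (cell, period) -> (values, probs).
    """

    def __init__(self, table: dict, n_categories: int):
        self.n_categories = int(n_categories)
        self._table = {}
        for key, (vals, probs) in table.items():
            vals = np.asarray(vals, float)
            probs = np.asarray(probs, float)
            if len(vals) != self.n_categories or len(probs) != self.n_categories:
                raise ValidationError("category arrays must have length K")
            if abs(probs.sum() - 1.0) > 1e-12:
                raise ValidationError("category probabilities must sum to 1")
            self._table[key] = (vals, probs)

    def categories(self, cell, period):
        return self._table[(int(cell), period)]

    def category_table(self, cells, period):
        vals = np.stack([self._table[(c, period)][0] for c in cells])
        probs = np.stack([self._table[(c, period)][1] for c in cells])
        return vals, probs
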