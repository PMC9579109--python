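"""Acoustic exposure probabilities and the behavioral response rule.

Seismic-survey sound fields arrive as block-level records: the maximum
sound pressure level (SPL, dB re 1 uPa^2) over short windows within small
spatial blocks (1 km^2 nearshore, 100 km^2 offshore), each block assigned
to one feeding cell.  A block counts as disturbed within a 6-h bin when any
of its windows in that bin reaches the behavioral threshold (163 dB,
inclusive); the per-cell exposure probability for the bin is the fraction
of that cell's reporting blocks that were disturbed.  A disturbed whale
relocates to the nearest undisturbed cell (by the cell's proximity-ordered
neighbor list) and loses the 6-h foraging opportunity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habitat import SeasonGrid, StudyArea

DEFAULT_THRESHOLD_DB = 163.0


@dataclass(frozen=True)
class DisturbanceRule:
    """Behavioral response to air-gun sound at or above the threshold."""

    threshold_db: float = DEFAULT_THRESHOLD_DB
    response_probability: float = 1.0  # conservative: every exposed whale responds

    def __post_init__(self):
        if not 0 <= self.response_probability <= 1:
            raise ValueError("response probability must be in [0, 1]")


class ExposureSeries:
    """Per-cell, per-6-h-bin probability of exposure at/above the threshold."""

    def __init__(self, p: np.ndarray, area: StudyArea, season: SeasonGrid,
                 threshold_db: float = DEFAULT_THRESHOLD_DB):
        p = np.asarray(p, float)
        if p.shape != (area.n_cells, season.n_bins):
            raise ValueError(
                f"exposure array must be (n_cells, n_bins) = "
                f"({area.n_cells}, {season.n_bins}), got {p.shape}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("exposure probabilities must be in [0, 1]")
        self.p = p
        self.area = area
        self.season = season
        self.threshold_db = threshold_db

    @classmethod
    def zeros(cls, area, season, threshold_db=DEFAULT_THRESHOLD_DB):
        return cls(np.zeros((area.n_cells, season.n_bins)), area, season,
                   threshold_db)

    def to_frame(self) -> pd.DataFrame:
        cells = np.repeat(self.area.ids, self.season.n_bins)
        bins = np.tile(np.arange(self.season.n_bins), self.area.n_cells)
        return pd.DataFrame(
            {"cell": cells, "bin_index": bins, "p_exposure": self.p.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, area: StudyArea, season: SeasonGrid,
                   threshold_db=DEFAULT_THRESHOLD_DB) -> "ExposureSeries":
        p = np.zeros((area.n_cells, season.n_bins))
        idx = [area.index(c) for c in df["cell"]]
        p[idx, df["bin_index"].to_numpy(int)] = df["p_exposure"].to_numpy(float)
        return cls(p, area, season, threshold_db)


def exposure_probability(
    grid: pd.DataFrame,
    area: StudyArea,
    season: SeasonGrid,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
    aggregation: str = "any",
) -> ExposureSeries:
    """Exposure probability per cell and 6-h bin from an acoustic block grid.

    Parameters
    ----------
    grid : DataFrame
        Columns ``block_id, cell, timestamp_iso, max_spl_db`` (an
        ``area_km2`` column may be present and is ignored here).  Window
        cadence may differ between blocks.
    aggregation : {"any", "fraction"}
        "any": a block is disturbed in a bin if any window reaches the
        threshold (default).  "fraction": a block contributes the fraction
        of its windows at/above the threshold.

    Cells or bins without any reporting block get probability zero.
    """
    if aggregation not in ("any", "fraction"):
        raise ValueError("aggregation must be 'any' or 'fraction'")
    p = np.zeros((area.n_cells, season.n_bins))
    if len(grid) == 0:
        return ExposureSeries(p, area, season, threshold_db)
    known = set(area.ids)
    bad = set(grid["cell"].unique()) - known
    if bad:
        raise ValueError(f"acoustic block(s) mapped to unknown cell(s) {sorted(bad)}")
    if not np.isfinite(grid["max_spl_db"].to_numpy(float)).all():
        raise ValueError("non-finite SPL in acoustic grid")
    df = grid.copy()
    df["bin"] = [season.bin_of_timestamp(t) for t in df["timestamp_iso"]]
    df["hit"] = (df["max_spl_db"] >= threshold_db)
    if aggregation == "any":
        per_block = df.groupby(["cell", "bin", "block_id"])["hit"].any()
    else:
        per_block = df.groupby(["cell", "bin", "block_id"])["hit"].mean()
    frac = per_block.groupby(["cell", "bin"]).mean()
    for (cell, b), val in frac.items():
        p[area.index(int(cell)), int(b)] = val
    return ExposureSeries(p, area, season, threshold_db)


def nearest_undisturbed(area: StudyArea, current_cell: int,
                        exposure_at_bin: np.ndarray) -> int:
    """Destination cell for a disturbed whale.

    First cell in the current cell's proximity-ordered neighbor list with
    zero exposure this bin; if every cell is exposed, the cell with minimal
    exposure, ties broken by neighbor order.
    """
    neighbors = area.cell(current_cell).neighbors
    for n in neighbors:
        if exposure_at_bin[area.index(n)] == 0.0:
            return n
    best = min(neighbors, key=lambda n: (exposure_at_bin[area.index(n)],
                                         neighbors.index(n)))
    return best


def apply_disturbance(state, rule: DisturbanceRule, exposure: ExposureSeries,
                      bin_index: int, rng: np.random.Generator,
                      bio=None):
    """Single-female disturbance draw (scalar operation).

    With probability ``p_exposure(cell, bin) * response_probability`` the
    whale relocates to the nearest undisturbed cell, pays the inter-cell
    travel cost from fat, and takes zero intake this bin.  Returns
    ``(state, disturbed)``.
    """
    from dataclasses import replace

    from .bioenergetics import BioenergeticParams

    if state.status != "alive" or state.location is None:
        raise ValueError("apply_disturbance requires an alive, in-area female")
    bio = bio or BioenergeticParams()
    p = exposure.p[exposure.area.index(state.location), bin_index]
    if rng.uniform() >= p * rule.response_probability:
        return state, False
    dest = nearest_undisturbed(exposure.area, state.location,
                               exposure.p[:, bin_index])
    dfat = bio.travel_cost_inter_MJ() / bio.catabolic_yield_MJ_per_kg
    new_fat = max(state.fat_kg - dfat, 0.0)
    status = "alive" if new_fat >= bio.fat_floor(state.length_m) else "dead"
    return replace(state, location=dest if status == "alive" else None,
                   fat_kg=new_fat, status=status), True
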