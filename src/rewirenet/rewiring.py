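"""Grid-cell rewiring potential and bivariate mapping classes.

The rewiring potential of a trophic level in a grid cell is the
standardized functional richness of the pooled metanetwork partners of
every focal-level species present in the cell: how much of the partner
trait space the local community could draw on when interactions have to
re-form.  Partners are taken from the metanetwork regardless of their
own local occurrence (the fundamental, not realised, pool); a
``local_partners`` switch restricts the pool for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CONSUMER, LEVELS, RESOURCE, OccurrenceGrid
from .metaweb import BinaryMetanetwork
from .traitspace import TraitSpace, fric_standardized


def local_community(grid: OccurrenceGrid, cell_id: str, level: str) -> set:
    """Species of one trophic level present in a cell (possibly empty)."""
    return grid.species_at(cell_id, level)


def partner_pool(
    community: set,
    network: BinaryMetanetwork,
    level: str,
    local_partners: set | None = None,
) -> set:
    """Union of metanetwork partner sets over a focal-level community."""
    pool: set = set()
    for sp in community:
        pool |= network.partners_of(sp, level)
    if local_partners is not None:
        pool &= local_partners
    return pool


@dataclass
class PotentialResult:
    potential: float  # NaN for an empty community
    richness: int
    partner_pool_size: int
    degenerate: bool
    empty: bool


def rewiring_potential(
    cell_id: str,
    level: str,
    grid: OccurrenceGrid,
    network: BinaryMetanetwork,
    partner_space: TraitSpace,
    local_partners: bool = False,
) -> PotentialResult:
    """Rewiring potential of one trophic level in one grid cell.

    Empty communities map to NaN (no species is different from species
    with no functional spread); partner pools too small to span the
    trait space score 0 and are flagged degenerate.
    """
    community = local_community(grid, cell_id, level)
    if not community:
        return PotentialResult(float("nan"), 0, 0, False, True)
    restriction = None
    if local_partners:
        other = CONSUMER if level == RESOURCE else RESOURCE
        restriction = local_community(grid, cell_id, other)
    pool = partner_pool(community, network, level, restriction)
    if not pool:
        return PotentialResult(0.0, len(community), 0, True, False)
    res = fric_standardized(sorted(pool), partner_space)
    return PotentialResult(res.value, len(community), len(pool), res.degenerate, False)


def potential_map(
    grid: OccurrenceGrid,
    network: BinaryMetanetwork,
    spaces: dict,
    local_partners: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Rewiring potential and richness for every cell and trophic level.

    ``spaces`` maps each focal level to the *partner* level's trait
    space (the geometry its potential is measured in).  Returns one row
    per (cell, level) with the bivariate potential x richness class, and
    a per-level summary with the fraction of non-NA cells above 0.8.
    """
    rows = []
    for level in LEVELS:
        for cid in grid.cell_ids:
            r = rewiring_potential(cid, level, grid, network, spaces[level], local_partners)
            cell = grid.cells.loc[cid]
            rows.append(
                (cid, cell.lon_min, cell.lat_min, level, r.richness,
                 r.partner_pool_size, r.potential, r.degenerate, r.empty)
            )
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "lon_min", "lat_min", "trophic_level", "richness",
                 "partner_pool_size", "potential", "degenerate", "empty"],
    )
    df["bivariate_class"] = np.nan
    summary = {}
    for level in LEVELS:
        mask = df.trophic_level == level
        sub = df[mask]
        classes = bivariate_classes(
            sub.potential.to_numpy(),
            sub.richness.to_numpy(dtype=float).copy(),
        )
        df.loc[mask, "bivariate_class"] = classes
        valid = sub.potential.dropna()
        summary[level] = {
            "n_cells": int(mask.sum()),
            "n_na": int(sub.potential.isna().sum()),
            "frac_potential_gt_0.8": float((valid > 0.8).mean()) if len(valid) else float("nan"),
        }
    return df, summary


def _tercile(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bins 1..n_bins over non-NA values; ties go to the lower bin."""
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    if not ok.any():
        return out
    qs = np.quantile(values[ok], np.arange(1, n_bins) / n_bins)
    bins = np.ones(ok.sum())
    for q in qs:
        bins += values[ok] > q  # strict: values equal to a break stay low
    out[ok] = bins
    return out


def bivariate_classes(
    potential: np.ndarray, richness: np.ndarray, n_bins: int = 3
) -> np.ndarray:
    """Joint quantile classes for co-mapping potential against richness.

    ``class = n_bins * (richness_bin - 1) + potential_bin`` with bins
    1..n_bins from quantile breaks over non-NA cells; an NA in either
    input propagates to the class.
    """
    potential = np.asarray(potential, dtype=float)
    richness = np.asarray(richness, dtype=float)
    if potential.shape != richness.shape:
        raise ValueError("potential and richness must be aligned")
    na = np.isnan(potential) | np.isnan(richness)
    p, r = potential.copy(), richness.copy()
    p[na] = np.nan
    r[na] = np.nan
    pb = _tercile(p, n_bins)
    rb = _tercile(r, n_bins)
    return n_bins * (rb - 1) + pb
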