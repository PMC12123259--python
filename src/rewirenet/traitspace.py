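"""Functional interaction niche geometry.

The functional-richness (FRic) construction used throughout: mixed
numeric/categorical traits -> Gower dissimilarity -> square-root
correction -> principal coordinates (PCoA) -> convex-hull volume on the
retained axes, standardised against the hull of all species at the
trophic level so a niche of 1 spans the entire partner trait space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .dataio import TraitTable

#: an eigenvalue counts as positive if above this fraction of the largest
EIG_TOL = 1e-10


class DegenerateSpaceError(ValueError):
    """All traits constant: no dissimilarity structure to ordinate."""


@dataclass
class DistanceMatrix:
    """Symmetric species dissimilarities (Gower output lies in [0, 1])."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
        if v.min() < -1e-12:
            raise ValueError("dissimilarities must be non-negative")


@dataclass
class TraitSpace:
    """PCoA embedding of one trophic level's trait dissimilarities.

    ``coordinates`` is species x m with axes scaled by sqrt(eigenvalue),
    so Euclidean distances in the space approximate the (square-root
    corrected) input dissimilarities.
    """

    ids: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray  # all eigenvalues, descending
    m: int
    sqrt_corrected: bool = True
    traits_used: tuple = ()

    def points(self, member_ids: Sequence) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.ids)}
        try:
            rows = [index[s] for s in member_ids]
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not in trait space") from exc
        return self.coordinates[rows]


@dataclass
class FricResult:
    value: float  # standardized, in [0, 1]
    raw: float  # hull volume before standardization
    degenerate: bool


def gower_matrix(table: TraitTable, trait_subset: Sequence[str] | None = None) -> DistanceMatrix:
    """Gower dissimilarity over a mixed numeric/categorical trait subset.

    Numeric traits contribute ``|x - y| / range``; categoricals contribute
    ``1[x != y]``; the unweighted mean over traits is returned.  Constant
    numeric traits have an undefined Gower term and are dropped with a
    warning; if every trait is constant a :class:`DegenerateSpaceError`
    is raised.
    """
    traits = list(trait_subset) if trait_subset is not None else table.trait_names
    for t in traits:
        if t not in table.schema:
            raise KeyError(f"trait {t!r} not declared for this table")
    n = len(table.data)
    if n < 2:
        raise ValueError("need at least two species")
    parts = []
    for t in traits:
        col = table.data[t]
        if table.schema[t]["kind"] == "numeric":
            x = col.to_numpy(dtype=float)
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                warnings.warn(f"dropping constant trait {t!r} (zero range)", stacklevel=2)
                continue
            parts.append(np.abs(x[:, None] - x[None, :]) / rng)
        else:
            x = col.to_numpy()
            parts.append((x[:, None] != x[None, :]).astype(float))
    if not parts:
        raise DegenerateSpaceError("all traits constant; Gower distance undefined")
    d = np.mean(parts, axis=0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.data.index), d)


def pcoa(d: DistanceMatrix, m_max: int = 4, sqrt_correct: bool = True) -> TraitSpace:
    """Principal coordinates of a dissimilarity matrix.

    With ``sqrt_correct`` (the default, appropriate for Gower input) the
    square roots of the dissimilarities are embedded, which makes
    metric Gower matrices Euclidean and suppresses negative eigenvalues.
    Keeps ``min(m_max, #positive eigenvalues)`` axes, coordinates scaled
    by the square root of each eigenvalue.
    """
    dm = np.sqrt(d.values) if sqrt_correct else d.values
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = EIG_TOL * max(vals.max(), 0) if vals.size else 0.0
    n_pos = int(np.sum(vals > tol))
    if n_pos == 0:
        raise DegenerateSpaceError("no positive eigenvalues; degenerate dissimilarities")
    neg_mass = -vals[vals < 0].sum()
    if neg_mass > 0.05 * np.abs(vals).sum():
        warnings.warn(
            f"negative eigenvalue mass {neg_mass / np.abs(vals).sum():.1%} of total; "
            "axes truncated to the positive part",
            stacklevel=2,
        )
    m = min(m_max, n_pos)
    coords = vecs[:, :m] * np.sqrt(vals[:m])
    return TraitSpace(list(d.ids), coords, vals, m, sqrt_corrected=sqrt_correct)


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull (hyper)volume of an n x m point set.

    Returns the range (max - min) for m = 1 and 0.0 for degenerate sets
    (fewer than m + 1 points, or affinely dependent points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, m = pts.shape
    if n < 2:
        return 0.0
    if m == 1:
        return float(pts.max() - pts.min())
    if n < m + 1:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0  # affinely dependent (flat) point set


def fric_standardized(
    member_ids: Sequence,
    space: TraitSpace,
    global_ids: Sequence | None = None,
) -> FricResult:
    """Standardized functional richness of a species subset.

    Hull volume of the members divided by the hull volume of
    ``global_ids`` (defaults to every species in the space) on the same
    axes.  Member sets that cannot span an m-dimensional hull
    (``len(members) <= m`` or affinely dependent) are degenerate and
    score 0 by convention, keeping all values on one m-dimensional scale.
    """
    global_ids = list(global_ids) if global_ids is not None else list(space.ids)
    gset = set(global_ids)
    for s in member_ids:
        if s not in gset:
            raise KeyError(f"member {s!r} not among the global species")
    denom = hull_volume(space.points(global_ids))
    if denom <= 0:
        raise DegenerateSpaceError("global species set has zero hull volume")
    if len(member_ids) <= space.m:
        return FricResult(0.0, 0.0, True)
    raw = hull_volume(space.points(member_ids))
    if raw == 0.0:
        return FricResult(0.0, 0.0, True)
    return FricResult(min(raw / denom, 1.0), raw, False)


def build_trait_space(table: TraitTable, trait_subset: Sequence[str] | None = None,
                      m_max: int = 4) -> TraitSpace:
    """Gower -> sqrt correction -> PCoA in one call (the standard route)."""
    space = pcoa(gower_matrix(table, trait_subset), m_max=m_max)
    space.traits_used = tuple(trait_subset) if trait_subset is not None else tuple(table.trait_names)
    return space
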