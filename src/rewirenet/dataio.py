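"""Tabular I/O, training-set assembly and trait imputation.

All on-disk formats are plain UTF-8 CSV with a mandatory header row; the
empty string encodes a missing value.  Trait tables carry a sidecar JSON
schema declaring every column as ``numeric`` (with units) or
``categorical`` (with a finite level set); readers validate against the
schema and reject rather than coerce malformed input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RESOURCE = "resource"
CONSUMER = "consumer"
LEVELS = (RESOURCE, CONSUMER)

#: reserved (non-trait) columns of a traits CSV
ID_COLUMNS = ("species_id", "trophic_level", "taxon_group")


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


class DataError(ValueError):
    """Internally inconsistent data (dangling ids, edges outside sites...)."""


class ImputationError(ValueError):
    """A trait cannot be imputed (e.g. no observed value at all)."""


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species-by-trait table for one trophic level.

    Parameters
    ----------
    data
        DataFrame indexed by ``species_id`` with a ``taxon_group`` column
        plus one column per declared trait.
    trophic_level
        ``"resource"`` or ``"consumer"``.
    schema
        Mapping trait name -> ``{"kind": "numeric", "units": str}`` or
        ``{"kind": "categorical", "levels": [..]}``.
    imputed
        Optional boolean mask (same shape as the trait columns) flagging
        cells filled by :func:`impute_traits`.
    """

    data: pd.DataFrame
    trophic_level: str
    schema: dict
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.trophic_level not in LEVELS:
            raise SchemaError(f"unknown trophic level {self.trophic_level!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise SchemaError(f"duplicate species_id {dup!r}")
        if "taxon_group" not in self.data.columns:
            raise SchemaError("missing taxon_group column")
        for col in self.trait_names:
            if col not in self.data.columns:
                raise SchemaError(f"trait {col!r} declared but absent from table")
        extra = set(self.data.columns) - set(self.trait_names) - {"taxon_group"}
        if extra:
            raise SchemaError(f"undeclared column(s): {sorted(extra)}")
        self._validate_values()

    def _validate_values(self) -> None:
        for name, spec in self.schema.items():
            col = self.data[name]
            if spec["kind"] == "numeric":
                bad = col.dropna().map(lambda v: not isinstance(v, (int, float, np.floating, np.integer)))
                if bad.any():
                    row = bad[bad].index[0]
                    raise SchemaError(f"non-numeric value in column {name!r}, species {row!r}")
            elif spec["kind"] == "categorical":
                levels = set(spec["levels"])
                bad = col.dropna().map(lambda v: v not in levels)
                if bad.any():
                    row = bad[bad].index[0]
                    raise SchemaError(
                        f"value {col[row]!r} outside declared levels of {name!r} (species {row!r})"
                    )
            else:
                raise SchemaError(f"unknown trait kind {spec['kind']!r} for {name!r}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.schema)

    def numeric_traits(self) -> list[str]:
        return [t for t, s in self.schema.items() if s["kind"] == "numeric"]

    def categorical_traits(self) -> list[str]:
        return [t for t, s in self.schema.items() if s["kind"] == "categorical"]

    def __eq__(self, other: object) -> bool:  # round-trip friendly
        if not isinstance(other, TraitTable):
            return NotImplemented
        return (
            self.trophic_level == other.trophic_level
            and self.schema == other.schema
            and self.data.equals(other.data)
        )


def write_traits(table: TraitTable, path: str | Path, schema_path: str | Path | None = None) -> None:
    """Write a trait table as CSV plus sidecar JSON schema (``<path>.schema.json``)."""
    path = Path(path)
    out = table.data.copy()
    out.insert(0, "trophic_level", table.trophic_level)
    out.index.name = "species_id"
    out.reset_index().to_csv(path, index=False)
    spath = Path(schema_path) if schema_path else path.with_suffix(path.suffix + ".schema.json")
    spath.write_text(json.dumps(table.schema, indent=1))


def read_traits(path: str | Path, schema: dict | str | Path | None = None) -> TraitTable:
    """Read a traits CSV validated against its schema.

    ``schema`` may be a mapping or a path to the sidecar JSON; by default
    the sidecar written by :func:`write_traits` is looked up next to
    ``path``.
    """
    path = Path(path)
    if schema is None:
        schema = path.with_suffix(path.suffix + ".schema.json")
    if not isinstance(schema, Mapping):
        schema = json.loads(Path(schema).read_text())
    df = pd.read_csv(path, dtype={"species_id": str, "taxon_group": str})
    if "species_id" not in df.columns or "trophic_level" not in df.columns:
        raise SchemaError("traits CSV must have species_id and trophic_level columns")
    levels = df["trophic_level"].unique()
    if len(levels) != 1:
        raise SchemaError(f"mixed trophic levels in one file: {sorted(levels)}")
    for name, spec in schema.items():
        if name not in df.columns:
            raise SchemaError(f"trait {name!r} declared but absent from {path.name}")
        if spec["kind"] == "numeric":
            try:
                df[name] = pd.to_numeric(df[name])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"non-numeric value in column {name!r}: {exc}") from exc
    df = df.set_index("species_id")
    return TraitTable(df.drop(columns="trophic_level"), str(levels[0]), dict(schema))


def impute_traits(table: TraitTable) -> TraitTable:
    """Fill missing trait values from the taxon group, with a global fallback.

    Numeric traits take the group mean, categorical traits the group mode
    (ties broken by the lexicographically smallest level).  A cell-level
    boolean mask of what was imputed is attached as ``table.imputed``.
    Raises :class:`ImputationError` if a trait has no observed value at all.
    """
    data = table.data.copy()
    flags = pd.DataFrame(False, index=data.index, columns=table.trait_names)
    for name, spec in table.schema.items():
        col = data[name]
        missing = col.isna()
        if not missing.any():
            continue
        if missing.all():
            raise ImputationError(f"trait {name!r} has no observed values")
        numeric = spec["kind"] == "numeric"

        def _fill(series: pd.Series) -> object:
            obs = series.dropna()
            if obs.empty:
                return np.nan
            if numeric:
                return obs.mean()
            counts = obs.value_counts()
            top = counts[counts == counts.max()]
            return sorted(top.index)[0]

        group_fill = data.groupby("taxon_group")[name].transform(lambda s: s.fillna(_fill(s)))
        global_value = _fill(col)
        data[name] = group_fill.fillna(global_value)
        flags[name] = missing
    return TraitTable(data, table.trophic_level, dict(table.schema), imputed=flags)


# ---------------------------------------------------------------------------
# site networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteNetwork:
    """One locality: its species lists and the observed binary interactions."""

    site_id: str
    lon: float
    lat: float
    resource_ids: frozenset
    consumer_ids: frozenset
    edges: frozenset  # of (resource_id, consumer_id)

    def __post_init__(self) -> None:
        for r, c in self.edges:
            if r not in self.resource_ids or c not in self.consumer_ids:
                raise DataError(
                    f"site {self.site_id!r}: edge ({r!r}, {c!r}) references a species "
                    "absent from the site's species lists"
                )


def write_networks(networks: Sequence[SiteNetwork], occ_path: str | Path, edge_path: str | Path) -> None:
    """Write site networks as an occurrence CSV and an edge CSV."""
    occ_rows, edge_rows = [], []
    for net in networks:
        for level, ids in ((RESOURCE, net.resource_ids), (CONSUMER, net.consumer_ids)):
            for sp in sorted(ids):
                occ_rows.append((net.site_id, sp, level, net.lon, net.lat))
        for r, c in sorted(net.edges):
            edge_rows.append((net.site_id, r, c))
    pd.DataFrame(occ_rows, columns=["site_id", "species_id", "trophic_level", "lon", "lat"]).to_csv(
        occ_path, index=False
    )
    pd.DataFrame(edge_rows, columns=["site_id", "resource_id", "consumer_id"]).to_csv(
        edge_path, index=False
    )


def read_networks(occ_path: str | Path, edge_path: str | Path) -> list[SiteNetwork]:
    occ = pd.read_csv(occ_path, dtype={"site_id": str, "species_id": str})
    edges = pd.read_csv(edge_path, dtype=str)
    nets = []
    edge_groups = dict(tuple(edges.groupby("site_id"))) if len(edges) else {}
    for site_id, g in occ.groupby("site_id", sort=True):
        res = frozenset(g.loc[g.trophic_level == RESOURCE, "species_id"])
        con = frozenset(g.loc[g.trophic_level == CONSUMER, "species_id"])
        e = edge_groups.get(site_id)
        pairs = frozenset(zip(e.resource_id, e.consumer_id)) if e is not None else frozenset()
        nets.append(SiteNetwork(site_id, float(g.lon.iloc[0]), float(g.lat.iloc[0]), res, con, pairs))
    return nets


def assemble_training_pairs(networks: Iterable[SiteNetwork]) -> pd.DataFrame:
    """Pool site networks into pair-level presence/absence training rows.

    A species pair gets label 1 if it was observed interacting in at least
    one site and label 0 if it co-occurred in at least one site but was
    never observed interacting anywhere (an inferred absence).  Pairs that
    never co-occur are excluded: nothing was observable about them.

    Returns a DataFrame with columns ``resource_id, consumer_id, label``,
    one row per distinct co-occurring pair.
    """
    observed: set[tuple] = set()
    cooccurring: set[tuple] = set()
    for net in networks:
        cooccurring.update((r, c) for r in net.resource_ids for c in net.consumer_ids)
        observed.update(net.edges)
    dangling = observed - cooccurring
    if dangling:  # SiteNetwork already guards this; double bookkeeping guard
        raise DataError(f"edges without co-occurrence: {sorted(dangling)[:3]}")
    rows = [(r, c, 1 if (r, c) in observed else 0) for r, c in sorted(cooccurring)]
    return pd.DataFrame(rows, columns=["resource_id", "consumer_id", "label"])


# ---------------------------------------------------------------------------
# occurrence grid
# ---------------------------------------------------------------------------

def cell_id_of(lon_min: float, lat_min: float) -> str:
    return f"{lon_min:g}_{lat_min:g}"


@dataclass
class OccurrenceGrid:
    """Species presence on a regular lon/lat grid.

    Cells are half-open squares ``[lon, lon + size) x [lat, lat + size)``
    identified by their lower-left corner.  ``presence`` holds one boolean
    species-by-cell DataFrame per trophic level (rows: species ids,
    columns: cell ids).
    """

    cells: pd.DataFrame  # columns cell_id, lon_min, lat_min; one row per cell
    cell_size: float
    presence: dict  # level -> DataFrame(bool)

    def __post_init__(self) -> None:
        self.cells = self.cells.set_index("cell_id", drop=False) if "cell_id" in self.cells.columns else self.cells
        for level in self.presence:
            if level not in LEVELS:
                raise DataError(f"unknown trophic level {level!r}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells["cell_id"])

    def centroid(self, cell_id: str) -> tuple[float, float]:
        row = self.cells.loc[cell_id]
        half = self.cell_size / 2.0
        return float(row.lon_min) + half, float(row.lat_min) + half

    def species_at(self, cell_id: str, level: str) -> set:
        if cell_id not in self.cells.index:
            raise KeyError(f"unknown cell {cell_id!r}")
        pres = self.presence[level]
        return set(pres.index[pres[cell_id]])

    def richness(self, level: str) -> pd.Series:
        return self.presence[level].sum(axis=0)


def write_occurrences(grid: OccurrenceGrid, path: str | Path) -> None:
    rows = []
    for level, pres in grid.presence.items():
        sp_idx, cell_idx = np.nonzero(pres.to_numpy())
        for i, j in zip(sp_idx, cell_idx):
            cid = pres.columns[j]
            cell = grid.cells.loc[cid]
            rows.append((cid, cell.lon_min, cell.lat_min, pres.index[i], level))
    pd.DataFrame(rows, columns=["cell_id", "lon_min", "lat_min", "species_id", "trophic_level"]).to_csv(
        path, index=False
    )


def read_occurrences(path: str | Path, cell_size: float = 0.5) -> OccurrenceGrid:
    df = pd.read_csv(path, dtype={"cell_id": str, "species_id": str})
    cells = (
        df[["cell_id", "lon_min", "lat_min"]]
        .drop_duplicates("cell_id")
        .sort_values(["lon_min", "lat_min"])
        .reset_index(drop=True)
    )
    presence = {}
    for level, g in df.groupby("trophic_level"):
        sp = sorted(g.species_id.unique())
        mat = pd.DataFrame(False, index=sp, columns=list(cells.cell_id))
        for _, row in g.iterrows():
            mat.loc[row.species_id, row.cell_id] = True
        presence[level] = mat
    for level in LEVELS:
        presence.setdefault(level, pd.DataFrame(index=[], columns=list(cells.cell_id), dtype=bool))
    return OccurrenceGrid(cells, cell_size, presence)
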